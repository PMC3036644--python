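# igs — evolution of the ribosomal DNA intergenic spacer

Tools and analyses for studying concerted evolution in the ribosomal
intergenic spacer (IGS), the region between the 28S and 18S rRNA genes
that carries interleaved arrays of regulatory repeats (types A/B/C in
the *Daphnia pulex* complex, the system this package models). Because
unequal crossing over and gene conversion continually duplicate,
delete, and homogenize repeat copies, the IGS records a tug-of-war
between mutation, recombination, and constraint. The package asks the
field's standard questions of it:

* **Array structure** — where are the repeat units, how many copies of
  each type does each spacer carry? (windowed self-comparison +
  Waterman–Eggert k-best local self-alignments + boundary snapping)
* **Divergence structure** — are paralogous repeats within an array
  more similar than orthologous repeats in other species (concerted
  evolution), or do copies cluster by array position? (per-type
  consensus condensation, progressive alignment, indel-aware
  p-distances under pairwise deletion, NJ dendrograms, and the
  intra/interspecific ratio x/y; under concerted evolution x/y < 1)
* **Variance partitioning** — how much variation lies among species,
  among individuals, within individuals? (AMOVA from pairwise
  difference counts, permutation significance)
* **Recombination** — where do breakpoints fall along the spacer
  (segment-wise NJ+JC69 fits, exact dynamic-programming placement,
  AICc model selection), and which sequence pairs share conversion
  tracts (Sawyer-style inner/outer fragment runs over polymorphic
  sites with permutation p-values)?
* **Ground truth** — a forward simulator of IGS evolution (mutation,
  conversion with geometric tracts, unequal crossover, indels,
  scheduled introgression) emits FASTA plus an event log whose replay
  reproduces the sequences exactly, so every stage above is testable
  without any downloads.

The distance core uses uncorrected p-distances with a conservative
indel encoding: the first position of each alignment gap run becomes a
state unique to that column, the rest of the run is missing data — so
a shared deletion is a match, and an indel of any length contributes
exactly one potential difference.

## Worked example

The analysis drivers run the whole study on a simulated 13-sequence
cohort (4 species, 10 individuals, two of them carrying introgressed
spacers — the sampling design of the motivating study):

```bash
python analysis/01_simulate_cohort.py      # 13 IGS records + truth log
python analysis/02_dissect_repeats.py      # repeat-unit annotations
python analysis/03_condense_align.py       # condensed alignment + encoding
python analysis/04_distances_trees.py      # p-distances, NJ trees, summaries
python analysis/05_amova.py                # variance partitioning
python analysis/06_recombination.py        # breakpoint scan + segment profile
python analysis/07_gene_conversion.py      # conversion-tract screen
python analysis/08_regimes.py              # regime discrimination rates
```

Outputs land under `results/`. On the default seed, step 04 prints

```
complete_IGS: OAM 0.0336, intra 0.0321, inter 0.0342, ratio 0.94
N1: OAM 0.0314, intra 0.0274, inter 0.0329, ratio 0.832
N2: OAM 0.0249, intra 0.0249, inter 0.0249, ratio 1.001
repeat A: 43 copies, within-cluster 0.033, between-cluster 0.141
```

— the study's fingerprint: intraspecific divergence nearly as high as
interspecific (ratio ≈ 0.9, the hybrids blur the species signal), and
repeat copies far more similar within their NJ clusters (array
positions) than between them. Step 05 prints the AMOVA analogue
(`entire_IGS: among-species 22.6% (p=0.0469)`; repeat types put >100%
of variation within individuals with negative higher-level
components), step 06 places breakpoints flanking the repeat region
(`selected K=2 breakpoints at 1-based columns [576, 1037]`), and step
07 recovers the planted interspecific conversion tracts in N2
(`inner Dpc2 x Dten, columns 1066-1565, global p = 0.016`).

The library surface mirrors the drivers (`igs.dissect`,
`igs.condense_igs`, `igs.progressive_align`, `igs.encode_gap_events`,
`igs.pdistance_matrix`, `igs.build_nj`, `igs.amova`,
`igs.breakpoint_search`, `igs.inner_fragments`, `igs.simulate_igs`,
...), and a thin CLI wraps it: `igs simulate`, `igs dissect`,
`igs condense`, `igs align`, `igs distances`, `igs njtree`,
`igs profile`, `igs amova`, `igs breakscan`, `igs geneconv`,
`igs partition`.

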