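# Methods

This package analyzes the evolution of the ribosomal DNA intergenic
spacer (IGS) — the region between the 28S and 18S rRNA genes that
carries interleaved arrays of regulatory repeats — and provides a
forward simulator of the processes that shape it: point mutation, gene
conversion between repeat copies, unequal crossing over, indels in the
nonrepetitive regions, and interspecific introgression. The pipeline
is the classical one for this problem: dissect each spacer's repeat
array, condense it to one consensus per repeat type, align the
condensed spacers, and quantify homogenization and recombination with
p-distance/NJ summaries, AMOVA, breakpoint scanning, and a
gene-conversion screen. This note records the models, the parameter
choices, and the places where the design was genuinely open.

## Sequence model and coordinates

An IGS record is an uppercase DNA string over {A,C,G,T,N} partitioned
into N1 (nonrepetitive, downstream of 28S), R (the repeat arrays), and
N2 (nonrepetitive, containing the ETS and core promoter, upstream of
18S). All coordinates are 0-based half-open internally; every report,
log, and serialized file is 1-based inclusive. N is accepted on input
but is conservative everywhere: it matches nothing in anchor scans and
dot plots, and it is missing data in distances and likelihoods.

Flank location uses an ungapped Hamming scan of two short conserved
anchors (the PCR-primer regions at the 3' end of 28S and the 5' end of
18S), best match wins, at most 3 mismatches by default. Ties go to the
earliest position for the 28S anchor and the latest for the 18S
anchor, since those genes bound the spacer from the left and right.

## Repeat dissection

Repetitive structure is detected twice, with different instruments:

* a windowed self-comparison (dot plot): window 25, threshold 40 under
  the +5/−4 DNA scoring, i.e. at least 16 matches in 25. Under this
  rule uniform-random sequence still produces a thin scatter of hits
  (the Bin(25, ¼) tail is ~3.5e−5 per window pair, which over the
  ~5e5 pairs of a 1-kb sequence means ~17 expected hits); repetitive
  regions stand out as long *runs* along off-diagonals, which is what
  `offset_runs` summarizes.
* the k best mutually non-overlapping local self-alignments
  (Waterman–Eggert declumping, k = 25 by default), Smith–Waterman with
  match +5, mismatch −4, gap open −12, gap extend −4 (a length-L gap
  costs 12 + 4(L−1)). Only the strict upper triangle of the DP matrix
  is searched, which removes the trivial identity alignment and mirror
  duplicates. The row fill is vectorized; the in-row affine gap state
  is computed with a running-maximum scan, exact whenever gap-open ≥
  gap-extend (a gap immediately following a gap is then dominated by
  the single merged gap).

Unit boundaries come from the self-alignments. Each alignment is
decomposed into its gap-free diagonal runs; each run is an offset map
pairing two homologous stretches. Run ends are snapped to the point
where sustained identity begins (10-nt window, 80% identity), because
local alignments over- or under-extend by a few nucleotides at repeat
junctions. The snapped endpoints witness boundaries; boundaries are
then propagated through every offset map to a fixpoint, clustered with
a 5-nt tolerance (cluster representative: median, ties toward the
earlier coordinate), and consecutive representatives delimit units.
Fragments shorter than 30 nt are absorbed into their neighbor.

**Stated limitation.** Self-similarity cannot expose a boundary that no
alignment endpoint ever lands on. In a strictly alternating block
(ABABAB...) every self-alignment offset is a multiple of |A|+|B|, so
the interior A|B junction is invisible — the dissection returns the
"AB" super-unit. Likewise the far edge of a type that occurs only once
(no partner to align against) cannot be delimited. In the original
workflow this information was supplied by manual inspection of
cross-individual alignments; the automated dissection recovers every
boundary that self-similarity determines, and the downstream
condensation is robust to the residual merging (condensing an "AB"
super-unit yields the same condensed sequence content as condensing A
and B separately; on the synthetic cohort the condensed-alignment
statistics computed from automated annotations agree with those from
true annotations to ~0.005 in the intra/inter ratio).

Family labels (A, B, C, ...) are assigned by single-linkage clustering
of unit sequences at 70% identity (identity = 1 − edit distance /
longer length), labelled in order of first occurrence along the array.
The 0.70 threshold sits between within-family divergence (≤ ~0.2) and
between-family similarity (~0.5 for unrelated DNA under this measure).

## Condensation and alignment

All copies of each repeat type within one IGS are aligned and
collapsed to a majority consensus (ties resolved to the base of the
earliest copy in array order; majority-gap columns dropped), and the
array is replaced by one consensus per type in order of first
occurrence: condensed = N1 + cons(A) + cons(B) + ... + N2. This makes
spacers with different copy numbers alignable. Condensation is
idempotent and the provenance map retains the source unit intervals.

Condensed spacers are aligned progressively: an NJ guide tree on k-mer
distances (k = 6, distance = 1 − shared-k-mer fraction), then
profile–profile merges bottom-up with affine-gap global DP (match +5,
mismatch −4, gap open −10, gap extend −0.5; column score = average
pairwise substitution score with existing gaps contributing zero).
Input order is canonicalized by sorting ids. The pairwise case equals
the exhaustive affine DP optimum (tested against a plain-loop oracle);
no claim is made that the multiple alignment reproduces any particular
hand-adjusted alignment.

**Indel encoding.** To let indels contribute conservatively to
divergence, the first position of each maximal gap run is replaced by
a state unique to that alignment column, and the remaining gap
positions (and N) become missing data. Keying the state by *column*
means rows whose deletion opens at the same column share the state:
shared indels count as matches, a gap of any length contributes
exactly one potential difference, and the encoding is a pure function
of the alignment (nothing extra to serialize; a printable-symbol view
with a column→symbol sidecar is provided for interchange). The
alternative reading — a state unique per row — would make shared
indels count as differences; the column reading is the conservative
one and is used throughout.

## Distances, trees, and summaries

p-distance is the proportion of differing sites among pairwise-compared
sites (pairwise deletion; encoded gap events are ordinary states).
Neighbor joining follows Saitou & Nei with two determinism rules:
agglomeration ties break on the lexicographically smallest pair of
subtree labels, and negative branch-length estimates are clamped to
zero with the deficit moved to the sister branch. NJ on any additive
matrix returns the generating tree exactly (property-tested against a
path-length oracle, and cross-checked against scikit-bio's
implementation on perturbed matrices).

Repeat-copy summaries report mean p-distance within and between
clusters, where clusters are obtained by cutting the n−1 longest
internal edges of the repeat NJ tree (the cluster count is supplied by
the caller; the analysis drivers use the modal per-array copy number).
Segment summaries report, per alignment slice, the overall mean (OAM),
mean intraspecific (MIA, x) and mean interspecific (MIR, y)
p-distance and the ratio x/y, printed to 3 decimals. Under concerted
evolution x/y falls below 1 and decreases with divergence time; under
shared constraint it stays near 1. The standard error attached to OAM
is the analytical binomial approximation sqrt(p(1−p)/L̄) with L̄ the
mean number of compared sites — a deliberate, cheap substitute for a
bootstrap.

## AMOVA

Variance is partitioned from pairwise squared distances, here the
difference *counts* on the gap-encoded alignment (counts, not
proportions, match the squared-Euclidean formulation). The
sum-of-squares identities are the classical ones — SS within a group
is the mean pairwise squared distance within it, total SS equals the
sum across levels — and variance components follow by method of
moments with the usual unequal-sample-size coefficients, for both the
two-level design (among/within species) and the three-level design
(among species / among individuals within species / within
individuals, used for repeat copies). Negative components are reported
as estimated. Significance uses random permutation with the +1
correction p = (b+1)/(n_perm+1): sequences among species for the
two-level design; whole individuals among species (among-species
level) and sequences among individuals within species
(among-individuals level) for the three-level design. The analysis
drivers use 1023 permutations. Type-I error at α = 0.05 calibrates to
0.05 ± 0.02 over 400 null data sets; note the permutation lattice is
discrete, so nominal levels are only attainable to ~1/(n_perm+1).

## Breakpoint scanning

Recombination leaves adjacent alignment segments supporting different
topologies. Candidate breakpoints are the variable columns (a
breakpoint can only be resolved to the nearest variable site; columns
made variable by a gap-event state count). For each K from 0 to K_max,
a dynamic program over candidates finds the placement maximizing the
summed per-segment log-likelihood — placement is exact, not heuristic
(verified against brute-force enumeration for K ≤ 2) — and K is chosen
by minimum AICc.

The per-segment model is deliberately simple: NJ topology on the
slice's p-distances, JC69 branch lengths refined by per-edge Newton
updates. For JC69 the per-site likelihood as a function of one edge is
a + b·e^(−4t/3), so each edge update needs no additional tree
traversals; two sweeps suffice at these divergences. The parameter
count per segment is its 2n−3 branch lengths; per-segment AICc uses
the segment's column count as sample size, and the total adds 2 per
breakpoint. A richer substitution model (e.g. discrete-gamma rate
variation) would change absolute likelihoods but the breakpoint signal
here is topology conflict, which JC69 captures. Each segment must
contain at least `min_segment` (default 50) variable sites — the guard
that keeps the selection honest: with it, a single-topology alignment
selects K = 0 in ≥ 90% of replicates, while a two-topology
concatenation places the breakpoint within ±5 variable sites of the
junction. A `stride` parameter thins the candidate grid for large
alignments (the drivers use 3–4; placement granularity degrades
accordingly).

## Gene-conversion screen

On the projection of the alignment onto its polymorphic columns, the
screen scores, for every sequence pair, runs of sites at which the two
agree ("inner" fragments — conversion between ancestors of the pair),
and for every single sequence, runs of sites at which it differs from
all other rows ("outer" fragments — conversion from outside the
alignment, or with the source erased). With the default mismatch
penalty g = 0 a fragment may contain no mismatched (or non-unique)
site, so fragments are maximal runs bounded by mismatches; missing
sites are transparent. With g > 0, fragments are disjoint
maximal-scoring segments (score = matches − g·mismatches) with no
negative-scoring prefix or suffix. All maximal runs are reported, not
only the best per pair.

Significance: the null permutes polymorphic-site columns, which
preserves each pair's number of agreements while destroying spatial
clustering; restricted to one pair this is a uniform shuffle of its
agreement vector, which is how it is computed (vectorized over
permutations). sim p is the per-pair tail with the +1 correction;
global p is Bonferroni over ordered pairs (inner) or rows (outer),
capped at 1. The correction constant is intentionally simple and
conservative — the screen's false-positive rate on tract-free data is
≈1–3% at the nominal 5%. Detectability requires *contrast*: a pair
that agrees almost everywhere (e.g. after a whole-region transfer
analyzed in isolation) has no clustering signal, which is why the
hybrid-detection helper screens the complete condensed spacer rather
than the transferred region alone. Fragment spans are reported in
alignment columns (1-based in tables); spans in a row's own ungapped
coordinates can be derived from the alignment, since whether published
tract lengths refer to alignment or ungapped coordinates is ambiguous.

## The simulator

The simulator is the package's ground-truth instrument. An ancestral
template — random N1 and N2, one random consensus per repeat type,
each template copy mutated away from its consensus by
`paralog_divergence` — evolves down a newick species tree whose branch
lengths are expected substitutions per site (so `mutation_rate` = 1 by
construction and every other rate is per that clock). Within a branch,
a Gillespie loop draws:

* point mutations, JC69 (uniform site, one of the three other bases);
* conversions at `conversion_rate` per ordered eligible same-type pair:
  a geometric tract (mean 100 nt, truncated at the unit boundary)
  copied donor→recipient at the same offset;
* crossovers at `crossover_rate` per eligible unit: duplication or
  deletion (50/50) of one unit; deletion never removes the last copy
  of a type; duplicated copies inherit their source's template origin;
* indels at `indel_rate` per N1/N2 site: insertion or deletion (50/50)
  of geometric length (mean 20–25 nt).

With `terminal_repeat_protected` (default on), the first and last
units of the array join neither conversion nor crossover, mirroring
the observed escape of terminal repeats from homogenization.
Hybridization events are scheduled, not stochastic: at a stated time a
named region (N1, R, or N2, optionally a sub-interval) of the
recipient lineage is replaced by the donor lineage's current copy. The
scheduler advances all branches chronologically between hybridization
checkpoints so donor states are correct at transfer time.

Every event is logged with all sampled choices, and the same
`_apply_event` code path serves simulation and replay, so replaying
the log from the template reproduces the emitted sequences exactly —
this is tested, not assumed. Truth output also records per-leaf
annotations and each unit's template origin, the orthology oracle used
by the regime scores. Intra- and interchromosomal exchange cannot be
distinguished here (one haplotype per lineage); cross-lineage transfer
is modeled only by the scheduled hybridization events.

### Study conditions

`study_cohort_config` encodes the sampling design of the motivating
study: 13 spacers from 10 individuals of 4 species (3 DpxNA, 3 Dpc,
1 Dten, and two cloned spacers from each of 3 DpxE individuals), on an
ultrametric tree with species splits at 0.010/0.015/0.020 and
intraspecific depths 0.003–0.008 substitutions/site, chosen so
condensed-spacer divergences land in the observed 0.01–0.04 range.
Conversion is rare (rate 1 — the position-specific regime the study
observed), crossover (rate 40) reproduces the reported copy-number
spread (A roughly 1–5, B 2–6), and indels (rate 0.01/site, mean 25 nt)
generate the length variation of the nonrepetitive regions. Two DpxE
individuals carry whole-spacer introgressions from the Dten and Dpc
lineages at time 0.018 — the hybrid individuals whose inadvertent
inclusion shaped the study's divergence patterns — plus two partial N2
transfers (Dten→Dpc2, DpxNA1→Dpc3 at 0.019) standing in for the
interchromosomal conversion tracts seen in hybrids. Template sizes are
desk-scaled (N1 400, units 200/130/90, N2 1200 nt, array ABABCC;
the real spacer is ~4–5.5 kb with N1 ~650–800 and N2 ~2.5–2.8 kb) so
the full pipeline runs in minutes on one CPU; rates are per site, so
the scaling changes power, not process. With these conditions the
pipeline reproduces the study's qualitative fingerprint: intra/inter
p-distance ratio ≈ 0.9 for the condensed spacer, most repeat variation
within individuals (including negative variance components), repeat
copies clustering by array position, and interspecific conversion
tracts confined to N2.

### Regime bundles

`regime_fixture` packages the headline contrast at the same desk scale
(N1 250, units 150/100/80, N2 1200; 8 leaves, 4 species):

* `position_specific`: conversion rate 1 — orthologous copies (same
  template origin) stay more similar than paralogs; detected when
  within-origin mean p-distance < between-origin mean.
* `concerted`: conversion rate 400 and terminal protection off (the
  regime being simulated is unconstrained homogenization); detected
  when within-array mean < between-species mean for same-type copies.
* `hybrid`: a recent (time 0.0195 of 0.020 — F1-like) transfer of N2
  from Dten into one DpxE lineage; detected when significant inner
  fragments between the recipient and donor-species leaves cover ≥50%
  of the N2 columns of the condensed alignment.

What the generator does *not* emulate: selection on repeat motifs (the
TATA-motif constraint hypothesis), coalescent variation within species
(one haplotype per lineage), PCR/cloning artifacts, and rate variation
among sites. Passing tests therefore demonstrate that the algorithms
recover the processes the generator implements at realistic sizes and
rates — not that real spacers evolve by exactly these processes.

## Numerical and procedural choices

* Local/global DP fills use the running-maximum trick for the in-row
  affine state; both require gap-open ≥ gap-extend (enforced).
* Global-alignment tracebacks compare float scores with tolerance
  1e−9; local alignment uses integer scores, so equality is exact.
* JC69 branch lengths are clamped to [1e−8, 10]; per-edge Newton runs
  at most 12 iterations in z = e^(−4t/3) with bound clamping.
* Likelihood pruning rescales partials per node (log accumulators), so
  segment likelihoods are stable for any realistic slice.
* All stochastic procedures take explicit seeds; fixed seed means
  byte-identical output (FASTA, truth logs, permutation p-values).
* Analysis problem sizes (cohort template, 25–50 replicate calibration
  studies, stride 3–4 breakpoint grids) are the package's desk-scale
  defaults chosen to keep the full analysis under ~10 CPU-minutes.

## Known limitations

* Strictly alternating repeat blocks and single-copy types are only
  partially dissectable (see above); copy numbers inferred by
  automated dissection undercount in those cases, while truth-based
  counts in the simulator are exact.
* The AICc breakpoint count is, like its inspiration, mildly liberal
  when segments are allowed to be very short; the `min_segment` floor
  is the control, and placements are more trustworthy than the exact
  count.
* The Bonferroni global correction for conversion fragments is
  conservative; marginal tracts (sim p ~1e−3) can fail the corrected
  threshold, as seen in the hybrid regime's miss rate (~10%).
* Whole-region introgressions are invisible to the conversion screen
  when the transferred region is analyzed in isolation — detection
  needs flanking contrast.
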