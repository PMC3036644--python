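"""AMOVA variance partitioning.

Two-level AMOVA (among / within species) for the complete condensed
IGS, N1, and N2 from pairwise difference counts on the gap-encoded
alignment; three-level AMOVA (among species / among individuals within
species / within individuals) for each repeat type, where the sampling
units are repeat copies.  Significance from 1023 permutations.
"""

import json
from pathlib import Path

import pandas as pd

from igs.amova import amova, permutation_test
from igs.distance import difference_matrix
from igs.msa import encode_gap_events, read_alignment, progressive_align
from igs.records import read_igs_fasta
from igs.repeats import annotation_from_json

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_PERM = 1023


def main() -> None:
    records = read_igs_fasta(RESULTS / "cohort.fasta")
    species = {r.id: r.species for r in records}
    individual = {r.id: r.individual for r in records}
    aln = read_alignment(RESULTS / "condensed_aln.fasta")
    enc = encode_gap_events(aln)
    with open(RESULTS / "region_spans.json") as fh:
        spans = {k: tuple(v) for k, v in json.load(fh).items()}

    out = []
    for name, span in [("entire_IGS", (0, enc.n_columns)),
                       ("N1", spans["N1"]), ("N2", spans["N2"])]:
        dm = difference_matrix(enc.slice(*span))
        res = amova(dm, species)
        res.p_values = permutation_test(dm, species, n_perm=N_PERM, seed=42)
        df = res.to_frame()
        df.insert(0, "region", name)
        out.append(df)
        among = df.iloc[0]
        print(f"{name}: among-species {among['percent']:.1f}% "
              f"(p={among['p']:.4f})")

    # per repeat type: copies nested in individuals nested in species
    with open(RESULTS / "cohort_annotations.json") as fh:
        annots = {a["record_id"]: annotation_from_json(json.dumps(a))
                  for a in json.load(fh)}
    by_id = {r.id: r for r in records}
    for t in ("A", "B", "C"):
        seqs, ids, structure = [], [], {}
        for rid, ann in annots.items():
            for u in ann.units:
                if u.type_label == t:
                    label = f"{rid}-{t}{u.copy_index}"
                    ids.append(label)
                    seqs.append(by_id[rid].sequence[u.interval[0]:u.interval[1]])
                    structure[label] = (species[rid], individual[rid])
        n_ind_multi = len({v[0] for v in structure.values()})
        if len(seqs) < 6 or n_ind_multi < 2:
            continue
        raln = progressive_align(seqs, ids=ids)
        dm = difference_matrix(encode_gap_events(raln))
        try:
            res = amova(dm, structure)
            res.p_values = permutation_test(dm, structure, n_perm=N_PERM, seed=42)
        except ValueError as e:
            print(f"repeat {t}: skipped ({e})")
            continue
        df = res.to_frame()
        df.insert(0, "region", f"{t}_repeat")
        out.append(df)
        print(f"repeat {t}: " + ", ".join(
            f"{r['source']} {r['percent']:.1f}%" for _, r in df.iterrows()))

    pd.concat(out).to_csv(RESULTS / "amova.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
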