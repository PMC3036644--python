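"""Divergence summaries and NJ dendrograms.

Computes p-distance matrices (pairwise deletion, gap events as states)
and NJ trees for the complete condensed IGS and the N1/N2 regions;
per-species-pair divergence tables; and, for each repeat type, the
within/between-cluster divergence of repeat copies pooled across
arrays, with clusters cut from the repeat NJ tree.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from igs.distance import pdistance_matrix
from igs.msa import encode_gap_events, read_alignment, progressive_align
from igs.nj import build_nj, tree_clusters
from igs.records import read_igs_fasta
from igs.repeats import annotation_from_json
from igs.summaries import cluster_divergence, divergence_summary

RESULTS = Path(__file__).resolve().parents[1] / "results"


def species_pair_table(dm, species):
    """Mean p-distance for every ordered species pair (lower triangle)."""
    rows = []
    sps = sorted(set(species.values()))
    for i, a in enumerate(sps):
        for b in sps[: i + 1]:
            vals = [dm.values[k, l]
                    for k in range(dm.n) for l in range(k + 1, dm.n)
                    if {species[dm.ids[k]], species[dm.ids[l]]} == ({a, b} if a != b else {a})]
            if vals:
                rows.append({"species_1": a, "species_2": b,
                             "mean_p": round(float(np.mean(vals)), 4),
                             "n_pairs": len(vals)})
    return pd.DataFrame(rows)


def main() -> None:
    records = read_igs_fasta(RESULTS / "cohort.fasta")
    species = {r.id: r.species for r in records}
    aln = read_alignment(RESULTS / "condensed_aln.fasta")
    enc = encode_gap_events(aln)
    with open(RESULTS / "region_spans.json") as fh:
        spans = {k: tuple(v) for k, v in json.load(fh).items()}

    summary_rows = []
    for name, span in [("complete_IGS", (0, enc.n_columns)),
                       ("N1", spans["N1"]), ("N2", spans["N2"])]:
        sub = enc.slice(*span)
        dm = pdistance_matrix(sub)
        tree = build_nj(dm)
        (RESULTS / f"nj_{name}.nwk").write_text(tree.newick() + "\n")
        species_pair_table(dm, species).to_csv(
            RESULTS / f"species_pairs_{name}.tsv", sep="\t", index=False)
        s = divergence_summary(dm, species)
        summary_rows.append({"region": name, "OAM": round(s.oam, 4),
                             "MIA_x": round(s.mia, 4), "MIR_y": round(s.mir, 4),
                             "ratio": s.ratio_3dp})
        print(f"{name}: OAM {s.oam:.4f}, intra {s.mia:.4f}, inter {s.mir:.4f}, "
              f"ratio {s.ratio_3dp}")
    pd.DataFrame(summary_rows).to_csv(RESULTS / "divergence_summary.tsv",
                                      sep="\t", index=False)

    # repeat copies pooled across arrays, one analysis per type
    with open(RESULTS / "cohort_annotations.json") as fh:
        annots = {a["record_id"]: annotation_from_json(json.dumps(a))
                  for a in json.load(fh)}
    by_id = {r.id: r for r in records}
    cluster_rows = []
    for t in ("A", "B", "C"):
        seqs, ids = [], []
        for rid, ann in annots.items():
            for u in ann.units:
                if u.type_label == t:
                    ids.append(f"{rid}-{t}{u.copy_index}")
                    seqs.append(by_id[rid].sequence[u.interval[0]:u.interval[1]])
        if len(seqs) < 4:
            continue
        raln = progressive_align(seqs, ids=ids)
        rdm = pdistance_matrix(encode_gap_events(raln))
        rtree = build_nj(rdm)
        (RESULTS / f"nj_repeat_{t}.nwk").write_text(rtree.newick() + "\n")
        n_positions = int(np.median([sum(1 for i in ids if i.startswith(rid + "-"))
                                     for rid in {i.split("-")[0] for i in ids}]))
        n_clusters = max(2, n_positions)
        clusters = tree_clusters(rtree, n_clusters)
        cd = cluster_divergence(rdm, clusters)
        cluster_rows.append({
            "type": t, "n_copies": len(ids), "n_clusters": n_clusters,
            "within_mean": round(cd.within_mean, 3),
            "between_mean": round(cd.between_mean, 3)})
        print(f"repeat {t}: {len(ids)} copies, within-cluster {cd.within_mean:.3f}, "
              f"between-cluster {cd.between_mean:.3f}")
    pd.DataFrame(cluster_rows).to_csv(RESULTS / "repeat_clusters.tsv",
                                      sep="\t", index=False)


if __name__ == "__main__":
    main()
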