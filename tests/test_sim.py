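"""Forward simulator: determinism, replay exactness, and statistics."""

import dataclasses

import numpy as np
import pytest

from igs.sim import (Hybridization, SimConfig, concerted_score,
                     position_clustering_score, read_truth, regime_fixture,
                     replay, simulate_igs, study_cohort_config,
                     truth_annotation, write_truth)

FOUR_TAXON = "((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01);"


def small_config(**kw):
    base = dict(tree=FOUR_TAXON, seed=0, n1_len=200, n2_len=300,
                unit_lengths={"A": 100, "B": 80, "C": 60}, array="ABABCC")
    base.update(kw)
    return SimConfig(**base)


class TestBasics:
    def test_zero_rates_emit_the_template(self):
        cfg = small_config(mutation_rate=0.0)
        recs, truth = simulate_igs(cfg)
        tpl = truth.template["n1"] + "".join(
            u["seq"] for u in truth.template["units"]) + truth.template["n2"]
        assert all(r.sequence == tpl for r in recs)
        assert truth.events == []

    def test_fixed_seed_is_byte_identical(self):
        cfg = small_config(conversion_rate=30.0, crossover_rate=10.0,
                           indel_rate=0.02)
        a_recs, a_truth = simulate_igs(cfg)
        b_recs, b_truth = simulate_igs(cfg)
        assert [r.sequence for r in a_recs] == [r.sequence for r in b_recs]
        assert a_truth.events == b_truth.events

    def test_conservation_without_crossover(self):
        cfg = small_config(conversion_rate=20.0, indel_rate=0.02, seed=3)
        recs, truth = simulate_igs(cfg)
        for leaf in truth.leaf_names:
            arr = "".join(u["type"] for u in truth.leaf_annotations[leaf])
            assert arr == "ABABCC"

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            small_config(mutation_rate=-1.0)
        with pytest.raises(ValueError):
            small_config(conversion_tract_mean=0.5)
        with pytest.raises(ValueError):
            small_config(array="ABX")
        with pytest.raises(ValueError):
            regime_fixture("unknown_regime")


class TestReplay:
    @pytest.mark.parametrize("seed", [3, 11])
    def test_replaying_the_log_reproduces_sequences(self, seed):
        cfg = small_config(seed=seed, conversion_rate=50.0, crossover_rate=20.0,
                           indel_rate=0.05)
        recs, truth = simulate_igs(cfg)
        assert any(truth.events), "fixture should generate events"
        got = replay(cfg, truth)
        assert [r.sequence for r in got] == [r.sequence for r in recs]

    def test_replay_with_hybridization(self):
        cfg = small_config(seed=5, indel_rate=0.02, hybridizations=(
            Hybridization(donor="A", recipient="C", time=0.015, region="N2"),))
        recs, truth = simulate_igs(cfg)
        assert any(e["type"] == "hybridization" for e in truth.events)
        got = replay(cfg, truth)
        assert [r.sequence for r in got] == [r.sequence for r in recs]


class TestTruthIO:
    def test_roundtrip(self, tmp_path):
        cfg = small_config(seed=7, conversion_rate=40.0, crossover_rate=15.0,
                           indel_rate=0.03)
        _, truth = simulate_igs(cfg)
        write_truth(truth, tmp_path / "t.json")
        back = read_truth(tmp_path / "t.json")
        assert back.events == truth.events
        assert back.leaf_annotations == truth.leaf_annotations
        assert back.template == truth.template

    def test_serialized_coordinates_are_1based(self, tmp_path):
        cfg = small_config(seed=8)
        _, truth = simulate_igs(cfg)
        write_truth(truth, tmp_path / "t.json")
        import json

        obj = json.loads((tmp_path / "t.json").read_text())
        for units in obj["leaf_annotations"].values():
            assert all(u["start"] >= 1 for u in units)
        for ev in obj["events"]:
            if "pos" in ev:
                assert ev["pos"] >= 1

    def test_empty_event_log_serializes_empty(self, tmp_path):
        cfg = small_config(mutation_rate=0.0)
        _, truth = simulate_igs(cfg)
        write_truth(truth, tmp_path / "t.json")
        assert read_truth(tmp_path / "t.json").events == []


class TestStatistics:
    def test_mutation_only_divergence_matches_jc(self):
        """Two leaves at divergence t: E[p] = (3/4)(1 - e^(-8t/3));
        the Monte-Carlo mean must sit within 3 MC standard errors."""
        t = 0.03
        ps = []
        for s in range(60):
            cfg = SimConfig(tree=f"(A:{t},B:{t});", seed=4000 + s,
                            n1_len=1200, n2_len=1200,
                            unit_lengths={"A": 100}, array="A")
            recs, _ = simulate_igs(cfg)
            a, b = recs[0].sequence, recs[1].sequence
            ps.append(sum(x != y for x, y in zip(a, b)) / len(a))
        expected = 0.75 * (1 - np.exp(-8 * t / 3))
        se = np.std(ps) / np.sqrt(len(ps))
        assert abs(np.mean(ps) - expected) < 3 * se

    def test_conversion_homogenization_is_monotone(self):
        """Increasing the conversion rate never increases expected
        within-array divergence (rate grid, paired seeds)."""
        rates = [0.0, 50.0, 400.0]
        means = []
        for rate in rates:
            vals = []
            for s in range(25):
                b = regime_fixture("concerted", seed=s)
                cfg = dataclasses.replace(
                    b["config"], conversion_rate=rate, seed=s)
                recs, truth = simulate_igs(cfg)
                w, _ = concerted_score(recs, truth, cfg.species_of)
                vals.append(w)
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]

    def test_protected_terminal_units_keep_their_identity(self):
        cfg = small_config(seed=9, crossover_rate=30.0, conversion_rate=30.0,
                           terminal_repeat_protected=True)
        recs, truth = simulate_igs(cfg)
        first_uid = truth.template["units"][0]["uid"]
        last_uid = truth.template["units"][-1]["uid"]
        for leaf in truth.leaf_names:
            ann = truth.leaf_annotations[leaf]
            assert ann[0]["uid"] == first_uid
            assert ann[-1]["uid"] == last_uid


class TestCohortAndAnnotations:
    def test_study_cohort_shape(self):
        cfg = study_cohort_config(seed=2)
        recs, truth = simulate_igs(cfg)
        assert len(recs) == 13
        species = {}
        for r in recs:
            species[r.species] = species.get(r.species, 0) + 1
        assert species == {"DpxNA": 3, "DpxE": 6, "Dpc": 3, "Dten": 1}
        individuals = {r.individual for r in recs}
        assert len(individuals) == 10

    def test_truth_annotation_is_valid(self):
        cfg = small_config(seed=10, crossover_rate=10.0)
        recs, truth = simulate_igs(cfg)
        for r in recs:
            ann = truth_annotation(truth, r.id)
            assert ann.record_id == r.id
            assert ann.units[-1].interval[1] <= r.length
            for t in {u.type_label for u in ann.units}:
                idx = [u.copy_index for u in ann.units if u.type_label == t]
                assert idx == list(range(1, len(idx) + 1))


class TestRegimeScores:
    def test_position_specific_bundle_shows_orthologous_clustering(self):
        hits = 0
        for s in range(10):
            b = regime_fixture("position_specific", seed=s)
            w, x = position_clustering_score(b["records"], b["truth"],
                                             b["config"].species_of)
            hits += (w < x)
        assert hits >= 8

    def test_concerted_bundle_homogenizes_arrays(self):
        hits = 0
        for s in range(10):
            b = regime_fixture("concerted", seed=s)
            w, x = concerted_score(b["records"], b["truth"],
                                   b["config"].species_of)
            hits += (w < x)
        assert hits >= 9

    def test_hybrid_bundle_flags_the_transfer(self):
        from igs.pipeline import detect_hybrid_transfer

        hits = 0
        n = 10
        for s in range(n):
            b = regime_fixture("hybrid", seed=s)
            cov = detect_hybrid_transfer(b["records"], b["truth"],
                                         ["Dten1", "Dten2"], "DpxE1",
                                         b["config"].species_of,
                                         n_perm=10000, seed=s)
            hits += (cov >= 0.5)
        assert hits >= 0.8 * n
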