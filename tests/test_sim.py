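"""Synthetic-data generator: determinism, configured-structure recovery,
and truth-channel consistency."""

import dataclasses
import math

import numpy as np
import pytest

from circmir.qpcr import analyze_ct_table, correlate_platforms
from circmir.sim import (
    SimConfig,
    simulate_counts,
    simulate_qpcr,
    simulate_reads,
    simulate_references,
)


def test_config_validation_rejects_bad_fractions():
    with pytest.raises(ValueError):
        SimConfig(category_fractions={"serum": {"miRNA": 0.7}, "plasma": {"miRNA": 1.0}})
    with pytest.raises(ValueError):
        SimConfig(n_reads={"serum": 0, "plasma": 10})
    with pytest.raises(ValueError):
        SimConfig(barcodes={"serum": "AAAAAA", "plasma": "AAAAAA"})
    with pytest.raises(ValueError):
        SimConfig(de_fold_change=-1.0)


class TestReferences:
    def test_counts_per_category_and_unique_names(self, small_config, small_refs):
        mirna_like = small_refs.by_category("miRNA", "miRNA*")
        # n_mirnas entries plus the flagged decoy fragment
        assert len(mirna_like) == small_config.n_mirnas + 1
        for cat in ("tRNA", "rRNA", "snRNA", "snoRNA"):
            assert len(small_refs.by_category(cat)) >= 1
        names = [r.name for r in small_refs]
        assert len(set(names)) == len(names)

    def test_star_fraction_rounding(self):
        cfg = SimConfig(n_mirnas=10, star_fraction=0.2, decoy_fragment=False)
        refs = simulate_references(cfg)
        stars = refs.by_category("miRNA*")
        assert len(stars) == round(0.2 * 10) == 2
        assert all(r.name.endswith("*") for r in stars)

    def test_same_seed_gives_identical_references(self, small_config):
        a = simulate_references(small_config)
        b = simulate_references(small_config)
        assert [(r.name, r.sequence, r.category) for r in a] == [
            (r.name, r.sequence, r.category) for r in b
        ]

    def test_decoy_fragment_flagged(self, small_refs):
        assert small_refs.excluded_names == {"mir-frag-0001"}


class TestReads:
    def test_error_free_inserts_are_reference_substrings(self, small_config, small_refs):
        reads, truth = simulate_reads(small_config, small_refs)
        by_name = {r.name: r.sequence for r in small_refs}
        for row in truth.reads.itertuples():
            assert row.insert in by_name[row.feature]

    def test_reads_start_with_library_barcode(self, small_config, small_refs):
        reads, truth = simulate_reads(small_config, small_refs)
        expected = dict(small_config.barcodes)
        barcode_of = dict(zip(truth.reads["read_id"], truth.reads["library"]))
        for read in reads:
            assert read.sequence.startswith(expected[barcode_of[read.id]])

    def test_category_fraction_recovered_within_binomial_error(self, small_refs):
        fracs = {"miRNA": 0.5, "tRNA": 0.5}
        cfg = SimConfig(
            seed=3,
            n_reads={"serum": 10_000, "plasma": 10},
            category_fractions={"serum": fracs, "plasma": fracs},
            n_mirnas=40,
            error_rate=0.0,
        )
        refs = simulate_references(cfg)
        _, truth = simulate_reads(cfg, refs)
        serum = truth.reads[truth.reads["library"] == "serum"]
        observed = (serum["category"].isin(["miRNA", "miRNA*"])).mean()
        # binomial standard error at p=0.5, n=10,000
        se = math.sqrt(0.5 * 0.5 / 10_000)
        assert abs(observed - 0.5) < 3 * se

    def test_degenerate_length_distribution(self, small_refs, small_config):
        cfg = dataclasses.replace(small_config, length_distribution={22: 1.0})
        _, truth = simulate_reads(cfg, small_refs)
        assert (truth.reads["insert"].str.len() == 22).all()

    def test_raw_mode_appends_adaptor(self, small_config, small_refs):
        cfg = dataclasses.replace(small_config, with_adaptor=True,
                                  n_reads={"serum": 50, "plasma": 50})
        reads, _ = simulate_reads(cfg, small_refs)
        assert all(r.sequence.endswith(cfg.adaptor) for r in reads)

    def test_impossible_insert_length_rejected(self, small_config, small_refs):
        cfg = dataclasses.replace(small_config, length_distribution={500: 1.0})
        with pytest.raises(ValueError):
            simulate_reads(cfg, small_refs)

    def test_determinism(self, small_config, small_refs):
        r1, t1 = simulate_reads(small_config, small_refs)
        r2, t2 = simulate_reads(small_config, small_refs)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert t1.reads.equals(t2.reads)

    def test_truth_has_no_orphans(self, small_config, small_refs):
        reads, truth = simulate_reads(small_config, small_refs)
        assert set(truth.reads["read_id"]) == {r.id for r in reads}
        ref_names = {r.name for r in small_refs}
        assert set(truth.reads["feature"]) <= ref_names


class TestCounts:
    def test_null_difference_centered_at_zero(self):
        cfg = SimConfig(
            seed=9,
            n_reads={"serum": 1_000_000, "plasma": 1_000_000},
            n_mirnas=1000,
            de_fraction=0.0,
            serum_exclusive_fraction=0.0,
        )
        serum, plasma, truth = simulate_counts(cfg)
        diffs = np.array(
            [serum.counts[f] - plasma.counts[f] for f in truth.fold_changes]
        )
        # var(x - y) = 2 * mean count under the Poisson null
        se_mean = math.sqrt(2 * 1_000_000 / 1000 / 1000)
        assert abs(diffs.mean()) < 3 * se_mean

    def test_zero_proportion_features_have_zero_counts(self):
        cfg = SimConfig(seed=4, n_mirnas=50, serum_exclusive_fraction=0.2)
        serum, plasma, truth = simulate_counts(cfg)
        for f in truth.serum_exclusive():
            assert plasma.counts[f] == 0
            assert truth.proportions["plasma"][f] == 0.0

    def test_proportions_sum_to_one(self):
        _, _, truth = simulate_counts(SimConfig(seed=5, n_mirnas=30))
        for lib in ("serum", "plasma"):
            assert sum(truth.proportions[lib].values()) == pytest.approx(1.0, abs=1e-9)

    def test_de_labels_match_fold_change_direction(self):
        cfg = SimConfig(seed=6, n_mirnas=60, de_fraction=0.2, de_down_fraction=0.5)
        _, _, truth = simulate_counts(cfg)
        for f, fc in truth.fold_changes.items():
            label = truth.de_labels[f]
            if label == "up":
                assert fc > 1
            elif label == "down":
                assert fc < 1
            elif label == "ns":
                assert fc == 1
        assert len(truth.de_features()) == round(0.2 * 60)

    def test_min_cpm_floor_respected(self):
        cfg = SimConfig(seed=7, n_mirnas=100, min_cpm=500.0,
                        de_fraction=0.0, serum_exclusive_fraction=0.0)
        _, _, truth = simulate_counts(cfg)
        smallest = min(truth.proportions["plasma"].values())
        assert smallest * 1e6 >= 500.0 * (1 - 1e-9)

    def test_determinism(self):
        cfg = SimConfig(seed=8, n_mirnas=25)
        a = simulate_counts(cfg)
        b = simulate_counts(cfg)
        assert a[0].counts == b[0].counts and a[1].counts == b[1].counts


class TestQpcr:
    def test_noise_free_round_trip_is_exact(self, small_config):
        ct = simulate_qpcr({"mir-a": 2.0, "mir-b": 1.0, "mir-c": 0.125},
                           small_config, noise_sd=0.0)
        results = {r.mirna: r for r in analyze_ct_table(ct)}
        assert results["mir-a"].fold_change == pytest.approx(2.0)
        assert results["mir-b"].ddct == pytest.approx(0.0)
        assert results["mir-c"].fold_change == pytest.approx(0.125)

    def test_noisy_recovery_correlates_with_truth(self, small_config):
        true_fc = {f"mir-{i:02d}": fc for i, fc in enumerate(
            np.geomspace(0.25, 4.0, 12))}
        ct = simulate_qpcr(true_fc, small_config, noise_sd=0.1)
        recovered = {r.mirna: r.log2_fold_change for r in analyze_ct_table(ct)}
        truth_log = {m: math.log2(fc) for m, fc in true_fc.items()}
        corr = correlate_platforms(truth_log, recovered)
        assert corr.defined and corr.r > 0.95

    def test_rejects_empty_and_nonpositive(self, small_config):
        with pytest.raises(ValueError):
            simulate_qpcr({}, small_config)
        with pytest.raises(ValueError):
            simulate_qpcr({"m": -2.0}, small_config)
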