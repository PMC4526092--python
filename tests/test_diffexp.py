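"""Exact Poisson-null test against enumeration oracles, fold-change
conventions, DE calling, and hierarchical clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from circmir.diffexp import (
    audic_claverie_pvalue,
    call_differential,
    cluster_matrix,
    hierarchical_cluster,
    log2_fold_change,
    poisson_exact_pvalue,
    poisson_exact_pvalues,
    to_newick,
)
from circmir.quantify import CountTable


def binomial_tail_oracle(x: int, t: int, p0: float) -> float:
    """Independent oracle: full enumeration of the conditional binomial."""
    pmf = [math.comb(t, i) * p0**i * (1 - p0) ** (t - i) for i in range(t + 1)]
    lower = sum(pmf[: x + 1])
    upper = sum(pmf[x:])
    return min(1.0, 2.0 * min(lower, upper))


class TestLog2FoldChange:
    def test_identity(self):
        assert log2_fold_change(100, 100) == 0.0

    def test_arithmetic(self):
        assert log2_fold_change(400, 100) == pytest.approx(2.0)

    def test_pseudocount_on_zero_side(self):
        assert log2_fold_change(100, 0, pseudocount=0.5) == pytest.approx(
            math.log2(100.5 / 0.5), abs=1e-9
        )

    def test_both_zero_is_flagged_missing(self):
        assert math.isnan(log2_fold_change(0, 0))

    def test_zero_pseudocount_with_zero_value_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(10, 0, pseudocount=0.0)


class TestPoissonExact:
    def test_symmetric_center_is_one(self):
        assert poisson_exact_pvalue(7, 100, 7, 100) == 1.0

    def test_worked_example_five_vs_zero(self):
        # t=5, equal sizes: P[X>=5] = 0.5^5 = 0.03125, doubled
        assert poisson_exact_pvalue(5, 100, 0, 100) == pytest.approx(0.0625, abs=1e-12)

    def test_degenerate_zero_total(self):
        assert poisson_exact_pvalue(0, 100, 0, 100) == 1.0

    @pytest.mark.parametrize("ratio", [1.0, 2.34])
    def test_matches_enumeration_oracle(self, ratio):
        n1, n2 = 1000.0 * ratio, 1000.0
        p0 = n1 / (n1 + n2)
        worst = 0.0
        for t in range(1, 31):
            for x in range(t + 1):
                got = poisson_exact_pvalue(x, n1, t - x, n2)
                want = binomial_tail_oracle(x, t, p0)
                worst = max(worst, abs(got - want))
        assert worst < 1e-12

    def test_symmetry_in_library_swap(self):
        for x, y in [(3, 9), (0, 4), (12, 12)]:
            assert poisson_exact_pvalue(x, 300, y, 700) == pytest.approx(
                poisson_exact_pvalue(y, 700, x, 300), abs=1e-15
            )

    def test_monotone_in_imbalance(self):
        t = 20
        ps = [poisson_exact_pvalue(x, 100, t - x, 100) for x in range(t // 2, t + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_vectorised_agrees_with_scalar(self):
        x = np.array([0, 3, 10, 25])
        y = np.array([0, 9, 10, 2])
        vec = poisson_exact_pvalues(x, 500, y, 1200)
        for i in range(len(x)):
            assert vec[i] == pytest.approx(
                poisson_exact_pvalue(int(x[i]), 500, int(y[i]), 1200), abs=1e-15
            )

    def test_audic_claverie_agrees_in_ordering(self):
        """The alternative posterior-predictive test ranks count pairs the
        same way as the conditional test on a small grid."""
        pairs = [(x, y) for x in range(0, 12) for y in range(0, 12) if x + y > 0]
        cond = [poisson_exact_pvalue(x, 100, y, 100) for x, y in pairs]
        ac = [audic_claverie_pvalue(x, 100, y, 100) for x, y in pairs]
        # rank agreement (ties from discreteness keep this below 1)
        r = pd.Series(cond).corr(pd.Series(ac), method="spearman")
        assert r > 0.95
        # and strict monotone agreement along increasing imbalance at fixed t
        for t in (6, 20):
            cond_ray = [poisson_exact_pvalue(x, 100, t - x, 100)
                        for x in range(t // 2, t + 1)]
            ac_ray = [audic_claverie_pvalue(x, 100, t - x, 100)
                      for x in range(t // 2, t + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(cond_ray, cond_ray[1:]))
            assert all(a >= b - 1e-15 for a, b in zip(ac_ray, ac_ray[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_exact_pvalue(-1, 100, 0, 100)
        with pytest.raises(ValueError):
            poisson_exact_pvalue(1, 0, 0, 100)


class TestCallDifferential:
    def test_clear_fold_change_called_up(self):
        serum = CountTable("serum", {"m": 200, "ref": 9800})
        plasma = CountTable("plasma", {"m": 50, "ref": 9950})
        res = {r.feature: r for r in call_differential(serum, plasma,
                                                       p_threshold=0.001)}
        m = res["m"]
        # oracle check of the p-value behind the call
        assert m.p_value == pytest.approx(
            binomial_tail_oracle(200, 250, m.n1 / (m.n1 + m.n2)), abs=1e-12
        )
        assert m.cpm_serum / m.cpm_plasma > 2
        assert (m.call == "up") == (m.p_value < 0.001)
        assert m.call == "up"

    def test_identical_cpm_is_ns(self):
        serum = CountTable("serum", {"m": 100, "k": 100})
        plasma = CountTable("plasma", {"m": 100, "k": 100})
        res = call_differential(serum, plasma)
        assert all(r.call == "ns" for r in res)

    def test_calls_partition_shared_features(self):
        cfg_counts = {f"f{i}": 20 + i for i in range(30)}
        serum = CountTable("serum", cfg_counts)
        plasma = CountTable("plasma", {k: v + 5 for k, v in cfg_counts.items()})
        res = call_differential(serum, plasma)
        shared = [r for r in res if r.exclusive == "shared"]
        assert len(shared) == sum(
            1 for r in res if r.call in ("up", "down", "ns") and r.exclusive == "shared"
        )
        assert {r.call for r in res} <= {"up", "down", "ns"}

    def test_exclusive_features_flagged_not_called(self):
        serum = CountTable("serum", {"only_s": 50, "both": 100})
        plasma = CountTable("plasma", {"only_p": 50, "both": 100})
        res = {r.feature: r for r in call_differential(serum, plasma)}
        assert res["only_s"].exclusive == "serum_only"
        assert res["only_p"].exclusive == "plasma_only"
        assert res["only_s"].call == "ns"
        assert res["both"].exclusive == "shared"

    def test_call_sign_consistent_with_log2fc(self):
        serum = CountTable("serum", {"a": 500, "b": 20, "c": 100, "d": 90})
        plasma = CountTable("plasma", {"a": 40, "b": 480, "c": 100, "d": 95})
        for r in call_differential(serum, plasma):
            if r.call == "up":
                assert r.log2fc > 0
            elif r.call == "down":
                assert r.log2fc < 0


class TestHierarchicalCluster:
    def test_identical_profiles_merge_at_zero(self):
        m = pd.DataFrame({"serum": [1.0, 1.0], "plasma": [2.0, 2.0]},
                         index=["a", "b"])
        result = hierarchical_cluster(m)
        assert result.linkage[0, 2] == 0.0

    def test_identical_pair_merges_first(self):
        m = pd.DataFrame(
            {"serum": [1.0, 1.0, 9.0], "plasma": [2.0, 2.0, -3.0]},
            index=["a", "b", "far"],
        )
        result = hierarchical_cluster(m)
        first = {int(result.linkage[0, 0]), int(result.linkage[0, 1])}
        assert first == {0, 1}

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 2)), columns=["serum", "plasma"],
                         index=[f"f{i}" for i in range(10)])
        result = hierarchical_cluster(m)
        heights = result.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_leaf_order_is_permutation(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(8, 2)), columns=["serum", "plasma"],
                         index=[f"f{i}" for i in range(8)])
        result = hierarchical_cluster(m)
        assert sorted(result.leaf_order) == sorted(m.index)

    def test_fewer_than_two_features_is_hard_error(self):
        m = pd.DataFrame({"serum": [1.0], "plasma": [2.0]}, index=["a"])
        with pytest.raises(ValueError):
            hierarchical_cluster(m)

    def test_newick_contains_all_leaves(self):
        m = pd.DataFrame(
            {"serum": [1.0, 2.0, 9.0], "plasma": [0.0, 2.0, -3.0]},
            index=["fa", "fb", "fc"],
        )
        nwk = to_newick(hierarchical_cluster(m))
        assert nwk.endswith(";")
        for leaf in m.index:
            assert leaf in nwk

    def test_cluster_matrix_uses_called_features(self):
        serum = CountTable("serum", {"a": 500, "b": 100, "c": 15})
        plasma = CountTable("plasma", {"a": 40, "b": 100, "c": 14})
        res = call_differential(serum, plasma)
        m = cluster_matrix(res, called_only=True)
        called = {r.feature for r in res if r.call != "ns"}
        assert set(m.index) == called
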