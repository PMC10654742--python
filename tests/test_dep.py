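import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from faimepath.dep import (
    benjamini_hochberg,
    dep_table,
    robust_effect_size_dr,
    trimmed_mean,
    winsorize,
    winsorized_t_test,
)

A = [1.0, 2.0, 3.0, 4.0, 5.0]
B = [3.0, 4.0, 5.0, 6.0, 7.0]


class TestWinsorize:
    def test_one_per_tail(self):
        assert winsorize([1, 2, 3, 4, 100], gamma=0.2).tolist() == [2, 2, 3, 4, 4]

    def test_gamma_zero_identity(self):
        x = [3.0, 1.0, 7.0]
        assert winsorize(x, gamma=0.0).tolist() == x

    def test_constant_unchanged(self):
        assert winsorize([2.0] * 6, gamma=0.3).tolist() == [2.0] * 6

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            winsorize([1.0], gamma=0.2)


class TestRobustEffectSize:
    def test_identical_groups_zero(self):
        assert robust_effect_size_dr(A, A) == 0.0

    def test_hand_computed(self):
        # trimmed means 3 and 5; winsorized SS 4 + 4 over 8 df -> s_W = 1
        assert robust_effect_size_dr(A, B, gamma=0.2) == pytest.approx(
            -1.284, abs=1e-9
        )

    def test_antisymmetry(self):
        assert robust_effect_size_dr(A, B) == -robust_effect_size_dr(B, A)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=9), rng.normal(size=11)
        assert robust_effect_size_dr(a + 10, b + 10) == pytest.approx(
            robust_effect_size_dr(a, b), abs=1e-12
        )


class TestYuen:
    def test_identical_groups(self):
        t, _, p = winsorized_t_test(A, A)
        assert t == 0.0 and p == 1.0

    def test_hand_computed(self):
        t, df, p = winsorized_t_test(A, B, gamma=0.2)
        assert t == pytest.approx(-np.sqrt(3.0), abs=1e-9)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(np.sqrt(3.0), 4), abs=1e-12)
        assert p == pytest.approx(0.158, abs=5e-4)

    def test_scale_invariance(self):
        t1, _, _ = winsorized_t_test(A, B)
        t2, _, _ = winsorized_t_test([3 * x for x in A], [3 * x for x in B])
        assert t1 == pytest.approx(t2, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_scipy_trimmed_ttest(self, seed):
        """Independent oracle: scipy's trimmed (Yuen) two-sample test."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(8, 20))
        b = rng.normal(loc=0.5, size=rng.integers(8, 20))
        t, _, p = winsorized_t_test(a, b, gamma=0.2)
        ref = stats.ttest_ind(a, b, equal_var=False, trim=0.2)
        assert t == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_pooled_variant_on_winsorized_values(self):
        t, df, _ = winsorized_t_test(A, B, method="pooled")
        # winsorized values have means 3 and 5, pooled SS 8 over 8 df
        assert df == 8.0
        assert t == pytest.approx(-2 / np.sqrt(1 * (1 / 5 + 1 / 5)), abs=1e-9)


class TestBenjaminiHochberg:
    def test_all_equal(self):
        assert np.allclose(benjamini_hochberg([0.2, 0.2, 0.2]), 0.2)

    def test_step_up_examples(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )
        assert np.allclose(
            benjamini_hochberg([0.005, 0.1, 0.9]), [0.015, 0.15, 0.9]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        assert np.allclose(benjamini_hochberg(p)[perm], benjamini_hochberg(p[perm]))


class TestDepTable:
    def test_self_comparison_nothing_significant(self, small_scores):
        psm, cm, _, baseline = small_scores
        half = baseline[: len(baseline) // 2]
        sc = pd.concat(
            [psm.scores[half].add_suffix("_x"), psm.scores[half].add_suffix("_y")],
            axis=1,
        )
        labels = pd.Series(
            ["x"] * len(half) + ["y"] * len(half), index=sc.columns
        )
        dt = dep_table(sc, labels)
        assert dt.n_significant == 0

    def test_dual_criterion_requires_effect_size(self):
        # large n makes a small shift highly significant by q, yet the
        # effect stays far below the moderate-|dR| threshold
        rng = np.random.default_rng(4)
        n = 500
        sc = pd.DataFrame(
            np.concatenate(
                [rng.normal(0, 1, (20, n)), rng.normal(0.25, 1, (20, n))], axis=1
            ),
            index=[f"p{i}" for i in range(20)],
            columns=[f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
        )
        labels = pd.Series(["A"] * n + ["B"] * n, index=sc.columns)
        dt = dep_table(sc, labels)
        assert (dt.table["q"] < 0.05).sum() >= 15
        assert dt.n_significant == 0

    def test_recovers_injected_pathways(self, small_dep):
        dt, truth = small_dep
        called = set(dt.significant)
        affected = set(truth["affected_pathways"])
        tp = len(called & affected)
        assert tp / len(affected) >= 0.9
        assert (len(called) - tp) / max(len(called), 1) <= 0.1

    def test_location_invariance(self, small_scores):
        psm, cm, _, baseline = small_scores
        labels = cm.metadata.loc[baseline, "group"]
        d1 = dep_table(psm.scores[baseline], labels).table
        d2 = dep_table(psm.scores[baseline] + 100.0, labels).table
        assert np.allclose(d1["t"], d2["t"])
        assert np.allclose(d1["dR"], d2["dR"])

    def test_small_groups_rejected(self):
        sc = pd.DataFrame(np.ones((3, 6)), columns=list("abcdef"))
        labels = pd.Series(["x"] * 3 + ["y"] * 3, index=sc.columns)
        with pytest.raises(ValueError, match=">= 5 samples"):
            dep_table(sc, labels)


def test_trimmed_mean_central_values():
    assert trimmed_mean([1, 2, 3, 4, 100], gamma=0.2) == 3.0
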