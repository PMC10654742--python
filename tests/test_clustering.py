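import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from faimepath.clustering import (
    cluster_composition,
    cluster_covariate_tests,
    collapse_to_root,
    exact_association_2x2,
    ward_clusters,
)
from faimepath.io import GeneSetCollection


def _blob_scores(means, n_per, n_pathways=20, sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    cols, truth = [], []
    for gi, mu in enumerate(means):
        for j in range(n_per):
            cols.append(rng.normal(mu, sd, size=n_pathways))
            truth.append(gi)
    sc = pd.DataFrame(
        np.column_stack(cols),
        index=[f"p{i}" for i in range(n_pathways)],
        columns=[f"s{i}" for i in range(len(cols))],
    )
    return sc, np.array(truth)


class TestWardClusters:
    def test_two_blobs_recovered_exactly(self):
        sc, truth = _blob_scores([0.0, 10.0], n_per=10)
        res = ward_clusters(sc, k=2)
        assert adjusted_rand_score(truth, res.assignment.to_numpy()) == 1.0

    def test_sample_order_invariance(self):
        sc, _ = _blob_scores([0.0, 3.0, 6.0], n_per=8, seed=1)
        res1 = ward_clusters(sc, k=3)
        perm = np.random.default_rng(2).permutation(sc.shape[1])
        res2 = ward_clusters(sc.iloc[:, perm], k=3)
        a1 = res1.assignment.loc[sc.columns].to_numpy()
        a2 = res2.assignment.loc[sc.columns].to_numpy()
        assert adjusted_rand_score(a1, a2) == 1.0

    def test_four_level_gradient_recovered(self):
        sc, truth = _blob_scores([0.0, 1.0, 2.0, 3.0], n_per=12, sd=0.1, seed=3)
        res = ward_clusters(sc, k=4)
        assert adjusted_rand_score(truth, res.assignment.to_numpy()) >= 0.9

    def test_merge_heights_nondecreasing(self):
        sc, _ = _blob_scores([0.0, 1.0, 2.0, 3.0], n_per=12, seed=4)
        res = ward_clusters(sc, k=4)
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_too_many_clusters_rejected(self):
        sc, _ = _blob_scores([0.0], n_per=3)
        with pytest.raises(ValueError, match="clusters"):
            ward_clusters(sc, k=5)


class TestComposition:
    @staticmethod
    def _metadata(groups):
        return pd.DataFrame(
            {"group": groups},
            index=[f"s{i}" for i in range(len(groups))],
        )

    def test_fractions_and_gradient_order(self):
        assignment = pd.Series(
            [1, 1, 1, 1, 2, 2], index=[f"s{i}" for i in range(6)]
        )
        md = self._metadata(["HC", "HC", "HC", "PreSSc", "PreSSc", "PreSSc"])
        comp = cluster_composition(assignment, md)
        assert comp.iloc[0]["cluster"] == 1
        assert comp.iloc[0]["frac_PreSSc"] == 0.25
        assert comp.iloc[1]["frac_PreSSc"] == 1.0
        assert comp["n_samples"].sum() == 6

    def test_pure_hc_cluster_fraction_zero(self):
        assignment = pd.Series([1, 1, 2], index=["s0", "s1", "s2"])
        md = self._metadata(["HC", "HC", "PreSSc"])
        comp = cluster_composition(assignment, md)
        assert comp.iloc[0]["frac_PreSSc"] == 0.0

    def test_label_permutation_invariant_gradient(self):
        assignment = pd.Series([1, 1, 2, 2], index=["s0", "s1", "s2", "s3"])
        md = self._metadata(["HC", "HC", "PreSSc", "PreSSc"])
        relabeled = assignment.map({1: 2, 2: 1})
        c1 = cluster_composition(assignment, md)
        c2 = cluster_composition(relabeled, md)
        assert c1["frac_PreSSc"].tolist() == c2["frac_PreSSc"].tolist()


class TestCollapseToRoot:
    def test_two_step_chain(self):
        sets = GeneSetCollection(
            sets={
                "a": ("a", ("g1", "g2")),
                "b": ("b", ("g3",)),
                "root": ("root", ("g4",)),
            },
            hierarchy={"a": "b", "b": "root"},
        )
        roots = collapse_to_root(sets)
        assert roots["a"] == "root"
        assert roots["root"] == "root"

    def test_orphan_is_own_root(self):
        sets = GeneSetCollection(sets={"solo": ("solo", ("g1",))})
        assert collapse_to_root(sets)["solo"] == "solo"


class TestExactAssociation:
    def test_aspirin_by_outcome_table(self):
        """The printed 2x2 of low-dose-aspirin use by 4-year outcome
        (19/0 stable vs 9/5 evolving) gives an exact p of 0.008."""
        p_exact, p_chisq = exact_association_2x2([[19, 0], [9, 5]])
        assert round(p_exact, 3) == 0.008
        assert p_chisq < 0.05

    def test_proportional_rows_null(self):
        p_exact, _ = exact_association_2x2([[10, 20], [5, 10]])
        assert p_exact == pytest.approx(1.0)

    def test_diagonal_enumeration(self):
        p_exact, _ = exact_association_2x2([[5, 0], [0, 5]])
        assert p_exact == pytest.approx(2 / 252)

    def test_transpose_invariance(self):
        t = [[7, 3], [2, 9]]
        assert exact_association_2x2(t) == exact_association_2x2(
            np.array(t).T.tolist()
        )

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            exact_association_2x2([[0, 0], [3, 4]])


class TestCovariateTests:
    @staticmethod
    def _frame(n=24, seed=0):
        rng = np.random.default_rng(seed)
        assignment = pd.Series(
            np.repeat([1, 2, 3], n // 3), index=[f"s{i}" for i in range(n)]
        )
        md = pd.DataFrame(
            {
                "subject_id": assignment.index,
                "group": ["PreSSc"] * n,
                "outcome": ["stable"] * n,
                "timepoint": ["baseline"] * n,
                "age": rng.normal(55, 10, size=n),
                "sex": rng.choice(["F", "M"], size=n),
                "site": ["x"] * n,
            },
            index=assignment.index,
        )
        return assignment, md

    def test_constant_covariate_degenerate(self):
        assignment, md = self._frame()
        out = cluster_covariate_tests(assignment, md)
        assert out.loc["site", "test"] == "degenerate"
        assert out.loc["site", "p"] == 1.0

    def test_cluster_tracking_numeric_covariate(self):
        assignment, md = self._frame(seed=1)
        rng = np.random.default_rng(2)
        md["age"] = assignment.to_numpy() + rng.normal(0, 1e-3, len(md))
        out = cluster_covariate_tests(assignment, md, covariates=["age"])
        assert out.loc["age", "p"] < 1e-6

    def test_independent_covariates_not_flagged(self):
        assignment, md = self._frame(seed=3)
        out = cluster_covariate_tests(assignment, md, covariates=["age", "sex"])
        assert (out["p"] > 1e-4).all()
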