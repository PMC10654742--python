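import numpy as np
import pandas as pd
import pytest
from scipy import stats

from faimepath.change import (
    ancova_change_table,
    pre_post_group_means,
    root_enrichment,
    split_pre_post,
)
from faimepath.clustering import ward_clusters
from faimepath.faime import minmax_normalize


def _paired(n_stable=10, n_evolving=8, n_pathways=12, seed=0, noise=0.3):
    rng = np.random.default_rng(seed)
    subjects = [f"S{i}" for i in range(n_stable + n_evolving)]
    outcomes = pd.Series(
        ["stable"] * n_stable + ["evolving"] * n_evolving, index=subjects
    )
    pre = pd.DataFrame(
        rng.normal(size=(n_pathways, len(subjects))),
        index=[f"p{i}" for i in range(n_pathways)],
        columns=subjects,
    )
    post = pre + rng.normal(0, noise, size=pre.shape)
    return pre, post, outcomes


class TestAncova:
    def test_no_change_nothing_significant(self):
        pre, _, outcomes = _paired()
        ct = ancova_change_table(pre, pre.copy(), outcomes)
        assert np.allclose(ct.table["beta_evolving"], 0.0)
        assert ct.n_significant == 0

    def test_shared_deterministic_change_has_zero_group_effect(self):
        pre, _, outcomes = _paired(seed=1)
        post = pre + 2.5
        ct = ancova_change_table(pre, post, outcomes)
        assert np.allclose(ct.table["beta_evolving"], 0.0, atol=1e-9)

    def test_group_constant_change_recovered_exactly(self):
        """Noiseless group-wise changes: the group coefficient equals the
        difference of mean changes (closed form, no cluster terms)."""
        pre, _, outcomes = _paired(seed=2)
        delta = np.where(outcomes == "evolving", 3.0, 1.0)
        post = pre + delta
        ct = ancova_change_table(pre, post, outcomes)
        assert np.allclose(ct.table["beta_evolving"], 2.0, atol=1e-9)

    def test_location_invariance(self):
        pre, post, outcomes = _paired(seed=3)
        c1 = ancova_change_table(pre, post, outcomes).table
        c2 = ancova_change_table(pre + 50.0, post + 50.0, outcomes).table
        assert np.allclose(c1["beta_evolving"], c2["beta_evolving"], atol=1e-9)

    def test_unpaired_subject_named(self):
        pre, post, outcomes = _paired()
        with pytest.raises(ValueError, match="S0"):
            ancova_change_table(pre.drop(columns="S0"), post, outcomes)

    def test_singleton_cluster_merged_with_warning(self, caplog):
        pre, post, outcomes = _paired(seed=4)
        clusters = pd.Series(2, index=pre.columns)
        clusters.iloc[0] = 1  # singleton
        clusters.iloc[-6:] = 3
        with caplog.at_level("WARNING"):
            ct = ancova_change_table(pre, post, outcomes, clusters=clusters)
        assert "single subject" in caplog.text
        assert ct.model_spec["covariates"] == ["evolving", "pre", "cluster[3]"]

    def test_recovers_progression_pathways(self, small_scores, small_dep):
        psm, cm, truth, baseline = small_scores
        dt, _ = small_dep
        pre, post, outcomes = split_pre_post(psm, cm.metadata)
        sig = list(dt.significant) or list(psm.scores.index)
        mm = minmax_normalize(psm)
        res = ward_clusters(mm.scores.loc[sig, baseline], k=4)
        base_md = cm.metadata.loc[baseline]
        sample_of = base_md.reset_index().set_index("subject_id")["sample_id"]
        clusters = pd.Series(
            {s: res.assignment[sample_of[s]] for s in pre.columns}
        )
        ct = ancova_change_table(pre, post, outcomes, clusters=clusters)
        called = set(ct.significant)
        prog = set(truth["progression_pathways"])
        tp = len(called & prog)
        assert tp / len(prog) >= 0.9
        assert (len(called) - tp) / max(len(called), 1) <= 0.1

    def test_null_pvalues_uniform(self):
        """Label-shuffled changes give uniform group-effect p-values."""
        rng = np.random.default_rng(5)
        pre, post, outcomes = _paired(
            n_stable=17, n_evolving=16, n_pathways=200, seed=5, noise=1.0
        )
        shuffled = pd.Series(
            rng.permutation(outcomes.to_numpy()), index=outcomes.index
        )
        ct = ancova_change_table(pre, post, shuffled)
        ks = stats.kstest(ct.table["p"], "uniform")
        assert ks.pvalue > 0.01


class TestRootEnrichment:
    def test_no_significant_degenerate(self):
        sig = pd.Series(False, index=[f"p{i}" for i in range(6)])
        roots = pd.Series("r1", index=sig.index)
        enr = root_enrichment(sig, roots, "r1")
        assert enr.degenerate and enr.p == 1.0

    def test_matches_pearson_formula(self):
        # target root: 30 significant / 20 not; others: 10 / 40
        idx = [f"p{i}" for i in range(100)]
        sig = pd.Series([True] * 30 + [False] * 20 + [True] * 10 + [False] * 40,
                        index=idx)
        roots = pd.Series(["tgt"] * 50 + ["oth"] * 50, index=idx)
        enr = root_enrichment(sig, roots, "tgt")
        obs = np.array([[30, 20], [10, 40]])
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / n
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert enr.p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)
        assert enr.prop_target_in_significant > enr.prop_target_in_nonsignificant

    def test_root_label_permutation_is_null(self):
        rng = np.random.default_rng(6)
        idx = [f"p{i}" for i in range(200)]
        sig = pd.Series(rng.random(200) < 0.3, index=idx)
        ps = []
        for _ in range(50):
            roots = pd.Series(
                rng.permutation(["tgt"] * 60 + ["oth"] * 140), index=idx
            )
            ps.append(root_enrichment(sig, roots, "tgt").p)
        assert (np.array(ps) < 0.05).mean() < 0.2


class TestPrePostMeans:
    def test_constant_matrix_equal_means(self):
        pre, post, outcomes = _paired(seed=7)
        pre.iloc[:, :] = 1.5
        means = pre_post_group_means(pre, pre.copy(), outcomes, "p0")
        assert set(means.values()) == {1.5}

    def test_hand_arithmetic(self):
        subjects = ["a", "b", "c", "d"]
        outcomes = pd.Series(
            ["stable", "stable", "evolving", "evolving"], index=subjects
        )
        pre = pd.DataFrame([[1.0, 2.0, 3.0, 5.0]], index=["p"], columns=subjects)
        post = pd.DataFrame([[2.0, 4.0, -1.0, -3.0]], index=["p"], columns=subjects)
        means = pre_post_group_means(pre, post, outcomes, "p")
        assert means == {
            "stable_pre": 1.5,
            "stable_post": 3.0,
            "evolving_pre": 4.0,
            "evolving_post": -2.0,
        }

    def test_unknown_pathway_rejected(self):
        pre, post, outcomes = _paired()
        with pytest.raises(KeyError):
            pre_post_group_means(pre, post, outcomes, "nope")


def test_split_pre_post_pairs_subjects(small_scores):
    psm, cm, _, _ = small_scores
    pre, post, outcomes = split_pre_post(psm, cm.metadata)
    assert list(pre.columns) == list(post.columns)
    md = cm.metadata
    assert set(pre.columns) == set(md[md["group"] == "PreSSc"]["subject_id"])
    assert set(outcomes.unique()) == {"stable", "evolving"}
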