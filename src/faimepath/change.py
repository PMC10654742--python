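"""Longitudinal change analysis of pathway scores.

For each pathway, the follow-up minus baseline change of every patient
is regressed on the progression outcome while adjusting for that
pathway's baseline score and for the patient's baseline clinical
cluster:

    delta_i = b0 + b1 * [evolving]_i + b2 * pre_i + cluster terms + e_i

b1 is the covariate-adjusted association between the pathway's change
and future progression; its two-sided p-values are BH-adjusted across
pathways.  Only patients enter (controls have no follow-up sample).
Cluster indicators use treatment coding against the first cluster;
clusters holding a single patient cannot support an indicator and are
merged into the reference level with a warning.

The module also reports the per-group mean score before and after (so
the direction of drift in evolving vs stable patients is explicit) and
a chi-square enrichment of any root category among change-associated
pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dep import benjamini_hochberg
from .faime import PathwayScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class ChangeTable:
    """Per-pathway ANCOVA change results."""

    table: pd.DataFrame
    alpha: float
    model_spec: dict

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def split_pre_post(
    scores: PathwayScoreMatrix | pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Split a score matrix into baseline and follow-up views indexed by
    subject, restricted to patients with both timepoints.

    Returns (pre, post, outcome) with matching subject columns.
    """
    sc = scores.scores if isinstance(scores, PathwayScoreMatrix) else scores
    md = metadata.loc[[s for s in sc.columns if s in metadata.index]]
    pat = md[md["group"] == "PreSSc"]
    pre_map = pat[pat["timepoint"] == "baseline"]["subject_id"]
    post_map = pat[pat["timepoint"] == "followup"]["subject_id"]
    subjects = [s for s in pre_map.values if s in set(post_map.values)]
    pre = sc[pre_map.index].copy()
    pre.columns = list(pre_map.values)
    post = sc[post_map.index].copy()
    post.columns = list(post_map.values)
    outcome = (
        pat.drop_duplicates("subject_id").set_index("subject_id")["outcome"]
    )
    return pre[subjects], post[subjects], outcome.loc[subjects]


def ancova_change_table(
    scores_pre: pd.DataFrame,
    scores_post: pd.DataFrame,
    outcomes: pd.Series,
    clusters: pd.Series | None = None,
    alpha: float = 0.05,
    robust_se: bool = False,
) -> ChangeTable:
    """Per-pathway ANCOVA of post-minus-pre change on outcome.

    *scores_pre* and *scores_post* are pathway x subject with identical
    columns; *outcomes* maps subject -> {stable, evolving}; *clusters*
    optionally maps subject -> baseline cluster label.
    """
    missing = set(scores_pre.columns) ^ set(scores_post.columns)
    if missing:
        raise ValueError(f"unpaired subject(s): {sorted(missing)}")
    subjects = list(scores_pre.columns)
    scores_post = scores_post[subjects]
    outcomes = outcomes.loc[subjects]
    bad = set(outcomes.unique()) - {"stable", "evolving"}
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")

    evolving = (outcomes == "evolving").astype(float).to_numpy()
    cluster_dummies = np.empty((len(subjects), 0))
    cluster_names: list[str] = []
    if clusters is not None:
        cl = clusters.loc[subjects]
        counts = cl.value_counts()
        singletons = counts.index[counts < 2].tolist()
        if singletons:
            logger.warning(
                "clusters with a single subject merged into reference: %s",
                singletons,
            )
        levels = sorted(counts.index[counts >= 2].tolist())
        for lev in levels[1:]:  # first usable level is the reference
            cluster_dummies = np.column_stack(
                [cluster_dummies, (cl == lev).astype(float).to_numpy()]
            )
            cluster_names.append(f"cluster[{lev}]")

    pre = scores_pre.to_numpy(dtype=float)
    post = scores_post.to_numpy(dtype=float)
    delta = post - pre

    rows = []
    for i, pid in enumerate(scores_pre.index):
        x = np.column_stack(
            [np.ones(len(subjects)), evolving, pre[i], cluster_dummies]
        )
        fit = sm.OLS(delta[i], x).fit(
            cov_type="HC1" if robust_se else "nonrobust"
        )
        p = fit.pvalues[1]
        if not np.isfinite(p):  # degenerate fit (e.g. zero residual)
            p = 1.0
        rows.append(
            {
                "beta_evolving": fit.params[1],
                "se": fit.bse[1],
                "p": p,
                "mean_change_stable": delta[i][evolving == 0].mean(),
                "mean_change_evolving": delta[i][evolving == 1].mean(),
            }
        )
    table = pd.DataFrame(rows, index=scores_pre.index)
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    table["direction_stable"] = np.sign(table["mean_change_stable"])
    table["direction_evolving"] = np.sign(table["mean_change_evolving"])
    return ChangeTable(
        table=table,
        alpha=alpha,
        model_spec={
            "covariates": ["evolving", "pre"] + cluster_names,
            "robust_se": robust_se,
            "n_subjects": len(subjects),
        },
    )


@dataclass
class RootEnrichment:
    """Chi-square enrichment of one root category among change-associated
    pathways."""

    table: pd.DataFrame  # 2x2: root membership x significance
    p: float
    prop_target_in_significant: float
    prop_target_in_nonsignificant: float
    degenerate: bool = False


def root_enrichment(
    significant: pd.Series, roots: pd.Series, target_root: str
) -> RootEnrichment:
    """Is *target_root* over-represented among significant pathways?

    Builds the 2x2 table of (root == target) x (significant) and applies
    a Pearson chi-square without continuity correction; the two observed
    proportions are returned so the direction of enrichment is explicit.
    Degenerate margins (no significant or no non-significant pathway)
    are flagged and reported with p = 1.
    """
    roots = roots.loc[significant.index]
    in_target = roots == target_root
    sig = significant.astype(bool)
    tab = np.array(
        [
            [int((in_target & sig).sum()), int((in_target & ~sig).sum())],
            [int((~in_target & sig).sum()), int((~in_target & ~sig).sum())],
        ]
    )
    table = pd.DataFrame(
        tab,
        index=[f"root={target_root}", "other root"],
        columns=["significant", "not significant"],
    )
    n_sig = int(sig.sum())
    n_nonsig = int((~sig).sum())
    prop_sig = tab[0, 0] / n_sig if n_sig else float("nan")
    prop_non = tab[0, 1] / n_nonsig if n_nonsig else float("nan")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return RootEnrichment(table, 1.0, prop_sig, prop_non, degenerate=True)
    chi = stats.chi2_contingency(tab, correction=False)
    return RootEnrichment(table, float(chi.pvalue), prop_sig, prop_non)


def pre_post_group_means(
    scores_pre: pd.DataFrame,
    scores_post: pd.DataFrame,
    outcomes: pd.Series,
    pathway_id: str,
) -> dict[str, float]:
    """Mean raw score by outcome group and timepoint for one pathway."""
    if pathway_id not in scores_pre.index:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    outcomes = outcomes.loc[scores_pre.columns]
    out = {}
    for grp in ("stable", "evolving"):
        cols = outcomes.index[outcomes == grp]
        out[f"{grp}_pre"] = float(scores_pre.loc[pathway_id, cols].mean())
        out[f"{grp}_post"] = float(scores_post.loc[pathway_id, cols].mean())
    return out
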