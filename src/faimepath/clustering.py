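"""Unsupervised cohort structure: Ward clustering of samples on pathway
scores, composition gradients, pathway root-category collapse, and
cluster-vs-covariate association tests.

Clustering runs by default on the [-1, 1]-normalized score view (the
heat-map representation) with Euclidean distances and Ward's linkage,
cut to a fixed number of clusters (default 4).  Clusters are reported
ordered by their fraction of patient (PreSSc) samples, which exposes
the healthy-to-patient gradient visible in the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .faime import PathwayScoreMatrix
from .io import GeneSetCollection


@dataclass
class ClusterResult:
    """Ward clustering of samples.

    ``linkage`` is the scipy merge history (with heights); ``assignment``
    maps sample id -> cluster label 1..k; ``ordering`` lists cluster
    labels sorted by ascending fraction of PreSSc samples (set once
    composition is computed; identity order until then).
    """

    linkage: np.ndarray
    assignment: pd.Series
    k: int
    ordering: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = set(self.assignment.unique())
        if labels != set(range(1, self.k + 1)):
            raise ValueError(
                f"expected non-empty clusters 1..{self.k}, got {sorted(labels)}"
            )
        if not self.ordering:
            self.ordering = list(range(1, self.k + 1))


def ward_clusters(
    scores: PathwayScoreMatrix | pd.DataFrame, k: int = 4
) -> ClusterResult:
    """Ward-linkage hierarchical clustering of samples, cut to k clusters.

    Samples are points in pathway-score space; distances are Euclidean.
    """
    sc = scores.scores if isinstance(scores, PathwayScoreMatrix) else scores
    x = sc.to_numpy(dtype=float).T  # samples x pathways
    n = x.shape[0]
    if k > n:
        raise ValueError(f"cannot cut {n} samples into {k} clusters")
    z = linkage(x, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(
        linkage=z,
        assignment=pd.Series(labels, index=sc.columns, name="cluster"),
        k=k,
    )


def cluster_composition(
    assignment: pd.Series, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster HC/PreSSc counts and PreSSc fraction, ordered by
    ascending PreSSc fraction (the healthy-to-patient gradient)."""
    md = metadata.loc[assignment.index]
    rows = []
    for label in sorted(assignment.unique()):
        members = assignment.index[assignment == label]
        groups = md.loc[members, "group"]
        n_hc = int((groups == "HC").sum())
        n_pre = int((groups == "PreSSc").sum())
        rows.append(
            {
                "cluster": int(label),
                "n_samples": len(members),
                "n_HC": n_hc,
                "n_PreSSc": n_pre,
                "frac_PreSSc": n_pre / len(members),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["frac_PreSSc", "cluster"], kind="stable"
    )
    return out.reset_index(drop=True)


def collapse_to_root(sets: GeneSetCollection) -> pd.Series:
    """Map every pathway to its top-level (root) category by following
    parent links to a fixed point; pathways absent from the hierarchy
    are their own roots."""
    parent_of = sets.hierarchy
    roots = {}
    for pid in sets:
        node = pid
        seen = {node}
        while node in parent_of:
            node = parent_of[node]
            if node in seen:  # defensive; construction already validates
                raise ValueError(f"cycle in hierarchy at {node!r}")
            seen.add(node)
        roots[pid] = node
    return pd.Series(roots, name="root")


def exact_association_2x2(table) -> tuple[float, float]:
    """Association in a 2x2 contingency table.

    Returns ``(p_exact, p_chisq)``: the two-sided Fisher exact p (sum of
    hypergeometric probabilities <= that of the observed table) and the
    Pearson chi-square p without continuity correction.  Both are
    reported because on sparse clinical tables the two can disagree at
    the printed precision.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin (a zero row or column sum)")
    _, p_exact = stats.fisher_exact(t, alternative="two-sided")
    chi = stats.chi2_contingency(t, correction=False)
    return float(p_exact), float(chi.pvalue)


def cluster_covariate_tests(
    assignment: pd.Series,
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Test each covariate for association with cluster membership.

    Categorical covariates use a Pearson chi-square on the cluster x
    level contingency table (no continuity correction; expected counts
    below 5 flagged); numeric covariates use one-way ANOVA across
    clusters.  A constant covariate is degenerate and reported with
    p = 1.
    """
    md = metadata.loc[assignment.index]
    if covariates is None:
        covariates = [
            c
            for c in md.columns
            if c not in ("subject_id", "group", "outcome", "timepoint")
        ]
    if assignment.nunique() < 2:
        raise ValueError("need at least 2 clusters to test associations")
    rows = []
    for cov in covariates:
        col = md[cov]
        numeric = pd.api.types.is_numeric_dtype(col)
        note = ""
        if col.nunique(dropna=True) <= 1:
            p, test = 1.0, "degenerate"
            note = "constant covariate"
        elif numeric:
            groups = [
                col[assignment == lab].dropna().to_numpy()
                for lab in sorted(assignment.unique())
            ]
            groups = [g for g in groups if len(g)]
            p = float(stats.f_oneway(*groups).pvalue)
            test = "anova"
        else:
            ct = pd.crosstab(assignment, col)
            chi = stats.chi2_contingency(ct.to_numpy(), correction=False)
            p = float(chi.pvalue)
            test = "chi2"
            if (chi.expected_freq < 5).any():
                note = "expected counts < 5"
        rows.append({"covariate": cov, "test": test, "p": p, "note": note})
    return pd.DataFrame(rows).set_index("covariate")
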