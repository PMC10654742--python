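"""Single-sample FAIME pathway scoring.

FAIME (Functional Analysis of Individual Microarray/RNA-seq Expression)
turns one sample's expression profile into one activity score per gene
set.  Within a sample, genes are ranked ascending by expression (average
ranks on ties) and weighted

    w(r) = r * exp(-r / N),

an increasing function of rank on [0, N] that concentrates weight on
highly expressed genes.  A pathway's score in that sample is the mean
weight of its member genes minus the mean weight of all non-member
genes, so positive scores mean the set sits higher in the sample's
expression ranking than the rest of the transcriptome.  Because only
within-sample ranks enter, scores are invariant to any strictly
increasing per-sample transform of expression.

The weighting is deliberately isolated in :func:`rank_weights` so a
different variant can be substituted without touching the scoring or
any downstream statistics.

Statistics downstream run on raw scores; :func:`minmax_normalize`
produces the [-1, 1] per-pathway view used for heat maps only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import GeneSetCollection
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PathwayScoreMatrix:
    """Pathway x sample FAIME scores.

    ``view`` is ``"raw"`` for scores straight from the algorithm and
    ``"minmax"`` after per-pathway [-1, 1] rescaling. ``n_genes`` holds
    the number of member genes actually present in the expression
    universe for each retained pathway.
    """

    scores: pd.DataFrame
    n_genes: pd.Series
    view: str = "raw"

    def __post_init__(self) -> None:
        if self.view not in ("raw", "minmax"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.view == "minmax":
            arr = self.scores.to_numpy()
            if (arr < -1 - 1e-12).any() or (arr > 1 + 1e-12).any():
                raise ValueError("minmax view has values outside [-1, 1]")

    @property
    def pathways(self) -> list[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)


def rank_weights(expr_column: np.ndarray) -> np.ndarray:
    """Rank-exponential gene weights for one sample.

    Ranks are ascending (lowest expression -> 1), ties get the average
    rank; the weight of rank r among N genes is r * exp(-r/N).
    """
    x = np.asarray(expr_column, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("expression column must be a non-empty 1-D array")
    if not np.isfinite(x).all():
        raise ValueError("expression column contains non-finite values")
    r = rankdata(x, method="average")
    return r * np.exp(-r / x.size)


def faime_score(weights: np.ndarray, member_mask: np.ndarray) -> float:
    """Mean weight over member genes minus mean weight over the rest."""
    w = np.asarray(weights, dtype=float)
    m = np.asarray(member_mask, dtype=bool)
    k = int(m.sum())
    if k == 0:
        raise ValueError("no member gene present in the expression universe")
    if k == w.size:
        raise ValueError("member set covers the whole universe (empty complement)")
    return float(w[m].mean() - w[~m].mean())


def _weight_matrix(values: np.ndarray) -> np.ndarray:
    """Per-sample rank-exponential weights for a genes x samples matrix."""
    n = values.shape[0]
    ranks = np.apply_along_axis(rankdata, 0, values)
    return ranks * np.exp(-ranks / n)


def score_matrix(
    expr: ExpressionMatrix | pd.DataFrame,
    sets: GeneSetCollection,
    min_genes: int = 5,
) -> PathwayScoreMatrix:
    """Score every pathway in every sample.

    Pathways whose intersection with the expression gene universe holds
    fewer than *min_genes* genes are dropped (count logged).  Member
    genes absent from the universe are ignored.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError("empty expression matrix")
    gene_index = {g: i for i, g in enumerate(values.index)}
    n_genes_total = len(gene_index)

    kept: list[str] = []
    masks: list[np.ndarray] = []
    mapped_counts: list[int] = []
    n_dropped = 0
    for pid in sets:
        idx = [gene_index[g] for g in sets.genes_of(pid) if g in gene_index]
        if len(idx) < min_genes:
            n_dropped += 1
            continue
        mask = np.zeros(n_genes_total, dtype=bool)
        mask[idx] = True
        kept.append(pid)
        masks.append(mask)
        mapped_counts.append(len(idx))
    if n_dropped:
        logger.info(
            "score_matrix: dropped %d pathways with < %d mapped genes",
            n_dropped,
            min_genes,
        )
    if not kept:
        raise ValueError(
            f"no pathway has >= {min_genes} genes in the expression universe"
        )

    w = _weight_matrix(values.to_numpy(dtype=float))  # genes x samples
    member = np.vstack(masks)  # pathways x genes
    k = member.sum(axis=1).astype(float)
    total = w.sum(axis=0)  # per-sample total weight
    member_sum = member @ w  # pathways x samples
    mean_in = member_sum / k[:, None]
    mean_out = (total[None, :] - member_sum) / (n_genes_total - k)[:, None]
    scores = pd.DataFrame(mean_in - mean_out, index=kept, columns=values.columns)
    return PathwayScoreMatrix(
        scores=scores,
        n_genes=pd.Series(mapped_counts, index=kept, name="n_genes"),
        view="raw",
    )


def minmax_normalize(psm: PathwayScoreMatrix) -> PathwayScoreMatrix:
    """Rescale each pathway row to [-1, 1] across samples (heat-map view).

    A constant row maps to all zeros.
    """
    if psm.view != "raw":
        raise ValueError("minmax_normalize expects the raw view")
    arr = psm.scores.to_numpy(dtype=float)
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(arr)
    nz = (span > 0).ravel()
    out[nz] = 2.0 * (arr[nz] - lo[nz]) / span[nz] - 1.0
    return PathwayScoreMatrix(
        scores=pd.DataFrame(out, index=psm.scores.index, columns=psm.scores.columns),
        n_genes=psm.n_genes,
        view="minmax",
    )
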