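"""Count preprocessing: CPM filtering, median-of-ratios size factors,
and log2 normalization.

The order of operations is: filter genes on CPM of the *raw* counts
first, then compute size factors on the filtered matrix, then log
transform.  CPM is defined on raw library sizes, so the low-expression
filter does not depend on the normalization; the alternative order
(normalize first) is available via :func:`preprocess` ``filter_first=False``.

Downstream single-sample pathway scores are rank-based within each
sample, so they are invariant to the choice between the log2 scale and
the normalized-count scale; the log2 scale is kept because it is the
conventional representation for inspection and export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix


@dataclass
class ExpressionMatrix:
    """Log2-normalized expression (genes x samples) with provenance."""

    values: pd.DataFrame
    size_factors: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: counts / column sum * 1e6."""
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    colsums = c.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(
            f"zero library size for sample(s): {zero.index.tolist()}"
        )
    return c / colsums * 1e6


def filter_by_cpm(
    counts: CountMatrix, threshold: float = 1.0, min_samples: int = 2
) -> CountMatrix:
    """Keep genes with CPM strictly above *threshold* in at least
    *min_samples* samples."""
    c = cpm(counts)
    keep = (c > threshold).sum(axis=1) >= min_samples
    out = CountMatrix(counts.counts.loc[keep], counts.metadata)
    return out


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample size factors.

    The reference for each gene is the geometric mean of its counts
    across samples, computed only over genes with strictly positive
    counts in every sample; each sample's factor is the median over
    those genes of count / reference.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = c.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; supply a "
            "pseudo-reference or pre-filter the matrix"
        )
    ref = np.exp(np.mean(np.log(arr[all_pos]), axis=1))
    ratios = arr[all_pos] / ref[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=c.columns, name="size_factor")


def log_normalize(
    counts: CountMatrix | pd.DataFrame, factors: pd.Series
) -> pd.DataFrame:
    """log2(count / size_factor + 1)."""
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    f = factors.loc[c.columns]
    if (f <= 0).any():
        bad = f[f <= 0].index.tolist()
        raise ValueError(f"nonpositive size factor for sample(s): {bad}")
    return np.log2(c / f + 1.0)


def preprocess(
    counts: CountMatrix,
    cpm_threshold: float = 1.0,
    min_samples: int = 2,
    filter_first: bool = True,
) -> ExpressionMatrix:
    """Full preprocessing: CPM filter, size factors, log2 normalization.

    ``filter_first=False`` computes size factors on the unfiltered matrix
    before filtering (normalize-then-filter order).
    """
    n_before = len(counts.genes)
    if filter_first:
        filtered = filter_by_cpm(counts, cpm_threshold, min_samples)
        factors = size_factors(filtered)
    else:
        factors = size_factors(counts)
        filtered = filter_by_cpm(counts, cpm_threshold, min_samples)
    values = log_normalize(filtered, factors)
    return ExpressionMatrix(
        values=values,
        size_factors=factors,
        provenance={
            "cpm_threshold": cpm_threshold,
            "min_samples": min_samples,
            "filter_first": filter_first,
            "n_genes_before": n_before,
            "n_genes_after": len(filtered.genes),
            "size_factors": {k: float(v) for k, v in factors.items()},
        },
    )
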