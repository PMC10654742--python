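"""Differential-pathway statistics on single-sample pathway scores.

Pathway activity scores are composites of many transcripts, so a fold
change is meaningless; group differences are expressed as a robust
effect size instead.  With per-tail trimming proportion gamma and
k = floor(gamma * n):

* winsorizing replaces the k smallest values by the (k+1)-th order
  statistic and the k largest by the (n-k)-th;
* the trimmed mean averages the central n - 2k values;
* the robust effect size is

      dR = 0.642 * (tmean_A - tmean_B) / s_W,

  where s_W pools the two winsorized sums of squares over
  n_A + n_B - 2 degrees of freedom.  The 0.642 constant rescales the
  20%-winsorized standard deviation so that dR matches Cohen's d under
  normality; |dR| > 0.62897 marks a moderate effect.
* the hypothesis test is Yuen's trimmed-mean Welch test:

      t = (tmean_A - tmean_B) / sqrt(d_A + d_B),
      d_i = (n_i - 1) * s2_{W,i} / (h_i * (h_i - 1)),   h_i = n_i - 2k_i,

  with Welch-Satterthwaite degrees of freedom and a two-sided Student-t
  p-value.  A pooled-variance t on winsorized values is available as an
  alternative.

A pathway is called differentially expressed only under the dual rule:
Benjamini-Hochberg q < alpha AND |dR| above the moderate-effect
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .faime import PathwayScoreMatrix

#: |dR| above this marks at least a moderate effect.
DR_MODERATE = 0.62897

#: Rescales the winsorized SD to the normal-theory SD at gamma = 0.2.
DR_SCALE = 0.642


def _check_gamma(gamma: float) -> None:
    if not 0 <= gamma < 0.5:
        raise ValueError(f"gamma must be in [0, 0.5), got {gamma}")


def winsorize(values, gamma: float = 0.2) -> np.ndarray:
    """Replace the floor(gamma*n) most extreme values in each tail by the
    nearest retained order statistic."""
    _check_gamma(gamma)
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values to winsorize")
    k = int(np.floor(gamma * n))
    if k == 0:
        return x.copy()
    srt = np.sort(x)
    lo, hi = srt[k], srt[n - k - 1]
    return np.clip(x, lo, hi)


def trimmed_mean(values, gamma: float = 0.2) -> float:
    """Mean of the central n - 2*floor(gamma*n) order statistics."""
    _check_gamma(gamma)
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    k = int(np.floor(gamma * n))
    return float(x[k : n - k].mean())


# -- vectorized internals (rows = pathways) ---------------------------------

def _winsorize_rows(x: np.ndarray, gamma: float) -> np.ndarray:
    n = x.shape[1]
    k = int(np.floor(gamma * n))
    if k == 0:
        return x
    srt = np.sort(x, axis=1)
    lo = srt[:, k : k + 1]
    hi = srt[:, n - k - 1 : n - k]
    return np.clip(x, lo, hi)


def _trimmed_mean_rows(x: np.ndarray, gamma: float) -> np.ndarray:
    n = x.shape[1]
    k = int(np.floor(gamma * n))
    srt = np.sort(x, axis=1)
    return srt[:, k : n - k].mean(axis=1)


def _winsorized_ss_rows(x: np.ndarray, gamma: float) -> np.ndarray:
    w = _winsorize_rows(x, gamma)
    return ((w - w.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)


def _dr_rows(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    na, nb = a.shape[1], b.shape[1]
    diff = _trimmed_mean_rows(a, gamma) - _trimmed_mean_rows(b, gamma)
    ss = _winsorized_ss_rows(a, gamma) + _winsorized_ss_rows(b, gamma)
    s_w = np.sqrt(ss / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        dr = DR_SCALE * diff / s_w
        dr = np.where((s_w == 0) & (diff == 0), 0.0, dr)
        dr = np.where((s_w == 0) & (diff != 0), np.sign(diff) * np.inf, dr)
    return dr


def _yuen_rows(
    a: np.ndarray, b: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    na, nb = a.shape[1], b.shape[1]
    ka, kb = int(np.floor(gamma * na)), int(np.floor(gamma * nb))
    ha, hb = na - 2 * ka, nb - 2 * kb
    if ha < 2 or hb < 2:
        raise ValueError(
            f"too few untrimmed observations (h_A={ha}, h_B={hb}); "
            "reduce gamma or supply larger groups"
        )
    diff = _trimmed_mean_rows(a, gamma) - _trimmed_mean_rows(b, gamma)
    va = _winsorized_ss_rows(a, gamma) / (na - 1)
    vb = _winsorized_ss_rows(b, gamma) / (nb - 1)
    da = (na - 1) * va / (ha * (ha - 1))
    db = (nb - 1) * vb / (hb * (hb - 1))
    denom = da + db
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(denom)
        df = denom**2 / (da**2 / (ha - 1) + db**2 / (hb - 1))
        t = np.where((denom == 0) & (diff == 0), 0.0, t)
        t = np.where((denom == 0) & (diff != 0), np.sign(diff) * np.inf, t)
        df = np.where(denom == 0, float(ha + hb - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, df, p


def _pooled_winsorized_t_rows(
    a: np.ndarray, b: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plain pooled-variance t on winsorized values (alternative to Yuen)."""
    wa = _winsorize_rows(a, gamma)
    wb = _winsorize_rows(b, gamma)
    na, nb = a.shape[1], b.shape[1]
    diff = wa.mean(axis=1) - wb.mean(axis=1)
    ss = ((wa - wa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (wb - wb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    sp = np.sqrt(ss / (na + nb - 2) * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / sp
    t = np.where((sp == 0) & (diff == 0), 0.0, t)
    t = np.where((sp == 0) & (diff != 0), np.sign(diff) * np.inf, t)
    df = np.full(t.shape, float(na + nb - 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, df, p


# -- public scalar operations ------------------------------------------------

def robust_effect_size_dr(group_a, group_b, gamma: float = 0.2) -> float:
    """Robust Cohen's-d analogue from trimmed means and pooled winsorized SD."""
    _check_gamma(gamma)
    a = np.asarray(group_a, dtype=float)[None, :]
    b = np.asarray(group_b, dtype=float)[None, :]
    if a.shape[1] < 5 or b.shape[1] < 5:
        raise ValueError("each group needs at least 5 observations")
    return float(_dr_rows(a, b, gamma)[0])


def winsorized_t_test(
    group_a, group_b, gamma: float = 0.2, method: str = "yuen"
) -> tuple[float, float, float]:
    """Two-sample test on trimmed/winsorized data.

    ``method="yuen"`` (default) is Yuen's Welch-type trimmed-mean test;
    ``method="pooled"`` is a pooled-variance t on winsorized values.
    Returns (t, df, two-sided p).
    """
    _check_gamma(gamma)
    a = np.asarray(group_a, dtype=float)[None, :]
    b = np.asarray(group_b, dtype=float)[None, :]
    if a.shape[1] < 5 or b.shape[1] < 5:
        raise ValueError("each group needs at least 5 observations")
    if method == "yuen":
        t, df, p = _yuen_rows(a, b, gamma)
    elif method == "pooled":
        t, df, p = _pooled_winsorized_t_rows(a, b, gamma)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(t[0]), float(df[0]), float(p[0])


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEPTable:
    """Per-pathway differential statistics and the dual-criterion call."""

    table: pd.DataFrame
    gamma: float
    alpha_q: float
    dr_threshold: float
    method: str = "yuen"
    groups: tuple[str, str] = ("A", "B")
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def dep_table(
    scores: PathwayScoreMatrix | pd.DataFrame,
    labels: pd.Series,
    group_a: str | None = None,
    group_b: str | None = None,
    gamma: float = 0.2,
    alpha_q: float = 0.05,
    dr_threshold: float = DR_MODERATE,
    method: str = "yuen",
) -> DEPTable:
    """Differential-pathway table comparing two sample groups.

    *labels* maps sample id -> group label; *group_a*/*group_b* default to
    the two labels in sorted order.  The test runs on raw scores; q-values
    are BH-adjusted across all tested pathways; ``significant`` requires
    q < alpha_q AND |dR| > dr_threshold.
    """
    if isinstance(scores, PathwayScoreMatrix):
        if scores.view != "raw":
            raise ValueError("differential statistics run on the raw view")
        sc = scores.scores
    else:
        sc = scores
    labels = labels.loc[[s for s in sc.columns if s in labels.index]]
    groups = sorted(labels.unique())
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(f"expected exactly 2 groups, found {groups}")
        group_a, group_b = groups
    sa = labels.index[labels == group_a]
    sb = labels.index[labels == group_b]
    if len(sa) < 5 or len(sb) < 5:
        raise ValueError(
            f"each group needs >= 5 samples (got {len(sa)} {group_a!r}, "
            f"{len(sb)} {group_b!r})"
        )
    a = sc[sa].to_numpy(dtype=float)
    b = sc[sb].to_numpy(dtype=float)

    if method == "yuen":
        t, df, p = _yuen_rows(a, b, gamma)
    elif method == "pooled":
        t, df, p = _pooled_winsorized_t_rows(a, b, gamma)
    else:
        raise ValueError(f"unknown method {method!r}")
    dr = _dr_rows(a, b, gamma)
    q = benjamini_hochberg(p)
    tm_a = _trimmed_mean_rows(a, gamma)
    tm_b = _trimmed_mean_rows(b, gamma)
    table = pd.DataFrame(
        {
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "dR": dr,
            f"trimmed_mean_{group_a}": tm_a,
            f"trimmed_mean_{group_b}": tm_b,
            "significant": (q < alpha_q) & (np.abs(dr) > dr_threshold),
        },
        index=sc.index,
    )
    return DEPTable(
        table=table,
        gamma=gamma,
        alpha_q=alpha_q,
        dr_threshold=dr_threshold,
        method=method,
        groups=(group_a, group_b),
        extra={"n_a": int(len(sa)), "n_b": int(len(sb))},
    )
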