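"""Cross-validated classification on pathway scores.

Two tasks are covered:

* patient-vs-control classification with L2-penalized logistic
  regression under repeated stratified k-fold cross-validation, where
  the differential-pathway selection (dual q/|dR| criterion) is redone
  inside every training fold so no information from held-out samples
  leaks into feature selection;
* progression prediction with nested cross-validation: within each
  outer training fold, pathways are ranked by a univariate trimmed-mean
  test and the top fraction kept, then an inner cross-validation tunes
  the single main hyper-parameter of the chosen model family (logistic
  regression, Gaussian naive Bayes, or random forest) before the outer
  held-out fold is scored.

All reports carry every held-out AUROC; the summary is the mean and SD
over all runs x folds.  Folds whose test set contains a single class
cannot yield an AUROC and are skipped and counted.  Stratified folds
are used throughout because the cohort class ratios (roughly 2:1) make
unstratified small folds frequently degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .dep import DR_MODERATE, _dr_rows, _yuen_rows, dep_table
from .faime import PathwayScoreMatrix

logger = logging.getLogger(__name__)

MODEL_GRIDS: dict[str, tuple] = {
    "logistic": (
        lambda seed: Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000)),
            ]
        ),
        {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    ),
    "naive_bayes": (
        lambda seed: GaussianNB(),
        {"var_smoothing": [1e-9, 1e-6, 1e-3]},
    ),
    "random_forest": (
        lambda seed: RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        {"min_samples_leaf": [1, 2, 4]},
    ),
}


@dataclass
class CVReport:
    """Held-out AUROCs from a (possibly repeated/nested) CV design."""

    design: dict
    records: pd.DataFrame  # run, fold, auroc, n_selected, n_test
    n_skipped_folds: int = 0
    fold_details: list = field(default_factory=list)

    @property
    def aurocs(self) -> np.ndarray:
        return self.records["auroc"].to_numpy()

    @property
    def mean_auroc(self) -> float:
        return float(self.aurocs.mean())

    @property
    def sd_auroc(self) -> float:
        return float(self.aurocs.std(ddof=1)) if len(self.records) > 1 else 0.0

    def summary(self) -> str:
        return (
            f"AUROC = {self.mean_auroc:.3f} +/- {self.sd_auroc:.3f} over "
            f"{len(self.records)} held-out folds "
            f"({self.n_skipped_folds} skipped)"
        )


def _as_frame(scores) -> pd.DataFrame:
    if isinstance(scores, PathwayScoreMatrix):
        if scores.view != "raw":
            raise ValueError("classification runs on the raw score view")
        return scores.scores
    return scores


def _binary_labels(labels: pd.Series, positive: str | None) -> tuple[pd.Series, str]:
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, found {classes}")
    if positive is None:
        positive = classes[1]
    return (labels == positive).astype(int), positive


def univariate_p(
    x_a: np.ndarray, x_b: np.ndarray, gamma: float = 0.2
) -> np.ndarray:
    """Per-row univariate two-sample p for feature ranking.

    Yuen's trimmed test when both groups are large enough for the
    trimming, otherwise Welch's t.
    """
    na, nb = x_a.shape[1], x_b.shape[1]
    ha = na - 2 * int(np.floor(gamma * na))
    hb = nb - 2 * int(np.floor(gamma * nb))
    if na >= 5 and nb >= 5 and ha >= 2 and hb >= 2:
        _, _, p = _yuen_rows(x_a, x_b, gamma)
    else:
        p = stats.ttest_ind(x_a, x_b, axis=1, equal_var=False).pvalue
    return np.nan_to_num(p, nan=1.0)


def repeated_cv_classifier(
    scores,
    labels: pd.Series,
    runs: int = 20,
    folds: int = 10,
    seed: int = 0,
    positive: str | None = None,
    gamma: float = 0.2,
    alpha_q: float = 0.05,
    dr_threshold: float = DR_MODERATE,
    C: float = 1.0,
    select_in_fold: bool = True,
    preselected: list[str] | None = None,
) -> CVReport:
    """Repeated stratified CV of an L2 logistic classifier with in-fold
    differential-pathway selection.

    In every training fold the dual-criterion caller (q < alpha_q and
    |dR| > dr_threshold) picks the features; if nothing passes, the
    single pathway with the largest |dR| is used (logged).  Setting
    ``select_in_fold=False`` with ``preselected`` fits on a fixed
    feature list instead — only useful to demonstrate selection leakage.
    """
    sc = _as_frame(scores)
    labels = labels.loc[sc.columns]
    y, positive = _binary_labels(labels, positive)
    x_all = sc.to_numpy(dtype=float).T  # samples x pathways
    yv = y.to_numpy()
    master = np.random.default_rng(seed)

    rows = []
    details = []
    n_skipped = 0
    for run in range(runs):
        run_seed = int(master.integers(2**31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=run_seed)
        for fold, (tr, te) in enumerate(skf.split(x_all, yv)):
            if len(np.unique(yv[te])) < 2:
                n_skipped += 1
                continue
            if select_in_fold:
                dt = dep_table(
                    sc.iloc[:, tr],
                    labels.iloc[tr],
                    gamma=gamma,
                    alpha_q=alpha_q,
                    dr_threshold=dr_threshold,
                )
                selected = list(dt.significant)
                if not selected:
                    selected = [dt.table["dR"].abs().idxmax()]
                    logger.info(
                        "run %d fold %d: no pathway passed the dual "
                        "criterion; falling back to top-1 by |dR|",
                        run,
                        fold,
                    )
            else:
                if preselected is None:
                    raise ValueError("preselected required when select_in_fold=False")
                selected = list(preselected)
            cols = [sc.index.get_loc(p) for p in selected]
            model = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("clf", LogisticRegression(C=C, max_iter=2000)),
                ]
            )
            model.fit(x_all[np.ix_(tr, cols)], yv[tr])
            prob = model.predict_proba(x_all[np.ix_(te, cols)])[:, 1]
            rows.append(
                {
                    "run": run,
                    "fold": fold,
                    "auroc": roc_auc_score(yv[te], prob),
                    "n_selected": len(selected),
                    "n_test": len(te),
                }
            )
            details.append(
                {"run": run, "fold": fold,
                 "test_samples": tuple(sc.columns[te]),
                 "train_samples": tuple(sc.columns[tr])}
            )
    if not rows:
        raise ValueError("every fold was degenerate; nothing to report")
    return CVReport(
        design={
            "task": f"classification ({positive} vs rest)",
            "model": "l2_logistic",
            "C": C,
            "runs": runs,
            "folds": folds,
            "stratified": True,
            "seed": seed,
            "select_in_fold": select_in_fold,
        },
        records=pd.DataFrame(rows),
        n_skipped_folds=n_skipped,
        fold_details=details,
    )


def nested_cv_progression(
    scores,
    labels: pd.Series,
    models: tuple[str, ...] = ("logistic", "naive_bayes", "random_forest"),
    k_fracs: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20),
    runs: int = 20,
    folds: int = 10,
    inner_folds: int = 3,
    seed: int = 0,
    positive: str = "evolving",
    gamma: float = 0.2,
) -> dict[tuple[str, float], CVReport]:
    """Nested CV over model families and top-k% univariate selection.

    Within each outer training fold, pathways are ranked by univariate
    trimmed-mean p (ties broken by |dR|) and the top ceil(k * m) kept;
    an inner stratified CV then tunes the model's main hyper-parameter
    before scoring the outer held-out fold.
    """
    sc = _as_frame(scores)
    labels = labels.loc[sc.columns]
    y, positive = _binary_labels(labels, positive)
    x_all = sc.to_numpy(dtype=float).T
    yv = y.to_numpy()
    m = sc.shape[0]

    out: dict[tuple[str, float], CVReport] = {}
    for model_name in models:
        if model_name not in MODEL_GRIDS:
            raise ValueError(f"unknown model {model_name!r}")
        for k in k_fracs:
            n_keep = max(1, int(np.ceil(k * m)))
            master = np.random.default_rng(seed)
            rows = []
            n_skipped = 0
            for run in range(runs):
                run_seed = int(master.integers(2**31))
                skf = StratifiedKFold(
                    n_splits=folds, shuffle=True, random_state=run_seed
                )
                for fold, (tr, te) in enumerate(skf.split(x_all, yv)):
                    if len(np.unique(yv[te])) < 2:
                        n_skipped += 1
                        continue
                    xa = x_all[tr][yv[tr] == 1].T
                    xb = x_all[tr][yv[tr] == 0].T
                    p = univariate_p(xa, xb, gamma)
                    dr = np.abs(_dr_rows(xa, xb, gamma)) if (
                        xa.shape[1] >= 5 and xb.shape[1] >= 5
                    ) else np.zeros(m)
                    order = np.lexsort((-dr, p))
                    cols = order[:n_keep]
                    build, grid = MODEL_GRIDS[model_name]
                    inner = StratifiedKFold(
                        n_splits=inner_folds, shuffle=True, random_state=run_seed
                    )
                    search = GridSearchCV(
                        build(run_seed),
                        grid,
                        scoring="roc_auc",
                        cv=inner,
                        n_jobs=1,
                    )
                    search.fit(x_all[np.ix_(tr, cols)], yv[tr])
                    prob = search.predict_proba(x_all[np.ix_(te, cols)])[:, 1]
                    rows.append(
                        {
                            "run": run,
                            "fold": fold,
                            "auroc": roc_auc_score(yv[te], prob),
                            "n_selected": n_keep,
                            "n_test": len(te),
                        }
                    )
            if not rows:
                raise ValueError("every fold was degenerate; nothing to report")
            out[(model_name, k)] = CVReport(
                design={
                    "task": f"progression ({positive})",
                    "model": model_name,
                    "k_frac": k,
                    "runs": runs,
                    "folds": folds,
                    "inner_folds": inner_folds,
                    "stratified": True,
                    "seed": seed,
                },
                records=pd.DataFrame(rows),
                n_skipped_folds=n_skipped,
            )
    return out


def permutation_null_auroc(
    scores,
    labels: pd.Series,
    n_permutations: int = 20,
    runs: int = 1,
    folds: int = 10,
    seed: int = 0,
    **cv_kwargs,
) -> dict:
    """Chance-level reference: mean held-out AUROC under label permutation.

    A single permuted labelling can chance-correlate with a dominant
    latent factor of the score matrix (pathway scores are strongly
    cross-correlated), so its CV AUROC is a high-variance draw around
    0.5; averaging over several independent permutations estimates the
    chance level properly.
    """
    sc = _as_frame(scores)
    labels = labels.loc[sc.columns]
    rng = np.random.default_rng(seed)
    per_perm = []
    for _ in range(n_permutations):
        permuted = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        rep = repeated_cv_classifier(
            sc, permuted, runs=runs, folds=folds,
            seed=int(rng.integers(2**31)), **cv_kwargs,
        )
        per_perm.append(rep.mean_auroc)
    return {
        "mean_auroc": float(np.mean(per_perm)),
        "per_permutation": per_perm,
        "n_permutations": n_permutations,
        "runs": runs,
        "folds": folds,
    }


def selection_leakage_demo(
    scores,
    labels: pd.Series,
    n_select: int = 10,
    runs: int = 10,
    folds: int = 10,
    seed: int = 0,
    gamma: float = 0.2,
) -> dict:
    """Quantify the AUROC inflation caused by selecting features on the
    full data set before cross-validation.

    Ranks pathways by univariate p on ALL samples, keeps the top
    *n_select*, and cross-validates a logistic model on that fixed list
    (the leaky protocol); compares with the same model selecting the top
    *n_select* inside each training fold (the honest protocol).  On
    label-independent data the leaky mean AUROC is optimistically
    biased; the honest one stays at chance.
    """
    sc = _as_frame(scores)
    labels = labels.loc[sc.columns]
    y, positive = _binary_labels(labels, None)
    xa = sc.loc[:, labels.index[y == 1]].to_numpy(dtype=float)
    xb = sc.loc[:, labels.index[y == 0]].to_numpy(dtype=float)
    p_full = univariate_p(xa, xb, gamma)
    top_full = list(sc.index[np.argsort(p_full)[:n_select]])

    leaky = repeated_cv_classifier(
        sc, labels, runs=runs, folds=folds, seed=seed,
        select_in_fold=False, preselected=top_full,
    )

    # honest: top-n univariate selection recomputed inside each fold
    x_all = sc.to_numpy(dtype=float).T
    yv = y.to_numpy()
    master = np.random.default_rng(seed)
    rows = []
    for run in range(runs):
        run_seed = int(master.integers(2**31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=run_seed)
        for fold, (tr, te) in enumerate(skf.split(x_all, yv)):
            if len(np.unique(yv[te])) < 2:
                continue
            p_tr = univariate_p(
                x_all[tr][yv[tr] == 1].T, x_all[tr][yv[tr] == 0].T, gamma
            )
            cols = np.argsort(p_tr)[:n_select]
            model = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("clf", LogisticRegression(max_iter=2000)),
                ]
            )
            model.fit(x_all[np.ix_(tr, cols)], yv[tr])
            prob = model.predict_proba(x_all[np.ix_(te, cols)])[:, 1]
            rows.append({"run": run, "fold": fold, "auroc":
                         roc_auc_score(yv[te], prob), "n_selected": n_select,
                         "n_test": len(te)})
    honest = pd.DataFrame(rows)
    return {
        "auroc_leaky": leaky.mean_auroc,
        "auroc_honest": float(honest["auroc"].mean()),
        "inflation": leaky.mean_auroc - float(honest["auroc"].mean()),
        "n_select": n_select,
        "runs": runs,
        "folds": folds,
    }
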