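"""Subject stratification from module activities.

Subject-level module activities (rows of H) are quantile normalized, the
modules most associated with the disease state are selected by Wilcoxon
rank-sum p-value, and a random forest (2000 trees) is evaluated by stratified
10-fold cross-validation (AUROC / AUPR on pooled out-of-fold scores; operating
point by Youden's index).  Multi-run model selection follows the rule: best
mean AUROC over the top-k curve, breaking near-ties (within 0.01) by lowest
reconstruction RMSE.  External-cohort validation trains on the discovery H and
tests on activities obtained by fixed-loadings projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu, rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "QuantileNormalizer",
    "quantile_normalize",
    "top_ranking_modules",
    "StratificationReport",
    "stratify",
    "auroc_vs_topk",
    "RunComparison",
    "compare_runs",
    "select_best_run",
    "youden_cutoff",
    "evaluate_validation",
]


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map every feature column to the mean order-statistic distribution.

    ``fit`` computes the reference distribution (the mean across columns of
    the sorted column values); ``transform`` replaces each column's values by
    the reference quantiles at their ranks (ties averaged), so monotone
    transforms of a column normalize identically.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-d matrix with >= 2 rows")
        n = X.shape[0]
        self.reference_ = np.sort(X, axis=0).mean(axis=1)
        self.quantiles_ = (np.arange(n) + 0.5) / n
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            q = (rankdata(X[:, j], method="average") - 0.5) / n
            out[:, j] = np.interp(q, self.quantiles_, self.reference_)
        return out


def quantile_normalize(H: np.ndarray) -> np.ndarray:
    """Classic quantile normalization of a subjects x modules activity matrix."""
    return QuantileNormalizer().fit_transform(H)


def top_ranking_modules(H: np.ndarray, labels, k: int = 100, module_ids=None):
    """Modules ranked by Wilcoxon rank-sum p-value against binary labels.

    Ties in p are broken by effect magnitude |U - n1*n2/2| (larger first),
    then by module index.  Returns the first ``k`` module ids.
    """
    H = np.asarray(H, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must be binary")
    if not 1 <= k <= H.shape[1]:
        raise ValueError(f"k must be in [1, {H.shape[1]}]")
    a = H[labels == uniq[0]]
    b = H[labels == uniq[1]]
    half = len(a) * len(b) / 2.0
    ps, mags = np.empty(H.shape[1]), np.empty(H.shape[1])
    for j in range(H.shape[1]):
        res = mannwhitneyu(a[:, j], b[:, j], alternative="two-sided", method="asymptotic")
        ps[j] = res.pvalue
        mags[j] = abs(res.statistic - half)
    ids = np.asarray(module_ids if module_ids is not None else np.arange(H.shape[1]))
    order = sorted(range(H.shape[1]), key=lambda j: (ps[j], -mags[j], j))
    return ids[order][:k]


@dataclass
class StratificationReport:
    """Classifier performance plus the Youden operating point."""

    auroc: float
    aupr: float
    fold_aurocs: list = field(default_factory=list)
    cutoff: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    precision: float = np.nan
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None


def _as_binary(labels):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return (labels == classes[1]).astype(int)


def stratify(
    features,
    labels,
    n_trees: int = 2000,
    folds: int = 10,
    seed=None,
) -> StratificationReport:
    """Random-forest stratification with stratified k-fold cross-validation.

    Out-of-fold probability scores are pooled before computing AUROC and AUPR;
    per-fold AUROCs are also reported.  Deterministic under ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    if X.ndim == 1:
        X = X[:, None]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    fold_aurocs = []
    for tr, te in skf.split(X, y):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        rf.fit(X[tr], y[tr])
        proba = rf.predict_proba(X[te])[:, list(rf.classes_).index(1)]
        oof[te] = proba
        if len(np.unique(y[te])) == 2:
            fold_aurocs.append(float(roc_auc_score(y[te], proba)))
    auroc = float(roc_auc_score(y, oof))
    aupr = float(average_precision_score(y, oof))
    cutoff, sens, spec, prec = youden_cutoff(oof, y)
    return StratificationReport(
        auroc=auroc,
        aupr=aupr,
        fold_aurocs=fold_aurocs,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        scores=oof,
        labels=y,
    )


def auroc_vs_topk(
    H,
    labels,
    k_grid,
    n_trees: int = 2000,
    folds: int = 10,
    seed=None,
    quantile: bool = True,
) -> dict:
    """AUROC of stratify() on the top-k ranked modules, for each k in the grid."""
    H = np.asarray(H, dtype=float)
    k_grid = list(k_grid)
    if any(k < 1 or k > H.shape[1] for k in k_grid):
        raise ValueError("k_grid values must be in [1, number of modules]")
    feats = quantile_normalize(H) if quantile else H
    ranked = top_ranking_modules(feats, labels, k=H.shape[1])
    curve = {}
    for k in k_grid:
        rep = stratify(feats[:, ranked[:k]], labels, n_trees=n_trees, folds=folds, seed=seed)
        curve[int(k)] = rep.auroc
    return curve


@dataclass
class RunComparison:
    """Summary of one random restart of the factorization."""

    seed: int
    auroc_curve: dict  # top-k -> AUROC
    rmse: float

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(list(self.auroc_curve.values())))


def compare_runs(fits, labels, k_grid, n_trees: int = 2000, folds: int = 10, seed=None):
    """Build RunComparison records for a list of fitted factorization models."""
    runs = []
    for fit in fits:
        n_active = max(fit.n_modules_, 1)
        grid = [k for k in k_grid if k <= n_active] or [n_active]
        curve = auroc_vs_topk(
            fit.subject_factors_[:, fit.active_modules_]
            if fit.n_modules_
            else fit.subject_factors_,
            labels,
            grid,
            n_trees=n_trees,
            folds=folds,
            seed=seed,
        )
        runs.append(
            RunComparison(
                seed=fit.random_state if fit.random_state is not None else -1,
                auroc_curve=curve,
                rmse=fit.rmse_,
            )
        )
    return runs


def select_best_run(runs, auroc_tol: float = 0.01):
    """Pick the run with the best mean AUROC; break near-ties by lowest RMSE.

    Among runs whose mean AUROC is within ``auroc_tol`` of the best, the one
    with the smallest reconstruction RMSE wins (first on exact ties).
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs to select from")
    best_auroc = max(r.mean_auroc for r in runs)
    candidates = [r for r in runs if r.mean_auroc >= best_auroc - auroc_tol]
    return min(candidates, key=lambda r: (r.rmse, runs.index(r)))


def youden_cutoff(scores, labels):
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are the observed scores (prediction: score >= cutoff);
    ties in J resolve to the lower cutoff.  Returns (cutoff, sensitivity,
    specificity, precision).
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    best = None
    for cut in np.sort(np.unique(s)):
        pred = s >= cut
        tp = np.sum(pred & (y == 1))
        fn = np.sum(~pred & (y == 1))
        tn = np.sum(~pred & (y == 0))
        fp = np.sum(pred & (y == 0))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        if best is None or j > best[0] + 1e-12:
            best = (j, cut, sens, spec, prec)
    _, cut, sens, spec, prec = best
    return float(cut), float(sens), float(spec), float(prec)


def evaluate_validation(
    reference,
    val_tensor,
    val_labels,
    ibd_module_ids,
    reference_labels,
    n_trees: int = 2000,
    seed=None,
    quantile: bool = True,
) -> StratificationReport:
    """Train on discovery-module activities, test on a projected cohort.

    ``reference`` is a fitted factorization; the validation tensor is
    projected through the fixed taxon loadings, the classifier is trained on
    the discovery subjects' activities in the flagged modules
    (``ibd_module_ids``) and tested on the projected activities.
    """
    ids = list(ibd_module_ids)
    if not ids:
        raise ValueError("ibd_module_ids must be nonempty")
    active = set(int(c) for c in reference.active_modules_)
    if not set(int(c) for c in ids) <= active:
        raise ValueError("ibd_module_ids must be active modules of the reference fit")
    H_train = reference.subject_factors_[:, ids]
    H_proj, _ = reference.project(val_tensor)
    H_test = H_proj[:, ids]
    if quantile:
        qn = QuantileNormalizer().fit(H_train)
        H_train = qn.transform(H_train)
        H_test = qn.transform(H_test)
    y_train = _as_binary(reference_labels)
    y_test = _as_binary(val_labels)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(H_train, y_train)
    proba = rf.predict_proba(H_test)[:, list(rf.classes_).index(1)]
    cutoff, sens, spec, prec = youden_cutoff(proba, y_test)
    return StratificationReport(
        auroc=float(roc_auc_score(y_test, proba)),
        aupr=float(average_precision_score(y_test, proba)),
        fold_aurocs=[],
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        scores=proba,
        labels=y_test,
    )
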