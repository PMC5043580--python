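"""L1-regularized classification of peaks from motif grammar, and metrics.

The core model is logistic regression with an L1 penalty fit over a
descending grid of penalties lambda (glmnet-style: 100 log-spaced values
from the smallest lambda that zeroes every coefficient down to 0.001x that
value).  Ten-fold cross-validated AUC selects lambda either by the classic
1-standard-error rule, or by the knowledge-based rule: compress the model to
the largest penalty at which a motif known a priori to belong in the model
(the "anchor", e.g. the assayed factor's own binding element) still carries
a nonzero coefficient.

Features are standardized internally before penalized fitting; coefficients
are reported on the original motifs-per-kb scale.  Comparator classifiers
(linear-kernel max-margin with a CV-chosen penalty C, and a tree ensemble
with conventional defaults) are library-backed and exposed through the same
FittedModel/predict interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureMatrix, POSITIVE

#: coefficients below this magnitude are treated as exactly zero
COEF_TOL = 1e-8

_UNDEFINED = float("nan")


class AnchorNotInformativeError(ValueError):
    """The anchor motif never enters the lasso path."""


@dataclass
class LassoPath:
    lambdas: np.ndarray  # strictly decreasing
    coefficients: np.ndarray  # n_lambda x p, original feature scale
    intercepts: np.ndarray  # per-lambda
    cv_auc_mean: np.ndarray
    cv_auc_se: np.ndarray
    n_folds: int
    seed: int
    motif_ids: list[str]

    def __post_init__(self):
        if not np.all(np.diff(self.lambdas) < 0):
            raise ValueError("lambda grid must be strictly decreasing")

    def index_of(self, lam: float) -> int:
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        if not np.isclose(self.lambdas[i], lam, rtol=1e-9, atol=0.0):
            raise ValueError(f"lambda {lam} is not on the fitted grid")
        return i

    def active_at(self, lam: float) -> dict[str, float]:
        row = self.coefficients[self.index_of(lam)]
        return {
            m: float(c)
            for m, c in zip(self.motif_ids, row)
            if abs(c) > COEF_TOL
        }


@dataclass
class FittedModel:
    kind: str  # lasso | linear_max_margin | tree_ensemble
    motif_ids: list[str]
    hyperparams: dict
    active_features: dict[str, float]
    coef: np.ndarray | None = None  # lasso: full coefficient vector
    intercept: float | None = None
    estimator: object | None = None  # sklearn estimator (comparators)
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, std)

    @property
    def size(self) -> int:
        return len(self.active_features)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# helpers


def _as_xy(features, labels, positive_label):
    if isinstance(features, FeatureMatrix):
        X = features.values
        ids = list(features.motif_ids)
        if labels is None:
            labels = features.labels
    else:
        X = np.asarray(features, dtype=float)
        ids = [f"f{i}" for i in range(X.shape[1])]
    if labels is None:
        raise ValueError("labels are required")
    y = binary_labels(labels, positive_label)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return X, y, ids


def binary_labels(labels, positive_label=POSITIVE) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu":
        return (arr != 0).astype(int)
    return (arr == positive_label).astype(int)


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)  # constant columns stay constant (=> coef 0)
    return (X - mu) / sd, mu, sd


def _lambda_grid(Xs, y, n_lambdas, min_ratio):
    # smallest lambda with an all-zero solution: max absolute gradient of the
    # mean log-loss at the null model
    r = y - y.mean()
    lmax = float(np.abs(Xs.T @ r).max() / len(y))
    if lmax <= 0:
        raise ValueError("features carry no signal; lambda grid undefined")
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def _l1_logistic(Xs, y, lam, seed):
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (len(y) * lam),
        solver="liblinear",
        intercept_scaling=100.0,
        tol=1e-7,
        max_iter=10000,
        random_state=seed,
    )
    clf.fit(Xs, y)
    w = clf.coef_[0].copy()
    w[np.abs(w) < COEF_TOL] = 0.0
    return w, float(clf.intercept_[0])


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


# ---------------------------------------------------------------------------
# lasso path


def fit_lasso_path(
    features,
    labels=None,
    n_folds: int = 10,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    seed: int = 0,
    positive_label: str = POSITIVE,
) -> LassoPath:
    """L1 logistic path with per-lambda cross-validated AUC.

    Fold assignment is stratified and seeded; the lambda grid is computed
    once on the full standardized data and shared across folds.  Reported
    coefficients are mapped back to the original feature scale.
    """
    from sklearn.model_selection import StratifiedKFold

    X, y, ids = _as_xy(features, labels, positive_label)
    if len(y) < n_folds:
        raise ValueError("need at least one row per CV fold")
    Xs_full, mu, sd = _standardize(X)
    lambdas = _lambda_grid(Xs_full, y, n_lambdas, lambda_min_ratio)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_aucs = np.zeros((n_folds, len(lambdas)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, mtr, str_ = _standardize(X[tr])
        Xte = (X[te] - mtr) / str_
        for i, lam in enumerate(lambdas):
            w, b = _l1_logistic(Xtr, y[tr], lam, seed)
            fold_aucs[f, i] = roc_auc(Xte @ w + b, y[te]).auc

    coefs = np.zeros((len(lambdas), X.shape[1]))
    intercepts = np.zeros(len(lambdas))
    for i, lam in enumerate(lambdas):
        w, b = _l1_logistic(Xs_full, y, lam, seed)
        coefs[i] = w / sd
        intercepts[i] = b - float((w * mu / sd).sum())

    return LassoPath(
        lambdas=lambdas,
        coefficients=coefs,
        intercepts=intercepts,
        cv_auc_mean=fold_aucs.mean(axis=0),
        cv_auc_se=fold_aucs.std(axis=0, ddof=1) / np.sqrt(n_folds),
        n_folds=n_folds,
        seed=seed,
        motif_ids=ids,
    )


def select_lambda_1se(path: LassoPath) -> float:
    """Largest lambda whose CV AUC is within 1 s.e. of the best CV AUC."""
    i_best = int(np.argmax(path.cv_auc_mean))  # first occurrence = largest lambda
    cutoff = path.cv_auc_mean[i_best] - path.cv_auc_se[i_best]
    ok = np.nonzero(path.cv_auc_mean >= cutoff - 1e-15)[0]
    return float(path.lambdas[ok[0]])


def select_lambda_knowledge(
    path: LassoPath, anchors: str | Sequence[str], mode: str = "any"
) -> float:
    """Knowledge-based compression: largest lambda retaining the anchor(s).

    mode "any": at least one anchor coefficient nonzero; "all": every anchor
    nonzero.  If the condition holds non-contiguously along the path the
    largest qualifying lambda is still returned, with a warning.
    """
    if isinstance(anchors, str):
        anchors = [anchors]
    missing = [a for a in anchors if a not in path.motif_ids]
    if missing:
        raise KeyError(f"anchor motif(s) not in the feature set: {missing}")
    cols = [path.motif_ids.index(a) for a in anchors]
    nonzero = np.abs(path.coefficients[:, cols]) > COEF_TOL
    cond = nonzero.any(axis=1) if mode == "any" else nonzero.all(axis=1)
    if not cond.any():
        raise AnchorNotInformativeError(
            f"anchor not informative: {list(anchors)} never active on the path"
        )
    j = int(np.argmax(cond))
    if not cond[j:].all():
        warnings.warn(
            "anchor condition holds non-contiguously along the path; "
            "returning the largest qualifying lambda",
            stacklevel=2,
        )
    return float(path.lambdas[j])


def model_at(path: LassoPath, lam: float) -> FittedModel:
    """Sparse logistic model at one grid lambda."""
    i = path.index_of(lam)
    return FittedModel(
        kind="lasso",
        motif_ids=list(path.motif_ids),
        hyperparams={"lambda": float(path.lambdas[i]), "seed": path.seed},
        active_features=path.active_at(lam),
        coef=path.coefficients[i].copy(),
        intercept=float(path.intercepts[i]),
    )


# ---------------------------------------------------------------------------
# comparators


def fit_comparators(
    features,
    labels=None,
    c_grid: Sequence[float] = tuple(10.0 ** np.arange(-5, 1)),
    n_folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    positive_label: str = POSITIVE,
) -> list[FittedModel]:
    """Linear-kernel max-margin and tree-ensemble comparator models.

    The margin penalty C is chosen by seeded stratified CV (AUC) over decade
    steps; the tree ensemble uses conventional defaults (500 trees, sqrt(p)
    features per split).  Both are acknowledged library-backed comparators.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    X, y, ids = _as_xy(features, labels, positive_label)
    Xs, mu, sd = _standardize(X)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    mean_aucs = []
    for c in c_grid:
        aucs = []
        for tr, te in folds:
            Xtr, mtr, str_ = _standardize(X[tr])
            svc = SVC(kernel="linear", C=c, random_state=seed)
            svc.fit(Xtr, y[tr])
            aucs.append(roc_auc(svc.decision_function((X[te] - mtr) / str_), y[te]).auc)
        mean_aucs.append(float(np.mean(aucs)))
    best_c = float(c_grid[int(np.argmax(mean_aucs))])
    svc = SVC(kernel="linear", C=best_c, random_state=seed)
    svc.fit(Xs, y)
    w = svc.coef_[0]
    svm_model = FittedModel(
        kind="linear_max_margin",
        motif_ids=ids,
        hyperparams={"C": best_c, "seed": seed, "cv_auc": dict(zip(map(float, c_grid), mean_aucs))},
        active_features={m: float(c) for m, c in zip(ids, w) if abs(c) > COEF_TOL},
        estimator=svc,
        scaler=(mu, sd),
    )

    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed
    )
    rf.fit(X, y)
    rf_model = FittedModel(
        kind="tree_ensemble",
        motif_ids=ids,
        hyperparams={"n_trees": n_trees, "max_features": "sqrt", "seed": seed},
        active_features={
            m: float(v) for m, v in zip(ids, rf.feature_importances_) if v > 0
        },
        estimator=rf,
    )
    return [svm_model, rf_model]


# ---------------------------------------------------------------------------
# prediction and metrics


def predict(model: FittedModel, features) -> np.ndarray:
    """Per-row score in [0, 1]; feature columns are aligned by motif id."""
    if isinstance(features, FeatureMatrix):
        missing = [m for m in model.motif_ids if m not in features.motif_ids]
        if missing:
            raise KeyError(f"features lack model columns: {missing[:5]}")
        order = [features.motif_ids.index(m) for m in model.motif_ids]
        X = features.values[:, order]
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(model.motif_ids):
            raise ValueError("feature column count does not match the model")
    if model.kind == "lasso":
        return _sigmoid(X @ model.coef + model.intercept)
    if model.kind == "linear_max_margin":
        mu, sd = model.scaler
        return _sigmoid(model.estimator.decision_function((X - mu) / sd))
    if model.kind == "tree_ensemble":
        return model.estimator.predict_proba(X)[:, 1]
    raise ValueError(f"unknown model kind {model.kind!r}")


def confusion(
    scores, labels, cutoff: float = 0.5, positive_label: str = POSITIVE
) -> ConfusionCounts:
    """Threshold scores at ``cutoff`` (>= is positive) and count outcomes."""
    s = np.asarray(scores, dtype=float)
    y = binary_labels(labels, positive_label)
    pred = s >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def _ratio(num, den):
    return _UNDEFINED if den == 0 else num / den


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN if no actual positives."""
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN if no actual negatives."""
    return _ratio(c.tn, c.tn + c.fp)


def ppv(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN if nothing was predicted positive."""
    return _ratio(c.tp, c.tp + c.fp)


def fdr(c: ConfusionCounts) -> float:
    """FP / (TP + FP) = 1 - PPV; NaN if nothing was predicted positive."""
    return _ratio(c.fp, c.tp + c.fp)


def roc_auc(scores, labels, positive_label: str = POSITIVE) -> RocCurve:
    """ROC curve from a threshold sweep; AUC is the trapezoidal area.

    Tied scores collapse to single curve points, so the area equals the
    Mann-Whitney (average-rank) statistic.
    """
    from sklearn.metrics import roc_curve as _sk_roc

    s = np.asarray(scores, dtype=float)
    y = binary_labels(labels, positive_label)
    if y.min() == y.max():
        raise ValueError("ROC needs both classes")
    fpr, tpr, thr = _sk_roc(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))
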