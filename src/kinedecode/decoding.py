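"""Cross-validated linear decoding of gender, traits, and preferences.

Gender is classified with a linear SVM (squared-hinge / L2 penalty,
tolerance 1e-5).  Continuous targets are predicted with Bayesian
linear regression (the primary family, giving posterior-mean weights
and predictive uncertainty) or principal-component regression.
Evaluation is 5-fold cross-validation with per-fold R^2 / RMSE (or
accuracy) averaged across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import BayesianRidge, LinearRegression
from sklearn.svm import LinearSVC

__all__ = [
    "TRAIT_NAMES",
    "GENRE_NAMES",
    "LabeledDataset",
    "FoldAssignment",
    "TrainedLinearModel",
    "RegressionEvaluation",
    "ClassificationEvaluation",
    "make_folds",
    "fit_linear_svm",
    "fit_bayesian_regression",
    "fit_pcr",
    "predict",
    "evaluate_regression",
    "crossval_experiment",
]

TRAIT_NAMES = (
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
)
GENRE_NAMES = (
    "blues",
    "country",
    "dance",
    "jazz",
    "metal",
    "pop",
    "rap",
    "reggae",
    "rock",
    "soul",
    "funk",
    "oldie",
)


@dataclass
class LabeledDataset:
    """Feature matrix plus participant-level labels resolved per sample."""

    features: np.ndarray  # (N, F)
    sample_ids: list[tuple[str, str]]  # (participant, stimulus) per row
    labels: pd.DataFrame  # indexed by participant id

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if len(self.sample_ids) != self.features.shape[0]:
            raise ValueError("one sample id per feature row required")
        if not np.isfinite(self.features).all():
            raise ValueError("missing or non-finite features")
        missing = {p for p, _ in self.sample_ids} - set(self.labels.index.astype(str))
        if missing:
            raise ValueError(f"participants without labels: {sorted(missing)[:5]}")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def participants(self) -> np.ndarray:
        return np.array([p for p, _ in self.sample_ids])

    def target_values(self, target: str) -> np.ndarray:
        """Per-sample label vector for ``target`` (a labels column)."""
        if target not in self.labels.columns:
            raise KeyError(f"unknown target {target!r}")
        col = self.labels[target]
        return col.loc[self.participants].to_numpy()


@dataclass
class FoldAssignment:
    fold_index: np.ndarray  # (N,) ints in [0, k)
    k: int
    seed: int
    mode: str  # random | grouped

    def __post_init__(self) -> None:
        self.fold_index = np.asarray(self.fold_index, dtype=int)
        counts = np.bincount(self.fold_index, minlength=self.k)
        if counts.size != self.k or (counts == 0).any():
            raise ValueError("every fold must receive at least one sample")
        if self.mode == "random" and counts.max() - counts.min() > 1:
            raise ValueError("random folds must be balanced to within one sample")


def make_folds(
    n: int,
    k: int = 5,
    seed: int = 0,
    groups: np.ndarray | list | None = None,
) -> FoldAssignment:
    """Seeded k-fold split; grouped mode keeps each participant in one fold."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    fold_index = np.empty(n, dtype=int)
    if groups is None:
        order = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(order, k)):
            fold_index[chunk] = f
        mode = "random"
    else:
        groups = np.asarray(groups)
        if groups.shape != (n,):
            raise ValueError("groups must give one id per sample")
        unique = np.unique(groups)
        if unique.size < k:
            raise ValueError(f"{unique.size} groups cannot fill {k} folds")
        shuffled = rng.permutation(unique)
        group_fold = {}
        for f, chunk in enumerate(np.array_split(shuffled, k)):
            for g in chunk:
                group_fold[g] = f
        fold_index = np.array([group_fold[g] for g in groups])
        mode = "grouped"
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed, mode=mode)


@dataclass
class TrainedLinearModel:
    """Linear decision/regression function w . x + b with provenance."""

    weights: np.ndarray  # (F,)
    intercept: float
    family: str  # svm | bayesian | pcr
    fold: int = -1
    predictive_noise: float = 0.0  # bayesian: sqrt(1/alpha_)
    target_name: str = ""
    extra: dict = field(default_factory=dict, repr=False)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept


def fit_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-5,
    C: float = 1.0,
    fold: int = -1,
) -> TrainedLinearModel:
    """Linear SVM with squared-hinge (L2) penalty; stops at gap <= tol."""
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("linear SVM needs exactly two classes")
    clf = LinearSVC(
        loss="squared_hinge", tol=tol, C=C, dual="auto", max_iter=100_000, random_state=0
    )
    clf.fit(X, y)
    return TrainedLinearModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        family="svm",
        fold=fold,
        extra={"classes": clf.classes_.tolist()},
    )


def fit_bayesian_regression(X: np.ndarray, y: np.ndarray, fold: int = -1) -> TrainedLinearModel:
    """Bayesian ridge: Gaussian weight prior, evidence-maximized precisions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(y).all():
        raise ValueError("non-finite targets")
    if np.ptp(y) == 0:  # degenerate constant target: intercept-only model
        return TrainedLinearModel(
            weights=np.zeros(X.shape[1]),
            intercept=float(y[0]),
            family="bayesian",
            fold=fold,
            predictive_noise=0.0,
        )
    reg = BayesianRidge()
    reg.fit(X, y)
    return TrainedLinearModel(
        weights=reg.coef_.copy(),
        intercept=float(reg.intercept_),
        family="bayesian",
        fold=fold,
        predictive_noise=float(np.sqrt(1.0 / reg.alpha_)),
        extra={"estimator": reg},
    )


def fit_pcr(
    X: np.ndarray,
    y: np.ndarray,
    variance_kept: float = 0.95,
    fold: int = -1,
) -> TrainedLinearModel:
    """PCA projection keeping >= ``variance_kept`` of variance, then OLS.

    The component-space fit is composed back into a full-length weight
    vector so importance attribution sees the same shape as the other
    families.
    """
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD; components = rows of Vt
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    nonzero = var > var[0] * 1e-12 if var.size and var[0] > 0 else np.zeros_like(var, bool)
    if not nonzero.any():
        return TrainedLinearModel(
            weights=np.zeros(X.shape[1]),
            intercept=float(y.mean()),
            family="pcr",
            fold=fold,
        )
    var = var[nonzero]
    Vt = Vt[nonzero]
    frac = np.cumsum(var) / var.sum()
    n_comp = int(np.searchsorted(frac, variance_kept - 1e-12) + 1)
    Vt = Vt[:n_comp]
    Z = Xc @ Vt.T
    ols = LinearRegression()
    ols.fit(Z, y)
    w = Vt.T @ ols.coef_
    b = float(ols.intercept_ - mean @ w)
    return TrainedLinearModel(
        weights=w,
        intercept=b,
        family="pcr",
        fold=fold,
        extra={"n_components": n_comp},
    )


def predict(
    model: TrainedLinearModel, X: np.ndarray, return_std: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Point predictions; for Bayesian models optionally posterior std."""
    mean = model.decision_values(X)
    if not return_std:
        return mean
    est = model.extra.get("estimator")
    if model.family != "bayesian" or est is None:
        raise ValueError("predictive std is only available for fitted Bayesian models")
    _, std = est.predict(np.asarray(X, dtype=float), return_std=True)
    return mean, std


def evaluate_regression(y_true, y_pred) -> tuple[float, float]:
    """(R^2, RMSE); errors out when y_true has zero variance."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length vectors of at least 2 values")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: zero variance in y_true")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return r2, rmse


@dataclass
class RegressionEvaluation:
    target_name: str
    family: str
    per_fold_r2: list[float]
    per_fold_rmse: list[float]

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_fold_r2))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.per_fold_rmse))


@dataclass
class ClassificationEvaluation:
    target_name: str
    family: str
    per_fold_accuracy: list[float]
    confusion_counts: np.ndarray  # (2, 2) ints, rows = true class

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))


def crossval_experiment(
    data: LabeledDataset,
    target: str,
    family: str,
    folds: FoldAssignment,
    **fit_kwargs,
):
    """Train/evaluate one model per fold; returns (evaluation, models).

    The returned per-fold models feed the joint-importance accumulation.
    """
    if family == "svm" and target != "gender":
        raise ValueError("the svm family is reserved for gender classification")
    if family in ("bayesian", "pcr") and target == "gender":
        raise ValueError(f"{family} regression needs a continuous target")
    y = data.target_values(target)
    X = data.features
    models: list[TrainedLinearModel] = []

    if family == "svm":
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("gender must be binary")
        accs, confusion = [], np.zeros((2, 2), dtype=int)
        for f in range(folds.k):
            test = folds.fold_index == f
            model = fit_linear_svm(X[~test], y[~test], fold=f, **fit_kwargs)
            model.target_name = target
            scores = model.decision_values(X[test])
            pred = np.where(scores > 0, model.extra["classes"][1], model.extra["classes"][0])
            accs.append(float(np.mean(pred == y[test])))
            for t, p in zip(y[test], pred):
                confusion[int(t == classes[1]), int(p == classes[1])] += 1
            models.append(model)
        return (
            ClassificationEvaluation(
                target_name=target,
                family=family,
                per_fold_accuracy=accs,
                confusion_counts=confusion,
            ),
            models,
        )

    fitter = {"bayesian": fit_bayesian_regression, "pcr": fit_pcr}.get(family)
    if fitter is None:
        raise ValueError(f"unknown family {family!r}")
    r2s, rmses = [], []
    for f in range(folds.k):
        test = folds.fold_index == f
        model = fitter(X[~test], y[~test], fold=f, **fit_kwargs)
        model.target_name = target
        r2, rmse = evaluate_regression(y[test], model.decision_values(X[test]))
        r2s.append(r2)
        rmses.append(rmse)
        models.append(model)
    return (
        RegressionEvaluation(
            target_name=target, family=family, per_fold_r2=r2s, per_fold_rmse=rmses
        ),
        models,
    )
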