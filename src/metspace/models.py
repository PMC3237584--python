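"""Metabolite-likeness classifiers: Random Forest, RBF-SVM, and a
from-scratch Naïve Bayes, with 5-fold cross-validated metaparameter tuning.

Every model, whatever the descriptor set, emits a metabolite-likeness
score in [0, 1]: the fraction of trees voting "metabolite" for RF, a
Platt-calibrated posterior for SVM, and the exact posterior for NB.  A
molecule scoring at or above the cutoff (default 0.5, the theoretical
optimum for balanced training data) is called a metabolite.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import roc_auc

METABOLITE_CLASS = 1

CLASSIFIERS = ("rf", "svm", "nb")


@dataclass
class ModelSpec:
    classifier: str  # rf | svm | nb
    descriptor: str  # atom_counts | pp_desc | ecfp4 | fcfp4 | mdl_keys
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")


class NaiveBayes:
    """Naïve Bayes with Bernoulli per-bit likelihoods (binary features,
    additive smoothing) or per-class Gaussian likelihoods (continuous
    descriptors); prior 0.5 for balanced data.
    """

    def __init__(self, smoothing: float = 1.0, mode: str | None = None, prior: float = 0.5):
        if smoothing <= 0:
            raise ValueError("smoothing must be positive")
        self.smoothing = smoothing
        self.mode = mode  # None -> infer from data
        self.prior = prior

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NaiveBayes":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("single-class training data")
        if self.mode is None:
            self.mode = "bernoulli" if np.isin(X, (0.0, 1.0)).all() else "gaussian"
        self.classes_ = np.array([0, 1])
        if self.mode == "bernoulli":
            s = self.smoothing
            self.theta_ = np.stack(
                [(X[y == c].sum(axis=0) + s) / ((y == c).sum() + 2 * s) for c in (0, 1)]
            )
        else:
            self.mean_ = np.stack([X[y == c].mean(axis=0) for c in (0, 1)])
            var = np.stack([X[y == c].var(axis=0) for c in (0, 1)])
            # variance floor keeps constant features from producing infinities
            floor = 1e-9 * max(X.var(axis=0).max(), 1.0)
            self.var_ = np.maximum(var, floor)
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        log_prior = np.log([1.0 - self.prior, self.prior])
        if self.mode == "bernoulli":
            log_t = np.log(self.theta_)
            log_1mt = np.log(1.0 - self.theta_)
            return X @ log_t.T + (1.0 - X) @ log_1mt.T + log_prior
        ll = np.empty((len(X), 2))
        for c in (0, 1):
            ll[:, c] = -0.5 * np.sum(
                np.log(2.0 * np.pi * self.var_[c]) + (X - self.mean_[c]) ** 2 / self.var_[c],
                axis=1,
            )
        return ll + log_prior

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _platt_fit(f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt sigmoid P(y=1|f) = 1 / (1 + exp(A f + B)) with smoothed targets."""
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    t = np.where(y == 1, (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0))

    def nll(params):
        a, b = params
        p = np.clip(expit(-(a * f + b)), 1e-12, 1 - 1e-12)
        return -np.sum(t * np.log(p) + (1 - t) * np.log(1 - p))

    x0 = np.array([-1.0, np.log((n0 + 1.0) / (n1 + 1.0))])
    res = minimize(nll, x0, method="L-BFGS-B")
    return float(res.x[0]), float(res.x[1])


class PlattSVC:
    """RBF-SVM with Platt sigmoid calibration fitted on training decision values."""

    def __init__(self, gamma: float, C: float, seed: int | None = None):
        self.svc = SVC(kernel="rbf", gamma=gamma, C=C, random_state=seed)

    def fit(self, X, y) -> "PlattSVC":
        self.svc.fit(X, y)
        f = self.svc.decision_function(X)
        self.a_, self.b_ = _platt_fit(f, np.asarray(y, dtype=int))
        return self

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(-(self.a_ * self.svc.decision_function(X) + self.b_))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _build_estimator(spec: ModelSpec, seed: int | None):
    hp = spec.hyperparams
    if spec.classifier == "rf":
        return RandomForestClassifier(
            n_estimators=int(hp.get("ntree", 500)),
            max_features=hp.get("mtry", "sqrt"),
            bootstrap=bool(hp.get("bootstrap", True)),
            random_state=seed,
            n_jobs=1,
        )
    if spec.classifier == "svm":
        return PlattSVC(gamma=float(hp.get("gamma", 1e-3)), C=float(hp.get("C", 1.0)), seed=seed)
    return NaiveBayes(smoothing=float(hp.get("smoothing", 1.0)))


def default_grid(classifier: str, n_features: int, small: bool = False) -> list[dict]:
    """Metaparameter grids: mtry around sqrt(p) for RF, log-spaced (gamma, C)
    for the RBF-SVM, and the single Laplace-smoothing point for NB."""
    if classifier == "rf":
        root = max(1, int(np.sqrt(n_features)))
        values = {max(1, root // 2), root, min(n_features, 2 * root), max(1, n_features // 4)}
        if small:
            values = {root, min(n_features, 2 * root)}
        return [{"mtry": v} for v in sorted(values)]
    if classifier == "svm":
        gammas = [2.0**e for e in range(-15, 4, 4)]
        costs = [2.0**e for e in range(-5, 16, 4)]
        if small:
            gammas, costs = [2.0**-7, 2.0**-3], [1.0, 2.0**5]
        return [{"gamma": g, "C": c} for g in gammas for c in costs]
    if classifier == "nb":
        return [{"smoothing": 1.0}]
    raise ValueError(f"unknown classifier {classifier!r}")


@dataclass
class CVResult:
    k: int
    grid: list[dict]
    mean_auc: list[float]
    mean_error: list[float]
    best_index: int

    @property
    def best_params(self) -> dict:
        return self.grid[self.best_index]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    grid: Sequence[dict],
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold tuning: best point maximizes mean held-out AUC,
    ties broken by smaller mean error, then smaller parameter values."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not len(grid):
        raise ValueError("empty grid")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > min(np.bincount(y)):
        raise ValueError("k exceeds the size of a class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    mean_auc, mean_error = [], []
    for point in grid:
        aucs, errs = [], []
        for tr, te in folds:
            model = _build_estimator(ModelSpec(spec.classifier, spec.descriptor, dict(point)), seed)
            model.fit(X[tr], y[tr])
            scores = model.predict_proba(X[te])[:, 1]
            aucs.append(roc_auc(y[te], scores)["auc"])
            errs.append(float(np.mean((scores >= 0.5).astype(int) != y[te])))
        mean_auc.append(float(np.mean(aucs)))
        mean_error.append(float(np.mean(errs)))

    def rank_key(i: int) -> tuple:
        params = tuple(grid[i][k] for k in sorted(grid[i]))
        return (-mean_auc[i], mean_error[i], params)

    best = min(range(len(grid)), key=rank_key)
    return CVResult(k=k, grid=list(grid), mean_auc=mean_auc, mean_error=mean_error, best_index=best)


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    n_features: int
    seed: int | None = None

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train(X: np.ndarray, y: np.ndarray, spec: ModelSpec, seed: int | None = 0) -> TrainedModel:
    """Fit the classifier named by ``spec`` on a labeled matrix (1 = metabolite)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    est = _build_estimator(spec, seed)
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est, n_features=X.shape[1], seed=seed)


def metabolite_likeness(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Score in [0, 1] for one vector or a matrix of them."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"descriptor mismatch: model expects {model.n_features} features, got {x.shape[1]}"
        )
    scores = model.estimator.predict_proba(x)[:, 1]
    return float(scores[0]) if single else scores


def classify(score, cutoff: float = 0.5):
    """"metabolite" iff score >= cutoff (boundary inclusive)."""
    arr = np.asarray(score, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or not 0 <= cutoff <= 1:
        raise ValueError("scores and cutoff must lie in [0, 1]")
    labels = np.where(arr >= cutoff, "metabolite", "non_metabolite")
    return labels.item() if arr.ndim == 0 else labels
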