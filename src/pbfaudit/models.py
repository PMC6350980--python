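"""Classifier families for over-reporting risk scoring.

Four families — naive Bayes, logistic regression, support vector machine,
random forest — fitted on facility-quarter features and searched over fixed
hyperparameter grids:

* naive Bayes: class-conditional densities as a single normal, a Gaussian
  kernel estimate, or supervised discretization;
* logistic regression: ridge penalty in {0, 1e-5, 1e-4, 1e-3, 1e-2};
* SVM: linear, polynomial degree 2/3, and radial kernels with width in
  {1e-3, 1e-2, 1e-1, 1};
* random forest: {50, 100, 200, 500} trees × 1–9 features per split.

Categorical covariates are one-hot encoded.  The latent gaming flag is
never a feature.  Classifier internals are delegated to scikit-learn; this
module owns the encoding, the grids, the seeding, and the [0, 1] risk-score
interface consumed by model-ranked audit targeting.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import CategoricalNB, GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import KBinsDiscretizer, StandardScaler
from sklearn.svm import SVC

from .labeling import N_INDICATORS
from .simulate import (AUDIT_ARMS, FACILITY_TYPES, LOCATIONS,
                       MANAGING_AUTHORITIES)

FAMILIES = ("naive_bayes", "logistic_regression", "svm", "random_forest")

#: Feature sets.  "basic" is the primary configuration: reported and
#: verified counts for the nine indicators plus district and audit arm
#: (one-hot).  "expanded" adds six facility-level covariates.
#: "reported_only" drops the verified counts (usable before any audit has
#: produced them); "covariates_only" keeps only facility covariates.
FEATURE_SETS = ("basic", "expanded", "reported_only", "covariates_only")

_REP_COLS = [f"rep_{i}" for i in range(1, N_INDICATORS + 1)]
_VER_COLS = [f"ver_{i}" for i in range(1, N_INDICATORS + 1)]


def default_grid(family: str) -> list[dict[str, Any]]:
    """The family's hyperparameter grid, ordered simplest model first."""
    if family == "naive_bayes":
        return [{"density": d} for d in ("normal", "kernel", "discretize")]
    if family == "logistic_regression":
        return [{"ridge": r} for r in (0.0, 1e-5, 1e-4, 1e-3, 1e-2)]
    if family == "svm":
        grid: list[dict[str, Any]] = [{"kernel": "linear"}]
        grid += [{"kernel": "poly", "degree": d} for d in (2, 3)]
        grid += [{"kernel": "rbf", "gamma": g} for g in (1e-3, 1e-2, 1e-1, 1.0)]
        return grid
    if family == "random_forest":
        return [
            {"n_trees": t, "mtry": m}
            for t in (50, 100, 200, 500)
            for m in range(1, 10)
        ]
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family, its hyperparameters (or grid), and a seed."""

    family: str
    params: Mapping[str, Any] | None = None
    grid: Sequence[Mapping[str, Any]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def resolved_grid(self) -> list[dict[str, Any]]:
        if self.grid is not None:
            return [dict(g) for g in self.grid]
        return default_grid(self.family)


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Bandwidth per class and feature follows Silverman's rule with a small
    floor so that one-hot columns (point masses) stay well defined.
    """

    def __init__(self, min_bandwidth: float = 1e-3):
        self.min_bandwidth = min_bandwidth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        self.train_ = [X[y == c] for c in self.classes_]
        self.bandwidths_ = []
        for Xc in self.train_:
            n = len(Xc)
            sd = Xc.std(axis=0, ddof=1) if n > 1 else np.zeros(X.shape[1])
            bw = 1.06 * sd * n ** (-1 / 5)
            self.bandwidths_.append(np.maximum(bw, self.min_bandwidth))
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), len(self.classes_)))
        for ci, (Xc, bw) in enumerate(zip(self.train_, self.bandwidths_)):
            # mean kernel density per feature, log-summed across features
            z = (X[:, None, :] - Xc[None, :, :]) / bw
            log_k = -0.5 * z**2 - np.log(bw * np.sqrt(2 * np.pi))
            with np.errstate(divide="ignore"):
                feat_ll = _logmeanexp(log_k, axis=1)
            out[:, ci] = feat_ll.sum(axis=1) + np.log(self.priors_[ci])
        return out

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def _logmeanexp(a, axis):
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).mean(axis=axis, keepdims=True))).squeeze(axis)


class SupervisedDiscretizer(BaseEstimator):
    """Equal-frequency binning with the bin count chosen per feature by
    class-conditional entropy (information gain with an MDL-style penalty).
    """

    def __init__(self, candidate_bins: Sequence[int] = (2, 3, 4, 5, 6, 8),
                 max_bins: int = 8):
        self.candidate_bins = candidate_bins
        self.max_bins = max_bins

    @staticmethod
    def _cond_entropy(bins: np.ndarray, y: np.ndarray) -> float:
        h = 0.0
        n = len(y)
        for b in np.unique(bins):
            mask = bins == b
            w = mask.mean()
            p = y[mask].mean()
            if 0 < p < 1:
                h += w * -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        return h

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n = len(y)
        self.edges_ = []
        for j in range(X.shape[1]):
            col = X[:, j]
            best_edges, best_score = np.array([]), np.inf
            for k in self.candidate_bins:
                qs = np.quantile(col, np.linspace(0, 1, k + 1)[1:-1])
                edges = np.unique(qs)
                binned = np.searchsorted(edges, col, side="right")
                # conditional entropy plus a per-cut penalty against
                # overfitting many bins at small n
                score = self._cond_entropy(binned, y) + len(edges) * np.log2(n) / n
                if score < best_score - 1e-12:
                    best_edges, best_score = edges, score
            self.edges_.append(best_edges)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.column_stack(
            [
                np.searchsorted(self.edges_[j], X[:, j], side="right")
                for j in range(X.shape[1])
            ]
        )

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def _build_estimator(family: str, params: Mapping[str, Any], seed: int):
    params = dict(params)
    if family == "naive_bayes":
        density = params.pop("density", "normal")
        if density == "normal":
            return GaussianNB(**params)
        if density == "kernel":
            return KernelNaiveBayes(**params)
        if density == "discretize":
            return Pipeline(
                [
                    ("disc", SupervisedDiscretizer()),
                    ("nb", CategoricalNB(min_categories=10)),
                ]
            )
        raise ValueError(f"unknown NB density treatment {density!r}")
    if family == "logistic_regression":
        ridge = params.pop("ridge", 0.0)
        C = np.inf if ridge == 0 else 1.0 / ridge
        lr = LogisticRegression(C=C, max_iter=5000, **params)
        return Pipeline([("scale", StandardScaler()), ("clf", lr)])
    if family == "svm":
        svc = SVC(probability=True, random_state=seed, **params)
        return Pipeline([("scale", StandardScaler()), ("clf", svc)])
    if family == "random_forest":
        n_trees = params.pop("n_trees", 200)
        mtry = params.pop("mtry", 3)
        return RandomForestClassifier(
            n_estimators=n_trees, max_features=mtry, random_state=seed, **params
        )
    raise ValueError(f"unknown family {family!r}")


def build_features(panel: pd.DataFrame,
                   feature_set: str = "basic") -> pd.DataFrame:
    """Encode a panel into a numeric feature matrix.

    Returns a frame indexed by (facility_id, quarter).  Categorical
    variables are one-hot encoded against their full level sets so the
    schema is identical across quarters and panels.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature_set {feature_set!r}")
    idx = pd.MultiIndex.from_frame(panel[["facility_id", "quarter"]])
    parts: list[pd.DataFrame] = []

    if feature_set in ("basic", "expanded", "reported_only"):
        parts.append(panel[_REP_COLS].astype(float).set_axis(idx))
    if feature_set in ("basic", "expanded"):
        parts.append(panel[_VER_COLS].astype(float).set_axis(idx))
    if feature_set != "covariates_only":
        districts = sorted(panel["district_id"].unique())
        parts.append(_onehot(panel["district_id"], "district", districts, idx))
        parts.append(_onehot(panel["audit_arm"], "arm",
                             list(AUDIT_ARMS), idx))
    if feature_set in ("expanded", "covariates_only"):
        parts.append(_onehot(panel["facility_type"], "ftype",
                             list(FACILITY_TYPES), idx))
        parts.append(_onehot(panel["managing_authority"], "auth",
                             list(MANAGING_AUTHORITIES), idx))
        parts.append(_onehot(panel["location"], "loc", list(LOCATIONS), idx))
        parts.append(
            panel[["catchment_population", "established_posts", "filled_posts"]]
            .astype(float)
            .set_axis(idx)
        )
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return X


def _onehot(col: pd.Series, prefix: str, levels: Sequence,
            idx: pd.MultiIndex) -> pd.DataFrame:
    data = {
        f"{prefix}_{lv}": (col == lv).astype(float).to_numpy() for lv in levels
    }
    out = pd.DataFrame(data, index=idx)
    if not np.allclose(out.sum(axis=1), 1.0):
        raise ValueError(f"unencoded level in {prefix}: rows without a match")
    return out


@dataclass
class FittedModel:
    """A fitted classifier bound to its training schema."""

    spec: ModelSpec
    params: dict[str, Any]
    estimator: Any
    columns: tuple[str, ...]

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns: {missing}")
        return X[list(self.columns)].to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(int)

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        arr = self._check(X)
        proba = self.estimator.predict_proba(arr)
        pos = list(self.estimator.classes_).index(1)
        scores = proba[:, pos]
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite risk scores produced")
        return scores

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "FittedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def fit(spec: ModelSpec, X: pd.DataFrame, y: Sequence[int]) -> FittedModel:
    """Fit one classifier; deterministic given spec.seed."""
    y = np.asarray(y, dtype=int)
    if len(y) != len(X):
        raise ValueError(f"len(y)={len(y)} != rows of X={len(X)}")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes (decision boundary "
                         "undefined otherwise)")
    params = dict(spec.params or {})
    est = _build_estimator(spec.family, params, spec.seed)
    est.fit(X.to_numpy(dtype=float), y)
    return FittedModel(spec, params, est, tuple(X.columns))


def predict_scores(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Per-row risk scores in [0, 1]; 0.5 is the class threshold."""
    return model.predict_scores(X)


def grid_search(spec: ModelSpec, X: pd.DataFrame, y: Sequence[int],
                folds: int = 10) -> tuple[dict[str, Any], float]:
    """Exhaustive CV accuracy search over the spec grid.

    Returns (best_params, mean CV accuracy); ties go to the earlier
    (smaller) grid entry.  Stratified folding is retried once with a fresh
    seed if a validation fold degenerates to a single class.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(y, dtype=int)
    splits = _stratified_splits(X, y, folds, spec.seed)
    best_params, best_acc = None, -1.0
    for params in spec.resolved_grid():
        accs = []
        for train_idx, val_idx in splits:
            m = fit(ModelSpec(spec.family, params, seed=spec.seed),
                    X.iloc[train_idx], y[train_idx])
            accs.append(float((m.predict(X.iloc[val_idx]) == y[val_idx]).mean()))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc + 1e-12:
            best_params, best_acc = params, mean_acc
    return best_params, best_acc


def _stratified_splits(X, y, folds, seed):
    for attempt, s in enumerate((seed, seed + 1)):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=s)
        splits = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[val])) == 2 for _, val in splits):
            return splits
    raise ValueError("could not build stratified folds with both classes in "
                     "every validation fold")
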