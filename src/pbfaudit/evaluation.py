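"""Strategy and classifier evaluation.

Metrics follow the standard definitions directly:

* accuracy = correctly classified samples / total samples;
* precision_a = samples correctly classified as class a / samples
  classified as class a; recall_a likewise over the true members of a;
* F1 is the macro score: the mean over classes of the per-class harmonic
  mean of precision and recall;
* the ROC curve sweeps the score threshold, AUC is its trapezoid area.

Detection yield of a sampling strategy — the share of audited facilities
found to be over-reporting — is averaged over 1,000 independent sampling
iterations without replacement, with per-iteration seeds spawned
reproducibly from a master seed.  Classifiers are scored by 10-fold
cross-validation (per-fold metrics averaged) and by a train-on-Q1,
predict-Q2..Q4 protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .models import FittedModel, ModelSpec, build_features
from .strategies import AuditPlan


@dataclass
class MetricsReport:
    """Classification metrics for one evaluation.

    precision/recall are per-class dicts keyed by class label; an absent
    true class yields NaN recall (undefined, reported missing, never 0).
    """

    accuracy: float
    precision: dict[int, float]
    recall: dict[int, float]
    f1: float
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    pr_points: list[tuple[float, float]] | None = None


def _safe_div(num: float, den: float) -> float:
    return num / den if den else float("nan")


def classification_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                           scores: Sequence[float] | None = None
                           ) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    accuracy = float((y_true == y_pred).mean())
    precision, recall, f1s = {}, {}, []
    for cls in (0, 1):
        tp = int(((y_pred == cls) & (y_true == cls)).sum())
        precision[cls] = _safe_div(tp, int((y_pred == cls).sum()))
        recall[cls] = _safe_div(tp, int((y_true == cls).sum()))
        p, r = precision[cls], recall[cls]
        if np.isnan(p) or np.isnan(r):
            f1s.append(float("nan"))
        else:
            f1s.append(_safe_div(2 * p * r, p + r) if (p + r) else 0.0)
    f1 = float(np.nanmean(f1s))

    auc = roc = pr = None
    if scores is not None:
        roc = roc_points(y_true, scores)
        auc = trapezoid_auc(roc)
        pr = pr_points(y_true, scores)
    return MetricsReport(accuracy, precision, recall, f1, auc, roc, pr)


def roc_points(y_true: Sequence[int], scores: Sequence[float]
               ) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs from sweeping the score threshold high → low.

    Starts at (0, 0) and ends at (1, 1); tied scores move in one step.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos, neg = int((y == 1).sum()), int((y == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("ROC undefined without both classes in y_true")
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    pts = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(y)):
        tp += y_sorted[i] == 1
        fp += y_sorted[i] == 0
        if i + 1 < len(y) and s_sorted[i + 1] == s_sorted[i]:
            continue
        pts.append((fp / neg, tp / pos))
    return pts


def pr_points(y_true: Sequence[int], scores: Sequence[float]
              ) -> list[tuple[float, float]]:
    """(recall, precision) pairs from sweeping the score threshold."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos = int((y == 1).sum())
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    pts = []
    tp = 0
    for i in range(len(y)):
        tp += y_sorted[i] == 1
        if i + 1 < len(y) and s_sorted[i + 1] == s_sorted[i]:
            continue
        pts.append((tp / pos if pos else float("nan"), tp / (i + 1)))
    return pts


def trapezoid_auc(points: Iterable[tuple[float, float]]) -> float:
    pts = sorted(points)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))


def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Random partition of range(n) into k near-equal validation folds."""
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), k)


def kfold_cv(spec: ModelSpec, X: pd.DataFrame, y: Sequence[int],
             k: int = 10, seed: int = 0) -> MetricsReport:
    """k-fold cross-validation with per-fold metrics averaged.

    Every observation appears in a validation fold exactly once.  Scalar
    metrics are the mean of the k per-fold values ("averaged the k
    results"); curves are not averaged and are omitted.
    """
    y = np.asarray(y, dtype=int)
    folds = kfold_indices(len(y), k, seed)
    reports = []
    for val_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        model = _models.fit(spec, X.iloc[train_idx], y[train_idx])
        scores = model.predict_scores(X.iloc[val_idx])
        y_val = y[val_idx]
        has_both = len(np.unique(y_val)) == 2
        reports.append(
            classification_metrics(
                y_val, (scores >= 0.5).astype(int),
                scores if has_both else None,
            )
        )
    return MetricsReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision={c: float(np.nanmean([r.precision[c] for r in reports]))
                   for c in (0, 1)},
        recall={c: float(np.nanmean([r.recall[c] for r in reports]))
                for c in (0, 1)},
        f1=float(np.nanmean([r.f1 for r in reports])),
        auc=(float(np.mean([r.auc for r in reports if r.auc is not None]))
             if any(r.auc is not None for r in reports) else None),
    )


def sampling_yield(strategy: Callable[[int], AuditPlan],
                   flagged: Iterable[str], reps: int = 1000,
                   seed: int = 0) -> float:
    """Mean detection yield of a seeded sampling strategy.

    ``strategy`` maps a per-iteration seed to an AuditPlan; ``flagged`` is
    the set of facilities that are truly over-reporting in the audited
    quarter.  Returns the mean over ``reps`` iterations of
    |plan ∩ flagged| / |plan|.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    flagged = set(flagged)
    child_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    yields = np.empty(reps)
    for i, s in enumerate(child_seeds):
        plan = strategy(int(s))
        if len(plan) == 0:
            raise ValueError("strategy produced an empty audit plan")
        yields[i] = sum(fid in flagged for fid in plan.selected) / len(plan)
    return float(yields.mean())


def cross_quarter_protocol(spec: ModelSpec, panel: pd.DataFrame,
                           labels: pd.DataFrame,
                           feature_set: str = "basic",
                           target: str = "over_report") -> dict[str, float]:
    """Train on quarter 1, predict quarters 2–4; no refitting.

    Returns {"Q2": accuracy, "Q3": ..., "Q4": ...}.
    """
    X = build_features(panel, feature_set)
    y = labels.set_index(["facility_id", "quarter"])[target].reindex(X.index)
    if y.isna().any():
        raise ValueError("labels do not cover every facility-quarter")
    q = X.index.get_level_values("quarter")
    y1 = y[q == 1].to_numpy(dtype=int)
    if len(np.unique(y1)) < 2:
        raise ValueError("quarter-1 labels are single-class; cannot train")
    model = _models.fit(spec, X[q == 1], y1)
    out = {}
    for quarter in (2, 3, 4):
        mask = q == quarter
        pred = model.predict(X[mask])
        out[f"Q{quarter}"] = float((pred == y[mask].to_numpy(dtype=int)).mean())
    return out


def report_to_frame(reports: Mapping[str, MetricsReport]) -> pd.DataFrame:
    """Table of scalar metrics, one row per model."""
    rows = []
    for name, r in reports.items():
        rows.append(
            {
                "model": name,
                "accuracy": r.accuracy,
                "precision_pos": r.precision[1],
                "recall_pos": r.recall[1],
                "f1": r.f1,
                "auc": r.auc,
            }
        )
    return pd.DataFrame(rows)
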