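"""Classifier evaluation: confusion metrics, MCC, ROC/AUC, experiment grid.

Scalar metrics follow the standard confusion-matrix definitions:

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is defined as 0 whenever any factor of its denominator vanishes
(the value conventionally reported for degenerate one-class
predictors); precision/recall/specificity with a zero denominator are
reported as 0 with a ``degenerate`` flag.  The ROC curve sweeps every
unique score threshold and the AUC is the trapezoid integral, which
equals the Mann-Whitney rank statistic (ties counted one half).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate_predictions",
    "run_grid",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    mcc: float
    degenerate: bool = False
    roc_points: np.ndarray | None = None
    auc: float | None = None
    counts: ConfusionCounts | None = None

    def as_row(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Tally the confusion matrix of binary labels vs predictions."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary")
    y = y.astype(bool)
    p = p.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(y & p)),
        fp=int(np.sum(~y & p)),
        tn=int(np.sum(~y & ~p)),
        fn=int(np.sum(y & ~p)),
    )


def metrics(c: ConfusionCounts) -> EvalReport:
    """Scalar metrics from confusion counts (zero denominators -> 0)."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    acc = (tp + tn) / c.total
    prec = ratio(tp, tp + fp)
    rec = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return EvalReport(acc, prec, rec, spec, mcc, degenerate, counts=c)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all unique score thresholds, and AUC.

    The curve starts at (0, 0) and ends at (1, 1); AUC is the trapezoid
    integral over FPR.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep the last point of each tied-score block
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def evaluate_predictions(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Full report: thresholded confusion metrics plus ROC/AUC."""
    preds = (np.asarray(probabilities) >= threshold).astype(int)
    rep = metrics(confusion(labels, preds))
    try:
        rep.roc_points, rep.auc = roc_auc(labels, probabilities)
    except ValueError:
        rep.roc_points, rep.auc = None, None
    return rep


def run_grid(
    cohort,
    models: tuple[str, ...] = ("simple", "aticnn", "crnn"),
    signal_types: tuple[str, ...] = ("unipolar", "bipolar", "lat-train"),
    lengths_ms: tuple[float, ...] = (500.0, 2500.0),
    rates_hz: tuple[float, ...] = (500.0, 250.0, 100.0),
    train_config=None,
    *,
    seed: int = 0,
    dataset_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Train and test every model x signal x length x rate combination.

    One row per combination with validation accuracy and test metrics;
    a combination that fails (e.g. an input too short for a model's
    pooling chain) is marked ``status="failed"`` and the sweep
    continues.  Each cell uses a seed derived from the base seed, so a
    rerun reproduces the table.
    """
    from . import nets
    from .datasets import build_dataset

    cfg = train_config or nets.TrainConfig(lr_grid=(1e-3,), epochs=3, patience=3)
    dataset_kwargs = dataset_kwargs or {}
    spec_builders = {
        "simple": nets.SimpleSpec,
        "aticnn": nets.AticnnSpec,
        "crnn": nets.CrnnSpec,
    }
    rows = []
    for i, (mdl, sig, length, rate) in enumerate(
        itertools.product(models, signal_types, lengths_ms, rates_hz)
    ):
        cell_seed = seed + 1000 * i
        base = {
            "model": mdl, "input": sig, "length_ms": length, "fs_hz": rate,
            "seed": cell_seed,
        }
        try:
            splits = build_dataset(
                cohort, signal_type=sig, window_ms=length, target_fs=rate,
                seed=cell_seed, **dataset_kwargs,
            )
            spec = spec_builders[mdl]()
            x_tr, y_tr = nets.windows_to_arrays(splits.train, spec)
            x_va, y_va = nets.windows_to_arrays(splits.val, spec)
            x_te, y_te = nets.windows_to_arrays(splits.test, spec)
            model = nets.build(spec, x_tr.shape[1:3] if mdl != "aticnn"
                               else (x_tr.shape[1], x_tr.shape[3]), seed=cell_seed)
            cell_cfg = nets.TrainConfig(
                lr_grid=cfg.lr_grid, batch_size=cfg.batch_size, epochs=cfg.epochs,
                patience=cfg.patience, val_every_steps=cfg.val_every_steps,
                max_steps_per_epoch=cfg.max_steps_per_epoch, seed=cell_seed,
            )
            model, hist = nets.train(model, (x_tr, y_tr), (x_va, y_va), cell_cfg)
            _, probs = nets.predict(model, x_te)
            rep = evaluate_predictions(y_te, probs)
            rows.append({
                **base, "status": "ok",
                "val_accuracy": hist["best_val_accuracy"], **rep.as_row(),
            })
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            rows.append({**base, "status": "failed", "error": str(exc)})
    return pd.DataFrame(rows)
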