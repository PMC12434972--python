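"""Confusion-matrix accuracy metrics for damage-level maps.

Conventions follow thematic-accuracy practice in remote sensing: rows of
the confusion matrix are true levels, columns are predicted levels.
With per-class true positives TP, false positives FP and false
negatives FN,

* overall accuracy  OA = trace / S,
* kappa = (OA - P_e) / (1 - P_e) with chance agreement
  P_e = sum_c Np_c * Nt_c / S^2  (Np: column sums, Nt: row sums),
* recall_c = TP / (TP + FN)   and   F1_c = 2 TP / (2 TP + FP + FN),
  macro-averaged over classes present in the truth,
* producer accuracy PA_c = TP_c / Nt_c, user accuracy UA_c = TP_c / Np_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionMatrix:
    """k x k count matrix; rows = true level, columns = predicted level."""

    counts: np.ndarray
    levels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = self.counts.shape[0]
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.levels) != k:
            raise ValueError("levels must match matrix dimension")

    @classmethod
    def from_predictions(cls, y_true, y_pred, levels=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if levels is None:
            levels = sorted(set(y_true) | set(y_pred))
        levels = list(levels)
        pos = {l: i for i, l in enumerate(levels)}
        counts = np.zeros((len(levels), len(levels)))
        for t, p in zip(y_true, y_pred):
            counts[pos[t], pos[p]] += 1
        return cls(counts, levels)

    @property
    def S(self) -> float:
        return float(self.counts.sum())

    @property
    def Nt(self) -> np.ndarray:
        """Per-class truth counts (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def Np(self) -> np.ndarray:
        """Per-class prediction counts (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    if cm.S == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.S)


def kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement.  NaN when chance agreement equals 1."""
    oa = overall_accuracy(cm)
    pe = float((cm.Np * cm.Nt).sum() / cm.S**2)
    if pe == 1.0:
        return np.nan
    return (oa - pe) / (1.0 - pe)


def per_class_metrics(cm: ConfusionMatrix) -> dict:
    """Per-class recall, F1, PA and UA; NaN where a class is absent."""
    tp = cm.tp
    fn = cm.Nt - tp
    fp = cm.Np - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(cm.Nt > 0, tp / np.where(cm.Nt > 0, cm.Nt, 1), np.nan)
        f1_den = 2 * tp + fp + fn
        f1 = np.where(f1_den > 0, 2 * tp / np.where(f1_den > 0, f1_den, 1), np.nan)
        pa = recall  # producer accuracy is the per-class recall
        ua = np.where(cm.Np > 0, tp / np.where(cm.Np > 0, cm.Np, 1), np.nan)
    return {"recall": recall, "f1": f1, "pa": pa, "ua": ua}


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """OA, kappa, macro recall, macro F1 and the per-class breakdown.

    Macro averages run over classes for which the metric is defined; a
    class absent from both truth and predictions contributes nothing.
    """
    pc = per_class_metrics(cm)
    return {
        "oa": overall_accuracy(cm),
        "kappa": kappa(cm),
        "recall": float(np.nanmean(pc["recall"])),
        "f1": float(np.nanmean(pc["f1"])),
        "per_class": pc,
    }
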