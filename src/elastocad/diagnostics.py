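"""Diagnostic performance of the hard-area classification.

Hard masses are considered positive for malignancy; soft and intermediate
masses are negative. For each reader and each cutoff Z the 3-class labels
are binarized and compared against histology-style ground truth, giving
sensitivity and specificity; the AUC is the empirical area under the ROC
curve of the 3-point ordinal score (1/2/3) against truth, computed as the
Mann–Whitney statistic with half credit for ties. A sweep over cutoffs
yields a per-reader grid of metrics; because raising Z can only move
predictions from positive to negative, sensitivity is non-increasing and
specificity non-decreasing in Z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score

from .stratification import HARD, LABEL_SCORES, CutoffConfig, classify_mass

__all__ = [
    "DiagnosticMetrics",
    "binarize",
    "sens_spec",
    "roc_auc",
    "cutoff_sweep",
]


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/AUC of one reader at one cutoff."""

    Z: float
    auc: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


def binarize(label: str) -> int:
    """Map a 3-class label to malignancy positivity: hard → 1, else 0."""
    if label not in LABEL_SCORES:
        raise ValueError(f"unknown label {label!r}")
    return int(label == HARD)


def _check_truth(truth: np.ndarray) -> None:
    if not ((truth == 0) | (truth == 1)).all():
        raise ValueError("truth must be binary (0 = benign, 1 = malignant)")
    if not (truth == 1).any():
        raise ValueError("degenerate truth: no positive (malignant) cases")
    if not (truth == 0).any():
        raise ValueError("degenerate truth: no negative (benign) cases")


def sens_spec(pred, truth) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) of binary calls."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    _check_truth(truth)
    tn, fp, fn, tp = confusion_matrix(truth, pred, labels=[0, 1]).ravel()
    return tp / (tp + fn), tn / (tn + fp)


def roc_auc(score, truth) -> float:
    """Empirical AUC of an ordinal/continuous score against binary truth.

    Equals the Mann–Whitney statistic (wins + half ties over all
    positive/negative pairs), i.e. the trapezoidal area under the
    empirical ROC curve; higher score = more suspicious.
    """
    score = np.asarray(score, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if score.shape != truth.shape:
        raise ValueError("score and truth must have equal length")
    _check_truth(truth)
    if np.ptp(score) == 0:
        return 0.5  # all ties: every pair contributes half credit
    return float(roc_auc_score(truth, score))


def cutoff_sweep(dataset: pd.DataFrame, Zs=(0.70, 0.75, 0.80, 0.90)) -> pd.DataFrame:
    """Reader × cutoff grid of diagnostic metrics.

    ``dataset`` has one row per (lesion, reader): columns lesion_id,
    reader_id, hard_fraction, truth (1 = malignant). For each reader and
    each Z the hard fractions are classified, binarized (hard = positive)
    and scored against truth; the AUC comes from the 3-point ordinal score.
    """
    required = {"lesion_id", "reader_id", "hard_fraction", "truth"}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset is missing columns: {sorted(missing)}")
    rows = []
    for reader, grp in dataset.groupby("reader_id", sort=True):
        truth = grp["truth"].to_numpy(int)
        _check_truth(truth)
        for Z in Zs:
            cfg = CutoffConfig(Z=Z)
            labels = [classify_mass(q, cfg) for q in grp["hard_fraction"]]
            pred = np.array([binarize(lb) for lb in labels])
            scores = np.array([LABEL_SCORES[lb] for lb in labels])
            sens, spec = sens_spec(pred, truth)
            rows.append(
                {
                    "reader_id": reader,
                    "Z": Z,
                    "auc": roc_auc(scores, truth),
                    "sensitivity": sens,
                    "specificity": spec,
                    "n_pos": int(truth.sum()),
                    "n_neg": int((1 - truth).sum()),
                }
            )
    return pd.DataFrame(rows)
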