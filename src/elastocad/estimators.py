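"""Scikit-learn–style estimators wrapping the stratification pipeline.

``ElastogramStratifier`` is a stateless transformer turning (image, ROI)
pairs into hard-area fractions; ``HardAreaClassifier`` applies the 3-class
cutoff rule to those fractions. Chained in a ``sklearn.pipeline.Pipeline``
they reproduce the full image → label pipeline and expose the standard
``get_params``/``set_params`` surface for grid searches over the cutoff Z.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .io import ElastogramImage, ROIMask
from .stratification import (
    LABEL_SCORES,
    CutoffConfig,
    StratificationResult,
    classify_mass,
    stratify,
)

__all__ = ["ElastogramStratifier", "HardAreaClassifier"]


def _as_pairs(X):
    pairs = list(X)
    for i, item in enumerate(pairs):
        if (
            not isinstance(item, (tuple, list))
            or len(item) != 2
            or not isinstance(item[0], ElastogramImage)
            or not isinstance(item[1], ROIMask)
        ):
            raise ValueError(
                f"X[{i}] is not an (ElastogramImage, ROIMask) pair"
            )
    return pairs


class ElastogramStratifier(TransformerMixin, BaseEstimator):
    """Transform (elastogram, ROI) pairs into hard-area fractions.

    Parameters
    ----------
    n_bins : int, default=256
        Histogram bins for the ROI-restricted Otsu threshold on a*.
    min_separation : float, default=0.75
        Minimum between-class/total variance ratio for the Otsu split;
        below it the per-pixel sign rule (hard ⇔ a* > 0) is used and the
        lesion is flagged degenerate.

    The transformer learns nothing from data; ``fit`` only validates input.
    """

    def __init__(self, n_bins: int = 256, min_separation: float = 0.75):
        self.n_bins = n_bins
        self.min_separation = min_separation

    def _cfg(self) -> CutoffConfig:
        return CutoffConfig(n_bins=self.n_bins, min_separation=self.min_separation)

    def fit(self, X, y=None):
        _as_pairs(X)
        self._cfg()  # parameter validation
        self.n_features_in_ = 1
        return self

    def results(self, X) -> list[StratificationResult]:
        """Full per-lesion stratification results (threshold, counts, flags)."""
        cfg = self._cfg()
        return [stratify(img, roi, cfg) for img, roi in _as_pairs(X)]

    def transform(self, X) -> np.ndarray:
        """Hard-area fraction q per lesion, as an (n, 1) column."""
        return np.array([[r.hard_fraction] for r in self.results(X)])

    def stratify_table(self, X, ids=None) -> pd.DataFrame:
        """Results as a tidy DataFrame (one row per lesion)."""
        res = self.results(X)
        return pd.DataFrame(
            {
                "lesion_id": ids if ids is not None else np.arange(len(res)),
                "hard_fraction": [r.hard_fraction for r in res],
                "n_roi_px": [r.n_roi_px for r in res],
                "n_hard_px": [r.n_hard_px for r in res],
                "threshold_a": [r.threshold_a for r in res],
                "degenerate": [r.degenerate for r in res],
            }
        )


class HardAreaClassifier(ClassifierMixin, BaseEstimator):
    """Fixed-rule 3-class classifier on hard-area fractions.

    soft iff q < soft_bound (50%), hard iff q > cutoff Z, intermediate in
    the closed band between. ``fit`` accepts and ignores ``y`` — the rule
    has no free parameters to estimate; it exists so the classifier slots
    into sklearn pipelines and model selection over ``cutoff``.
    """

    def __init__(self, cutoff: float = 0.75, soft_bound: float = 0.50):
        self.cutoff = cutoff
        self.soft_bound = soft_bound

    def _cfg(self) -> CutoffConfig:
        return CutoffConfig(Z=self.cutoff, soft_bound=self.soft_bound)

    def fit(self, X, y=None):
        self._cfg()
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] != 1:
            raise ValueError("X must be a single column of hard fractions")
        self.classes_ = np.array(["hard", "intermediate", "soft"])
        self.n_features_in_ = 1
        return self

    def _q(self, X) -> np.ndarray:
        q = np.asarray(X, dtype=float).reshape(-1)
        if ((q < 0) | (q > 1)).any():
            raise ValueError("hard fractions must lie in [0, 1]")
        return q

    def predict(self, X) -> np.ndarray:
        """3-class labels ('soft' / 'intermediate' / 'hard') per lesion."""
        if not hasattr(self, "classes_"):
            self.fit(X)
        cfg = self._cfg()
        return np.array([classify_mass(q, cfg) for q in self._q(X)])

    def predict_score(self, X) -> np.ndarray:
        """Ordinal 3-point score (1 soft, 2 intermediate, 3 hard)."""
        return np.array([LABEL_SCORES[lb] for lb in self.predict(X)])

    def predict_positive(self, X) -> np.ndarray:
        """Binary malignancy call: 1 for hard, 0 otherwise."""
        return (self.predict(X) == "hard").astype(int)
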