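"""Hard-area stratification of an elastogram ROI.

The classification statistic is the hard-area fraction q: the proportion of
ROI pixels whose a* (green↔red) coordinate falls on the red — hard — side
of an Otsu threshold computed from the ROI's own a* histogram. A lesion is
then called soft (q < 50%), intermediate (50% ≤ q ≤ Z) or hard (q > Z) for
a configurable cutoff Z; cutoffs of 70%, 75%, 80% and 90% are the values of
clinical interest, and Z = 90% corresponds to the visual BI-RADS-style
reading.

Otsu runs on ROI pixels only: hardness is defined *within the mass*, and
surrounding tissue would bias the threshold. When the ROI's a* distribution
carries no usable two-class structure (a constant a*, or a split whose
between-class variance explains less than ``min_separation`` of the total),
the threshold is undefined and pixels are labelled by the sign rule
hard ⇔ a* > 0, i.e. red side of the achromatic axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ElastogramImage, LabImage, ROIMask, rgb_to_cielab

__all__ = [
    "CutoffConfig",
    "StratificationResult",
    "otsu_threshold",
    "hardness_map",
    "hard_fraction",
    "classify_mass",
    "visual_classify",
    "stratify",
    "SOFT",
    "INTERMEDIATE",
    "HARD",
    "LABEL_SCORES",
]

SOFT = "soft"
INTERMEDIATE = "intermediate"
HARD = "hard"

#: 3-point reader score encoding of the class labels.
LABEL_SCORES = {SOFT: 1, INTERMEDIATE: 2, HARD: 3}

#: Default fraction of total variance the Otsu split must explain; below
#: this the ROI is treated as single-class (see module docstring).
DEFAULT_MIN_SEPARATION = 0.75


@dataclass(frozen=True)
class CutoffConfig:
    """Cutoff configuration for the 3-class rule.

    Parameters
    ----------
    Z : float
        Hard-class cutoff on q, as a fraction in (0.5, 1.0]. Values of
        clinical interest: 0.70, 0.75, 0.80, 0.90.
    soft_bound : float
        Lower boundary of the intermediate class; fixed at 0.50.
    n_bins : int
        Histogram bins for the Otsu threshold (8-bit practice: 256).
    min_separation : float
        Minimum between-class/total variance ratio for the Otsu split to be
        considered informative.
    """

    Z: float = 0.75
    soft_bound: float = 0.50
    n_bins: int = 256
    min_separation: float = DEFAULT_MIN_SEPARATION

    def __post_init__(self) -> None:
        if not (self.soft_bound < self.Z <= 1.0):
            raise ValueError(
                f"cutoff Z must satisfy soft_bound < Z <= 1.0, got Z={self.Z} "
                f"with soft_bound={self.soft_bound}"
            )
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not (0.0 <= self.min_separation <= 1.0):
            raise ValueError("min_separation must lie in [0, 1]")


@dataclass(frozen=True)
class StratificationResult:
    """Outcome of stratifying one lesion.

    ``threshold_a`` is the Otsu threshold on a* (NaN when the ROI was
    degenerate/single-class and the sign rule was used instead).
    """

    hard_fraction: float
    n_roi_px: int
    n_hard_px: int
    label: str
    threshold_a: float
    degenerate: bool = False


def _between_class_variance(counts: np.ndarray) -> np.ndarray:
    """Between-class variance for every split of a histogram.

    Element k is the between-class variance of the two classes formed by
    bins [0..k] vs [k+1..]; splits leaving a class empty score 0.
    """
    counts = counts.astype(float)
    total = counts.sum()
    centers = np.arange(counts.size, dtype=float)
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    s0 = np.cumsum(counts * centers)[:-1]
    mu_total = (counts * centers).sum() / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = ((counts * centers).sum() - s0) / w1
        bcv = w0 / total * (mu0 - mu_total) ** 2 + w1 / total * (mu1 - mu_total) ** 2
    bcv[~np.isfinite(bcv)] = 0.0
    return bcv


def otsu_threshold(values, n_bins: int = 256) -> float:
    """Otsu threshold of a set of real values.

    The values are binned into ``n_bins`` equal-width bins spanning their
    observed range; the returned threshold is the bin edge that maximizes
    the between-class variance of the two classes it induces (class
    membership by ``value >= threshold``). Deterministic: ties between
    splits go to the lowest threshold.

    Raises
    ------
    ValueError
        On empty input or when all values are identical (degenerate
        distribution — no two-class structure exists).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("otsu_threshold: empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("otsu_threshold: input contains non-finite values")
    if n_bins < 2:
        raise ValueError("otsu_threshold: n_bins must be >= 2")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise ValueError("otsu_threshold: degenerate distribution (all values identical)")
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    bcv = _between_class_variance(counts)
    k = int(np.argmax(bcv))  # first maximum → lowest threshold
    return float(edges[k + 1])


def otsu_separation(values, n_bins: int = 256) -> tuple[float, float]:
    """Otsu threshold together with its separability measure.

    Returns ``(threshold, eta)`` where eta = between-class variance at the
    chosen split divided by the total variance of the binned values
    (Otsu's effectiveness criterion, in [0, 1]).
    """
    v = np.asarray(values, dtype=float).ravel()
    thr = otsu_threshold(v, n_bins=n_bins)
    lo, hi = float(v.min()), float(v.max())
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    bcv = _between_class_variance(counts)
    centers = np.arange(counts.size, dtype=float)
    p = counts / counts.sum()
    total_var = float((p * (centers - (p * centers).sum()) ** 2).sum())
    eta = float(bcv.max() / total_var) if total_var > 0 else 0.0
    return thr, eta


def hardness_map(lab: LabImage, roi: ROIMask, thr: float) -> np.ndarray:
    """Binary H×W map of hard pixels: inside the ROI and a* >= thr.

    Red (positive a*) codes hard tissue; ties at the threshold go hard so
    results are deterministic. Pixels outside the ROI are never hard.
    """
    if lab.shape != roi.shape:
        raise ValueError(f"Lab grid {lab.shape} does not match ROI grid {roi.shape}")
    if roi.area_px == 0:
        raise ValueError("hardness_map: empty ROI")
    if not np.isfinite(thr):
        raise ValueError("hardness_map: threshold must be finite")
    return roi.mask & (lab.a_star >= thr)


def hard_fraction(hmap: np.ndarray, roi: ROIMask) -> float:
    """Fraction q of ROI pixels marked hard."""
    if roi.area_px == 0:
        raise ValueError("hard_fraction: empty ROI")
    n_hard = int((np.asarray(hmap, dtype=bool) & roi.mask).sum())
    return n_hard / roi.area_px


def classify_mass(q: float, cfg: CutoffConfig) -> str:
    """3-class rule: soft iff q < 50%, hard iff q > Z, else intermediate.

    Both boundaries (q exactly 0.50 or exactly Z) map to intermediate —
    the intermediate band is the closed interval [50%, Z].
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"hard fraction q must lie in [0, 1], got {q}")
    if q < cfg.soft_bound:
        return SOFT
    if q > cfg.Z:
        return HARD
    return INTERMEDIATE


def visual_classify(q: float) -> str:
    """Visual-pattern rule: soft (< 50%), intermediate (50–90%), hard (> 90%)."""
    return classify_mass(q, CutoffConfig(Z=0.90))


def stratify(
    img: ElastogramImage, roi: ROIMask, cfg: CutoffConfig | None = None
) -> StratificationResult:
    """Run the full stratification pipeline on one lesion.

    RGB → CIELab; Otsu threshold on the ROI-restricted a* values; hard map;
    hard fraction; 3-class label. When the ROI a* distribution is constant,
    or its best Otsu split explains less than ``cfg.min_separation`` of the
    total variance, the result is flagged degenerate and pixels are
    labelled hard ⇔ a* > 0 instead.
    """
    if cfg is None:
        cfg = CutoffConfig()
    if img.shape != roi.shape:
        raise ValueError(f"image grid {img.shape} does not match ROI grid {roi.shape}")
    if roi.area_px == 0:
        raise ValueError("stratify: empty ROI")

    lab = rgb_to_cielab(img)
    a_roi = lab.a_star[roi.mask]

    degenerate = False
    if a_roi.min() == a_roi.max():
        degenerate = True
    else:
        thr, eta = otsu_separation(a_roi, n_bins=cfg.n_bins)
        degenerate = eta < cfg.min_separation

    if degenerate:
        # Sign rule: red side of the achromatic axis is hard.
        hmap = roi.mask & (lab.a_star > 0.0)
        thr_out = float("nan")
    else:
        hmap = hardness_map(lab, roi, thr)
        thr_out = thr

    n_hard = int(hmap.sum())
    q = n_hard / roi.area_px
    return StratificationResult(
        hard_fraction=q,
        n_roi_px=roi.area_px,
        n_hard_px=n_hard,
        label=classify_mass(q, cfg),
        threshold_a=thr_out,
        degenerate=degenerate,
    )
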