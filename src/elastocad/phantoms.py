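"""Synthetic elastogram phantoms with known ground truth.

A phantom is an elastogram-like two-tone color image: a lesion ROI whose
pixels are drawn from a "hard" red and a "soft" blue cluster, with
per-channel Gaussian color jitter, on a gray tissue background. The
generator controls the exact pre-jitter hard-pixel set, so the true hard
fraction is known to the pixel and every pipeline stage can be validated
without clinical images.

The only color property the stratification pipeline relies on is that hard
and soft clusters separate on the CIELab a* axis (red positive, soft
negative). The soft default is a cyan-cast blue — on-screen elastogram soft
tones carry a green/cyan component, and a fully saturated RGB blue would
sit on the red side of the a* axis, which no red/blue stiffness display
intends.

Cohorts emulate a clinical reading study: benign and malignant lesions
with Beta-distributed true hard fractions, and simulated readers who
re-segment each lesion with a systematic area scale and boundary noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ElastogramImage, ROIMask

__all__ = [
    "PhantomSpec",
    "ReaderProfile",
    "CohortSpec",
    "generate_phantom",
    "simulate_readers",
    "generate_cohort",
    "cohort_reader_table",
]

HARD_COLOR_DEFAULT = (220, 30, 30)
SOFT_COLOR_DEFAULT = (30, 170, 220)  # cyan-cast blue: a* < 0 under sRGB/D65
BACKGROUND_COLOR = (120, 120, 120)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic elastogram.

    true_hard_fraction f is realised exactly (pre-jitter) as
    round(f · ROI area) hard pixels. spatial_pattern "speckle" scatters
    hard pixels uniformly in the ROI; "split" makes one contiguous hard
    region. Identical spec + seed → bit-identical phantom.
    """

    true_hard_fraction: float
    seed: int
    height: int = 128
    width: int = 128
    lesion_shape: str = "ellipse"  # ellipse | blob
    lesion_area_px: int = 2000
    hard_color: tuple[int, int, int] = HARD_COLOR_DEFAULT
    soft_color: tuple[int, int, int] = SOFT_COLOR_DEFAULT
    color_jitter_sd: float = 10.0
    spatial_pattern: str = "speckle"  # speckle | split

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_hard_fraction <= 1.0):
            raise ValueError("true_hard_fraction must lie in [0, 1]")
        if self.lesion_area_px > self.height * self.width:
            raise ValueError(
                f"lesion ({self.lesion_area_px} px) larger than the "
                f"{self.height}×{self.width} frame"
            )
        if self.lesion_shape not in ("ellipse", "blob"):
            raise ValueError(f"unknown lesion_shape {self.lesion_shape!r}")
        if self.spatial_pattern not in ("speckle", "split"):
            raise ValueError(f"unknown spatial_pattern {self.spatial_pattern!r}")


@dataclass(frozen=True)
class ReaderProfile:
    """Systematic segmentation behaviour of one simulated reader.

    area_scale multiplies the reference ROI area (experienced readers
    segment tighter, inexperienced ones larger); boundary_noise is the
    amplitude (in pixels of distance) of random boundary irregularity.
    """

    reader_id: str
    area_scale: float = 1.0
    boundary_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.area_scale <= 0:
            raise ValueError("area_scale must be positive")
        if self.boundary_noise < 0:
            raise ValueError("boundary_noise must be >= 0")


#: Default reading panel: the most experienced reader segments tightest,
#: the least experienced the largest area.
DEFAULT_READERS = (
    ReaderProfile("R1", area_scale=0.85, boundary_noise=0.5),
    ReaderProfile("R2", area_scale=1.25, boundary_noise=1.0),
    ReaderProfile("R3", area_scale=1.00, boundary_noise=0.5),
)


@dataclass(frozen=True)
class CohortSpec:
    """A benign/malignant phantom cohort with simulated readers.

    True hard fractions are Beta-distributed per class: malignant
    Beta(8, 2) (mean 0.8) and benign Beta(2, 8) (mean 0.2) by default —
    overlapping but separable classes, so cutoff sweeps are non-trivial.
    Default cohort size mirrors a typical single-centre biopsy series
    (31 malignant / 52 benign).
    """

    seed: int
    n_malignant: int = 31
    n_benign: int = 52
    alpha_malignant: float = 8.0
    beta_malignant: float = 2.0
    alpha_benign: float = 2.0
    beta_benign: float = 8.0
    readers: tuple[ReaderProfile, ...] = DEFAULT_READERS
    phantom: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(true_hard_fraction=0.5, seed=0)
    )

    def __post_init__(self) -> None:
        if self.n_malignant < 1 or self.n_benign < 1:
            raise ValueError("cohort needs at least one lesion of each class")
        for p in (self.alpha_malignant, self.beta_malignant, self.alpha_benign, self.beta_benign):
            if p <= 0:
                raise ValueError("Beta distribution parameters must be positive")
        if len(self.readers) < 2:
            raise ValueError("cohort needs at least two readers")


def _ellipse_mask(height: int, width: int, area_px: int, aspect: float = 1.5) -> np.ndarray:
    """Centred ellipse of approximately the requested pixel area."""
    b = np.sqrt(area_px / (np.pi * aspect))
    a = aspect * b
    r, c = np.ogrid[:height, :width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    return ((c - cx) / a) ** 2 + ((r - cy) / b) ** 2 <= 1.0


def _blob_mask(height: int, width: int, area_px: int, rng: np.random.Generator) -> np.ndarray:
    """Irregular lesion: ellipse deformed by smooth radial noise."""
    base = _ellipse_mask(height, width, area_px)
    noise = ndimage.gaussian_filter(rng.normal(size=(height, width)), sigma=6)
    inside = ndimage.distance_transform_edt(base)
    outside = ndimage.distance_transform_edt(~base)
    signed = inside - outside
    deformed = signed + noise * 3.0 > 0
    return _match_area(deformed, area_px=int(base.sum()), rng=rng)


def _match_area(mask: np.ndarray, area_px: int, rng: np.random.Generator,
                noise: float = 0.0) -> np.ndarray:
    """Level-set resize of a mask to exactly ``area_px`` pixels.

    Pixels are ranked by signed distance to the current boundary (plus
    optional noise, which roughens the boundary); the top ``area_px``
    pixels form the result. This is a morphological grow/shrink that
    preserves the overall shape.
    """
    if area_px < 1:
        raise ValueError("target mask area vanished (area_px < 1)")
    if area_px > mask.size:
        raise ValueError("target mask area exceeds the frame")
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = (inside - outside).astype(float)
    if noise > 0:
        signed = signed + ndimage.gaussian_filter(
            rng.normal(scale=noise * 4.0, size=mask.shape), sigma=2
        )
    flat = signed.ravel()
    order = np.argsort(-flat, kind="stable")
    out = np.zeros(mask.size, dtype=bool)
    out[order[:area_px]] = True
    return out.reshape(mask.shape)


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(ElastogramImage, ROIMask, truth)`` where ``truth`` records
    the exact pre-jitter hard-pixel set, the realised hard fraction
    round(f·area)/area, and the generator parameters.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.lesion_shape == "ellipse":
        mask = _ellipse_mask(spec.height, spec.width, spec.lesion_area_px)
    else:
        mask = _blob_mask(spec.height, spec.width, spec.lesion_area_px, rng)
    area = int(mask.sum())
    if area < 1:
        raise ValueError("lesion mask is empty")

    rr, cc = np.nonzero(mask)
    n_hard = int(round(spec.true_hard_fraction * area))
    if spec.spatial_pattern == "speckle":
        pick = rng.choice(area, size=n_hard, replace=False)
    else:  # split: contiguous block along the row order
        pick = np.arange(n_hard)
    hard_sel = np.zeros(area, dtype=bool)
    hard_sel[pick] = True

    img = np.empty((spec.height, spec.width, 3), dtype=float)
    img[:] = BACKGROUND_COLOR
    img[rr, cc] = spec.soft_color
    img[rr[hard_sel], cc[hard_sel]] = spec.hard_color
    if spec.color_jitter_sd > 0:
        img = img + rng.normal(scale=spec.color_jitter_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = {
        "true_hard_fraction": spec.true_hard_fraction,
        "realized_hard_fraction": n_hard / area,
        "n_hard_px": n_hard,
        "roi_area_px": area,
        "hard_pixels": (rr[hard_sel].copy(), cc[hard_sel].copy()),
        "spec": spec,
    }
    return ElastogramImage(img), ROIMask(mask), truth


def simulate_readers(
    base_roi: ROIMask,
    profiles=DEFAULT_READERS,
    seed: int | np.random.Generator = 0,
) -> dict[str, ROIMask]:
    """Per-reader re-segmentations of a reference ROI.

    Each reader mask is a level-set grow/shrink of the base mask to
    area_scale × base area, with boundary noise roughening the contour;
    the realised area is exact by construction.
    """
    if base_roi.area_px == 0:
        raise ValueError("simulate_readers: empty base ROI")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, ROIMask] = {}
    for prof in profiles:
        target = int(round(prof.area_scale * base_roi.area_px))
        if target < 1:
            raise ValueError(
                f"reader {prof.reader_id}: scale {prof.area_scale} shrinks the "
                "mask to nothing"
            )
        if prof.area_scale == 1.0 and prof.boundary_noise == 0.0:
            out[prof.reader_id] = ROIMask(base_roi.mask.copy())
            continue
        m = _match_area(base_roi.mask, target, rng, noise=prof.boundary_noise)
        out[prof.reader_id] = ROIMask(m)
    return out


def generate_cohort(cspec: CohortSpec) -> pd.DataFrame:
    """Generate a full phantom cohort.

    Returns a long DataFrame with one row per lesion: lesion_id, truth
    (1 = malignant), true/realised hard fraction, the rendered image, the
    reference mask and the per-reader masks (object columns). All
    randomness flows from ``cspec.seed``.
    """
    root = np.random.SeedSequence(cspec.seed)
    f_rng = np.random.default_rng(root.spawn(1)[0])
    n_total = cspec.n_malignant + cspec.n_benign
    child_seeds = root.spawn(n_total + 1)

    records = []
    idx = 0
    for cls, n, a, b in (
        ("malignant", cspec.n_malignant, cspec.alpha_malignant, cspec.beta_malignant),
        ("benign", cspec.n_benign, cspec.alpha_benign, cspec.beta_benign),
    ):
        fs = f_rng.beta(a, b, size=n)
        for f in fs:
            # per-lesion integer seed derived from the cohort seed
            lesion_seed = int(child_seeds[idx].generate_state(1)[0] % (2**31))
            spec = replace(cspec.phantom, true_hard_fraction=float(f), seed=lesion_seed)
            img, base_mask, truth = generate_phantom(spec)
            reader_rng = np.random.default_rng(child_seeds[idx])
            masks = simulate_readers(base_mask, cspec.readers, reader_rng)
            records.append(
                {
                    "lesion_id": f"L{idx + 1:03d}",
                    "truth_label": cls,
                    "truth": int(cls == "malignant"),
                    "true_hard_fraction": float(f),
                    "realized_hard_fraction": truth["realized_hard_fraction"],
                    "image": img,
                    "base_mask": base_mask,
                    "reader_masks": masks,
                }
            )
            idx += 1
    return pd.DataFrame(records)


def cohort_reader_table(cohort: pd.DataFrame, cfg=None) -> pd.DataFrame:
    """Stratify every lesion under every reader's mask.

    Returns the long reader table consumed by the agreement and
    diagnostics modules: lesion_id, reader_id, label (1/2/3),
    hard_fraction, area_px, truth.
    """
    from .stratification import LABEL_SCORES, CutoffConfig, stratify

    if cfg is None:
        cfg = CutoffConfig()
    rows = []
    for rec in cohort.itertuples(index=False):
        for reader_id, mask in rec.reader_masks.items():
            res = stratify(rec.image, mask, cfg)
            rows.append(
                {
                    "lesion_id": rec.lesion_id,
                    "reader_id": reader_id,
                    "label": LABEL_SCORES[res.label],
                    "hard_fraction": res.hard_fraction,
                    "area_px": mask.area_px,
                    "truth": rec.truth,
                }
            )
    return pd.DataFrame(rows)
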