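"""Image and ROI-mask representation, file I/O, and RGB→CIELab conversion.

Elastography frames are handled as plain 8-bit RGB pixel grids. Lesion
regions of interest (ROIs) are binary masks on the same grid: the manual
B-mode segmentation is transferred to the elastogram as an identity mapping,
since both frames come from one co-registered dual display.

Color conversion follows the sRGB standard (IEC 61966-2-1 companding, D65
reference white, 2° observer), the universal default for consumer-format
image exports; vendors do not document their elastogram RGB working space.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import rgb2lab

__all__ = [
    "ElastogramImage",
    "LabImage",
    "ROIMask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "rgb_to_cielab",
]


@dataclass(frozen=True)
class ElastogramImage:
    """8-bit RGB elastography frame.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        Channel order R, G, B; row-major, 0-based (row, col) indexing.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an H×W×3 RGB array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if px.dtype != np.uint8:
            raise ValueError(f"expected 8-bit (uint8) channels, got dtype {px.dtype}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class LabImage:
    """CIELab planes of an elastogram.

    L* is lightness (0 black – 100 white), a* the green(−)/red(+) axis and
    b* the blue(−)/yellow(+) axis. Grids align pixel-for-pixel with the
    source RGB frame.
    """

    L_star: np.ndarray
    a_star: np.ndarray
    b_star: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L_star.shape == self.a_star.shape == self.b_star.shape):
            raise ValueError("L*, a*, b* planes must share one H×W grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L_star.shape


@dataclass(frozen=True)
class ROIMask:
    """Binary lesion mask on the image grid (True = inside the lesion)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {m.shape}")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def read_image(path: str | Path) -> ElastogramImage:
    """Read an 8-bit PNG or TIFF elastography frame.

    Grayscale inputs are promoted to three identical channels; an alpha
    channel, if present, is discarded. Bit depths above 8 bits/channel are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise ValueError(
            f"unsupported bit depth in {path}: dtype {arr.dtype} "
            "(only 8 bits/channel is supported)"
        )
    if arr.ndim == 2:  # grayscale → replicate
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = np.stack([arr[:, :, 0]] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"cannot interpret {path} as an RGB image (shape {arr.shape})")
    return ElastogramImage(arr)


def write_image(img: ElastogramImage, path: str | Path) -> None:
    """Write an elastogram as an 8-bit PNG or TIFF (by file extension)."""
    iio.imwrite(Path(path), img.pixels)


def _read_mask_csv(path: Path, shape: tuple[int, int]) -> np.ndarray:
    """Run-length mask: rows of (row, start_col, end_col), 0-based, end-exclusive."""
    mask = np.zeros(shape, dtype=bool)
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].strip().lower() in ("row", ""):
                continue
            try:
                r, c0, c1 = (int(v) for v in row[:3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed run-length row {row!r}") from exc
            if not (0 <= r < shape[0] and 0 <= c0 <= c1 <= shape[1]):
                raise ValueError(
                    f"{path}:{lineno}: run ({r},{c0},{c1}) outside grid {shape}"
                )
            mask[r, c0:c1] = True
    return mask


def read_mask(path: str | Path, shape: tuple[int, int]) -> ROIMask:
    """Read a binary ROI mask (PNG, nonzero = inside; or run-length CSV).

    ``shape`` is the (H, W) grid of the paired elastogram; a mask on a
    different grid is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    if path.suffix.lower() == ".csv":
        return ROIMask(_read_mask_csv(path, tuple(shape)))
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)  # any nonzero channel counts
    if arr.shape != tuple(shape):
        raise ValueError(
            f"mask shape {arr.shape} from {path} does not match image shape {tuple(shape)}"
        )
    return ROIMask(arr != 0)


def write_mask(roi: ROIMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (255 = inside)."""
    iio.imwrite(Path(path), (roi.mask.astype(np.uint8) * 255))


def rgb_to_cielab(img: ElastogramImage) -> LabImage:
    """Convert an 8-bit RGB elastogram to CIELab.

    Per-pixel sRGB → linear RGB (IEC companding) → XYZ (D65 white, 2°
    observer) → L*a*b*. For any 8-bit input, L* lies in [0, 100] and gray
    pixels map to the achromatic axis (a* ≈ b* ≈ 0).
    """
    lab = rgb2lab(img.pixels)
    return LabImage(
        L_star=np.ascontiguousarray(lab[..., 0]),
        a_star=np.ascontiguousarray(lab[..., 1]),
        b_star=np.ascontiguousarray(lab[..., 2]),
    )
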