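"""Colour-threshold tissue segmentation and per-region track statistics.

Haematoxylin/eosin-stained liver sections show necrotic tumour as an
eosin-pink region and viable tissue as purple.  Segmentation is by fixed
8-bit thresholds: a pixel is *tissue* when its grayscale value (unweighted
RGB mean) is below 138 (stained tissue is darker than the blank detector),
and *pink* when additionally R in [123, 177], G in [42, 84] and B in
[94, 139] (closed bands).  *Purple* is tissue that is not pink, so the three
masks obey pink | purple == tissue and pink & purple == {} by construction.

Registered tracks are counted per mask by nearest-pixel lookup and the
region track density carries a Poisson 1-sigma counting error
(sigma = sqrt(count)/area); the concentration efficiency is the pink/purple
density ratio with the relative errors added in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SegmentationThresholds",
    "RegionMask",
    "RegionDensity",
    "ConcentrationEfficiency",
    "to_grayscale",
    "binarize_tissue",
    "band_pass_mask",
    "segment_regions",
    "count_tracks_in_mask",
    "region_density",
    "concentration_efficiency",
    "read_rgb_image",
    "write_rgb_image",
    "write_mask_png",
    "read_mask_png",
]


@dataclass(frozen=True)
class SegmentationThresholds:
    """Fixed 8-bit thresholds for tissue binarisation and the pink band-pass."""

    gray_threshold_8bit: int = 138
    pink_red: tuple[int, int] = (123, 177)
    pink_green: tuple[int, int] = (42, 84)
    pink_blue: tuple[int, int] = (94, 139)
    grayscale_weights: tuple[float, float, float] | None = None  # None = unweighted mean

    def __post_init__(self) -> None:
        if not 0 <= self.gray_threshold_8bit <= 255:
            raise ValueError("gray threshold must be in [0, 255]")
        for lo, hi in (self.pink_red, self.pink_green, self.pink_blue):
            if not 0 <= lo <= hi <= 255:
                raise ValueError("band bounds must satisfy 0 <= low <= high <= 255")


@dataclass
class RegionMask:
    """Binary pixel mask aligned to the tissue image."""

    mask: np.ndarray
    pixel_size_um: float
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def area_mm2(self) -> float:
        return float(np.count_nonzero(self.mask)) * (self.pixel_size_um * 1e-3) ** 2


def _check_rgb(rgb) -> np.ndarray:
    img = np.asarray(rgb)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) 8-bit RGB image")
    return img.astype(np.float64)


def to_grayscale(rgb_image, thresholds: SegmentationThresholds | None = None) -> np.ndarray:
    """8-bit grayscale: unweighted channel mean, rounded half-up.

    Luminance weighting is available through
    ``SegmentationThresholds.grayscale_weights``.
    """
    img = _check_rgb(rgb_image)
    w = thresholds.grayscale_weights if thresholds is not None else None
    if w is None:
        g = img.mean(axis=2)
    else:
        w = np.asarray(w, dtype=float)
        g = img @ (w / w.sum())
    return np.floor(g + 0.5).astype(np.uint8)


def binarize_tissue(
    gray_image,
    thresholds: SegmentationThresholds = SegmentationThresholds(),
    pixel_size_um: float = 0.28,
) -> RegionMask:
    """Tissue mask: gray strictly below the threshold (dark = stained)."""
    gray = np.asarray(gray_image)
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    return RegionMask(gray < thresholds.gray_threshold_8bit, pixel_size_um, "tissue")


def band_pass_mask(
    rgb_image,
    thresholds: SegmentationThresholds = SegmentationThresholds(),
    pixel_size_um: float = 0.28,
) -> RegionMask:
    """Pink (eosin/necrotic tumour) mask: RGB band-pass intersected with tissue."""
    img = _check_rgb(rgb_image)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    in_band = (
        (r >= thresholds.pink_red[0]) & (r <= thresholds.pink_red[1])
        & (g >= thresholds.pink_green[0]) & (g <= thresholds.pink_green[1])
        & (b >= thresholds.pink_blue[0]) & (b <= thresholds.pink_blue[1])
    )
    tissue = binarize_tissue(to_grayscale(rgb_image, thresholds), thresholds, pixel_size_um)
    return RegionMask(in_band & tissue.mask, pixel_size_um, "pink")


def segment_regions(
    rgb_image,
    thresholds: SegmentationThresholds = SegmentationThresholds(),
    pixel_size_um: float = 0.28,
) -> tuple[RegionMask, RegionMask, RegionMask]:
    """(tissue, pink, purple) masks; purple is defined as tissue & ~pink."""
    tissue = binarize_tissue(to_grayscale(rgb_image, thresholds), thresholds, pixel_size_um)
    pink = band_pass_mask(rgb_image, thresholds, pixel_size_um)
    purple = RegionMask(tissue.mask & ~pink.mask, pixel_size_um, "purple")
    return tissue, pink, purple


def count_tracks_in_mask(tracks, mask: RegionMask, transform=None) -> tuple[int, int]:
    """Count tracks whose (transformed) position lands on a true pixel.

    ``tracks`` is an (n, 2) array of detector-frame positions (um) or a
    DataFrame with x_um/y_um columns; ``transform`` maps the detector frame
    into the image frame (None = identity).  Assignment is
    nearest-pixel-centre with ties toward the lower index; positions off the
    image are excluded and returned as the second element.
    """
    if isinstance(tracks, pd.DataFrame):
        pts = tracks[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(tracks, dtype=float).reshape(-1, 2)
    if transform is not None:
        pts = transform.apply(pts)
    if pts.size == 0:
        return 0, 0
    # nearest pixel centre; ceil(v - 0.5) sends exact half-ties downward
    cols = np.ceil(pts[:, 0] / mask.pixel_size_um - 0.5).astype(int)
    rows = np.ceil(pts[:, 1] / mask.pixel_size_um - 0.5).astype(int)
    h, w = mask.mask.shape
    in_img = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    count = int(np.count_nonzero(mask.mask[rows[in_img], cols[in_img]]))
    return count, int(np.count_nonzero(~in_img))


@dataclass(frozen=True)
class RegionDensity:
    """Track density with Poisson counting error over one region."""

    track_count: float
    area_mm2: float
    density_per_mm2: float
    sigma_per_mm2: float

    @classmethod
    def from_density(cls, density_per_mm2: float, sigma_per_mm2: float) -> "RegionDensity":
        """Rebuild the implied count and area from a published density +/- sigma."""
        if sigma_per_mm2 <= 0:
            raise ValueError("sigma must be positive to invert the Poisson relation")
        count = (density_per_mm2 / sigma_per_mm2) ** 2
        return cls(count, count / density_per_mm2, density_per_mm2, sigma_per_mm2)


def region_density(count: float, area_mm2: float) -> RegionDensity:
    """Density = count/area with 1-sigma Poisson error sqrt(count)/area."""
    if not area_mm2 > 0:
        raise ValueError("area_mm2 must be positive")
    return RegionDensity(
        track_count=count,
        area_mm2=float(area_mm2),
        density_per_mm2=count / area_mm2,
        sigma_per_mm2=float(np.sqrt(count)) / area_mm2,
    )


@dataclass(frozen=True)
class ConcentrationEfficiency:
    """Pink/purple track-density ratio with propagated 1-sigma error."""

    ratio: float
    sigma: float


def concentration_efficiency(pink: RegionDensity, purple: RegionDensity) -> ConcentrationEfficiency:
    """Density ratio r = rho_pink/rho_purple; relative errors in quadrature."""
    if purple.density_per_mm2 <= 0:
        raise ZeroDivisionError("purple region density is zero")
    r = pink.density_per_mm2 / purple.density_per_mm2
    rel = 0.0
    if pink.density_per_mm2 > 0:
        rel = np.hypot(
            pink.sigma_per_mm2 / pink.density_per_mm2,
            purple.sigma_per_mm2 / purple.density_per_mm2,
        )
    return ConcentrationEfficiency(ratio=float(r), sigma=float(r * rel))


# ---------------------------------------------------------------------------
# Image I/O (PNG/TIFF via Pillow; masks as 1-bit PNG)

def read_rgb_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_rgb_image(image, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def write_mask_png(mask: RegionMask, path) -> None:
    Image.fromarray((mask.mask * 255).astype(np.uint8)).convert("1").save(path)


def read_mask_png(path, pixel_size_um: float, label: str = "") -> RegionMask:
    arr = np.asarray(Image.open(path).convert("1"), dtype=bool)
    return RegionMask(arr, pixel_size_um, label)
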