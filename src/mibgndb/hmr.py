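"""Planar heart-to-mediastinum ratio (HMR).

The HMR is the mean count in a cardiac region of interest divided by the
mean count in an upper-mediastinal reference region on an anterior planar
image; it is the standard global index of cardiac sympathetic innervation
in 123I-MIBG scintigraphy.  Because the raw ratio depends on collimator and
camera, values are standardized to a common medium-energy general-purpose
collimator condition with the one-point-fixed linear conversion

    HMR_std = c * (HMR_raw - 1) + 1,

whose fixed point at 1 corresponds to a heart with no specific uptake above
background.  Conversion coefficients c come from phantom cross-calibration
and are supplied per acquisition condition in configuration (default 1.0,
the identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class HMRError(ValueError):
    """Raised for invalid images, ROIs or calibration coefficients."""


@dataclass
class PlanarImage:
    """2D non-negative count grid from an anterior planar acquisition."""

    counts: np.ndarray
    pixel_size_mm: float | None = None
    phase: str = "early"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise HMRError("planar image must be 2D")
        if not np.all(np.isfinite(self.counts)) or self.counts.min() < 0:
            raise HMRError("counts must be finite and >= 0")


@dataclass(frozen=True)
class ROIPair:
    """Circular heart ROI and rectangular mediastinum ROI, in pixel units.

    ``heart_center`` is (row, col); ``med_corner`` is the top-left (row, col)
    of the mediastinal box.
    """

    heart_center: tuple[float, float]
    heart_radius: float
    med_corner: tuple[int, int]
    med_height: int
    med_width: int

    def heart_mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
        d2 = (rows - self.heart_center[0]) ** 2 + (cols - self.heart_center[1]) ** 2
        return d2 <= self.heart_radius**2

    def med_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        r0, c0 = self.med_corner
        m[r0:r0 + self.med_height, c0:c0 + self.med_width] = True
        return m

    def validate(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        h = self.heart_mask(shape)
        r0, c0 = self.med_corner
        if r0 < 0 or c0 < 0 or r0 + self.med_height > shape[0] \
                or c0 + self.med_width > shape[1]:
            raise HMRError("mediastinum ROI extends outside the image")
        m = self.med_mask(shape)
        if not h.any() or not m.any():
            raise HMRError("each ROI must cover at least one pixel")
        if (h & m).any():
            raise HMRError("heart and mediastinum ROIs overlap")
        return h, m


@dataclass
class HMRResult:
    raw: float
    standardized: float
    coefficient: float
    source_condition: str = "unspecified"
    target_condition: str = "ME-GP"
    below_unity: bool = False


def compute_hmr(image: PlanarImage, rois: ROIPair) -> float:
    """Raw HMR: mean heart-ROI count / mean mediastinum-ROI count."""
    h, m = rois.validate(image.counts.shape)
    med_mean = image.counts[m].mean()
    if med_mean == 0:
        raise HMRError("mediastinal mean count is zero")
    return float(image.counts[h].mean() / med_mean)


def standardize_hmr(
    raw_hmr: float, coefficient: float = 1.0,
    source_condition: str = "unspecified", target_condition: str = "ME-GP",
) -> HMRResult:
    """Convert a raw HMR to the target collimator condition.

    Applies HMR_std = c * (HMR_raw - 1) + 1.  Raw values below 1 are allowed
    (no specific cardiac uptake) but flagged.  Composing two conversions
    multiplies their coefficients.
    """
    if coefficient <= 0:
        raise HMRError(f"conversion coefficient must be > 0, got {coefficient}")
    std = coefficient * (float(raw_hmr) - 1.0) + 1.0
    return HMRResult(
        raw=float(raw_hmr), standardized=std, coefficient=coefficient,
        source_condition=source_condition, target_condition=target_condition,
        below_unity=raw_hmr < 1.0,
    )
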