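"""AHA 17-segment polar-map geometry and segmental profiles.

A polar map (bullseye) projects left-ventricular tracer uptake onto a disc:
apex at the center, base at the rim.  The American Heart Association model
partitions the disc into 17 segments — 6 basal, 6 mid-cavity, 4 apical
sectors plus an apex disc.  This module realizes that partition on a raster
grid, converts rasters to per-segment mean-count profiles and back, and
normalizes profiles to percent of a reference segment.

Geometry convention
-------------------
Rings are equal-width in radius fraction: apex disc r <= 0.25, apical
0.25-0.5, mid 0.5-0.75, basal 0.75-1.0.  Angle 0 deg points at the anterior
wall (map top as displayed) and increases clockwise toward the septum.
Basal and mid sectors are 60 deg wide, apical sectors 90 deg wide, each
centered on its wall, so the anterior sector of every ring straddles 0 deg.
Segment numbering follows the AHA standard: 1-6 basal (anterior,
anteroseptal, inferoseptal, inferior, inferolateral, anterolateral), 7-12
mid in the same order, 13-16 apical (anterior, septal, inferior, lateral),
17 apex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_SEGMENTS = 17

#: AHA segment names, index 0 = segment 1.
SEGMENT_NAMES = (
    "basal anterior", "basal anteroseptal", "basal inferoseptal",
    "basal inferior", "basal inferolateral", "basal anterolateral",
    "mid anterior", "mid anteroseptal", "mid inferoseptal",
    "mid inferior", "mid inferolateral", "mid anterolateral",
    "apical anterior", "apical septal", "apical inferior", "apical lateral",
    "apex",
)


class PolarMapError(ValueError):
    """Raised for out-of-map pixels, degenerate geometry or bad profiles."""


@dataclass(frozen=True)
class SegmentGeometry:
    """Radial and angular bounds realizing the AHA partition.

    ``ring_bounds`` are outer radius fractions of (apex, apical, mid, basal)
    rings; they must be strictly increasing and end at 1.0.
    ``angle_offset_deg`` rotates the whole sector pattern (0 keeps the
    anterior sector centered on 0 deg).
    """

    ring_bounds: tuple[float, float, float, float] = (0.25, 0.5, 0.75, 1.0)
    angle_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        rb = self.ring_bounds
        if len(rb) != 4 or any(b <= a for a, b in zip(rb, rb[1:])) or rb[0] <= 0:
            raise PolarMapError(f"ring bounds must be increasing in (0, 1]: {rb}")
        if abs(rb[-1] - 1.0) > 1e-12:
            raise PolarMapError("outermost ring bound must be 1.0")


DEFAULT_GEOMETRY = SegmentGeometry()


@dataclass
class PolarMapRaster:
    """Square raster of non-negative counts with a centered disc mask."""

    grid: np.ndarray
    mask: np.ndarray
    phase: str = "early"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise PolarMapError("grid must be a square matrix")
        if self.mask.shape != self.grid.shape:
            raise PolarMapError("mask shape must match grid shape")
        vals = self.grid[self.mask]
        if vals.size and (not np.all(np.isfinite(vals)) or vals.min() < 0):
            raise PolarMapError("masked values must be finite and >= 0")


@dataclass
class SegmentProfile:
    """17 segmental uptake values for one subject and phase.

    Values are percent of reference after :func:`normalize_profile`, raw
    segment means before.  Indexing is by AHA segment number: ``values[s-1]``
    is segment ``s``.
    """

    values: np.ndarray
    phase: str = "early"
    subject_id: str = ""
    sex: str = "all"
    population: str = "other"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SEGMENTS,):
            raise PolarMapError(f"profile needs exactly {N_SEGMENTS} values")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise PolarMapError("segment values must be finite and >= 0")


def disc_mask(resolution: int) -> np.ndarray:
    """Boolean centered-disc mask for a ``resolution`` x ``resolution`` grid."""
    r, _ = _pixel_polar(resolution)
    return (r > 0) & (r <= 1.0)


def _pixel_polar(resolution: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (radius fraction, angle deg) with 0 deg up, clockwise."""
    c = (resolution - 1) / 2.0
    radius = resolution / 2.0
    y, x = np.mgrid[0:resolution, 0:resolution]
    dx = (x - c) / radius
    dy = (c - y) / radius  # +y up in display
    r = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dx, dy)) % 360.0  # 0 at top, clockwise
    return r, ang


def segment_of_pixel(
    radius: float, angle_deg: float, geometry: SegmentGeometry = DEFAULT_GEOMETRY
) -> int:
    """Map a polar pixel coordinate to its AHA segment number (1-17).

    Parameters
    ----------
    radius : radius as a fraction of the map radius, in (0, 1].
    angle_deg : angle in degrees, 0 at the anterior wall, clockwise.
    """
    seg = _segments_of(np.atleast_1d(float(radius)),
                       np.atleast_1d(float(angle_deg) % 360.0), geometry)
    return int(seg[0])


def _segments_of(r: np.ndarray, ang: np.ndarray,
                 geometry: SegmentGeometry) -> np.ndarray:
    if np.any(r <= 0) or np.any(r > 1.0):
        raise PolarMapError("radius outside (0, 1] is not on the map")
    apex_b, apical_b, mid_b, _ = geometry.ring_bounds
    a = (ang - geometry.angle_offset_deg) % 360.0
    seg = np.empty(r.shape, dtype=int)

    apex = r <= apex_b
    apical = (r > apex_b) & (r <= apical_b)
    mid = (r > apical_b) & (r <= mid_b)
    basal = r > mid_b

    seg[apex] = 17
    # 90-deg apical sectors centered on anterior/septal/inferior/lateral walls
    seg[apical] = 13 + (np.floor((a[apical] + 45.0) / 90.0).astype(int) % 4)
    # 60-deg sectors centered on each wall; anterior straddles 0 deg
    seg[mid] = 7 + (np.floor((a[mid] + 30.0) / 60.0).astype(int) % 6)
    seg[basal] = 1 + (np.floor((a[basal] + 30.0) / 60.0).astype(int) % 6)
    return seg


def segment_label_map(
    resolution: int, geometry: SegmentGeometry = DEFAULT_GEOMETRY
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel segment labels (0 outside the disc) and the disc mask."""
    r, ang = _pixel_polar(resolution)
    mask = (r > 0) & (r <= 1.0)
    labels = np.zeros((resolution, resolution), dtype=int)
    labels[mask] = _segments_of(r[mask], ang[mask], geometry)
    return labels, mask


def profile_from_raster(
    raster: PolarMapRaster, geometry: SegmentGeometry = DEFAULT_GEOMETRY,
    **profile_kwargs,
) -> SegmentProfile:
    """Per-segment mean counts of the masked pixels (raw, pre-normalization)."""
    n = raster.grid.shape[0]
    labels, _ = segment_label_map(n, geometry)
    labels = np.where(raster.mask, labels, 0)
    values = np.empty(N_SEGMENTS)
    for s in range(1, N_SEGMENTS + 1):
        sel = labels == s
        if not sel.any():
            raise PolarMapError(f"segment {s} has no masked pixels (degenerate geometry)")
        values[s - 1] = raster.grid[sel].mean()
    return SegmentProfile(values, phase=raster.phase, **profile_kwargs)


def raster_from_profile(
    profile: SegmentProfile, geometry: SegmentGeometry = DEFAULT_GEOMETRY,
    resolution: int = 128,
) -> PolarMapRaster:
    """Piecewise-constant raster whose segment means round-trip exactly."""
    labels, mask = segment_label_map(resolution, geometry)
    counts = np.bincount(labels.ravel(), minlength=N_SEGMENTS + 1)
    if np.any(counts[1:] == 0):
        raise PolarMapError(
            f"resolution {resolution} leaves a segment empty (degenerate geometry)")
    grid = np.zeros((resolution, resolution))
    grid[mask] = profile.values[labels[mask] - 1]
    return PolarMapRaster(grid, mask, phase=profile.phase)


def normalize_profile(
    profile: SegmentProfile, reference: str = "max_segment"
) -> SegmentProfile:
    """Rescale a raw profile so the reference maps to 100%.

    ``reference='max_segment'`` (default) takes the highest segment mean as
    100%; ``reference='mean'`` uses the 17-segment mean, in which case values
    above the mean exceed 100%.  Scaling is linear, so
    ``normalize(c*x) == normalize(x)`` for any c > 0.
    """
    if reference == "max_segment":
        ref = profile.values.max()
    elif reference == "mean":
        ref = profile.values.mean()
    else:
        raise PolarMapError(f"unknown normalization reference {reference!r}")
    if ref <= 0:
        raise PolarMapError("cannot normalize an all-zero profile")
    return SegmentProfile(
        profile.values / ref * 100.0, phase=profile.phase,
        subject_id=profile.subject_id, sex=profile.sex,
        population=profile.population, normalized=True,
    )
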