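"""Fixed-cell colocalization statistics.

Two measures used on immunofluorescence images of late-prophase cells:

* an auto-thresholded colocalization percentage on a small (default
  4.2 µm²) region of interest of a maximum-intensity projection, in the
  style of the Fiji "Colocalization Threshold" plugin (Costes-type
  downward threshold sweep until the below-threshold Pearson correlation
  is non-positive, then a thresholded Manders-style overlap fraction);

* a 1D profile-overlap percentage along a manually defined line ROI
  (default 6 µm) at the nuclear envelope: the area of the reference
  profile covered by the second profile, ∫min(a, b)dx / ∫a dx.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import VoxelGrid
from .errors import (
    InvalidParameterError,
    UndefinedOverlapError,
    UndefinedPercentError,
    UndefinedRegressionError,
)

__all__ = [
    "Roi2D",
    "IntensityProfile",
    "ThresholdPair",
    "ColocResult2D",
    "max_projection",
    "auto_threshold_pair",
    "coloc_percent_fixed",
    "profile_overlap_percent",
]

#: ROI area used in the published fixed-cell analysis, µm².
DEFAULT_ROI_AREA_UM2 = 4.2
#: Line-ROI length used for nuclear-envelope profiles, µm.
DEFAULT_PROFILE_LENGTH_UM = 6.0


@dataclass
class Roi2D:
    """Rectangular region of interest on a 2D image.

    ``origin`` is (row, col) in pixels; ``area`` derives from the pixel
    size. Use :meth:`square_of_area` for the conventional 4.2 µm² square.
    """

    origin: tuple[int, int]
    height: int
    width: int
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise InvalidParameterError("ROI must span at least one pixel")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")

    @property
    def area(self) -> float:
        """ROI area in µm²."""
        return self.height * self.width * self.pixel_size**2

    @classmethod
    def square_of_area(
        cls, pixel_size: float, area_um2: float = DEFAULT_ROI_AREA_UM2,
        origin: tuple[int, int] = (0, 0),
    ) -> "Roi2D":
        side = max(1, int(round(np.sqrt(area_um2) / pixel_size)))
        return cls(origin=origin, height=side, width=side, pixel_size=pixel_size)

    @classmethod
    def full(cls, image: np.ndarray, pixel_size: float = 1.0) -> "Roi2D":
        return cls(origin=(0, 0), height=image.shape[0], width=image.shape[1],
                   pixel_size=pixel_size)

    def slices(self) -> tuple[slice, slice]:
        r, c = self.origin
        return slice(r, r + self.height), slice(c, c + self.width)

    def extract(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        if image.ndim != 2:
            raise InvalidParameterError("ROI extraction expects a 2D image")
        r, c = self.origin
        if r < 0 or c < 0 or r + self.height > image.shape[0] or c + self.width > image.shape[1]:
            raise InvalidParameterError("ROI extends beyond the image")
        return image[self.slices()]


@dataclass
class IntensityProfile:
    """Intensity samples along a line ROI (positions in µm)."""

    positions: np.ndarray
    values: np.ndarray
    baseline: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise InvalidParameterError("positions and values must be equal-length 1D arrays")
        if self.positions.size < 2:
            raise InvalidParameterError("profile needs at least two samples")
        if np.any(np.diff(self.positions) <= 0):
            raise InvalidParameterError("positions must be strictly increasing")
        if np.any(self.values < 0):
            raise InvalidParameterError("profile values must be >= 0 after baseline subtraction")

    @property
    def roi_length(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    @classmethod
    def from_raw(
        cls, positions: np.ndarray, raw_values: np.ndarray, subtract_baseline: bool = True
    ) -> "IntensityProfile":
        """Build a profile, optionally subtracting the per-profile minimum
        as baseline (negative residuals clipped at 0)."""
        raw_values = np.asarray(raw_values, dtype=float)
        baseline = float(raw_values.min()) if subtract_baseline else 0.0
        vals = np.clip(raw_values - baseline, 0.0, None)
        return cls(positions=np.asarray(positions, dtype=float), values=vals, baseline=baseline)


@dataclass
class ThresholdPair:
    """Result of the Costes-style downward threshold sweep."""

    threshold_a: float
    threshold_b: float
    pearson_below: float   # correlation of below-threshold pixels at termination (NaN if undefined)
    at_floor: bool         # sweep exhausted without reaching Pearson <= 0
    slope: float
    intercept: float


@dataclass
class ColocResult2D:
    """Thresholded colocalization percentage with provenance."""

    percent: float
    threshold_a: float
    threshold_b: float
    pearson_below_threshold: float
    at_floor: bool
    denominator: str   # "reference" or "roi_total"

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent <= 100.0):
            raise InvalidParameterError("percent must lie in [0, 100]")


def max_projection(grid: VoxelGrid | np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along z: out[y, x] = max_z in[z, y, x]."""
    data = grid.data if isinstance(grid, VoxelGrid) else np.asarray(grid)
    if data.ndim != 3:
        raise InvalidParameterError("max projection expects a 3D (Z, Y, X) volume")
    return data.max(axis=0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def auto_threshold_pair(
    a: np.ndarray, b: np.ndarray, roi: Roi2D | None = None, n_steps: int = 256
) -> ThresholdPair:
    """Costes-style automatic threshold pair for two channels.

    Fits ``b ≈ m·a + c`` by ordinary least squares over the ROI, then
    sweeps candidate pairs ``(T, m·T + c)`` downward from max(a) in
    ``n_steps`` histogram-bin steps. The chosen pair is the highest for
    which the Pearson correlation of pixels *below both* thresholds is
    ≤ 0. If no candidate qualifies (e.g. identical channels), the sweep
    floor is returned with ``at_floor=True``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("channels must share a shape")
    roi = roi or Roi2D.full(a)
    a_roi = roi.extract(a).ravel()
    b_roi = roi.extract(b).ravel()
    if np.ptp(a_roi) == 0 or np.ptp(b_roi) == 0:
        raise UndefinedRegressionError("zero-variance channel in ROI: regression undefined")
    slope, intercept = np.polyfit(a_roi, b_roi, 1)

    lo, hi = float(a_roi.min()), float(a_roi.max())
    # start one step below max(a): a threshold at the maximum leaves no
    # above-threshold reference pixels and is degenerate by construction
    candidates = np.linspace(hi, lo, n_steps + 1)[1:]
    chosen_t, chosen_r, at_floor = candidates[-1], np.nan, True
    for t in candidates:
        below = (a_roi < t) & (b_roi < slope * t + intercept)
        r = _pearson(a_roi[below], b_roi[below])
        if np.isfinite(r) and r <= 0:
            chosen_t, chosen_r, at_floor = t, r, False
            break
    return ThresholdPair(
        threshold_a=float(chosen_t),
        threshold_b=float(slope * chosen_t + intercept),
        pearson_below=chosen_r,
        at_floor=at_floor,
        slope=float(slope),
        intercept=float(intercept),
    )


def coloc_percent_fixed(
    a: np.ndarray,
    b: np.ndarray,
    roi: Roi2D | None = None,
    denominator: str = "reference",
    n_steps: int = 256,
) -> ColocResult2D:
    """Auto-thresholded colocalization percentage of channel a with b.

    With the default ``denominator="reference"``, the percentage is
    100 × |{a > Tₐ and b > T_b}| / |{a > Tₐ}| over the ROI — the fraction
    of above-threshold reference pixels that are also above threshold in
    the second channel (a thresholded Manders-style fraction).
    ``denominator="roi_total"`` divides by the ROI pixel count instead.
    """
    if denominator not in ("reference", "roi_total"):
        raise InvalidParameterError("denominator must be 'reference' or 'roi_total'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    roi = roi or Roi2D.full(a)
    pair = auto_threshold_pair(a, b, roi, n_steps=n_steps)
    a_roi = roi.extract(a).ravel()
    b_roi = roi.extract(b).ravel()
    above_a = a_roi > pair.threshold_a
    both = above_a & (b_roi > pair.threshold_b)
    if denominator == "reference":
        n_ref = int(above_a.sum())
        if n_ref == 0:
            raise UndefinedPercentError("no reference-channel pixels above threshold")
        percent = 100.0 * both.sum() / n_ref
    else:
        percent = 100.0 * both.sum() / a_roi.size
    return ColocResult2D(
        percent=float(percent),
        threshold_a=pair.threshold_a,
        threshold_b=pair.threshold_b,
        pearson_below_threshold=pair.pearson_below,
        at_floor=pair.at_floor,
        denominator=denominator,
    )


def profile_overlap_percent(a: IntensityProfile, b: IntensityProfile) -> float:
    """Percentage of the reference profile's area covered by the second.

    100 × ∫min(a, b)dx / ∫a dx with trapezoidal integration; asymmetric
    by design (a is the reference channel). Profiles must share sample
    positions and be baseline-subtracted already.
    """
    if a.positions.shape != b.positions.shape or not np.allclose(a.positions, b.positions):
        raise InvalidParameterError("profiles must share the same positions")
    denom = float(np.trapezoid(a.values, a.positions))
    if denom <= 0:
        raise UndefinedOverlapError("reference profile integrates to zero")
    num = float(np.trapezoid(np.minimum(a.values, b.values), a.positions))
    return 100.0 * num / denom
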