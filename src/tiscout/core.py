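"""Automated optimal-TI selection from a black-blood LGE TI scout.

The algorithm mimics the manual reading: among the scout images, pick the
one in which blood pool and healthy myocardium are best nulled.  It does so
without any segmentation, in two steps:

1. Derive a region of interest (ROI) — a rectangle or disk concentric with
   the operator-placed shim box, shrunk by a divisor ``k`` (ROI dimension =
   shim dimension / k).  The ROI samples blood pool, or blood pool plus
   myocardium, without needing to know which pixel is which.

2. Build a bin-size-1 intensity histogram of the ROI for every image.  The
   best-nulled image has the narrowest intensity distribution, hence the
   tallest histogram peak across the whole series; the gray level of that
   global peak becomes a common threshold ``S_thr``.  The image with the
   most sub-threshold ROI pixels is selected and its TI returned.

All argmax ties resolve deterministically and independently of storage
order: gray-level ties toward the lower level, peak-height ties across
images toward the lower modal gray level then the lower TI, and
sub-threshold-count ties toward the lower TI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .scout_io import ScoutSeries, ShimBox, ScoutValidationError

__all__ = [
    "RoiSpec",
    "RoiMask",
    "SelectionResult",
    "DegenerateRoiError",
    "DEFAULT_ROI_SPEC",
    "derive_roi",
    "compute_histograms",
    "find_threshold",
    "count_subthreshold",
    "select_ti",
]

#: Minimum ROI pixel count below which the histogram statistics are
#: meaningless and selection refuses to run.
MIN_ROI_PIXELS = 16

ThresholdMode = Literal["inclusive", "strict"]


class DegenerateRoiError(ValueError):
    """ROI too small (fewer than ``MIN_ROI_PIXELS`` pixels) to be usable."""


@dataclass(frozen=True)
class RoiSpec:
    """Parametric ROI: shape plus the shim-box divisor ``k``.

    ``k = 1`` reproduces the shim box itself; ``k = 4`` is one quarter of
    it.  The validated operating point is a rectangle at ``k = 2.5``.
    """

    shape: Literal["rectangle", "circle"] = "rectangle"
    divisor: float = 2.5

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "circle"):
            raise ValueError(f"ROI shape must be 'rectangle' or 'circle', got {self.shape!r}")
        if not self.divisor >= 1.0:
            raise ValueError(f"ROI divisor must be >= 1, got {self.divisor}")


DEFAULT_ROI_SPEC = RoiSpec("rectangle", 2.5)


@dataclass(frozen=True)
class RoiMask:
    """Boolean pixel mask congruent with the image grid."""

    mask: np.ndarray
    pixel_count: int = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "pixel_count", int(m.sum()))
        if self.pixel_count < MIN_ROI_PIXELS:
            raise DegenerateRoiError(
                f"ROI has {self.pixel_count} pixels; at least {MIN_ROI_PIXELS} required"
            )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of automated TI selection, with full provenance.

    ``subthreshold_counts[n]`` is the number of ROI pixels of image ``n``
    (TI-ascending order) at or below the threshold (or strictly below, per
    ``threshold_mode``); the selected image maximizes this count.
    """

    selected_ti_ms: float
    selected_index: int
    threshold: int
    peak_image_index: int
    subthreshold_counts: tuple[int, ...]
    roi_pixel_count: int
    roi_shape: str
    roi_divisor: float
    threshold_mode: str
    series_id: str = ""
    ti_grid_ms: tuple[float, ...] = ()

    @property
    def subthreshold_fraction(self) -> float:
        return self.subthreshold_counts[self.selected_index] / self.roi_pixel_count

    def to_dict(self) -> dict:
        return {
            "selected_ti_ms": self.selected_ti_ms,
            "selected_index": self.selected_index,
            "threshold": self.threshold,
            "peak_image_index": self.peak_image_index,
            "subthreshold_counts": list(self.subthreshold_counts),
            "roi_pixel_count": self.roi_pixel_count,
            "roi_shape": self.roi_shape,
            "roi_divisor": self.roi_divisor,
            "threshold_mode": self.threshold_mode,
            "series_id": self.series_id,
            "ti_grid_ms": list(self.ti_grid_ms),
            "subthreshold_fraction": self.subthreshold_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        required = (
            "selected_ti_ms",
            "selected_index",
            "threshold",
            "peak_image_index",
            "subthreshold_counts",
            "roi_pixel_count",
        )
        missing = [k for k in required if k not in d or d[k] is None]
        if missing:
            raise ScoutValidationError(f"incomplete selection result: missing {missing}")
        return cls(
            selected_ti_ms=float(d["selected_ti_ms"]),
            selected_index=int(d["selected_index"]),
            threshold=int(d["threshold"]),
            peak_image_index=int(d["peak_image_index"]),
            subthreshold_counts=tuple(int(c) for c in d["subthreshold_counts"]),
            roi_pixel_count=int(d["roi_pixel_count"]),
            roi_shape=str(d.get("roi_shape", "rectangle")),
            roi_divisor=float(d.get("roi_divisor", 2.5)),
            threshold_mode=str(d.get("threshold_mode", "inclusive")),
            series_id=str(d.get("series_id", "")),
            ti_grid_ms=tuple(float(t) for t in d.get("ti_grid_ms", ())),
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def derive_roi(shim: ShimBox, spec: RoiSpec, grid_shape: tuple[int, int]) -> RoiMask:
    """Build the ROI mask concentric with the shim box.

    Rectangle: width = shim.width/k and height = shim.height/k, each rounded
    to the nearest integer pixel count (at least 4), centered on the shim
    box.  Circle: a disk of diameter min(shim.width, shim.height)/k, so the
    disk is always contained in the shim box; a pixel belongs to the disk
    when its center lies within the radius.
    """
    if not shim.fits_in(grid_shape):
        raise ScoutValidationError(f"shim box {shim} exceeds grid {grid_shape}")
    rows, cols = grid_shape
    mask = np.zeros((rows, cols), dtype=bool)
    k = spec.divisor
    if spec.shape == "rectangle":
        w = max(4, _round_half_up(shim.width / k))
        h = max(4, _round_half_up(shim.height / k))
        x0 = shim.x0 + (shim.width - w) // 2
        y0 = shim.y0 + (shim.height - h) // 2
        mask[y0 : y0 + h, x0 : x0 + w] = True
    else:
        radius = min(shim.width, shim.height) / k / 2.0
        cx, cy = shim.center
        yy, xx = np.mgrid[0:rows, 0:cols]
        # pixel centers at (col + 0.5, row + 0.5)
        mask = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= radius**2
    return RoiMask(mask)


def compute_histograms(series: ScoutSeries, roi: RoiMask) -> np.ndarray:
    """Bin-size-1 intensity histograms of the ROI, one row per image.

    Returns an ``(N, max_pi + 1)`` array where row ``n``, column ``i``
    counts ROI pixels of image ``n`` with gray level exactly ``i``.
    """
    if roi.mask.shape != series.grid_shape:
        raise ScoutValidationError(
            f"ROI grid {roi.mask.shape} does not match series grid {series.grid_shape}"
        )
    nbins = series.max_pi + 1
    hists = np.empty((len(series), nbins), dtype=np.int64)
    for n, image in enumerate(series.images):
        hists[n] = np.bincount(image.pixels[roi.mask], minlength=nbins)
    return hists


def find_threshold(hists: np.ndarray) -> tuple[int, int]:
    """Common threshold ``S_thr`` and the index of the image that sets it.

    The image whose histogram attains the tallest peak over the whole
    series defines the threshold; the threshold is the gray level of that
    peak.  Ties across gray levels break toward the lower level; ties in
    peak height across images break toward the image whose peak sits at
    the lower gray level (the better-nulled image), then toward the lower
    TI.  Both rules are deterministic and independent of storage order.
    """
    hists = np.asarray(hists)
    if hists.ndim != 2 or hists.shape[0] == 0:
        raise ValueError("histogram set must be a non-empty 2-D array")
    peak_heights = hists.max(axis=1)
    top = peak_heights.max()
    candidates = np.flatnonzero(peak_heights == top)
    # per-candidate modal gray level (first occurrence = lowest level)
    modes = [int(np.argmax(hists[n])) for n in candidates]
    alpha = int(candidates[int(np.argmin(modes))])  # argmin is first = lowest TI
    s_thr = int(np.argmax(hists[alpha]))
    return s_thr, alpha


def count_subthreshold(
    hists: np.ndarray, s_thr: int, mode: ThresholdMode = "inclusive"
) -> np.ndarray:
    """Per-image count of sub-threshold ROI pixels ``g(n)``.

    ``inclusive`` counts gray levels ``i <= s_thr`` (the modal level of the
    best-nulled image itself represents nulled tissue); ``strict`` counts
    ``i < s_thr``.
    """
    hists = np.asarray(hists)
    if not 0 <= s_thr < hists.shape[1]:
        raise ValueError(f"threshold {s_thr} outside gray-level range [0, {hists.shape[1] - 1}]")
    if mode == "inclusive":
        return hists[:, : s_thr + 1].sum(axis=1)
    if mode == "strict":
        return hists[:, :s_thr].sum(axis=1)
    raise ValueError(f"threshold mode must be 'inclusive' or 'strict', got {mode!r}")


def select_ti(
    series: ScoutSeries,
    spec: RoiSpec = DEFAULT_ROI_SPEC,
    threshold_mode: ThresholdMode = "inclusive",
) -> SelectionResult:
    """Run the full pipeline and return the optimal TI with provenance.

    Composes ROI derivation, per-image histograms, common-threshold
    detection and sub-threshold counting; the selected image maximizes the
    sub-threshold count, ties toward the lower TI.
    """
    roi = derive_roi(series.shim, spec, series.grid_shape)
    hists = compute_histograms(series, roi)
    s_thr, alpha = find_threshold(hists)
    g = count_subthreshold(hists, s_thr, threshold_mode)
    selected = int(np.argmax(g))  # first occurrence = lowest TI
    return SelectionResult(
        selected_ti_ms=float(series.ti_grid_ms[selected]),
        selected_index=selected,
        threshold=s_thr,
        peak_image_index=alpha,
        subthreshold_counts=tuple(int(c) for c in g),
        roi_pixel_count=roi.pixel_count,
        roi_shape=spec.shape,
        roi_divisor=spec.divisor,
        threshold_mode=threshold_mode,
        series_id=series.series_id,
        ti_grid_ms=tuple(float(t) for t in series.ti_grid_ms),
    )
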