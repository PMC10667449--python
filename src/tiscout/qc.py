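"""Quality control for automated TI selection.

Two failure modes call for re-acquisition rather than trusting the chosen
TI:

* **Sub-optimal TI range** — the true nulling point lies outside the
  scouted grid, which manifests as the first or last scout image being
  selected.  The remedy is to scout again with smaller (respectively
  larger) TIs; :func:`check_boundary` flags the case and suggests a range.

* **Artifacts in the ROI** — bright artifacts inflate the hyperintense
  pixel population and depress the proportion of sub-threshold pixels in
  the selected image.  :func:`check_artifact` compares that proportion
  against a reference median built from trusted cases
  (:func:`build_reference`); a selected image whose sub-threshold fraction
  falls below ``tolerance_factor`` times the reference is flagged.

Neither rule has a clinically validated cut-off; the defaults here are
engineering choices, exposed as parameters.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import SelectionResult
from .scout_io import ScoutSeries

__all__ = [
    "QcReport",
    "InsufficientReferenceError",
    "check_boundary",
    "check_artifact",
    "build_reference",
    "evaluate",
    "DEFAULT_TOLERANCE_FACTOR",
]

#: Artifact flag fires when the selected image's sub-threshold fraction is
#: below this multiple of the reference median.  A bright artifact covering
#: a fraction f of the ROI scales the fraction by roughly (1 - f), so 0.75
#: catches artifacts occupying more than about a quarter of the ROI while
#: tolerating ordinary anatomical variation.
DEFAULT_TOLERANCE_FACTOR = 0.75

#: Suggested TI extension spans this many native grid increments.
DEFAULT_EXTENSION_STEPS = 5

#: Physical floor for suggested TIs (ms); an inversion time must stay positive.
MIN_SUGGESTED_TI_MS = 10.0


class InsufficientReferenceError(ValueError):
    """Too few trusted cases to form an artifact reference median."""


@dataclass(frozen=True)
class QcReport:
    """Aggregated QC verdict for one selection.

    ``boundary_flag`` is ``"none"``, ``"extend_lower"`` or ``"extend_upper"``;
    ``artifact_flag`` is ``None`` when no reference median was available
    (check skipped), otherwise a boolean.
    """

    boundary_flag: str
    subthreshold_fraction: float
    artifact_flag: bool | None = None
    reference_median_fraction: float | None = None
    tolerance_factor: float | None = None
    suggested_ti_range_ms: tuple[float, float] | None = None

    @property
    def acceptable(self) -> bool:
        """True when no QC rule fired."""
        return self.boundary_flag == "none" and not self.artifact_flag

    def to_dict(self) -> dict:
        return {
            "boundary_flag": self.boundary_flag,
            "subthreshold_fraction": self.subthreshold_fraction,
            "artifact_flag": self.artifact_flag,
            "reference_median_fraction": self.reference_median_fraction,
            "tolerance_factor": self.tolerance_factor,
            "suggested_ti_range_ms": list(self.suggested_ti_range_ms)
            if self.suggested_ti_range_ms
            else None,
            "acceptable": self.acceptable,
        }


def _native_increment(series: ScoutSeries) -> float:
    return float(np.median(np.diff(series.ti_grid_ms)))


def check_boundary(
    result: SelectionResult,
    series: ScoutSeries,
    n_steps: int = DEFAULT_EXTENSION_STEPS,
) -> tuple[str, tuple[float, float] | None]:
    """Flag selections landing on the first or last scouted TI.

    Returns ``(flag, suggested_range)`` where the suggested range extends
    the scout by ``n_steps`` native increments below (``extend_lower``) or
    above (``extend_upper``) the scouted grid, clipped so TIs stay at or
    above ``MIN_SUGGESTED_TI_MS``.
    """
    step = _native_increment(series)
    ti = series.ti_grid_ms
    if result.selected_index == 0:
        lo = max(MIN_SUGGESTED_TI_MS, ti[0] - n_steps * step)
        hi = ti[0] - step
        if hi < lo:  # grid already starts at the physical floor
            return "extend_lower", None
        return "extend_lower", (float(lo), float(hi))
    if result.selected_index == len(series) - 1:
        return "extend_upper", (float(ti[-1] + step), float(ti[-1] + n_steps * step))
    return "none", None


def check_artifact(
    result: SelectionResult,
    reference_median: float,
    tolerance_factor: float = DEFAULT_TOLERANCE_FACTOR,
) -> bool:
    """Flag a suspected artifact in the ROI of the selected image.

    Fires when the selected image's sub-threshold fraction is strictly
    below ``tolerance_factor * reference_median``.
    """
    if not 0.0 < reference_median <= 1.0:
        raise ValueError(f"reference median must lie in (0, 1], got {reference_median}")
    if not 0.0 < tolerance_factor <= 1.0:
        raise ValueError(f"tolerance factor must lie in (0, 1], got {tolerance_factor}")
    return result.subthreshold_fraction < tolerance_factor * reference_median


def build_reference(results: Iterable[SelectionResult] | Sequence[float]) -> float:
    """Median sub-threshold fraction over a collection of trusted selections.

    Accepts selection results or raw fractions; with an even count the mean
    of the two central values is returned.  At least 3 cases are required.
    """
    fractions = [
        r.subthreshold_fraction if isinstance(r, SelectionResult) else float(r)
        for r in results
    ]
    if len(fractions) < 3:
        raise InsufficientReferenceError(
            f"need at least 3 results for a reference median, got {len(fractions)}"
        )
    return float(statistics.median(fractions))


def evaluate(
    result: SelectionResult,
    series: ScoutSeries,
    reference_median: float | None = None,
    tolerance_factor: float = DEFAULT_TOLERANCE_FACTOR,
    n_steps: int = DEFAULT_EXTENSION_STEPS,
) -> QcReport:
    """Run all QC rules and assemble a report.

    The artifact check is skipped (flag ``None``) when no reference median
    is supplied.
    """
    flag, suggested = check_boundary(result, series, n_steps=n_steps)
    artifact: bool | None = None
    if reference_median is not None:
        artifact = check_artifact(result, reference_median, tolerance_factor)
    return QcReport(
        boundary_flag=flag,
        subthreshold_fraction=result.subthreshold_fraction,
        artifact_flag=artifact,
        reference_median_fraction=reference_median,
        tolerance_factor=tolerance_factor if reference_median is not None else None,
        suggested_ti_range_ms=suggested,
    )
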