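"""Synthetic TI-scout phantoms with known ground-truth nulling TI.

The phantom emulates a mid-ventricular short-axis slice: a circular blood
pool inside a myocardial annulus, an optional scar sector within the
annulus, and background tissue.  Each compartment follows a surrogate
inversion-recovery magnitude signal

    S(TI) = | m0 * (1 - (1 + eta) * exp(-TI / T1_eff)) |

with equilibrium amplitude ``m0`` (gray levels), effective recovery
constant ``T1_eff`` (ms) and inversion efficiency ``eta``.  This stands in
for the sequence's magnetization-prepared bSSFP contrast; the one property
it must preserve is that blood and healthy myocardium null near a common
TI inside the scouted range, which is what the preparation is tuned to
achieve on the scanner.

Real tissue is not uniform: proton density and receive sensitivity vary
smoothly across a compartment, so the intensity spread of a tissue scales
with its mean signal — the narrow-histogram-at-nulling property the
selection algorithm exploits.  The phantom reproduces this with a
deterministic multiplicative heterogeneity field (default +-20 percent);
without it every noiseless compartment would collapse to a single gray
level and histogram peak heights would carry no information.

Noise is Rician (magnitude of a complex Gaussian perturbation), as for any
MR magnitude image.  A bright-streak artifact can be injected for QC
testing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .core import DEFAULT_ROI_SPEC, RoiSpec, select_ti
from .scout_io import DEFAULT_MAX_PI, ScoutImage, ScoutSeries, ShimBox, quantize_pixels

__all__ = [
    "TissueParams",
    "StreakSpec",
    "PhantomSpec",
    "DEFAULT_TI_GRID_MS",
    "ground_truth_ti",
    "generate_scout",
    "recovery_experiment",
    "RecoveryResult",
    "sample_phantom_spec",
]

logger = logging.getLogger(__name__)

#: Default scout grid: 60-160 ms in 10 ms increments, 11 images.
DEFAULT_TI_GRID_MS: tuple[float, ...] = tuple(float(t) for t in range(60, 161, 10))


@dataclass(frozen=True)
class TissueParams:
    """Surrogate inversion-recovery parameters of one tissue compartment."""

    m0: float
    t1_eff_ms: float
    inv_eff: float = 1.0

    def __post_init__(self) -> None:
        if self.m0 <= 0:
            raise ValueError(f"m0 must be positive, got {self.m0}")
        if self.t1_eff_ms <= 0:
            raise ValueError(f"t1_eff_ms must be positive, got {self.t1_eff_ms}")
        if not 0.0 <= self.inv_eff <= 1.0:
            raise ValueError(f"inv_eff must lie in [0, 1], got {self.inv_eff}")

    def signal(self, ti_ms: float | np.ndarray) -> np.ndarray:
        """Noiseless magnitude signal at inversion time ``ti_ms``."""
        ti = np.asarray(ti_ms, dtype=float)
        return np.abs(self.m0 * (1.0 - (1.0 + self.inv_eff) * np.exp(-ti / self.t1_eff_ms)))

    @property
    def null_ti_ms(self) -> float:
        """TI at which the signal crosses zero: T1_eff * ln(1 + eta)."""
        return self.t1_eff_ms * math.log(1.0 + self.inv_eff)


@dataclass(frozen=True)
class StreakSpec:
    """Bright horizontal streak artifact, constant across TIs.

    ``center_row = None`` centers the streak on the phantom's heart center.
    ``heterogeneity`` widens the streak's intensity spread so it emulates
    modulated ghosting rather than a flat bar.
    """

    width_px: int
    amplitude: float
    center_row: int | None = None
    heterogeneity: float = 0.2


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic scout acquisition."""

    grid_shape: tuple[int, int] = (128, 128)
    center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    blood_radius: float = 18.0
    myo_inner_radius: float = 18.0
    myo_outer_radius: float = 26.0
    blood: TissueParams = TissueParams(600.0, 150.0, 1.0)
    myocardium: TissueParams = TissueParams(400.0, 160.0, 1.0)
    background: TissueParams = TissueParams(300.0, 800.0, 1.0)
    scar: TissueParams | None = None
    scar_angle_deg: tuple[float, float] = (0.0, 60.0)
    scar_radii: tuple[float, float] | None = None  # defaults to the annulus
    streak: StreakSpec | None = None
    heterogeneity: float = 0.2
    ti_grid_ms: tuple[float, ...] = DEFAULT_TI_GRID_MS
    noise_sigma: float = 12.0
    seed: int = 0
    max_pi: int = DEFAULT_MAX_PI
    shim_pad_px: int = 2

    def __post_init__(self) -> None:
        if self.myo_inner_radius < self.blood_radius:
            raise ValueError("myocardial annulus must enclose the blood disk")
        if self.myo_outer_radius <= self.myo_inner_radius:
            raise ValueError("annulus outer radius must exceed inner radius")
        tis = list(self.ti_grid_ms)
        if len(tis) < 2 or any(b <= a for a, b in zip(tis, tis[1:])):
            raise ValueError("ti_grid_ms must be strictly increasing with >= 2 entries")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.scar_radii is not None:
            lo, hi = self.scar_radii
            if not (self.myo_inner_radius <= lo < hi <= self.myo_outer_radius):
                raise ValueError("scar sector must lie within the myocardial annulus")


# compartment labels in the phantom map
_BACKGROUND, _BLOOD, _MYO, _SCAR = 0, 1, 2, 3


def _label_map(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.grid_shape
    cy, cx = spec.center
    yy, xx = np.mgrid[0:rows, 0:cols]
    r = np.hypot(yy - cy, xx - cx)
    labels = np.full((rows, cols), _BACKGROUND, dtype=np.int8)
    labels[(r > spec.myo_inner_radius) & (r <= spec.myo_outer_radius)] = _MYO
    labels[r <= spec.blood_radius] = _BLOOD
    if spec.scar is not None:
        lo_a, hi_a = spec.scar_angle_deg
        theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
        lo_r, hi_r = spec.scar_radii or (spec.myo_inner_radius, spec.myo_outer_radius)
        in_sector = (theta >= lo_a % 360.0) & (theta < hi_a % 360.0)
        labels[(labels == _MYO) & in_sector & (r >= lo_r) & (r <= hi_r)] = _SCAR
    return labels


def _heterogeneity_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth multiplicative field 1 + beta * u with u in [-1, 1].

    ``u`` is a deterministic diagonal ramp through the heart center,
    scaled so it spans roughly [-1, 1] across a default (shim/2.5) ROI —
    a coarse stand-in for proton-density and receive-profile variation at
    anatomical scale.  A ramp is used rather than a periodic texture
    because its value density is flat: it widens each tissue's intensity
    band in proportion to the signal level without introducing density
    spikes that would masquerade as histogram peaks.
    """
    rows, cols = spec.grid_shape
    cy, cx = spec.center
    yy = np.arange(rows)[:, None] - cy
    xx = np.arange(cols)[None, :] - cx
    u = (yy + xx) / (0.8 * spec.myo_outer_radius)
    return 1.0 + spec.heterogeneity * u


def _shim_box(spec: PhantomSpec) -> ShimBox:
    """Tight bounding box of the myocardial outer circle, padded.

    Emulates the operator guideline of placing the shim-box outline in
    direct contact with the myocardial border.
    """
    rows, cols = spec.grid_shape
    cy, cx = spec.center
    r = spec.myo_outer_radius
    pad = spec.shim_pad_px
    y0 = max(0, int(math.floor(cy - r)) - pad)
    x0 = max(0, int(math.floor(cx - r)) - pad)
    y1 = min(rows, int(math.ceil(cy + r)) + 1 + pad)
    x1 = min(cols, int(math.ceil(cx + r)) + 1 + pad)
    return ShimBox(x0=x0, y0=y0, width=x1 - x0, height=y1 - y0)


def _noiseless_image(spec: PhantomSpec, labels: np.ndarray, het: np.ndarray, ti: float) -> np.ndarray:
    """Continuous-valued noiseless image at one TI (before quantization)."""
    values = np.empty(4)
    values[_BACKGROUND] = spec.background.signal(ti)
    values[_BLOOD] = spec.blood.signal(ti)
    values[_MYO] = spec.myocardium.signal(ti)
    values[_SCAR] = spec.scar.signal(ti) if spec.scar is not None else 0.0
    img = values[labels] * het
    if spec.streak is not None:
        st = spec.streak
        c = st.center_row if st.center_row is not None else int(round(spec.center[0]))
        r0 = max(0, c - st.width_px // 2)
        rows_slice = slice(r0, min(spec.grid_shape[0], r0 + st.width_px))
        cols = spec.grid_shape[1]
        ramp = np.linspace(-1.0, 1.0, cols)[None, :]
        img[rows_slice, :] = st.amplitude * (1.0 + st.heterogeneity * ramp)
    return img


def ground_truth_ti(spec: PhantomSpec) -> float:
    """Grid TI minimizing the noiseless mean magnitude over blood + myocardium.

    The mean is taken over the quantized noiseless images, i.e. over
    exactly what a noise-free acquisition of this phantom would record;
    ties break toward the lower TI.
    """
    labels = _label_map(spec)
    het = _heterogeneity_field(spec)
    target = (labels == _BLOOD) | (labels == _MYO)
    means = []
    for ti in spec.ti_grid_ms:
        img = quantize_pixels(_noiseless_image(spec, labels, het, ti), spec.max_pi)
        means.append(float(img[target].mean()))
    return float(spec.ti_grid_ms[int(np.argmin(means))])


def generate_scout(spec: PhantomSpec, rng: np.random.Generator | None = None) -> ScoutSeries:
    """Simulate the scout series described by ``spec``.

    One image per grid TI; Rician noise of scale ``noise_sigma`` is applied
    to the continuous image (magnitude of two independent Gaussian
    channels), then pixels are quantized to ``[0, max_pi]``.  Deterministic
    under a fixed ``spec.seed`` when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    labels = _label_map(spec)
    het = _heterogeneity_field(spec)
    shim = _shim_box(spec)
    images = []
    for ti in spec.ti_grid_ms:
        clean = _noiseless_image(spec, labels, het, ti)
        if clean.max() > spec.max_pi:
            logger.warning(
                "phantom signal %.0f exceeds max_pi=%d at TI=%.0f ms; clipping",
                clean.max(), spec.max_pi, ti,
            )
        if spec.noise_sigma > 0:
            noisy = np.hypot(
                clean + rng.normal(0.0, spec.noise_sigma, clean.shape),
                rng.normal(0.0, spec.noise_sigma, clean.shape),
            )
        else:
            noisy = clean
        images.append(ScoutImage(quantize_pixels(noisy, spec.max_pi), ti, spec.max_pi))
    return ScoutSeries(tuple(images), shim, series_id=f"phantom-{spec.seed}")


@dataclass(frozen=True)
class RecoveryResult:
    """Per-run recovery table plus summary statistics."""

    table: pd.DataFrame  # columns: run, true_ti_ms, selected_ti_ms, abs_error_ms
    mean_abs_error_ms: float
    fraction_within_one_step: float


def recovery_experiment(
    n_runs: int,
    spec_sampler: Callable[[np.random.Generator], PhantomSpec],
    roi_spec: RoiSpec = DEFAULT_ROI_SPEC,
    threshold_mode: str = "inclusive",
    seed: int = 0,
) -> RecoveryResult:
    """Measure how well automated selection recovers the simulated truth.

    Each run draws a phantom from ``spec_sampler``, simulates its scout,
    runs :func:`tiscout.core.select_ti` and records the absolute TI error.
    ``fraction_within_one_step`` counts runs with error at most one native
    grid increment.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(n_runs):
        spec = spec_sampler(rng)
        truth = ground_truth_ti(spec)
        series = generate_scout(spec)
        result = select_ti(series, roi_spec, threshold_mode)
        step = float(np.median(np.diff(spec.ti_grid_ms)))
        rows.append(
            {
                "run": run,
                "true_ti_ms": truth,
                "selected_ti_ms": result.selected_ti_ms,
                "abs_error_ms": abs(result.selected_ti_ms - truth),
                "grid_step_ms": step,
            }
        )
    table = pd.DataFrame(rows)
    within = (table["abs_error_ms"] <= table["grid_step_ms"] + 1e-9).mean()
    return RecoveryResult(
        table=table,
        mean_abs_error_ms=float(table["abs_error_ms"].mean()),
        fraction_within_one_step=float(within),
    )


def _grid_argmin_ti(tissue: TissueParams, ti_grid: Iterable[float]) -> float:
    grid = np.asarray(list(ti_grid), dtype=float)
    return float(grid[int(np.argmin(tissue.signal(grid)))])


def sample_phantom_spec(
    rng: np.random.Generator,
    noise_sigma_frac: float = 0.02,
    shared_null: bool = False,
    scar_probability: float = 0.3,
    grid_shape: tuple[int, int] = (128, 128),
    ti_grid_ms: tuple[float, ...] = DEFAULT_TI_GRID_MS,
    heterogeneity: float = 0.2,
) -> PhantomSpec:
    """Draw a randomized but anatomically plausible phantom.

    Geometry (heart position, cavity and wall size, scar presence) varies
    across draws; the tissue signal parameters stay at the module defaults,
    which encode the study conditions (blood and myocardium nulling close
    together inside the scouted range).  With ``shared_null=True`` the
    blood and myocardium recovery constants are instead drawn around a
    common nulling point — the condition the scanner-side preparation is
    optimized to realize — and the draw is rejected until both tissues
    share their grid-argmin nulling TI.  ``noise_sigma_frac`` scales the
    Rician noise to the blood equilibrium amplitude.
    """
    rows, cols = grid_shape
    defaults = PhantomSpec()
    for _ in range(1000):
        r_out = rng.uniform(22.0, 30.0)
        wall = rng.uniform(6.0, 10.0)
        r_in = r_out - wall
        cy = rows / 2.0 + rng.uniform(-6.0, 6.0)
        cx = cols / 2.0 + rng.uniform(-6.0, 6.0)
        if shared_null:
            t_null = rng.uniform(75.0, 145.0)
            t1_common = t_null / math.log(2.0)
            blood = TissueParams(defaults.blood.m0, t1_common * (1.0 + rng.uniform(-0.03, 0.03)))
            myo = TissueParams(defaults.myocardium.m0, t1_common * (1.0 + rng.uniform(-0.03, 0.03)))
            if _grid_argmin_ti(blood, ti_grid_ms) != _grid_argmin_ti(myo, ti_grid_ms):
                continue
        else:
            blood = defaults.blood
            myo = defaults.myocardium
        scar = None
        angles = (0.0, 60.0)
        if rng.uniform() < scar_probability:
            scar = TissueParams(rng.uniform(400.0, 600.0), rng.uniform(50.0, 80.0), 1.0)
            start = rng.uniform(0.0, 300.0)
            angles = (start, start + rng.uniform(30.0, 60.0))
        return PhantomSpec(
            grid_shape=grid_shape,
            center=(cy, cx),
            blood_radius=r_in,
            myo_inner_radius=r_in,
            myo_outer_radius=r_out,
            blood=blood,
            myocardium=myo,
            scar=scar,
            scar_angle_deg=angles,
            heterogeneity=heterogeneity,
            ti_grid_ms=ti_grid_ms,
            noise_sigma=noise_sigma_frac * blood.m0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    raise RuntimeError("could not sample a phantom satisfying the constraints")
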