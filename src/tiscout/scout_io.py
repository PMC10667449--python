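"""Data model and I/O for inversion-time (TI) scout series.

A TI scout is a short series of co-registered 2-D short-axis magnitude
images, each acquired at a different inversion time, from which the TI that
best nulls blood and healthy myocardium is chosen.  The series carries a
shim-box rectangle (the adjustment volume positioned over the heart at the
scanner) which serves as a coarse heart localizer downstream.

Two on-disk layouts are supported:

``stack+json``
    A multi-page TIFF (page axis = TI axis) or a 3-D NIfTI volume (slice
    axis = TI axis) next to a JSON sidecar holding ``series_id``, the
    ``ti_ms`` list, the ``shim`` rectangle and ``max_pi``.

``dicom_dir``
    A directory of standard DICOM files, one per scout image; the inversion
    time is read from the standard Inversion Time attribute and the shim
    rectangle is supplied by the caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ScoutFormatError",
    "ScoutValidationError",
    "ScoutImage",
    "ShimBox",
    "ScoutSeries",
    "quantize_pixels",
    "read_series",
    "write_series",
    "write_result",
    "read_result",
    "DEFAULT_MAX_PI",
]

#: Default maximum representable pixel intensity (12-bit grayscale).
#: The scouts' true bit depth is scanner-dependent; 12-bit is the common
#: case for reconstructed MR magnitude images and is configurable everywhere.
DEFAULT_MAX_PI = 4095


class ScoutFormatError(ValueError):
    """Raised when on-disk data cannot be interpreted as a scout series."""


class ScoutValidationError(ValueError):
    """Raised when in-memory data violates a scout-series invariant."""


def quantize_pixels(pixels: np.ndarray, max_pi: int = DEFAULT_MAX_PI) -> np.ndarray:
    """Clamp to ``[0, max_pi]`` and round half up to integer gray levels.

    Histograms of bin size 1 over integer gray levels are the algorithm's
    substrate, so floating-point input is quantized once at the boundary.
    """
    arr = np.asarray(pixels, dtype=float)
    arr = np.clip(arr, 0.0, float(max_pi))
    # floor(x + 0.5): round-half-up, independent of banker's rounding
    return np.floor(arr + 0.5).astype(np.int64)


@dataclass(frozen=True)
class ScoutImage:
    """One scout image: a 2-D grid of integer gray levels tagged with its TI."""

    pixels: np.ndarray
    ti_ms: float
    max_pi: int = DEFAULT_MAX_PI

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ScoutValidationError(f"image grid must be at least 2x2, got {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ScoutValidationError("pixels must be integer gray levels; quantize first")
        if self.ti_ms <= 0:
            raise ScoutValidationError(f"ti_ms must be positive, got {self.ti_ms}")
        if self.max_pi < 1:
            raise ScoutValidationError(f"max_pi must be >= 1, got {self.max_pi}")
        if px.min() < 0 or px.max() > self.max_pi:
            raise ScoutValidationError(
                f"pixel intensities must lie in [0, {self.max_pi}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ShimBox:
    """Half-open axis-aligned rectangle [x0, x0+width) x [y0, y0+height).

    ``x`` indexes columns, ``y`` rows, both 0-based.  The box is the
    scanner-side shim volume projected onto the image plane and must lie
    entirely inside the image grid.
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 4 or self.height < 4:
            raise ScoutValidationError(
                f"shim box must be at least 4x4 pixels, got {self.width}x{self.height}"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise ScoutValidationError("shim box corner must be non-negative")

    def fits_in(self, grid_shape: tuple[int, int]) -> bool:
        rows, cols = grid_shape
        return self.y0 + self.height <= rows and self.x0 + self.width <= cols

    @property
    def center(self) -> tuple[float, float]:
        """(cx, cy) in continuous pixel coordinates."""
        return self.x0 + self.width / 2.0, self.y0 + self.height / 2.0

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "width": self.width, "height": self.height}

    @classmethod
    def from_dict(cls, d: dict) -> "ShimBox":
        return cls(int(d["x0"]), int(d["y0"]), int(d["width"]), int(d["height"]))


@dataclass(frozen=True)
class ScoutSeries:
    """Ordered TI-tagged image stack plus the shim-box heart localizer.

    Images are stored sorted by ascending TI regardless of construction
    order; TIs must be distinct and all images must share grid dimensions
    and bit depth.
    """

    images: tuple[ScoutImage, ...]
    shim: ShimBox
    series_id: str = ""

    def __post_init__(self) -> None:
        images = tuple(sorted(self.images, key=lambda im: im.ti_ms))
        if len(images) < 2:
            raise ScoutValidationError("a scout series needs at least 2 images")
        tis = [im.ti_ms for im in images]
        if len(set(tis)) != len(tis):
            raise ScoutFormatError(f"duplicate inversion times in series: {sorted(tis)}")
        shapes = {im.shape for im in images}
        if len(shapes) != 1:
            raise ScoutValidationError(f"mixed image dimensions in series: {shapes}")
        depths = {im.max_pi for im in images}
        if len(depths) != 1:
            raise ScoutValidationError(f"mixed bit depths in series: {depths}")
        if not self.shim.fits_in(images[0].shape):
            raise ScoutValidationError(
                f"shim box {self.shim} exceeds image grid {images[0].shape}"
            )
        object.__setattr__(self, "images", images)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def ti_grid_ms(self) -> np.ndarray:
        return np.array([im.ti_ms for im in self.images], dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.images[0].shape

    @property
    def max_pi(self) -> int:
        return self.images[0].max_pi

    @property
    def pixel_stack(self) -> np.ndarray:
        """All images as one (N, rows, cols) integer array, TI-ascending."""
        return np.stack([im.pixels for im in self.images])


# ---------------------------------------------------------------------------
# stack+json layout
# ---------------------------------------------------------------------------

def _resolve_stack_paths(path: Path) -> tuple[Path, Path]:
    """Locate (stack file, json sidecar) from a file or directory path."""
    path = Path(path)
    if path.is_dir():
        sidecars = sorted(path.glob("*.json"))
        if len(sidecars) != 1:
            raise ScoutFormatError(
                f"expected exactly one JSON sidecar in {path}, found {len(sidecars)}"
            )
        sidecar = sidecars[0]
        stem = sidecar.with_suffix("")
        for ext in (".tif", ".tiff", ".nii", ".nii.gz"):
            cand = stem.parent / (stem.name + ext)
            if cand.exists():
                return cand, sidecar
        raise ScoutFormatError(f"no TIFF/NIfTI stack next to sidecar {sidecar}")
    if not path.exists():
        raise ScoutFormatError(f"no such file: {path}")
    name = path.name
    if name.endswith(".nii.gz"):
        sidecar = path.parent / (name[: -len(".nii.gz")] + ".json")
    else:
        sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ScoutFormatError(f"missing JSON sidecar for {path}")
    return path, sidecar


def _load_stack(stack_path: Path) -> np.ndarray:
    """Read a (N, rows, cols) float array from TIFF or NIfTI."""
    name = stack_path.name.lower()
    if name.endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(stack_path)
    elif name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(stack_path))
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ScoutFormatError(f"NIfTI stack must be 3-D, got shape {data.shape}")
        # slice axis (last) becomes the TI axis (first)
        arr = np.moveaxis(data, -1, 0)
    else:
        raise ScoutFormatError(f"unsupported stack format: {stack_path}")
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ScoutFormatError(f"stack must be 3-D, got shape {arr.shape}")
    return arr


def _read_stack_json(path: Path) -> ScoutSeries:
    stack_path, sidecar = _resolve_stack_paths(path)
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ScoutFormatError(f"invalid JSON sidecar {sidecar}: {exc}") from exc
    for key in ("ti_ms", "shim"):
        if key not in meta:
            raise ScoutFormatError(f"sidecar {sidecar} lacks required key {key!r}")
    ti_ms = [float(t) for t in meta["ti_ms"]]
    max_pi = int(meta.get("max_pi", DEFAULT_MAX_PI))
    shim = ShimBox.from_dict(meta["shim"])
    arr = _load_stack(stack_path)
    if arr.shape[0] != len(ti_ms):
        raise ScoutFormatError(
            f"stack has {arr.shape[0]} pages but sidecar lists {len(ti_ms)} TIs"
        )
    images = [
        ScoutImage(quantize_pixels(arr[n], max_pi), ti, max_pi)
        for n, ti in enumerate(ti_ms)
    ]
    return ScoutSeries(tuple(images), shim, series_id=str(meta.get("series_id", "")))


def write_series(series: ScoutSeries, path: Path | str, format: str = "stack+json") -> Path:
    """Write a series as a multi-page TIFF plus JSON sidecar; returns the stack path.

    ``path`` is the stack file path (``.tif``/``.tiff``); the sidecar is
    written next to it with the same stem.
    """
    if format != "stack+json":
        raise ValueError(f"unsupported write format: {format}")
    import tifffile

    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        path = path.with_suffix(".tiff")
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = series.pixel_stack.astype(np.uint16 if series.max_pi <= 65535 else np.uint32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "series_id": series.series_id,
        "ti_ms": [float(t) for t in series.ti_grid_ms],
        "shim": series.shim.to_dict(),
        "max_pi": series.max_pi,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1) + "\n")
    return path


# ---------------------------------------------------------------------------
# dicom_dir layout
# ---------------------------------------------------------------------------

def _read_dicom_dir(path: Path, shim: ShimBox | None, max_pi: int | None) -> ScoutSeries:
    import pydicom

    path = Path(path)
    if not path.is_dir():
        raise ScoutFormatError(f"dicom_dir input must be a directory: {path}")
    if shim is None:
        raise ScoutFormatError("dicom_dir input requires an explicit shim box")
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".json")
    entries: list[tuple[float, np.ndarray]] = []
    series_id = ""
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:  # pragma: no cover - non-DICOM stray file
            raise ScoutFormatError(f"cannot read DICOM file {f}: {exc}") from exc
        if "InversionTime" not in ds:
            raise ScoutFormatError(f"DICOM file {f} lacks an Inversion Time attribute")
        entries.append((float(ds.InversionTime), ds.pixel_array))
        series_id = str(getattr(ds, "SeriesDescription", "") or series_id)
    if not entries:
        raise ScoutFormatError(f"no DICOM files found in {path}")
    tis = [t for t, _ in entries]
    if len(set(tis)) != len(tis):
        raise ScoutFormatError(f"duplicate inversion times in DICOM series: {sorted(tis)}")
    if max_pi is None:
        # use the smallest standard bit depth that holds the data
        peak = max(int(np.max(px)) for _, px in entries)
        max_pi = DEFAULT_MAX_PI if peak <= DEFAULT_MAX_PI else (1 << int(peak).bit_length()) - 1
    images = [ScoutImage(quantize_pixels(px, max_pi), ti, max_pi) for ti, px in entries]
    return ScoutSeries(tuple(images), shim, series_id=series_id)


def read_series(
    path: Path | str,
    format: str = "stack+json",
    shim: ShimBox | None = None,
    max_pi: int | None = None,
) -> ScoutSeries:
    """Read a TI scout series; images are returned sorted by ascending TI.

    Parameters
    ----------
    path:
        Stack file, sidecar directory (``stack+json``) or DICOM directory.
    format:
        ``"stack+json"`` or ``"dicom_dir"``.
    shim:
        Shim rectangle in pixel coordinates; required for ``dicom_dir``
        (DICOM carries no portable shim geometry), ignored for
        ``stack+json`` where the sidecar provides it.
    max_pi:
        Override the maximum representable intensity (``dicom_dir`` only).
    """
    if format == "stack+json":
        return _read_stack_json(Path(path))
    if format == "dicom_dir":
        return _read_dicom_dir(Path(path), shim, max_pi)
    raise ValueError(f"unknown series format: {format!r}")


# ---------------------------------------------------------------------------
# selection-result documents
# ---------------------------------------------------------------------------

def write_result(result, path: Path | str, qc: dict | None = None) -> Path:
    """Write a selection result (plus optional QC block) as a JSON document.

    The document round-trips losslessly through :func:`read_result`; the
    result must be complete (per-image counts included).
    """
    from .core import SelectionResult

    if not isinstance(result, SelectionResult):
        raise ScoutValidationError(f"expected a SelectionResult, got {type(result).__name__}")
    doc = {"selection": result.to_dict()}
    if qc is not None:
        doc["qc"] = qc
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1) + "\n")
    return path


def read_result(path: Path | str):
    """Read back a selection result written by :func:`write_result`.

    Returns ``(SelectionResult, qc_dict_or_None)``.
    """
    from .core import SelectionResult

    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ScoutFormatError(f"invalid result document {path}: {exc}") from exc
    if "selection" not in doc:
        raise ScoutFormatError(f"result document {path} lacks a 'selection' block")
    return SelectionResult.from_dict(doc["selection"]), doc.get("qc")
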