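"""Hyperspectral cube I/O, reflectance calibration and ROI extraction.

A pushbroom NIR imager delivers raw sensor counts; reflectance is recovered
against a white (diffuse panel, ~99.9 % reflective) and a dark
(lens-capped) reference::

    R = (R0 - Rb) / (Rw - Rb)

Sample spectra are then averaged over an elliptical region of interest and
the modeling window (950-1650 nm by default) is cut out.  Cubes are stored
in the standard ENVI header + flat-binary layout (BIL/BIP/BSQ).

Conventions: pixel coordinates are 0-based ``(row, col)``; the ROI ellipse
uses image-axis order, i.e. semi-axis ``a`` runs along columns and ``b``
along rows.  Calibrated reflectance is *not* clipped to [0, 1] — artifact
handling is the preprocessing stage's job.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import SpectrumSet

__all__ = [
    "HyperCube",
    "CalibrationFrames",
    "RoiSpec",
    "calibrate_reflectance",
    "generate_roi_pixel_grid",
    "extract_mean_spectrum",
    "subset_bands",
    "read_envi",
    "write_envi",
    "read_spectra_csv",
    "write_spectra_csv",
]


@dataclass
class HyperCube:
    """A rows x cols x bands image with a wavelength axis in nm.

    Serves both as the raw-counts cube and the calibrated reflectance cube.
    """

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows x cols x bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band axis does not match wavelength vector")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class CalibrationFrames:
    """White and dark reference frames.

    Either per-band vectors of shape ``(bands,)`` (column-averaged
    references, the default the synthetic generator emits) or full per-pixel
    images of shape ``(rows, cols, bands)``.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")
        if self.white.ndim not in (1, 3):
            raise ValueError("frames must be per-band vectors or 3-D images")


def calibrate_reflectance(raw: HyperCube, frames: CalibrationFrames) -> HyperCube:
    """Convert raw counts to reflectance: R = (R0 - Rb) / (Rw - Rb).

    Raises
    ------
    ValueError
        If white == dark anywhere it is used, naming the offending
        band (and pixel, for per-pixel frames).
    """
    denom = frames.white - frames.dark
    bad = denom == 0
    if np.any(bad):
        loc = np.argwhere(bad)[0]
        if frames.white.ndim == 1:
            where = f"band {loc[0]}"
        else:
            where = f"pixel (row={loc[0]}, col={loc[1]}), band {loc[2]}"
        raise ValueError(f"white == dark at {where}: reflectance undefined")
    r = (raw.data - frames.dark) / denom
    return HyperCube(data=r, wavelengths=raw.wavelengths.copy())


@dataclass
class RoiSpec:
    """Elliptical region of interest.

    ``center`` is (row, col); ``semi_axes`` is (a, b) with ``a`` the column
    half-width and ``b`` the row half-height; ``axial_interval`` subsamples
    the pixel lattice on both axes relative to the center.
    """

    center: tuple[int, int]
    semi_axes: tuple[float, float]
    axial_interval: int = 1

    def __post_init__(self) -> None:
        if self.semi_axes[0] < 0 or self.semi_axes[1] < 0:
            raise ValueError("semi-axes must be non-negative")
        if self.axial_interval < 1:
            raise ValueError("axial_interval (stride) must be >= 1")


def generate_roi_pixel_grid(
    spec: RoiSpec, image_shape: tuple[int, int]
) -> list[tuple[int, int]]:
    """Integer pixels inside the ellipse, stride-subsampled, row-major sorted.

    A pixel (r, c) is inside when ``((r-r0)/b)^2 + ((c-c0)/a)^2 <= 1``;
    degenerate axes select only the center line/point.  The ROI must fit in
    the image: an error reports by how many pixels it overflows.
    """
    r0, c0 = spec.center
    a, b = spec.semi_axes
    rows, cols = image_shape
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError(f"ROI center {spec.center} outside image {image_shape}")

    over = {
        "top": int(np.ceil(b - r0)) if r0 - b < 0 else 0,
        "bottom": int(np.ceil(r0 + b - (rows - 1))) if r0 + b > rows - 1 else 0,
        "left": int(np.ceil(a - c0)) if c0 - a < 0 else 0,
        "right": int(np.ceil(c0 + a - (cols - 1))) if c0 + a > cols - 1 else 0,
    }
    if any(v > 0 for v in over.values()):
        detail = ", ".join(f"{k} by {v}px" for k, v in over.items() if v > 0)
        raise ValueError(f"ROI exceeds image bounds: {detail}")

    stride = spec.axial_interval
    pixels: list[tuple[int, int]] = []
    for r in range(int(np.floor(r0 - b)), int(np.ceil(r0 + b)) + 1):
        if (r - r0) % stride:
            continue
        for c in range(int(np.floor(c0 - a)), int(np.ceil(c0 + a)) + 1):
            if (c - c0) % stride:
                continue
            dr = (r - r0) / b if b > 0 else (0.0 if r == r0 else np.inf)
            dc = (c - c0) / a if a > 0 else (0.0 if c == c0 else np.inf)
            if dr * dr + dc * dc <= 1.0:
                pixels.append((r, c))
    return pixels


def extract_mean_spectrum(
    cube: HyperCube, pixels: list[tuple[int, int]]
) -> np.ndarray:
    """Arithmetic mean over ROI pixels, per band."""
    if not pixels:
        raise ValueError("empty pixel list")
    rows, cols, _ = cube.shape
    idx = np.asarray(pixels)
    if idx.min() < 0 or idx[:, 0].max() >= rows or idx[:, 1].max() >= cols:
        raise ValueError("pixel list contains out-of-bounds coordinates")
    return cube.data[idx[:, 0], idx[:, 1], :].mean(axis=0)


def subset_bands(spectra: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Restrict to the closed wavelength interval [lo, hi] nm."""
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    keep = (spectra.wavelengths >= lo) & (spectra.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no bands inside [{lo}, {hi}] nm")
    return SpectrumSet(
        sample_ids=list(spectra.sample_ids),
        reflectance=spectra.reflectance[:, keep],
        wavelengths=spectra.wavelengths[keep],
        metadata={**spectra.metadata, "band_window_nm": (lo, hi)},
    )


# ---------------------------------------------------------------------------
# ENVI header + flat binary I/O (standard dialect: samples/lines/bands/
# interleave/data type/byte order/wavelength).

_ENVI_DTYPES = {4: "<f4", 5: "<f8"}
_ENVI_CODES = {np.dtype("float32"): 4, np.dtype("float64"): 5}


def write_envi(cube: HyperCube, path: str | Path, interleave: str = "bil") -> Path:
    """Write ``path`` (binary) and ``path.hdr``; returns the header path."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}")
    path = Path(path)
    rows, cols, bands = cube.shape
    data = cube.data.astype("<f8")  # (lines, samples, bands) == BIP order
    if interleave == "bip":
        arr = data
    elif interleave == "bil":
        arr = data.transpose(0, 2, 1)  # (lines, bands, samples)
    else:  # bsq
        arr = data.transpose(2, 0, 1)  # (bands, lines, samples)
    arr.tofile(path)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 5\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    hdr_path.write_text(hdr)
    return hdr_path


def _parse_envi_header(text: str) -> dict:
    # Collapse brace-delimited values (possibly multi-line) to one entry.
    fields: dict[str, str] = {}
    buf = ""
    key = None
    for raw_line in text.splitlines():
        line = raw_line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, _, val = line.partition("=")
            key = key.strip().lower()
            buf = val.strip()
        else:
            buf += " " + line
        if buf.count("{") == buf.count("}"):
            fields[key] = buf
            key, buf = None, ""
    return fields


def read_envi(header_path: str | Path) -> HyperCube:
    """Read an ENVI cube given its ``.hdr`` path."""
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    for req in ("samples", "lines", "bands", "interleave", "data type"):
        if req not in fields:
            raise ValueError(f"ENVI header missing '{req}' field")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing wavelength metadata")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    interleave = fields["interleave"].lower()
    wl = np.array(
        [float(t) for t in fields["wavelength"].strip("{} ").split(",") if t.strip()]
    )
    if wl.size != bands:
        raise ValueError("wavelength list length does not match bands")
    bin_path = (
        header_path.with_suffix("")
        if header_path.suffix == ".hdr"
        else header_path
    )
    raw = np.fromfile(bin_path, dtype=_ENVI_DTYPES[code])
    if raw.size != rows * cols * bands:
        raise ValueError("ENVI binary size does not match header dimensions")
    if interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    return HyperCube(data=np.ascontiguousarray(data, dtype=float), wavelengths=wl)


def read_spectra_csv(path: str | Path) -> SpectrumSet:
    return SpectrumSet.from_csv(path)


def write_spectra_csv(spectra: SpectrumSet, path: str | Path) -> None:
    spectra.to_csv(path)
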