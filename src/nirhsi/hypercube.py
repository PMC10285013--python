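"""Hyperspectral cube container, ENVI-style I/O, and reflectance calibration.

A line-scan NIR camera (here modelled on a 900-1700 nm, 224-band, 640-sample
instrument) produces cubes of raw sensor counts. Together with a white
reference and a closed-shutter dark frame, raw counts are converted to
reflectance with the standard flat-field correction

    R[l, s, b] = (I[l, s, b] - D[s, b]) / (W[s, b] - D[s, b])

applied per sample column ``s`` and band ``b`` and clipped to
``[0, clip_max]`` to guard against specular glints.

Cubes are serialised in the minimal ENVI dialect: an ASCII ``key = value``
header next to a flat binary file, with BIL/BIP/BSQ interleaves and uint16
(raw counts) or float32 (reflectance) sample types.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "CalibrationPair",
    "EnviFormatError",
    "EnviConsistencyError",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "band_statistics",
]

#: Default sensor geometry: 224 evenly spaced band centres on [900, 1700] nm.
DEFAULT_N_BANDS = 224
DEFAULT_RANGE_NM = (900.0, 1700.0)
DEFAULT_CLIP_MAX = 1.5


class EnviFormatError(ValueError):
    """Header is missing or has garbled required fields."""


class EnviConsistencyError(ValueError):
    """Header fields are mutually inconsistent (e.g. wavelength count != bands)."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-centre wavelengths in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("wavelength grid needs at least two band centres")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", w)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        lo, hi = DEFAULT_RANGE_NM
        return cls(np.linspace(lo, hi, DEFAULT_N_BANDS))

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def band_index(self, target_nm: float) -> int:
        """Ordinal of the band centre nearest ``target_nm``.

        Ties break toward the lower ordinal. Targets more than half a band
        spacing outside the grid raise ``ValueError``.
        """
        w = self.wavelengths_nm
        lo = w[0] - (w[1] - w[0]) / 2.0
        hi = w[-1] + (w[-1] - w[-2]) / 2.0
        if not (lo <= target_nm <= hi):
            raise ValueError(
                f"target {target_nm} nm outside grid range [{w[0]}, {w[-1]}] nm"
            )
        # argmin returns the first minimum -> lower-ordinal tie-break
        return int(np.argmin(np.abs(w - target_nm)))


def band_index(grid: WavelengthGrid, target_nm: float) -> int:
    """Module-level convenience for :meth:`WavelengthGrid.band_index`."""
    return grid.band_index(target_nm)


@dataclass
class Hypercube:
    """A (lines, samples, bands) intensity or reflectance cube on a grid.

    ``kind`` is ``"raw"`` for sensor counts and ``"reflectance"`` after
    calibration; reflectance values must lie in ``[0, clip_max]``.
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"
    clip_max: float = DEFAULT_CLIP_MAX

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, samples, bands)")
        if d.shape[2] != len(self.grid):
            raise EnviConsistencyError(
                f"cube has {d.shape[2]} bands but grid has {len(self.grid)}"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if not np.all(np.isfinite(d)):
            raise ValueError("cube contains non-finite values")
        if self.kind == "reflectance":
            if d.min() < 0 or d.max() > self.clip_max:
                raise ValueError(
                    f"reflectance values outside [0, {self.clip_max}]"
                )
        self.data = d

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationPair:
    """White-reference and dark (closed shutter) frames, shape (samples, bands).

    A single reference spectrum of shape (bands,) is accepted and broadcast
    across sample columns.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.white, dtype=float))
        d = np.atleast_2d(np.asarray(self.dark, dtype=float))
        if w.shape != d.shape:
            raise ValueError("white and dark frames must share a shape")
        self.white, self.dark = w, d

    @property
    def invalid_mask(self) -> np.ndarray:
        """Elements where white <= dark; these cannot be calibrated."""
        return self.white <= self.dark


# ---------------------------------------------------------------------------
# ENVI serialisation

_ENVI_DTYPES = {4: np.float32, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}
_INTERLEAVES = ("bil", "bip", "bsq")

_REQUIRED_KEYS = ("samples", "lines", "bands", "data type", "interleave", "wavelength")


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("not an ENVI header (missing leading 'ENVI' magic)")
    # Collapse brace-delimited lists onto one line before splitting on '='.
    fields: dict[str, str] = {}
    body = text.lstrip()[4:]
    pattern = re.compile(r"^\s*([^={}]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _header_int(fields: dict, key: str) -> int:
    if key not in fields:
        raise EnviFormatError(f"header missing required key: {key}")
    try:
        return int(fields[key])
    except ValueError as exc:
        raise EnviFormatError(f"header key {key!r} is not an integer: {fields[key]!r}") from exc


def read_envi(header_path: str | Path) -> Hypercube:
    """Read a cube from an ENVI header + raw binary pair.

    The binary file is located by replacing the header's ``.hdr`` suffix
    with ``.raw`` (or ``.img``), or by stripping the suffix entirely.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise EnviFormatError(f"header file not found: {header_path}")
    fields = _parse_header(header_path.read_text())
    for key in _REQUIRED_KEYS:
        if key not in fields:
            raise EnviFormatError(f"header missing required key: {key}")

    lines = _header_int(fields, "lines")
    samples = _header_int(fields, "samples")
    bands = _header_int(fields, "bands")
    dtype_code = _header_int(fields, "data type")
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type code {dtype_code}")
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")

    wl_text = fields["wavelength"]
    if not (wl_text.startswith("{") and wl_text.endswith("}")):
        raise EnviFormatError("wavelength list must be brace-delimited")
    try:
        wavelengths = [float(tok) for tok in wl_text[1:-1].replace("\n", " ").split(",") if tok.strip()]
    except ValueError as exc:
        raise EnviFormatError("garbled wavelength list") from exc
    if len(wavelengths) != bands:
        raise EnviConsistencyError(
            f"header declares {bands} bands but {len(wavelengths)} wavelengths"
        )

    data_path = None
    for candidate in (header_path.with_suffix(".raw"), header_path.with_suffix(".img"),
                      header_path.with_suffix("")):
        if candidate.exists() and candidate != header_path:
            data_path = candidate
            break
    if data_path is None:
        raise EnviFormatError(f"binary data file for {header_path} not found")

    flat = np.fromfile(data_path, dtype=_ENVI_DTYPES[dtype_code])
    expected = lines * samples * bands
    if flat.size != expected:
        raise EnviConsistencyError(
            f"binary file holds {flat.size} values, header implies {expected}"
        )
    if interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    else:  # bsq
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)

    kind = "reflectance" if dtype_code == 4 else "raw"
    return Hypercube(np.ascontiguousarray(data), WavelengthGrid(np.array(wavelengths)), kind=kind)


def write_envi(cube: Hypercube, header_path: str | Path, interleave: str = "bil") -> Path:
    """Write ``cube`` as an ENVI header + ``.raw`` binary pair.

    Raw cubes are stored as uint16, reflectance cubes as float32 (the two
    sample types the line-scan workflow needs). Returns the header path.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    data_path = header_path.with_suffix(".raw")

    dtype = np.uint16 if cube.kind == "raw" else np.float32
    arr = np.asarray(cube.data).astype(dtype)
    if interleave == "bil":
        ordered = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        ordered = arr
    else:  # bsq
        ordered = arr.transpose(2, 0, 1)

    wl = ", ".join(f"{w:.6f}" for w in cube.grid.wavelengths_nm)
    header = (
        "ENVI\n"
        "description = {nirhsi cube}\n"
        f"samples = {cube.n_samples}\n"
        f"lines = {cube.n_lines}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    np.ascontiguousarray(ordered).tofile(data_path)
    return header_path


# ---------------------------------------------------------------------------
# Calibration

def calibrate_reflectance(
    raw: Hypercube,
    pair: CalibrationPair,
    clip_max: float = DEFAULT_CLIP_MAX,
) -> Hypercube:
    """Flat-field a raw cube to reflectance using white/dark references.

    R = (I - D) / (W - D) per sample column and band, clipped to
    ``[0, clip_max]``. Elements where ``W <= D`` cannot be calibrated; they
    are set to 0 and counted in a warning rather than raising.
    """
    if raw.kind != "raw":
        raise ValueError("calibrate_reflectance expects a raw-kind cube")
    white, dark = pair.white, pair.dark
    if white.shape[1] != raw.n_bands:
        raise ValueError("calibration frames do not match the cube band count")
    if white.shape[0] not in (1, raw.n_samples):
        raise ValueError("calibration frames do not match the cube sample count")

    denom = white - dark
    invalid = denom <= 0
    n_invalid = int(invalid.sum())
    if n_invalid:
        warnings.warn(
            f"{n_invalid} calibration elements have white <= dark; set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(invalid, 1.0, denom)
    refl = (raw.data.astype(float) - dark[None, :, :]) / safe[None, :, :]
    refl = np.where(invalid[None, :, :], 0.0, refl)
    refl = np.clip(refl, 0.0, clip_max)
    return Hypercube(refl.astype(np.float32), raw.grid, kind="reflectance", clip_max=clip_max)


def band_statistics(cube: Hypercube):
    """Per-band summary statistics as a DataFrame (CSV-exportable)."""
    import pandas as pd

    d = cube.data.reshape(-1, cube.n_bands)
    return pd.DataFrame(
        {
            "wavelength_nm": cube.grid.wavelengths_nm,
            "mean": d.mean(axis=0),
            "std": d.std(axis=0),
            "min": d.min(axis=0),
            "max": d.max(axis=0),
        }
    )
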