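"""Per-particle spectra and binary peak/trough feature encoding.

NIR reflectance spectra of commodity polymers carry narrow, diagnostic
absorption features — polyethylene a peak near 1540 nm, polypropylene
troughs near 1196 and 1215 nm — while natural materials (pumice, carapace,
wood, algae) show only broad slopes. The classifier therefore consumes a
tiny binary feature vector: one bit per prescribed wavelength window,
set when a detected local extremum of the right sense falls inside it.

Spectra are normalised to their average reflectance before extremum
detection, which makes the encoding invariant to illumination gain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .hypercube import Hypercube, WavelengthGrid

__all__ = [
    "Spectrum",
    "FeatureRegion",
    "FeatureSchema",
    "Extremum",
    "ReferenceLibrary",
    "SchemaConfigurationError",
    "extract_mean_spectrum",
    "normalize_spectrum",
    "find_extrema",
    "encode_features",
    "encode_spectrum",
    "DEFAULT_PROMINENCE_MIN",
    "DEFAULT_HALFWIDTH_NM",
]

DEFAULT_PROMINENCE_MIN = 0.01  # in normalised-reflectance units
DEFAULT_HALFWIDTH_NM = 8.0

#: Resin names collapsed to one trainable class: high- and low-density
#: polyethylene are spectrally indistinguishable in this range.
CLASS_ALIASES = {"HDPE": "PE", "LDPE": "PE"}


class SchemaConfigurationError(ValueError):
    """A schema region lies outside the wavelength grid."""


@dataclass
class Spectrum:
    """A length-B spectrum aligned to a wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != len(self.grid):
            raise ValueError("spectrum length must match the wavelength grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum contains non-finite values")
        if self.normalized and abs(v.mean() - 1.0) > 1e-9:
            raise ValueError("normalized spectrum must have mean 1")
        self.values = v


@dataclass(frozen=True)
class FeatureRegion:
    """One diagnostic wavelength window: a peak or trough is expected here."""

    label: str
    center_nm: float
    kind: str  # "peak" | "trough"
    halfwidth_nm: float = DEFAULT_HALFWIDTH_NM

    def __post_init__(self) -> None:
        if self.kind not in ("peak", "trough"):
            raise ValueError("region kind must be 'peak' or 'trough'")
        if self.halfwidth_nm <= 0:
            raise ValueError("halfwidth must be positive")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered set of diagnostic regions defining the binary feature vector."""

    regions: tuple[FeatureRegion, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("schema region labels must be unique")

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    @classmethod
    def default(cls) -> "FeatureSchema":
        """The printed polyolefin windows plus a polystyrene aromatic peak.

        The PS window (1680 nm, an aromatic C-H overtone region) is a package
        addition: without it the PS class would have no encodable feature.
        """
        return cls(
            (
                FeatureRegion("pe_peak_1540", 1540.0, "peak"),
                FeatureRegion("pp_trough_1196", 1196.0, "trough"),
                FeatureRegion("pp_trough_1215", 1215.0, "trough"),
                FeatureRegion("ps_peak_1680", 1680.0, "peak"),
            )
        )

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "label": r.label,
                "center_nm": r.center_nm,
                "kind": r.kind,
                "halfwidth_nm": r.halfwidth_nm,
            }
            for r in self.regions
        ]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        return cls(tuple(FeatureRegion(**entry) for entry in payload))


@dataclass(frozen=True)
class Extremum:
    band: int
    kind: str  # "peak" | "trough"
    prominence: float


def extract_mean_spectrum(cube: Hypercube, region_pixels) -> Spectrum:
    """Band-wise mean spectrum over a particle's pixels (unnormalised)."""
    coords = np.asarray(list(region_pixels), dtype=int).reshape(-1, 2)
    if coords.size == 0:
        raise ValueError("empty particle region")
    values = cube.data[coords[:, 0], coords[:, 1], :].mean(axis=0)
    return Spectrum(values, cube.grid, normalized=False)


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Divide by the spectral mean so the result has mean reflectance 1."""
    m = s.values.mean()
    if m <= 0:
        raise ValueError("cannot normalise a spectrum with non-positive mean")
    return Spectrum(s.values / m, s.grid, normalized=True)


def find_extrema(
    s: Spectrum,
    prominence_min: float = DEFAULT_PROMINENCE_MIN,
    smooth_window: int | None = 7,
) -> list[Extremum]:
    """Local maxima/minima with topographic prominence >= ``prominence_min``.

    Operates on a normalised spectrum; endpoints are never extrema. Troughs
    are peaks of the negated spectrum under the same prominence rule. A
    quadratic Savitzky-Golay filter over ``smooth_window`` bands (None to
    disable) suppresses residual sensor noise before peak picking: without
    it, band-wise noise well below ``prominence_min`` still throws frequent
    spurious extrema, while windows much wider than 7 bands start to merge
    the closely spaced polypropylene troughs (1196/1215 nm, ~5 bands apart).
    """
    if not s.normalized:
        raise ValueError("find_extrema expects a normalised spectrum")
    values = s.values
    if smooth_window is not None and smooth_window >= 3:
        from scipy.signal import savgol_filter

        values = savgol_filter(values, smooth_window, polyorder=2)
    out: list[Extremum] = []
    for sign, kind in ((1.0, "peak"), (-1.0, "trough")):
        idx, props = find_peaks(sign * values, prominence=prominence_min)
        out.extend(
            Extremum(int(i), kind, float(p)) for i, p in zip(idx, props["prominences"])
        )
    return sorted(out, key=lambda e: e.band)


def encode_features(
    extrema: list[Extremum], schema: FeatureSchema, grid: WavelengthGrid
) -> np.ndarray:
    """Binary feature vector: bit j set iff a matching-kind extremum falls
    within +-halfwidth of region j's centre wavelength."""
    w = grid.wavelengths_nm
    bits = np.zeros(len(schema), dtype=np.uint8)
    for j, region in enumerate(schema.regions):
        if not (w[0] <= region.center_nm <= w[-1]):
            raise SchemaConfigurationError(
                f"region {region.label!r} centre {region.center_nm} nm outside grid"
            )
        for e in extrema:
            if e.kind == region.kind and abs(w[e.band] - region.center_nm) <= region.halfwidth_nm:
                bits[j] = 1
                break
    return bits


def encode_spectrum(
    s: Spectrum,
    schema: FeatureSchema,
    prominence_min: float = DEFAULT_PROMINENCE_MIN,
) -> np.ndarray:
    """Normalise (if needed), detect extrema, and encode in one call."""
    if not s.normalized:
        s = normalize_spectrum(s)
    return encode_features(find_extrema(s, prominence_min), schema, s.grid)


@dataclass
class ReferenceLibrary:
    """Labelled polymer/natural reference spectra sharing one grid.

    Labels are collapsed through :data:`CLASS_ALIASES` at construction
    (HDPE and LDPE both become PE). ``provenance`` is a free-text note.
    """

    ids: list[str]
    labels: list[str]
    spectra: list[Spectrum]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.labels) == len(self.spectra)):
            raise ValueError("ids, labels, spectra must align")
        if not self.spectra:
            raise ValueError("reference library is empty")
        grid = self.spectra[0].grid
        for s in self.spectra:
            if len(s.grid) != len(grid) or not np.allclose(
                s.grid.wavelengths_nm, grid.wavelengths_nm
            ):
                raise ValueError("all library spectra must share one grid")
        self.labels = [CLASS_ALIASES.get(lbl, lbl) for lbl in self.labels]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def grid(self) -> WavelengthGrid:
        return self.spectra[0].grid

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def feature_matrix(
        self,
        schema: FeatureSchema | None = None,
        prominence_min: float = DEFAULT_PROMINENCE_MIN,
    ) -> tuple[np.ndarray, np.ndarray]:
        """One-hot encode every entry -> (X of shape (n, n_regions), y)."""
        schema = schema or FeatureSchema.default()
        X = np.vstack([encode_spectrum(s, schema, prominence_min) for s in self.spectra])
        return X, np.asarray(self.labels)

    # -- serialisation: wavelength column + one column per specimen, with a
    #    JSON sidecar mapping specimen id -> class label.

    def to_csv(self, csv_path: str | Path, labels_path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame({"wavelength_nm": self.grid.wavelengths_nm})
        for sid, s in zip(self.ids, self.spectra):
            df[sid] = s.values
        df.to_csv(csv_path, index=False)
        Path(labels_path).write_text(
            json.dumps(
                {"labels": dict(zip(self.ids, self.labels)), "provenance": self.provenance},
                indent=2,
            )
        )

    @classmethod
    def from_csv(cls, csv_path: str | Path, labels_path: str | Path) -> "ReferenceLibrary":
        import pandas as pd

        df = pd.read_csv(csv_path)
        if "wavelength_nm" not in df.columns:
            raise ValueError("library CSV needs a 'wavelength_nm' column")
        sidecar = json.loads(Path(labels_path).read_text())
        label_map = sidecar["labels"]
        grid = WavelengthGrid(df["wavelength_nm"].to_numpy())
        ids, labels, spectra = [], [], []
        for col in df.columns:
            if col == "wavelength_nm":
                continue
            if col not in label_map:
                raise ValueError(f"specimen {col!r} missing from label sidecar")
            ids.append(col)
            labels.append(label_map[col])
            spectra.append(Spectrum(df[col].to_numpy(), grid))
        return cls(ids, labels, spectra, provenance=sidecar.get("provenance", ""))
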