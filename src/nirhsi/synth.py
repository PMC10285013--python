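"""Synthetic scenes, spectra, libraries, lengths, and tow tables.

Every stage of the pipeline is testable without instrument data: this module
generates reflectance cubes with planted particles and a 10-mm scale bar,
polymer and natural-material spectra with known diagnostic features, labelled
reference libraries, particle lengths from truncated power laws, and tow
tables with known totals. All outputs are reproducible under a fixed seed
and come with machine-readable ground truth.

Material models are qualitative emulations of benchtop reference spectra:
polyethylene carries its 1540 nm peak (plus the weak 1215 nm trough it
shares with polypropylene), polypropylene its 1196 and 1215 nm troughs,
polystyrene an aromatic overtone peak near 1680 nm. Natural materials — a
pumice-like rising slope, an organic carapace-like fall-off above 1300 nm,
and a broad woody curve — contain no extrema inside any diagnostic window,
which is the only property the feature encoder consumes. Amplitudes and
widths are free parameters of the generator, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .features import ReferenceLibrary, Spectrum
from .hypercube import Hypercube, WavelengthGrid
from .survey import TowRecord

__all__ = [
    "GaussianFeature",
    "MaterialModel",
    "ParticleSpec",
    "BarSpec",
    "SceneSpec",
    "material",
    "MATERIAL_NAMES",
    "synth_spectrum",
    "make_reference_library",
    "synth_cube",
    "synth_raw_and_references",
    "sample_power_law",
    "synth_tow_table",
]

BACKGROUND_REFLECTANCE = 0.05  # matte black adhesive mounting background
BAR_REFLECTANCE = 0.9  # broadband white calibration bar


@dataclass(frozen=True)
class GaussianFeature:
    """One diagnostic Gaussian bump (peak) or dip (trough) in reflectance."""

    center_nm: float
    kind: str  # "peak" | "trough"
    amplitude: float
    sigma_nm: float


@dataclass(frozen=True)
class MaterialModel:
    """Class label plus a smooth baseline and signed Gaussian features.

    ``baseline`` holds polynomial coefficients (lowest order first) in the
    scaled coordinate x = (wavelength - 900)/800, so baselines stay smooth
    and slope-like across the sensor range.
    """

    label: str
    name: str
    baseline: tuple[float, ...]
    features: tuple[GaussianFeature, ...] = ()

    def reflectance(self, grid: WavelengthGrid) -> np.ndarray:
        w = grid.wavelengths_nm
        x = (w - 900.0) / 800.0
        r = np.polynomial.polynomial.polyval(x, np.asarray(self.baseline))
        for f in self.features:
            sign = 1.0 if f.kind == "peak" else -1.0
            r = r + sign * f.amplitude * np.exp(-((w - f.center_nm) ** 2) / (2 * f.sigma_nm**2))
        return np.clip(r, 1e-6, None)


def _materials() -> dict[str, MaterialModel]:
    return {
        "HDPE": MaterialModel(
            "HDPE",
            "virgin high-density polyethylene bead",
            baseline=(0.60,),
            features=(
                GaussianFeature(1540.0, "peak", 0.15, 10.0),
                GaussianFeature(1215.0, "trough", 0.03, 6.0),
            ),
        ),
        "LDPE": MaterialModel(
            "LDPE",
            "virgin low-density polyethylene bead",
            baseline=(0.55,),
            features=(
                GaussianFeature(1540.0, "peak", 0.13, 11.0),
                GaussianFeature(1215.0, "trough", 0.025, 6.0),
            ),
        ),
        "PP": MaterialModel(
            "PP",
            "virgin polypropylene bead",
            baseline=(0.58,),
            features=(
                GaussianFeature(1196.0, "trough", 0.10, 5.0),
                GaussianFeature(1215.0, "trough", 0.06, 5.0),
            ),
        ),
        "PS": MaterialModel(
            "PS",
            "virgin polystyrene bead",
            baseline=(0.52,),
            features=(GaussianFeature(1680.0, "peak", 0.12, 10.0),),
        ),
        "pumice": MaterialModel(
            "other",
            "floating pumice stone (reflectance rises with wavelength)",
            baseline=(0.32, 0.15),
        ),
        "organic": MaterialModel(
            "other",
            "crustacean carapace (reflectance falls above ~1300 nm)",
            # smooth monotone fall-off: linear decline, no interior extrema
            baseline=(0.48, -0.02, -0.18),
        ),
        "wood": MaterialModel(
            "other",
            "driftwood / algal fragment (broad featureless curve)",
            baseline=(0.36, 0.10, -0.05),
        ),
    }


MATERIAL_NAMES = tuple(_materials())


def material(name: str) -> MaterialModel:
    """Look up a predefined material model by name."""
    try:
        return _materials()[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; choose from {MATERIAL_NAMES}") from None


def synth_spectrum(
    mat: MaterialModel,
    grid: WavelengthGrid | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> Spectrum:
    """Material reflectance plus optional per-band Gaussian sensor noise."""
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(rng)
    values = mat.reflectance(grid)
    if noise_sd > 0:
        values = np.clip(values + rng.normal(0.0, noise_sd, values.shape), 1e-6, None)
    return Spectrum(values, grid, normalized=False)


def _jitter(mat: MaterialModel, rng: np.random.Generator) -> MaterialModel:
    """Per-specimen variation: +-10% feature amplitudes, +-5% baseline."""
    feats = tuple(
        replace(f, amplitude=f.amplitude * rng.uniform(0.9, 1.1)) for f in mat.features
    )
    base = tuple(c * rng.uniform(0.95, 1.05) for c in mat.baseline)
    return replace(mat, baseline=base, features=feats)


def make_reference_library(
    grid: WavelengthGrid | None = None,
    n_per_class: int = 12,
    noise_sd: float = 0.02,
    seed: int = 0,
    n_pixel_draws: int = 100,
) -> ReferenceLibrary:
    """Labelled synthetic reference library covering PE, PP, PS, and other.

    PE specimens alternate HDPE/LDPE (collapsed to PE at load); natural
    specimens cycle pumice/organic/wood. ``noise_sd`` is per-band sensor
    noise in reflectance units at the single-pixel level; each specimen
    spectrum is the mean over ``n_pixel_draws`` pixels of the imaged bead,
    exactly as the pipeline pools particle spectra, so the noise on a
    library spectrum is ``noise_sd / sqrt(n_pixel_draws)`` per band.
    """
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(seed)
    effective_sd = noise_sd / np.sqrt(max(n_pixel_draws, 1))
    ids, labels, spectra = [], [], []

    plan: list[tuple[str, str]] = []
    for i in range(n_per_class):
        plan.append(("HDPE" if i % 2 == 0 else "LDPE", "pe"))
    plan += [("PP", "pp")] * n_per_class
    plan += [("PS", "ps")] * n_per_class
    naturals = ("pumice", "organic", "wood")
    plan += [(naturals[i % 3], "oth") for i in range(n_per_class)]

    counter: dict[str, int] = {}
    for mat_name, _tag in plan:
        mat = _jitter(material(mat_name), rng)
        k = counter.get(mat_name, 0)
        counter[mat_name] = k + 1
        ids.append(f"{mat_name}_{k}")
        labels.append(mat.label if mat.label == "other" else mat_name)
        spectra.append(synth_spectrum(mat, grid, noise_sd=effective_sd, rng=rng))
    return ReferenceLibrary(
        ids, labels, spectra, provenance="synthetic reference library (nirhsi.synth)"
    )


# ---------------------------------------------------------------------------
# Scenes

@dataclass(frozen=True)
class ParticleSpec:
    """One planted particle: shape, size in pixels, centre, material name.

    ``size`` is the radius for a disk, (major, minor, angle_deg) full axis
    lengths for an ellipse, and a nominal radius for a random blob.
    """

    shape: str  # "disk" | "ellipse" | "blob"
    size: tuple
    center: tuple[int, int]  # (line, sample)
    material: str


@dataclass(frozen=True)
class BarSpec:
    """Scale bar along the bottom edge: physical length is 10 mm."""

    length_px: int
    height_px: int = 6
    length_mm: float = 10.0


@dataclass(frozen=True)
class SceneSpec:
    """A full synthetic scan: geometry, particles, bar, noise, seed."""

    shape: tuple[int, int] = (200, 640)
    particles: tuple[ParticleSpec, ...] = ()
    bar: BarSpec | None = BarSpec(length_px=500)
    noise_sd: float = 0.005
    background: float = BACKGROUND_REFLECTANCE
    seed: int = 0
    allow_overlap: bool = False


def _particle_mask(spec: ParticleSpec, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    ll, ss = np.indices(shape)
    cl, cs = spec.center
    dl, ds = ll - cl, ss - cs
    if spec.shape == "disk":
        (r,) = spec.size if isinstance(spec.size, tuple) else (spec.size,)
        return dl**2 + ds**2 <= r**2
    if spec.shape == "ellipse":
        major, minor, angle_deg = spec.size
        a, b = major / 2.0, minor / 2.0
        t = np.deg2rad(angle_deg)
        u = dl * np.cos(t) + ds * np.sin(t)
        v = -dl * np.sin(t) + ds * np.cos(t)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if spec.shape == "blob":
        (r,) = spec.size if isinstance(spec.size, tuple) else (spec.size,)
        theta = np.arctan2(ds, dl)
        wobble = 1.0 + 0.25 * np.sin(3 * theta + rng.uniform(0, 2 * np.pi))
        return np.hypot(dl, ds) <= r * wobble
    raise ValueError(f"unknown particle shape {spec.shape!r}")


def synth_cube(
    scene: SceneSpec, grid: WavelengthGrid | None = None
):
    """Render a scene -> (reflectance cube, truth label map, truth table).

    Particles are filled with their material spectrum, the bar is broadband
    bright, the background dark; per-band Gaussian noise is added last. The
    truth table has one row per particle: id, material, class, and the true
    pixel extents along the mask's principal directions.
    """
    import pandas as pd

    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(scene.seed)
    n_lines, n_samples = scene.shape
    cube = np.full((n_lines, n_samples, len(grid)), scene.background, dtype=float)
    labels = np.zeros((n_lines, n_samples), dtype=np.int32)

    rows = []
    for idx, pspec in enumerate(scene.particles, start=1):
        mask = _particle_mask(pspec, scene.shape, rng)
        if not mask.any():
            raise ValueError(f"particle {idx} rasterises to zero pixels")
        if not scene.allow_overlap and (labels[mask] != 0).any():
            raise ValueError(f"particle {idx} overlaps an earlier particle")
        mat = material(pspec.material)
        cube[mask] = mat.reflectance(grid)
        labels[mask] = idx

        coords = np.argwhere(mask).astype(float)
        centred = coords - coords.mean(axis=0)
        if len(coords) == 1:
            ext = np.array([1.0, 1.0])
        else:
            _, _, vt = np.linalg.svd(centred, full_matrices=False)
            proj = centred @ vt.T
            ext = proj.max(axis=0) - proj.min(axis=0) + 1.0
        length_px, width_px = sorted(ext, reverse=True)
        rows.append(
            {
                "id": idx,
                "material": pspec.material,
                "class": mat.label,
                "length_px": length_px,
                "width_px": width_px,
                "center_line": pspec.center[0],
                "center_sample": pspec.center[1],
                "area_px": int(mask.sum()),
            }
        )

    if scene.bar is not None:
        h = scene.bar.height_px
        lo = (n_samples - scene.bar.length_px) // 2
        cube[n_lines - h :, lo : lo + scene.bar.length_px, :] = BAR_REFLECTANCE

    if scene.noise_sd > 0:
        cube = cube + rng.normal(0.0, scene.noise_sd, cube.shape)
    cube = np.clip(cube, 0.0, 1.5)

    truth = pd.DataFrame(
        rows,
        columns=[
            "id", "material", "class", "length_px", "width_px",
            "center_line", "center_sample", "area_px",
        ],
    )
    return Hypercube(cube, grid, kind="reflectance"), labels, truth


def synth_raw_and_references(
    cube: Hypercube,
    full_scale: float = 4000.0,
    dark_level: float = 120.0,
    rng: np.random.Generator | int | None = None,
):
    """Invert calibration: reflectance cube -> (raw uint16 cube, white, dark).

    Emulates the sensor by mapping reflectance 1.0 to ``full_scale`` counts
    above a dark offset, with a mild spatial vignette across sample columns
    so the per-column calibration is actually exercised.
    """
    from .hypercube import CalibrationPair

    rng = np.random.default_rng(rng)
    n_samples, n_bands = cube.n_samples, cube.n_bands
    vignette = 1.0 - 0.2 * np.linspace(-1, 1, n_samples) ** 2
    white = dark_level + full_scale * vignette[:, None] * np.ones((1, n_bands))
    dark = np.full((n_samples, n_bands), dark_level)
    raw = dark[None, :, :] + cube.data * (white - dark)[None, :, :]
    raw_cube = Hypercube(np.round(raw).astype(np.uint16), cube.grid, kind="raw")
    return raw_cube, CalibrationPair(white=white, dark=dark)


# ---------------------------------------------------------------------------
# Particle lengths and tow tables

def sample_power_law(
    alpha: float,
    l_min: float,
    l_max: float,
    n: int | None = None,
    rng: np.random.Generator | int | None = None,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """Inverse-CDF samples from the truncated density ~ l^-alpha on [l_min, l_max].

    l = [l_min^(1-a) - u (l_min^(1-a) - l_max^(1-a))]^(1/(1-a)); at alpha = 1
    the log-uniform closed form applies. Pass ``u`` directly to evaluate the
    quantile transform at chosen uniforms (u = 0 -> l_min, u = 1 -> l_max).
    """
    if not (l_max > l_min > 0):
        raise ValueError("need l_max > l_min > 0")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if u is None:
        if n is None:
            raise ValueError("provide n or explicit uniforms u")
        u = np.random.default_rng(rng).uniform(0.0, 1.0, n)
    u = np.asarray(u, dtype=float)
    if alpha == 1.0:
        return l_min * (l_max / l_min) ** u
    a1 = 1.0 - alpha
    return (l_min**a1 - u * (l_min**a1 - l_max**a1)) ** (1.0 / a1)


def synth_tow_table(
    n_stations: int = 9,
    tows_per_station: int = 3,
    seed: int = 0,
    clog_probability: float = 0.1,
) -> list[TowRecord]:
    """Tow records with known totals: volumes, per-class counts, clog flags.

    Volumes span the realistic 25-340 m3 range of 20-minute surface tows;
    station mean concentrations are lognormal around ~0.5 particles/m3 and
    the polymer mix is PE-dominated, mirroring open-ocean surface samples.
    """
    rng = np.random.default_rng(seed)
    mix = {"PE": 0.70, "PP": 0.12, "PS": 0.03, "other": 0.15}
    records = []
    for st in range(n_stations):
        conc = rng.lognormal(mean=np.log(0.5), sigma=0.8)
        for tow in range(tows_per_station):
            volume = float(np.round(rng.uniform(25, 340), 0))
            lam = conc * volume * rng.uniform(0.5, 1.5)
            counts = {cls: int(rng.poisson(lam * f)) for cls, f in mix.items()}
            total = sum(counts.values())
            if total == 0:
                counts["PE"] = 1
                total = 1
            records.append(
                TowRecord(
                    station=f"S{st + 1:02d}-{tow + 1}",
                    volume_m3=volume,
                    total=total,
                    counts=counts,
                    clogged=bool(rng.uniform() < clog_probability),
                )
            )
    return records
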