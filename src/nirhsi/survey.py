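"""Tow-level survey statistics: concentrations, proportions, size spectra.

A surface net tow with a flowmeter yields a filtered seawater volume (m3)
and a particle count, hence a concentration in particles per m3. Tows whose
flowmeter was blocked (net clogged with weed) carry an unreliable volume and
are excluded from range summaries. Particle lengths are binned into nine
logarithmically spaced size classes spanning the net mesh (0.3 mm) to 40 mm;
bin counts n are divided by bin width to give the normalised abundance
n/dl (mm^-1). Above ~2 mm the abundance follows a power law n/dl ~ l^-alpha
whose exponent is a fragmentation-process fingerprint; it is estimated by
ordinary least squares on log(n/dl) vs log(geometric bin centre), with a
truncated-distribution maximum-likelihood estimator as a cross-check.

The package ships a transcription of the cruise tow table (station, volume,
total particle count, printed concentration, clogged flag) and the Raman
cross-check particle breakdown used for the method's validation arithmetic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TowRecord",
    "SizeDistribution",
    "PowerLawFit",
    "round_half_up",
    "tow_concentration",
    "concentration_range",
    "polymer_proportions",
    "default_size_bins",
    "bin_size_distribution",
    "fit_power_law",
    "fit_power_law_mle",
    "load_tow_table",
    "load_raman_crosscheck",
    "raman_summary",
]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (0.5625 -> 0.563), used for table display."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TowRecord:
    """One net tow: station id, filtered volume, particle counts."""

    station: str
    volume_m3: float
    total: int
    counts: Mapping[str, int] | None = None
    clogged: bool = False

    def __post_init__(self) -> None:
        if self.volume_m3 <= 0:
            raise ValueError("tow volume must be positive")
        if self.total < 0:
            raise ValueError("particle count cannot be negative")
        if self.counts is not None and any(v < 0 for v in self.counts.values()):
            raise ValueError("class counts cannot be negative")


def tow_concentration(record: TowRecord) -> float:
    """Particles per m3 = total count / filtered volume (unrounded)."""
    return record.total / record.volume_m3


def concentration_range(
    records: Sequence[TowRecord], exclude_clogged: bool = True
) -> tuple[float, float]:
    """(min, max) concentration over eligible tows."""
    eligible = [r for r in records if not (exclude_clogged and r.clogged)]
    if not eligible:
        raise ValueError("no eligible tows (all excluded)")
    concs = [tow_concentration(r) for r in eligible]
    return min(concs), max(concs)


def polymer_proportions(records: Sequence[TowRecord]) -> dict[str, float]:
    """Pooled per-class particle fractions over all tows; sums to 1."""
    totals: dict[str, float] = {}
    for r in records:
        if r.counts is None:
            continue
        for cls, n in r.counts.items():
            totals[cls] = totals.get(cls, 0) + n
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("no class counts available to compute proportions")
    return {cls: n / grand for cls, n in sorted(totals.items())}


# ---------------------------------------------------------------------------
# Size distributions

#: Net mesh to largest-particle span, split into nine log-spaced classes.
DEFAULT_SIZE_RANGE_MM = (0.3, 40.0)
DEFAULT_N_BINS = 9


def default_size_bins() -> np.ndarray:
    lo, hi = DEFAULT_SIZE_RANGE_MM
    return np.geomspace(lo, hi, DEFAULT_N_BINS + 1)


@dataclass
class SizeDistribution:
    """Binned particle lengths with bin-width-normalised abundance."""

    bin_edges_mm: np.ndarray
    counts: np.ndarray
    n_below: int = 0
    n_above: int = 0

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges_mm, dtype=float)
        if e.ndim != 1 or e.size < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("bin edges must be 1-D and strictly increasing")
        c = np.asarray(self.counts)
        if c.shape != (e.size - 1,):
            raise ValueError("counts must have one entry per bin")
        self.bin_edges_mm, self.counts = e, c

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges_mm)

    @property
    def normalized(self) -> np.ndarray:
        """n/dl: counts divided by bin width, in mm^-1."""
        return self.counts / self.widths

    @property
    def geometric_centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges_mm[:-1] * self.bin_edges_mm[1:])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "edge_lo_mm": self.bin_edges_mm[:-1],
                "edge_hi_mm": self.bin_edges_mm[1:],
                "center_mm": self.geometric_centers,
                "count": self.counts,
                "normalized_per_mm": self.normalized,
            }
        )


def bin_size_distribution(
    lengths_mm: Sequence[float], edges: np.ndarray | None = None
) -> SizeDistribution:
    """Histogram lengths into half-open bins [e_i, e_{i+1}).

    Lengths outside the edge span are tallied separately in ``n_below`` /
    ``n_above`` rather than silently dropped.
    """
    edges = default_size_bins() if edges is None else np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    lengths = np.asarray(lengths_mm, dtype=float)
    below = lengths < edges[0]
    above = lengths >= edges[-1]
    in_range = lengths[~below & ~above]
    idx = np.searchsorted(edges, in_range, side="right") - 1
    counts = np.bincount(idx, minlength=edges.size - 1)
    return SizeDistribution(edges, counts, n_below=int(below.sum()), n_above=int(above.sum()))


# ---------------------------------------------------------------------------
# Power-law exponent

@dataclass
class PowerLawFit:
    """Fitted size-spectrum exponent alpha with its standard error."""

    alpha: float
    alpha_se: float
    fit_range_mm: tuple[float, float]
    n_bins_used: int
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.alpha_se < 0:
            raise ValueError("standard error cannot be negative")
        if self.n_bins_used < 3:
            raise ValueError("fit must use at least 3 bins")

    def summary(self) -> str:
        lo, hi = self.fit_range_mm
        return (
            "Power-law size spectrum fit (n/dl ~ l^-alpha)\n"
            f"  alpha     : {self.alpha:.3f} +/- {self.alpha_se:.3f} (OLS slope se)\n"
            f"  fit range : {lo:.3g} - {hi:.3g} mm ({self.n_bins_used} bins)\n"
            f"  R^2       : {self.r_squared:.4f}"
        )


def fit_power_law(
    dist: SizeDistribution,
    l_min_fit: float = 2.0,
    edge_rule: str = "edge",
) -> PowerLawFit:
    """OLS fit of log(n/dl) on log(geometric bin centre) over large bins.

    Eligible bins are non-empty and, under the default ``edge_rule="edge"``,
    lie wholly at or above ``l_min_fit`` (lower edge >= l_min_fit), so a bin
    only partially covered by the fitted range cannot distort the slope.
    ``edge_rule="center"`` instead admits any bin whose geometric centre
    reaches ``l_min_fit``. Empty bins are dropped (log undefined); zero
    replacement is deliberately not offered. alpha = -slope.
    """
    if edge_rule not in ("edge", "center"):
        raise ValueError("edge_rule must be 'edge' or 'center'")
    if edge_rule == "edge":
        large = dist.bin_edges_mm[:-1] >= l_min_fit * (1 - 1e-12)
    else:
        large = dist.geometric_centers >= l_min_fit
    eligible = large & (dist.counts > 0)
    if eligible.sum() < 3:
        raise ValueError(
            f"need >= 3 non-empty bins above {l_min_fit} mm, have {int(eligible.sum())}"
        )
    x = np.log(dist.geometric_centers[eligible])
    y = np.log(dist.normalized[eligible])
    res = stats.linregress(x, y)
    lo = float(dist.bin_edges_mm[:-1][eligible].min())
    hi = float(dist.bin_edges_mm[1:][eligible].max())
    return PowerLawFit(
        alpha=float(-res.slope),
        alpha_se=float(res.stderr),
        fit_range_mm=(lo, hi),
        n_bins_used=int(eligible.sum()),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def fit_power_law_mle(
    lengths_mm: Sequence[float], l_min: float, l_max: float
) -> float:
    """Maximum-likelihood exponent of a truncated power law on [l_min, l_max].

    Cross-check utility for the binned OLS estimator: maximises the
    truncated-density log-likelihood over alpha.
    """
    x = np.asarray(lengths_mm, dtype=float)
    x = x[(x >= l_min) & (x <= l_max)]
    if x.size < 10:
        raise ValueError("too few lengths inside the truncation range")
    slog = np.log(x).sum()
    n = x.size

    def neg_loglik(alpha: float) -> float:
        if alpha == 1.0:
            norm = np.log(np.log(l_max / l_min))
        else:
            norm = np.log((l_min ** (1 - alpha) - l_max ** (1 - alpha)) / (alpha - 1))
        return alpha * slog + n * norm

    res = optimize.minimize_scalar(neg_loglik, bounds=(1.0 + 1e-6, 10.0), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# Packaged survey inputs

def _data_path(name: str):
    return importlib.resources.files("nirhsi.data").joinpath(name)


def load_tow_table(path=None):
    """The cruise tow table as ``(DataFrame, list[TowRecord])``.

    With no ``path``, loads the packaged North Atlantic gyre transcription
    (27 tows across 8 stations; only the unambiguous columns: station,
    position, volume, total count, printed concentration, clogged flag).
    """
    import pandas as pd

    src = _data_path("north_atlantic_tows.csv") if path is None else path
    with importlib.resources.as_file(src) if path is None else _nullcontext(src) as p:
        df = pd.read_csv(p)
    records = [
        TowRecord(
            station=f"{row.station}-{row.tow}",
            volume_m3=float(row.volume_m3),
            total=int(row.total_mp),
            clogged=bool(row.clogged),
        )
        for row in df.itertuples()
    ]
    return df, records


class _nullcontext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def load_raman_crosscheck(path=None) -> dict[str, int]:
    """Counts from the Raman-microscopy validation subset (category -> n)."""
    import pandas as pd

    src = _data_path("raman_crosscheck.csv") if path is None else path
    with importlib.resources.as_file(src) if path is None else _nullcontext(src) as p:
        df = pd.read_csv(p)
    return dict(zip(df["category"], df["count"].astype(int)))


def raman_summary(counts: Mapping[str, int]) -> dict[str, float]:
    """Fractions of the Raman validation breakdown, on a percent scale.

    ``not_evaluable`` covers particles too fluorescent or too weakly
    scattering for a Raman match.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty Raman breakdown")
    out = {f"pct_{k}": 100.0 * v / total for k, v in counts.items()}
    out["total"] = float(total)
    return out
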