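"""Mean-force profiles along a forced-dissociation coordinate.

A slow umbrella pull drags the inter-site distance x with a stiff harmonic
restraint; when pulling is quasi-static the restraint force balances the
systematic force, so its negative, binned over x, estimates the mean force
the pair exerts along the coordinate.  The sign convention throughout is
**positive = repulsive** (the pair pushed apart): positive below the
equilibrium distance, negative in an attractive window, zero at pmf extrema.
The long-range reference is the screened Coulomb force between two point
charges, f_C z_a z_b / (eps_r r^2) with eps_r = 80 for bulk water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_KJ_MOL_NM
from .trajectory_io import TimeSeries

__all__ = [
    "PullRecord",
    "ForceProfile",
    "RegimeReport",
    "bin_mean_force",
    "screened_coulomb_force",
    "find_regimes",
    "compare_to_reference",
]


@dataclass
class PullRecord:
    """Times (ps), reaction coordinate x (nm), restraint force (kJ mol^-1 nm^-1)."""

    times: np.ndarray
    x: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.x = np.asarray(self.x, dtype=float).reshape(-1)
        self.force = np.asarray(self.force, dtype=float).reshape(-1)
        if not len(self.times) == len(self.x) == len(self.force):
            raise ValueError("times, x and force must have equal lengths")
        if len(self.times) == 0:
            raise ValueError("empty pull record")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.x <= 0):
            raise ValueError("reaction-coordinate distances must be positive")

    @classmethod
    def from_timeseries(cls, series: TimeSeries, x_col: str = "x",
                        force_col: str = "force") -> "PullRecord":
        return cls(series.times, series.column(x_col), series.column(force_col))


@dataclass
class ForceProfile:
    """Binned mean force vs distance; empty bins are flagged, never interpolated."""

    bin_edges: np.ndarray
    mean_force: np.ndarray
    stderr: np.ndarray
    n_samples: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mean_force = np.asarray(self.mean_force, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        widths = np.diff(self.bin_edges)
        if np.any(np.abs(widths - widths[0]) > 1e-9 * widths[0]):
            raise ValueError("bins must be uniformly spaced")
        if np.any(self.stderr[self.n_samples > 1] < 0):
            raise ValueError("stderr must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def occupied(self) -> np.ndarray:
        return self.n_samples > 0


@dataclass
class RegimeReport:
    """Zero crossings of the mean force and the sign-labelled windows between them."""

    zero_crossings: list[float]
    windows: list[tuple[tuple[float, float], str]]

    def __post_init__(self) -> None:
        if sorted(self.zero_crossings) != list(self.zero_crossings):
            raise ValueError("zero crossings must be sorted ascending")
        signs = [s for _, s in self.windows]
        for a, b in zip(signs, signs[1:]):
            if a == b:
                raise ValueError("adjacent windows must alternate sign")


# ---------------------------------------------------------------------------


def bin_mean_force(record: PullRecord, bin_width: float = 0.005) -> ForceProfile:
    """Bin the pull record over x into a mean-force profile.

    Samples fall into half-open bins by coordinate value (no time
    dependence, so the profile is invariant under time reversal of the
    record).  The reported mean force is the **negative** of the binned
    restraint force: under quasi-static balance the restraint force equals
    +dV/dx, so its negative is the force the pair exerts, positive =
    repulsive.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(record.x.min() / bin_width) * bin_width
    hi = record.x.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width + 1e-12)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    idx = np.clip(((record.x - lo) / bin_width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=record.force, minlength=n_bins)
    sq_sums = np.bincount(idx, weights=record.force**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        var = sq_sums / counts - mean**2
        stderr = np.sqrt(np.clip(var, 0.0, None) / np.maximum(counts - 1, 1))
    mean_force = -mean  # pair force, positive = repulsive
    mean_force[counts == 0] = np.nan
    stderr[counts == 0] = np.nan
    if np.count_nonzero(counts) == 1:
        warnings.warn(
            "all samples fall in a single bin: pull too short or bins too wide",
            RuntimeWarning,
            stacklevel=2,
        )
    return ForceProfile(edges, mean_force, stderr, counts)


def screened_coulomb_force(r, eps_r: float = 80.0, z_a: float = 1.0,
                           z_b: float = -1.0):
    """Screened Coulomb force between point charges, kJ mol^-1 nm^-1.

    f = f_C z_a z_b / (eps_r r^2); positive (repulsive) for like charges,
    negative for unlike.  f_C = 138.935458 kJ mol^-1 nm e^-2.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if eps_r < 1:
        raise ValueError("relative permittivity must be >= 1")
    out = COULOMB_KJ_MOL_NM * z_a * z_b / (eps_r * r**2)
    return float(out) if out.ndim == 0 else out


def find_regimes(profile: ForceProfile, noise_floor: float | None = None) -> RegimeReport:
    """Locate zero crossings of the mean force and label the windows between.

    A sign change between adjacent occupied bins counts only when the mean
    force exceeds ``noise_floor`` in magnitude on both flanks (default:
    median per-bin standard error); the crossing position is linearly
    interpolated between the bin centers.  Windows alternate between
    ``repulsive`` (positive) and ``attractive`` (negative).  No crossing
    above the noise is an empty report, not an error.
    """
    occ = profile.occupied
    if occ.sum() < 3:
        raise ValueError("profile must contain at least 3 occupied bins")
    centers = profile.bin_centers[occ]
    force = profile.mean_force[occ]
    stderr = profile.stderr[occ]
    if noise_floor is None:
        finite = stderr[np.isfinite(stderr)]
        noise_floor = float(np.median(finite)) if len(finite) else 0.0
    # scan only bins significant above the noise floor; bins inside the noise
    # band neither make nor break a crossing
    sig = np.where(np.abs(force) > noise_floor)[0]
    crossings: list[float] = []
    for i, j in zip(sig[:-1], sig[1:]):
        f0, f1 = force[i], force[j]
        if np.sign(f0) * np.sign(f1) < 0:
            x0, x1 = centers[i], centers[j]
            crossings.append(float(x0 + (x1 - x0) * f0 / (f0 - f1)))
    bounds = [float(centers[0])] + crossings + [float(centers[-1])]
    windows: list[tuple[tuple[float, float], str]] = []
    prev_sign = None
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        inside = (centers >= lo) & (centers <= hi)
        sign = "repulsive" if np.nansum(force[inside]) >= 0 else "attractive"
        if sign == prev_sign:
            sign = "attractive" if prev_sign == "repulsive" else "repulsive"
        windows.append(((lo, hi), sign))
        prev_sign = sign
    return RegimeReport(crossings, windows)


def compare_to_reference(profile: ForceProfile, eps_r: float = 80.0,
                         z_a: float = 1.0, z_b: float = -1.0) -> np.ndarray:
    """Per-bin residual of the profile against the screened Coulomb force.

    Returns ``mean_force - f_screened`` at every bin center (NaN for empty
    bins).  Residuals consistent with zero beyond the structured window mean
    the dissociated pair interacts like two screened point charges.
    """
    ref = screened_coulomb_force(profile.bin_centers, eps_r, z_a, z_b)
    return profile.mean_force - ref
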