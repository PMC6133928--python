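"""Reorientation dynamics: vector autocorrelation functions and exponential fits.

The observable is the rank-1 (first Legendre) orientational correlation
function of an ensemble of unit vectors (water dipoles, OH bonds, ...):

    C1(t) = < u(t0) . u(t0 + t) >

averaged over every molecule and every valid time origin.  For isotropic
rotational diffusion with diffusion constant D_r this decays as
C1(t) = exp(-2 D_r t), so a mono-exponential fit recovers tau = 1/(2 D_r).
A stiffened hydrogen-bond network shows up as a second, slower exponential
component carried by the affected sub-population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.optimize import curve_fit

from .trajectory_io import SiteGroup, Trajectory, minimum_image

__all__ = [
    "VectorSeries",
    "ACFResult",
    "ExpFitResult",
    "extract_vectors",
    "vector_acf",
    "fit_exponentials",
    "time_constant_ratio",
]


@dataclass
class VectorSeries:
    """Per-molecule unit vectors over time: shape (n_steps, n_molecules, 3)."""

    vectors: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError(
                f"vectors must be (n_steps, n_molecules, 3), got {self.vectors.shape}"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        norms = np.linalg.norm(self.vectors, axis=2)
        if self.vectors.size and np.max(np.abs(norms - 1.0)) > 1e-6:
            raise ValueError("vectors must be unit length within 1e-6")

    @property
    def n_steps(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ACFResult:
    """Normalized autocorrelation on a uniform lag grid starting at 0.

    ``stderr``, when present, is the per-lag standard error of the pooled
    estimate (scatter of per-unit contributions across the ensemble).
    """

    lags: np.ndarray
    values: np.ndarray
    n_origins: np.ndarray
    meta: dict | None = None
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_origins = np.asarray(self.n_origins, dtype=int)
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
        if self.lags[0] != 0:
            raise ValueError("lag grid must start at 0")

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0]) if len(self.lags) > 1 else 0.0


@dataclass
class ExpFitResult:
    """Multi-exponential fit sum_i a_i exp(-t / tau_i), tau ascending."""

    amplitudes: np.ndarray
    time_constants: np.ndarray
    fit_window: tuple[float, float]
    rss: float

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.time_constants = np.asarray(self.time_constants, dtype=float)
        if np.any(self.time_constants <= 0):
            raise ValueError("time constants must be positive")

    @property
    def n_components(self) -> int:
        return len(self.time_constants)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.amplitudes[:, None] * np.exp(-t[None, :] / self.time_constants[:, None]),
            axis=0,
        )


# ---------------------------------------------------------------------------


def _anchor_positions(positions: np.ndarray, box: np.ndarray, group: SiteGroup,
                      anchor: np.ndarray) -> np.ndarray:
    """Positions of a group made continuous with respect to per-molecule anchors."""
    p = positions[group.array]
    return anchor + minimum_image(p - anchor, box)


def extract_vectors(trajectory: Trajectory, endpoint_from, endpoint_to) -> VectorSeries:
    """Build unit vectors from one site (group) to another, per molecule per frame.

    Each endpoint is a :class:`SiteGroup` or a sequence of equally sized
    SiteGroups whose positions are averaged (e.g. the two water hydrogens to
    form the dipole direction of a 3-site water).  Periodic images are chosen
    so the intramolecular vector uses the minimum image before normalizing.
    """
    from_groups = [endpoint_from] if isinstance(endpoint_from, SiteGroup) else list(endpoint_from)
    to_groups = [endpoint_to] if isinstance(endpoint_to, SiteGroup) else list(endpoint_to)
    sizes = {len(g) for g in from_groups + to_groups}
    if len(sizes) != 1:
        raise ValueError(
            "endpoint groups must resolve to equal molecule counts, got sizes "
            f"{[len(g) for g in from_groups + to_groups]}"
        )
    (n_mol,) = sizes
    if n_mol == 0:
        raise ValueError("endpoint groups are empty")
    anchor_group = from_groups[0]
    out = np.empty((trajectory.n_frames, n_mol, 3))
    for f, frame in enumerate(trajectory.frames):
        anchor = frame.positions[anchor_group.array]
        p_from = np.mean(
            [_anchor_positions(frame.positions, frame.box, g, anchor) for g in from_groups],
            axis=0,
        )
        p_to = np.mean(
            [_anchor_positions(frame.positions, frame.box, g, anchor) for g in to_groups],
            axis=0,
        )
        d = minimum_image(p_to - p_from, frame.box)
        norm = np.linalg.norm(d, axis=1)
        if np.any(norm < 1e-12):
            raise ValueError(f"zero-length vector in frame {f}")
        out[f] = d / norm[:, None]
    dt = trajectory.dt if trajectory.dt > 0 else 1.0
    return VectorSeries(out, dt)


def _acf_numerator_fft(x: np.ndarray, n_lags: int, chunk: int = 64,
                       sumsq: bool = False):
    """Sum over columns of the lagged autocorrelation numerator of x (n_steps, m).

    With ``sumsq`` also returns the per-lag sum of squared per-column
    numerators, from which the across-column scatter (standard error of the
    pooled estimate) follows.
    """
    n = x.shape[0]
    nfft = next_fast_len(2 * n)
    total = np.zeros(n_lags)
    total_sq = np.zeros(n_lags) if sumsq else None
    for j0 in range(0, x.shape[1], chunk):
        block = x[:, j0 : j0 + chunk]
        spec = rfft(block, n=nfft, axis=0)
        corr = irfft(spec * np.conj(spec), n=nfft, axis=0)[:n_lags].real
        total += corr.sum(axis=1)
        if sumsq:
            total_sq += (corr**2).sum(axis=1)
    if sumsq:
        return total, total_sq
    return total


def vector_acf(series: VectorSeries, max_lag: float | None = None,
               method: str = "fft") -> ACFResult:
    """Rank-1 vector ACF pooled over all molecules and all time origins.

    ``max_lag`` is in ps and defaults to half the trajectory length (origin
    statistics degrade beyond that).  ``method="direct"`` computes the same
    quantity by the O(N^2) double loop over origins; it exists as the slow
    reference implementation and agrees with the transform route to
    round-off.
    """
    if series.n_steps == 0 or series.n_molecules == 0:
        raise ValueError("empty vector series")
    n, m = series.n_steps, series.n_molecules
    if max_lag is None:
        max_lag = (n - 1) * series.dt / 2.0
    n_lags = int(np.floor(max_lag / series.dt)) + 1
    n_lags = max(1, min(n_lags, n))
    v = series.vectors
    if method == "fft":
        flat = v.reshape(n, m * 3)
        num = _acf_numerator_fft(flat, n_lags)
    elif method == "direct":
        num = np.empty(n_lags)
        for lag in range(n_lags):
            num[lag] = np.sum(v[: n - lag] * v[lag:])
    else:
        raise ValueError(f"unknown method {method!r}")
    origins = m * (n - np.arange(n_lags))
    values = num / origins
    values = values / values[0]
    lags = np.arange(n_lags) * series.dt
    return ACFResult(lags, values, origins, meta={"rank": 1, "method": method})


# ---------------------------------------------------------------------------
# exponential fitting


def _loglinear_tau(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Deterministic (amplitude, tau) seed from a log-linear fit of positive C."""
    mask = c > 1e-12
    if mask.sum() < 2:
        return 1.0, max(t[-1], 1.0)
    slope, intercept = np.polyfit(t[mask], np.log(c[mask]), 1)
    tau = -1.0 / slope if slope < 0 else max(t[-1], 1.0)
    return float(np.exp(intercept)), float(tau)


def fit_exponentials(acf: ACFResult, n_components: int = 1,
                     fit_window: tuple[float, float] | None = None) -> ExpFitResult:
    """Unweighted least-squares fit of a sum of decaying exponentials to C(t).

    The fit is on C(t) itself, not log C, so the noisy tail is not
    overweighted.  Initialization is deterministic: the slow component is
    seeded from a log-linear fit of the tail of the window, the fast one from
    the early part, so repeated fits are reproducible.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if fit_window is None:
        fit_window = (float(acf.lags[0]), float(acf.lags[-1]))
    lo, hi = fit_window
    mask = (acf.lags >= lo) & (acf.lags <= hi)
    if mask.sum() < 10:
        raise ValueError(
            f"fit window ({lo}, {hi}) ps contains {int(mask.sum())} points; need >= 10"
        )
    t, c = acf.lags[mask], acf.values[mask]

    if n_components == 1:
        a0, tau0 = _loglinear_tau(t, c)
        p0 = [min(a0, 1.0), tau0]

        def model(tt, a, tau):
            return a * np.exp(-tt / tau)

        bounds = ([0.0, 1e-12], [1.5, np.inf])
    else:
        half = len(t) // 2
        a_s, tau_s = _loglinear_tau(t[half:], c[half:])
        resid = c[:half] - a_s * np.exp(-t[:half] / max(tau_s, 1e-12))
        a_f, tau_f = _loglinear_tau(t[:half], np.clip(resid, 1e-12, None))
        if tau_f >= tau_s:
            tau_f = tau_s / 5.0
        p0 = [max(min(a_f, 1.0), 1e-3), tau_f, max(min(a_s, 1.0), 1e-3), tau_s]

        def model(tt, a1, tau1, a2, tau2):
            return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

        bounds = ([0.0, 1e-12, 0.0, 1e-12], [1.5, np.inf, 1.5, np.inf])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, t, c, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"exponential fit did not converge (initial guesses {p0}, maxfev 20000): {exc}"
        ) from exc
    amps = np.array(popt[0::2])
    taus = np.array(popt[1::2])
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    rss = float(np.sum((model(t, *popt) - c) ** 2))
    return ExpFitResult(amps, taus, (float(lo), float(hi)), rss)


def time_constant_ratio(fit_salt: ExpFitResult, fit_pure: ExpFitResult) -> float:
    """Slow time constant of a salt system relative to a mono-exponential reference.

    Quantifies the reorientation slow-down of the ion-affected water
    sub-population against pure water.
    """
    if fit_pure.n_components != 1:
        raise ValueError(
            "reference fit must be mono-exponential; got "
            f"{fit_pure.n_components} components"
        )
    return float(np.max(fit_salt.time_constants) / fit_pure.time_constants[0])
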