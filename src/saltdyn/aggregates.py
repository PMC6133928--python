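"""Aggregate lifetimes from distance criteria via intermittent autocorrelation.

An aggregate (ion pair, hydrogen-bonded dimer) is defined purely geometrically:
pair (a, b) is bonded at frame t when their minimum-image distance is at or
below a cutoff.  The intermittent bond autocorrelation

    C_raw(t) = <b(t0) b(t0 + t)> / <b>

lets a pair break and re-form between the two correlated times, which makes it
far less noisy than its "continuous" counterpart.  In a finite system C_raw
decays not to zero but to the ensemble average p — the long-run probability of
finding any one specific pair bonded — so the plateau is removed by the affine
ensemble-average correction

    C_corr(t) = (C_raw(t) - p) / (1 - p),

which keeps C_corr(0) = 1 and sends the long-lag limit to 0.  The lifetime is
the time integral of C_corr; for a mono-exponential decay it equals the decay
time constant (for a two-state Markov pair process, 1 / (k_on + k_off)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reorientation import ACFResult, _acf_numerator_fft, _loglinear_tau
from .trajectory_io import SiteGroup, Trajectory, minimum_image

__all__ = [
    "PairCriterion",
    "IndicatorSeries",
    "LifetimeResult",
    "pair_indicator",
    "intermittent_acf",
    "estimate_ensemble_average",
    "ensemble_average_correction",
    "lifetime_integral",
    "compute_lifetime",
]


@dataclass(frozen=True)
class PairCriterion:
    """Distance criterion defining one aggregate type (cutoff in nm)."""

    group_a: SiteGroup
    group_b: SiteGroup
    cutoff: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if not self.name:
            object.__setattr__(self, "name", f"{self.group_a.name}-{self.group_b.name}")


@dataclass
class IndicatorSeries:
    """Boolean bond matrix b[pair, frame] with its frame spacing and pair ids."""

    indicator: np.ndarray
    dt: float
    pair_ids: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.indicator.ndim != 2:
            raise ValueError("indicator must be (n_pairs, n_frames)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.pair_ids) != self.indicator.shape[0]:
            raise ValueError("one pair id per indicator row required")
        if len(set(self.pair_ids)) != len(self.pair_ids):
            raise ValueError("pair ids must be unique")

    @property
    def n_pairs(self) -> int:
        return self.indicator.shape[0]

    @property
    def n_frames(self) -> int:
        return self.indicator.shape[1]


@dataclass
class LifetimeResult:
    """Full lifetime pipeline output for one pair criterion."""

    acf_raw: ACFResult
    ensemble_average: float
    acf_corrected: ACFResult
    lifetime: float
    lifetime_windowed: float
    lifetime_tail: float


# ---------------------------------------------------------------------------


def pair_indicator(trajectory: Trajectory, criterion: PairCriterion) -> IndicatorSeries:
    """Evaluate the distance criterion for every (a, b) pair in every frame.

    All ``len(a) * len(b)`` pairs are enumerated; a distance exactly equal to
    the cutoff counts as bonded (``<=`` convention).
    """
    a, b = criterion.group_a, criterion.group_b
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"criterion {criterion.name!r}: empty site group")
    shared = set(a.indices) & set(b.indices)
    if shared:
        raise ValueError(
            f"criterion {criterion.name!r}: groups share atoms {sorted(shared)}"
        )
    half_box = min(float(np.min(fr.box)) for fr in trajectory.frames) / 2.0
    if criterion.cutoff >= half_box:
        raise ValueError(
            f"criterion {criterion.name!r}: cutoff {criterion.cutoff} nm exceeds half "
            f"the smallest box edge ({half_box} nm)"
        )
    n_frames = trajectory.n_frames
    ind = np.empty((len(a) * len(b), n_frames), dtype=bool)
    ia, ib = a.array, b.array
    for f, frame in enumerate(trajectory.frames):
        d = minimum_image(
            frame.positions[ib][None, :, :] - frame.positions[ia][:, None, :], frame.box
        )
        dist = np.linalg.norm(d, axis=2)
        ind[:, f] = (dist <= criterion.cutoff).ravel()
    pair_ids = [(int(i), int(j)) for i in ia for j in ib]
    dt = trajectory.dt if trajectory.dt > 0 else 1.0
    return IndicatorSeries(ind, dt, pair_ids)


def intermittent_acf(indicator: IndicatorSeries, max_lag: float | None = None) -> ACFResult:
    """Intermittent bond ACF pooled over pairs and time origins, C_raw(0) = 1.

    The per-lag standard error is the scatter of single-pair contributions
    across the ensemble; rarer bonds give fewer events per pair and hence
    noisier estimates.
    """
    n = indicator.n_frames
    if max_lag is None:
        max_lag = (n - 1) * indicator.dt / 2.0
    n_lags = max(1, min(int(np.floor(max_lag / indicator.dt)) + 1, n))
    b = indicator.indicator.T.astype(float)  # (frames, pairs)
    mean_b = b.mean()
    if mean_b == 0:
        raise ValueError("no aggregates observed: indicator is identically zero")
    num, num_sq = _acf_numerator_fft(b, n_lags, sumsq=True)
    m = indicator.n_pairs
    per_origin = n - np.arange(n_lags)
    origins = m * per_origin
    values = num / origins
    norm0 = values[0]
    values = values / norm0
    # FFT round-off can leave tiny negatives on an all-false-tail series
    values[np.abs(values) < 1e-12] = 0.0
    # scatter of per-pair ACF contributions around the pooled mean
    if m > 1:
        per_pair_mean = num / m
        var_pairs = np.clip(num_sq / m - per_pair_mean**2, 0.0, None)
        stderr = np.sqrt(var_pairs / (m - 1)) / per_origin / norm0
    else:
        stderr = np.full(n_lags, np.nan)
    lags = np.arange(n_lags) * indicator.dt
    return ACFResult(
        lags, values, origins,
        meta={"kind": "intermittent", "mean_b": float(mean_b)},
        stderr=stderr,
    )


def estimate_ensemble_average(indicator: IndicatorSeries) -> float:
    """Pooled bond occupancy over all pairs and frames (the long-lag ACF plateau)."""
    if indicator.indicator.size == 0:
        raise ValueError("empty indicator series")
    return float(indicator.indicator.mean())


def ensemble_average_correction(acf_raw: ACFResult, ensemble_average: float) -> ACFResult:
    """Remove the finite-size plateau: C_corr = (C_raw - p) / (1 - p).

    The affine map fixes C_corr(0) = 1 and sends the long-lag limit to zero,
    so the integral of C_corr equals the decay time constant for a
    mono-exponential process.
    """
    p = float(ensemble_average)
    if not 0.0 <= p < 1.0:
        raise ValueError(
            f"ensemble average must lie in [0, 1), got {p}"
            + (" (degenerate always-bonded system)" if p >= 1.0 else "")
        )
    values = (acf_raw.values - p) / (1.0 - p)
    meta = dict(acf_raw.meta or {})
    meta["ensemble_average"] = p
    stderr = None if acf_raw.stderr is None else acf_raw.stderr / (1.0 - p)
    return ACFResult(acf_raw.lags.copy(), values, acf_raw.n_origins.copy(), meta, stderr)


def _tail_extension(lags: np.ndarray, values: np.ndarray, fraction: float) -> float:
    """Analytic integral beyond the window from a mono-exponential tail fit."""
    n = len(lags)
    start = int(np.floor(n * (1.0 - fraction)))
    t, c = lags[start:], values[start:]
    pos = c > 1e-12
    if pos.sum() < 3:
        return 0.0
    amp, tau = _loglinear_tau(t[pos], c[pos])
    if not np.isfinite(tau) or tau <= 0:
        return 0.0
    t_end = lags[-1]
    return float(amp * tau * np.exp(-t_end / tau))


def lifetime_integral(acf_corrected: ACFResult, tail_fraction: float = 0.25,
                      extend_tail: bool = True) -> tuple[float, float, float]:
    """Integrate the corrected ACF to a lifetime in ps.

    Returns ``(lifetime, windowed, tail)`` where ``windowed`` is the
    trapezoidal integral over the lag window and ``tail`` the analytic
    extension of a mono-exponential fitted to the final ``tail_fraction`` of
    the window (lifetimes of slowly decaying aggregates exceed any feasible
    lag window, so the truncated integral alone underestimates them).
    """
    lags, values = acf_corrected.lags, acf_corrected.values
    if len(lags) == 1:
        return float(values[0]) * 0.0, 0.0, 0.0
    windowed = float(np.trapezoid(values, lags))
    tail = _tail_extension(lags, values, tail_fraction) if extend_tail else 0.0
    lifetime = windowed + tail
    if lifetime < 0:
        warnings.warn(
            f"negative lifetime integral ({lifetime:.3g} ps): anti-correlated input",
            RuntimeWarning,
            stacklevel=2,
        )
    return lifetime, windowed, tail


def compute_lifetime(indicator: IndicatorSeries, max_lag: float | None = None,
                     tail_fraction: float = 0.25) -> LifetimeResult:
    """Full pipeline: raw intermittent ACF -> plateau correction -> lifetime."""
    acf_raw = intermittent_acf(indicator, max_lag)
    p = estimate_ensemble_average(indicator)
    acf_corr = ensemble_average_correction(acf_raw, p)
    lifetime, windowed, tail = lifetime_integral(acf_corr, tail_fraction)
    return LifetimeResult(acf_raw, p, acf_corr, lifetime, windowed, tail)
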