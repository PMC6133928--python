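"""Radial distribution functions, coordination numbers and regional densities.

g(r) is normalized to uniform partner density: pair counts in a spherical
shell are divided by ``n_a * rho_b * V_shell * n_frames``, so g = 1 means the
partner is found at that distance exactly as often as at a random point of
the simulation cell.  The running coordination number

    n(r) = 4 pi rho_b  integral_0^r g(r') r'^2 dr'

is evaluated with exact per-bin shell volumes, so it is an exact re-count of
the pairs inside r.  First-shell structure (first peak, first minimum —
which is where distance cutoffs for aggregate criteria come from),
frame-level shell occupancy, and the density ratio of a species inside a
spherical region between two sites relative to its bulk density complete the
coordination analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregates import PairCriterion
from .trajectory_io import SiteGroup, Trajectory, minimum_image

__all__ = [
    "RDFResult",
    "ShellReport",
    "OccupancyResult",
    "DensityRatioReport",
    "compute_rdf",
    "first_peak",
    "first_minimum",
    "coordination_number",
    "shell_occupancy",
    "region_density_ratio",
    "analyze_first_shell",
]


@dataclass
class RDFResult:
    """Binned g(r) with the bookkeeping needed to integrate it exactly."""

    bin_edges: np.ndarray
    g: np.ndarray
    rho_b: float
    n_frames: int
    n_a: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_edges) != len(self.g) + 1:
            raise ValueError("need one more bin edge than g values")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def r_max(self) -> float:
        return float(self.bin_edges[-1])


@dataclass
class ShellReport:
    """First-shell geometry and strength for one site pair."""

    r_first_peak: float
    r_first_min: float
    coordination_number: float
    occupancy_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.r_first_peak < self.r_first_min:
            raise ValueError("first peak must precede first minimum")
        if self.occupancy_fraction is not None and not 0 <= self.occupancy_fraction <= 1:
            raise ValueError("occupancy fraction must lie in [0, 1]")


@dataclass
class OccupancyResult:
    """Frame-level shell occupancy: fraction of frames with >= 1 bonded pair."""

    fraction: float
    mean_partner_count: float


@dataclass
class DensityRatioReport:
    """Species density inside an inter-site region relative to its bulk density."""

    region_density: float
    bulk_density: float
    ratio: float

    def __post_init__(self) -> None:
        if self.region_density < 0 or self.bulk_density < 0:
            raise ValueError("densities must be non-negative")


# ---------------------------------------------------------------------------


def _shell_volumes(edges: np.ndarray) -> np.ndarray:
    return 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)


def compute_rdf(trajectory: Trajectory, group_a: SiteGroup, group_b: SiteGroup,
                bin_width: float = 0.002, r_max: float | None = None) -> RDFResult:
    """Radial distribution function of group_b partners around group_a sites.

    Distances use the minimum-image convention; bins are half-open
    ``[edge_i, edge_{i+1})``.  ``r_max`` defaults to half the smallest box
    edge, the largest radius at which the minimum image is unambiguous.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("site groups must be non-empty")
    if set(group_a.indices) & set(group_b.indices):
        raise ValueError(
            f"groups {group_a.name!r} and {group_b.name!r} share atoms; "
            "disjoint groups required"
        )
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    half_box = min(float(np.min(fr.box)) for fr in trajectory.frames) / 2.0
    if r_max is None:
        r_max = half_box
    if r_max > half_box + 1e-12:
        raise ValueError(
            f"r_max {r_max} nm exceeds half the smallest box edge ({half_box} nm); "
            "beyond that the minimum image is ambiguous"
        )
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    ia, ib = group_a.array, group_b.array
    rho_sum = 0.0
    for frame in trajectory.frames:
        d = minimum_image(
            frame.positions[ib][None, :, :] - frame.positions[ia][:, None, :], frame.box
        )
        dist = np.linalg.norm(d, axis=2).ravel()
        hist, _ = np.histogram(dist, bins=edges)
        counts += hist
        rho_sum += len(group_b) / float(np.prod(frame.box))
    n_frames = trajectory.n_frames
    rho_b = rho_sum / n_frames
    norm = len(group_a) * rho_b * _shell_volumes(edges) * n_frames
    g = counts / norm
    return RDFResult(edges, g, rho_b, n_frames, len(group_a), counts)


def _smooth(g: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (window forced odd)."""
    window = max(1, int(window) | 1)
    kernel = np.ones(window)
    num = np.convolve(g, kernel, mode="same")
    den = np.convolve(np.ones_like(g), kernel, mode="same")
    return num / den


def _first_peak_index(rdf: RDFResult, smoothing_window: int) -> tuple[int, np.ndarray]:
    gs = _smooth(rdf.g, smoothing_window)
    noise = float(np.std(rdf.g - gs))
    threshold = 1.0 + 3.0 * noise
    interior = np.arange(1, len(gs) - 1)
    is_max = (gs[interior] >= gs[interior - 1]) & (gs[interior] > gs[interior + 1])
    candidates = interior[is_max & (gs[interior] > threshold)]
    if len(candidates) == 0:
        raise ValueError(
            "no structured first shell: no local maximum of smoothed g(r) exceeds "
            f"1 + 3 x bin noise ({threshold:.3f})"
        )
    return int(candidates[0]), gs


def first_peak(rdf: RDFResult, smoothing_window: int = 5) -> float:
    """Position (bin center, nm) of the first maximum of the smoothed g(r)."""
    idx, _ = _first_peak_index(rdf, smoothing_window)
    return float(rdf.bin_centers[idx])


def first_minimum(rdf: RDFResult, smoothing_window: int = 5) -> float:
    """Position (bin center, nm) of the first local minimum after the first peak.

    Extremum search runs on a moving-average-smoothed copy; the raw g is
    never modified.  This is the radius from which aggregate distance
    cutoffs are conventionally taken.
    """
    peak_idx, gs = _first_peak_index(rdf, smoothing_window)
    # first bin after the peak where the smoothed curve stops decreasing
    # (a flat depletion plateau counts from its start)
    for i in range(peak_idx + 1, len(gs) - 1):
        if gs[i] <= gs[i - 1] and gs[i] <= gs[i + 1]:
            return float(rdf.bin_centers[i])
    raise ValueError("no first minimum found after the first peak inside r_max")


def coordination_number(rdf: RDFResult, r_cut: float) -> float:
    """Running coordination number n(r_cut): mean partner count within r_cut.

    Uses exact per-bin shell volumes (equivalently, re-counts the binned
    pairs), with the partial final bin taken pro rata by shell volume.
    """
    if r_cut > rdf.r_max + 1e-12:
        raise ValueError(f"r_cut {r_cut} nm exceeds the histogram range {rdf.r_max} nm")
    edges = rdf.bin_edges
    vols = _shell_volumes(edges)
    full = edges[1:] <= r_cut + 1e-15
    n = float(np.sum(rdf.g[full] * vols[full]) * rdf.rho_b)
    partial = np.where(~full & (edges[:-1] < r_cut))[0]
    if len(partial):
        i = partial[0]
        v_part = 4.0 / 3.0 * np.pi * (r_cut**3 - edges[i] ** 3)
        n += float(rdf.g[i] * v_part * rdf.rho_b)
    return n


def shell_occupancy(trajectory: Trajectory, criterion: PairCriterion) -> OccupancyResult:
    """Fraction of frames in which the first shell is occupied at all.

    A frame counts as occupied when at least one group_b member lies within
    the cutoff of any group_a member.  ``mean_partner_count`` is the average
    number of bonded (a, b) pairs per frame — for rarely multiply-occupied
    shells it nearly equals the coordination number integrated to the same
    cutoff, but the two are distinct observables and both are reported.
    """
    a, b = criterion.group_a, criterion.group_b
    ia, ib = a.array, b.array
    occupied = 0
    pair_total = 0
    for frame in trajectory.frames:
        d = minimum_image(
            frame.positions[ib][None, :, :] - frame.positions[ia][:, None, :], frame.box
        )
        bonded = np.linalg.norm(d, axis=2) <= criterion.cutoff
        if bonded.any():
            occupied += 1
        pair_total += int(bonded.sum())
    n_frames = trajectory.n_frames
    return OccupancyResult(occupied / n_frames, pair_total / n_frames)


def region_density_ratio(trajectory: Trajectory, site_a, site_b,
                         species_group: SiteGroup, region_radius: float) -> DensityRatioReport:
    """Species density in a sphere between two sites, relative to bulk.

    The region is a sphere of ``region_radius`` centered on the midpoint of
    the minimum-image segment site_a -> site_b, re-evaluated every frame.
    Ratios above 1 mean the species is enriched between the sites (attracted
    to the inter-ionic region), below 1 depleted.
    """
    ia = site_a.indices[0] if isinstance(site_a, SiteGroup) else int(site_a)
    ib = site_b.indices[0] if isinstance(site_b, SiteGroup) else int(site_b)
    if isinstance(site_a, SiteGroup) and len(site_a) != 1:
        raise ValueError("site_a must be a single atom")
    if isinstance(site_b, SiteGroup) and len(site_b) != 1:
        raise ValueError("site_b must be a single atom")
    if region_radius <= 0:
        raise ValueError("region_radius must be positive")
    half_box = min(float(np.min(fr.box)) for fr in trajectory.frames) / 2.0
    if region_radius > half_box:
        raise ValueError(
            f"region radius {region_radius} nm extends beyond half the box ({half_box} nm)"
        )
    isp = species_group.array
    v_region = 4.0 / 3.0 * np.pi * region_radius**3
    inside_sum = 0.0
    bulk_sum = 0.0
    for frame in trajectory.frames:
        pa = frame.positions[ia]
        mid = pa + 0.5 * minimum_image(frame.positions[ib] - pa, frame.box)
        d = minimum_image(frame.positions[isp] - mid, frame.box)
        inside_sum += int(np.sum(np.linalg.norm(d, axis=1) <= region_radius))
        bulk_sum += len(species_group) / float(np.prod(frame.box))
    n_frames = trajectory.n_frames
    region_density = inside_sum / n_frames / v_region
    bulk_density = bulk_sum / n_frames
    ratio = region_density / bulk_density if bulk_density > 0 else float("nan")
    return DensityRatioReport(region_density, bulk_density, ratio)


def analyze_first_shell(rdf: RDFResult, smoothing_window: int = 5,
                        occupancy: float | None = None) -> ShellReport:
    """Bundle first-peak position, first minimum, and n(first minimum)."""
    r_peak = first_peak(rdf, smoothing_window)
    r_min = first_minimum(rdf, smoothing_window)
    coord = coordination_number(rdf, r_min)
    return ShellReport(r_peak, r_min, coord, occupancy)
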