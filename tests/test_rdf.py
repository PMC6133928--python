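"""g(r) normalization, first-shell analysis, occupancy and regional density."""

import numpy as np
import pytest

import saltdyn as sd
from saltdyn.rdf import RDFResult, analyze_first_shell, first_minimum, first_peak


def _gas_groups(n=1000, frames=20, box=(4.0, 4.0, 4.0), seed=33):
    spec = sd.ShellFluidSpec(n_particles=2 * n, box=box, n_frames=frames, seed=seed)
    traj = sd.gen_ideal_gas(spec)
    ga = sd.select_sites(traj, "a", list(range(n)))
    gb = sd.select_sites(traj, "b", list(range(n, 2 * n)))
    return traj, ga, gb


def _shell_setup(occupants=6, centers=4, bulk=0, frames=20, seed=34):
    n = centers + centers * occupants + bulk
    spec = sd.ShellFluidSpec(
        n_particles=n, box=(4.0, 4.0, 4.0), n_frames=frames,
        shell_center_count=centers, shell_radius=0.30, shell_occupants=occupants,
        seed=seed,
    )
    traj = sd.gen_shell_config(spec)
    cen = sd.select_sites(traj, "centers", "CEN")
    rest = sd.select_sites(
        traj, "partners", list(range(centers, n))
    )
    return traj, cen, rest


# ---------------------------------------------------------------------------
# compute_rdf


def test_ideal_gas_rdf_is_unity():
    traj, ga, gb = _gas_groups()
    rdf = sd.compute_rdf(traj, ga, gb, bin_width=0.01)
    mask = rdf.bin_centers >= 0.2
    rms = np.sqrt(np.mean((rdf.g[mask] - 1.0) ** 2))
    assert rms < 0.02


def test_shell_config_peak_bin_contains_shell_radius():
    traj, cen, rest = _shell_setup()
    rdf = sd.compute_rdf(traj, cen, rest, bin_width=0.01)
    peak_bin = int(np.argmax(rdf.g))
    # radial jitter is +-0.005 nm, so the tallest bin sits within one bin of 0.30
    assert abs(rdf.bin_centers[peak_bin] - 0.30) <= 0.01


def test_rdf_rejects_overlapping_groups(two_frame_traj):
    a = sd.select_sites(two_frame_traj, "a", [0, 1])
    b = sd.select_sites(two_frame_traj, "b", [1, 2])
    with pytest.raises(ValueError, match="disjoint"):
        sd.compute_rdf(two_frame_traj, a, b)


def test_rdf_rejects_r_max_beyond_half_box(two_frame_traj):
    a = sd.select_sites(two_frame_traj, "a", [0])
    b = sd.select_sites(two_frame_traj, "b", [1])
    with pytest.raises(ValueError, match="half the smallest box edge"):
        sd.compute_rdf(two_frame_traj, a, b, r_max=2.5)


def test_rdf_symmetric_under_group_swap():
    traj, ga, gb = _gas_groups(n=200, frames=3)
    ab = sd.compute_rdf(traj, ga, gb, bin_width=0.02)
    ba = sd.compute_rdf(traj, gb, ga, bin_width=0.02)
    np.testing.assert_allclose(ab.g, ba.g, atol=1e-9)


def test_rdf_count_bookkeeping_identity():
    """Sum of binned counts is exactly recovered from the normalized g."""
    traj, ga, gb = _gas_groups(n=150, frames=4)
    rdf = sd.compute_rdf(traj, ga, gb, bin_width=0.02)
    vols = 4.0 / 3.0 * np.pi * np.diff(rdf.bin_edges**3)
    reconstructed = rdf.g * len(ga) * rdf.rho_b * vols * rdf.n_frames
    np.testing.assert_allclose(reconstructed.sum(), rdf.counts.sum(), rtol=1e-9)


# ---------------------------------------------------------------------------
# coordination number


def test_shell_coordination_number_exact():
    traj, cen, rest = _shell_setup(bulk=0)
    rdf = sd.compute_rdf(traj, cen, rest, bin_width=0.002)
    assert sd.coordination_number(rdf, 0.35) == pytest.approx(6.0, rel=0.01)


def test_ideal_gas_coordination_closed_form():
    traj, ga, gb = _gas_groups(n=800, frames=10)
    rdf = sd.compute_rdf(traj, ga, gb, bin_width=0.01)
    for r_cut in (0.5, 1.0, 1.5):
        expected = rdf.rho_b * 4.0 / 3.0 * np.pi * r_cut**3
        assert sd.coordination_number(rdf, r_cut) == pytest.approx(expected, rel=0.02)


def test_coordination_zero_below_first_occupied_bin():
    traj, cen, rest = _shell_setup()
    rdf = sd.compute_rdf(traj, cen, rest, bin_width=0.002)
    assert sd.coordination_number(rdf, 0.1) == 0.0


def test_coordination_stable_under_bin_doubling():
    traj, cen, rest = _shell_setup(bulk=100)
    fine = sd.compute_rdf(traj, cen, rest, bin_width=0.005)
    coarse = sd.compute_rdf(traj, cen, rest, bin_width=0.01)
    n_fine = sd.coordination_number(fine, 0.4)
    n_coarse = sd.coordination_number(coarse, 0.4)
    assert n_coarse == pytest.approx(n_fine, rel=0.02)


# ---------------------------------------------------------------------------
# first peak / first minimum


def _synthetic_rdf(bin_width=0.005, r_max=2.0, peak=0.30, dip=0.40):
    edges = np.arange(0, r_max + bin_width, bin_width)
    r = 0.5 * (edges[:-1] + edges[1:])
    g = (
        1.0
        + 2.0 * np.exp(-((r - peak) ** 2) / (2 * 0.02**2))
        - 0.8 * np.exp(-((r - dip) ** 2) / (2 * 0.02**2))
    )
    g[r < 0.2] = 0.0
    return RDFResult(edges, np.clip(g, 0, None), 10.0, 1, 1, np.zeros(len(r)))


def test_first_extrema_on_constructed_curve():
    rdf = _synthetic_rdf()
    assert first_peak(rdf) == pytest.approx(0.30, abs=0.005)
    assert first_minimum(rdf) == pytest.approx(0.40, abs=0.005)


def test_first_minimum_requires_structured_shell():
    edges = np.arange(0, 2.0, 0.005)
    r = 0.5 * (edges[:-1] + edges[1:])
    g = np.clip((r - 0.2) / 0.3, 0, 1.0)  # monotone rise to 1: pure repulsion
    rdf = RDFResult(edges, g, 10.0, 1, 1, np.zeros(len(r)))
    with pytest.raises(ValueError, match="no structured first shell"):
        first_minimum(rdf)


def test_first_minimum_of_shell_config_in_expected_window():
    traj, cen, rest = _shell_setup(bulk=300)
    rdf = sd.compute_rdf(traj, cen, rest, bin_width=0.01)
    r_min = first_minimum(rdf)
    assert 0.30 < r_min < 0.45


def test_analyze_first_shell_report():
    traj, cen, rest = _shell_setup(bulk=300)
    rdf = sd.compute_rdf(traj, cen, rest, bin_width=0.01)
    report = analyze_first_shell(rdf, occupancy=1.0)
    assert report.r_first_peak < report.r_first_min
    assert report.coordination_number == pytest.approx(6.0, rel=0.05)


# ---------------------------------------------------------------------------
# shell occupancy


def test_occupancy_matches_markov_stationary_probability():
    spec = sd.TwoStateKineticsSpec(
        n_pairs=1, k_on=0.01, k_off=0.04, dt=0.1, n_steps=100000, seed=35
    )
    ind = sd.gen_two_state_bonds(spec)
    traj = sd.embed_bonds_as_trajectory(ind, 0.3, (4.0, 4.0, 4.0))
    crit = sd.PairCriterion(
        sd.select_sites(traj, "a", [0]), sd.select_sites(traj, "b", [1]), 0.3
    )
    occ = sd.shell_occupancy(traj, crit)
    # frame counting reproduces the generator indicator occupancy exactly ...
    assert occ.fraction == pytest.approx(float(ind.indicator.mean()), abs=1e-12)
    # ... which converges on p_eq (single chain: ~500 independent samples)
    assert occ.fraction == pytest.approx(0.2, abs=3 * 0.018)


@pytest.mark.parametrize("fill,expected", [("ones", 1.0), ("zeros", 0.0)])
def test_occupancy_extremes(fill, expected):
    mat = np.ones((3, 50), bool) if fill == "ones" else np.zeros((3, 50), bool)
    ind = sd.IndicatorSeries(mat, 0.1, [(2 * k, 2 * k + 1) for k in range(3)])
    traj = sd.embed_bonds_as_trajectory(ind, 0.3, (6.0, 6.0, 6.0))
    crit = sd.PairCriterion(
        sd.select_sites(traj, "a", [0]), sd.select_sites(traj, "b", [1]), 0.3
    )
    assert sd.shell_occupancy(traj, crit).fraction == expected


# ---------------------------------------------------------------------------
# region density ratio


def _two_anchor_trajectory(species_positions, box=(4.0, 4.0, 4.0)):
    """Anchors at fixed points; species positions given per frame."""
    a = np.array([1.0, 2.0, 2.0])
    b = np.array([2.0, 2.0, 2.0])
    frames = [
        sd.Frame(np.vstack([a, b, pos]), box, time=float(t))
        for t, pos in enumerate(species_positions)
    ]
    labels = ["SA", "SB"] + ["X"] * species_positions[0].shape[0]
    return sd.Trajectory(frames, labels)


def test_density_ratio_uniform_species_is_unity(rng):
    positions = rng.random((40, 400, 3)) * 4.0
    traj = _two_anchor_trajectory(list(positions))
    sa = sd.select_sites(traj, "sa", [0])
    sb = sd.select_sites(traj, "sb", [1])
    species = sd.select_sites(traj, "x", list(range(2, 402)))
    report = sd.region_density_ratio(traj, sa, sb, species, region_radius=0.8)
    assert report.ratio == pytest.approx(1.0, abs=0.05)


def test_density_ratio_pinned_species():
    midpoint = np.array([[1.5, 2.0, 2.0]])
    traj = _two_anchor_trajectory([midpoint] * 5)
    sa = sd.select_sites(traj, "sa", [0])
    sb = sd.select_sites(traj, "sb", [1])
    species = sd.select_sites(traj, "x", [2])
    radius = 0.5
    report = sd.region_density_ratio(traj, sa, sb, species, radius)
    v_box, v_region = 64.0, 4.0 / 3.0 * np.pi * radius**3
    assert report.ratio == pytest.approx(v_box / v_region, rel=1e-9)


def test_density_ratio_excluded_species_is_zero():
    far = np.array([[3.9, 0.1, 0.1]])
    traj = _two_anchor_trajectory([far] * 5)
    sa = sd.select_sites(traj, "sa", [0])
    sb = sd.select_sites(traj, "sb", [1])
    species = sd.select_sites(traj, "x", [2])
    report = sd.region_density_ratio(traj, sa, sb, species, 0.4)
    assert report.ratio == 0.0


def test_density_ratio_region_beyond_half_box_rejected():
    traj = _two_anchor_trajectory([np.array([[1.0, 1.0, 1.0]])] * 2)
    sa = sd.select_sites(traj, "sa", [0])
    sb = sd.select_sites(traj, "sb", [1])
    species = sd.select_sites(traj, "x", [2])
    with pytest.raises(ValueError, match="half the box"):
        sd.region_density_ratio(traj, sa, sb, species, 2.5)
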