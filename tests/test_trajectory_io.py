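"""Format readers/writers, periodic geometry and site selection."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import saltdyn as sd
from saltdyn.trajectory_io import FormatError

NM = 1e-9  # noqa: F841 - all lengths below are nm


# ---------------------------------------------------------------------------
# XYZ


def test_read_xyz_two_frames(tmp_path):
    path = tmp_path / "t.xyz"
    path.write_text(
        "3\n"
        "time=0.0 box=4 4 4\n"
        "OW 0.1 0.2 0.3\nHW 0.4 0.5 0.6\nLI 0.7 0.8 0.9\n"
        "3\n"
        "time=0.5 box=4 4 4\n"
        "OW 0.1 0.2 0.3\nHW 0.4 0.5 0.6\nLI 0.7 0.8 0.9\n"
    )
    traj = sd.read_xyz(path)
    assert traj.n_frames == 2
    assert traj.dt == pytest.approx(0.5)
    assert traj.atom_labels == ["OW", "HW", "LI"]
    assert np.allclose(traj.frames[0].box, 4.0)
    assert traj.frames[0].positions[1, 2] == pytest.approx(0.6)


def test_read_xyz_bare_box_comment(tmp_path):
    path = tmp_path / "t.xyz"
    path.write_text("1\n4.0 4.0 4.0\nX 1 1 1\n")
    traj = sd.read_xyz(path)
    assert np.allclose(traj.frames[0].box, 4.0)


def test_read_xyz_inconsistent_atom_count(tmp_path):
    path = tmp_path / "t.xyz"
    path.write_text(
        "3\nbox=4 4 4\nA 0 0 0\nB 1 1 1\nC 2 2 2\n"
        "2\nbox=4 4 4\nA 0 0 0\nB 1 1 1\n"
    )
    with pytest.raises(FormatError, match="frame 1"):
        sd.read_xyz(path)


def test_read_xyz_missing_box_mentions_convention(tmp_path):
    path = tmp_path / "t.xyz"
    path.write_text("1\njust a comment\nX 1 1 1\n")
    with pytest.raises(FormatError, match="box"):
        sd.read_xyz(path)


def test_read_xyz_malformed_count_names_line(tmp_path):
    path = tmp_path / "t.xyz"
    path.write_text("nonsense\nbox=4 4 4\nX 1 1 1\n")
    with pytest.raises(FormatError, match="line 1"):
        sd.read_xyz(path)


def test_xyz_roundtrip_ideal_gas(tmp_path):
    spec = sd.ShellFluidSpec(n_particles=30, box=(3, 4, 5), n_frames=3, seed=7)
    traj = sd.gen_ideal_gas(spec)
    path = tmp_path / "gas.xyz"
    sd.write_xyz(traj, path)
    back = sd.read_xyz(path)
    assert back.n_frames == traj.n_frames
    np.testing.assert_allclose(back.positions, traj.positions, atol=1e-6)
    np.testing.assert_allclose(back.frames[0].box, traj.frames[0].box)


def test_xyz_gzip_roundtrip(tmp_path, two_frame_traj):
    path = tmp_path / "t.xyz.gz"
    sd.write_xyz(two_frame_traj, path)
    with gzip.open(path, "rt") as fh:
        assert fh.readline().strip() == "3"
    back = sd.read_xyz(path)
    np.testing.assert_allclose(back.positions, two_frame_traj.positions, atol=1e-6)


# ---------------------------------------------------------------------------
# GRO


GRO_ONE_FRAME = (
    "one frame t= 0.00000\n"
    "3\n"
    "    1SOL     OW    1   0.100   0.200   0.300\n"
    "    1SOL    HW1    2   0.400   0.500   0.600\n"
    "    2LI      LI    3   0.700   0.800   0.900\n"
    "   4.00000   4.00000   4.00000\n"
)


def test_read_gro_single_frame(tmp_path):
    path = tmp_path / "t.gro"
    path.write_text(GRO_ONE_FRAME)
    traj = sd.read_gro(path)
    assert traj.n_frames == 1
    assert np.allclose(traj.frames[0].box, (4.0, 4.0, 4.0))
    assert traj.atom_labels == ["OW", "HW1", "LI"]
    assert traj.atom_resnames == ["SOL", "SOL", "LI"]
    assert traj.frames[0].positions[2, 0] == pytest.approx(0.7)


def test_gro_roundtrip_within_format_precision(tmp_path, two_frame_traj):
    path = tmp_path / "t.gro"
    sd.write_gro(two_frame_traj, path)
    back = sd.read_gro(path)
    assert back.n_frames == 2
    np.testing.assert_allclose(back.positions, two_frame_traj.positions, atol=1e-3)


def test_read_gro_missing_box_line(tmp_path):
    path = tmp_path / "t.gro"
    path.write_text("title\n2\n    1SOL     OW    1   0.1   0.2   0.3\n")
    with pytest.raises(FormatError, match="frame 0"):
        sd.read_gro(path)


def test_read_gro_rejects_triclinic(tmp_path):
    path = tmp_path / "t.gro"
    path.write_text(
        "title\n1\n    1SOL     OW    1   0.100   0.200   0.300\n"
        "   4.0   4.0   4.0   0.0   0.0   1.0   0.0   0.0   0.0\n"
    )
    with pytest.raises(FormatError, match="triclinic"):
        sd.read_gro(path)


def test_gro_reader_agrees_with_mdtraj(tmp_path, two_frame_traj):
    """Independent cross-check of the GRO reader against mdtraj."""
    mdtraj = pytest.importorskip("mdtraj")
    path = tmp_path / "t.gro"
    sd.write_gro(two_frame_traj, path)
    ours = sd.read_gro(path)
    ref = mdtraj.load(str(path))
    np.testing.assert_allclose(ours.positions, ref.xyz, atol=1e-3)
    np.testing.assert_allclose(
        ours.frames[0].box, ref.unitcell_lengths[0], atol=1e-4
    )


# ---------------------------------------------------------------------------
# xvg


def test_read_xvg_basic(tmp_path):
    path = tmp_path / "t.xvg"
    path.write_text("0 1.0\n1 2.0\n2 3.0\n")
    ts = sd.read_xvg_series(path)
    np.testing.assert_allclose(ts.times, [0, 1, 2])
    np.testing.assert_allclose(ts.values[:, 0], [1, 2, 3])


def test_read_xvg_skips_headers_and_reads_legends(tmp_path):
    path = tmp_path / "t.xvg"
    path.write_text(
        '@ title "pull"\n# a comment\n@ s0 legend "x"\n@ s1 legend "force"\n'
        "0 0.4 12.0\n1 0.41 11.0\n"
    )
    ts = sd.read_xvg_series(path)
    assert ts.names == ["x", "force"]
    assert ts.column("force")[1] == pytest.approx(11.0)


def test_read_xvg_nonnumeric_names_line(tmp_path):
    path = tmp_path / "t.xvg"
    path.write_text("0 1.0\n1 oops\n")
    with pytest.raises(FormatError, match="line 2"):
        sd.read_xvg_series(path)


def test_xvg_roundtrip_of_pull_output(tmp_path):
    pmf = sd.make_pmf("flat")
    spec = sd.UmbrellaPullSpec(
        pmf=pmf, k_spring=100.0, pull_speed=0.001, x_start=0.5,
        friction=10.0, temperature=296.0, dt=0.01, n_steps=200, seed=3,
    )
    series = sd.gen_umbrella_pull(spec)
    path = tmp_path / "pull.xvg"
    sd.write_xvg(series, path)
    back = sd.read_xvg_series(path)
    assert back.names == ["x", "force"]
    np.testing.assert_allclose(back.times, series.times, rtol=1e-9)
    np.testing.assert_allclose(back.values, series.values, rtol=1e-9)


# ---------------------------------------------------------------------------
# periodic geometry


def test_minimum_image_wrap_case(cubic_frame):
    assert sd.minimum_image_distance(cubic_frame, 0, 1) == pytest.approx(0.2)


def test_minimum_image_full_box_translation(cubic_frame):
    frame = sd.Frame(
        np.vstack([cubic_frame.positions, cubic_frame.positions[0] + [4.0, 8.0, -4.0]]),
        cubic_frame.box,
    )
    assert sd.minimum_image_distance(frame, 0, 3) == pytest.approx(0.0, abs=1e-12)


def test_minimum_image_self_distance_rejected(cubic_frame):
    with pytest.raises(ValueError):
        sd.minimum_image_distance(cubic_frame, 1, 1)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_minimum_image_matches_27_image_enumeration(seed):
    """Oracle: brute force over all 27 periodic image translations."""
    rng = np.random.default_rng(seed)
    box = rng.uniform(2.0, 6.0, 3)
    pos = rng.uniform(-1.0, 1.0, (2, 3)) * box * 2
    frame = sd.Frame(pos, box)
    d = sd.minimum_image_distance(frame, 0, 1)
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    delta = pos[1] - pos[0]
    delta -= box * np.round(delta / box)  # bring within one cell first
    brute = np.min(np.linalg.norm(delta + shifts * box, axis=1))
    assert d == pytest.approx(brute, abs=1e-12)
    # symmetry and translation invariance
    assert sd.minimum_image_distance(frame, 1, 0) == pytest.approx(d, abs=1e-12)
    shifted = sd.Frame(pos + box * rng.integers(-3, 4, 3), box)
    assert sd.minimum_image_distance(shifted, 0, 1) == pytest.approx(d, abs=1e-9)


def test_wrapped_coordinates_in_box(rng):
    pos = rng.uniform(-10, 10, (20, 3))
    frame = sd.Frame(pos, (4.0, 5.0, 6.0))
    w = frame.wrapped()
    assert np.all(w >= 0) and np.all(w < frame.box)


# ---------------------------------------------------------------------------
# site selection and invariants


def test_select_sites_pattern(two_frame_traj):
    group = sd.select_sites(two_frame_traj, "cation", "LI")
    assert group.indices == (2,)


def test_select_sites_explicit_list(two_frame_traj):
    group = sd.select_sites(two_frame_traj, "pair", [2, 0])
    assert group.indices == (0, 2)  # ascending order


def test_select_sites_duplicate_rejected(two_frame_traj):
    with pytest.raises(ValueError, match="duplicate"):
        sd.select_sites(two_frame_traj, "bad", [0, 0])


def test_select_sites_no_match_names_role(two_frame_traj):
    with pytest.raises(ValueError, match="anion"):
        sd.select_sites(two_frame_traj, "anion", "CL")


def test_trajectory_rejects_varying_atom_count(cubic_frame):
    bad = sd.Frame(cubic_frame.positions[:2], cubic_frame.box, time=1.0)
    with pytest.raises(FormatError):
        sd.Trajectory([cubic_frame, bad], ["A", "B", "C"])


def test_trajectory_rejects_nonuniform_dt(cubic_frame):
    frames = [
        sd.Frame(cubic_frame.positions, cubic_frame.box, time=t) for t in (0.0, 1.0, 2.5)
    ]
    with pytest.raises(ValueError, match="uniform"):
        sd.Trajectory(frames, ["A", "B", "C"])
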