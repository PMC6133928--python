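"""Trajectory containers, periodic-box geometry and plain-text trajectory formats.

The package works in MD-engine units throughout: lengths in nm, times in ps,
forces in kJ mol^-1 nm^-1.  Only orthorhombic periodic boxes are supported;
triclinic input is rejected.  Frames are stored as read — coordinates are not
wrapped, so intramolecular vectors stay continuous; wrapping is applied lazily
inside distance computations via the minimum-image convention.

Supported formats (all readers transparently accept gzip-compressed input):

* extended XYZ with the box carried on the comment line, e.g.
  ``time=0.5 box=4.0 4.0 4.0`` (coordinates in nm);
* GRO, single- and multi-frame, fixed-column records with a trailing box line;
* xvg-style whitespace-separated numeric columns with ``#``/``@`` comments.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from fnmatch import fnmatchcase
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "FormatError",
    "Frame",
    "Trajectory",
    "SiteGroup",
    "TimeSeries",
    "minimum_image",
    "minimum_image_displacement",
    "minimum_image_distance",
    "select_sites",
    "resolve_roles",
    "read_xyz",
    "write_xyz",
    "read_gro",
    "write_gro",
    "read_xvg_series",
    "write_xvg",
]


class FormatError(ValueError):
    """Raised when a trajectory or time-series file violates its format."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class Frame:
    """One trajectory frame: positions (nm), orthorhombic box edges (nm), time (ps)."""

    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.box = np.asarray(self.box, dtype=float).reshape(-1)
        if self.box.shape != (3,):
            raise FormatError(
                f"expected 3 orthorhombic box edge lengths, got shape {self.box.shape}; "
                "triclinic boxes are not supported"
            )
        if not np.all(self.box > 0):
            raise ValueError(f"box edges must be positive, got {self.box}")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (n_atoms, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def wrapped(self) -> np.ndarray:
        """Positions wrapped into [0, box_edge) along every axis."""
        return self.positions - self.box * np.floor(self.positions / self.box)


@dataclass
class Trajectory:
    """Ordered frames with a uniform time step and per-atom labels."""

    frames: list[Frame]
    atom_labels: list[str]
    atom_resnames: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.frames[0].n_atoms
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise FormatError(
                    f"frame {k} has {fr.n_atoms} atoms but frame 0 has {n}"
                )
        if len(self.atom_labels) != n:
            raise ValueError(
                f"{len(self.atom_labels)} atom labels for {n} atoms"
            )
        times = np.array([fr.time for fr in self.frames])
        if len(times) >= 3:
            steps = np.diff(times)
            ref = steps[0]
            if ref != 0 and np.any(np.abs(steps - ref) > 1e-9 * max(abs(ref), 1.0)):
                raise ValueError("frame spacing is not uniform")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def dt(self) -> float:
        """Frame spacing in ps (0.0 for a single-frame trajectory)."""
        if len(self.frames) < 2:
            return 0.0
        return self.frames[1].time - self.frames[0].time

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def positions(self) -> np.ndarray:
        """All coordinates as an (n_frames, n_atoms, 3) array."""
        return np.stack([fr.positions for fr in self.frames])


@dataclass(frozen=True)
class SiteGroup:
    """A named set of atom indices playing one chemical role (0-based)."""

    name: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(set(idx)) != len(idx):
            raise ValueError(f"site group {self.name!r} contains duplicate indices")
        if idx and min(idx) < 0:
            raise ValueError(f"site group {self.name!r} contains negative indices")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)


@dataclass
class TimeSeries:
    """Strictly increasing times (ps) with one or more named value columns."""

    times: np.ndarray
    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times and values disagree in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.names:
            self.names = [f"col{i + 1}" for i in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("one name per value column required")

    def column(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.names.index(name)]
        except ValueError:
            raise KeyError(f"no column {name!r}; have {self.names}") from None


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map displacement vector(s) onto their minimum periodic image.

    Works on any array whose last axis is the 3 Cartesian components.
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_displacement(frame: Frame, i: int, j: int) -> np.ndarray:
    """Minimum-image displacement from atom i to atom j (nm)."""
    if i == j:
        raise ValueError(f"distance of atom {i} to itself requested")
    return minimum_image(frame.positions[j] - frame.positions[i], frame.box)


def minimum_image_distance(frame: Frame, i: int, j: int) -> float:
    """Minimum-image distance between atoms i and j (nm)."""
    return float(np.linalg.norm(minimum_image_displacement(frame, i, j)))


# ---------------------------------------------------------------------------
# site selection

Selector = Union[str, Sequence[int]]


def select_sites(trajectory: Trajectory, name: str, selector: Selector) -> SiteGroup:
    """Resolve a role to a :class:`SiteGroup`.

    ``selector`` is either a glob-style label pattern matched against
    ``atom_labels`` (``"LI"``, ``"OW*"``) or an explicit 0-based index list.
    Matching indices are returned in ascending order.
    """
    n = trajectory.n_atoms
    if isinstance(selector, str):
        idx = [i for i, lab in enumerate(trajectory.atom_labels) if fnmatchcase(lab, selector)]
        if not idx:
            raise ValueError(
                f"role {name!r}: pattern {selector!r} matches no atom labels"
            )
    else:
        idx = [int(i) for i in selector]
        if len(set(idx)) != len(idx):
            raise ValueError(f"role {name!r}: explicit index list contains duplicates")
        bad = [i for i in idx if not 0 <= i < n]
        if bad:
            raise ValueError(f"role {name!r}: indices {bad} outside 0..{n - 1}")
        idx = sorted(idx)
    return SiteGroup(name, tuple(idx))


def resolve_roles(trajectory: Trajectory, role_spec: Mapping[str, Selector]) -> dict[str, SiteGroup]:
    """Resolve every role in a mapping of role name -> pattern or index list."""
    return {name: select_sites(trajectory, name, sel) for name, sel in role_spec.items()}


# ---------------------------------------------------------------------------
# extended XYZ

_BOX_RE = re.compile(
    r"box\s*=?\s*\"?([-+0-9.eE]+)[\s,]+([-+0-9.eE]+)[\s,]+([-+0-9.eE]+)"
)
_TIME_RE = re.compile(r"\b(?:time|t)\s*=\s*([-+0-9.eE]+)")

_XYZ_BOX_HINT = (
    "the comment line must carry the orthorhombic box as three edge lengths in "
    'nm, e.g. time=0.0 box=4.0 4.0 4.0 (or a bare "a b c" comment)'
)


def _parse_xyz_comment(comment: str, frame_index: int) -> tuple[np.ndarray, float]:
    m = _BOX_RE.search(comment)
    if m:
        box = np.array([float(g) for g in m.groups()])
    else:
        parts = comment.split()
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            vals = []
        if len(vals) == 3:
            box = np.array(vals)
        else:
            raise FormatError(
                f"frame {frame_index}: no box found on XYZ comment line; {_XYZ_BOX_HINT}"
            )
    tm = _TIME_RE.search(comment)
    time = float(tm.group(1)) if tm else float(frame_index)
    return box, time


def read_xyz(path) -> Trajectory:
    """Read an extended-XYZ trajectory (coordinates in nm, box on the comment line)."""
    frames: list[Frame] = []
    labels: list[str] = []
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    ln = 0
    frame_index = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n_atoms = int(lines[ln].strip())
        except ValueError:
            raise FormatError(
                f"line {ln + 1}: expected an atom count, got {lines[ln]!r}"
            ) from None
        if ln + 1 >= len(lines):
            raise FormatError(f"frame {frame_index}: truncated after atom count")
        box, time = _parse_xyz_comment(lines[ln + 1], frame_index)
        body = lines[ln + 2 : ln + 2 + n_atoms]
        if len(body) < n_atoms:
            raise FormatError(
                f"frame {frame_index}: expected {n_atoms} atom lines, file ends after "
                f"{len(body)} (line {ln + 2 + len(body)})"
            )
        pos = np.empty((n_atoms, 3))
        frame_labels: list[str] = []
        for k, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"line {ln + 3 + k}: malformed atom record {line!r}")
            frame_labels.append(parts[0])
            try:
                pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise FormatError(
                    f"line {ln + 3 + k}: non-numeric coordinate in {line!r}"
                ) from None
        if frame_index == 0:
            labels = frame_labels
        elif len(frame_labels) != len(labels):
            raise FormatError(
                f"frame {frame_index} has {len(frame_labels)} atoms but frame 0 had {len(labels)}"
            )
        frames.append(Frame(pos, box, time))
        ln += 2 + n_atoms
        frame_index += 1
    if not frames:
        raise FormatError(f"no frames found in {path}")
    return Trajectory(frames, labels)


def write_xyz(trajectory: Trajectory, path) -> None:
    """Write the extended-XYZ dialect read by :func:`read_xyz` (nm, %.9f)."""
    with _open_text(path, "wt") as fh:
        for fr in trajectory.frames:
            fh.write(f"{fr.n_atoms}\n")
            bx, by, bz = fr.box
            fh.write(f"time={fr.time:.9f} box={bx:.9f} {by:.9f} {bz:.9f}\n")
            for lab, p in zip(trajectory.atom_labels, fr.positions):
                fh.write(f"{lab} {p[0]:.9f} {p[1]:.9f} {p[2]:.9f}\n")


# ---------------------------------------------------------------------------
# GRO


def _parse_gro_frame(lines: list[str], ln: int, frame_index: int):
    if ln + 1 >= len(lines):
        raise FormatError(f"frame {frame_index}: truncated file (missing atom count)")
    title = lines[ln]
    try:
        n_atoms = int(lines[ln + 1].strip())
    except ValueError:
        raise FormatError(
            f"frame {frame_index}: expected atom count on line {ln + 2}, got {lines[ln + 1]!r}"
        ) from None
    end = ln + 2 + n_atoms
    if end >= len(lines):
        raise FormatError(
            f"frame {frame_index}: truncated file (need {n_atoms} atom lines plus a box line)"
        )
    pos = np.empty((n_atoms, 3))
    labels, resnames = [], []
    for k in range(n_atoms):
        line = lines[ln + 2 + k]
        try:
            resnames.append(line[5:10].strip())
            labels.append(line[10:15].strip())
            pos[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except (ValueError, IndexError):
            raise FormatError(
                f"frame {frame_index}: malformed GRO atom record on line {ln + 3 + k}: {line!r}"
            ) from None
    box_parts = lines[end].split()
    try:
        box_vals = [float(v) for v in box_parts]
    except ValueError:
        box_vals = []
    if len(box_vals) < 3:
        raise FormatError(
            f"frame {frame_index}: missing or malformed box line on line {end + 1}"
        )
    if len(box_vals) > 3 and any(abs(v) > 1e-12 for v in box_vals[3:]):
        raise FormatError(
            f"frame {frame_index}: triclinic box detected; only orthorhombic boxes are supported"
        )
    tm = _TIME_RE.search(title)
    time = float(tm.group(1)) if tm else float(frame_index)
    return Frame(pos, np.array(box_vals[:3]), time), labels, resnames, end + 1


def read_gro(path) -> Trajectory:
    """Read a single- or multi-frame GRO file (fixed columns, nm)."""
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    labels: list[str] = []
    resnames: list[str] = []
    ln, frame_index = 0, 0
    while ln < len(lines):
        if not lines[ln].strip() and ln == len(lines) - 1:
            break
        frame, frame_labels, frame_res, ln = _parse_gro_frame(lines, ln, frame_index)
        if frame_index == 0:
            labels, resnames = frame_labels, frame_res
        frames.append(frame)
        frame_index += 1
        while ln < len(lines) and not lines[ln].strip():
            ln += 1
    if not frames:
        raise FormatError(f"no frames found in {path}")
    return Trajectory(frames, labels, resnames)


def write_gro(trajectory: Trajectory, path, title: str = "saltdyn") -> None:
    """Write GRO frames (%8.3f coordinates; residue numbering kept 1-based)."""
    res = trajectory.atom_resnames or ["MOL"] * trajectory.n_atoms
    with _open_text(path, "wt") as fh:
        for fr in trajectory.frames:
            fh.write(f"{title} t= {fr.time:.5f}\n{fr.n_atoms}\n")
            for i, (lab, rn, p) in enumerate(zip(trajectory.atom_labels, res, fr.positions)):
                resid = (i % 99999) + 1
                atnum = (i % 99999) + 1
                fh.write(
                    f"{resid:5d}{rn:<5.5s}{lab:>5.5s}{atnum:5d}"
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}\n"
                )
            bx, by, bz = fr.box
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# xvg-style series

_LEGEND_RE = re.compile(r"@\s*s(\d+)\s+legend\s+\"([^\"]*)\"")


def read_xvg_series(path) -> TimeSeries:
    """Read an xvg-style table: first column times, the rest named value columns.

    Lines starting with ``#`` or ``@`` are comments; ``@ sN legend "..."``
    headers, when present, name the value columns.
    """
    times, rows = [], []
    legends: dict[int, str] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(("#", "@")):
                m = _LEGEND_RE.match(line)
                if m:
                    legends[int(m.group(1))] = m.group(2)
                continue
            parts = line.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-numeric data row {line!r}"
                ) from None
            if len(vals) < 2:
                raise FormatError(f"line {lineno}: need at least two columns, got {line!r}")
            times.append(vals[0])
            rows.append(vals[1:])
    if not rows:
        raise FormatError(f"no data rows found in {path}")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"ragged columns in {path}")
    names = [legends.get(i, f"col{i + 1}") for i in range(width)]
    return TimeSeries(np.array(times), np.array(rows), names)


def write_xvg(series: TimeSeries, path, comment: str = "") -> None:
    with _open_text(path, "wt") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for i, name in enumerate(series.names):
            fh.write(f'@ s{i} legend "{name}"\n')
        for t, row in zip(series.times, series.values):
            cols = " ".join(f"{v:.10g}" for v in row)
            fh.write(f"{t:.10g} {cols}\n")
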