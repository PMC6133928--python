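"""Seeded synthetic inputs with known ground truth for every analysis stage.

Each generator emulates the statistical structure of one observable of an
ionic-solution MD trajectory, with closed-form expectations that the
downstream estimators must recover:

* rotor ensembles under isotropic rotational diffusion — C1(t) = exp(-2 D t),
  optionally a slow sub-population (mixture of exponentials);
* two-state Markov bond processes with Poissonian formation/breakage —
  occupancy k_on/(k_on+k_off), relaxation time 1/(k_on+k_off);
* homogeneous (ideal-gas) and shell-structured particle configurations in
  periodic orthorhombic boxes — g(r) = 1, respectively an exact first-shell
  coordination number;
* an overdamped particle dragged by a moving harmonic restraint across an
  analytic potential of mean force — quasi-static mean restraint force
  equal to the pmf gradient.

Every generator is a pure function of its spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOLTZMANN_KJ_MOL
from .reorientation import VectorSeries
from .aggregates import IndicatorSeries
from .trajectory_io import Frame, TimeSeries, Trajectory

__all__ = [
    "RotorEnsembleSpec",
    "TwoStateKineticsSpec",
    "ShellFluidSpec",
    "UmbrellaPullSpec",
    "AnalyticPMF",
    "make_pmf",
    "gen_rotor_ensemble",
    "gen_two_state_bonds",
    "embed_bonds_as_trajectory",
    "embed_vectors_as_trajectory",
    "gen_ideal_gas",
    "gen_shell_config",
    "gen_umbrella_pull",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class RotorEnsembleSpec:
    """Ensemble of unit vectors under isotropic rotational diffusion.

    d_rot is the rotational diffusion constant in ps^-1; a ``slow_fraction``
    of the rotors diffuses with ``d_rot_slow`` instead, emulating the
    ion-slowed water sub-population.
    """

    n_rotors: int
    d_rot: float
    dt: float
    n_steps: int
    slow_fraction: float = 0.0
    d_rot_slow: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_rot < 0:
            raise ValueError("d_rot must be non-negative")
        if not 0.0 <= self.slow_fraction <= 1.0:
            raise ValueError("slow_fraction must lie in [0, 1]")
        if self.slow_fraction > 0 and self.d_rot_slow < 0:
            raise ValueError("d_rot_slow must be non-negative when slow_fraction > 0")
        if self.dt <= 0 or self.n_steps < 1 or self.n_rotors < 1:
            raise ValueError("dt, n_steps, n_rotors must be positive")


@dataclass(frozen=True)
class TwoStateKineticsSpec:
    """Independent bonded/unbonded Markov chains with rates k_on, k_off (ps^-1)."""

    n_pairs: int
    k_on: float
    k_off: float
    dt: float
    n_steps: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("k_on and k_off must be positive")
        if self.k_off * self.dt >= 0.1:
            raise ValueError(
                f"k_off*dt = {self.k_off * self.dt:.3g} >= 0.1: time step too coarse "
                "for the discretized kinetics"
            )
        if self.dt <= 0 or self.n_steps < 1 or self.n_pairs < 1:
            raise ValueError("dt, n_steps, n_pairs must be positive")

    @property
    def p_eq(self) -> float:
        """Stationary bonded probability k_on / (k_on + k_off)."""
        return self.k_on / (self.k_on + self.k_off)


@dataclass(frozen=True)
class ShellFluidSpec:
    """Particles in a periodic box, optionally with tight first shells.

    ``shell_center_count`` designated centers each receive exactly
    ``shell_occupants`` partners at ``shell_radius`` (isotropic directions,
    +-0.005 nm radial jitter); all remaining particles are uniform.
    """

    n_particles: int
    box: tuple[float, float, float]
    n_frames: int
    shell_center_count: int = 0
    shell_radius: float = 0.3
    shell_occupants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "box", tuple(float(b) for b in self.box))
        if any(b <= 0 for b in self.box):
            raise ValueError("box edges must be positive")
        if self.shell_radius >= min(self.box) / 2:
            raise ValueError("shell_radius must be below half the smallest box edge")
        if self.shell_occupants < 0 or self.shell_center_count < 0:
            raise ValueError("shell counts must be non-negative")
        if self.n_particles < 1 or self.n_frames < 1:
            raise ValueError("n_particles and n_frames must be positive")


@dataclass(frozen=True)
class UmbrellaPullSpec:
    """Overdamped particle pulled by a moving harmonic restraint.

    The restraint minimum moves as x0(t) = x_start + pull_speed * t; the
    particle feels pmf(x) + 0.5 k_spring (x - x0)^2 plus thermal noise at
    ``temperature``.  ``friction`` is the collision rate in ps^-1 acting on a
    unit mass of 1 amu (in nm/ps/kJ-mol units the drag coefficient is then
    numerically equal to ``friction``).
    """

    pmf: "AnalyticPMF"
    k_spring: float
    pull_speed: float
    x_start: float
    friction: float
    temperature: float
    dt: float
    n_steps: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_spring <= 0:
            raise ValueError("k_spring must be positive")
        if self.pull_speed < 0:
            raise ValueError("pull_speed must be non-negative")
        if self.friction <= 0 or self.dt <= 0 or self.n_steps < 1:
            raise ValueError("friction, dt, n_steps must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.k_spring * self.dt / self.friction > 0.1:
            raise ValueError(
                f"k_spring*dt/friction = {self.k_spring * self.dt / self.friction:.3g} "
                "> 0.1: unstable overdamped step; reduce dt or k_spring"
            )


# ---------------------------------------------------------------------------
# analytic potentials of mean force


@dataclass(frozen=True)
class AnalyticPMF:
    """Named analytic potential V(x) in kJ/mol with x in nm."""

    name: str
    params: dict = field(default_factory=dict)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.name == "flat":
            return np.zeros_like(x)
        if self.name == "harmonic":
            return 0.5 * p["k"] * (x - p["center"]) ** 2
        if self.name == "double_well":
            a, b, h = p["min_a"], p["min_b"], p["barrier"]
            d = (b - a) / 2.0
            return h * ((x - a) * (x - b)) ** 2 / d**4
        if self.name == "screened_coulomb":
            from .constants import COULOMB_KJ_MOL_NM

            return COULOMB_KJ_MOL_NM * p["z_a"] * p["z_b"] / (p["eps_r"] * x)
        raise ValueError(f"unknown pmf {self.name!r}")

    def gradient(self, x):
        """dV/dx in kJ mol^-1 nm^-1 (analytic)."""
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.name == "flat":
            return np.zeros_like(x)
        if self.name == "harmonic":
            return p["k"] * (x - p["center"])
        if self.name == "double_well":
            a, b, h = p["min_a"], p["min_b"], p["barrier"]
            d = (b - a) / 2.0
            return h * 2.0 * (x - a) * (x - b) * (2.0 * x - a - b) / d**4
        if self.name == "screened_coulomb":
            from .constants import COULOMB_KJ_MOL_NM

            return -COULOMB_KJ_MOL_NM * p["z_a"] * p["z_b"] / (p["eps_r"] * x**2)
        raise ValueError(f"unknown pmf {self.name!r}")

    def scalar_gradient(self):
        """Plain-Python closure for dV/dx, cheap inside integrator loops."""
        p = self.params
        if self.name == "flat":
            return lambda x: 0.0
        if self.name == "harmonic":
            k, c = p["k"], p["center"]
            return lambda x: k * (x - c)
        if self.name == "double_well":
            a, b, h = p["min_a"], p["min_b"], p["barrier"]
            d4 = ((b - a) / 2.0) ** 4
            return lambda x: h * 2.0 * (x - a) * (x - b) * (2.0 * x - a - b) / d4
        if self.name == "screened_coulomb":
            from .constants import COULOMB_KJ_MOL_NM

            pref = -COULOMB_KJ_MOL_NM * p["z_a"] * p["z_b"] / p["eps_r"]
            return lambda x: pref / (x * x)
        raise ValueError(f"unknown pmf {self.name!r}")

    @property
    def extrema(self) -> list[float]:
        """Stationary points of V inside the physically relevant range."""
        p = self.params
        if self.name == "harmonic":
            return [float(p["center"])]
        if self.name == "double_well":
            a, b = p["min_a"], p["min_b"]
            return [float(a), float((a + b) / 2.0), float(b)]
        return []


def make_pmf(name: str, **params) -> AnalyticPMF:
    """Factory for the named analytic potentials.

    ``flat``; ``harmonic(k, center)``; ``double_well(min_a, min_b, barrier)``
    — quartic with minima at min_a/min_b and barrier height ``barrier`` at the
    midpoint; ``screened_coulomb(eps_r, z_a, z_b)``.
    """
    pmf = AnalyticPMF(name, dict(params))
    pmf.energy(np.array([max(params.get("min_a", 1.0), 0.5)]))  # validate name/params
    return pmf


# ---------------------------------------------------------------------------
# rotational diffusion


def gen_rotor_ensemble(spec: RotorEnsembleSpec) -> VectorSeries:
    """Evolve unit vectors by sequential small random rotations.

    Each step rotates every vector about two axes orthogonal to it by
    independent Gaussian angles of variance ``2 d_rot dt`` each, the simplest
    scheme whose rank-1 ACF has the closed form exp(-2 d_rot t) in the small
    step limit (for Gaussian angles E[cos a cos b] = exp(-2 D dt) exactly, so
    the discretization error is tiny at valid step sizes).
    """
    d_eff = max(spec.d_rot, spec.d_rot_slow if spec.slow_fraction > 0 else 0.0)
    if d_eff * spec.dt > 0.05:
        raise ValueError(
            f"d_rot*dt = {d_eff * spec.dt:.3g} > 0.05: rotation step too coarse"
        )
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_steps, spec.n_rotors
    n_slow = int(round(spec.slow_fraction * m))
    sigma = np.full(m, np.sqrt(2.0 * spec.d_rot * spec.dt))
    if n_slow:
        sigma[:n_slow] = np.sqrt(2.0 * spec.d_rot_slow * spec.dt)
    # random initial directions (isotropic)
    u = rng.normal(size=(m, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    out = np.empty((n, m, 3))
    out[0] = u
    for t in range(1, n):
        # tangent basis at the current direction
        helper = np.zeros_like(u)
        smallest = np.argmin(np.abs(u), axis=1)
        helper[np.arange(m), smallest] = 1.0
        e1 = np.cross(u, helper)
        e1 /= np.linalg.norm(e1, axis=1)[:, None]
        e2 = np.cross(u, e1)
        alpha = rng.normal(scale=sigma)
        beta = rng.normal(scale=sigma)
        # rotate about e1 (u is orthogonal to e1, so Rodrigues reduces)
        u = u * np.cos(alpha)[:, None] + np.cross(e1, u) * np.sin(alpha)[:, None]
        # rotate about e2 with the full Rodrigues formula (u no longer exactly orthogonal)
        cb, sb = np.cos(beta)[:, None], np.sin(beta)[:, None]
        dot = np.sum(e2 * u, axis=1)[:, None]
        u = u * cb + np.cross(e2, u) * sb + e2 * dot * (1.0 - cb)
        u /= np.linalg.norm(u, axis=1)[:, None]
        out[t] = u
    return VectorSeries(out, spec.dt)


# ---------------------------------------------------------------------------
# two-state kinetics


def gen_two_state_bonds(spec: TwoStateKineticsSpec) -> IndicatorSeries:
    """Simulate independent bonded/unbonded Markov chains.

    Per-step transition probabilities are 1 - exp(-k dt); chains start from
    the stationary distribution, so the process is stationary from frame 0
    (no burn-in, as the intermittent-ACF formalism assumes).
    """
    rng = np.random.default_rng(spec.seed)
    p_on = 1.0 - np.exp(-spec.k_on * spec.dt)   # off -> on
    p_off = 1.0 - np.exp(-spec.k_off * spec.dt)  # on -> off
    m, n = spec.n_pairs, spec.n_steps
    ind = np.empty((m, n), dtype=bool)
    state = rng.random(m) < spec.p_eq
    ind[:, 0] = state
    for t in range(1, n):
        u = rng.random(m)
        state = np.where(state, u >= p_off, u < p_on)
        ind[:, t] = state
    pair_ids = [(2 * k, 2 * k + 1) for k in range(m)]
    return IndicatorSeries(ind, spec.dt, pair_ids)


def embed_bonds_as_trajectory(indicator: IndicatorSeries, cutoff: float,
                              box: tuple[float, float, float]) -> Trajectory:
    """Realize a bond indicator as pair geometry in a periodic box.

    Pair p sits in its own grid cell (spacing 4x cutoff): atom A at the cell
    center, atom B at distance 0.8*cutoff when bonded and 1.5*cutoff when
    unbonded.  Distances between atoms of different pairs always exceed the
    cutoff, so running the geometric pair-indicator on the result recovers
    the input exactly on the matched (diagonal) pairs and is identically
    zero elsewhere.
    """
    box = np.asarray(box, dtype=float)
    if cutoff >= min(box) / 2:
        raise ValueError("cutoff must be below half the smallest box edge")
    spacing = 4.0 * cutoff
    grid = np.floor(box / spacing).astype(int)
    n_cells = int(np.prod(grid))
    m = indicator.n_pairs
    if n_cells < m:
        raise ValueError(
            f"box {tuple(box)} nm fits {n_cells} pair cells at spacing {spacing} nm "
            f"but {m} pairs were requested"
        )
    cells = np.array(np.unravel_index(np.arange(m), grid)).T  # (m, 3)
    centers = (cells + 0.5) * spacing
    frames = []
    for f in range(indicator.n_frames):
        pos = np.empty((2 * m, 3))
        bonded = indicator.indicator[:, f]
        offset = np.where(bonded, 0.8 * cutoff, 1.5 * cutoff)
        pos[0::2] = centers
        pos[1::2] = centers + np.outer(offset, [1.0, 0.0, 0.0])
        frames.append(Frame(pos, box, time=f * indicator.dt))
    labels = []
    for k in range(m):
        labels += [f"A{k}", f"B{k}"]
    return Trajectory(frames, labels)


def embed_vectors_as_trajectory(series: VectorSeries, bond_length: float,
                                box: tuple[float, float, float]) -> Trajectory:
    """Realize unit vectors as rigid two-atom molecules on a grid.

    Molecule k has its first atom at a fixed grid point and its second at
    ``bond_length`` along the instantaneous vector, so vector extraction from
    the trajectory reproduces the generator's vectors.
    """
    box = np.asarray(box, dtype=float)
    if bond_length >= min(box) / 2:
        raise ValueError("bond_length must be below half the smallest box edge")
    m = series.n_molecules
    spacing = max(4.0 * bond_length, min(box) / np.ceil(m ** (1.0 / 3.0)) * 0.999)
    grid = np.maximum(np.floor(box / spacing).astype(int), 1)
    if int(np.prod(grid)) < m:
        raise ValueError(f"box too small for {m} molecules at spacing {spacing} nm")
    cells = np.array(np.unravel_index(np.arange(m), grid)).T
    centers = (cells + 0.5) * spacing
    frames = []
    for f in range(series.n_steps):
        pos = np.empty((2 * m, 3))
        pos[0::2] = centers
        pos[1::2] = centers + bond_length * series.vectors[f]
        frames.append(Frame(pos, box, time=f * series.dt))
    labels = []
    for k in range(m):
        labels += ["TAIL", "HEAD"]
    return Trajectory(frames, labels)


# ---------------------------------------------------------------------------
# particle configurations


def gen_ideal_gas(spec: ShellFluidSpec) -> Trajectory:
    """Uncorrelated uniform positions each frame: the g(r) = 1 null model."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box)
    frames = [
        Frame(rng.random((spec.n_particles, 3)) * box, box, time=float(f))
        for f in range(spec.n_frames)
    ]
    labels = ["GAS"] * spec.n_particles
    return Trajectory(frames, labels)


def gen_shell_config(spec: ShellFluidSpec) -> Trajectory:
    """Centers with an exact number of first-shell partners, rest uniform.

    Labels are ``CEN`` for centers, ``SHL`` for shell occupants and ``BLK``
    for bulk particles, so site groups select them directly.  Occupants are
    placed isotropically at ``shell_radius`` with +-0.005 nm radial jitter,
    resampled each frame (shells persist in every frame by construction).
    Bulk particles are uniform outside an excluded zone of
    ``shell_radius + 0.05 nm`` around every center — the analogue of the
    excluded volume that separates a first shell from the bulk in a real
    fluid, and what makes the first minimum of g(r) well defined.
    """
    n_shell = spec.shell_center_count * spec.shell_occupants
    n_bulk = spec.n_particles - spec.shell_center_count - n_shell
    if n_bulk < 0:
        raise ValueError(
            f"{spec.shell_center_count} centers x {spec.shell_occupants} occupants "
            f"exceed the particle budget of {spec.n_particles}"
        )
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box)
    # fixed center positions on a grid, clear of each other's shells
    spacing = min(box) / max(1, int(np.ceil(spec.shell_center_count ** (1 / 3))))
    if spec.shell_center_count:
        grid = np.maximum(np.floor(box / spacing).astype(int), 1)
        cells = np.array(np.unravel_index(np.arange(spec.shell_center_count), grid)).T
        centers = (cells + 0.5) * spacing
    else:
        centers = np.empty((0, 3))
    frames = []
    for f in range(spec.n_frames):
        parts = [centers]
        if n_shell:
            directions = rng.normal(size=(spec.shell_center_count, spec.shell_occupants, 3))
            directions /= np.linalg.norm(directions, axis=2)[:, :, None]
            radii = spec.shell_radius + rng.uniform(
                -0.005, 0.005, size=(spec.shell_center_count, spec.shell_occupants, 1)
            )
            occ = centers[:, None, :] + directions * radii
            parts.append(occ.reshape(-1, 3))
        if n_bulk:
            exclude = spec.shell_radius + 0.05
            bulk = np.empty((0, 3))
            while len(bulk) < n_bulk:
                cand = rng.random((2 * n_bulk, 3)) * box
                if len(centers):
                    d = cand[:, None, :] - centers[None, :, :]
                    d -= box * np.round(d / box)
                    ok = np.all(np.linalg.norm(d, axis=2) > exclude, axis=1)
                    cand = cand[ok]
                bulk = np.vstack([bulk, cand])
            parts.append(bulk[:n_bulk])
        frames.append(Frame(np.vstack(parts), box, time=float(f)))
    labels = (
        ["CEN"] * spec.shell_center_count + ["SHL"] * n_shell + ["BLK"] * n_bulk
    )
    return Trajectory(frames, labels)


# ---------------------------------------------------------------------------
# umbrella pulling


def gen_umbrella_pull(spec: UmbrellaPullSpec) -> TimeSeries:
    """Euler-Maruyama integration of the overdamped pulled coordinate.

    dx = -(V'(x) + k (x - x0(t))) / gamma dt + sqrt(2 kB T dt / gamma) xi,
    with gamma = friction (unit mass 1 amu).  Emits columns ``x`` (nm) and
    ``force`` — the instantaneous restraint force k (x0 - x), positive when
    the restraint pulls the coordinate forward.
    """
    rng = np.random.default_rng(spec.seed)
    gamma = spec.friction
    kbt = BOLTZMANN_KJ_MOL * spec.temperature
    noise_scale = np.sqrt(2.0 * kbt * spec.dt / gamma)
    n = spec.n_steps
    noise = rng.normal(size=n) * noise_scale if spec.temperature > 0 else np.zeros(n)
    times = np.arange(n) * spec.dt
    x0s = spec.x_start + spec.pull_speed * times
    xs = np.empty(n)
    forces = np.empty(n)
    x = spec.x_start
    grad = spec.pmf.scalar_gradient()
    k = spec.k_spring
    dt_over_gamma = spec.dt / gamma
    noise_list = noise.tolist()
    x0_list = x0s.tolist()
    for i in range(n):
        spring = k * (x0_list[i] - x)
        xs[i] = x
        forces[i] = spring
        x = x + (spring - grad(x)) * dt_over_gamma + noise_list[i]
    return TimeSeries(times, np.column_stack([xs, forces]), ["x", "force"])
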