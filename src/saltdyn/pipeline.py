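"""Configuration-driven orchestration of the full analysis battery.

A single YAML document drives synthetic-data generation and/or trajectory
input, then the analysis stages in order: vector-reorientation ACFs,
intermittent aggregate lifetimes, radial distribution functions, and the
mean-force profile.  Validation is exhaustive before anything is written;
every default is echoed back into the output directory so no silent defaults
exist, and all randomness derives from the single config seed via named
substreams (one spawned child stream per stage, so stages are individually
reproducible).

The shipped default criteria profile encodes the six aggregate types of a
salt-bridge solution — water/ion partners of the aspartate and arginine
sites — with first-minimum-derived cutoffs (0.30 nm cation-O(Asp); 0.33 nm
anion-H(Arg), anion-H(Water), cation-O(Water); 0.25 nm H(Water)-O(Asp),
O(Water)-H(Arg)).
"""

from __future__ import annotations

import copy
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aggregates import PairCriterion, compute_lifetime, pair_indicator
from .constants import PER_MOLAR_PER_NM3
from .meanforce import PullRecord, bin_mean_force, compare_to_reference, find_regimes
from .rdf import compute_rdf, coordination_number, shell_occupancy
from .reorientation import fit_exponentials, vector_acf
from .synthetic import (
    RotorEnsembleSpec,
    ShellFluidSpec,
    TwoStateKineticsSpec,
    UmbrellaPullSpec,
    embed_bonds_as_trajectory,
    gen_rotor_ensemble,
    gen_shell_config,
    gen_two_state_bonds,
    gen_umbrella_pull,
    make_pmf,
)
from .trajectory_io import read_gro, read_xvg_series, read_xyz, resolve_roles

__all__ = [
    "ConfigError",
    "RunReport",
    "ion_count_for_concentration",
    "default_criteria_profile",
    "demo_config",
    "validate_config",
    "run_config",
]


class ConfigError(ValueError):
    """Raised when an analysis configuration is invalid (before any stage runs)."""


#: role name, partner role name, cutoff in nm (converted from the pm-scale
#: first-minimum values at the config boundary)
DEFAULT_CRITERIA: list[tuple[str, str, float]] = [
    ("O_Asp", "H_Water", 0.250),
    ("H_Arg", "O_Water", 0.250),
    ("O_Asp", "cation", 0.300),
    ("H_Arg", "anion", 0.330),
    ("O_Water", "cation", 0.330),
    ("H_Water", "anion", 0.330),
]


def default_criteria_profile() -> list[dict]:
    """The six shipped aggregate criteria as config entries (cutoffs in nm)."""
    return [
        {"name": f"{a}-{b}", "group_a": a, "group_b": b, "cutoff": c}
        for a, b, c in DEFAULT_CRITERIA
    ]


def ion_count_for_concentration(concentration: float, box: tuple[float, float, float]) -> int:
    """Per-species ion count for a molar concentration in an orthorhombic box.

    round(c * N_A * V) with V in nm^3; 1 M in a 6 x 4 x 4 nm box gives 58
    ions of each species.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    return int(round(concentration * PER_MOLAR_PER_NM3 * float(np.prod(box))))


@dataclass
class RunReport:
    """Manifest of a pipeline run: stage outcomes, files, timings, config echo."""

    outdir: Path
    stages: dict[str, str] = field(default_factory=dict)
    manifest: dict[str, list[str]] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = __version__

    @property
    def ok(self) -> bool:
        return all(s == "ok" for s in self.stages.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "stages": self.stages,
                "manifest": self.manifest,
                "wall_clock_s": {k: round(v, 3) for k, v in self.wall_clock.items()},
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# demo configuration


def demo_config(seed: int = 0) -> dict:
    """Self-contained demo: synthetic inputs for every stage, modest sizes."""
    return {
        "seed": int(seed),
        "stages": ["acf", "lifetimes", "rdf", "meanforce"],
        "synth": {
            "rotor": {
                "n_rotors": 200, "d_rot": 0.05, "dt": 0.1, "n_steps": 2000,
                "slow_fraction": 0.3, "d_rot_slow": 0.01,
            },
            "bonds": {
                "n_pairs": 50, "k_on": 0.01, "k_off": 0.04, "dt": 0.1,
                "n_steps": 10000, "cutoff": 0.30, "box": [12.0, 12.0, 6.0],
            },
            "shell": {
                "n_particles": 128, "box": [4.0, 4.0, 4.0], "n_frames": 20,
                "shell_center_count": 4, "shell_radius": 0.30, "shell_occupants": 6,
            },
            "pull": {
                "pmf": {"name": "double_well", "min_a": 0.43, "min_b": 0.60, "barrier": 5.0},
                "k_spring": 4000.0, "pull_speed": 2.3e-3, "x_start": 0.40,
                "friction": 20.0, "temperature": 296.0, "dt": 5e-4, "n_steps": 200000,
            },
        },
        "acf": {"max_lag": 100.0, "n_components": 2, "fit_window": [0.0, 100.0]},
        "lifetimes": {"max_lag": 200.0},
        "rdf": {"bin_width": 0.01, "r_max": 1.9, "r_cut": 0.35},
        "meanforce": {"bin_width": 0.005, "eps_r": 80.0},
    }


# ---------------------------------------------------------------------------
# validation

_KNOWN_STAGES = ("acf", "lifetimes", "rdf", "meanforce")


def validate_config(config: dict) -> dict:
    """Validate exhaustively and fill defaults; raises ConfigError, writes nothing."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    cfg = copy.deepcopy(config)
    cfg.setdefault("seed", 0)
    if not isinstance(cfg["seed"], int) or cfg["seed"] < 0:
        raise ConfigError("seed must be a non-negative integer")
    stages = cfg.setdefault("stages", list(_KNOWN_STAGES))
    unknown = [s for s in stages if s not in _KNOWN_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; known: {list(_KNOWN_STAGES)}")
    synth = cfg.setdefault("synth", {})
    inputs = cfg.setdefault("input", {})

    if "trajectory" in inputs:
        path = Path(inputs["trajectory"])
        if not path.exists():
            raise ConfigError(f"input trajectory {path} does not exist")
        if "role_spec" not in inputs:
            raise ConfigError("input.role_spec is required with an input trajectory")
    if "pull_xvg" in inputs and not Path(inputs["pull_xvg"]).exists():
        raise ConfigError(f"input pull record {inputs['pull_xvg']} does not exist")

    if "acf" in stages and "rotor" not in synth and "trajectory" not in inputs:
        raise ConfigError("acf stage needs synth.rotor or an input trajectory")
    if "lifetimes" in stages and "bonds" not in synth and "trajectory" not in inputs:
        raise ConfigError("lifetimes stage needs synth.bonds or an input trajectory")
    if "rdf" in stages and "shell" not in synth and "trajectory" not in inputs:
        raise ConfigError("rdf stage needs synth.shell or an input trajectory")
    if "meanforce" in stages and "pull" not in synth and "pull_xvg" not in inputs:
        raise ConfigError("meanforce stage needs synth.pull or input.pull_xvg")

    criteria = inputs.get("criteria")
    if criteria is not None:
        for ent in criteria:
            if not {"group_a", "group_b", "cutoff"} <= set(ent):
                raise ConfigError(f"criterion entry {ent} needs group_a, group_b, cutoff")
            if ent["cutoff"] <= 0:
                raise ConfigError(f"criterion {ent.get('name', ent)}: cutoff must be positive")

    # fill analysis defaults so the echoed config is complete
    acf = cfg.setdefault("acf", {})
    acf.setdefault("max_lag", None)
    acf.setdefault("n_components", 1)
    acf.setdefault("fit_window", None)
    if acf["n_components"] not in (1, 2):
        raise ConfigError("acf.n_components must be 1 or 2")
    life = cfg.setdefault("lifetimes", {})
    life.setdefault("max_lag", None)
    rdf = cfg.setdefault("rdf", {})
    rdf.setdefault("bin_width", 0.002)
    rdf.setdefault("r_max", None)
    rdf.setdefault("r_cut", None)
    if rdf["bin_width"] <= 0:
        raise ConfigError("rdf.bin_width must be positive")
    mf = cfg.setdefault("meanforce", {})
    mf.setdefault("bin_width", 0.005)
    mf.setdefault("eps_r", 80.0)
    if mf["bin_width"] <= 0:
        raise ConfigError("meanforce.bin_width must be positive")
    return cfg


# ---------------------------------------------------------------------------
# stage implementations


def _write_tsv(path: Path, header: str, columns: list[np.ndarray]) -> None:
    """Deterministic TSV output (%.10g) so reruns are byte-identical."""
    rows = np.column_stack(columns)
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for row in rows:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def _stage_acf(cfg: dict, outdir: Path, rng_seed: int) -> list[str]:
    opts = cfg["acf"]
    if "rotor" in cfg["synth"]:
        spec = RotorEnsembleSpec(seed=rng_seed, **cfg["synth"]["rotor"])
        series = gen_rotor_ensemble(spec)
    else:
        traj = _load_trajectory(cfg)
        roles = resolve_roles(traj, cfg["input"]["role_spec"])
        from .reorientation import extract_vectors

        ep = cfg["input"].get("dipole_endpoints", {})
        frm = [roles[r] for r in ep.get("from", [])] or list(roles.values())[:1]
        to = [roles[r] for r in ep.get("to", [])] or list(roles.values())[1:2]
        series = extract_vectors(traj, frm, to)
    acf = vector_acf(series, opts["max_lag"])
    window = tuple(opts["fit_window"]) if opts["fit_window"] else None
    fit = fit_exponentials(acf, opts["n_components"], window)
    _write_tsv(outdir / "acf.tsv", "lag_ps\tC\tn_origins",
               [acf.lags, acf.values, acf.n_origins.astype(float)])
    summary = {
        "amplitudes": fit.amplitudes.tolist(),
        "time_constants_ps": fit.time_constants.tolist(),
        "fit_window_ps": list(fit.fit_window),
        "rss": fit.rss,
        "correlation_rank": 1,
    }
    (outdir / "acf_fit.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return ["acf.tsv", "acf_fit.json"]


def _stage_lifetimes(cfg: dict, outdir: Path, rng_seed: int) -> list[str]:
    opts = cfg["lifetimes"]
    files: list[str] = []
    summary = {}
    if "bonds" in cfg["synth"]:
        b = dict(cfg["synth"]["bonds"])
        cutoff, box = b.pop("cutoff"), b.pop("box")
        spec = TwoStateKineticsSpec(seed=rng_seed, **b)
        indicator = gen_two_state_bonds(spec)
        traj = embed_bonds_as_trajectory(indicator, cutoff, box)
        from .trajectory_io import select_sites

        ga = select_sites(traj, "A", "A*")
        gb = select_sites(traj, "B", "B*")
        crit = PairCriterion(ga, gb, cutoff, name="synthetic-bonds")
        ind_geo = pair_indicator(traj, crit)
        # keep the matched pairs only: cross pairs never bond by construction
        diag = [k for k, (i, j) in enumerate(ind_geo.pair_ids) if j == i + 1]
        from .aggregates import IndicatorSeries

        ind_geo = IndicatorSeries(
            ind_geo.indicator[diag], ind_geo.dt, [ind_geo.pair_ids[k] for k in diag]
        )
        named = [("synthetic-bonds", ind_geo)]
    else:
        traj = _load_trajectory(cfg)
        roles = resolve_roles(traj, cfg["input"]["role_spec"])
        entries = cfg["input"].get("criteria") or default_criteria_profile()
        named = []
        for ent in entries:
            crit = PairCriterion(
                roles[ent["group_a"]], roles[ent["group_b"]], ent["cutoff"],
                name=ent.get("name", f"{ent['group_a']}-{ent['group_b']}"),
            )
            named.append((crit.name, pair_indicator(traj, crit)))
    for name, indicator in named:
        result = compute_lifetime(indicator, opts["max_lag"])
        safe = name.replace("/", "_")
        _write_tsv(
            outdir / f"lifetime_{safe}.tsv",
            "lag_ps\tC_raw\tC_corrected",
            [result.acf_raw.lags, result.acf_raw.values, result.acf_corrected.values],
        )
        files.append(f"lifetime_{safe}.tsv")
        summary[name] = {
            "lifetime_ps": result.lifetime,
            "lifetime_windowed_ps": result.lifetime_windowed,
            "lifetime_tail_ps": result.lifetime_tail,
            "ensemble_average": result.ensemble_average,
        }
    (outdir / "lifetimes.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    files.append("lifetimes.json")
    return files


def _stage_rdf(cfg: dict, outdir: Path, rng_seed: int) -> list[str]:
    opts = cfg["rdf"]
    from .trajectory_io import select_sites

    if "shell" in cfg["synth"]:
        spec = ShellFluidSpec(seed=rng_seed, **cfg["synth"]["shell"])
        traj = gen_shell_config(spec)
        ga = select_sites(traj, "centers", "CEN")
        gb = select_sites(traj, "partners", "SHL") if spec.shell_occupants else \
            select_sites(traj, "partners", "BLK")
    else:
        traj = _load_trajectory(cfg)
        roles = resolve_roles(traj, cfg["input"]["role_spec"])
        pair = cfg["input"].get("rdf_pair")
        if pair:
            ga, gb = roles[pair[0]], roles[pair[1]]
        else:
            names = list(roles)
            ga, gb = roles[names[0]], roles[names[1]]
    rdf = compute_rdf(traj, ga, gb, opts["bin_width"], opts["r_max"])
    centers = rdf.bin_centers
    running = np.array([coordination_number(rdf, r) for r in rdf.bin_edges[1:]])
    _write_tsv(outdir / "rdf.tsv", "r_nm\tg\tn_running", [centers, rdf.g, running])
    shell: dict = {"rho_b_per_nm3": rdf.rho_b}
    r_cut = opts.get("r_cut")
    if r_cut:
        shell["r_cut_nm"] = r_cut
        shell["coordination_number"] = coordination_number(rdf, r_cut)
        occ = shell_occupancy(traj, PairCriterion(ga, gb, r_cut, name="first-shell"))
        shell["occupancy_fraction"] = occ.fraction
        shell["mean_partner_count"] = occ.mean_partner_count
    (outdir / "rdf_shell.json").write_text(json.dumps(shell, indent=2, sort_keys=True))
    return ["rdf.tsv", "rdf_shell.json"]


def _stage_meanforce(cfg: dict, outdir: Path, rng_seed: int) -> list[str]:
    opts = cfg["meanforce"]
    if "pull" in cfg["synth"]:
        p = dict(cfg["synth"]["pull"])
        pmf_cfg = dict(p.pop("pmf"))
        pmf = make_pmf(pmf_cfg.pop("name"), **pmf_cfg)
        spec = UmbrellaPullSpec(pmf=pmf, seed=rng_seed, **p)
        series = gen_umbrella_pull(spec)
        record = PullRecord.from_timeseries(series)
    else:
        series = read_xvg_series(cfg["input"]["pull_xvg"])
        if "x" in series.names and "force" in series.names:
            record = PullRecord.from_timeseries(series)
        else:
            record = PullRecord(series.times, series.values[:, 0], series.values[:, 1])
    profile = bin_mean_force(record, opts["bin_width"])
    occ = profile.occupied
    _write_tsv(
        outdir / "meanforce.tsv",
        "x_nm\tmean_force_kJ_mol_nm (positive = repulsive)\tstderr\tn_samples\tresidual_vs_screened_coulomb",
        [
            profile.bin_centers[occ],
            profile.mean_force[occ],
            profile.stderr[occ],
            profile.n_samples[occ].astype(float),
            compare_to_reference(profile, opts["eps_r"])[occ],
        ],
    )
    regimes = find_regimes(profile)
    report = {
        "sign_convention": "positive = repulsive",
        "zero_crossings_nm": regimes.zero_crossings,
        "windows": [
            {"range_nm": list(rng_), "sign": sign} for rng_, sign in regimes.windows
        ],
        "eps_r_reference": opts["eps_r"],
    }
    (outdir / "meanforce_regimes.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return ["meanforce.tsv", "meanforce_regimes.json"]


def _load_trajectory(cfg: dict):
    path = Path(cfg["input"]["trajectory"])
    name = path.name.removesuffix(".gz")
    if name.endswith(".gro"):
        return read_gro(path)
    return read_xyz(path)


_STAGE_FUNCS = {
    "acf": _stage_acf,
    "lifetimes": _stage_lifetimes,
    "rdf": _stage_rdf,
    "meanforce": _stage_meanforce,
}


def run_config(config: dict, outdir, log=print) -> RunReport:
    """Validate, then execute the requested stages in order.

    A failing stage is recorded and later independent stages still run; the
    report's ``ok`` flag (and the CLI exit code) signals partial failure.
    Identical config + seed reruns produce byte-identical TSV outputs.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=outdir, config=cfg)
    # one named substream per stage, derived from the single config seed
    root = np.random.SeedSequence(cfg["seed"])
    children = root.spawn(len(_KNOWN_STAGES))
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_KNOWN_STAGES, children)
    }
    (outdir / "config_echo.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    report.manifest["config"] = ["config_echo.yaml"]
    for stage in cfg["stages"]:
        t0 = _time.perf_counter()
        log(f"[saltdyn] stage {stage} start (seed substream {stage_seeds[stage]})")
        try:
            files = _STAGE_FUNCS[stage](cfg, outdir, stage_seeds[stage])
            report.stages[stage] = "ok"
            report.manifest[stage] = files
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            report.stages[stage] = f"failed: {exc}"
            log(f"[saltdyn] ERROR stage {stage}: {exc}")
        report.wall_clock[stage] = _time.perf_counter() - t0
        log(f"[saltdyn] stage {stage} end ({report.wall_clock[stage]:.2f} s)")
    (outdir / "run_report.json").write_text(report.to_json())
    return report
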