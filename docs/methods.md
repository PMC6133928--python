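# Methods

This note records the models behind each analysis stage, the conventions
and defaults that matter for reproducibility, what the synthetic generators
do and do not emulate, and the design choices made where more than one
reasonable convention exists. Units throughout: nm, ps, kJ/mol,
kJ mol⁻¹ nm⁻¹, elementary charges, kelvin.

## Trajectory model and geometry

Frames hold raw (unwrapped) coordinates with an orthorhombic box per frame;
triclinic cells are rejected rather than approximated. Coordinates are
never wrapped on read — wrapping would break intramolecular vectors across
the boundary — and all distances apply the minimum-image convention
`d − box·round(d/box)` at computation time, which is exact for orthorhombic
cells up to half the smallest box edge. That half-box radius is enforced as
the hard upper limit for RDF ranges and region radii.

Sites are named by role (e.g. `O_Asp`, `H_Arg`, `cation`, `anion`,
`O_Water`, `H_Water`) and resolved to 0-based atom indices either by a
glob pattern over atom labels or by explicit lists; resolution is
deterministic (ascending index). Cutoffs quoted in pm in the literature are
converted once at the configuration boundary (300 pm → 0.30 nm).

File formats are deliberately plain text: extended XYZ with
`time=… box=a b c` on the comment line (coordinates in nm), single- and
multi-frame GRO, and xvg-style numeric tables with `#`/`@` comments. All
readers accept gzip input and report the offending line or frame on parse
errors. Round-trip identity within format precision (10⁻⁶ nm for XYZ as
written, 10⁻³ nm for GRO's fixed columns) is part of the tested contract.

## Reorientation analysis

The observable is the rank-1 (first Legendre) correlation
C₁(t) = ⟨û(t₀)·û(t₀+t)⟩. Rank 1 is the dipole-vector convention of
standard trajectory-analysis tools; the rank is recorded in the result
metadata so downstream comparison with rank-2/NMR observables cannot happen
silently. Every frame serves as a time origin, and per-lag origin counts
are reported so standard errors are computable. The default maximum lag is
half the series length, beyond which origin statistics degrade.

The FFT evaluation of the pooled numerator is exact (identical to the
direct double loop to ~10⁻¹⁶; a 10⁻¹⁰ bound is asserted in tests), so the
transform is a speed choice, not an approximation.

Exponential fits minimize unweighted squared error on C(t) itself — not
log C, which would overweight the noisy tail. Initialization is
deterministic: the slow component is seeded by a log-linear fit of the tail
half of the window, the fast one from the early residual, so fits are
reproducible run to run. Components are reported with τ ascending, and the
slow-down ratio is defined only against a mono-exponential reference fit.

## Intermittent lifetimes

Bonding is a pure distance criterion, `r ≤ cutoff` (ties count as bonded; a
fixed convention matters more than its direction, and exact ties are
measure-zero). All |a|×|b| pairs are enumerated with no nearest-partner
exclusivity, matching the "every possible aggregate" definition. Groups
sharing an atom are rejected.

The intermittent ACF is normalized to C_raw(0) = 1 and pooled over pairs
and origins. The finite-size plateau p is estimated as the pooled occupancy
over all pairs and frames — stabler for rare pairs than averaging per-pair
plateaus — and removed by the affine map C_corr = (C_raw − p)/(1 − p).
The renormalization by (1 − p) is deliberate: with subtraction alone the
integral of the corrected function would not equal the decay constant of a
mono-exponential process, which is the property that makes the integral a
lifetime. Per-lag standard errors are the scatter of per-pair contributions
across the ensemble; they grow at short lags as occupancy falls (rare
bonds give fewer events), which is asserted as a sanity property.

The lifetime integral is trapezoidal over the lag window plus the analytic
tail of a mono-exponential fitted to the window's final quarter; windowed
and tail contributions are reported separately, because slowly decaying
aggregates (lifetimes of nanoseconds against lag windows of hundreds of
ps) are dominated by the extrapolated tail and the reader should see how
much was measured versus extended.

## Radial distribution functions and coordination

g(r) uses half-open bins, exact spherical-shell volumes, and normalization
by n_a·ρ_b·V_shell·n_frames with ρ_b the partner-group number density, so
g = 1 is the uniform-density expectation at any r. The default bin width
is 0.002 nm — fine enough to resolve first minima at the 10-pm scale on
which aggregate cutoffs are chosen — and r_max defaults to the half-box
limit. The coordination number n(r) integrates g with the same per-bin
shell volumes (pro-rata for a partial final bin), making it an exact
re-count of the binned pairs.

Extremum detection for the first peak and first minimum runs on a centered
moving-average copy (default 5 bins; raw g is never modified). A first
peak must exceed 1 by three times the residual bin noise; the first
minimum is the first bin after the peak where the smoothed curve stops
decreasing, so a flat depletion plateau counts from its start.

Shell occupancy is a frame-level indicator (at least one partner within
the cutoff of any site of the group), reported together with the mean
bonded-pair count per frame. The two coincide only when shells are rarely
multiply occupied, so both are always emitted rather than conflated with
the first-peak integral.

The regional density ratio uses a sphere centered each frame on the
midpoint of the minimum-image segment between two single-atom sites. The
exact region geometry behind published "between the charge groups"
statistics is rarely specified, so the radius here is a mandatory explicit
parameter, never defaulted.

## Mean force along the pulling coordinate

The pull record carries the instantaneous restraint (spring) force
k(x₀(t) − x), positive when the restraint pulls the coordinate forward.
Under quasi-static pulling the restraint force balances the systematic
force, so its bin mean over x estimates +dV/dx; the reported profile is
its negative — the force the pair exerts along the coordinate, **positive
= repulsive** — so a repulsive core, an attractive well and a repulsive
barrier appear with the physically intuitive signs. The convention is
stated in every output header. No stiff-spring correction is applied;
instead the spring stiffness and pull speed are validated by a monotone
quasi-static convergence property on synthetic data.

Two systematic errors of the x-binned estimator are worth knowing.
Binning by instantaneous x convolves the profile with the restrained
thermal width σ = √(k_B T/k), attenuating features on scales comparable
to σ (for a harmonic pmf the estimator is exactly unbiased; for varying
curvature the error is O(σ²·V‴)). And bins within ~3σ of the schedule
boundaries are biased because the restraint-center distribution is
truncated there. The validation settings (k = 4×10⁴ kJ mol⁻¹ nm⁻²,
σ ≈ 0.008 nm against 0.085 nm features, schedule extending 0.05 nm past
the compared window) were chosen from this analysis.

Zero crossings are located by linear interpolation between the nearest
bins whose mean force is significant above a noise floor (default: the
median per-bin standard error); bins inside the noise band neither make
nor break a crossing. Windows between crossings are labeled repulsive or
attractive. Empty bins are flagged, never interpolated. The long-range
reference is f_C z_a z_b/(ε_r r²) with f_C = 138.935458 kJ mol⁻¹ nm e⁻²
frozen in the constants table.

## Synthetic generators: what they emulate, and what not

All generators are pure functions of their spec including the seed
(bitwise-reproducible), and every stage's estimator is tested against
their closed forms:

- **Rotor ensembles** apply, per step, Gaussian rotations about two axes
  orthogonal to each vector with angular variance 2 D_r dt per axis; for
  Gaussian angles E[cos α cos β] = exp(−2 D_r dt), so C₁(t) = exp(−2 D_r t)
  holds essentially exactly at valid step sizes (D_r·dt ≤ 0.05 enforced).
  A slow sub-population with its own D_r produces the bi-exponential decay
  characteristic of ion-stiffened water. What is *not* emulated: coupling
  between rotors, translation–rotation coupling, exchange between fast and
  slow populations — so a passing bi-exponential fit shows the estimator
  works, not that real water is a static two-population mixture.
- **Two-state bond processes** are independent Markov chains with per-step
  transition probabilities 1 − exp(−k dt), started from the stationary
  distribution (the intermittent formalism assumes stationarity; no
  burn-in). Truth values: occupancy k_on/(k_on+k_off), relaxation time
  1/(k_on+k_off). Not emulated: correlated breaking/re-forming among
  pairs, non-exponential waiting times.
- **Bond embedding** places each pair in its own grid cell (spacing 4×
  cutoff; bonded partner at 0.8×cutoff, unbonded at 1.5×cutoff), so the
  geometric pair indicator recovers the generator's indicator exactly on
  matched pairs and is identically zero for cross pairs.
- **Ideal-gas and shell configurations**: uniform positions are the g ≡ 1
  null model; shell configurations give each designated center exactly
  `shell_occupants` partners at `shell_radius` (±0.005 nm jitter,
  isotropic, every frame), making the coordination number exact by
  construction. Bulk particles stay outside an excluded zone of
  shell_radius + 0.05 nm around centers — the analogue of excluded volume,
  and what makes a first minimum well defined. No inter-particle
  correlations beyond that are emulated.
- **Umbrella pulling** integrates the overdamped Langevin equation
  (Euler–Maruyama) for one coordinate in pmf(x) plus the moving harmonic
  restraint, with thermal noise √(2 k_B T dt/γ). The friction parameter is
  a collision rate in ps⁻¹ acting on a unit mass of 1 amu; in nm/ps/kJ-mol
  units the drag coefficient is then numerically equal to it (1 amu nm²/ps²
  = 1 kJ/mol to 5 significant digits). Stability requires
  k_spring·dt/γ ≤ 0.1, enforced as a precondition. Analytic pmfs: flat,
  harmonic, quartic double-well (parameterized by its two minima and
  barrier height), screened Coulomb. Not emulated: inertia, hydrodynamic
  or multidimensional coupling, work-fluctuation effects of fast pulling.

## Pipeline and reproducibility

The configuration is a single YAML document; validation is exhaustive
before anything is written, and the fully defaulted config is echoed into
the output directory so no silent defaults exist. Each stage draws its
randomness from a named substream spawned from the single config seed, so
stages are individually reproducible. Numeric outputs are written with a
fixed `%.10g` format; identical config and seed give byte-identical TSV
files. Timing and stage status live in a separate JSON manifest. A failing
stage is recorded and later independent stages still run (nonzero exit
code at the end).

The shipped criteria profile covers the six aggregate types of a
salt-bridge solution — water and ion partners of the anionic carboxylate
oxygens and the cationic guanidinium hydrogens — with first-minimum-derived
cutoffs: 0.30 nm cation–O(Asp); 0.33 nm anion–H(Arg), anion–H(Water),
cation–O(Water); 0.25 nm H(Water)–O(Asp), O(Water)–H(Arg).

## Validation problem sizes

The test suite and `scripts/acceptance.py` use sizes at which the
closed-form targets are resolvable with comfortable statistical margin on
a single CPU in about a minute each: 10³ rotors × 10⁴ steps for the
reorientation constant (5% target vs ~1% sampling error), 500 pairs ×
2×10⁵ steps for the lifetime (10% target) and occupancy (2% target),
2000 particles × 50 frames for the RDF null (RMS < 0.02 vs ~0.01
expected), and a 1.24×10⁷-step pull across the double well (RMSE target
10% of the maximum gradient vs ~7% achieved, crossings within one
0.005 nm bin).

## Known limitations

- Only orthorhombic periodic boxes; no triclinic support.
- Rank-1 orientational correlations only; no rank-2/NMR observables.
- Continuous (no-reformation) lifetimes are deliberately not implemented:
  they are noise-prone, and the intermittent formalism with plateau
  correction is the supported estimator.
- Single-pull mean-force estimation only; no WHAM/umbrella-integration
  over multiple windows and no Jarzynski-type work relations.
- The GRO writer renumbers residues modulo the format's 5-digit field; raw
  residue topology is not round-tripped, only labels and coordinates.
- Lifetimes far beyond the lag window rest on the mono-exponential tail
  extrapolation; multi-exponential tails will be underestimated, which is
  why the windowed and tail parts are reported separately.
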