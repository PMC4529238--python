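# Methods

## Model overview

`neurodose` estimates the microscopic energy deposition (ED) that charged
particles leave in a neuron, compartment by compartment, as a function of
particle type and dose. Four stochastic layers are composed: (1) track
structure — where a single particle deposits its energy; (2) morphology —
the neuron's cylinder-segment geometry with stochastically placed spines and
filopodia; (3) scoring — the random relative placement of beams and the
neuron inside a co-axial cylinder geometry; (4) fluence sampling — the
Poisson statistics of how many beams make up a given dose. The simulations
run in track-segment mode: over a 20 μm segment the ions lose ~10⁻⁴ of their
kinetic energy (`tracks.fractional_energy_loss`), so velocity and LET are
treated as constant.

## Surrogate track-structure generator

Each history is a set of 20 nm cubic voxels with summed ED, produced by a
two-component surrogate:

* **On-track core.** Collision events form a Poisson stream along +z with
  exponential event energies (mean `on_track_mean_ev`) and a nm-scale
  isotropic lateral Gaussian smear (`on_track_lateral_nm`), representing the
  primary's ionization core plus sub-cutoff secondary electrons.
* **δ rays.** Secondary electrons are emitted with an inverse-power-law
  energy spectrum `E^-s` between a 20 eV transport cutoff and the kinematic
  maximum 2·m_e·c²·β²γ² (β, γ from the kinetic energy per nucleon). The
  classical binary-encounter ejection angle cos θ = √(E/E_max) is used. Each
  ray first advances a ballistic offset `range_r0_nm` (initial free flight /
  thermalization displacement), then deposits fixed-energy chunks
  (`delta_step_ev`) spaced by CSDA range differences of the power law
  R(E) = 50 nm · (E/keV)^1.7, so deposits crowd toward the end of the path.
  The step direction random-walks with a per-step wander ∝ E^-1/2: fast
  electrons run nearly straight, slow ones diffuse.

Event rates are derived from the nominal LET — the on-track stream carries
(1−f)·LET and the δ stream f·LET (f = `delta_fraction`) — so the *expected*
realized LET equals the nominal value by construction; only straggling
remains. The voxel grid is anchored with a voxel center on the entry point:
the few-nm core then occupies a single voxel column, which is what produces
the observed high-ED voxel population for ⁵⁶Fe (~2.7 % of voxels above
1 keV carrying ~44 % of the energy). A corner-anchored grid would split the
core across four columns and suppress that population entirely.

### Calibration

Per particle, `tracks.calibrate_generator` fits three knobs by damped fixed
point iteration — `delta_step_ev` (mean ED per voxel), `delta_exponent`
(radial ED containment at 100 nm) and `range_r0_nm` (fraction of voxels
within 100 nm) — while `delta_fraction` is set from the high-ED tail share
and the LET is exact by construction. The fit was run once and the results
ship as `tracks.DEFAULT_PARAMS`:

| particle | f_δ | s | step (eV) | r₀ (nm) |
|---|---|---|---|---|
| ⁵⁶Fe 600 MeV/u | 0.55 | 2.013 | 30.3 | 60 |
| ¹²C 300 MeV/u | 0.50 | 1.940 | 38.5 | 13.7 |
| ¹H 250 MeV | 0.58 | 2.036 | 10.1 | 60 |
| e⁻ 500→490 keV | 0.40 | 2.0 | 20.5 | 10 |

A 20 eV δ cutoff (rather than ~100 eV) is required for the observed voxel
occupancy: with a 100 eV cutoff a ¹²C history carries only ~150 δ rays,
far too few to populate ~3500 off-core voxels per 20 μm.

Electron histories follow the primary over a fixed 500→490 keV energy
window: collisions terminate exactly at 10 keV of cumulative loss, and the
path length is pinned to window/LET (46.45 μm; the raw renewal process
overshoots because the window-crossing event is size-biased under the
heavy-tailed spectrum). A small persistent angular wander reproduces the
~46.4 μm mean final on-axis extent.

### Straggling

Single-history LET straggling is dominated by the rare high-energy δ rays
and is large for light particles (CV ≈ 17 % for Fe, ~40 % for C, ~200 % for
H). Consistency checks of the realized mean LET therefore use sample sizes
scaled per particle (300 / 4000 / 30 000 histories for Fe/C/H, roughly equal
compute), chosen so the standard error is ~1 % against the 2 % test band.

## Morphology and decoration

SWC records (id, type, x, y, z, radius, parent) become right cylinders: one
per child-parent pair with the child's radius; type-1 pairs are soma. The
synthetic fixture grows a monopolar binary tree above a two-cylinder soma;
a bisection on path tortuosity makes 1392 μm of dendrite fit the target
bounding box (169 × 180 × 69 μm, ~256 μm diagonal, 16 terminal branches)
with the exact total length and dendrite volume; radii taper with branch
order and are scaled to the 1559 μm³ dendrite volume. Dendrite sections are
~7.25 μm, giving ~212 dendrite segments (mean volume ≈ 7.3 μm³).

Decoration draws N = round((L_DN/10)·Normal(4.3, 0.4)) spines and the same
for filopodia, places anchors uniformly over the dendritic arc length, and
re-places one member of any anchor pair closer than 0.5 μm until no pair
violates the minimum separation (capped at 10⁴ re-placements). Azimuths are
uniform on [0, 2π) in a frame built from the length-weighted centroid of the
segment midpoints, which makes decoration commute with rigid transforms of
the neuron. Spine types use two normal draws (binomial-approximation SDs)
plus remainder at ratios 0.38/0.33/0.29. Each protrusion is a neck cylinder
on the dendrite surface plus a distal head cylinder with per-instance
dimensions drawn from per-type normals, truncated at a 0.01 μm floor. The
two-cylinder volumes average 0.114 μm³ (filopodia) and 0.119 μm³ (ratio-
pooled spines); note the stubby row's neck diameter (0.54 μm) exceeding its
head diameter (0.46 μm) is kept as published, not "corrected".

## Scoring geometry and coincidence detection

The neuron, rotated uniformly (quaternion sampling) about its geometric
center (bounding-box center), is placed with its center at
(0, 0, L_Forward + L_Neuron,i/2), where L_Neuron,i is the rotated z-extent
of that trial. The beam enters at a uniform point on the R_Score disc and
stitches ⌈L_Score,i/20 μm⌉ random histories (electron histories chain at the
previous history's final voxel z). Scoring transforms beam voxels into the
fixed neuron frame (equivalent to rotating the neuron, with the inverse
transform recorded) and tests them against a uniform-grid spatial index of
the segments; a bounding-sphere pre-test rejects most voxels first. The
pruning is exact by construction and is verified against an all-pairs
brute-force scorer in the tests. A coincident voxel is attributed to exactly
one segment by priority head > neck > dendrite > soma (finest structure
wins), conserving energy where protrusions overlap their host dendrite.
Zero-length segments are excluded with a warning. The per-trial hot loop is
a numba kernel (~2.5 ms for a 540 000-voxel ⁵⁶Fe beam).

Doses convert ED at water density: 1 eV/μm³ = 1.602·10⁻⁴ Gy. The neuron
dose denominator defaults to the decorated volume (soma + dendrites +
protrusions, ~2830 μm³); the bare volume (2688 μm³, ~5 % smaller) is
selectable via `volume_basis="bare"`.

## Electronic equilibrium

`equilibrium.compute_kernels` reduces a library to cumulative kernels: the
radial ED fraction versus lateral distance from the track axis, and the
longitudinal cumulative dose-deposition function (LCDF) versus z from the
track start — plus one LCDF per radial shell. `predict_capture` treats each
beam-axis point as a source and combines the entry-averaged radial overlap
with the inner cylinder (disc-overlap arc integration, 1 μm entry grid) with
the stitched-track LCDF window sum. Using the per-shell LCDFs matters: the
radial and longitudinal fates of a deposit are strongly correlated (far-out
δ energy is far out in both coordinates), and a marginal-kernel product
under-predicts capture by ~7 % where the shell-resolved product agrees with
a direct voxel tally within ~2 % (the tally normalizes by the library's
realized LET, since the kernels are shape-only). `choose_buildup` scans a
grid of symmetric build-up lengths and gaps for the smallest configuration
reaching a target capture.

## Dose sampling

For a target dose the expected beam count is target / (library mean
per-trial neuron dose); the realized count is Poisson, and that many
*distinct* trials are drawn without replacement (the library must hold ≥10×
the expected count). This library-mean calibration makes the mean realized
neuron dose an unbiased estimator of the target — matching the reference
behaviour where sampled means at 10–500 mGy equal the nominal doses — and
is the default (`basis="neuron"`); `basis="fluence"` instead uses the
nominal dose per beam, in which case realized doses are smaller by the
library's capture ratio. Compartment statistics count a compartment as hit
when it holds ≥1 coincident voxel and compute dose statistics over hit
compartments only; both the across-realization SD and the mean
within-realization SD are reported, since either reading is defensible. The
CV power law is an unweighted OLS fit of log CV on log dose.

Under compound-Poisson sampling CV ∝ dose^−1/2 exactly in expectation; the
without-replacement correction at ≤10 % library usage biases the fitted
exponent by ≲0.015.

## Problem sizes and study conditions

The shipped test and acceptance configurations run on one CPU in minutes:
calibration-scale track libraries of 200–300 Fe histories (more for lighter
particles, see Straggling); a 15 000-trial ⁵⁶Fe coincidence library in a
reduced geometry (R_Gap 12 μm, L_Forward = L_Backward 40 μm) for the
500 mGy mean and CV-exponent checks, whose self-calibrated sampling is
geometry-insensitive; and a 20 000-trial library at the full geometry
(R_Score 278 μm, L 80 μm) for hit-composition statistics (hit fraction,
low-dose realization shape), which do not survive geometry reduction.

## What the synthetic data do and do not show

The surrogate generator reproduces the calibrated near-field observables
(LET, mean ED/voxel, 100 nm containment and occupancy, the Fe high-ED voxel
hump) and a physically shaped mid/far field, but its far field is only
constrained indirectly: the fraction of energy carried beyond ~150 μm is
~9–11 %, giving electronic-equilibrium capture ratios of ~0.83–0.95
depending on the library realization (capture estimates are heavy-tail
noisy: single soma core-crossings carry MeV-scale deposits). Full
track-structure transport yields somewhat deeper equilibrium deficits;
statistics that depend on the fluence at fixed neuron dose (e.g. the
fraction of 10 mGy realizations below 2 mGy, measured here at ~0.37–0.46
across library seeds) inherit that sensitivity. The synthetic morphology
matches the reference granule cell's aggregate morphometry, not its actual
branch geometry; per-branch dose patterns are therefore illustrative only.
Bragg-peak (stopping) transport, nuclear fragmentation, radiochemistry and
any biological response model are out of scope.
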