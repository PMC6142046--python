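# Methods

## Model overview and assumptions

A single mesenchymal cell (a fibroblast archetype) is reduced to a spherical
body of radius 10 um plus a set of one-dimensional protrusions radiating
from its centre. Three mechanisms run on two clocks:

* **Chemistry (seconds).** The RTK/PI3K network is well mixed at the
  whole-cell level; the chemoattractant concentration [F] enters as an
  external parameter, constant within each 5-min epoch (ligand depletion by
  the cell is neglected, and the extracellular profile is a fixed linear
  field, clamped at zero). Receptor binding (R1/R2) and the PI3K
  activation cycle (R3/R4) conserve RTK + RTKF = 4275 and
  PI3K + PI3K_A = 75,000 exactly.
* **Mechanics (minutes).** Every dt = 5 min the accumulated signal drives
  protrusion birth/growth/death and the cell translocates. 48 steps cover
  the 4-h horizon, matching a 5-min imaging cadence (49 checkpoints).

## Stochastic steppers

`ssa_step` is the exact Gillespie direct method. `tau_leap_step` fires
Poisson(a_j tau) counts per reaction. The leap tau comes from a bounded
relative-change criterion: for each species the drift |mu_i| tau and the
diffusion sigma_i^2 tau are held below eps * max(x_i, 1) (and its square),
with eps = 0.03; the bound is linear in eps so the candidate vanishes as
eps -> 0. The candidate is then clamped to the operating range
[0.5, 1.5] s, and the final sub-step of each 300-s epoch is truncated so
epochs tile exactly.

Negative excursions are handled by reject-and-halve: a draw that would make
any count negative is discarded and tau halved; below a floor of 1e-3 s the
(tiny) remaining sub-interval is simulated exactly by SSA. With the
published rate constants the binding pair is extremely stiff
(k1 [F] ~ 3.7e4 /s per free receptor at 50 nM), so this fallback fires on
roughly every other leap; the exact/approximate interleaving preserves
nonnegativity and the conservation laws without binomial corrections.

The simulator's hot path uses a numba-compiled twin of the same loop
(`_kernels.advance_window`), seeded per epoch from the run's seed sequence;
the pure-Python path in `chemistry.py` is the reference contract and the
two are compared distributionally in the tests. The deterministic
mass-action ODE (`ode_limit`) is used only as a test oracle; its closed-form
steady state is RTKF* = R_tot k1[F]/(k1[F]+k2) and
PI3KA* = P_tot k3 RTKF*/(k3 RTKF* + k4).

## Membrane signal

The membrane is flattened onto a regular 72x36 chart in (alpha, beta) —
periodic in alpha, pole-to-pole in beta — following the flat-chart
simplification of the model; metric distortion is not corrected beyond
sin(beta) area weights. Each epoch's R3 firings are allocated to sites with
probability proportional to local [F] times site area (inverse-CDF
sampling; the bulk path draws the aggregated multinomial, which has the
identical joint distribution). The event map is smoothed with an isotropic
Gaussian kernel, sigma = 2 grid sites by default, chosen so the footprint
is roughly a protrusion cross-section on the default grid; the kernel is
normalised, wrapped in alpha and mirrored at the beta poles so no mass is
lost. Epoch fields accumulate into the monotone persistence signal `s`, and
a separate delta-s buffer collects everything since the last mechanical
step.

Candidate protrusion sites are the 8-connected components (periodic in
alpha) of the binary map `s >= s_binary`, one centroid per component
(area-weighted mean, circular in alpha). Degenerate components that wrap
(almost) the whole sphere have no defined circular mean — their resultant
vector vanishes and an arctangent of the cancellation residue would pick a
fixed, biased direction; such components fall back to their peak-signal
site, which restores statistical isotropy under uniform fields and matches
the model's reading of centroids as signal peaks.

## Protrusion mechanics

The free strain law is read as the saturating ratio
`eps_f = alpha ds / (||p|| (beta + ds))`, so the free length increment
`alpha ds/(beta + ds)` is bounded by alpha (0.14 mm for expansion, 0.05 mm
for retraction, calibrated). The typeset product form diverges with the
calibrated beta values and produces unphysical kilometre-scale increments;
the ratio is the only biologically sized reading, and it is isolated in
`free_strain` so alternatives can be swapped. delta-s for a protrusion is
integrated over its component (area-weighted mean times component area).

Signal gating per mechanical step: a component whose signal exceeds
`s_birth` and which contains no live protrusion sprouts a new one
(components already hosting a protrusion reinforce it instead of
double-creating); a live protrusion reinforces above `s_exp`, holds between
`s_ret` and `s_exp` (retracting only if its delta-s is negative, which
cannot occur while deposits are nonnegative — the retraction law is
exercised by tests and available to alternative deposit conventions), and
dies below `s_ret` (equality survives). Death is permanent; a later birth
at the same centroid is a new protrusion.

The ECM constraint treats the protrusion as a prolate spheroidal inclusion
(long axis = length, diameter 2 um, aspect ratio floored just above 1) in
an infinite isotropic matrix. The Eshelby tensor is evaluated from the
closed-form spheroid I-integrals and assembled in 6x6 Voigt
(engineering-shear) form; the constrained strain is the literal bracket
`S [(C_I - C_M) S + C_M]^{-1} C_I eps_f` and the axial component feeds the
1D length update `(1 + eps_EXP + eps_RET) ||p||`, floored at zero. Strains
are capped at |eps| <= 1 per step to stay in the infinitesimal-deformation
regime. Newborn protrusions seed at the Eshelby-constrained free increment
(near-spherical inclusion), keeping them on the same mechanical footing as
one growth step. A useful emergent feature: as a protrusion elongates its
aspect ratio grows, the axial constraint factor falls, and growth
self-limits.

## Translocation

Only the longest live protrusion adheres (ties: earliest birth, then lowest
id). Its traction `alpha_adhesion ||p_lp||` balances Stokes drag
`6 pi r eta v` through the fluid phase of the matrix, so
`v = alpha_adhesion p_lp / (6 pi r eta)`; with alpha_adhesion in pN/um,
r in um and eta in Pa s (1 Pa = 1 pN/um^2) the ratio is directly in um/s.
Position advances by explicit Euler at dt = 5 min — velocity is piecewise
constant between mechanical steps, so a higher-order integrator would add
nothing. Non-leading protrusions exert no net force.

## Parameter defaults and units

| parameter | default | unit | origin |
|---|---|---|---|
| k1, k2, k3, k4 | 735, 0.01, 4e-4, 1 | nM^-1 s^-1, s^-1, per pair s^-1, s^-1 | published kinetics (literal) |
| initial counts | 4275 RTK, 75,000 PI3K | molecules | published |
| tau range / eps / floor | [0.5, 1.5] / 0.03 / 1e-3 | s / - / s | published range; leap control here |
| s_birth, s_exp, s_ret, s_binary | 85, 76, 0, 62500 | signal units | calibrated values |
| alpha_exp, beta_exp, alpha_ret, beta_ret | 0.14, 100, 0.05, 54.86 | mm, -, mm, - | calibrated values |
| E_protrusion / E_matrix | 1e7 / 1e4 | Pa | calibrated / 2 mg/ml collagen |
| nu (both) | 0.3 | - | unprinted; common soft-tissue choice |
| protrusion diameter | 2 | um | unprinted; dendritic cross-section |
| cell radius | 10 | um | unprinted; fibroblast body scale |
| eta | 7.5 | Pa s | unprinted; collagen-gel viscosity scale |
| alpha_adhesion | 1 | pN/um | unprinted; sets the speed scale |
| grid | 72x36 (reduced: 36x18) | sites | resolution/runtime balance |
| kernel sigma | 2 | sites | protrusion-section footprint |
| calibration medium | 0.05 uM, zero gradient | - | "very low, fixed" growth medium |

All unprinted constants are config-exposed; the calibrated behaviour can
depend on them jointly with the nine calibrated parameters.

## Calibration

Checkpoint observations pool into fixed histograms: 20-um llp bins over
[0, 200] with overflow folded into the last bin (zero lengths count in the
first bin) and unit np bins over [0, 20]. Each parametrization is scored by
one simulation per seed of a fixed, shared 20-seed set (reducing comparison
noise across parametrizations); per-seed Bhattacharyya coefficients against
the targets are averaged per feature (a pooled-histogram variant sits
behind a flag). Invalid threshold orderings are rejected before any
simulation is spent; out-of-range values raise a distinct error.

The proposal loop fits independent Matern-5/2 Gaussian processes (with a
small white-noise term, unit-cube encoding of the mixed space: log grid for
the modulus, integer thresholds, arithmetic s_binary grid) to each metric,
draws a fresh random scalarization weight each iteration, and maximises
expected improvement over a batch of validity-passing random candidates.
The first 10 points are space-filling draws. The final selection is the
Pareto point maximising min(BC_llp, BC_np), ties broken by the sum — a
concrete reading of "balanced" selection.

## Synthetic targets

Raw single-cell quantifications are not available, so targets emulate the
printed summaries: llp from a normal truncated to (0, 140] um whose
truncated mean/sd equal 63.71/31.20 um (location and scale solved
numerically — using the printed moments directly would bias the truncated
mean by ~+0.95 um); np from the maximum-entropy distribution on 1..14
matching mean 7.57 and sd 3.27 (an exponential family in k and k^2).
The default sample size of 10,000 keeps target sampling noise well below
simulation noise; the real experiment pooled ~196 observations from four
cells. The generator reproduces moments and supports, not the skewed shape
of the real length histogram (its mode sits in the 60-80 um bin rather than
the reported 40-60 um) and none of the temporal autocorrelation,
cell-to-cell heterogeneity, or measurement error of real microscopy — tests
that pass against these targets validate the pipeline, not the biology.

## Numerical choices

* Seeding: a master seed feeds `numpy.random.SeedSequence`; per-simulation
  streams are keyed by (master, index) so ensembles are order-independent,
  and per-epoch chemistry seeds derive from the per-simulation sequence.
  Fixed (config, seed) reproduces trajectories bit-for-bit.
* Histograms are right-open at the top only through overflow folding;
  Bhattacharyya requires identical edges and rejects mismatches.
* The Eshelby bracket is solved with a dense 6x6 `solve`; admissible moduli
  keep it well conditioned (singularity raises rather than silently
  degrading). Aspect ratios within 1e-7 of a sphere use the exact sphere
  integrals to avoid cancellation.
* Degenerate inputs: all-zero sampling weights with pending events, empty
  histograms, grid mismatches, invalid threshold orderings and
  out-of-range parameters all raise typed errors.

## Problem sizes used by the test suite

The suite runs the full published operating conditions where they are
cheap (20-seed ensembles, 49 checkpoints, full 72x36 grid for the headline
statistics) and the 36x18 reduced grid for the chemotaxis sweeps and the
calibration self-recovery experiment; kinetics cross-checks use 1/100-scaled
copy numbers where an exact-SSA oracle is involved, and full counts for the
deterministic-limit check. The self-recovery experiment stops a repeat's
search once the recovery criterion is attained, since further evaluations
cannot change the outcome.

## Known limitations

* **Scale tension inherited from the source model.** The literal kinetic
  constants put the steady-state PI3K activation flux near 4.7e4 events/s,
  which matches the calibrated `s_binary` scale (~6e4 is crossed mid-run)
  but leaves the [0, 100]-ranged thresholds `s_birth`/`s_exp`/`s_ret`
  saturated (any thresholded component carries s >> 100) and drives the
  strain law deep into saturation. Consequently the calibrated
  parametrization grows one giant, millimetre-scale leading protrusion in a
  uniform medium instead of the reported handful of ~60-um protrusions; no
  alternative unit reading reconciles both threshold scales (the
  pseudo-first-order reading of k3 fits the [0, 100] scale but makes
  `s_binary` unreachable and the model inert). The implementation keeps the
  literal constants and exposes every unit choice in config.
* The ECM is isotropic, homogeneous, and un-remodelled; protrusions do not
  branch, and only one cell is simulated.
* The flat-chart convolution ignores metric distortion near the poles
  beyond area weighting and pole reflection.
* GP surrogates treat the integer/grid dimensions as continuous in the
  unit cube; proposals are snapped back to the grids.
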