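# Methods

## Model

The package implements a deterministic ODE model of acute HPA-axis
dynamics with nine state variables: CRH (`C`), ACTH (`A`), free plasma GC
(`O`), the GC–GR and GC–MR complexes (`O_G`, `O_M`), free receptors (`G`,
`M`), and an exogenous GR ligand with its complex (`D`, `D_G`) carrying
dexamethasone challenges. The axis input is `p(t) = B + b·α·e^(−αt)`: a
constant basal demand `B` plus an acute stressor of total integrated
magnitude `b` decaying at rate `α`. Production is linear down the cascade
(`k_A`, `k_O`), clearance first-order (`b_C`, `b_A`, `b_O`), and receptor
binding mass-action (`k_G`, `k_−G`, `k_M`, `k_−M`). Receptor-bound GC
(and receptor-bound DEX) feeds back negatively on CRH and ACTH
production with a common strength `k_fb` (individual terms overridable).

Assumptions worth stating explicitly:

* feedback is proportional to *occupancy*, not to free hormone, so its
  leverage saturates together with the receptors;
* MR is the high-affinity receptor (`K_M = k_−M/k_M << K_G`), so MR
  occupancy is nearly constant across the acute range and GR dominates
  the stress-dependent part of the feedback — a parameter set violating
  this ordering triggers a validation warning, not an error;
* binding is simulated kinetically (the complexes are state variables);
  the closed-form equilibrium curve `R·O/(O+K)` is exposed separately,
  serves as a stationarity oracle in the tests, and defines the
  "physiological response magnitude" readout (peak GC–GR occupancy);
* observed plasma GC maps one-to-one onto model `O` (no observation-scale
  parameter); all times are minutes, concentrations are model units read
  as ng/ml;
* no circadian/ultradian baseline, no CBG or pre-receptor metabolism, no
  adrenal self-inhibition or hippocampal input, one GR pool (no
  tissue-specific expression).

## Default parameters

The defaults were chosen once to yield a realistic songbird-like
corticosterone stress series and are used as the reference condition in
every analysis and test:

| parameter | value | meaning |
|---|---|---|
| B | 0.35 | basal demand (keeps baseline GC ≈ 5 ng/ml) |
| b | 5.0 | stressor intensity (stress-induced GC ≈ 12 ng/ml at 25 min) |
| α | 0.08 /min | stressor decay (acute phase over ~30–40 min) |
| b_C, b_A | 0.2, 0.15 /min | CRH/ACTH clearance (minutes-scale half-lives) |
| b_O | 0.09 /min | GC clearance (half-life ≈ 8 min) |
| k_A, k_O | 0.6, 1.0 /min | cascade production gains |
| k_fb | 0.1 | feedback strength (all four terms equal) |
| k_G, k_−G | 0.02, 0.6 | GR kinetics, K_G = 30 (GR sub-saturated at stress levels) |
| k_M, k_−M | 0.1, 0.15 | MR kinetics, K_M = 1.5 (MR near-saturated at baseline) |
| G_tot, M_tot | 6, 2 | receptor pools |
| b_D | 0.02 /min | DEX clearance (half-life ≈ 35 min, see below) |

Default challenge protocol: DEX bolus (15 units) at minute 30, ACTH bolus
(60 units) at minute 80; sampling classes read at 1.5 / 25 / 70 / 100 min
within the protocol windows 0–3, 20–30, 60–80 and 100 min.

Two quantitative targets guided the calibration: the four class levels
must order post-ACTH > stress-induced > post-DEX-suppressed relative to
their controls, and GR occupancy must be far from saturation at stress
levels (O ≈ K_G/2) while the post-ACTH excursion saturates it — this
separation is what makes the GC-vs-GR slope steepest for the post-ACTH
class and weakest at baseline. With K_G comparable to stress-induced GC
and a large ACTH bolus, that ordering is robust across a 10-fold GR
range.

### Why DEX gets its own clearance rate

Treating DEX exactly like GC (clearance `b_O`) empties the bolus within
~20 minutes; worse, its transient GR occupancy *displaces* endogenous GC
from the receptor, so measured GC in the 60–80 min window can sit *above*
the no-DEX control — the suppression probe fails to suppress. Real
dexamethasone persists for hours; with `b_D = 0.02`/min the bolus holds
GR occupancy (and hence feedback) through the sampling window and
measured GC stays clearly below the no-DEX trajectory, which is the whole
point of the test. Setting `b_D = None` restores GC-like clearance.

## Numerics

* **Trajectories** integrate with LSODA (`solve_ivp`, rtol 1e-8, atol
  1e-10) from the baseline steady state, hard-restarting at each bolus so
  the discontinuity is exact (the event log stores before/after states).
  Output grid 0.1 min, linear interpolation between stored points.
* **Baseline steady state** reduces, at rest, to one scalar equation in
  free GC (complexes on their equilibrium curves, CRH/ACTH from
  production–degradation balance floored at zero); it is bracketed and
  solved by Brent's method and verified against the full RHS (residual
  norm < 1e-8).
* **Non-negativity.** Feedback can formally push CRH/ACTH production
  negative. A hard derivative cutoff at zero makes the RHS discontinuous
  and stalls LSODA in a sliding mode, so negative derivatives of the
  non-conserved species fade out linearly over a thin band (1e-4
  concentration units ≈ 1e-5 of typical levels); above the band the
  equations are untouched. Free receptors and complexes are structurally
  non-negative and are left alone, which keeps the receptor conservation
  sums exact in floating point (the free-receptor derivatives are
  computed as negated complex sums).
* **Likelihood hot path.** Fitting evaluates GC only at observation times
  via segment-wise `odeint` (rtol 1e-6) with a numba-compiled RHS
  (~3 ms per evaluation; a pure-Python fallback keeps the package
  functional without numba). Integration failures in pathological
  parameter regions return +inf so the simplex retreats.
* **Optimization.** Nelder–Mead on log-transformed parameters (positivity
  by construction; optional boxes via a logistic transform), standard
  coefficients, adaptive variant beyond 4 free parameters, maxiter 5000.
  Termination tolerance defaults to 1e-5 on both simplex spread and
  function values: the likelihood inherits ~1e-5-scale solver noise, so
  tighter tolerances spend the full iteration budget without changing
  estimates (verified: identical log-likelihood to 4 decimals).
  Multi-start jitters the transformed start with seeded Gaussian noise;
  fits are bit-reproducible for a fixed seed.
* **Verification integrator.** A deliberately simple fixed-step RK4
  (`integrate_rk4`) cross-checks the adaptive solution; at dt = 0.001 min
  the two agree to ~5e-9 relative sup-norm on GC for the default
  scenario.

## Fitting

The likelihood is iid Gaussian on raw GC with the residual variance
profiled at its MLE (`σ̂² = RSS/n`); a log-scale residual option exists
for right-skewed data, and a fixed-σ mode for diagnostics. Four timepoint
classes cannot identify the full 15-parameter model, so the default mask
frees a parsimonious, well-separated quartet — `b`, `k_O`, `b_O`,
`G_tot` — with data-driven starting values (`visual_start`): production
scaled to the baseline mean (scale-equivariant), stressor intensity from
the relative stress contrast, clearance from the log-decline between the
stress-induced and post-DEX class means. The deliberately rich
`ParameterMask.protocol()` mask (all rates + receptor totals) is provided
but flagged as unidentifiable on sparse designs. `fit_individual_gr`
fixes all shared kinetics and frees `G_tot` per individual — the analysis
that infers receptor abundance when only GC profiles are measurable.
Whether one fits pooled class profiles or individuals is left to the
caller; both paths are supported and tested.

## Synthetic populations

`generate_population` emulates field stress-series data: individuals draw
`G_tot` from a log-normal (median = reference value, CV 0.5 by default —
right-skewed like real expression data; optionally also `b`), sampling
times jitter uniformly within the class windows, and measurements carry
mean-one multiplicative log-normal noise (CV 0.10 default; Gaussian
option). A `gr_expression` covariate is emitted as true `G_tot` times an
independent log-normal factor (CV 0.20), so tests of observed
GC-vs-expression relations face realistic attenuation rather than the
noiseless truth. What the generator does *not* emulate: assay-specific
error structure, circadian sampling confounds, repeated captures, or
among-individual variation in any kinetic rate — passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to real-world model violation.

The packaged example dataset is 12 individuals × 4 classes generated with
seed 1234; regeneration is bit-identical to the shipped CSV.

## Analysis conventions

* GR sweeps use a 9-point log-spaced grid over a 10-fold range around the
  reference `G_tot`; stressor sweeps a 6-point log-spaced grid over an
  8-fold range of `b` (no printed grid exists to inherit, so round
  log-spaced designs were chosen once).
* Concavity of response range vs `b` is assessed on divided differences
  (slopes between adjacent grid points): on a geometric grid, raw second
  differences of the values would conflate curvature with grid spacing.
* The saturation (endocrine-flexibility) index is the ratio of the
  response range at the highest to the mid-grid stressor intensity; it
  equals `b_high/b_mid` in the linear regime and approaches 1 at
  saturation.
* Associations are summarized by Spearman rank correlation (the relations
  are monotone but strongly nonlinear); Pearson is reported alongside.
  Degenerate (zero-variance) inputs yield explicitly flagged missing
  correlations rather than errors.
* The association analysis simulates pure stressor responses (no
  boluses) at t = 0, 30, 120 min over a 180-min horizon, by which time
  the default dynamics have returned near baseline, making the 120-min
  sample a genuine recovery level.

## Problem sizes used in the shipped checks

The acceptance script and test suite run, per invocation: a 5×5
(free-GC × GR) equilibrium grid; four conserved 180-min trajectories; the
9-point GR sweep and 9×6 GR×stressor sweep; a 200-individual association
draw; one 180-min RK4 run at dt = 0.001; and a recovery study of 20
seeded replicates (populations of 30 individuals × 4 classes, 5%
measurement noise, free `G_tot`/`k_O`/`b_O`, starts displaced from truth
via `visual_start` plus a 1.6× GR offset), with additional noise levels
1.25% and 2.5% in the test suite to exhibit the error-vs-noise trend.

## Known limitations

* The feedback terms act directly (and linearly) on production; there is
  no production floor other than the non-negativity treatment, and no
  saturation of the stimulus itself.
* Parameter estimates from four-class designs are conditional on the
  fixed kinetics of the mask; freeing more parameters degrades
  identifiability quickly (flagged, not forbidden).
* Pooled fits to heterogeneous populations return effective-average
  parameters that are not the median of the individual truths (nonlinear
  averaging); per-individual GR fits avoid this at the cost of shared
  kinetics being assumed known.
* DEX pharmacology is reduced to "GR ligand with slow clearance and GC
  potency"; potency differences and MR cross-binding are not modelled.
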