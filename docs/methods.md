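# Methods

## Model

titrofit fits reference-subtracted titration sensorgrams to the 1:1
Langmuir interaction model. For cycle *i* at analyte concentration
*C_i* the association phase relaxes toward its plateau with observed
rate k_obs = k_a·C_i + k_d,

    R(t) = Rshift_i + Rmax_i · occ_i · (1 − e^{−k_obs (t − t0_i)}),
    occ_i = k_a C_i / (k_a C_i + k_d),

and the dissociation phase decays mono-exponentially at k_d from the
response reached at the association end t_asso. Two algebraic forms of
the dissociation drift term exist: an additive form, in which the drift
amplitude persists as a constant floor, and an amplitude-scaled form,
in which (Rmax_i + Rdrift_i) replaces Rmax_i so the drift decays with
the signal. The package fits the amplitude-scaled form — the additive
form is retained (`eval_dissociation_legacy`) for comparison only,
because a persistent floor trades off directly against slow k_d values
and destabilizes the fit. With Rdrift_i = 0 the two forms coincide
exactly, which the test suite asserts.

Assumptions inherited from the model: pseudo-first-order binding (free
analyte concentration constant within a cycle), a homogeneous 1:1
surface, no mass-transport limitation, and upstream reference
subtraction/smoothing. Bivalent, heterogeneous, two-state and
steady-state (R_eq) analyses are out of scope.

### Non-regenerative (single-cycle) titrations

Without regeneration, cycle *i* starts from the response left over by
cycle *i−1*. Rather than adding an explicit carry-over term, the
association start time t0_i is floated per cycle as the extrapolated
time at which the response would have been zero; the shifted exponential
then passes through the carried response at the actual injection start.
t0_i is bounded to [t0 − 10·(t_asso − t0), t0]: the extrapolated
zero-response time cannot postdate the injection start, and ten
association lengths is a loose, stability-oriented lower bound.

## Parameters

| parameter | units | fixed/floated | default/role |
|---|---|---|---|
| C_i | M | fixed | from the sample sheet (assay design) |
| t0, t_asso | s | fixed | from phase lengths in the sample sheet |
| k_a | M⁻¹s⁻¹ | floated (log10) | association rate constant |
| k_d | s⁻¹ | floated (log10) | dissociation rate constant |
| Rmax or Rmax_i | response units | floated | global (shared) or local (per cycle) |
| Rshift_i | response units | optional | bulk shift, association only |
| Rdrift_i | response units | optional | dissociation-onset drift; dropped if Rshift_i is fitted |
| t0_i | s | floated iff non-regenerative | extrapolated zero-response time |

Rates are carried in log10 inside the optimization vector, enforcing
positivity and conditioning the span of decades encountered in practice
(k_a ~ 10³–10⁶, k_d ~ 10⁻⁵–10⁻²). Reported rate standard errors are
delta-method transforms of the log-space errors,
SE = ln(10)·value·SE_log10.

## Preprocessing pipeline

Steps run in this order; each is a pure series-to-series function.

1. **Baseline alignment.** Regenerative: each cycle is shifted so its
   baseline-window mean ([baseline_start, t0)) is zero. Non-regenerative:
   cycle 1 is zeroed the same way; each later cycle is shifted so its
   baseline mean equals the mean of the final 5 s of the previous
   cycle's dissociation. The 5 s terminal anchor is this package's
   choice: a short window is robust to noise while standing close to the
   junction. The operation is idempotent, and the junction statistic it
   controls (baseline mean minus previous tail mean) is driven below
   1e-9 even when step artifacts are injected between cycles. Note the
   simulator's output is already aligned by construction; alignment
   exists for instrument exports with arbitrary per-cycle offsets, and
   re-aligning a decaying baseline moves the data slightly (the baseline
   mean of a decaying carry-over differs from the 5 s tail mean by the
   decay over the baseline, ~1% at k_d = 1e-4 and 120 s).
2. **Blank subtraction** (optional, when a zero-concentration cycle is
   listed): the blank response at the same cycle-relative time (t − t0)
   is subtracted pointwise, with linear interpolation between blank
   samples; the blank must cover each cycle's time span.
3. **Thinning** to a target rate (default 1 Hz) keeps the first point of
   each 1/rate bin from the cycle's first timestamp — thinning, not
   smoothing; it never upsamples and never reorders.
4. **Down-selection.** After sorting concentrations ascending, at most
   five are fitted. Auto mode picks, among all windows of five
   consecutive sorted concentrations, the one with the largest
   accumulated increase of end-of-association response, computed as
   E_last − E_first of the window (identical to the sum of successive
   increments; a sum-of-positive-increments reading would differ only
   for non-monotone E). Ties go to the lowest-concentration window.
   End-of-association response is the last observed point of the
   association window, not a fitted plateau. Manual mode takes the
   user's ≤ 5 concentrations verbatim.
5. **Window extraction**: association keeps t0 + skip_assoc ≤ t ≤
   t_asso; dissociation keeps t_asso + skip_dissoc ≤ t ≤ t_asso +
   dissoc_fit_len, strictly after t_asso so the shared boundary point is
   fitted once.

## Estimation

All selected cycles are fitted jointly: the residual vector pools every
association and dissociation point, unweighted, and
`scipy.optimize.least_squares` (trust-region reflective, numeric
Jacobian, ftol = xtol = gtol = 1e-10, ≤ 2000 evaluations) minimizes the
sum of squares. Initialization is deterministic: k_d is seeded from the
log-linear slope of the last half of the highest-concentration
dissociation window (floored at 1e-6 s⁻¹), k_a from a coarse grid over
log10 k_a ∈ {2,…,7} with the amplitude solved linearly at each node
(variable projection), Rmax at 1.5× the largest observed response, and —
for non-regenerative series — each t0_i from the closed-form inversion
of the association equation at the cycle's first observed window
response, which places heavily accumulated late cycles inside their
basin of attraction. No randomness anywhere in the fit: identical inputs
yield bit-identical estimates, which the batch-level byte-identity test
asserts.

Standard errors use the standard linearized covariance at the optimum,
cov = (rss/dof)·(JᵀJ)⁻¹ with dof = n_points − n_floated_parameters (the
conventional choice). A rank-deficient JᵀJ — an over-parameterized
variant — yields SEs flagged as unavailable rather than fabricated
numbers. K_D = k_d/k_a inherits ΔK_D = K_D·√((Δk_a/k_a)² + (Δk_d/k_d)²).
Non-convergence is a reportable outcome (flagged row and report page),
never an exception, so batch runs complete.

One caveat on published comparisons: when reproducing tabulated ΔK_D
values from tabulated 3-significant-digit inputs, the printed error
column follows from the *rounded* K_D; `propagate_kd` itself always
propagates at full precision, and the acceptance script applies the
rounding chain only where it reproduces printed table entries.

Replicate QC (`summarize_replicates`) reports, per parameter, the
arithmetic mean, %CV = 100·sd/mean with the sample (n−1) standard
deviation, fold = max/min, and each replicate's relative SE — all on the
linear-scale estimates, not on logs.

## Simulator

`simulate_series` generates titrations directly from the model
equations: regenerative cycles each rise from a zero baseline;
non-regenerative cycles continue the previous cycle's decay through the
baseline and absorb the carried response by solving the association
equation for t0_i — exactly the mechanism the fit uses, so noise-free
data are exactly representable and simulate→fit round trips recover the
generating parameters to numerical precision (the headline recovery
check requires 0.1%). Defaults mirror a typical high-throughput SPRi
acquisition: 120 s baseline, 300 s association, 750 s dissociation,
0.5 Hz sampling, eight two-fold dilutions topping at 1 µM, k_a = 1e5
M⁻¹s⁻¹, k_d = 1e-4 s⁻¹, Rmax = 100 RU.

Noise is i.i.d. Gaussian per point with a seeded generator. What the
simulator does **not** emulate — autocorrelated drift, spikes and air
bubbles, mass-transport limitation, heterogeneous surfaces, imperfect
reference subtraction — bounds what passing tests show: they validate
the estimation machinery on model-faithful data, not robustness to
instrument artifacts on real sensorgrams.

## Numerical and design choices

* Scale of the shipped checks: the recovery and coverage experiments use
  the default 8-concentration, 0.5 Hz series (2625 fitted points over
  five selected cycles); the coverage experiment runs 100 seeded noisy
  replicates at σ = 1 RU and requires the estimate ± 3·SE interval to
  contain the true k_a and k_d in ≥ 99% of them.
* Platform adapters target the described export *shapes* (one file, one
  time column, many response columns), not byte-level vendor formats.
  The Carterra adapter splits each spot's stitched trace into as many
  equal-duration cycles as the sheet lists concentrations; Biacore/Octet
  adapters map response columns to cycles in sheet order, and the same
  file may appear under several sheet entries with different analysis
  preferences.
* Whether t_asso may differ per cycle is left open by convention;
  per-cycle schedules are supported throughout since instrument
  schedules can vary.
* Empty cells in exports are dropped per point, never imputed; delimiter
  auto-detection covers comma/tab/semicolon with decimal points only.
* The estimates CSV carries 12 significant digits so write→read round
  trips preserve numeric fields; displayed report numbers are the same
  values at display precision.

## Known limitations

Only the 1:1 model is implemented; systematic deviations (biphasic
dissociation, mass transport) must be judged from the residual panel.
Steady-state (dose-response plateau) affinity estimation is not
implemented. Standard errors are asymptotic linearized values, not
profile or bootstrap intervals, and different vendor packages use
different (often undocumented) SE conventions — cross-software SE
comparisons are indicative only.
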