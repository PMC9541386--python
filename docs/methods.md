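# Methods

This note records the modelling assumptions, parameter defaults, numerical
choices and known limitations of `mphpk`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The convolution model

Plasma kinetics are described by a one-compartment disposition driven by a
parametric in vivo input:

    dA/dt = Dose · f(t − t_admin) − kel · A,   A(t_admin) = 0,
    C(t)  = A(t) / vd_f · 1000   (mg/L → ng/mL)

with `f = dr/dt` the derivative of a cumulative release function `r`.
Assumptions: linear first-order elimination, no distribution compartments,
no enterohepatic recirculation, and a release function that is the sole
source of absorption delay. Because the observed data are concentrations
while the model propagates amounts, one apparent volume `vd_f` (V/F)
converts between them; bioavailability and volume are confounded in this
structure, so `vd_f` doubles as the amplitude/bioavailability scale and no
separate F is identifiable.

Two release families are provided.

* **Sigmoid (Hill)**: `r(t) = t^ga / (EC^ga + t^ga)`. `EC` (h) is the time
  to release half the dose — `r(EC) = 0.5` holds exactly for every valid
  parameter pair and is asserted as a property test. `ga` (dimensionless)
  controls steepness. A form of this function that *decreases* from 1 to 0
  cannot be a cumulative released fraction, so the increasing Hill form is
  the one implemented. The Hill tail is a power law, `1 − r ≈ (EC/t)^ga`,
  which is what makes the apparent terminal half-life grow for late, shallow
  release (flip-flop kinetics) even at fixed `kel`.
* **Double Weibull**: `r(t) = ff·(1 − exp(−(t/td1)^ss1)) + (1−ff)·(1 −
  exp(−(t/td2)^ss2))` — the standard two-process input for biphasic
  absorption. The packaged illustration (`default_biphasic_params`: ff 0.22,
  td1 0.7 h, ss1 1.2, td2 9 h, ss2 2.5) produces an early fast process plus
  a slower process centred near 7 h, i.e. two well-separated input-rate
  maxima; it is an illustration, not an estimate from any dataset, and users
  comparing against a real osmotic product should supply published parameter
  values.

Input rates are computed analytically, not by numeric differentiation; for
the Hill family `dr/dt = (ga/t)·r·(1 − r)` is used, which stays accurate
near t = 0 where shape parameters below 1 make the rate diverge (the limit
is returned as `inf`; the ODE path never evaluates it, see below).

## Numerical choices

* ODE integration: `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8,
  atol 1e-10. Integration starts at t = 1e-6 h after dosing with the
  already-released amount as the initial state, which sidesteps input rates
  that diverge at exactly t = 0. Against an adaptive-quadrature convolution
  oracle the solution agrees to better than 1e-6 relative at step endpoints
  and to ~1e-8 on dense interpolated grids (both tested).
* Metric extraction uses a dense grid of 0.05 h spanning the release median
  plus 8 elimination half-lives by default; a grid coarser than 0.25 h logs
  a warning but still returns metrics. AUC0-∞ is the grid trapezoid plus the
  exponential tail `Clast/kel`; for heavy-tailed (low `ga`) inputs this tail
  mirrors the same convention NCA applies to data and slightly understates
  the true integral.
* tmax ties on a grid resolve to the earliest time, matching the NCA
  convention.
* Windowed AUC interpolates linearly at the window endpoints.

## NCA conventions

* **BLQ rules** (positional): missing predose values and BLQ values before
  the first quantifiable concentration are set to 0; BLQ values after the
  first quantifiable concentration, and missing postdose values wherever
  they fall, are excluded from all downstream computation. "Quantifiable"
  means an observed value > 0. These substitutions happen at analysis time,
  never at parse time — the CSV layer preserves BLQ and missing markers
  verbatim so the rules always see original positions.
* **AUC**: linear trapezoid throughout (not lin-up/log-down): the simplest
  auditable default, and consistent with every closed-form check in the
  suite. Excluded points are bridged by their neighbours. The predose sample
  (nominal t ≤ 0) anchors the curve at t = 0.
* **λz**: ordinary log-linear regression over candidate terminal sets — all
  runs of ≥ 3 consecutive quantifiable points strictly after tmax ending at
  the last quantifiable point. The set maximizing adjusted R² wins;
  near-ties (1e-10) prefer more points, then a later start. Negative-slope
  candidates only; if none exists λz, t½ and AUC0-∞ are reported missing.
  This mirrors common NCA software behaviour while being fully specified.
* **Summaries**: arithmetic mean and CV% (100·SD/mean, SD with n−1) for
  Cmax and AUCs; median and range for tmax; mean and SD for t½. Groups with
  fewer than two evaluable subjects are excluded with a logged warning;
  non-evaluable subjects stay in the reported denominator.

## The synthetic cohort generator

The generator emulates a phase-1 three-way crossover in healthy adults:
n = 18, a single 100-mg dose per period, three formulations (SI, PC, DC)
in randomized period order, sampling at predose (−5 min) and 2, 4, 6-20
(hourly), 22, 24, 26, 36, 48 h post dose, and censoring of concentrations
below the 0.02 ng/mL LLOQ as BLQ markers.

* **Between-subject variability**: lognormal on EC, ga, kel and vd_f with a
  default CV of 0.25 each. One random effect per subject per parameter is
  drawn and *shared across formulations*, since a crossover administers all
  treatments to the same body; this induces the within-subject correlation
  that makes formulation contrasts far more stable than independent cohorts
  would be. The trial reports no variance components, so these CVs are this
  package's calibration: together with the residual error they reproduce
  observed-scale CVs in the high-20s to high-30s percent range (checked in
  the ordering panel).
* **Residual error**: combined proportional (0.10) + additive (0.01 ng/mL),
  floored at zero. The additive term exercises LLOQ censoring in the tails.
* **Typical values**: calibrated once by least squares — noise-free model
  curves sampled at the trial schedule were pushed through the package's own
  NCA and matched to the reported per-formulation summary statistics (Cmax,
  tmax, AUC0-∞, t½), with `kel` shared across formulations because the drug
  and subjects are the same and the half-life differences are
  absorption-driven. The frozen values (EC 7.33/10.37/13.06 h, ga
  7.68/4.99/3.73, vd_f 2573/3219/3838 L, kel 0.161 /h for SI/PC/DC) are
  calibration products of this package, not reported estimates; the source
  study publishes no fitted parameters. The fit is a compromise across
  twelve summary targets and lands within roughly 10% of each; the four
  qualitative orderings (Cmax ↓, tmax ↑, AUC ↓, t½ ↑ from SI → PC → DC) are
  reproduced on every seed of a fixed 10-seed panel and that panel is the
  tested contract.
* **What the generator does not emulate**: sampling-time deviations (actual
  = nominal), food and circadian effects, period or sequence effects,
  carryover (the 4-day washout is ≫ 5 half-lives, so none is simulated),
  dropout, and any covariate structure. Passing tests therefore demonstrate
  internal consistency of the pipeline under idealized trial conditions,
  not agreement with any individual-level real data.

## Model fitting

Mixed-effects (FOCE-I-style) estimation is out of scope; two fully
specified surrogates are provided. The **pooled** fit minimizes ordinary
(unweighted) least squares on the linear concentration scale over all
subjects' quantifiable records jointly; the **two-stage** fit estimates each
subject independently and summarizes with geometric means and geometric CVs.
Both optimize log-transformed parameters inside generous positive bounds
with `scipy.optimize.least_squares` (TRF), giving positivity by construction
and scale-free steps. Zeros substituted before the first quantifiable
concentration are data and enter the objective; excluded values do not. OLS
is the default because the residual model is otherwise unspecified; a
proportional-weighting option is exposed.

`least_squares` offers no per-iteration callback, so the recorded objective
trace holds every function evaluation (including finite-difference probes);
the convergence contract asserted in tests is that the final cost does not
exceed the initial cost and matches the trace minimum.

Verified recovery behaviour (both are tests): noise-free pooled fits recover
all four parameters to well under 0.1% from inits perturbed by ×1.5, and
across 20 seeded default cohorts the median relative bias of EC and kel
stays below 10%. The pooled estimate of `ga` is biased low under lognormal
heterogeneity — averaging sigmoid curves over a population flattens the
population-mean curve — which is an expected property of naive pooling, not
an optimizer defect; the two-stage route does not share it.

## Formulation comparison

Comparing a delayed-release bead with a conventional morning product aligns
*release* clocks: the delayed formulation is modelled as administered 4 h
earlier (offset −4 h) so both initial releases sit at t = 0. Synchronization
is a rigid time shift; Cmax, AUC and curve shape are untouched and only the
clock reference of tmax moves (tested). Dose restatement uses exact linear
scaling (value × dose_to/dose_from), which matches re-simulation to solver
tolerance. Percent differences follow pd(a, b) = 100·(a/b − 1); narrative
output rounds half-away-from-zero to integer percent, reports retain full
precision. The monophasic/biphasic contrast is operationalized as the count
of strict local maxima of the input rate on a 0.05-h grid with a 1e-9
plateau tolerance. The default comparison window runs from the synchronized
dose time to 24 h.

## Dissolution analysis

The three-stage media schedule (0.1 N HCl 0-2 h; pH 6.0 phosphate buffer
2-6 h; pH 7.2 6-24 h; 2-h sampling to 24 h) is carried as metadata only —
deliberately, nothing in the analysis keys off pH, encoding the finding that
release timing is a property of the delayed-release layer rather than of
reaching a pH threshold. Methylphenidate degrades at high pH, so cumulative
release is the pointwise sum of parent drug, erythro isomer and related
compound A. Release onset is the earliest sampling time whose corrected
release strictly exceeds a threshold, default 1.0% of label claim — chosen
because published onsets are read off figures without a numeric criterion,
and 1% sits above assay-noise scale while catching early release; onset is
monotone in the threshold (tested).

Packaged fixtures use lag-plus-Weibull kinetics, `release(t) = 100·(1 −
exp(−((t−lag)/td)^ss))` beyond the lag, with lags 5/7/9 h and scales
3/5/8 h for SI/PC/DC: onsets land at 6, 8 and 10 h on the 2-h grid and the
release rate orders SI > PC > DC. Released amount splits 97/2/1% across
parent/erythro/compound A — a fixed, arbitrary split that exercises the
correction arithmetic. Optional seeded noise (SD 0.2%) is clamped so the
corrected series stays within [0, 105]% and the onset sample never moves.
Only the onset pattern and qualitative rate ordering are emulated; the
fixtures do not reproduce any published numeric dissolution values.

## Problem sizes

Default test and acceptance workloads are sized for a single CPU: cohort
simulations use the full 18×3×22 design, the ordering panel runs 10 seeds,
and the stochastic recovery study runs 20 seeded cohorts with pooled fits
(~1.5 s each). The whole suite completes in about a minute.

## Known limitations

* One-compartment disposition only; no multi-compartment, nonlinear or
  recirculation kinetics.
* `vd_f` absorbs bioavailability, so absolute F is not identifiable and
  cross-formulation AUC differences appear as volume differences in the
  parameterization.
* Pooled fitting targets the population-average curve, biasing shape
  parameters under heterogeneity (see above).
* The double-Weibull comparator defaults are illustrative; quantitative
  comparison against a specific marketed product requires its published
  input parameters.
* No statistical bioequivalence machinery (LS-means ANOVA, 90% CIs on
  geometric mean ratios) — percent differences of summary metrics are
  descriptive only.
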