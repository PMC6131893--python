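# Methods

## Tracer-dilution model

The package treats ferumoxytol as an ideal intravascular tracer with
mono-exponential elimination.  Three assumptions matter:

1. **Fast mixing relative to sampling.** The agent is assumed uniformly
   distributed in plasma by the first fitted time point, so each T1 map
   reads out a single well-mixed concentration.
2. **Linear relaxivity.** `R1 = R1,∅ + r1·[CA]` holds over the working
   range; concentrations above ~1 mM are avoided in practice because
   relaxivity becomes nonlinear and T2* dephasing intrudes.  The default
   `r1 = 18 mM⁻¹ s⁻¹` is the in-blood value at 1.5 T; it scales the
   volume estimate linearly, so an inaccurate relaxivity biases volumes
   proportionally.
3. **Constant dose `n_Fe` during fitting.** The amount eliminated over
   the hour is expressed through `R1(t)` itself; the dose in the
   numerator of `V′(t) = r1·n_Fe/ΔR1(t)` is held at the injected value.

Units are fixed package-wide: T1 in ms, R1 in s⁻¹ (the 1000× conversion
lives only in `t1_to_r1`/`r1_to_t1`), times in minutes since the end of
infusion, τ in minutes, half-life reported in hours, volumes in liters
(ml/kg for weight-normalized values).

### The elimination fit

`DilutionModel.fit()` performs ordinary least squares of `log V′(t)`
against `t` (statsmodels OLS).  The default window is **20–60 min**:
in vivo the first ~20 min show a non-mono-exponential washout
(physiological response to the agent), so early points are excluded;
the window is a parameter.  Points whose T1 is not below baseline carry
no defined volume and are dropped; fewer than two usable points is an
error.  A non-positive fitted slope (apparent volume not growing) is
flagged via `positive_elimination=False` rather than raised, since
noisy short-window fits can legitimately produce it.  The plasma-volume
95% CI half-width is `1.96 × SE(intercept)` by the delta method
(`Var(exp a) ≈ exp(2a)·Var(a)`), reported as a fraction of V_plasma;
it is NaN for a saturated two-point fit.

### Error propagation

From `V′ = r1·n_Fe/(R1 − R1,∅)`, the relative-error amplification
factors are `R1/ΔR1` for the post-contrast T1 and `R1,∅/ΔR1` for the
baseline.  At the working point (230 ms post, 1600 ms baseline) these
are 1.168 and 0.168: a 4% post-contrast T1 error maps to a 4.7% volume
error, a 1% baseline error to only 0.17%.  This asymmetry is why a
single baseline measurement suffices while post-contrast precision
dominates.

## Saturation-recovery T1 fitting

The mapping scheme acquires an unsaturated "equilibrium" image plus
saturation-prepared images (8 each at 200 and 400 ms saturation time;
17 images total).  The two-parameter model `S = A(1 − e^(−TS/T1))`
treats the equilibrium image as TS = ∞ rather than fitting a third
parameter.  Initialization is deterministic (A from the equilibrium
signal, T1 from the closed-form single-point inversion), the optimizer
is bounded to T1 ∈ (1, 10⁴) ms, and replicate images enter as
independent points rather than being averaged (identical expectation,
honest residuals).  A series with equal signal at every distinct
saturation time is non-identifiable — any sufficiently small T1 fits —
and is flagged `converged=False` up front instead of returning the
arbitrary interior minimizer the optimizer happens to stop at.

## CO rebreathing reference

`V_blood = V_CO,eff · K · 100 / ([Hb]·Δ%COHb·n_H)`; the expression is
dimensionally complete in liters (ml of CO ÷ 1.31 ml/g → g of bound Hb;
×100/Δ% → total Hb; ÷[Hb] g/L → L).  Δ%COHb is mean(post, nominally
6/7/8 min) − mean(baseline, nominally 3 samples).  The effective dose
applies, in order: the 1% affinity loss to the administered volume,
then subtraction of the apparatus remnant (bag 2.7 L + spirometer
0.04 L + lung 1 L, at the residual ppm measured after the maneuver) and
of expired CO (empirical `5.09·COHb% + 2.34` ppm at 5 L/min alveolar
ventilation for 7 min, the mean blood-sampling time).  Whether the 1%
loss applies before or after the remnant subtraction is not specified
by the source method; applied first here, which changes the result by
<0.1% at realistic values.  Holding the lung at the residual
concentration at disconnection is likewise an assumption carried from
the apparatus description.  `K` defaults to 1; ambient temperature and
pressure give the standard STPD factor `(273/(273+T))·(P/760)`.

## Monte Carlo protocol simulation

The forward model anchors: baseline T1 1600 ms, immediate post-contrast
T1 230 ms, half-life 3.4 h, 1.0 ml ferumoxytol, r1 18 mM⁻¹ s⁻¹ —
representative of a 0.7 mg/kg dose in ~40 kg swine.  Dose and
post-contrast T1 jointly imply the true plasma volume (2.597 L) through
the dilution equation; concentration decays mono-exponentially with
τ = 294.3 min.  Noise is **multiplicative Gaussian on T1** with 0.6% CV
(the measured in vivo baseline repeatability of the mapping sequence);
one noisy baseline draw and independent noisy post-contrast draws per
replicate.  Replicates where any sample shows non-positive enhancement
are rejected, counted and redrawn (at default parameters this never
triggers; it matters only for near-baseline T1 or large noise).
"Error" of a protocol means the percent SD of the plasma-volume
estimates across replicates, matching how protocol precision curves are
read.

Estimators: the log-linear fit (closed-form per-replicate OLS,
vectorized over replicates), or the single-point apparent volume with
no elimination correction.  The single-point protocol at 4 min
therefore carries a deterministic +exp(4/τ)−1 ≈ +1.4% bias by
construction; it is documented, not corrected, because correcting it
would require assuming the half-life the protocol does not measure.

Default replicate count is 10,000 (runs in well under a second,
vectorized); the test suite uses 2,000 and tolerances account for the
Monte Carlo standard error.  A single seeded generator drives each
simulation; sweep rows get independent child seeds spawned from the
design seed, so a sweep is reproducible row-by-row.

## Synthetic studies

`generate_study` emulates a multi-animal experiment: per subject,
uniform draws of weight (35–49 kg), hematocrit (0.26–0.33), plasma
volume per kg (57.6–66.2 ml/kg) and half-life (2.94–3.92 h) — ranges
are mean ± 1 SD of the in vivo summary statistics; a 0.7 mg/kg dose
then implies the enhancement, and blood-pool T1 series follow the
forward model plus multiplicative noise.  The LV/RV baselines differ
(1604.2 / 1807.9 ms) but share the same ΔR1, as in blood.  The
pre-contrast baseline is the mean of 5 noisy replicate maps.
Myocardial T1 follows a phenomenological profile interpolated through
the observed 4/20/60-min recovery ratios of the reference table; it is
generated for visual/ROI realism only and is never fitted.

What the generator does **not** emulate: the early (<20 min)
non-mono-exponential washout (available only as an optional, clearly
phenomenological second-exponential transient, off by default, so that
fit-window logic can be exercised); between-session physiological
variation (so the synthetic test-retest CV reflects measurement noise
only and sits far below the in vivo 6.9%, which includes physiology);
cardiac motion, partial volume, coil shading or any MR signal
formation.  Passing tests therefore demonstrate correctness of the
estimation pipeline under the stated noise model, not robustness to
in vivo confounds.

T1 maps are 2-D piecewise-constant single-slice images: each ROI is
the exact requested number of pixels nearest its centre (LV 150, RV 60
by default, matching typical hand-drawn ROI sizes), overlaps are an
error, and per-pixel noise is multiplicative.  NIfTI is used on disk
for maps and integer label masks; CSV for series and truths.

Note one deliberate inconsistency in the reference values: the
observed LV T1 rise from 4 to 60 min (21.3%) is steeper than the
3.4 h-half-life forward model predicts (~17.4%), reflecting in vivo
dose-dependent elimination kinetics that the mono-exponential truth
does not capture.  The reference-table percentages are therefore
computed from the table itself, not from regenerated series.

## Repeatability statistics

Coefficient of variation is `100·σ/μ` with the sample (n−1) SD — note
the convention is the standard one even though such formulas are
sometimes printed inverted — and the repeatability coefficient is
`1.96·CV`, the bound below which 95% of test-retest differences fall.
Bland-Altman reports mean difference, SD and `mean ± 1.96·SD` limits of
agreement.  Wilcoxon and Mann-Whitney tests are thin scipy wrappers
provided for study replication, not re-derived.

## Known limitations

- Single-compartment, mono-exponential elimination only; no saturable
  or two-compartment kinetics (relevant at low doses, where half-life
  shortens).
- No body-to-large-vessel hematocrit ratio correction; the measured
  hematocrit is applied directly.
- The relaxivity calibration assumes linearity; it is only testable on
  synthetic dilution series since no per-dilution data ship with the
  package.
- The CO module models a single rebreathing maneuver; COHb kinetics
  between administration and sampling are not modelled.
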