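# Methods

## Kinetic model

The simulator treats the nicotine arm as a linear chain of first-order
compartments,

    depot --ka--> parent --k_p--> [f_m1 -> cotinine] --k_m1--> [f_m2 -> 3-hydroxycotinine] --k_m2--> out

with k_p = (CL/F)/(V/F).  A fraction `f_m1` of parent elimination forms
cotinine (CYP2A6-mediated) and a fraction `f_m2` of cotinine elimination
forms 3-hydroxycotinine (CYP2A6-specific); the remainders leave the system
directly.  Amounts follow the classic Bateman sum-of-exponentials solution;
rate constants closer than a relative 1e-8 are handled by the matrix
exponential of the chain matrix, which is the exact repeated-root limit for
any multiplicity.  Concentrations are amounts over apparent volumes; the
metabolite volumes are expressed relative to the parent's
(`vol_ratio_m1/2`).  Letrozole is the degenerate one-compartment case
(`f_m1 = f_m2 = 0`).

Gum absorption is reduced to a single first-order depot (ka = 6 /h); the
chew-and-park procedure is not modelled mechanistically because only the
resulting profile shape matters downstream.

Relative CYP2A6 activity `phi(t)` multiplies the two formation
micro-constants only (the non-CYP2A6 pathways are untouched), so a constant
`phi` changes both the branching fractions and the totals:
k_p_eff = k_p (1 − f_m1 (1 − phi)), and analogously for cotinine.  Constant
activity keeps the closed form; time-varying activity (modes `recovering`,
phi(t) = 1 − (1 − phi0) e^(−k_change t), and `progressive`,
phi(t) = phi0 + (1 − phi0) e^(−k_change t)) switches to a fixed-step RK4
integration with step ≤ 0.01 h that lands exactly on every sampling time and
aborts on any negative state.  The two modes realise the two mechanistic
narratives the slope approach is meant to distinguish: an inhibitor that is
cleared (activity recovers → slopes parallel) versus inactivation that
accrues over the sampling day (slope reduced).

## Default parameters and calibration

Published single-dose endpoints, not micro-rate constants, are available
for calibration, so defaults were fitted once against the observed baseline
endpoints and then frozen:

| parameter | value | why |
|---|---|---|
| nicotine CL/F | 111 L/h | observed geometric mean |
| nicotine t1/2 | 3.4 h → V/F ≈ 545 L | observed; fixes k_p |
| ka | 6 /h | buccal absorption fast; observed tmax 0.5 h |
| f_m1 | 0.75 | accepted cotinine conversion fraction |
| k_m1 | 0.13 /h | cotinine grid tmax 6 h (observed range 3–8 h) |
| f_m2, k_m2 | 0.40, 0.23 /h | NMR rise shape (slope/partial-AUC ratio) |
| vol_ratio_m1 | 0.1200 | cotinine Cmax = 64 nM |
| vol_ratio_m2 | 0.0963 | linear-window NMR slope = 0.022 /h |
| letrozole CL/F, t1/2, ka | 2.16 L/h, 46 h, 1.5 /h | observed; V/F ≈ 143 L |
| doses | 2 mg nicotine, 2.5 mg letrozole | study doses, converted with molar masses 162.23 / 176.22 / 192.21 / 285.30 g/mol |

The resulting noise-free study day gives nicotine Cmax 20 nM at 0.5 h,
AUC0–4 ≈ 58 h·nM, exact t1/2 recovery; cotinine 64 nM at 6 h with AUC0–12
611 h·nM; 3-hydroxycotinine AUC0–12 109 h·nM; NMR 0.115/0.167/0.215 at
4/6/8 h, partial-AUC ratio 0.155, linear-window slope 0.0220 /h.  Two
published values are *not* reproducible inside this reduced structure and
are knowingly approximated: the cotinine tmax median (4 h observed; 6 h
here — a three-compartment linear chain with the parent's 3.4-h half-life
cannot peak cotinine at 4 h while also rising as slowly as the observed
NMR), and the letrozole Cmax (87 nM observed; ≤ 61 nM here, since
CL/F = 2.16 L/h with t1/2 = 46 h forces V/F = 143 L in one compartment —
matching Cmax would need a distribution phase).  The metabolite rate
constants are therefore effective values, not literature half-lives.

Variability defaults: intra-subject (period-to-period) CV 26% on nicotine
clearance and 16% on letrozole clearance (the design's planning values);
inter-subject CV 30% (nicotine) and 50% (letrozole) on CL/F and V/F,
back-computed from the width of the published 90% CIs at n = 10;
proportional assay error 10% (the assays' inter-day variability bound).
All log-normal deviates are median-preserving (CL = default · e^(σZ),
σ² = ln(1+CV²)).  One `numpy` generator seeded from the design drives every
draw in a fixed order (subject deviates, then per-period clearance deviate,
then the noise matrix), so a seed reproduces a study byte for byte.

Limits of quantification: 1.2 ng/mL converted per analyte for nicotine,
cotinine and 3-hydroxycotinine (7.40/6.81/6.24 nM), 1.56 nM for letrozole
(each assay's lowest calibrator).  A value exactly at the LOQ is retained;
only strictly-below is censored.  With these defaults the simulated
nicotine tail falls below LOQ after ~5 h and the 240-h letrozole sample
sits at ~1.7 nM — both mirror the patterns of missingness the real study
reported.

## What the generator does and does not emulate

It reproduces: the two-period crossover structure, the sampling grids
(0.5–12 h; plus 24–240 h for letrozole), log-normal between- and
within-subject variability of the planned magnitudes, proportional assay
noise, LOQ censoring with its knock-on exclusions, and a constant or
time-varying inhibition effect entering through the mechanistically correct
rate constants.  It does not emulate: multi-compartment distribution
(hence the letrozole Cmax gap), first-pass metabolite formation (hence the
late cotinine peak), enterohepatic recirculation, renal-flow or
pH-dependent nicotine clearance, CYP2A6 genotype classes (the continuous
activity factor subsumes them), or correlated residual errors.  Passing
tests therefore demonstrate correctness of the estimators under the stated
kinetic-statistical model, not fidelity of that model to every feature of
real plasma data.

## Non-compartmental analysis conventions

- AUC: linear trapezoid on rising or zero-touching segments, logarithmic
  trapezoid (C1−C2)/ln(C1/C2)·Δt on strictly declining positive segments
  (`linear_up_log_down`, the common default; pure linear available).
  Window endpoints between grid points are interpolated with the matching
  rule (log on declining segments).
- BLQ: censored samples are missing.  Censored samples *before the first
  quantifiable one* count as zero concentration in AUC windows (the analyte
  has not appeared yet); internal gaps are bridged between quantifiable
  neighbours; trailing BLQ leaves a window uncovered → endpoint missing.
- A C(0) = 0 anchor is inserted for single-dose profiles whose sampling
  starts after dosing.  Predose (negative-time) samples become the t = 0
  baseline: zero/censored ones anchor at zero, quantifiable ones keep
  their value (carry-over).
- λz: OLS of ln C vs t over candidate terminal sets (last 3, 4, …
  quantifiable points after and excluding tmax), requiring a positive
  elimination rate; the set maximising adjusted R² wins, ties to the larger
  set.  AUC0–∞ adds C_last/λz (observed C_last); an extrapolated fraction
  > 0.20 raises a warning flag, not an error.
- CL/F is reported only for dosed analytes; a zero dose yields CL/F = 0
  with an `invalid dose` flag.
- tmax ties go to the earliest time; tmax is summarised as median
  (min–max) with no test.

## NMR endpoints

The NMR series is defined only at nominal times where both metabolites are
quantifiable and cotinine is positive (a zero denominator excludes the
point, never an infinity).  The 3–8 h partial-AUC row is the ratio of the
two metabolites' partial AUCs by default; the alternative reading — the
time-averaged AUC of the NMR series itself — is available via
`pauc_convention="auc_of_ratio"` and agrees when the ratio is near-linear.
Slopes need ≥ 3 points; the linear window runs from the cotinine tmax to
the 3-hydroxycotinine tmax of the same subject-period (no extrapolation if
that tmax falls on the last sample).  Pattern classification compares the
linear-window slopes with a default relative tolerance of 0.10 — the
original assessment was visual, so the numeric cutoff is this package's
convention.  The slope GMR responds *more* than proportionally to a
constant activity factor applied to both CYP2A6 steps (phi = 0.8 gives a
slope GMR ≈ 0.70): inhibition also slows the cascade, shifting the window
later on a convex ratio-time curve.  This over-response is a property of
the estimator — consistent with the slope being a more sensitive
interaction signal than AUC — and is recovered within the 15% band the
effect-recovery tests assert.

## Paired statistics

Geometric means and GMRs are computed on the log scale with t-based
intervals (default level 0.90); the paired t-test is two-sided; the
no-effect bounds 0.80–1.25 are treated as a closed interval; subjects
missing either period are excluded listwise per endpoint and logged.
With zero within-subject variance the CI is degenerate at the GMR and the
p-value is reported as 1 when the GMR is exactly 1, NaN otherwise.

Sample size and power use the noncentral t distribution with
df = n − 1 and noncentrality (Δ/CV)·√n — the detectable proportional
change over the intra-subject CV, both on the proportional scale.  This
convention reproduces the published planning numbers (n = 16 at CV 26%,
power 94% at n = 10 and CV 16%); the log-normal-exact alternative
(ln(1+Δ)/√ln(1+CV²)) is exposed via `convention="log"` but is not the
default precisely because it does not.  `empirical_power` is the
Monte-Carlo twin (vectorised one-sample t-tests on Normal(Δ, CV) draws)
and agrees with the noncentral-t value within Monte-Carlo error.

## Static predictors

The mechanistic static model is implemented in its hepatic
time-dependent-inhibition form only — no intestinal term, no
reversible-inhibition term — matching the hepatic-CYP2A6 framing of the
application; the predicted ratio is bounded by 1/(1−fm).  HED conversion
uses the FDA body-surface-area Km table (mouse 3, rat 6, …, human 37).
The steady-state inhibitor concentration helper simply multiplies a
single-dose concentration by the accumulation ratio.

## Problem sizes and numerical choices

Test and acceptance runs use the study's own scales: n = 16 subjects for
pipeline checks, n = 50 noise-free subjects for effect recovery, 200 for
variance propagation, 1000 replicates for CI coverage, 10,000 for
Monte-Carlo power, 20 random parameter sets for the Bateman-vs-ODE oracle
(agreement < 1e-6 relative, floored at 1e-9 of the dose where amounts
vanish).  The RK4 step (0.01 h), the rate-distinctness tolerance (1e-8
relative), and the LOQ boundary convention are fixed constants at the top
of `simulate.py`.
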