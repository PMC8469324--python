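# Methods

## Behavioural endpoint

The formalin test records, per animal, the number of paw flinches in a
1-min window every 5 min for one hour after the formalin injection. We take
the observation times as the window start minutes (0, 5, …, 60 — 13
observations) and treat counts as flinches/min rates at those times. The
effect measure is the area under the piecewise-linear rate–time curve
(composite trapezoid), split at the 15-min phase boundary: phase 1
(0–15 min) reflects direct nociceptor activation, phase 2 (15–60 min)
inflammatory pain. The boundary observation belongs to both windows, so
phase AUCs partition the overall AUC exactly.

Antinociception of a treated animal is expressed against the vehicle
group's mean AUC,

    %AN = (AUC_vehicle_mean − AUC_treated) / AUC_vehicle_mean × 100 ,

with phase-specific vehicle denominators for the phase percentages (a drug
acting only on inflammation scores 0% in phase 1). We average per-animal
percentages rather than taking a ratio of mean AUCs so that each group has
a standard error; the two differ only at second order. Negative values
(hyperalgesia) are retained, never truncated.

## Dose–response model

Effect is modelled as linear in log10(dose) over the tested range,
`E(%) = b0 + b1·log10 D`, fitted by OLS either to group means (one point
per dose — "table mode") or to per-animal effects (all animals as points).
No Hill/4PL or probit model is attempted: over the one-to-two decades of
dose used in these designs the log-linear segment is the model actually
being exercised, and the effective-dose arithmetic below depends on it.

The effective dose at level L is the inverse prediction
`log10 ED = (L − b0)/b1`, antilogged. Uncertainty comes from the delta
method: the gradient of log10 ED in (b0, b1) is (−1/b1, −log10 ED/b1), its
quadratic form with the OLS coefficient covariance gives Var(log10 ED),
the confidence interval is a t-band on the log scale exponentiated (hence
asymmetric in dose), and the reported SE is the dose-scale value
ln(10)·ED·SE(log10 ED). An ED falling outside the fitted dose range is
returned with an extrapolation warning rather than an error — in the
published combination table the lowest tested total already produces ≈30%,
so mild extrapolation is part of normal use.

## Fixed-ratio isobole

With drug A contributing fraction f of its own ED and drug B the rest, the
additive prediction is Z_add = f·ED_A + (1−f)·ED_B with
Var = f²V_A + (1−f)²V_B and df = df_A + df_B. The combination arm is the
halving series whose top level is exactly (f·ED_A, (1−f)·ED_B) — the top
total *is* Z_add — and the experimental ED30E comes from the combination's
own fitted curve. The additivity test is the Student's t

    t = (ED30T − ED30E) / sqrt(SE_T² + SE_E²),   df = df_T + df_E ,

two-sided. The interaction index γ = ED30E/ED30T carries a first-order
ratio SE, γ·sqrt((SE_E/ED_E)² + (SE_T/ED_T)²). Classification demands both
signals: synergistic requires γ < 1 *and* p < α; antagonistic γ > 1 and
p < α; otherwise additive. γ alone never classifies — this is the
conservative combination of the index rule and the significance rule.

Isobologram coordinates are exported in (dose_B, dose_A) axes: the
additivity line joins (ED_B, 0) and (0, ED_A), the theoretical point is its
f-weighted interior point (collinear by construction), and the experimental
total is decomposed onto the fixed ray in the design's component ratio.

## Group statistics

One-way ANOVA on per-animal % effects, followed by pooled-variance t
comparisons of each group against a designated control with the
multiplicative Bonferroni adjustment p_adj = min(1, m·p). This is the
plain stated-variant adjustment, not Holm or Šidák.

## Synthetic study generator

The generator emulates what the pipeline needs from real data, with known
ground truth:

- **vehicle intensity** λ(t) = a1·e^(−t/τ1) + a2·e^(−(t−μ2)²/(2σ2²)),
  defaults a1 = 6 flinches/min, τ1 = 4 min, a2 = 4 flinches/min,
  μ2 = 35 min, σ2 = 12 min — an early nociceptive spike, a quiescent dip
  around 10–15 min and a broad inflammatory bump, at the flinch-rate scale
  typical of 2% formalin in rats. These are order-of-magnitude choices,
  not fitted values.
- **suppression**: single drugs follow %-scale lines in log10(dose),
  clamped to [0, 99]; defaults are the refits of the published group-mean
  curves (A: slope 22.79, intercept 9.70; B: slope 35.26, intercept
  −31.85), so default simulations live in the published dose regime.
  Combinations follow Loewe additivity modulated by a potency factor ψ:
  the effect E* solves d_A/D_A(E*) + d_B/D_B(E*) = ψ (bisection; the left
  side is strictly decreasing in E). ψ = 1 is exact additivity; ψ = 0.1
  makes the combination ten-fold more potent than predicted, and the true
  combination ED along the fixed ray equals ψ·Z_add.
- **noise**: each 1-min count is Poisson with mean λ(t)·(1 − E). Poisson
  is the minimal count-noise model; it implies AUC CVs of ~19% per animal
  at the default intensity scale, which sets the realistic difficulty of
  n = 6 designs. No between-animal random effects are modelled, so passing
  calibration here says nothing about overdispersed real colonies.

The default study design (`standard_study_design`) places the six
single-drug doses at equi-effect targets 10–70% (bracketing the ED30
within each drug's linear range) and builds the combination arm as the
halving series from the additive top dose. Dilution stops once the
expected effect floors at zero, keeping a single floored level as a
no-effect anchor: fully floored levels carry no dose–response information
and deterministically flatten the fitted combination line (with two such
levels the ED30E refit is biased upward ≈25% under additivity).

## Calibration and its limits

Monte-Carlo over replicate studies (`analysis/03_calibration_and_power.py`,
mirrored in the acceptance tests):

- Under additivity at n = 24/group the γ̂ distribution is centred on 1
  (mean ≈ 1.1) and the additivity test rejects in ≈2% of studies at
  α = 0.05.
- At the standard n = 6/group the *median* γ̂ is ≈1.00 and ≥90% of studies
  are correctly classified additive, but the *mean* of γ̂ is not a useful
  summary there: γ̂ is a ratio whose denominator and numerator are
  antilogged regression inversions, and a handful of near-flat combination
  fits give it a heavy right tail (mean ≈ 1.7). Calibration-in-mean is
  therefore assessed at n = 24, small-sample behaviour by median and
  classification rate at n = 6.
- Under strong synergy (ψ = 0.1) at n = 6/group, essentially every
  replicate is detected as synergistic.

## Numerical choices

- AUC windows interpolate endpoint values linearly, so adjacent windows
  partition exactly; windows outside the observed range are errors.
- OLS is delegated to statsmodels; tests cross-check coefficients and
  covariance against closed-form normal equations to 1e−8.
- Bisections (Loewe effect, combination ED) run to interval widths of
  1e−12 with a 200-iteration cap.
- Doses are carried at full precision everywhere; 2-decimal rounding
  happens only in CSV report writers (the published tables' 8.51-vs-8.50
  style discrepancies are display rounding, which we do not try to
  reproduce digit-for-digit).
- Degenerate inputs fail loudly: non-positive vehicle AUC, fewer than
  three distinct doses, non-positive fitted slope, both SEs zero in the
  t-test.

## Known limitations

- The log-linear effect model cannot represent saturation; EDs near the
  0% or 100% ends of the scale are extrapolations of a straight line.
- Delta-method SEs and the dose-scale t-test are first-order; at n = 6
  the test is mildly anticonservative (≈9% rejection under additivity in
  our simulations, vs the nominal 5%).
- Reproduction of the published per-animal estimates (ED30E = 0.927 ±
  0.63) is not possible from group means; the table-mode refit (1.15)
  agrees within the published uncertainty, and all qualitative
  conclusions (ED30E ≪ ED30T, γ ≪ 1, synergism) are reproduced exactly.
- Only two-drug, fixed-ratio, single-endpoint designs are supported; no
  response-surface models, no pharmacokinetics, no time-varying effects.
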