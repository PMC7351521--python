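# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `busulfan-mipd`. Units throughout: mg, L, hours, mg·h/L;
time runs in continuous hours from the first infusion start; treatment
days are consecutive 24-h windows.

## Structural PK model

Busulfan is modeled with linear one-compartment kinetics, zero-order
infusion input and first-order elimination. Concentrations are the
superposition of per-dose closed forms: with infusion rate
`R0 = amount/duration` and `ke = CL/V`,

- during infusion: `C(τ) = (R0/CL)(1 − e^(−ke·τ))`
- after infusion: `C(τ) = (R0/CL)(1 − e^(−ke·D)) e^(−ke·(τ−D))`

The per-dose cumulative-AUC antiderivative is also closed-form, so AUC
over any window — and the course total, `Σ dose / CL` — is exact. Both are
verified in the test suite against adaptive ODE integration (relative
error < 1e-6) and quadrature.

With inter-occasion variability (IOV) enabled, a dose's kinetics use the
clearance of the day on which it starts (`CL_day = CL·exp(κ_day)`). The
course AUC then sums `day dose / CL_day` per day. This per-dose occasion
assignment is an approximation at day boundaries (a dose's tail into the
next day still decays at its own day's `ke`) that keeps everything
closed-form; IOV defaults to 0.

## Covariate model ("second generation")

- **Size:** allometric scaling on fat-free mass, exponent 0.75 on CL and
  1.0 on V. FFM uses the Janmahasatian sex-specific equation
  (`FFM = 9270·WT/(6680 + 216·BMI)` male, `9270·WT/(8780 + 244·BMI)`
  female), capped at body weight; when height is unavailable FFM falls
  back to a fixed fraction of weight (default 0.85).
- **Maturation:** Hill sigmoid on postnatal age,
  `age^h/(age^h + TM50^h)`, defaults TM50 = 0.3 y, h = 2 — most of the
  clearance maturation happens within the first year of life, consistent
  with busulfan ontogeny. Postnatal (not postmenstrual) age is used
  because the cohort descriptions only carry age in years.
- **Conditioning regimen:** a multiplicative factor on CL per regimen
  label; the reference label carries exactly 1.0.

### Default parameter values (illustrative configuration)

The defaults are **not published estimates** (the final clinical model's
parameters are not in the public domain); they are a documented,
pediatric-plausible configuration:

| parameter | default | rationale |
|---|---|---|
| θ_CL | 4.4 L/h at FFM 13 kg | ≈ 0.25 L/h/kg body weight (≈ 4 mL/min/kg), the magnitude reported for pediatric busulfan; also reproduces the clinically documented sub-therapeutic bias of 0.8–1.1 mg/kg label dosing |
| θ_V | 10.5 L at FFM 13 kg | ≈ 0.65 L/kg, standard busulfan volume |
| TM50, h | 0.3 y, 2 | fast infant maturation |
| Ω | [[0.0484, 0.012], [0.012, 0.04]] | 22% CV on CL, 20% on V, mild positive correlation ("moderate IIV") |
| σ_prop | 0.10 | 10% proportional assay/model residual |
| σ_add | 0 | pure proportional error by default |
| ω²_IOV(CL) | 0 | between-day variability exists clinically but is unquantified; off by default, configurable |
| regimen factors | bu_flu 1.0 (ref), bu_cy 1.05, bu_mel 0.9 | placeholder labels exercising the code path |

The "first-generation" model (strategy B initial dosing only) is
total-body-weight allometry (θ_CL 4.1 L/h at 16 kg weight, no maturation,
no FFM). Its deliberate, moderate misspecification relative to the
second-generation truth is what makes strategy B's initial-dose bias —
intermediate between A and C — reproducible in silico. Both models are
plain configuration objects; swapping in other parameterizations needs no
code changes.

Residual model: `y = f·exp(ε_prop) + ε_add`. Both sigmas may be zero for
deterministic simulation; MAP estimation requires a positive residual
variance and refuses otherwise.

## MAP-Bayesian estimation

The individual random effects `η = (η_CL, η_V)` minimize

```
Σ_j [(ln y_j − ln f_j(η))²/σ² + ln σ²] + ηᵀΩ⁻¹η
```

(log-transform-both-sides, used whenever σ_add = 0; with an additive
component the untransformed residual with variance σ_prop²f² + σ_add² is
used instead). Minimization is a Nelder–Mead simplex from η = 0 with 1e-8
tolerances — the objective is a smooth 2-parameter function, and the
derivative-free simplex is robust to the exponential parameterization.
Samples below the quantification limit are excluded from the fit. With no
usable observations the prior mode (η = 0, population-typical parameters)
is returned. A near-zero Ω pins η at 0 (degenerate prior) rather than
inverting an ill-conditioned matrix.

## Dose individualization

- **NCA path (strategies A/B).** Each TDM day, the day's samples plus a
  zero-concentration anchor at the anchored infusion start are integrated
  with the linear trapezoid (log-down available as an option), λz is the
  negated least-squares slope of ln C over the last 3 quantifiable points,
  and AUC∞ = trapezoid + C_last/λz. The next days' dose is
  `prev · AUC_target/AUC_obs`, rounded to 0.1 mg (ties half-up). The
  zero-anchor single-dose convention ignores carry-over from earlier
  doses; on days 2–3 of q6/q12 dosing this residual inflates AUC_obs —
  deliberately retained, since it is exactly the kind of bias bedside NCA
  incurs.
- **MIPD path (strategy C).** After each TDM day the MAP estimate is
  refreshed on all samples so far, and the remaining slots get one shared
  per-dose amount chosen by grid search (0.1 mg steps, bounds 0.5×–2× the
  current dose) minimizing |accrued AUC + remaining/CL_EBE − target|, ties
  toward the lower dose. If the exact solution lies outside the grid, the
  boundary amount is returned and the course flagged as saturated.
  Candidates share one amount across the remaining slots deliberately:
  clinical dose updates change one amount per TDM cycle, and under linear
  kinetics the predicted cAUC depends only on the remaining *total*
  amount, so freeing each slot separately would not change the reachable
  exposures — only blur the recommendation.
- **Sampling schedule.** Three samples per monitored day at infusion end
  + 0.25, 1.0, 3.5 h, anchored at the day's first dose (dose-3 anchoring
  is available for q6/q12 day 1). TDM occurs on days 1–3 only; day 4 is
  extrapolated — for C via the final EBE clearance, for A/B via the
  implied clearance (dose/AUC_obs) of the latest successful assessment.
  Estimation failures (e.g., a non-declining terminal slope) leave the
  dose unchanged and are flagged, and the course continues.

## Virtual cohorts

The generator emulates the *marginal* demographic structure of the three
clinical dosing-era cohorts: per disease class, the median and range of
weight, age and predefined cAUC target, the sex ratio, and class counts
(53/76/59 patients; e.g. 42 malignant / 17 non-malignant in the MIPD-era
cohort).

- Age and target: truncated log-normals matched by median, log-SD set so
  the stated range ≈ the central 99% interval, rejection-sampled into the
  range.
- Weight: conditional on age through a monotone piecewise-linear median
  weight-for-age curve anchored so the class's median age maps to the
  class's median weight, with 18% log-normal scatter, truncated to the
  class range. Height is imputed deterministically from the companion
  height-for-age curve (needed by the FFM equation).
- True parameters: η ~ N(0, Ω), optional per-day κ ~ N(0, ω²_IOV).
- Dose interval: non-malignant patients under 2 years get q24 (3-h
  infusions), everyone else q6 (2-h infusions); an explicit interval mix
  is configurable. The clinical allocation of intervals was never
  published; this rule mirrors the practice of once-daily dosing in
  infant non-malignant protocols.

What the generator does **not** emulate: the true joint distribution of
age, weight, interval and target (only marginals are known), real
covariate measurement error, non-log-normal tails, comorbidity-driven
target selection, drug interactions, or assay scheduling constraints.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative strategy ordering under these study conditions — not clinical
performance on real patients.

## Attainment analytics

Attainment ratio = 100 × AUC_obs/AUC_target, computed both for the first
PK assessment (per-interval target = cAUC/planned doses) and for the
course (estimated cAUC/target). The therapeutic band is [80%, 120%]
inclusive on both boundaries (the outer categories are strict < 80 and
> 120). %CV uses the sample (n−1) standard deviation. Cohorts are
compared by one-way ANOVA with pairwise two-sample t tests, p-values
multiplied by the number of pairs and capped at 1 (Bonferroni);
significance at 0.05. The report computes and labels both PK1-based and
cAUC-based comparisons.

## Reproducibility and problem sizes

Every simulation consumes a single user seed; cohorts and per-patient
courses draw from independent child streams derived from it (SHA-256 of
seed + tag, < 2^31), so runs are reproducible as a whole and per patient.
The acceptance script runs the 59-patient MIPD cohort (~10 s); the test
suite's heaviest fixtures are a 10,000-patient generator check and a
200-patient MAP recovery study — sizes chosen to make medians and
covariances stable while keeping the whole suite under a minute.

## Known limitations

- One-compartment, linear kinetics only; no saturable clearance, no
  µM·min exposure units.
- The MAP objective, error model and dose-search space of the commercial
  bedside platform are proprietary; the formulation here is the standard
  penalized-least-squares MAP with a grid search, labelled as such.
- NCA terminal fits on 3 points are fragile under high noise; failures
  are handled (dose carried forward, flagged) but not modeled further.
- Estimated (EBE-based) course exposure is the reported attainment
  quantity, as in clinical TDM practice; with the estimation model equal
  to the generative model this is partially self-confirming — the
  true-parameter ratio is logged alongside for honesty.
- Population parameters are not re-estimable from data with this package
  (out of scope by design); they enter only as configuration.
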