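# Methods

`agepath` implements a cohort analysis linking biomarker-based biological
aging to multimorbidity trajectories, mortality, and life expectancy. This
note records the models, the synthetic-data generator that stands in for a
real cohort, and the numerical and design choices a maintainer would want
to know about.

## Biological-age scores

**KDM-BA.** For biomarkers `x_i` regressed on chronological age within sex
strata (`x_i ≈ q_i + k_i·CA`, residual RMSE `s_i`), the Klemera–Doubal
biological age is the inverse-variance-weighted combination

    KDM-BA = [ Σ_i (x_i − q_i)·k_i/s_i² + CA/s_BA² ] / [ Σ_i (k_i/s_i)² + 1/s_BA² ]

We use the standard convention that `q` is the intercept and `k` the slope
of the biomarker-on-age regression. `s_BA` is implemented as
`sqrt(R²·Var(CA))` from a multiple regression of age on the full biomarker
set within the stratum; an override is exposed for users who prefer the
fuller Klemera–Doubal variance correction. Biomarkers whose `|k|/s` falls
below a configurable floor are flagged: their weight in the score is
numerically negligible and a near-zero `s` (a perfect fit) would make the
weight blow up. Training is sex-stratified; scoring a participant uses their
stratum's parameters.

**PhenoAge.** The phenotypic age maps a Gompertz 120-month mortality risk
onto the age scale:

    xb        = intercept + Σ w_j·m_j   (ln-transform applied to C-reactive protein)
    ln(1−risk) = −exp(xb)·(exp(120·γ) − 1)/γ,   γ = 0.0076927 per month
    PhenoAge  = 141.50225 + ln(−0.00553·ln(1−risk)) / 0.090165

The computation stays in log space throughout: the risk saturates to 1.0 in
double precision long before the score degenerates, so forming `risk`
explicitly would destroy the outer transform. The marker weights ship as a
versioned CSV (`data/phenoage_coefficients.csv`) with provenance in its
header (the published Levine et al. 2018 mortality-score coefficients); the
file can be replaced without touching code. The outer denominator follows
the value printed in our source description (0.090165).

**Acceleration.** Aging acceleration is the residual of OLS of biological
age on chronological age (with intercept, pooled across sexes by default; a
stratified option exists). Positive residuals define the "accelerated"
group; the residual divided by its SD is the per-SD exposure used by every
downstream model. Quartile cutpoints are the empirical 25/50/75 percentiles
with ties assigned to the lower quartile; Q1 is the referent. Scores beyond
5 SD of the cohort mean are flagged and excluded, and participants missing
any score biomarker are excluded from that score rather than imputed —
imputation applies to covariates only.

## Multimorbidity states

Disorder domains (physical, psychological, cognitive) accumulate
monotonically; the health state is the count: none, single, dual, triple,
plus absorbing death. Timelines are built from per-domain first-onset ages:
onsets at or before baseline define the baseline state; simultaneous onsets
on one recorded date are split physical → psychological → cognitive with a
one-day epsilon, because the transition graph has no multi-level jumps.
Panels record the state at baseline, each onset age and the end of
follow-up; death is exactly observed. Participants whose only transition is
no-condition → death are excluded from the multistate analysis (that edge
is not in the graph) and counted in the run report. A landmark sensitivity
utility drops participants with any event in the first five years of
follow-up.

## Multistate model

A continuous-time Markov illness-death model on the progressive chain
1→2→3→4 with death exits from states 2–4 (no direct 1→death edge).
Intensities follow proportional hazards, `q_rs(z) = q⁰_rs·exp(β_rs·z)`,
with per-transition covariate effects (sex, baseline age, acceleration in
SD in the pipeline). The interval-censored likelihood uses
`P(dt|z) = exp(dt·Q(z))`; an exact death at the end of an interval
contributes `Σ_s P(dt)[s_prev,s]·q_{s,death}`.

Numerics: the public transition-probability API uses `scipy.linalg.expm`.
The fitting path evaluates the likelihood and its exact analytic gradient
by a uniformization series (`P = e^{−Λt} Σ_k w_k M^k`, `M = I + Q/Λ`) with
per-interval Poisson truncation at tail mass 1e−15; the gradient uses the
term-wise forward/backward recurrence for `v dP sel` and is verified against
finite differences in the test-suite. The series kernel is JIT-compiled with
numba when available, with an equivalent vectorised numpy path kept as a
cross-checked fallback. Intensities are capped at 5/year during
optimisation (far beyond plausible chronic-disease rates) so the series
stays bounded while the optimizer explores. Optimisation is L-BFGS-B from
crude occurrence/exposure initial rates and zero covariate effects; standard
errors come from the inverse observed information, obtained by central
finite differences of the analytic gradient. Time runs on the follow-up
scale with baseline age entering as a fixed covariate — a stated limitation;
the age timescale is reserved for the life-expectancy model.

## Association models

Cross-sectional logistic models (statsmodels maximum likelihood) estimate
ORs for baseline single disorder and dual-or-worse status; longitudinal Cox
models (lifelines, Efron tie handling) estimate HRs for incident single
disorder, incident dual/triple multimorbidity and death among the baseline
disorder-free. Because deaths among the baseline disorder-free are rare at
the problem sizes the package runs (the graph has no direct
no-condition → death edge), the Cox block also fits overall mortality on
the full cohort with the baseline hazard stratified by baseline state —
the well-powered mortality design — alongside the disorder-free analysis. Exposures enter per SD or as quartile indicators with Q1
referent; a separate refit with the ordinal quartile score (1–4) supplies
the p-for-trend. Dose-response curves use Harrell-form restricted cubic
splines (linear term plus truncated-cubic combinations normalised by the
squared boundary-knot span; linear beyond the boundary knots; C²
continuous), default four knots at the 5/35/65/95th exposure percentiles,
reference at acceleration 0 — the accelerated/non-accelerated boundary —
with delta-method CIs; `HR(ref) = 1` by construction. All model wrappers
accept a list of imputed datasets and pool coefficients on the log scale by
Rubin's rules.

## Multiple imputation

Three fixed per-column strategies (no chained equations): proportional-odds
ordered logistic draws for ordinal covariates (education, income), a
regression-based conditional normal draw with coefficients redrawn from
their sampling distribution and rejection-then-clamp at plausibility bounds
for continuous covariates that may be negative (Townsend index), and mean
substitution for non-negative continuous covariates (physical activity, air
pollution). Default m = 20 completed datasets (the pipeline exposes m; the
heavier test and acceptance runs use m = 5 to keep the problem sizes
modest). Imputation-model predictors default to baseline age (configurable);
missing predictor cells are mean-filled inside the imputation model only.
Rubin pooling: point = mean estimate, total variance
`W + (1 + 1/m)·B`, df `(m−1)(1 + W/((1+1/m)B))²`; with `B = 0` the df is
infinite and normal quantiles apply.

## Life expectancy

A Royston–Parmar flexible parametric model on the age timescale with
delayed entry: `ln H(t|z) = s(ln t; γ) + β·z`, where `s` is a restricted
cubic spline with df = 4 (boundary knots at the min/max log event age,
internal knots at event-age quantiles — common stpm2 practice). Each subject
contributes `h(exit)^event · S(exit)/S(entry)`.

Two numerical points deserve note. First, the spline basis is centred and
scaled internally (ln age spans well under one unit on cohort data, so the
raw basis is nearly collinear); coefficients and covariance are mapped back
to the raw basis. Second, with *every* subject left-truncated the data
identify the cumulative hazard only up to an additive constant (the hazard
below the youngest entry age is never observed). The package resolves this
with an explicit convention: the level is chosen so that ln H continues the
observed power law below the entry window — estimated from a delayed-entry
Nelson–Aalen curve by a scale-free lack-of-fit search — and a ridge anchor
pulls the spline coefficients toward that line, pinning the flat direction
while leaving within-window hazards and covariate effects essentially
untouched. Conditional survival is computed from cumulative-hazard
differences (`e^{η(a)}·expm1(η(t)−η(a))`), which is stable and
convention-free.

Residual life expectancy at age `a` is the area under the conditional
survival curve to age 100, integrated by 5-node Gauss–Legendre quadrature
on 1-year panels (quadrature error ≪ 1e−6 years). Years of life lost is the
difference in that area between an index group and the no-condition
referent. CIs come from parametric simulation of the parameter covariance
(seeded; the same draws are applied to both curves of a contrast so their
correlation is preserved; B = 1,000 by default, smaller in the pipeline's
table builder). The life-table grid covers conditioning ages 45–99; LE at
100 is identically 0.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real cohort's marginals:

- **Latent frailty.** One standard-normal draw per participant enters
  biomarkers additively (`loading × frailty × residual_sd`) and transition
  intensities multiplicatively (`exp(loghr × frailty)`). This single shared
  factor is the minimal structure making biological-age acceleration
  prognostic — the property the pipeline must detect.
- **Biomarkers.** Linear in age with sex offsets and Gaussian residuals, in
  the training units of the packaged score coefficients; C-reactive protein
  is modelled on the log scale. Means and slopes are fixed at values
  typical of a middle-aged European cohort.
- **Disease process.** Competing exponential clocks refreshed at every
  jump over the illness-death graph. Disorder intensities are constant per
  year; the death intensity is Gompertz in age
  (`exp(rate_intercept + slope·age)` times per-edge offsets), approximated
  as piecewise-constant on calendar-year segments evaluated at the segment
  midpoint — 1-year steps match the life-expectancy grid and make an
  independent thinning-based simulation an exact oracle. Participants are
  disease-free at age 25; pre-baseline history yields prevalent states, and
  death is enabled only from baseline (enrolment implies survival).
  Which domain an upward jump adds is uniform among absent domains
  (domain identity is exchangeable given the state).
- **Calibration.** Default intensities are calibrated once so the baseline
  mix is ≈ 18% none / 55% single / 23% dual / 3–4% triple with ≈ 8%
  mortality over 14 years of follow-up; they live in the versioned
  `data/default_generator.yaml`, not in code.
- **Missingness.** MCAR per-column rates echoing typical cohort covariate
  missingness (MAR-by-age available as a switch); outcome, date, id, age
  and sex columns can never be masked.

What the generator does *not* emulate: correlated biomarker measurement
error beyond the single frailty factor, domain-specific progression rates,
covariate-outcome confounding (covariates are noise), informative
censoring, or real-cohort marginal distributions. Passing tests therefore
demonstrate that the pipeline recovers the directions, orderings and
magnitudes implied by this generative structure — not that it reproduces
any particular real-world estimate.

## Problem sizes and determinism

Tests run the generator at 1,200–20,000 participants; parameter-recovery
checks use n = 5,000 panels (four visits), the null-calibration study 200
replicates at n = 2,000, and the end-to-end check a 20,000-participant
cohort with 5 imputations. All randomness flows from explicit seeds; two
runs with the same configuration produce byte-identical artifacts. The
Weibull life-expectancy recovery uses an uncensored design so that events
cover the whole 45–100 integration range; recovery tolerances reflect the
sampling noise of those designs.

## Known limitations

- The multistate model treats baseline age as fixed rather than as a
  time-varying age effect on the follow-up timescale.
- The cumulative-hazard level in the life-expectancy model is a convention
  (power-law continuation), as it must be under universal delayed entry;
  absolute (unconditional) survival should not be over-interpreted.
- Ordered-logistic imputation fits on observed rows with mean-filled
  predictors rather than full chained equations.
- The generator's covariates are independent of outcomes, so covariate
  adjustment in the pipeline is exercised structurally, not substantively.
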