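# Methods

## The modelling problem

TBARS series from a meat storage experiment come as triplicate measurements
per sample group (control meat plus 13 extract treatments) at five constant
storage temperatures (4, 8, 12, 16, 20 °C), over up to 13 days of chill
storage and 5 days of abuse-temperature storage. The package estimates how
fast lipid oxidation proceeds (the rate constant), how that rate depends on
temperature (the secondary model), and what TBARS level to expect at any
time–temperature combination (the integrated predictor), and it ranks the
extracts' antioxidant efficacy.

## Primary kinetics

TBARS is normalized to percent of the day-0 value and modelled as
first-order growth, `TBARS(t) = 100 · exp(k t)`. `k` (day⁻¹) is the slope
of the OLS regression of `ln(TBARS%)` on time. Two intercept conventions
are provided:

- **free intercept (default)** — plain log-linear OLS; the intercept absorbs
  the day-0 observation noise that percent normalization propagates into
  every later point, so the slope is unbiased.
- **pinned intercept** — regression through `(0, ln 100)`; closed form
  `k = Σ tᵢ (ln pᵢ − ln 100) / Σ tᵢ²`. Provided because the model fixes
  `TBARS₀ = 100 %`, but the free intercept is the default precisely because
  the day-0 anchor is itself a noisy measurement.

The slope uses the centered closed form, so a constant series returns
exactly `k = 0`. R² is the squared Pearson correlation of `ln(percent)`
with time; for a constant series (zero variance) it is defined as 1 when
the residuals vanish. Replicates are summarized as mean ± sample SD
(n−1 denominator) of `k`; a single replicate is reported with SD 0 and a
flag.

## Secondary models

**Arrhenius.** `ln k = ln k₀ − Eₐ/(R T)` is fitted by OLS of `ln k` on
`1/T` with `R = 8.314 J mol⁻¹ K⁻¹`; `Eₐ = −slope · R`, `k₀ = exp(intercept)`.
The activation energy measures temperature sensitivity: the higher `Eₐ`,
the steeper the rate increase with temperature. The packaged reference
table uses the integer kelvins 277/281/289/293 for the nominal 4/8/16/20 °C
conditions, matching the source table's rounding, so refits reproduce the
printed parameters exactly within their printed SDs.

**Log-logistic (softplus).** `k(T) = m′ · ln(1 + exp(c (T − T_c)))` avoids
the activation-energy concept; `c` (K⁻¹) sets the steepness and `T_c` (K)
the bend. `m′` is pinned at 1 by default (the common simplification; a
3-parameter mode exists for ≥ 4 temperatures). Temperatures are kelvin
throughout: the published `T_c` values (294–308) are only meaningful in
kelvin against storage temperatures of 277–293 K. The fit is nonlinear
least squares on the `k` scale with Levenberg–Marquardt, multistarted from
the grid `c ∈ {0.02, 0.05, 0.1, 0.2, 0.5}` × `T_c ∈ {T_min − 10, median T,
T_max + 15}` because the two-parameter softplus surface has a flat,
curved valley; the lowest-SSE solution wins. Softplus is evaluated as
`logaddexp(0, x)` and is finite for arguments of ±10⁴. In tests the
optimizer is required to match or beat both the published `(c, T_c)` point
and a brute-force grid search (step 0.0005 × 0.05) in SSE; parameter-level
agreement with the grid argmin is asserted at the control anchor, where the
valley is steep enough for the argmin node to be identified to one cell.

The Arrhenius equation is implemented with the standard negative exponent
`k = k₀ · exp(−Eₐ/(R T))` everywhere; the fitted parameter tables are only
consistent with that sign.

## Integrated predictors and external validation

`TBARS(T, t) = 100 · exp(k(T) · t)` with `k(T)` from either secondary law.
Validation mirrors the study design: fit at 4/8/16/20 °C, hold out 12 °C,
and score predictions against the held-out observations. R² is
`1 − SSE/SST` (it penalizes bias, which squared-correlation R² would hide;
both are reported), RMSE is on the TBARS% scale, and adjusted R² uses
p = 2 parameters for either variant. Per-temperature metrics, their sum
(ΣR²), and pooled metrics are reported. Only constant-temperature storage
is modelled; no dynamic temperature profiles.

## Dummy-variable regression

`ln(TBARS%)` is regressed on time (days), temperature (°C — the published
coefficient scale, with intercept ≈ ln 100, is only consistent with small
Celsius values) and k−1 = 13 treatment indicators, control uncoded as the
reference. The solve is closed-form OLS with standard errors from the
inverse normal-equations matrix and two-sided t-tests on n−p degrees of
freedom; a rank-deficient design raises an error naming the offending
columns. Extracts are ranked by ascending coefficient: a more negative
slope offset means stronger oxidation inhibition relative to control.
Rows pool all replicates and time points with no within-series correlation
correction; since the replicate noise shares a day-0 anchor within each
series, the reported p-values are exact only under the linear model's iid
assumption — a known statistical limitation of this (standard) analysis.
The type-I calibration experiment therefore simulates under the linear
model itself; kinetic data additionally carry a time × temperature
interaction that plain MLR absorbs as lack of fit.

## MLP ensemble

Each observation is encoded as 16 inputs — 14 one-hot sample indicators
plus storage time and temperature, min-max scaled to [0, 1] on the training
split — with TBARS% as target, min-max scaled into [0.1, 0.9] so that both
output activations (exponential and logistic) can reach every scaled target
with finite weights. The data are split 2:1:1 into train/validation/test
(random, seeded; within one row of exact proportions). Twenty candidate
networks are drawn with per-candidate seeds: hidden size uniform on 3–9,
hidden activation tanh or logistic, output activation exponential or
logistic. Each is a single-hidden-layer perceptron trained by BFGS
(analytic gradients, sum-of-squares loss, at most 200 iterations) with
early stopping after 10 consecutive validation-error rises; the
best-validating parameter vector along the trajectory is kept.
Initialization is Glorot-style normal with the output bias started at the
pullback of the scaled-target mean. A candidate whose optimizer fails or
produces non-finite weights is excluded; the best 5 by validation R² form
the ensemble (ties break on validation error, then candidate seed), and
predictions are the member mean, which by convexity can never have higher
MSE than the members' average. The network is implemented directly in
numpy because the protocol requires output-layer activations and
quasi-Newton training with validation-based early stopping.

## Synthetic-study generator

The generator emulates the study design: for each group × temperature ×
replicate, sampling days 0, 1, 3, 5, 7, 9, 11, 13 at ≤ 12 °C and
0, 1, 2, 3, 4, 5 above (the source storage periods are 13 and 5 days; the
exact sampling days are the package's choice), true percent
`100 · exp(k(T) t)` with `k(T)` from the group's ground-truth law, and
observed raw values `0.25 mg/kg · (percent/100) · exp(ε)` with
`ε ~ N(−σ²/2, σ²)`, `σ = sqrt(ln(1 + CV²))` — unit-mean multiplicative
lognormal noise, chosen because TBARS is strictly positive and replicate
scatter grows with the mean. The default CV is 5 %, a plausible assay
repeatability; the true replicate noise of the original experiment is
unknowable from the published summaries, so recovery results quantify
estimator behaviour at this assumed noise level, not the original assay's.
The 12 °C condition is generated like any other so the held-out-validation
workflow can be rehearsed end to end. The generator does not emulate
systematic effects absent from the model — no lag phases, no plateau at
high oxidation, no between-day batch effects — so passing recovery tests
demonstrates correctness of the estimation chain, not robustness to model
misspecification in real data.

## Problem sizes and known limits

The recovery experiment uses 50 replicate studies; at 5 % noise the
activation-energy standard error of the full chain (free-intercept primary
fits, triplicate means, unweighted Arrhenius regression over four
temperatures) is ≈ 1.7 kJ/mol for every group. For the low-Eₐ groups
(≈ 52 kJ/mol: clove, cardamom, caraway, thyme) a 5 % relative band is
therefore only ≈ 1.5 SE wide, and the per-seed probability of landing
inside it is ≈ 87 %; groups with Eₐ ≥ 56 kJ/mol recover within 5 % in
≥ 90 % of seeds. A weighted Arrhenius regression would narrow this but
would depart from the standard ln k vs 1/T practice implemented here. The
median recovery error for any group is well under 1 %.

The regression-calibration experiment runs 1000 simulations of a compact
4-group design; the ensemble experiment trains 20 candidates on 10
replicate studies (1512 rows each). The full test suite and the
reproduction script each run in well under a minute on one CPU.
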