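# tbarskinetics

Kinetic and machine-learning shelf-life models of lipid oxidation in raw
ground pork enriched with plant extracts.

Lipid oxidation is the main chemical route by which raw meat loses quality
during chilled storage. Its standard index is TBARS (thiobarbituric-acid
reactive substances, expressed as mg malondialdehyde per kg meat, here
normalized to % of the initial value). This package implements the full
modelling chain a food-quality lab uses to turn TBARS storage series into
shelf-life predictions and antioxidant rankings:

- **Primary kinetics** — first-order growth per storage temperature,
  `TBARS(t) = TBARS₀ · exp(k t)` with `TBARS₀ = 100 %`, estimated by OLS of
  `ln(TBARS%)` on time (free or pinned intercept).
- **Secondary models** — temperature dependence of the rate constant by the
  Arrhenius law `k(T) = k₀ · exp(−Eₐ/(R T))` (fitted as `ln k` vs `1/T`,
  R = 8.314 J mol⁻¹ K⁻¹) and by the log-logistic (softplus) law
  `k(T) = m′ · ln(1 + exp(c (T − T_c)))` (multistart Levenberg–Marquardt,
  `m′ = 1` by default).
- **Integrated predictors** — `TBARS(T, t) = 100 · exp(k(T) · t)` for either
  secondary law, with external validation at a held-out temperature
  (12 °C in the study design) scored by R² = 1 − SSE/SST and RMSE on the
  percent scale.
- **Dummy-variable regression** — `ln(TBARS%)` on time, temperature (°C) and
  13 treatment indicators against the control, with t-tests ranking the
  extracts by oxidation inhibition (most negative coefficient = strongest).
- **MLP ensemble** — 16 inputs (14 one-hot sample indicators + time +
  temperature), 2:1:1 train/validation/test split, 20 candidate
  single-hidden-layer perceptrons (3–9 hidden units, tanh/logistic hidden,
  exponential/logistic output) trained by BFGS on sum-of-squares loss,
  best 5 by validation R² retained, ensemble-mean prediction.
- **Synthetic studies** — a generator reproducing the study design
  (14 groups × 5 temperatures × triplicates, multiplicative lognormal noise)
  for end-to-end parameter-recovery and validation rehearsals.

The packaged reference tables carry the published per-group rate constants,
Arrhenius parameters (Eₐ, k₀), log-logistic parameters (c, T_c) and the
antioxidant assay values (TEAC by DPPH, total phenolic content) for the 13
extracts.

## Worked example

```python
import tbarskinetics as tk

# refit the Arrhenius line to the published control rate constants
params = tk.load_secondary_fixture()["Control"]
fit = tk.fit_arrhenius(params.k_by_temperature, "Control")
print(f"Ea = {fit.ea:.0f} J/mol, k0 = {fit.k0:.3g} 1/day, R2 = {fit.r2:.4f}")

# integrated predictor: TBARS% in control meat after 7 days at 12 degC
model = tk.build_model("Control", "arrhenius", fit)
print(f"TBARS(12 degC, 7 d) = {tk.predict_tbars(model, 285.15, 7.0):.0f} %")
```

prints

```
Ea = 64528 J/mol, k0 = 1.72e+11 1/day, R2 = 0.9974
TBARS(12 degC, 7 d) = 614 %
```

i.e. the refitted activation energy reproduces the published
64 549 ± 505 J/mol, and the integrated model predicts a roughly six-fold
TBARS increase after a week of storage at 12 °C — untreated chilled pork
oxidizes fast, which is why the extract treatments matter.

The same chain runs end to end on synthetic data from the command line:

```bash
tbarskinetics run --out runs/demo --seed 7
tbarskinetics predict --sample Clove --temperature-c 4 --days 0:13:1
```

`run` writes per-stage JSON (primary fits, secondary fits, predictions,
held-out 12 °C validation, regression ranking, MLP ensemble) plus a
reproducibility manifest.

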