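# ohca-counterfactual

Regional counterfactual analysis of out-of-hospital cardiac arrest (OHCA)
outcomes from Utstein-style emergency medical service (EMS) records.

Japan's 47 prefectures adapt national resuscitation guidelines to local
conditions, so the EMS activity-time reductions most associated with better
neurological outcomes differ by region. This package implements the full
analysis for asking *which* reductions matter *where*:

1. **Registry** — a seeded synthetic generator of Utstein-style record tables
   (one row per adult cardiogenic arrest: demographics, witness/bystander
   fields, initial rhythm, intervention counts, minute-resolution activity
   times, ROSC, CPC outcome) with a known logistic ground-truth outcome model
   and region-varying time effects. The generator stands in for the
   non-public national registry and doubles as a Bayes-optimal oracle.
2. **Cohort filter** — age ≥ 18, cardiogenic etiology, valid activity times
   (non-negative, ≤ 24 h, present when the intervention was performed).
3. **Encoding** — one-hot categoricals with explicit `missing` levels,
   minute-bin one-hot activity times with `no intervention` and overflow
   bins, z-scored continuous variables (training-set parameters only),
   prefecture as a continuous or one-hot feature.
4. **Outcome model** — a five-hidden-layer neural network (batch norm,
   dropout, sigmoid output, Adam, batch 1,024) predicting good neurological
   outcome (CPC1/2, ~5% of records). The positive-class weight `w` in the
   loss

   `L = −mean[ w·y·log p + (1−y)·log(1−p) ]`

   is swept over 1.0–100.0 in 0.1 steps and calibrated by five-fold
   stratified cross-validation so CPC1/2 sensitivity reaches 80% while
   CPC3–5 sensitivity stays maximal.
5. **Counterfactual grids** — for the factor pairs transport×defibrillation
   and transport×drug-administration, every joint minute shift
   (δ_transport ∈ −5..+10, δ_intervention ∈ −5..+5) is applied to the
   eligible test records (shockable rhythms only for defibrillation;
   EMS-witnessed arrests excluded for drugs), re-encoded with the fitted
   schema, and summarised as the percent change in mean predicted CPC1/2
   against the unadjusted cell:

   `pct(δt, δi) = 100 · (mean p(δt, δi) − mean p(0, 0)) / mean p(0, 0)`

6. **Reporting** — diverging heatmaps of each surface (baseline cell
   outlined), per-prefecture panels, and a best-adjustment summary table.

## Worked example

```python
import ohca_counterfactual as oc

cfg = oc.GroundTruthConfig(n_records=50_000, seed=101)
table = oc.generate_cohort(cfg)
table, report = oc.apply_inclusion(table)
train, test = oc.stratified_split(table, 0.2, seed=101)

schema = oc.fit_schema(train)
net = oc.train_model(
    oc.encode(train, schema), train["cpc12"].to_numpy(int),
    oc.ModelConfig(hidden_width=64, epochs=30, seed=101), class_weight=20.0,
)
print(oc.evaluate(net, test, schema))

grid = oc.simulate_grid(net, schema, test, oc.AdjustmentSpec("transport_defib"))
print(grid.pct_change(-5, -5), grid.pct_change(10, 5))
print(oc.best_adjustment(grid))
```

prints (seed 101):

```
EvalMetrics(auroc=0.8152909951521546, accuracy=0.8269,
            sens_cpc12=0.6929133858267716, sens_cpc35=0.834070796460177,
            n=10000)
15.243980380951102 -35.69...
(-5, -5, 15.243980380951102)
```

The test AUROC of 0.815 sits within 0.03 of the Bayes-optimal 0.831 computed
from the generator's exact probabilities. The defibrillation-pair surface
rises +15.2% when both times drop 5 minutes and falls −35.7% when transport
lengthens 10 minutes and defibrillation 5 — shorter activity times are
associated with better predicted outcomes, and the (−5, −5) corner is the
best adjustment. Class weight 20 (≈ 1/prevalence) trades CPC3–5 sensitivity
for CPC1/2 sensitivity relative to an unweighted fit; the calibrated sweep
(`oc.calibrate_class_weight`) picks the weight meeting the 80% CPC1/2
sensitivity target automatically.

A full pipeline (generate → filter → split → calibrate → train → evaluate →
simulate → report, with a reproducibility manifest) is available as
`ohca-cf run-all --seed 0 --out runs/demo` or `oc.run_pipeline(...)`.

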