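# Methods

## The question and the approach

Emergency medical service (EMS) activity times — from patient contact to
hospital arrival, to first defibrillation, and to first drug administration —
are strong prognostic factors in out-of-hospital cardiac arrest (OHCA), and
regions adapt their protocols independently. The package trains a classifier
of good neurological outcome (cerebral performance category 1–2, "CPC1/2") on
Utstein-style records and then perturbs the three activity times minute by
minute in the held-out test set, reading off the percent change in the mean
predicted CPC1/2 probability. Stratifying the perturbation surfaces by
prefecture shows which time reductions are associated with the largest
predicted gains in each region. The outputs are model-predicted
*associations* under input perturbation, not causal effects; no
identification assumptions are made or needed for the stated claim.

## Synthetic registry

The national registry is not public, so the package ships a generative
stand-in whose outcome law is known exactly. One record is one adult
cardiogenic arrest: prefecture (1..47), demographics, witness and bystander
fields, initial rhythm, airway management, intervention counts,
minute-resolution activity times (integers; absent interventions carry no
time), prehospital ROSC, and the binary CPC1/2 label.

The label is Bernoulli with logit linear in: transport time, defibrillation
time (shockable-rhythm cases only, in the defaults defibrillation is
essentially confined to VF/pulseless VT), drug time, shockable rhythm,
witnessed status, ROSC, and centred age. Default coefficients (log-odds per
minute or per indicator): transport −0.04, defibrillation −0.10, drug −0.05,
shockable +2.0, witnessed +0.8, ROSC +3.0, age −0.02/y. Each prefecture
scales the three time coefficients by its own modifiers (default: drawn once
from the seed, uniform in [0.5, 1.5]) — this is the regional heterogeneity
the counterfactual analysis is meant to recover. The intercept is tuned by
bisection so the cohort-mean outcome probability equals the target prevalence
(default 5%); realized prevalence then sits within binomial noise of the
target.

Marginals mimic a national registry's published profile: age ≈ N(78, 14)
clipped to ≥ 18; 57% male; rhythm mix ≈ 9% VF / 0.3% pulseless VT / 21% PEA /
65% asystole; call-to-contact ≈ 2 + Poisson(7) (median 9 min); transport time
≈ discretised lognormal, median 23 min; defibrillation in shockable cases
plus a 2% fraction of others; drugs in 23% of cases (median 14 min); ROSC
10%. Missingness is injected missing-completely-at-random per field, with
default rates 7.2% (witness type), 21.5% (bystander compressions), 38.3%
(bystander ventilation), 0.2% (airway device).

What the generator does **not** emulate: inter-field correlations beyond
those implied by the outcome law (e.g. witness type vs bystander CPR),
informative missingness, temporal drift across onset years, or
prefecture-specific case-mix differences (prefecture sizes are uniform by
default). Tests passing on this generator therefore demonstrate that the
pipeline recovers a known data-generating process of the assumed logistic
form — not that the real registry satisfies that form.

## Cohort filter

Rules in fixed order, each record counted at its first failure: (1) age ≥ 18;
(2) cardiogenic etiology; (3) time validity — all present elapsed times
non-negative, intervention times ≥ 1 min when the intervention was performed
(a performed intervention with a missing time is excluded here), every
activity time ≤ 1,440 min, and age/etiology present. The 24-hour ceiling is
applied to each elapsed-time field independently — the strictest reading —
and the ceiling is a parameter of `apply_inclusion`. Filtering is idempotent
and row-order independent.

## Encoding

* Categoricals (sex, onset month, witness fields, bystander fields, rhythm,
  airway, ROSC) are one-hot with an explicit `missing` level in every group;
  unseen levels at transform time map to `missing` with a warning, so the
  design width is fixed by the schema.
* Activity times are one-hot at minute resolution (their outcome relation is
  non-linear in general): bins 1..t_max, an overflow bin, and — for
  defibrillation and drugs — a `no intervention` bin. Defaults: t_max = 120
  for transport, 60 for the two interventions. The ceilings are conventions
  (they keep vectors finite under the 24-h filter); adjusted times beyond
  t_max fall in the overflow bin and are counted in the log.
* Continuous variables (age, onset year, call-to-contact time, intervention
  counts, and prefecture number in continuous mode) are z-scored with
  training-table means/SDs; zero variance is an error naming the field.
* Prefecture is continuous by default (numbering is roughly north-to-south,
  so adjacency carries weak spatial information) with a one-hot mode for
  sensitivity analysis.

Feature order is canonical (sorted field name, then level order), so matrices
are reproducible across runs; every one-hot group sums to exactly 1 per row.
The fitted schema hashes all parameters, which the tests use as a leakage
guard: encoding held-out data can never change a fitted parameter.

## Outcome network

Five hidden layers, ReLU activations with batch normalisation and (inverted)
dropout per layer, a sigmoid output unit and binary cross-entropy loss,
optimised by Adam at learning rate 0.001 with batch size 1,024 for 100
epochs; no early stopping by default. Hidden width defaults to 256 and
dropout to 0.3 (configurable). The network is written directly in NumPy —
explicit forward/backward passes, Adam state, and batch-norm running
statistics — which makes training bit-reproducible for a fixed seed
(initialisation, shuffling and dropout masks all derive from it) with no
framework dependency. Batches smaller than two records are skipped when
batch norm is on (their statistics are undefined).

Class imbalance (~5% positives) is handled in the loss: positive-class terms
are multiplied by a weight `w`, and classification stays at threshold 0.5 —
calibration moves the weight, never the threshold. The sweep tests
w ∈ {1.0, 1.1, …, 100.0}: among grid points whose five-fold cross-validated
CPC1/2 sensitivity reaches the 80% target, the selected point maximises
CPC3–5 sensitivity, ties toward the smaller weight. Because minority
sensitivity is non-decreasing and majority sensitivity non-increasing in `w`
(up to CV noise), that optimum is the smallest feasible weight, which a
bisection over the grid finds in ~10 probes; a full scan is available via
`search="full"`. Each probe fits a logistic-regression surrogate per fold;
the network itself is then cross-validated at the final candidate and, if it
falls short of the target, the search resumes upward with network-based
probes. The reported sensitivity is always the network's own CV mean. The
80% constraint is assessed on the CV-fold mean. An infeasible target returns
the most sensitive probed point, flagged rather than raised.

Every fold refits the encoding schema on its own training part; schema hashes
are asserted distinct in the tests (no preprocessing leakage).

## Counterfactual grids

A grid is declared by a factor pair, two contiguous integer delta ranges that
must contain 0 (defaults −5..+10 for transport, −5..+5 for the
intervention), and an eligibility rule: the defibrillation pair keeps only
shockable initial rhythms; the drug pair drops EMS-witnessed arrests (their
pre-contact times are undefined). Eligibility is applied once, to the whole
grid including the baseline, so every cell averages over the same records.

Per cell both deltas are applied jointly: each present time becomes
max(1, t + δ) — absent interventions are never shifted, and no delta can
create or remove an intervention — the records are re-encoded with the
*fitted* schema and scored, and the mean predicted probability is the cell
value ("expected CPC1/2 count" per record; a thresholded-count mode is
available). Percent change is taken against the (0, 0) cell of the same
grid, so the baseline cell is exactly zero by construction. Per-prefecture
grids require ≥ 50 eligible records by default; smaller strata are skipped
with a warning. The best adjustment is the cell with maximal percent change,
ties broken toward the smallest total absolute adjustment, then toward
transport reduction.

Known limitation: shifting transport and intervention times independently can
produce orderings impossible in practice (e.g. a drug time exceeding the
shifted hospital-arrival time); no cross-field consistency is enforced, since
each factor is encoded separately.

## Numerical and design choices

* Float32 arithmetic inside the network (BLAS-friendly); probabilities are
  returned in float64. The logistic in the generator is computed in a
  numerically stable split form.
* Intercept bisection runs 100 halvings on [−30, 30] — resolution ~1e-28,
  far below label noise.
* Grid means are float64 over identical record orderings, so the brute-force
  equivalence tests hold to 1e-9.
* Reported experiments use desk-scale sizes chosen once: cohorts of 50,000
  records for calibration and Bayes-gap checks, 5,000-record tables for grid
  checks, and a 64-wide network trained 15–30 epochs; the paper-scale
  defaults (width 256, 100 epochs) remain the `ModelConfig` defaults.
* The pipeline config is YAML validated by pydantic models; every run writes
  a manifest (config hash, seeds, per-stage counts, metrics, artifact paths)
  sufficient to reproduce the run.

## What the tests show

The suite verifies: prevalence control and oracle consistency of the
generator; filter arithmetic on hand-enumerated tables; one-hot partition,
z-score, overflow and leakage properties of the encoding; split/CV stratified
arithmetic; the weighted-loss direction; exact agreement of the grid engine
with an independently coded per-record brute force; exact baseline identity;
recovery of a planted 3×-vs-0× regional drug effect in ≥ 90% of replicates;
the sign of the pooled surfaces under harmful time effects; the calibrated
weight reaching 80% CV CPC1/2 sensitivity; and the trained network scoring
within 0.03 AUROC of the Bayes optimum computed from the generator's exact
probabilities. All of these are statements about the synthetic data-generating
process described above.
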