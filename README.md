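# ubandit

Estimation-uncertainty in reinforcement learning: simulators, models,
fitting and model-agnostic analyses for two-phase probabilistic bandit
tasks.

## The problem

When people learn option values from partial feedback (only the chosen
option's outcome is revealed), better-learned pairs are sampled
asymmetrically: the Good option is chosen often and becomes well known,
while the Bad option is rarely sampled and its value estimate stays
uncertain. `ubandit` is built to study whether this *estimation-
uncertainty* — not just expected value — shapes choices, both during
learning and in a later feedback-free test phase where previously learned
options are recombined into new pairs.

The package targets researchers in computational cognitive modelling /
decision neuroscience who want to simulate such experiments, fit
trial-level choice models, compare them at the group level, and validate
the pipeline with model- and parameter-recovery studies — all on synthetic
cohorts, with no data download required.

## Models

Six learning rules update the expected value `Q_i` of the chosen option
`i` from outcome `R`:

* **1α** — Q-learning, `Q_i ← Q_i + α δ_i` with `δ_i = R − Q_i`;
* **2α** — separate rates `α₊ / α₋` for positive / negative `δ`;
* **SelectReject** — additionally updates the rejected option with the
  reverse-signed prediction error, `Q_rej ← Q_rej + α_rej (−δ_sel)`;
* **RELATIVE** — centers outcomes on a learned context value `V_c`,
  `δ_i = R − V_c − Q_i`, with `V_c` tracking `(R + Q_rej)/2`;
* **RANGE** — normalizes outcomes by learned range trackers,
  `R_RAN = (R − R_MIN)/(1 + R_MAX − R_MIN)`;
* **Kalman** — a Kalman filter with per-option uncertainty `σ_i`:
  `α_i = σ_i²/(σ_i² + σ₀²)`, `Q_i ← Q_i + α_i δ_i`,
  `σ_i² ← σ_i² − α_i σ_i²`. `σ_i` shrinks monotonically with the number
  of times option `i` was sampled; `σ₀` is the standard deviation of the
  task's outcome alphabet (no free learning-rate parameter).

Two softmax decision rules map beliefs to choices,
`p_i = e^{u_i}/(e^{u_i} + e^{u_j})`:

* **Q**:  `u_i = Q_i β_Q`
* **QU**: `u_i = Q_i β_Q + σ_i β_U`  (negative `β_U` = uncertainty
  aversion)

The Kalman σ-recursion can be attached to any value learner
(`attach_uncertainty_tracker`), because σ depends only on which option
was sampled — yielding the full 6 × 2 model grid.

Fitting is per-subject MAP (Gaussian priors, mean 0.5 for rates and 0 for
weights, variance 16.25, truncated to bounds α ∈ [0,1], β ∈ [−20,20]),
with a bound-aware Laplace approximation of the model evidence and
variational random-effects Bayesian model selection (model frequencies,
protected exceedance probabilities). Model fit is summarized by
McFadden's pseudo-R² = 1 − LL/LL_null against a coin-flip null.

## Worked example

```python
import ubandit as ub

design = ub.make_main_design()                       # 5 conditions x 3 blocks
cohort = ub.generate_cohort(20, "kalman:qu", design, seed=7)

perf = ub.learning_performance(cohort)
print("mean learning performance: %.3f" % perf["performance"].mean())

fits = ub.fit_dataset(cohort, ["kalman:q", "kalman:qu"], phase="learning", seed=0)
table = fits.pivot(index="subject", columns="model_id", values="log_evidence")
result = ub.rfx_bms(table.to_numpy(), model_ids=list(table.columns), seed=0)
for m, f, pxp in zip(result.model_ids, result.model_frequencies,
                     result.protected_exceedance):
    print(f"{m:10s}  frequency={f:.3f}  pxp={pxp:.3f}")
```

prints

```
mean learning performance: 0.690
kalman:q    frequency=0.057  pxp=0.001
kalman:qu   frequency=0.943  pxp=0.999
```

The 20 virtual subjects learned above chance (0.690 vs 0.5), and group
model selection correctly attributes their behavior to the generating
Kalman:QU model (protected exceedance probability 0.999) rather than the
value-only Kalman:Q variant.

The same pipeline is available from a shell:

```bash
ubandit simulate --design main --model kalman:qu --n 20 --seed 7 --out runs/sim
ubandit fit --trials runs/sim/trials.csv --models kalman:q,kalman:qu --out runs/fits
ubandit compare --fits runs/fits/fits.csv --out runs/bms
ubandit analyze --trials runs/sim/trials.csv --out runs/tables
ubandit recover --mode params --n 50 --out runs/recovery
```

## Layout

```
src/ubandit/
  designs.py    experiment designs, ground-truth EV/entropy, schedules
  learners.py   the six learning rules + uncertainty-tracker composition
  deciders.py   softmax choice rules
  cohort.py     synthetic-cohort simulation
  fitting.py    likelihood replay, MAP, Laplace evidence, pseudo-R^2
  bms.py        random-effects Bayesian model selection
  recovery.py   model-/parameter-recovery harnesses
  behavior.py   sampling-rate statistics, correlations, permutation test
  io.py, cli.py trial CSV dialect, configs, command-line interface
docs/methods.md detailed model, fitting and design notes
```
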