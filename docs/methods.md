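# Methods notes

## Task designs

**Main design.** Five conditions, each a pair of one Good option
(positive feedback with probability 0.75) and one Bad option (0.25).
Conditions differ in `p_appetitive` ∈ {1.0, 0.75, 0.5, 0.25, 0.0}, the
probability that feedback is drawn from an appetitive context (positive /
negative feedback = +1 / 0 currency units) rather than an aversive one
(0 / −1). On each feedback we draw context ~ Bernoulli(p_appetitive) and
valence ~ Bernoulli(q_role) independently; this factorization reproduces
all marginal outcome probabilities the design states. An option's expected
value is therefore `p_appetitive − (1 − q_role)` and the Good − Bad gap is
0.5 in every condition; outcome entropy varies non-monotonically in
`p_appetitive` and is reported in nats by default (bits via `base="bits"`),
since no log base is canonical for this quantity.

Learning: 3 blocks × 5 conditions × 16 consecutive trials = 240 trials,
fresh option pairs per block (option ids `"{block}_{condition}_{G|B}"`,
which makes test-pair construction and sampling-rate joins unambiguous).
The condition order of block 3 reverses block 1; block 2 is randomized
independently. Test: per block all C(5,2) Good-vs-Good and Bad-vs-Bad
recombinations (30 + 30), plus 30 Good-vs-Bad pairs combining a Good
option with the same condition's Bad option from a different block; each
unique pair is shown twice (180 trials), in randomized order, without
feedback. Left/right screen position is randomized uniformly per trial
and recorded but has no effect in any model.

**Validation designs.** Four pairs with reward probabilities 0.75 / 0.25
and magnitudes +10 (pairs A1B1, A2B2) or +1 (C1D1, C2D2) versus 0;
30 learning trials per pair, presented interleaved or block-wise; test
pairs exactly {A1C1, B1D1, A2D2, B2C2} × 30, feedback-free. These are
encoded with the same condition type by setting both contexts' positive
magnitude to the pair's reward, which keeps value/entropy ground truths
and belief initialization uniform across designs.

## Belief initialization

`q0` is the mean and `σ0` the standard deviation of the experiment-wide
outcome alphabet under equal outcome probabilities: alphabet {−1, 0, +1}
gives `q0 = 0`, `σ0 = √(2/3)`; the validation alphabet {0, 1, 10} gives
`q0 = 11/3`, `σ0 ≈ 4.497`. Using the experiment-wide alphabet (rather
than per-pair alphabets) mirrors the main design's recipe; per-pair
initialization would require options to know their context before any
feedback, which the partial-feedback setting does not grant. Context
trackers start at `V_c = 0` and `R_MAX = R_MIN = 0`; zero is the
omnipresent non-reward outcome in all supported designs, and the trackers
are ordinary fields, so alternative initializations are a one-line change.

## Learning rules

The update equations are listed in the README. Implementation decisions
worth recording:

* **2α** at exactly zero prediction error performs no update (neither the
  positive nor the negative branch applies).
* **Kalman** updates only the observed option; the environment is static,
  so there is no diffusion term and unsampled options keep `σ = σ0`
  exactly. Closed forms follow from the recursion: after `k` observations
  `σ² = σ0²/(k+1)`, the effective learning rate is `1/(k+1)`, and `q`
  equals the running mean `(q0 + ΣR)/(k+1)` — i.e. the prior acts as one
  pseudo-observation. These closed forms serve as the oracle for the
  sequential implementation in the tests.
* **Composition.** The σ-recursion depends only on which option was
  sampled, never on how its value is learned, so it can be attached to
  any learner (`attach_uncertainty_tracker`) to support the QU decision
  rule on top of it. The likelihood kernel always runs the recursion;
  it is simply unread when the decider ignores σ.
* **RANGE** computes `R_RAN` from the trackers *before* they absorb the
  current outcome, so the very first outcome in a context is normalized
  against the initial range.

## Decision rules and numerics

Choice probabilities are computed as a logistic of the utility difference
via `scipy.special.expit` / `log_expit`. With weights bounded at |20| and
validation rewards of magnitude 10, naive exponentiation of utilities
overflows; the logistic-of-difference form is exact and saturates
gracefully. There is no lapse parameter.

## Synthetic cohorts

A virtual participant is (learner, decider, parameter draw). Learning
trials sample a choice from the softmax, then an outcome from the chosen
option's generative tree (fresh i.i.d. draw per trial), then update
beliefs — partial feedback throughout. Test trials sample choices from
the frozen end-of-learning beliefs and never update. Test-phase decision
weights are an independent draw from the learning-phase ones, matching
the separate per-phase fits; the two draws live side by side in the
cohort manifest for recovery joins. Each subject owns an RNG stream
seeded by (master seed, subject index), so cohorts are reproducible
under any iteration order, and per-subject schedule randomizations are
derived from that stream.

Default parameter sampler for recovery studies: rates uniform on [0, 1],
`β_Q ~ U(0.5, 6)`, `β_U ~ U(−8, 0)` — uniform over the span of fitted
subject-level values. A second sampler (`fitted_sampler`) draws decision
weights from truncated normals around the group-level fitted means
(learning: β_Q ≈ 2.9 ± 1.47, β_U ≈ −1.1 ± 2.07; test: β_Q ≈ 1.2 ± 0.74,
β_U ≈ −5.5 ± 2.14, truncated to the ranges above) and is used to emulate
a realistic, uncertainty-averse population.

What the generator does *not* emulate: reaction times, forgetting between
blocks, working-memory contributions, and any non-stationarity of the
contingencies. Passing recovery and sign-pattern tests therefore shows
the pipeline is sound under the task's assumed generative structure, not
that real participants satisfy that structure.

## Fitting

Each model is fit separately per phase. Learning fits replay the
subject's recorded choices and outcomes, accumulating `log p(choice)`
before each update. Test fits replay the full learning history first —
under partial feedback the subject's own sampling determines what was
observed, so beliefs cannot be reconstructed any other way — then score
the 180 test choices only, with any learner parameters fit jointly with
the test-phase decision weights.

MAP estimation maximizes `LL + log prior` with L-BFGS-B under the bounds,
from the prior mean plus 9 uniform random restarts (10 total); the best
restart wins and non-convergence is flagged rather than silently NaN'd.
Priors are independent Gaussians (mean 0.5 for rates, 0 for weights,
variance 16.25) truncated and renormalized over the bounds — effectively
near-flat on [0, 1] for rates, in keeping with the deliberately broad
priors of the original fitting setup. The likelihood replay itself is a
numba-compiled kernel mirroring the reference (object-level) update
rules; a test pins the two paths to 1e-9 agreement across all twelve
models and both phases.

**Evidence.** A Laplace approximation at the MAP with a central
finite-difference Hessian of the negative log posterior. Two safeguards
matter in practice. First, eigenvalues are floored at the prior
precision: the optimized objective includes the prior, so no direction
can truly be flatter than that, and the floor also regularizes Hessians
at a bound. Second, the Gaussian volume along each eigendirection,
`√(2π/w)`, is truncated at the width of the feasible parameter box along
that direction. Without this truncation a weakly identified learning rate
on [0, 1] would be credited with `√(2π·16.25) ≈ 10` units of volume —
an order of magnitude more than the interval holds — systematically
inflating the evidence of over-parameterized models. A test checks the
resulting evidence against 2-D trapezoid integration of the exact
posterior to 0.2 nats.

**Group selection.** Variational random-effects model selection over the
subjects × models evidence matrix (Dirichlet prior α₀ = 1): exceedance
probabilities by Dirichlet Monte Carlo (exact Beta integral for two
models), and protected exceedance probabilities
`PXP = EP·(1 − BOR) + BOR/K`, where the Bayesian omnibus risk compares
the random-effects free energy against the fixed equal-frequency null.
This MAP + Laplace + RFX-BMS stack is a deliberately simple stand-in for
concurrent hierarchical fitting: it produces the same outputs (subject
parameters, model frequencies, PXP) without hierarchical shrinkage of
per-subject estimates.

## Recovery harnesses

Model recovery simulates a cohort per generating model, fits all
candidates, and stacks the BMS model frequencies into a confusion matrix;
the minimal bar is that every row's argmax lies on the diagonal. For the
test phase, learning behavior is generated by the winning learning model
(Kalman:QU) and only test choices vary by candidate. Parameter recovery
correlates generating against recovered values per parameter. Defaults
are n = 50 virtual subjects (desk scale); the headline parameter-recovery
runs use n = 200.

Known limitation, measured rather than hidden: test-phase `β_U` recovery
reaches ≈ 0.83–0.89 here versus ≈ 0.94 under hierarchical fitting. The
cause is identifiable in the scatter: subjects whose learning draw gives
weak value guidance sample both options evenly, so their test pairs carry
almost no σ contrast, `β_U` is unidentifiable from their 180 test
choices, and the MAP falls back to the prior mean 0 — outside the
generating range — attenuating the correlation. Hierarchical shrinkage
toward the group mean would instead land such subjects mid-range. The
per-subject MAP stand-in keeps this attenuation; it is visible in the
recovery report's per-subject table.

## Behavioral statistics

Learning performance is the proportion of Good choices per pair; under
partial feedback the sampling rate of the Good option equals it exactly
and the Bad option's is its complement — the package asserts this as an
identity, not an estimate. Test selection rates are computed per unique
pair toward a reference option, defined uniformly as the option with the
higher true expected value (the Good option in Good-vs-Bad pairs).
Performance-selection correlations are reported per condition (GvB), per
pairwise comparison and pooled by pair type (GvG/BvB), with Pearson and
Spearman side by side; zero-variance cells are flagged instead of
propagating NaNs.

The permutation test for a difference of correlations `Δr = r(actual, A)
− r(actual, B)` shuffles the actual vector (1000 permutations by
default), reports the two-tailed p as the proportion of null `|Δr|` at
least as large as the observed one (ties count toward the null, so
identical comparands yield p = 1 rather than 0), the [2.5, 97.5]
percentile band of the null, and the standardized effect size
`SES = (Δr − mean(Δr_null))/std(Δr_null)`. Calibration is verified by
simulation: under an uninformative null the rejection rate at α = 0.05
is 0.05 ± 0.02 over 500 replicate datasets.

Linear mixed-effects ANOVAs over selection biases are not re-implemented;
their scientific content — condition-wise and pair-type-wise contrasts of
performance-selection coupling — is covered by the correlation tables and
the permutation machinery above.

## Problem sizes and defaults

The shipped defaults are the study's conditions: 240 learning + 180 test
trials per subject, 200 virtual participants for parameter recovery,
50 per generating model (across all 12 models) for the confusion matrix,
1000 permutations, 10 optimizer restarts, 200,000 Dirichlet samples for
exceedance probabilities. The full test suite, including the recovery
studies at these sizes, runs in roughly ten minutes on a single CPU.
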