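# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic test suite does and does not show.

## Problem format and containers

A `Problem` is a CPC15-format gamble pair.  Gamble A is always the
two-outcome lottery {`Ha` w.p. `pHa`; `La` otherwise}.  Gamble B's high
branch (`Hb` w.p. `pHb`) may be spread over `lot_num_b` outcomes:

- **symmetric** — `lot_num_b` (odd) outcomes at unit spacing centred on
  `Hb`, weighted by Binomial(`lot_num_b`−1, ½), total mass `pHb`;
- **right-/left-skewed** — outcomes at `Hb ± (2^j − 1)` for
  `j = 0 … lot_num_b−1` with geometrically decaying probabilities
  (ratio ½), the long tail pointing in the skew direction.

The skewed expansion is a reconstruction of the published format
description from its qualitative shape (geometric decay, widening
spacing); it is the one place where the container layer carries fidelity
risk, and every downstream computation is independent of the specific
choice — only tests that pin exact expanded supports would notice.

`ChoiceObservation` stores, per (problem, block), the participant count
`n` and the aggregate B-choice rate.  Blocks are first-class: choices13k
has two five-trial blocks, CPC15 five, and the models receive the block
index as a base feature.  Train/test splits operate at the problem level
(all blocks of a problem travel together) and are stratified by the
feedback flag so neither side is starved of either condition.

## Stochastic dominance

Dominance of discrete lotteries is decided exactly on the union support.
With CDFs `F_A`, `F_B`:

- **FOSD**: `F_A ≤ F_B` everywhere, strictly somewhere;
- **SOSD**: `D2(t) = ∫_{−∞}^t (F_B − F_A) du ≥ 0` for all `t`, strictly
  somewhere.  The integrand is a step function, so `D2` is piecewise
  linear and its sign is decided at the support points plus the limit
  `D2(∞) = EV(A) − EV(B)`;
- **TOSD**: `D3(t) = ∫ D2 ≥ 0` for all `t` **and** `EV(A) ≥ EV(B)`.
  `D3` is piecewise quadratic; interior minima (where the linear `D2`
  crosses zero inside a support gap) are evaluated in closed form, so the
  decision is exact, not grid-approximated.

Numerical tolerances scale with the payoff magnitude (1e−9 relative) so
that equal-up-to-rounding distributions are classified as "neither".
Lower-order dominance implies higher-order dominance; the suite checks
this nesting on 10,000 random problems.

## Features

Signed features are oriented positive-favours-B, matching the target
P(B); `Dom`, `SOSD`, `TOSD` are +1 when B dominates.  `pBbet_Unbiased1`
couples the lotteries independently (described choice, no feedback);
`pBbet_UnbiasedFB` couples them by the problem's correlation flag
(+1 comonotone, −1 antimonotone) — the joint a participant experiences
once outcomes are revealed.  `diffBEV0`/`diffBEVfb` are best-estimate
EV differences with ambiguity resolved pessimistically before feedback
and exactly after.  The feature list covers the named naive and
psychological features; the full historical feature battery from which
they were drawn is larger, and unimplemented members are deliberately out
of scope.

## BEAST

An agent decides for A iff
`[BEV_A − BEV_B] + [ST_A − ST_B] + e > 0`, with `e ~ N(0, σ)`.
Population predictions average 4,000 agents whose properties are drawn
uniformly from `[0, upper_bound]`:

| property | default upper bound | role |
|---|---|---|
| `sigma` | 8.0 (payoff units) | decision-noise s.d., halved under FOSD |
| `kappa` | 5 | number of sampling-tool draws (integer ≥ 1) |
| `tool_*` (4) | 1.0 | relative tendency for each sampling tool |
| `pessimism` | 1.0 | ambiguity resolution and worst-case weighting |
| `feedback` | 1.0 | pull toward the true distribution in feedback blocks |

The four tools concretize qualitative tendencies: uniform draw over
distinct outcomes; a true-distribution draw with payoffs replaced by
`sign(payoff)·max|payoff|`; the minimum outcome; and a regret draw that
applies one shared uniform quantile to both inverse CDFs.  Under
unresolved ambiguity the tools sample B from a uniform belief over its
outcomes, and BEV(B) blends the uniform-probability estimate with the
worst case by the agent's pessimism weight.  In feedback blocks ≥ 2,
ambiguity is resolved and each draw is replaced, with probability equal
to the agent's feedback weight, by an unbiased draw from the true
distribution coupled by the problem's correlation.  The σ/2 dominance
reduction, the tool formulas and the identity of the last two agent
properties are this package's concretizations of qualitative
descriptions; the upper bounds are not hard-coded doctrine but fitted by
`fit_upper_bounds` (full-product grid search, ties toward the smallest
bounds vector).

Per-(problem, block) predictions use a dedicated RNG substream keyed by
the config seed and a CRC of the problem id and block, so predictions are
reproducible and independent of evaluation order, with seed-to-seed
variance at the binomial bound `0.25/n_agents`.

## Synthetic study conditions

The generator is the package's stand-in for the real data collections and
its defaults are fixed study conditions, not tuning knobs: payoffs
log-uniform on [1, 100] rounded to integers (low branch strictly below
the high branch), probabilities from a CPC-style grid
{0.01, 0.05, …, 0.95, 0.99, 1.0}, 30% of problems with a multi-outcome
B-shape, ambiguity and feedback each at rate 0.2, correlation −1/0/+1
with probabilities 0.1/0.8/0.1, five blocks for feedback problems, 15
participants per online problem, and online corruption at the fitted
posterior means `f = 0.6236`, `p_guess = 0.2757`.  The recovery
experiment uses round-number truth (`f = 0.6`, `p_guess = 0.25`), 1,000
problems and 100 participants.  What the generator does **not** emulate:
the marginal payoff distributions of any specific published problem set,
participant-level heterogeneity, and sequential (within-block) effects —
aggregate rates are generated directly.  Tests passing on these
conditions therefore validate the machinery (estimators, invariances,
recovery), not claims about any particular real dataset.

## Decision-noise model and inference

Per problem `i`: `k_i ~ Binomial(n_i, p_final,i)` with
`p_final,i = (1 − p_guess)·σ(f·logit(p_i)) + p_guess/2`, where `p_i` is
the lab-side choice probability (clipped to [1e−6, 1−1e−6] before the
logit).  Priors are Uniform(0, 2) on `f` and Uniform(0, 1) on `p_guess`.
The single-binomial observation model is mathematically the mean of the
guesser/non-guesser mixture; modelling the two counts separately would
only matter at very small `n`.

The posterior is sampled with the emcee affine-invariant ensemble sampler
(32 walkers, 1,000 warm-up steps, at least 1,500 retained steps per
walker, ≥ 10,000 retained draws), a reliable choice for this smooth
two-dimensional posterior.  Split-R̂ and bulk ESS are computed via arviz
with walkers as chains; R̂ > 1.05 raises a warning and flags the result —
never silently.  Parameter recovery at the default conditions returns
posterior means within ±0.05 of truth with the truth inside the central
95% interval, and the identity regime (`f = 1`, `p_guess = 0`)
concentrates at the boundary as it should.

## Choice models

The sparse MLP follows the published architecture (200/275/100 SReLU
units, dropout 0.15, RMSProp, sigmoid output, MSE loss).  SReLU carries
four learnable parameters per unit, initialized to identity behaviour
(unit slopes, thresholds ±1).  Sparse evolutionary training uses one
sparsity level for all layers — the active fraction `ε = 0.2` of possible
connections — and per epoch removes the `ζ = 0.3` fraction of smallest
positive and largest negative active weights, regrowing the same number
of random connections (count conserved, asserted).  The published
hyperparameter search over SET parameters and batch size is replaced by
these fixed defaults.  Pre-training runs at lr 1e−3 with best-validation
checkpointing (10% held out); fine-tuning at lr 1e−6 with rewiring off.
The context network (two 32-unit sigmoid layers, Adam 1e−3, 100 epochs,
optional 20-epoch pre-train) predicts P(A) from zero-padded
`(x_A, p_A, x_B, p_B)` vectors of up to 10 outcomes per gamble and by
construction ignores ambiguity/correlation/feedback/block; it is
reported as P(B) = 1 − P(A).  It has no regularization and is expected to
overfit very small datasets.  Random forest (500 trees, ≥ 5 samples per
leaf, ≤ 4 features per split) and RBF-SVM (C = 1, standardized inputs)
consume base+naive+psychological features; their outputs are clipped to
[0, 1].

## Transfer testing and attribution

Transfer scores are MSE×100 at the (problem, block) grain with unweighted
averaging over rows.  The attribution target is the per-problem
prediction difference between a lab-trained and an online-trained model.
Group regressions are OLS with intercept via pseudo-inverse (collinear
groups degrade gracefully); in-sample R² is monotone in nested feature
sets by construction.  Per-feature confidence intervals use the Fisher
z-transform of the correlation at the dataset's N.  Kernel-SHAP
enumerates all coalitions exactly when `2^p − 2` fits the sample budget
(all base-feature explanations, p = 10) and otherwise samples coalition
sizes by their Shapley-kernel mass; the sum constraint is eliminated
algebraically, so local accuracy holds exactly in both paths.  SHAP over
base features is exact for shapeless problems; perturbed rows inherit the
explained problem set's lottery shape from its first member, an
approximation for multi-outcome shapes whose expansion is not itself a
base feature.

## Problem sizes and budgets

Default test-suite sizes — 300–1,000 synthetic problems, 400–4,000
agents, ≥ 48,000 retained posterior draws, 10,000 problems for the
dominance-nesting sweep — were chosen so the full suite completes in
about a minute while keeping every estimate's Monte-Carlo error an order
of magnitude below the asserted tolerance.  The real-data analyses
(dominance prevalence on the online dataset, the full pre-train/fine-tune
noise-model pipeline, the attribution regressions) require the original
CSVs under `data/real/` and hours of CPU for the published training
schedule; their tests state this requirement explicitly and fail when the
data are absent rather than silently skipping.

## Known limitations

- The BEAST tool formulas, ambiguity/feedback treatment and the σ/2
  dominance factor are reconstructions of qualitative descriptions;
  absolute BEAST error levels on real data depend on them.
- The skewed lottery-shape expansion is likewise a reconstruction.
- The noise model treats `n` as exact and the aggregate rate as `k/n`
  with `k` recovered by rounding; fractional reported rates at odd `n`
  round to the nearest count.
- Only aggregate choice proportions are modelled; individual differences
  and sequential effects are out of reach of the data format.
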