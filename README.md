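# choicebias

Tools for analysing **dataset bias in human risky-choice data** — the
systematic behavioural difference between choice proportions collected in
laboratory experiments (CPC15/CPC18-style) and in large online experiments
(choices13k-style), and for modelling that difference as structured
decision noise.

## Who this is for

Computational cognitive scientists and behavioural economists who model
aggregate binary choices between gambles: pairs of lotteries A and B in the
CPC15 format (`Ha, pHa, La` vs `Hb, pHb, Lb` plus lottery shape, ambiguity,
correlation, feedback and block flags), with the modelling target

> **P(B)** — the proportion of trials in which gamble B was chosen,
> averaged over participants and a five-trial block.

## What the package does

- **Data handling** — typed `Lottery` / `Problem` / `ChoiceObservation`
  containers, readers for the `cpc15`, `cpc18`, `choices13k` and the
  package's `canonical` CSV dialects, the CPC18→CPC15 compatibility filter,
  and problem-level stratified train/test splitting.
- **BEAST** — an agent-based choice simulator: 4,000 heterogeneous agents
  combine best-estimate expected values, four outcome-sampling tools
  (equal weighting, payoff sign, pessimism, regret) and Gaussian decision
  noise that is halved under first-order dominance; uniform upper bounds of
  the agent-property distributions are fitted by grid search.
- **Synthetic study conditions** — a CPC-style problem-space sampler,
  lab-like rates from BEAST, and online-like rates obtained by corrupting
  them with the noise model below, so the whole pipeline is testable
  without any data download.
- **Features** — survival functions; first-, second- and third-order
  stochastic dominance decided exactly on discrete lotteries; naive
  (`diffEV`, `diffSDs`, …) and psychological features (`Dom`,
  `pBbet_Unbiased1/FB`, `diffBEV0/fb`) and higher-order dominance
  (`SOSD`, `TOSD`).
- **Choice models** — a sparse MLP (200/275/100 SReLU units, dropout 0.15,
  RMSProp, sparse evolutionary training, pre-train/fine-tune schedule), a
  context network on padded `(x_A, p_A, x_B, p_B)` vectors, and random
  forest / RBF-SVM baselines on base+naive+psychological features.
- **Transfer testing** — MSE×100 of every model on every split; the
  dataset-bias signature is own-family error < cross-family error.
- **Decision-noise model** — the package's core computation.  A lab choice
  probability `p` is corrupted by (1) log-odds rescaling
  `p₁ = σ(f·logit(p))` with `0 < f < 1` shrinking choices toward
  equipreference, and (2) a proportion `p_guess` of guessers at 0.5:

  ```
  p_final = (1 − p_guess)·σ(f·logit(p)) + 0.5·p_guess,
  k ~ Binomial(n, p_final),  observed rate = k/n.
  ```

  The posterior over `(f, p_guess)` under the binomial likelihood is
  sampled by MCMC with convergence diagnostics, and validated by parameter
  recovery on synthetic data.
- **Attribution** — nested-group OLS regressions of the model-prediction
  difference, per-feature R² with Fisher-z confidence intervals, and
  Kernel-SHAP additive attributions (exact coalition enumeration up to ~11
  features) satisfying local accuracy on every row.

## Worked example

```bash
python examples/worked_dominance_example.py
```

```
x      P(A >= x)  P(B >= x)
12     1.00       1.00
14     0.95       0.90
90     0.90       0.90
96     0.90       0.85
first-order stochastic dominance: A dominates B
second-order stochastic dominance: A dominates B
third-order stochastic dominance: A dominates B
EV(A) = 87.70, EV(B) = 87.30
P(B pays more) - P(A pays more), independent draws: -0.050
```

Lottery A's survival function is everywhere at least B's, so A first-order
(hence second- and third-order) dominates B: every payoff-monotone decision
maker should choose A, which makes such gamble pairs diagnostic of decision
noise in observed choice rates.

The other examples each run one capability end to end and print what the
numbers mean:

- `examples/synthesize_and_transfer.py` — paired lab/online data and the
  transfer-test matrix (dataset-bias signature),
- `examples/fit_decision_noise.py` — posterior inference of `(f, p_guess)`
  with parameter recovery against known truth,
- `examples/attribute_model_difference.py` — nested regressions, top
  single features, and SHAP attributions of the model difference.

A thin CLI mirrors the pipeline (`choicebias synthesize | beast-predict |
featurize | train | transfer-test | fit-noise | attribute | recover`);
`choicebias show-config` prints every tunable with its default.

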