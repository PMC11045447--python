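"""Hybrid generative decision-noise model for aggregate choice rates.

Online crowd-sourced choice data shows systematically less extreme choice
proportions than laboratory data on the same kind of gamble.  This module
models that discrepancy with two noise sources applied to a "lab" choice
probability ``p`` (e.g. the prediction of a network trained on laboratory
data):

1. *log-odds rescaling* — a multiplicative factor ``f`` in log-odds space,

       p1 = sigmoid(f * logit(p)),

   which for ``0 < f < 1`` shrinks probabilities toward 0.5 and can be read
   as limited internal computational precision;
2. *guessing* — a proportion ``p_guess`` of participants choose uniformly
   at random (probability 0.5 for either gamble), so the expected number of
   guessers on a problem with ``n`` participants is ``p_guess * n``.

The generated B-choice rate for a problem is then ``k / n`` with

    k ~ Binomial(n, p_final),
    p_final = (1 - p_guess) * sigmoid(f * logit(p)) + 0.5 * p_guess.

Posterior inference over ``(f, p_guess)`` uses a binomial likelihood per
problem with uniform priors (``f ~ U(0, 2)``, ``p_guess ~ U(0, 1)``) and
the emcee affine-invariant ensemble sampler; convergence is summarized by
split-R-hat and effective sample size via arviz.  The posterior is
two-dimensional, smooth and (in every regime exercised here) unimodal, a
setting in which the ensemble sampler is reliable and fast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import binom

__all__ = [
    "NoiseParams",
    "NoisePosterior",
    "logodds_rescale",
    "mixture_predict",
    "fit_noise_model",
    "posterior_predictive",
    "corrupt_rates",
    "SamplerConfig",
]

_CLIP = 1e-6  # rates are clipped to [CLIP, 1-CLIP] before the logit


@dataclass(frozen=True)
class NoiseParams:
    """Log-odds multiplier ``f`` (> 0) and guessing proportion ``p_guess``."""

    f: float
    p_guess: float

    def __post_init__(self):
        if not self.f > 0:
            raise ValueError("f must be > 0")
        if not (0.0 <= self.p_guess <= 1.0):
            raise ValueError("p_guess must lie in [0, 1]")


@dataclass(frozen=True)
class NoisePosterior:
    """MCMC samples of (f, p_guess) with summaries and diagnostics."""

    samples_f: np.ndarray        # flattened posterior draws
    samples_p_guess: np.ndarray
    mean: NoiseParams
    sd_f: float
    sd_p_guess: float
    rhat_f: float
    rhat_p_guess: float
    ess_f: float
    ess_p_guess: float
    converged: bool

    def interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        """Central credible interval from the stored samples."""
        draws = {"f": self.samples_f, "p_guess": self.samples_p_guess}[param]
        alpha = (1.0 - level) / 2.0
        return (float(np.quantile(draws, alpha)), float(np.quantile(draws, 1.0 - alpha)))


def _clip(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.clip(arr, _CLIP, 1.0 - _CLIP)


def logodds_rescale(p, f: float):
    """``sigmoid(f * logit(p))``: rescale a probability in log-odds space.

    Strictly increasing in ``p`` with fixed points at 0, 0.5 and 1;
    ``f < 1`` shrinks toward equipreference, ``f > 1`` sharpens.
    """
    if not f > 0:
        raise ValueError("f must be > 0")
    out = expit(f * logit(_clip(p)))
    return float(out) if np.isscalar(p) else out


def mixture_predict(p_cpc, params: NoiseParams):
    """Expected corrupted rate: guessers at 0.5, the rest log-odds rescaled."""
    rescaled = logodds_rescale(p_cpc, params.f)
    return (1.0 - params.p_guess) * rescaled + 0.5 * params.p_guess


def corrupt_rates(rates, f: float, p_guess: float, n: int, seed: int) -> np.ndarray:
    """Sample corrupted aggregate rates ``k/n`` with ``k ~ Binom(n, p_final)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = NoiseParams(f=f, p_guess=p_guess)
    p_final = np.asarray(mixture_predict(np.asarray(rates, dtype=float), params))
    rng = np.random.default_rng(seed)
    return rng.binomial(n, p_final) / float(n)


@dataclass(frozen=True)
class SamplerConfig:
    n_samples: int = 10_000      # total retained posterior draws
    n_warmup: int = 1_000        # discarded steps per walker
    n_walkers: int = 32
    min_steps: int = 1500        # floor on retained steps per walker (mixing)
    seed: int = 0
    rhat_threshold: float = 1.05


def _log_posterior(theta, logit_p, counts, n):
    f, p_guess = theta
    if not (0.0 < f < 2.0 and 0.0 <= p_guess <= 1.0):
        return -np.inf
    p1 = expit(f * logit_p)
    p_final = np.clip((1.0 - p_guess) * p1 + 0.5 * p_guess, _CLIP, 1.0 - _CLIP)
    return float(np.sum(binom.logpmf(counts, n, p_final)))


def fit_noise_model(p_cpc: Sequence[float], counts: Sequence[int],
                    n: Sequence[int] | int,
                    sampler_config: SamplerConfig | None = None) -> NoisePosterior:
    """Posterior over (f, p_guess) given lab rates and observed B-counts.

    ``counts[i] ~ Binomial(n[i], p_final_i)`` with ``p_final_i`` the mixture
    mean of ``p_cpc[i]``.  Non-convergence (split-R-hat above the threshold)
    is flagged on the returned posterior and warned about, never silent.
    """
    import arviz as az
    import emcee

    cfg = sampler_config or SamplerConfig()
    p_cpc = np.asarray(p_cpc, dtype=float)
    counts = np.asarray(counts, dtype=int)
    n_arr = (np.full_like(counts, n) if np.isscalar(n)
             else np.asarray(n, dtype=int))
    if not (len(p_cpc) == len(counts) == len(n_arr)):
        raise ValueError("p_cpc, counts and n must be aligned")
    if np.any(n_arr < 1):
        raise ValueError("participant counts must be >= 1")
    if np.any(counts < 0) or np.any(counts > n_arr):
        raise ValueError("counts must lie in [0, n]")
    logit_p = logit(_clip(p_cpc))

    rng = np.random.default_rng(cfg.seed)
    nw = cfg.n_walkers
    init = np.column_stack([rng.uniform(0.3, 1.5, nw), rng.uniform(0.05, 0.6, nw)])
    steps = cfg.n_warmup + max(int(np.ceil(cfg.n_samples / nw)), cfg.min_steps)
    sampler = emcee.EnsembleSampler(
        nw, 2, _log_posterior, args=(logit_p, counts, n_arr),
        # emcee uses the legacy RandomState API internally
    )
    sampler.random_state = np.random.RandomState(cfg.seed ^ 0x5EED).get_state()
    sampler.run_mcmc(init, steps, progress=False)

    chain = sampler.get_chain(discard=cfg.n_warmup)          # (step, walker, dim)
    posterior = {
        "f": np.moveaxis(chain[..., 0], 1, 0),               # (chain, draw)
        "p_guess": np.moveaxis(chain[..., 1], 1, 0),
    }
    idata = az.from_dict(posterior=posterior)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summ = az.summary(idata, var_names=["f", "p_guess"], round_to=None)
    rhat_f = float(summ.loc["f", "r_hat"])
    rhat_p = float(summ.loc["p_guess", "r_hat"])
    ess_f = float(summ.loc["f", "ess_bulk"])
    ess_p = float(summ.loc["p_guess", "ess_bulk"])
    converged = max(rhat_f, rhat_p) <= cfg.rhat_threshold
    if not converged:
        warnings.warn(
            f"noise-model sampler may not have converged: "
            f"r_hat(f)={rhat_f:.3f}, r_hat(p_guess)={rhat_p:.3f}",
            RuntimeWarning, stacklevel=2,
        )

    flat_f = chain[..., 0].reshape(-1)[-cfg.n_samples:]
    flat_p = chain[..., 1].reshape(-1)[-cfg.n_samples:]
    return NoisePosterior(
        samples_f=flat_f,
        samples_p_guess=flat_p,
        mean=NoiseParams(f=float(flat_f.mean()), p_guess=float(flat_p.mean())),
        sd_f=float(flat_f.std(ddof=1)),
        sd_p_guess=float(flat_p.std(ddof=1)),
        rhat_f=rhat_f, rhat_p_guess=rhat_p,
        ess_f=ess_f, ess_p_guess=ess_p,
        converged=converged,
    )


def posterior_predictive(params: NoiseParams | NoisePosterior, p_cpc,
                         n: Sequence[int] | int, seed: int = 0) -> np.ndarray:
    """One posterior-predictive sample of aggregate B-rates per problem.

    Given a :class:`NoisePosterior`, each problem draws its own parameter
    sample; given point :class:`NoiseParams`, those are used throughout.
    """
    rng = np.random.default_rng(seed)
    p_cpc = np.asarray(p_cpc, dtype=float)
    n_arr = np.full(len(p_cpc), n) if np.isscalar(n) else np.asarray(n, dtype=int)
    if isinstance(params, NoisePosterior):
        idx = rng.integers(0, len(params.samples_f), len(p_cpc))
        f_draw = params.samples_f[idx]
        pg_draw = params.samples_p_guess[idx]
        p_final = np.array([
            mixture_predict(p, NoiseParams(f=float(fi), p_guess=float(gi)))
            for p, fi, gi in zip(p_cpc, f_draw, pg_draw)
        ])
    else:
        p_final = np.asarray(mixture_predict(p_cpc, params))
    return rng.binomial(n_arr, p_final) / n_arr.astype(float)
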