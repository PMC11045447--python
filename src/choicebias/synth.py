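"""Synthetic problem spaces and paired lab-like / online-like choice data.

The generator emulates the study conditions end to end without any real
download: problems are sampled from a CPC15-style problem space, "lab"
B-choice rates are produced by the BEAST agent simulator, and "online"
rates are produced by corrupting the lab rates with the guess/log-odds
noise model followed by binomial sampling at a fixed number of
participants.  Every stage is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .beast import BeastConfig, predict_many
from .data import ChoiceObservation, LotShape, Problem
from .noise import corrupt_rates

__all__ = [
    "SynthConfig",
    "DEFAULT_PROB_GRID",
    "sample_problem_space",
    "generate_lab_rates",
    "corrupt_with_noise",
    "make_paired_datasets",
]

#: CPC-style probability grid, including near-certain and certain branches.
DEFAULT_PROB_GRID = (0.01, 0.05, 0.1, 0.2, 0.25, 0.3, 0.4, 0.5,
                     0.6, 0.7, 0.75, 0.8, 0.9, 0.95, 0.99, 1.0)


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for the synthetic problem space and noise corruption.

    Defaults mirror the emulated study: positive payoffs up to ~100 currency
    units sampled log-uniformly, CPC-style probability grid, ambiguity and
    feedback each on a fifth of problems, 5 blocks of trials, and online
    corruption at ``f=0.6236``/``p_guess=0.2757`` (the fitted posterior
    means) with 15 participants per problem (choices13k's median scale).
    """

    n_problems: int = 1000
    seed: int = 0
    payoff_range: tuple = (1.0, 100.0)
    prob_grid: tuple = DEFAULT_PROB_GRID
    amb_rate: float = 0.2
    fb_rate: float = 0.2
    n_blocks: int = 5
    n_participants: int = 15
    noise_f: float = 0.6236
    noise_p_guess: float = 0.2757
    lot_shape_rate: float = 0.3
    max_lot_num: int = 7

    def __post_init__(self):
        if self.n_problems < 1:
            raise ValueError("n_problems must be >= 1")
        if not (self.payoff_range[0] > 0 and self.payoff_range[1] > self.payoff_range[0]):
            raise ValueError("payoff_range must be a positive, increasing interval")
        if len(self.prob_grid) == 0:
            raise ValueError("prob_grid must be nonempty")
        for name in ("amb_rate", "fb_rate", "noise_p_guess", "lot_shape_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.noise_f > 0:
            raise ValueError("noise_f must be > 0")
        if self.n_participants < 1 or self.n_blocks < 1:
            raise ValueError("n_participants and n_blocks must be >= 1")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def sample_problem_space(config: SynthConfig) -> list[Problem]:
    """Sample ``n_problems`` CPC15-format problems (block 1 of each).

    Payoffs are log-uniform in ``payoff_range`` rounded to the nearest unit
    (high branch strictly above the low branch); probabilities come from
    ``prob_grid``; a ``lot_shape_rate`` share of problems spread B's high
    branch over a multi-outcome shape; ambiguity and feedback flags are
    Bernoulli at their configured rates.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.payoff_range
    grid = np.asarray(config.prob_grid, dtype=float)
    problems = []
    for i in range(config.n_problems):
        ha, hb = np.round(_log_uniform(rng, lo, hi, 2))
        # low branches strictly below their high branch (0 allowed)
        la = float(rng.integers(0, int(ha))) if ha >= 1 else 0.0
        lb = float(rng.integers(0, int(hb))) if hb >= 1 else 0.0
        p_ha, p_hb = rng.choice(grid, 2)
        if rng.random() < config.lot_shape_rate:
            shape = rng.choice([LotShape.SYMM, LotShape.R_SKEW, LotShape.L_SKEW])
            if shape is LotShape.SYMM:
                num = int(rng.choice([3, 5, 7][: max(1, (config.max_lot_num - 1) // 2)]))
            else:
                num = int(rng.integers(2, config.max_lot_num + 1))
        else:
            shape, num = LotShape.NONE, 1
        feedback = bool(rng.random() < config.fb_rate)
        problems.append(Problem(
            id=f"synth-{config.seed}-{i}",
            ha=float(ha), p_ha=float(p_ha), la=la,
            hb=float(hb), p_hb=float(p_hb), lb=lb,
            lot_shape_b=shape, lot_num_b=num,
            ambiguity=bool(rng.random() < config.amb_rate),
            correlation=int(rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1])),
            feedback=feedback,
            block=1,
        ))
    return problems


def _with_blocks(problems: Sequence[Problem], n_blocks: int) -> list[Problem]:
    out = []
    for p in problems:
        blocks = range(1, n_blocks + 1) if p.feedback else [1]
        out.extend(p.with_block(b) for b in blocks)
    return out


def generate_lab_rates(problems: Sequence[Problem],
                       beast_config: BeastConfig | None = None,
                       n_blocks: int = 1,
                       n_participants: int = 100) -> list[ChoiceObservation]:
    """Lab-like aggregate B-rates: BEAST predictions per problem/block.

    Feedback problems are expanded to ``n_blocks`` blocks (behaviour changes
    once outcomes are experienced); no-feedback problems keep block 1.
    """
    expanded = _with_blocks(problems, n_blocks)
    rates = predict_many(expanded, beast_config or BeastConfig())
    return [ChoiceObservation(problem=p, n_participants=n_participants, b_rate=float(r))
            for p, r in zip(expanded, rates)]


def corrupt_with_noise(observations: Sequence[ChoiceObservation],
                       f: float, p_guess: float, n: int, seed: int,
                       ) -> list[ChoiceObservation]:
    """Online-like rates: guess/log-odds corruption + binomial sampling."""
    rates = np.array([obs.b_rate for obs in observations])
    corrupted = corrupt_rates(rates, f=f, p_guess=p_guess, n=n, seed=seed)
    return [ChoiceObservation(problem=obs.problem, n_participants=n, b_rate=float(r))
            for obs, r in zip(observations, corrupted)]


def make_paired_datasets(config: SynthConfig,
                         beast_config: BeastConfig | None = None,
                         ) -> tuple[list[ChoiceObservation], list[ChoiceObservation]]:
    """Generate aligned (lab, online) observation lists from one config."""
    problems = sample_problem_space(config)
    bcfg = beast_config or BeastConfig(seed=config.seed)
    lab = generate_lab_rates(problems, bcfg, n_blocks=config.n_blocks,
                             n_participants=config.n_participants)
    online = corrupt_with_noise(lab, f=config.noise_f, p_guess=config.noise_p_guess,
                                n=config.n_participants, seed=config.seed + 1)
    return lab, online
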