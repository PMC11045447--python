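"""BEAST: an agent-based model of risky binary choice.

The model predicts the population proportion choosing gamble B by simulating
a population of heterogeneous agents (4,000 by default).  Each agent decides
for gamble A iff

    [BEV_A - BEV_B] + [ST_A - ST_B] + e > 0,

where BEV is the agent's best estimate of each gamble's expected value,
ST is the mean of ``kappa`` payoff samples drawn with one of four sampling
tools per draw, and ``e`` is zero-mean Gaussian decision noise with standard
deviation ``sigma`` — halved when one gamble first-order stochastically
dominates the other (dominance makes the choice easier, so agents are less
noisy).

Each agent owns six properties drawn independently from uniform
distributions on ``[0, upper_bound]`` (``kappa`` is a positive integer):
``sigma``, ``kappa``, the four tool tendencies, a pessimism weight (used
both to resolve ambiguity about B's probabilities and to weight the
worst-case tool) and a feedback-reliance weight (how strongly feedback
blocks pull sampling towards the true payoff distribution).  The upper
bounds are the model's free parameters and are fitted by grid search on a
training set.

The four sampling tools concretize four qualitative tendencies:

* ``uniform`` — equal weighting: each distinct outcome of a gamble is
  treated as equally likely;
* ``sign`` — best payoff sign: a draw from the true distribution whose
  payoff is replaced by ``sign(payoff) * max |payoff|`` over the problem;
* ``pessimism`` — assume the worst: the minimum outcome;
* ``regret`` — minimize immediate regret: a shared uniform quantile applied
  to both gambles' inverse CDFs, so the draw compares like-ranked outcomes.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data import ChoiceObservation, Lottery, Problem, expand_problem
from .features import dominance

__all__ = [
    "AgentParams",
    "BeastConfig",
    "DEFAULT_UPPER_BOUNDS",
    "best_estimate_ev",
    "agent_decision",
    "predict_brate",
    "predict_many",
    "generate_observations",
    "fit_upper_bounds",
]

PROPERTY_NAMES = (
    "sigma", "kappa", "tool_uniform", "tool_sign", "tool_pessimism",
    "tool_regret", "pessimism", "feedback",
)

#: Default per-property upper bounds of the uniform agent distributions.
#: ``sigma`` is on the payoff scale of the CPC problem space; ``pessimism``
#: and ``feedback`` are mixing weights and stay in [0, 1].
DEFAULT_UPPER_BOUNDS: dict = {
    "sigma": 8.0, "kappa": 5, "tool_uniform": 1.0, "tool_sign": 1.0,
    "tool_pessimism": 1.0, "tool_regret": 1.0, "pessimism": 1.0, "feedback": 1.0,
}


@dataclass(frozen=True)
class AgentParams:
    """One agent's decision properties."""

    sigma: float
    kappa: int
    tool_tendencies: tuple  # (uniform, sign, pessimism, regret), nonnegative
    pessimism: float = 0.5
    feedback: float = 0.5

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if int(self.kappa) < 1:
            raise ValueError("kappa must be an integer >= 1")
        if len(self.tool_tendencies) != 4 or any(w < 0 for w in self.tool_tendencies):
            raise ValueError("tool_tendencies must be 4 nonnegative weights")
        if not (0 <= self.pessimism <= 1 and 0 <= self.feedback <= 1):
            raise ValueError("pessimism and feedback weights must lie in [0, 1]")


@dataclass(frozen=True)
class BeastConfig:
    n_agents: int = 4000
    seed: int = 0
    upper_bounds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UPPER_BOUNDS))

    def __post_init__(self):
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        bounds = dict(DEFAULT_UPPER_BOUNDS)
        bounds.update(self.upper_bounds)
        for name in PROPERTY_NAMES:
            if bounds[name] <= 0:
                raise ValueError(f"upper bound for {name} must be > 0")
        for name in ("pessimism", "feedback"):
            bounds[name] = min(float(bounds[name]), 1.0)
        object.__setattr__(self, "upper_bounds", bounds)


def best_estimate_ev(lottery: Lottery, ambiguous: bool = False,
                     resolved: bool = False, pessimism: float = 0.5) -> float:
    """Best-estimate expected value of a gamble.

    With known probabilities (or after feedback has ``resolved`` ambiguity)
    this is the true expected value.  Under unresolved ambiguity the stated
    probabilities are distrusted: the estimate blends a uniform-probability
    guess with the worst case, weighted by ``pessimism``.
    """
    if not ambiguous or resolved:
        return lottery.ev()
    uniform_ev = float(np.mean(lottery.support))
    return (1.0 - pessimism) * uniform_ev + pessimism * lottery.min()


def _problem_seed(base_seed: int, problem: Problem) -> np.random.SeedSequence:
    tag = f"{problem.id}#{problem.block}".encode()
    return np.random.SeedSequence([int(base_seed) % 2**31, zlib.crc32(tag)])


def _draw_agents(config: BeastConfig, rng: np.random.Generator, n: int):
    ub = config.upper_bounds
    sigma = rng.uniform(0.0, ub["sigma"], n)
    kappa = rng.integers(1, int(ub["kappa"]) + 1, n)
    tools = np.column_stack([
        rng.uniform(0.0, ub[f"tool_{t}"], n)
        for t in ("uniform", "sign", "pessimism", "regret")
    ])
    pess = rng.uniform(0.0, ub["pessimism"], n)
    fb = rng.uniform(0.0, ub["feedback"], n)
    return sigma, kappa, tools, pess, fb


def _coupled_quantiles(rng: np.random.Generator, shape, correlation: int):
    u = rng.random(shape)
    if correlation == -1:
        return u, 1.0 - u
    if correlation == 1:
        return u, u.copy()
    return u, rng.random(shape)


def _simulate_choices(problem: Problem, config: BeastConfig,
                      rng: np.random.Generator,
                      sigma, kappa, tools, pess, fb) -> np.ndarray:
    """Vector of {0=A, 1=B} choices, one per agent row of the inputs."""
    n = len(sigma)
    a, b = expand_problem(problem)
    resolved = problem.feedback and problem.block >= 2

    # --- best-estimate EVs ------------------------------------------------
    bev_a = np.full(n, a.ev())
    if problem.ambiguity and not resolved:
        uniform_ev = float(np.mean(b.support))
        bev_b = (1.0 - pess) * uniform_ev + pess * b.min()
    else:
        bev_b = np.full(n, b.ev())

    # under unresolved ambiguity the sampling tools use a uniform belief
    # over B's outcomes instead of the (unknown) stated probabilities
    if problem.ambiguity and not resolved:
        b_belief = Lottery(b.support, np.full(len(b.support), 1.0 / len(b.support)))
    else:
        b_belief = b

    # --- sampling-tool draws ---------------------------------------------
    k_max = int(kappa.max())
    valid = np.arange(k_max)[None, :] < kappa[:, None]          # (n, k)
    weights = tools / np.maximum(tools.sum(axis=1, keepdims=True), 1e-12)
    flat_w = np.where(tools.sum(axis=1, keepdims=True) > 0, weights, 0.25)
    tool_idx = (rng.random((n, k_max, 1)) > np.cumsum(flat_w, axis=1)[:, None, :]).sum(axis=2)
    tool_idx = np.minimum(tool_idx, 3)

    ua, ub_ = _coupled_quantiles(rng, (n, k_max), problem.correlation)
    pay_a = np.empty((n, k_max))
    pay_b = np.empty((n, k_max))

    # tool 0: uniform over distinct outcomes, independent per gamble
    ia = rng.integers(0, len(a.support), (n, k_max))
    ib = rng.integers(0, len(b_belief.support), (n, k_max))
    uni_a, uni_b = a.support[ia], b_belief.support[ib]
    # tool 1: sign draw from the believed distributions
    maxabs = max(abs(a.min()), abs(a.max()), abs(b.min()), abs(b.max()))
    sign_a = np.sign(a.quantile(ua)) * maxabs
    sign_b = np.sign(b_belief.quantile(ub_)) * maxabs
    # tool 2: pessimism
    pes_a = np.full((n, k_max), a.min())
    pes_b = np.full((n, k_max), b.min())
    # tool 3: regret — one shared quantile drives both inverse CDFs
    u_shared = rng.random((n, k_max))
    reg_a = a.quantile(u_shared)
    reg_b = b_belief.quantile(u_shared)

    for idx, (ta, tb) in enumerate([(uni_a, uni_b), (sign_a, sign_b),
                                    (pes_a, pes_b), (reg_a, reg_b)]):
        sel = tool_idx == idx
        pay_a[sel] = ta[sel]
        pay_b[sel] = tb[sel]

    # feedback blocks pull draws toward the true (experienced) distribution
    if resolved:
        unb = rng.random((n, k_max)) < fb[:, None]
        va, vb = _coupled_quantiles(rng, (n, k_max), problem.correlation)
        pay_a[unb] = a.quantile(va)[unb]
        pay_b[unb] = b.quantile(vb)[unb]

    st_a = np.where(valid, pay_a, 0.0).sum(axis=1) / kappa
    st_b = np.where(valid, pay_b, 0.0).sum(axis=1) / kappa

    # --- decision noise, reduced under first-order dominance --------------
    sigma_eff = sigma / 2.0 if dominance(a, b, 1) != 0 else sigma
    e = rng.standard_normal(n) * sigma_eff
    statistic = (bev_a - bev_b) + (st_a - st_b) + e
    return (statistic <= 0).astype(float)  # 1 = chooses B


def agent_decision(agent: AgentParams, problem: Problem, block: int,
                   rng: np.random.Generator) -> str:
    """Decision of a single agent; returns ``"A"`` or ``"B"``."""
    prob = problem if problem.block == block else problem.with_block(block)
    choice = _simulate_choices(
        prob, BeastConfig(n_agents=1), rng,
        sigma=np.array([agent.sigma]),
        kappa=np.array([int(agent.kappa)]),
        tools=np.array([agent.tool_tendencies], dtype=float),
        pess=np.array([agent.pessimism]),
        fb=np.array([agent.feedback]),
    )
    return "B" if choice[0] > 0 else "A"


def predict_brate(problem: Problem, config: BeastConfig | None = None) -> float:
    """Predicted proportion of agents choosing gamble B on this problem/block.

    Deterministic given ``config.seed``; each (problem id, block) pair gets
    its own substream so predictions do not depend on evaluation order.
    """
    config = config or BeastConfig()
    rng = np.random.default_rng(_problem_seed(config.seed, problem))
    agents = _draw_agents(config, rng, config.n_agents)
    choices = _simulate_choices(problem, config, rng, *agents)
    return float(choices.mean())


def predict_many(problems: Sequence[Problem],
                 config: BeastConfig | None = None) -> np.ndarray:
    config = config or BeastConfig()
    return np.array([predict_brate(p, config) for p in problems])


def generate_observations(problems: Sequence[Problem],
                          config: BeastConfig | None = None,
                          n_participants: int = 4000) -> list[ChoiceObservation]:
    """Wrap BEAST predictions as ChoiceObservation records."""
    rates = predict_many(problems, config)
    return [ChoiceObservation(problem=p, n_participants=n_participants, b_rate=float(r))
            for p, r in zip(problems, rates)]


def fit_upper_bounds(train: Sequence[ChoiceObservation],
                     grid: Mapping[str, Sequence[float]] | Sequence[Mapping[str, float]],
                     config: BeastConfig | None = None) -> BeastConfig:
    """Grid-search the uniform upper bounds to minimize MSE on ``train``.

    ``grid`` is either a mapping from property name to candidate values
    (expanded as a full product) or an explicit sequence of candidate bound
    mappings.  Ties break toward the lexicographically smallest bounds
    vector (in :data:`PROPERTY_NAMES` order).
    """
    if not train:
        raise ValueError("training data must be nonempty")
    base = config or BeastConfig()
    if isinstance(grid, Mapping):
        names = sorted(grid)
        if any(len(v) == 0 for v in grid.values()):
            raise ValueError("grid axes must be nonempty")
        candidates = [dict(zip(names, combo))
                      for combo in itertools.product(*(grid[n] for n in names))]
    else:
        candidates = [dict(c) for c in grid]
    if not candidates:
        raise ValueError("grid must be nonempty")

    targets = np.array([obs.b_rate for obs in train])
    problems = [obs.problem for obs in train]
    best = None
    for cand in candidates:
        bounds = dict(base.upper_bounds)
        bounds.update(cand)
        cfg = replace(base, upper_bounds=bounds)
        preds = predict_many(problems, cfg)
        mse = float(np.mean((preds - targets) ** 2))
        key = (mse, tuple(float(cfg.upper_bounds[n]) for n in PROPERTY_NAMES))
        if best is None or key < best[0]:
            best = (key, cfg)
    return best[1]
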