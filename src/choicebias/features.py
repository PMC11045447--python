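"""Gamble features: survival functions, stochastic dominance, and the
naive/psychological feature groups used by the classical choice models.

Feature orientation convention: every signed feature is positive when it
favours gamble B, matching the modelling target P(B).  ``Dom``/``SOSD``/
``TOSD`` are therefore +1 when B dominates A, -1 when A dominates B, 0 when
neither does.

Stochastic dominance of discrete lotteries is decided exactly on the union
support.  Writing ``F`` for the CDFs:

* first order (FOSD): A dominates B iff ``F_A(x) <= F_B(x)`` everywhere,
  strictly somewhere — equivalently A's survival function is everywhere at
  least B's;
* second order (SOSD): iff ``D2(t) = ∫_{-inf}^t [F_B - F_A] du >= 0`` for
  every ``t``, strictly somewhere (risk-averse decision-makers agree);
* third order (TOSD): iff ``D3(t) = ∫_{-inf}^t D2(u) du >= 0`` for every
  ``t`` and additionally ``EV(A) >= EV(B)`` (adds decreasing absolute risk
  aversion).

The CDFs are step functions, so ``D2`` is piecewise linear and ``D3``
piecewise quadratic; both are evaluated in closed form on the union support,
including interior extrema of ``D3``.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import Lottery, Problem, expand_problem

__all__ = [
    "survival",
    "dominance",
    "naive_features",
    "p_better",
    "psychological_features",
    "hosd_features",
    "feature_table",
    "FEATURE_GROUPS",
]


def survival(lottery: Lottery, x: float) -> float:
    """P(payoff >= x)."""
    return float(lottery.pmf[lottery.support >= x].sum())


def _cdf_on_grid(lottery: Lottery, grid: np.ndarray) -> np.ndarray:
    """F(x) evaluated at each grid point (right-continuous step function)."""
    idx = np.searchsorted(lottery.support, grid, side="right")
    cum = np.concatenate([[0.0], np.cumsum(lottery.pmf)])
    return cum[idx]


def _sign_from_conditions(a_ok: bool, b_ok: bool) -> int:
    if a_ok and b_ok:  # distributions coincide (up to tolerance)
        return 0
    if a_ok:
        return 1
    if b_ok:
        return -1
    return 0


def dominance(a: Lottery, b: Lottery, order: int = 1) -> int:
    """Stochastic dominance of the given order: +1 A dominates, -1 B, 0 neither."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    grid = np.union1d(a.support, b.support)
    fa = _cdf_on_grid(a, grid)
    fb = _cdf_on_grid(b, grid)
    scale = max(1.0, float(np.max(np.abs(grid))))
    tol = 1e-9 * scale
    diff = fb - fa  # >= 0 everywhere  <=>  A FOSD-dominates B

    if order == 1:
        return _sign_from_conditions(bool(np.all(diff >= -tol)),
                                     bool(np.all(-diff >= -tol)))

    # D2 at grid points: integral of the step function (fb - fa)
    gaps = np.diff(grid)
    d2 = np.concatenate([[0.0], np.cumsum(diff[:-1] * gaps)])
    # beyond the support D2 stays at EV(A) - EV(B)
    tail = a.ev() - b.ev()
    d2_all = np.concatenate([d2, [tail]])
    tol2 = tol * max(1.0, float(grid[-1] - grid[0]))
    if order == 2:
        return _sign_from_conditions(bool(np.all(d2_all >= -tol2)),
                                     bool(np.all(-d2_all >= -tol2)))

    # D3 at grid points plus interior extrema (where the linear D2 crosses 0)
    d3_vals = [0.0]
    acc = 0.0
    for i in range(len(grid) - 1):
        d2_i, slope, width = d2[i], diff[i], gaps[i]
        if slope != 0.0:
            t_star = -d2_i / slope
            if 0.0 < t_star < width:
                d3_vals.append(acc + d2_i * t_star + 0.5 * slope * t_star**2)
        acc += d2_i * width + 0.5 * slope * width**2
        d3_vals.append(acc)
    d3 = np.asarray(d3_vals)
    tol3 = tol2 * max(1.0, float(grid[-1] - grid[0]))
    a_ok = bool(np.all(d3 >= -tol3)) and a.ev() >= b.ev() - tol
    b_ok = bool(np.all(-d3 >= -tol3)) and b.ev() >= a.ev() - tol
    return _sign_from_conditions(a_ok, b_ok)


def p_better(a: Lottery, b: Lottery, correlation: int = 0) -> float:
    """P(B pays more than A) - P(A pays more than B) under the stated joint.

    ``correlation`` 0 couples the lotteries independently, +1 comonotonically
    (a shared uniform quantile drives both) and -1 antimonotonically.
    """
    if correlation == 0:
        sign = np.sign(np.subtract.outer(b.support, a.support))  # [i_b, i_a]
        weights = np.outer(b.pmf, a.pmf)
        return float(np.sum(sign * weights))
    if correlation not in (-1, 1):
        raise ValueError("correlation must be -1, 0 or 1")
    cum_b = np.cumsum(b.pmf)
    cuts_b = cum_b if correlation == 1 else 1.0 - cum_b  # Q_B(1-u) jumps at 1-cum
    cuts = np.union1d(np.cumsum(a.pmf), np.clip(cuts_b, 0.0, 1.0))
    cuts = np.concatenate([[0.0], cuts[cuts <= 1.0 + 1e-12]])
    cuts[-1] = 1.0
    lo, hi = cuts[:-1], cuts[1:]
    width = hi - lo
    keep = width > 1e-15
    mid = (lo + hi) / 2.0
    pay_a = a.quantile(mid[keep])
    u_b = mid[keep] if correlation == 1 else 1.0 - mid[keep]
    pay_b = b.quantile(u_b)
    return float(np.sum(np.sign(pay_b - pay_a) * width[keep]))


def base_features(problem: Problem) -> dict:
    return {
        "Ha": problem.ha, "pHa": problem.p_ha, "La": problem.la,
        "Hb": problem.hb, "pHb": problem.p_hb, "Lb": problem.lb,
        "Amb": float(problem.ambiguity), "Corr": float(problem.correlation),
        "Feedback": float(problem.feedback), "Block": float(problem.block),
    }


def naive_features(problem: Problem) -> dict:
    """Features naively derived from the payoff distributions (B minus A)."""
    a, b = expand_problem(problem)
    return {
        "diffEV": b.ev() - a.ev(),
        "diffSDs": b.sd() - a.sd(),
        "diffMins": b.min() - a.min(),
        "diffMaxs": b.max() - a.max(),
    }


def psychological_features(problem: Problem) -> dict:
    """Features drawn from the behavioural-decision literature.

    ``Dom`` is signed first-order stochastic dominance; the ``pBbet``
    variants give the probability advantage of B paying more, without
    feedback (independent coupling — outcomes are only described) and with
    feedback (the experienced correlation structure applies).  ``diffBEV0``
    and ``diffBEVfb`` are best-estimate expected-value differences, where
    ambiguity about B's probabilities is resolved pessimistically before
    feedback and exactly after feedback.
    """
    from .beast import best_estimate_ev  # BEV estimator lives with the agent model

    a, b = expand_problem(problem)
    bev_a = a.ev()
    bev_b0 = best_estimate_ev(b, ambiguous=problem.ambiguity, resolved=False)
    bev_bfb = best_estimate_ev(b, ambiguous=problem.ambiguity, resolved=True)
    return {
        "Dom": float(-dominance(a, b, 1)),
        "pBbet_Unbiased1": p_better(a, b, correlation=0),
        "pBbet_UnbiasedFB": p_better(a, b, correlation=problem.correlation),
        "diffBEV0": bev_b0 - bev_a,
        "diffBEVfb": bev_bfb - bev_a,
    }


def hosd_features(problem: Problem) -> dict:
    """Signed second- and third-order stochastic dominance."""
    a, b = expand_problem(problem)
    return {
        "SOSD": float(-dominance(a, b, 2)),
        "TOSD": float(-dominance(a, b, 3)),
    }


FEATURE_GROUPS = {
    "base": ["Ha", "pHa", "La", "Hb", "pHb", "Lb", "Amb", "Corr", "Feedback", "Block"],
    "naive": ["diffEV", "diffSDs", "diffMins", "diffMaxs"],
    "psychological": ["Dom", "pBbet_Unbiased1", "pBbet_UnbiasedFB", "diffBEV0", "diffBEVfb"],
    "hosd": ["SOSD", "TOSD"],
}


def feature_table(problems: Sequence[Problem],
                  groups: Iterable[str] = ("base", "naive", "psychological", "hosd"),
                  ) -> pd.DataFrame:
    """Per-problem feature table with the requested feature groups."""
    builders = {
        "base": base_features,
        "naive": naive_features,
        "psychological": psychological_features,
        "hosd": hosd_features,
    }
    unknown = set(groups) - set(builders)
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    rows = []
    for problem in problems:
        row: dict = {"id": problem.id, "block": problem.block}
        for g in groups:
            row.update(builders[g](problem))
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["groups"] = {g: list(FEATURE_GROUPS[g]) for g in groups}
    return frame
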