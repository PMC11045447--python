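"""Domain types and dataset I/O for risky binary-choice experiments.

The experiments modelled here present participants with a pair of monetary
gambles, A and B.  Gamble A pays ``Ha`` with probability ``pHa`` and ``La``
otherwise.  Gamble B pays ``Hb`` with probability ``pHb`` and ``Lb``
otherwise, except that the high branch of B may be spread over several
outcomes according to a "lottery shape" (symmetric, right- or left-skewed).
The behavioural target is the proportion of trials in which B was chosen,
aggregated over participants and a block of five trials — ``b_rate``.

Three public CSV dialects are supported (``cpc15``, ``cpc18``,
``choices13k``) plus the package's own ``canonical`` dialect used by every
writer.  CPC18 extended the problem format (gamble A may itself carry a
lottery shape); :func:`cpc18_compatible` filters the extension away so the
remaining rows fit the earlier format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LotShape",
    "Lottery",
    "Problem",
    "ChoiceObservation",
    "expand_problem",
    "read_dataset",
    "write_dataset",
    "observations_to_frame",
    "cpc18_compatible",
    "split_train_test",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when a CSV file or a problem definition is malformed."""


class LotShape(Enum):
    """Shape of the multi-outcome expansion of gamble B's high branch."""

    NONE = "none"
    SYMM = "symmetric"
    R_SKEW = "right-skewed"
    L_SKEW = "left-skewed"

    @classmethod
    def parse(cls, value) -> "LotShape":
        if isinstance(value, LotShape):
            return value
        aliases = {
            "-": cls.NONE, "": cls.NONE, "none": cls.NONE, "0": cls.NONE,
            "symm": cls.SYMM, "symmetric": cls.SYMM, "1": cls.SYMM,
            "r-skew": cls.R_SKEW, "rskew": cls.R_SKEW, "right-skewed": cls.R_SKEW, "2": cls.R_SKEW,
            "l-skew": cls.L_SKEW, "lskew": cls.L_SKEW, "left-skewed": cls.L_SKEW, "3": cls.L_SKEW,
        }
        key = str(value).strip().lower()
        if key not in aliases:
            raise FormatError(f"unknown lottery shape: {value!r}")
        return aliases[key]


_PROB_TOL = 1e-9


@dataclass(frozen=True)
class Lottery:
    """A discrete probability distribution over monetary payoffs.

    Outcomes are kept sorted ascending with duplicate payoffs merged, so two
    lotteries describing the same distribution compare equal.
    """

    outcomes: tuple
    probs: tuple

    def __init__(self, outcomes: Sequence[float], probs: Sequence[float]):
        out = np.asarray(outcomes, dtype=float)
        pr = np.asarray(probs, dtype=float)
        if out.ndim != 1 or out.shape != pr.shape or out.size < 1:
            raise ValueError("outcomes and probs must be equal-length 1-d sequences")
        if not np.all(np.isfinite(out)):
            raise ValueError("outcomes must be finite")
        if np.any(pr < -_PROB_TOL) or np.any(pr > 1 + _PROB_TOL):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(pr.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {pr.sum()!r}")
        # merge duplicate outcomes, drop zero-probability atoms, sort ascending
        order = np.argsort(out, kind="stable")
        out, pr = out[order], np.clip(pr[order], 0.0, 1.0)
        uniq, inv = np.unique(out, return_inverse=True)
        merged = np.zeros_like(uniq)
        np.add.at(merged, inv, pr)
        keep = merged > 0
        if not keep.any():  # all mass lost to clipping; keep the largest atom
            keep = merged == merged.max()
        object.__setattr__(self, "outcomes", tuple(uniq[keep]))
        object.__setattr__(self, "probs", tuple(merged[keep] / merged[keep].sum()))

    @property
    def support(self) -> np.ndarray:
        return np.asarray(self.outcomes)

    @property
    def pmf(self) -> np.ndarray:
        return np.asarray(self.probs)

    def ev(self) -> float:
        return float(np.dot(self.support, self.pmf))

    def sd(self) -> float:
        mu = self.ev()
        return float(math.sqrt(max(np.dot((self.support - mu) ** 2, self.pmf), 0.0)))

    def min(self) -> float:
        return float(self.outcomes[0])

    def max(self) -> float:
        return float(self.outcomes[-1])

    def cdf(self, x: float) -> float:
        """P(payoff <= x)."""
        return float(self.pmf[self.support <= x].sum())

    def quantile(self, u) -> np.ndarray:
        """Inverse CDF: smallest outcome whose CDF reaches ``u``."""
        cum = np.cumsum(self.pmf)
        idx = np.searchsorted(cum, np.asarray(u, dtype=float), side="left")
        idx = np.clip(idx, 0, len(self.outcomes) - 1)
        return self.support[idx]

    def sample(self, rng: np.random.Generator, size=None):
        return self.quantile(rng.random(size))


@dataclass(frozen=True)
class Problem:
    """A CPC15-format choice problem: gamble A vs gamble B with context flags."""

    id: str
    ha: float
    p_ha: float
    la: float
    hb: float
    p_hb: float
    lb: float
    lot_shape_b: LotShape = LotShape.NONE
    lot_num_b: int = 1
    ambiguity: bool = False
    correlation: int = 0
    feedback: bool = False
    block: int = 1

    def __post_init__(self):
        if not (0.0 <= self.p_ha <= 1.0 and 0.0 <= self.p_hb <= 1.0):
            raise FormatError(f"problem {self.id}: pHa/pHb must lie in [0, 1]")
        if self.lot_num_b < 1:
            raise FormatError(f"problem {self.id}: lot_num_b must be >= 1")
        if self.correlation not in (-1, 0, 1):
            raise FormatError(f"problem {self.id}: correlation must be -1, 0 or 1")
        if self.block < 1:
            raise FormatError(f"problem {self.id}: block must be >= 1")
        if self.lot_shape_b is LotShape.NONE and self.lot_num_b != 1:
            raise FormatError(f"problem {self.id}: shapeless B requires lot_num_b == 1")
        if self.lot_shape_b is LotShape.SYMM and self.lot_num_b % 2 == 0:
            raise FormatError(f"problem {self.id}: symmetric shape requires odd lot_num_b")

    def key(self) -> str:
        """Identity of the underlying gamble pair, ignoring the block index."""
        return self.id

    def with_block(self, block: int) -> "Problem":
        return replace(self, block=block)


@dataclass(frozen=True)
class ChoiceObservation:
    """Aggregate behaviour on one problem/block: n participants, B-choice rate."""

    problem: Problem
    n_participants: int
    b_rate: float

    def __post_init__(self):
        if self.n_participants < 1:
            raise FormatError("n_participants must be >= 1")
        if not (0.0 <= self.b_rate <= 1.0):
            raise FormatError(f"b_rate must lie in [0, 1], got {self.b_rate}")


def _expand_b(hb: float, p_hb: float, lb: float, shape: LotShape, num: int):
    """Spread gamble B's high branch over ``num`` outcomes, total mass ``p_hb``."""
    if shape is LotShape.NONE or num == 1:
        return [hb], [p_hb]
    if shape is LotShape.SYMM:
        # num outcomes centred on Hb with binomial(num-1, 1/2) weights
        half = (num - 1) // 2
        outs = [hb + k for k in range(-half, half + 1)]
        weights = [math.comb(num - 1, k) / 2 ** (num - 1) for k in range(num)]
        return outs, [w * p_hb for w in weights]
    # skewed shapes: geometric probability decay (ratio 1/2) over outcomes
    # spaced Hb ± (2^j - 1), the long tail pointing in the skew direction
    sign = 1.0 if shape is LotShape.R_SKEW else -1.0
    outs = [hb + sign * (2.0**j - 1.0) for j in range(num)]
    raw = [0.5 ** (j + 1) for j in range(num)]
    total = sum(raw)
    return outs, [r / total * p_hb for r in raw]


def expand_problem(problem: Problem) -> tuple[Lottery, Lottery]:
    """Expand a problem into its two payoff distributions (A, B)."""
    a = Lottery([problem.ha, problem.la], [problem.p_ha, 1.0 - problem.p_ha])
    outs, probs = _expand_b(problem.hb, problem.p_hb, problem.lb,
                            problem.lot_shape_b, problem.lot_num_b)
    outs.append(problem.lb)
    probs.append(1.0 - problem.p_hb)
    b = Lottery(outs, probs)
    return a, b


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

CANONICAL_COLUMNS = [
    "id", "ha", "p_ha", "la", "hb", "p_hb", "lb", "lot_shape_b", "lot_num_b",
    "ambiguity", "correlation", "feedback", "block", "n_participants", "b_rate",
]

# per-dialect mapping: canonical name -> column name in the source file
_DIALECTS = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    "cpc15": {
        "id": "Problem", "ha": "Ha", "p_ha": "pHa", "la": "La",
        "hb": "Hb", "p_hb": "pHb", "lb": "Lb",
        "lot_shape_b": "LotShape", "lot_num_b": "LotNum",
        "ambiguity": "Amb", "correlation": "Corr", "feedback": "Feedback",
        "block": "block", "n_participants": "N", "b_rate": "B_rate",
    },
    "cpc18": {
        "id": "GameID", "ha": "Ha", "p_ha": "pHa", "la": "La",
        "hb": "Hb", "p_hb": "pHb", "lb": "Lb",
        "lot_shape_b": "LotShapeB", "lot_num_b": "LotNumB",
        "ambiguity": "Amb", "correlation": "Corr", "feedback": "Feedback",
        "block": "block", "n_participants": "N", "b_rate": "B_rate",
    },
    "choices13k": {
        "id": "problem_id", "ha": "Ha", "p_ha": "pHa", "la": "La",
        "hb": "Hb", "p_hb": "pHb", "lb": "Lb",
        "lot_shape_b": "LotShapeB", "lot_num_b": "LotNumB",
        "ambiguity": "Amb", "correlation": "Corr", "feedback": "Feedback",
        "block": "Block", "n_participants": "n", "b_rate": "bRate",
    },
}


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "t", "yes")
    return bool(int(x))


def _row_to_observation(row: pd.Series, cols: dict) -> ChoiceObservation:
    problem = Problem(
        id=str(row[cols["id"]]),
        ha=float(row[cols["ha"]]), p_ha=float(row[cols["p_ha"]]), la=float(row[cols["la"]]),
        hb=float(row[cols["hb"]]), p_hb=float(row[cols["p_hb"]]), lb=float(row[cols["lb"]]),
        lot_shape_b=LotShape.parse(row[cols["lot_shape_b"]]),
        lot_num_b=int(row[cols["lot_num_b"]]),
        ambiguity=_as_bool(row[cols["ambiguity"]]),
        correlation=int(row[cols["correlation"]]),
        feedback=_as_bool(row[cols["feedback"]]),
        block=int(row[cols["block"]]),
    )
    return ChoiceObservation(
        problem=problem,
        n_participants=int(row[cols["n_participants"]]),
        b_rate=float(row[cols["b_rate"]]),
    )


def cpc18_compatible(frame: pd.DataFrame) -> pd.Series:
    """Boolean mask of CPC18 rows expressible in the CPC15/choices13k format.

    CPC18 generalized the format: gamble A may itself carry a lottery shape
    (``LotShapeA``/``LotNumA``).  Rows where A is a plain two-outcome gamble
    are retained.
    """
    mask = pd.Series(True, index=frame.index)
    if "LotShapeA" in frame.columns:
        shapes = frame["LotShapeA"].map(lambda s: LotShape.parse(s))
        mask &= shapes == LotShape.NONE
    if "LotNumA" in frame.columns:
        mask &= frame["LotNumA"].astype(int) == 1
    return mask


def read_dataset(path, dialect: str = "canonical") -> list[ChoiceObservation]:
    """Read one ChoiceObservation per (problem, block) row of a CSV file."""
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    cols = _DIALECTS[dialect]
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if frame.empty:
        raise FormatError(f"{path}: no data rows")
    missing = [c for c in cols.values() if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns for dialect {dialect!r}: {missing}")
    if dialect == "cpc18":
        frame = frame[cpc18_compatible(frame)]
        if frame.empty:
            raise FormatError(f"{path}: no CPC15-format-compatible rows")
    return [_row_to_observation(row, cols) for _, row in frame.iterrows()]


def observations_to_frame(observations: Iterable[ChoiceObservation]) -> pd.DataFrame:
    """Tabulate observations in the canonical dialect."""
    rows = []
    for obs in observations:
        p = obs.problem
        rows.append({
            "id": p.id, "ha": p.ha, "p_ha": p.p_ha, "la": p.la,
            "hb": p.hb, "p_hb": p.p_hb, "lb": p.lb,
            "lot_shape_b": p.lot_shape_b.value, "lot_num_b": p.lot_num_b,
            "ambiguity": int(p.ambiguity), "correlation": p.correlation,
            "feedback": int(p.feedback), "block": p.block,
            "n_participants": obs.n_participants, "b_rate": obs.b_rate,
        })
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def write_dataset(observations: Iterable[ChoiceObservation], path) -> None:
    """Write observations as canonical-dialect CSV."""
    observations_to_frame(observations).to_csv(Path(path), index=False)


def split_train_test(
    data: Sequence[ChoiceObservation], fraction: float, seed: int
) -> tuple[list[ChoiceObservation], list[ChoiceObservation]]:
    """Split observations at the problem level (all blocks travel together).

    The split is stratified by the feedback flag so that neither side is
    starved of either condition, and is deterministic given ``seed``.
    ``fraction`` is the share of problems assigned to the training side.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    by_problem: dict[str, list[ChoiceObservation]] = {}
    feedback_of: dict[str, bool] = {}
    for obs in data:
        by_problem.setdefault(obs.problem.key(), []).append(obs)
        feedback_of[obs.problem.key()] = obs.problem.feedback
    keys = sorted(by_problem)
    if len(keys) < 2:
        raise ValueError("need at least 2 distinct problems to split")
    rng = np.random.default_rng(seed)
    train_keys: set[str] = set()
    for flag in (False, True):
        stratum = [k for k in keys if feedback_of[k] == flag]
        if not stratum:
            continue
        n_train = int(round(fraction * len(stratum)))
        n_train = min(max(n_train, 0), len(stratum))
        picked = rng.permutation(len(stratum))[:n_train]
        train_keys.update(stratum[i] for i in picked)
    train = [obs for k in keys if k in train_keys for obs in by_problem[k]]
    test = [obs for k in keys if k not in train_keys for obs in by_problem[k]]
    if not train or not test:
        # degenerate rounding on tiny strata; move one problem across
        donor = train if not test else test
        receiver = test if not test else train
        key = donor[0].problem.key()
        moved = [o for o in donor if o.problem.key() == key]
        donor[:] = [o for o in donor if o.problem.key() != key]
        receiver.extend(moved)
    return train, test
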