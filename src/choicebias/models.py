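"""The four learned choice models and their training procedures.

All models map problems to predicted P(B) in [0, 1]:

* ``bourgin`` — sparse MLP on the ten base features: hidden layers of
  200/275/100 SReLU units, per-layer dropout 0.15, RMSProp, sigmoid output,
  trained with sparse evolutionary training (SET).  Supports the
  pre-train-on-synthetic / fine-tune-on-target schedule (pre-train at
  lr 1e-3 with best-validation checkpointing, fine-tune at lr 1e-6).
* ``peterson`` — context network on padded outcome/probability vectors
  ``(xA, pA, xB, pB)``: two 32-unit sigmoid hidden layers, Adam at 1e-3,
  100 epochs, optional short pre-training.  Context flags (ambiguity,
  correlation, feedback, block) are deliberately not encoded.  The
  architecture predicts P(A); the wrapper reports P(B) = 1 - P(A).
* ``rf`` — random forest of 500 trees, min 5 samples per leaf, at most 4
  features per split, on base+naive+psychological features.
* ``svm`` — RBF-kernel support vector regression with C=1 on standardized
  base+naive+psychological features; predictions clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .data import ChoiceObservation, Problem, expand_problem
from .features import feature_table
from .nets import SparseMLP

__all__ = [
    "MAX_SUPPORT",
    "TrainSchedule",
    "ChoiceModel",
    "to_context_input",
    "context_matrix",
    "base_matrix",
    "train_model",
]

MAX_SUPPORT = 10  # outcomes per gamble after expansion; covers CPC-format shapes


@dataclass(frozen=True)
class TrainSchedule:
    """Pre-train / fine-tune schedule for the network models.

    Paper-scale defaults; tests and the synthetic pipeline shrink
    ``pretrain_epochs``/``finetune_epochs`` (the loss landscape is the same,
    only the compute budget differs).
    """

    pretrain_lr: float = 1e-3
    pretrain_epochs: int = 300
    finetune_lr: float = 1e-6
    finetune_epochs: int = 100
    batch_size: int = 64
    set_epsilon: float = 0.2    # fraction of possible connections kept active
    set_zeta: float = 0.3       # fraction pruned/regrown per epoch
    dropout: float = 0.15
    validation_fraction: float = 0.1


class ChoiceModel(Protocol):
    def predict(self, problems: Sequence[Problem]) -> np.ndarray: ...


def to_context_input(problem: Problem,
                     max_support: int = MAX_SUPPORT) -> tuple[np.ndarray, ...]:
    """Padded ``(xA, pA, xB, pB)`` vectors for the context network."""
    a, b = expand_problem(problem)
    out = []
    for lot in (a, b):
        if len(lot.support) > max_support:
            raise ValueError(
                f"problem {problem.id}: support of size {len(lot.support)} "
                f"exceeds the maximum of {max_support}")
        x = np.zeros(max_support)
        p = np.zeros(max_support)
        x[: len(lot.support)] = lot.support
        p[: len(lot.support)] = lot.pmf
        out.extend([x, p])
    return tuple(out)


def context_matrix(problems: Sequence[Problem]) -> np.ndarray:
    return np.array([np.concatenate(to_context_input(p)) for p in problems])


def base_matrix(problems: Sequence[Problem]) -> np.ndarray:
    """Base features as a numeric matrix (flags 0/1, block as integer)."""
    return np.array([
        [p.ha, p.p_ha, p.la, p.hb, p.p_hb, p.lb,
         float(p.ambiguity), float(p.correlation), float(p.feedback), float(p.block)]
        for p in problems
    ])


def _split_validation(x, y, fraction: float, rng: np.random.Generator):
    n = len(x)
    n_val = max(1, int(round(fraction * n))) if n > 4 else 0
    if n_val == 0:
        return x, y, None, None
    order = rng.permutation(n)
    val, tr = order[:n_val], order[n_val:]
    return x[tr], y[tr], x[val], y[val]


class _NetModel:
    """Shared wrapper: encoder + SparseMLP + optional standardization."""

    def __init__(self, net: SparseMLP, encode, scaler=None, flip: bool = False):
        self.net = net
        self._encode = encode
        self.scaler = scaler
        self.flip = flip  # net predicts P(A); report P(B)

    def _x(self, problems):
        x = self._encode(problems)
        return self.scaler.transform(x) if self.scaler is not None else x

    def predict(self, problems: Sequence[Problem]) -> np.ndarray:
        pred = self.net.predict(self._x(problems))
        return 1.0 - pred if self.flip else pred


class _SklearnModel:
    def __init__(self, estimator, scaler=None):
        self.estimator = estimator
        self.scaler = scaler

    @staticmethod
    def _features(problems):
        table = feature_table(problems, groups=("base", "naive", "psychological"))
        cols = [c for c in table.columns if c not in ("id", "block")]
        return table[cols].to_numpy(dtype=float)

    def fit(self, problems, rates):
        x = self._features(problems)
        if self.scaler is not None:
            x = self.scaler.fit_transform(x)
        self.estimator.fit(x, rates)
        return self

    def predict(self, problems: Sequence[Problem]) -> np.ndarray:
        x = self._features(problems)
        if self.scaler is not None:
            x = self.scaler.transform(x)
        return np.clip(self.estimator.predict(x), 0.0, 1.0)


def _unpack(observations: Sequence[ChoiceObservation]):
    problems = [o.problem for o in observations]
    rates = np.array([o.b_rate for o in observations])
    return problems, rates


def train_model(kind: str,
                train: Sequence[ChoiceObservation],
                pretrain: Sequence[ChoiceObservation] | None = None,
                schedule: TrainSchedule | None = None,
                seed: int = 0) -> ChoiceModel:
    """Train one of the four model kinds; reproducible given ``seed``."""
    if not train:
        raise ValueError("training data must be nonempty")
    schedule = schedule or TrainSchedule()
    problems, rates = _unpack(train)
    rng = np.random.default_rng(seed)

    if kind == "rf":
        est = RandomForestRegressor(
            n_estimators=500, min_samples_leaf=5, max_features=4,
            random_state=int(rng.integers(2**31)), n_jobs=1)
        return _SklearnModel(est).fit(problems, rates)
    if kind == "svm":
        return _SklearnModel(SVR(kernel="rbf", C=1.0),
                             scaler=StandardScaler()).fit(problems, rates)
    if kind == "bourgin":
        scaler = StandardScaler().fit(base_matrix(problems))
        net = SparseMLP(
            n_in=10, hidden=[200, 275, 100], seed=int(rng.integers(2**31)),
            activation="srelu", dropout=schedule.dropout,
            density=schedule.set_epsilon, zeta=schedule.set_zeta,
            optimizer="rmsprop", lr=schedule.pretrain_lr)
        model = _NetModel(net, base_matrix, scaler)
        if pretrain:
            pre_problems, pre_rates = _unpack(pretrain)
            x_pre = scaler.transform(base_matrix(pre_problems))
            x_tr, y_tr, x_val, y_val = _split_validation(
                x_pre, pre_rates, schedule.validation_fraction, rng)
            net.fit(x_tr, y_tr, epochs=schedule.pretrain_epochs,
                    batch_size=schedule.batch_size,
                    x_val=x_val, y_val=y_val, checkpoint=x_val is not None)
            net.set_lr(schedule.finetune_lr)
            net.zeta = 0.0  # rewiring only during pre-training
        x = scaler.transform(base_matrix(problems))
        net.fit(x, rates, epochs=schedule.finetune_epochs,
                batch_size=schedule.batch_size)
        return model
    if kind == "peterson":
        net = SparseMLP(
            n_in=4 * MAX_SUPPORT, hidden=[32, 32],
            seed=int(rng.integers(2**31)), activation="sigmoid",
            dropout=0.0, density=1.0, optimizer="adam", lr=1e-3)
        model = _NetModel(net, context_matrix, flip=True)
        if pretrain:
            pre_problems, pre_rates = _unpack(pretrain)
            net.fit(context_matrix(pre_problems), 1.0 - pre_rates,
                    epochs=min(20, schedule.pretrain_epochs),
                    batch_size=schedule.batch_size)
        net.fit(context_matrix(problems), 1.0 - rates,
                epochs=schedule.finetune_epochs, batch_size=schedule.batch_size)
        return model
    raise ValueError(f"unknown model kind {kind!r}; "
                     "choose from bourgin, peterson, rf, svm")
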