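"""Transfer testing: evaluate every model on every dataset split.

Models fit on one dataset family should, absent dataset bias, generalize to
the other family's splits.  The harness scores each (model, split) pair by
MSE x 100 at the (problem, block) grain and tabulates the result; the bias
signature is a model scoring visibly better on its own family's test split
than on the other family's.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ChoiceObservation, Problem
from .models import ChoiceModel

__all__ = ["mse100", "evaluate", "transfer_matrix", "nn_difference"]


def mse100(pred, target) -> float:
    """100 x mean squared difference between two rate vectors."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape or pred.size < 1:
        raise ValueError("pred and target must be equal-length, nonempty")
    return float(100.0 * np.mean((pred - target) ** 2))


def evaluate(model: ChoiceModel, split: Sequence[ChoiceObservation]) -> float:
    problems = [o.problem for o in split]
    targets = [o.b_rate for o in split]
    return mse100(model.predict(problems), targets)


def transfer_matrix(models: Mapping[str, ChoiceModel],
                    splits: Mapping[str, Sequence[ChoiceObservation]]) -> pd.DataFrame:
    """MSE x 100 for every model on every named split (rows = models)."""
    table = {
        split_name: [evaluate(model, split) for model in models.values()]
        for split_name, split in splits.items()
    }
    return pd.DataFrame(table, index=list(models))


def nn_difference(model_lab: ChoiceModel, model_online: ChoiceModel,
                  problems: Sequence[Problem]) -> np.ndarray:
    """Per-problem prediction difference, lab-trained minus online-trained."""
    return np.asarray(model_lab.predict(problems)) - np.asarray(model_online.predict(problems))
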