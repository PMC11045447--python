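"""High-level analysis assemblies shared by the CLI and the examples.

Bridges the low-level operations (feature tables, regressions, SHAP) into
the report shapes the study produces: nested group regressions of the
model-prediction difference, per-feature univariate R2 values, and the
SHAP matrix over base features.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .attribution import (fit_group_regression, per_feature_r2,
                          regress_feature_on_shap, shap_attributions)
from .data import LotShape, Problem
from .features import FEATURE_GROUPS, feature_table
from .models import ChoiceModel, base_matrix

__all__ = [
    "frame_to_problems",
    "nested_group_regressions",
    "per_feature_table",
    "difference_shap",
    "attribution_report",
]

NESTED_GROUPS = [
    ("base", ("base",)),
    ("base + naive", ("base", "naive")),
    ("base + naive + psych.", ("base", "naive", "psychological")),
    ("base + naive + psych. + HOSD", ("base", "naive", "psychological", "hosd")),
]


def frame_to_problems(frame: pd.DataFrame) -> list[Problem]:
    """Canonical-dialect rows -> Problem values."""
    return [
        Problem(
            id=str(r["id"]), ha=float(r["ha"]), p_ha=float(r["p_ha"]), la=float(r["la"]),
            hb=float(r["hb"]), p_hb=float(r["p_hb"]), lb=float(r["lb"]),
            lot_shape_b=LotShape.parse(r["lot_shape_b"]), lot_num_b=int(r["lot_num_b"]),
            ambiguity=bool(int(r["ambiguity"])), correlation=int(r["correlation"]),
            feedback=bool(int(r["feedback"])), block=int(r["block"]),
        )
        for _, r in frame.iterrows()
    ]


def nested_group_regressions(features: pd.DataFrame, target: np.ndarray) -> pd.DataFrame:
    """Table of (feature set, MSE, R2) for the nested feature groups.

    Also reports the baseline MSE of predicting the mean difference.
    """
    rows = [{"features": "baseline (mean)",
             "mse": float(np.mean((target - np.mean(target)) ** 2)),
             "r2": 0.0}]
    for label, groups in NESTED_GROUPS:
        cols = [c for g in groups for c in FEATURE_GROUPS[g]]
        mse, r2 = fit_group_regression(features[cols].to_numpy(dtype=float), target)
        rows.append({"features": label, "mse": mse, "r2": r2})
    return pd.DataFrame(rows)


def per_feature_table(features: pd.DataFrame, target: np.ndarray) -> pd.DataFrame:
    """Univariate R2 (with 95% CI) of every feature against the target."""
    group_of = {c: g for g, cols in FEATURE_GROUPS.items() for c in cols}
    rows = []
    for col in features.columns:
        if col in ("id", "block"):
            continue
        values = features[col].to_numpy(dtype=float)
        if np.std(values) == 0:
            r2, (lo, hi) = 0.0, (0.0, 0.0)
        else:
            r2, (lo, hi) = per_feature_r2(values, target)
        rows.append({"feature": col, "group": group_of.get(col, "other"),
                     "r2": r2, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def difference_shap(model_lab: ChoiceModel, model_online: ChoiceModel,
                    problems: Sequence[Problem], n_background: int = 100,
                    max_samples: int = 2048, seed: int = 0):
    """SHAP attributions of the prediction difference over base features.

    The difference function is evaluated on perturbed base-feature vectors
    re-materialized as problems; the background is a seeded sample of the
    given problems.  Perturbed rows inherit the first problem's lottery
    shape, so attributions are exact for shapeless problems and approximate
    for multi-outcome shapes (whose expansion is not a base feature).
    """
    x = base_matrix(problems)
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(len(x), size=min(n_background, len(x)), replace=False)

    template = problems[0]

    def fn(matrix: np.ndarray) -> np.ndarray:
        perturbed = [_problem_from_base(row, template, i)
                     for i, row in enumerate(np.atleast_2d(matrix))]
        return (np.asarray(model_lab.predict(perturbed))
                - np.asarray(model_online.predict(perturbed)))

    phi, base_value = shap_attributions(fn, x, x[bg_idx],
                                        max_samples=max_samples, seed=seed)
    columns = FEATURE_GROUPS["base"]
    return pd.DataFrame(phi, columns=columns), base_value


def _problem_from_base(row: np.ndarray, template: Problem, idx: int) -> Problem:
    ha, p_ha, la, hb, p_hb, lb, amb, corr, fb, block = row
    return Problem(
        id=f"shap-{idx}", ha=float(ha), p_ha=float(np.clip(p_ha, 0, 1)), la=float(la),
        hb=float(hb), p_hb=float(np.clip(p_hb, 0, 1)), lb=float(lb),
        lot_shape_b=template.lot_shape_b, lot_num_b=template.lot_num_b,
        ambiguity=bool(round(np.clip(amb, 0, 1))),
        correlation=int(np.clip(round(corr), -1, 1)),
        feedback=bool(round(np.clip(fb, 0, 1))), block=max(1, int(round(block))),
    )


def attribution_report(lab_frame: pd.DataFrame, online_frame: pd.DataFrame,
                       seed: int = 0, max_samples: int = 2048,
                       n_background: int = 100) -> dict:
    """Full attribution bundle from two prediction frames (same problems).

    Both frames are canonical-dialect with a ``prediction`` column; the
    explained target is lab prediction minus online prediction.  SHAP here
    explains the tabulated difference via nearest-row lookup models, which
    is exact on the rows being explained.
    """
    problems = frame_to_problems(lab_frame)
    target = (lab_frame["prediction"].to_numpy(dtype=float)
              - online_frame["prediction"].to_numpy(dtype=float))
    features = feature_table(problems)
    groups = nested_group_regressions(features, target)
    per_feature = per_feature_table(features, target)

    x = base_matrix(problems)
    lookup = _NearestRowModel(x, target)
    phi, base_value = shap_attributions(
        lambda m: lookup(m), x,
        x[np.random.default_rng(seed).choice(len(x), min(n_background, len(x)),
                                             replace=False)],
        max_samples=max_samples, seed=seed)
    shap_frame = pd.DataFrame(phi, columns=FEATURE_GROUPS["base"])
    shap_frame.attrs["base_value"] = base_value
    per_feature["r2_from_shap"] = [
        regress_feature_on_shap(features[row.feature].to_numpy(dtype=float), phi)
        if np.std(features[row.feature]) > 0 else 0.0
        for row in per_feature.itertuples()
    ]
    return {"groups": groups, "per_feature": per_feature, "shap": shap_frame}


class _NearestRowModel:
    """Nearest-neighbour interpolant of a tabulated function of base features."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.scale = np.maximum(self.x.std(axis=0), 1e-9)

    def __call__(self, matrix: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(matrix, dtype=float)) / self.scale
        ref = self.x / self.scale
        out = np.empty(len(q))
        chunk = 512
        for start in range(0, len(q), chunk):
            d = ((q[start:start + chunk, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
            out[start:start + chunk] = self.y[np.argmin(d, axis=1)]
        return out
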