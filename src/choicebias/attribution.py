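"""Explaining model disagreement: regressions and Kernel-SHAP attributions.

Given the per-problem difference between a lab-trained and an online-trained
model, this module asks which gamble features account for it:

* grouped ordinary-least-squares regressions of the difference on nested
  feature sets (base, +naive, +psychological, +higher-order dominance);
* univariate R-squared per feature with Fisher-z confidence intervals;
* Kernel-SHAP additive attributions of the difference function over the
  base-feature space, and regressions of each feature on the SHAP matrix.

The Kernel-SHAP solver enumerates all coalitions exactly when feasible
(at most ``max_samples`` coalitions, i.e. up to ~11 features) and otherwise
samples coalitions by Shapley-kernel weight.  Attributions satisfy local
accuracy by construction: base value plus attributions equals the explained
function's output on every row.
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "fit_group_regression",
    "per_feature_r2",
    "shap_attributions",
    "regress_feature_on_shap",
]


def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """In-sample (MSE, R^2) of OLS with intercept; pseudo-inverse solve."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return mse, r2


def fit_group_regression(features: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """OLS of the model-difference target on a feature block: (MSE, R^2).

    Rank-deficient designs are handled by the least-norm (pseudo-inverse)
    solution, so collinear feature groups degrade gracefully.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] == 1 and features.shape[1] == len(np.ravel(target)):
        features = features.T
    if len(features) != len(np.ravel(target)) or len(features) < 2:
        raise ValueError("need >= 2 aligned rows")
    return _ols_r2(features, np.ravel(target))


def per_feature_r2(feature: np.ndarray, target: np.ndarray,
                   level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Univariate R^2 with a Fisher-z confidence interval.

    The CI is computed on the correlation scale (``atanh(r) ± z/sqrt(N-3)``)
    and mapped back; an interval straddling zero correlation yields a lower
    R^2 bound of 0.  Zero-variance features get R^2 = 0 with a warning.
    """
    from scipy.stats import norm
    import warnings

    feature = np.ravel(np.asarray(feature, dtype=float))
    target = np.ravel(np.asarray(target, dtype=float))
    if len(feature) != len(target) or len(feature) < 3:
        raise ValueError("need >= 3 aligned values")
    if np.std(feature) == 0 or np.std(target) == 0:
        warnings.warn("zero-variance input; R^2 set to 0", RuntimeWarning, stacklevel=2)
        return 0.0, (0.0, 0.0)
    r = float(np.corrcoef(feature, target)[0, 1])
    r = max(min(r, 1.0 - 1e-15), -1.0 + 1e-15)
    z = math.atanh(r)
    half = norm.ppf(0.5 + level / 2.0) / math.sqrt(len(feature) - 3)
    lo_r, hi_r = math.tanh(z - half), math.tanh(z + half)
    if lo_r <= 0.0 <= hi_r:
        lo2 = 0.0
    else:
        lo2 = min(lo_r**2, hi_r**2)
    hi2 = max(lo_r**2, hi_r**2)
    return r**2, (lo2, hi2)


def _kernel_weight(p: int, s: int) -> float:
    return (p - 1) / (math.comb(p, s) * s * (p - s))


def _coalitions(p: int, max_samples: int, rng: np.random.Generator):
    """(Z, weights): 0/1 coalition matrix and WLS weights."""
    total = 2**p - 2
    if total <= max_samples:
        z = np.array([list(c) for c in itertools.product([0, 1], repeat=p)][1:-1])
        w = np.array([_kernel_weight(p, int(row.sum())) for row in z])
        return z, w
    # sample coalition sizes by their total kernel-weight mass
    sizes = np.arange(1, p)
    mass = np.array([_kernel_weight(p, s) * math.comb(p, s) for s in sizes])
    mass /= mass.sum()
    picked = rng.choice(sizes, size=max_samples, p=mass)
    z = np.zeros((max_samples, p), dtype=int)
    for i, s in enumerate(picked):
        z[i, rng.choice(p, size=s, replace=False)] = 1
    return z, np.ones(max_samples)


def shap_attributions(difference_fn: Callable[[np.ndarray], np.ndarray],
                      instances: np.ndarray,
                      background: np.ndarray,
                      max_samples: int = 2048,
                      seed: int = 0) -> tuple[np.ndarray, float]:
    """Kernel-SHAP attributions of ``difference_fn`` for each instance row.

    ``difference_fn`` maps a feature matrix to one value per row.  Missing
    features are marginalized over the ``background`` rows.  Returns the
    attribution matrix (instances x features) and the base value
    (mean output on the background); ``base + attributions.sum(1)``
    reproduces ``difference_fn(instances)`` exactly.
    """
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must be nonempty")
    n, p = instances.shape
    rng = np.random.default_rng(seed)
    z, w = _coalitions(p, max_samples, rng)
    m, n_bg = len(z), len(background)

    base_value = float(np.mean(difference_fn(background)))
    fx = np.asarray(difference_fn(instances), dtype=float)

    phi = np.empty((n, p))
    for i in range(n):
        # v(S): expectation over background of f(x_S, b_notS)
        stacked = np.repeat(background[None, :, :], m, axis=0)        # (m, bg, p)
        mask = z.astype(bool)[:, None, :]
        stacked = np.where(mask, instances[i][None, None, :], stacked)
        vals = difference_fn(stacked.reshape(m * n_bg, p)).reshape(m, n_bg)
        v = vals.mean(axis=1)

        # constrained WLS: phi_p eliminated via sum(phi) = fx - base
        y = v - base_value - z[:, -1] * (fx[i] - base_value)
        a = z[:, :-1] - z[:, [-1]]
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(a * sw[:, None], y * sw, rcond=None)
        phi[i, :-1] = beta
        phi[i, -1] = (fx[i] - base_value) - beta.sum()
    return phi, base_value


def regress_feature_on_shap(feature: np.ndarray, shap_matrix: np.ndarray) -> float:
    """R^2 of OLS regressing one feature on the full SHAP value matrix."""
    shap_matrix = np.atleast_2d(np.asarray(shap_matrix, dtype=float))
    if shap_matrix.shape[0] != len(np.ravel(feature)):
        raise ValueError("feature and SHAP matrix must be row-aligned")
    _, r2 = _ols_r2(shap_matrix, np.ravel(feature))
    return r2
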