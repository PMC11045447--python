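"""Minimal feed-forward network machinery for the choice models.

Implements exactly what the two architectures need, in numpy: dense layers
with optional sparse connection masks, SReLU and sigmoid activations,
inverted dropout, RMSProp and Adam, mean-squared-error training with
validation checkpointing, and the sparse-evolutionary-training (SET)
rewiring step.

SReLU (s-shaped rectified linear unit) is piecewise linear with four
learnable parameters per unit — left/right thresholds ``t_l``/``t_r`` and
slopes ``a_l``/``a_r``:

    y = t_l + a_l * (x - t_l)   if x <= t_l
    y = x                       if t_l < x < t_r
    y = t_r + a_r * (x - t_r)   if x >= t_r

Initialized with unit slopes (identity behaviour); training bends the tails.

The SET step removes, per layer, the ``zeta`` fraction of smallest-magnitude
positive weights and the ``zeta`` fraction of largest (closest to zero)
negative weights among active connections, then activates the same number of
new random connections, so the total connection count is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SparseMLP", "set_step"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _SReLU:
    def __init__(self, width: int):
        self.tl = np.full(width, -1.0)
        self.al = np.ones(width)
        self.tr = np.full(width, 1.0)
        self.ar = np.ones(width)

    def forward(self, x):
        lo = x <= self.tl
        hi = x >= self.tr
        y = np.where(lo, self.tl + self.al * (x - self.tl),
                     np.where(hi, self.tr + self.ar * (x - self.tr), x))
        self._cache = (x, lo, hi)
        return y

    def backward(self, grad):
        x, lo, hi = self._cache
        dx = grad * np.where(lo, self.al, np.where(hi, self.ar, 1.0))
        self.g_tl = np.sum(grad * np.where(lo, 1.0 - self.al, 0.0), axis=0)
        self.g_al = np.sum(grad * np.where(lo, x - self.tl, 0.0), axis=0)
        self.g_tr = np.sum(grad * np.where(hi, 1.0 - self.ar, 0.0), axis=0)
        self.g_ar = np.sum(grad * np.where(hi, x - self.tr, 0.0), axis=0)
        return dx

    def params_grads(self):
        return [(self.tl, self.g_tl), (self.al, self.g_al),
                (self.tr, self.g_tr), (self.ar, self.g_ar)]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 density: float = 1.0):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, (n_in, n_out))
        self.b = np.zeros(n_out)
        if density >= 1.0:
            self.mask = None
        else:
            n_active = max(1, int(round(density * n_in * n_out)))
            flat = np.zeros(n_in * n_out, dtype=bool)
            flat[rng.permutation(n_in * n_out)[:n_active]] = True
            self.mask = flat.reshape(n_in, n_out)
            self.w *= self.mask

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.g_w = self._x.T @ grad
        if self.mask is not None:
            self.g_w *= self.mask
        self.g_b = grad.sum(axis=0)
        return grad @ self.w.T

    def params_grads(self):
        return [(self.w, self.g_w), (self.b, self.g_b)]

    def n_connections(self) -> int:
        return int(self.mask.sum()) if self.mask is not None else self.w.size


class _Optimizer:
    def __init__(self, kind: str, lr: float):
        if kind not in ("rmsprop", "adam"):
            raise ValueError("optimizer must be 'rmsprop' or 'adam'")
        self.kind, self.lr, self.t = kind, lr, 0
        self.state: dict = {}

    def step(self, params_grads):
        self.t += 1
        for i, (p, g) in enumerate(params_grads):
            st = self.state.setdefault(i, {"v": np.zeros_like(p), "m": np.zeros_like(p)})
            if self.kind == "rmsprop":
                st["v"] = 0.9 * st["v"] + 0.1 * g * g
                p -= self.lr * g / (np.sqrt(st["v"]) + 1e-8)
            else:
                st["m"] = 0.9 * st["m"] + 0.1 * g
                st["v"] = 0.999 * st["v"] + 0.001 * g * g
                m_hat = st["m"] / (1 - 0.9**self.t)
                v_hat = st["v"] / (1 - 0.999**self.t)
                p -= self.lr * m_hat / (np.sqrt(v_hat) + 1e-8)


def set_step(layer: _Dense, zeta: float, rng: np.random.Generator) -> None:
    """One SET rewiring step on a sparse layer (no-op when ``zeta`` is 0).

    Prunes the ``zeta`` fraction of smallest positive and largest negative
    active weights (both are the connections closest to zero from either
    side) and grows an equal number of random new connections.
    """
    if layer.mask is None:
        raise ValueError("SET requires a layer with a sparse mask")
    if not (0.0 <= zeta < 1.0):
        raise ValueError("zeta must lie in [0, 1)")
    if zeta == 0.0:
        return
    before = layer.n_connections()
    w, mask = layer.w, layer.mask
    active = np.flatnonzero(mask.ravel())
    vals = w.ravel()[active]

    pos = active[vals > 0]
    neg = active[vals < 0]
    n_pos = int(np.floor(zeta * len(pos)))
    n_neg = int(np.floor(zeta * len(neg)))
    drop = []
    if n_pos:
        drop.append(pos[np.argsort(w.ravel()[pos])[:n_pos]])        # smallest positive
    if n_neg:
        drop.append(neg[np.argsort(w.ravel()[neg])[-n_neg:]])       # largest negative
    drop_idx = np.concatenate(drop) if drop else np.array([], dtype=int)
    if drop_idx.size == 0:
        return

    flat_mask = mask.ravel()
    flat_mask[drop_idx] = False
    w.ravel()[drop_idx] = 0.0

    inactive = np.flatnonzero(~flat_mask)
    new_idx = rng.permutation(inactive)[: drop_idx.size]
    flat_mask[new_idx] = True
    limit = np.sqrt(6.0 / sum(w.shape))
    w.ravel()[new_idx] = rng.uniform(-limit, limit, new_idx.size) * 0.1

    layer.mask = flat_mask.reshape(mask.shape)
    assert layer.n_connections() == before, "SET must conserve connections"


@dataclass
class TrainResult:
    train_losses: list
    val_losses: list
    best_epoch: int


class SparseMLP:
    """Feed-forward regressor with sigmoid output trained on MSE.

    ``hidden`` sets the layer widths; ``activation`` is ``"srelu"`` or
    ``"sigmoid"``; ``density < 1`` makes every layer sparse (SET applies
    between epochs when ``zeta > 0``).
    """

    def __init__(self, n_in: int, hidden: Sequence[int], seed: int = 0,
                 activation: str = "srelu", dropout: float = 0.0,
                 density: float = 1.0, optimizer: str = "rmsprop",
                 lr: float = 1e-3, zeta: float = 0.0):
        self.rng = np.random.default_rng(seed)
        self.dropout = dropout
        self.zeta = zeta
        self.activation = activation
        sizes = [n_in, *hidden, 1]
        self.layers = [_Dense(sizes[i], sizes[i + 1], self.rng, density)
                       for i in range(len(sizes) - 1)]
        self.acts = [_SReLU(h) if activation == "srelu" else None for h in hidden]
        self.opt = _Optimizer(optimizer, lr)
        self._best_state = None

    # --- forward / backward ------------------------------------------------

    def _forward(self, x, training: bool):
        self._drop_masks = []
        h = x
        for i, layer in enumerate(self.layers[:-1]):
            h = layer.forward(h)
            if self.activation == "srelu":
                h = self.acts[i].forward(h)
            else:
                h = _sigmoid(h)
                self._sig_cache = getattr(self, "_sig_cache", {})
                self._sig_cache[i] = h
            if training and self.dropout > 0:
                keep = (self.rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                self._drop_masks.append(keep)
                h = h * keep
            else:
                self._drop_masks.append(None)
        z = self.layers[-1].forward(h)
        y = _sigmoid(z)
        self._out = y
        return y

    def predict(self, x) -> np.ndarray:
        return self._forward(np.asarray(x, dtype=float), training=False).ravel()

    def _backward(self, y_true):
        y = self._out
        n = y.shape[0]
        grad = 2.0 * (y - y_true.reshape(-1, 1)) / n * y * (1.0 - y)
        grad = self.layers[-1].backward(grad)
        for i in range(len(self.layers) - 2, -1, -1):
            if self._drop_masks[i] is not None:
                grad = grad * self._drop_masks[i]
            if self.activation == "srelu":
                grad = self.acts[i].backward(grad)
            else:
                s = self._sig_cache[i]
                grad = grad * s * (1.0 - s)
            grad = self.layers[i].backward(grad)

    def _params_grads(self):
        pg = []
        for layer in self.layers:
            pg.extend(layer.params_grads())
        if self.activation == "srelu":
            for act in self.acts:
                pg.extend(act.params_grads())
        return pg

    # --- training ----------------------------------------------------------

    def loss(self, x, y) -> float:
        pred = self.predict(x)
        return float(np.mean((pred - np.asarray(y, dtype=float)) ** 2))

    def fit(self, x, y, epochs: int, batch_size: int = 64,
            x_val=None, y_val=None, checkpoint: bool = False) -> TrainResult:
        """Minibatch MSE training; with ``checkpoint`` the weights of the
        best-validation epoch are restored at the end."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(x)
        train_losses, val_losses = [], []
        best = (np.inf, -1)
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                self._forward(x[idx], training=True)
                self._backward(y[idx])
                self.opt.step(self._params_grads())
                for layer in self.layers:
                    if layer.mask is not None:
                        layer.w *= layer.mask
            if self.zeta > 0:
                for layer in self.layers:
                    if layer.mask is not None:
                        set_step(layer, self.zeta, self.rng)
            train_losses.append(self.loss(x, y))
            if x_val is not None:
                vl = self.loss(x_val, y_val)
                val_losses.append(vl)
                if checkpoint and vl < best[0]:
                    best = (vl, epoch)
                    self._best_state = self._snapshot()
        if checkpoint and self._best_state is not None:
            self._restore(self._best_state)
        return TrainResult(train_losses, val_losses, best[1])

    def set_lr(self, lr: float, optimizer: str | None = None) -> None:
        self.opt = _Optimizer(optimizer or self.opt.kind, lr)

    def n_connections(self) -> list[int]:
        return [layer.n_connections() for layer in self.layers]

    def _snapshot(self):
        state = [(layer.w.copy(), layer.b.copy(),
                  None if layer.mask is None else layer.mask.copy())
                 for layer in self.layers]
        acts = ([(a.tl.copy(), a.al.copy(), a.tr.copy(), a.ar.copy())
                 for a in self.acts] if self.activation == "srelu" else None)
        return (state, acts)

    def _restore(self, snapshot):
        state, acts = snapshot
        for layer, (w, b, m) in zip(self.layers, state):
            layer.w, layer.b, layer.mask = w.copy(), b.copy(), (None if m is None else m.copy())
        if acts is not None:
            for a, (tl, al, tr, ar) in zip(self.acts, acts):
                a.tl, a.al, a.tr, a.ar = tl.copy(), al.copy(), tr.copy(), ar.copy()
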