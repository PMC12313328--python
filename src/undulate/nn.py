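"""Minimal recurrent and convolutional-recurrent classifiers in numpy.

Two sequence models mirror the study design: a gated recurrent unit
(GRU) over per-frame scalar shape features, and a CNN-GRU in which a
small convolutional encoder with weights shared across timesteps embeds
each 96×96 two-channel mask image before the recurrence.  A static CNN
head (no recurrence) serves as the morphology-only control.

The networks are deliberately small — tens of hidden units, two conv
blocks — and are trained with Adam on binary cross-entropy.  Padded
timesteps are excluded from the recurrence via the validity mask: the
hidden state is carried through unchanged, so zero padding can never
masquerade as signal.  All weights and the shuffling are seeded;
training is deterministic up to BLAS reduction order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------- GRU core

class GRUCore:
    """Single-layer GRU with masked updates and a sigmoid head."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        s_in = 1.0 / math.sqrt(n_in)
        s_h = 1.0 / math.sqrt(units)
        p = {}
        for gate in ("z", "r", "h"):
            p[f"W{gate}"] = rng.normal(0, s_in, (n_in, units))
            p[f"U{gate}"] = rng.normal(0, s_h, (units, units))
            p[f"b{gate}"] = np.zeros(units)
        p["w_out"] = rng.normal(0, s_h, units)
        p["b_out"] = np.zeros(1)
        self.p = p
        self.units = units
        self.n_in = n_in

    def forward(self, x: np.ndarray, valid: np.ndarray,
                cache: bool = False):
        """x: (N, T, n_in); valid: (N, T) bool.  Returns p(y=1)."""
        n, t_len, _ = x.shape
        p = self.p
        h = np.zeros((n, self.units))
        steps = []
        for t in range(t_len):
            xt = x[:, t]
            m = valid[:, t, None].astype(float)
            z = _sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
            c = np.tanh(xt @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
            h_new = (1 - z) * h + z * c
            h_next = m * h_new + (1 - m) * h
            if cache:
                steps.append((xt, h.copy(), z, r, c, m))
            h = h_next
        logits = h @ p["w_out"] + p["b_out"][0]
        prob = _sigmoid(logits)
        if cache:
            return prob, (steps, h)
        return prob

    def backward(self, x, valid, y, prob, cache
                 ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Mean-BCE gradients; also returns dL/dx for upstream encoders."""
        steps, h_last = cache
        n, t_len, _ = x.shape
        p = self.p
        g = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = (prob - y) / n
        g["w_out"] = h_last.T @ dlogits
        g["b_out"] = np.array([dlogits.sum()])
        dh = np.outer(dlogits, p["w_out"])
        dx = np.zeros_like(x)
        for t in range(t_len - 1, -1, -1):
            xt, h_prev, z, r, c, m = steps[t]
            dh_eff = dh * m
            dh_prev = dh * (1 - m)
            dc = dh_eff * z
            dz = dh_eff * (c - h_prev)
            dh_prev += dh_eff * (1 - z)
            dac = dc * (1 - c * c)
            daz = dz * z * (1 - z)
            drh = dac @ p["Uh"].T
            dr = drh * h_prev
            dh_prev += drh * r
            dar = dr * r * (1 - r)
            dh_prev += daz @ p["Uz"].T + dar @ p["Ur"].T
            g["Wz"] += xt.T @ daz
            g["Wr"] += xt.T @ dar
            g["Wh"] += xt.T @ dac
            g["Uz"] += h_prev.T @ daz
            g["Ur"] += h_prev.T @ dar
            g["Uh"] += (r * h_prev).T @ dac
            g["bz"] += daz.sum(axis=0)
            g["br"] += dar.sum(axis=0)
            g["bh"] += dac.sum(axis=0)
            dx[:, t] = daz @ p["Wz"].T + dar @ p["Wr"].T + dac @ p["Wh"].T
            dh = dh_prev
        return g, dx


# ------------------------------------------------------------- CNN encoder

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(F, H, W, C) → (F, H-k+1, W-k+1, k·k·C) by stacking k² shifts."""
    f, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    cols = np.empty((f, oh, ow, k * k, c), dtype=x.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[:, :, :, idx, :] = x[:, di:di + oh, dj:dj + ow, :]
            idx += 1
    return cols.reshape(f, oh, ow, k * k * c)


def _col2im(dcols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    f, h, w, c = shape
    oh, ow = h - k + 1, w - k + 1
    dcols = dcols.reshape(f, oh, ow, k * k, c)
    dx = np.zeros(shape, dtype=dcols.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            dx[:, di:di + oh, dj:dj + ow, :] += dcols[:, :, :, idx, :]
            idx += 1
    return dx


class ConvEncoder:
    """Shared-weight per-frame encoder: pool4 → conv3×3 → pool2 → conv3×3
    → global average pool.  Input frames (F, 96, 96, 2) → (F, emb)."""

    def __init__(self, filters1: int, filters2: int,
                 rng: np.random.Generator, in_channels: int = 2,
                 input_pool: int = 4):
        self.k = 3
        self.input_pool = input_pool
        self.f1, self.f2 = filters1, filters2
        # float32 throughout: halves the matmul cost of the per-frame
        # encoder, which dominates CNN-GRU training time
        self.p = {
            "C1": rng.normal(0, math.sqrt(2.0 / (9 * in_channels)),
                             (9 * in_channels, filters1)
                             ).astype(np.float32),
            "c1b": np.zeros(filters1, dtype=np.float32),
            "C2": rng.normal(0, math.sqrt(2.0 / (9 * filters1)),
                             (9 * filters1, filters2)
                             ).astype(np.float32),
            "c2b": np.zeros(filters2, dtype=np.float32),
        }
        self.emb = filters2

    def pool_input(self, frames: np.ndarray) -> np.ndarray:
        """Parameter-free input average pooling, computable once."""
        ip = self.input_pool
        frames = np.ascontiguousarray(frames, dtype=np.float32)
        f, h, w, c = frames.shape
        return frames.reshape(f, h // ip, ip, w // ip, ip, c).mean(
            axis=(2, 4), dtype=np.float32)

    def forward(self, frames: np.ndarray, cache: bool = False,
                prepooled: bool = False):
        """frames: (F, H, W, C), any dtype; computed in float32."""
        x0 = frames if prepooled else self.pool_input(frames)
        col1 = _im2col(x0, self.k)
        a1 = col1 @ self.p["C1"] + self.p["c1b"]
        r1 = np.maximum(a1, 0.0)
        # 2x2 max pool
        f_, oh, ow, ch = r1.shape
        oh2, ow2 = oh // 2, ow // 2
        r1c = r1[:, :oh2 * 2, :ow2 * 2, :]
        blocks = r1c.reshape(f_, oh2, 2, ow2, 2, ch)
        p1 = blocks.max(axis=(2, 4))
        col2 = _im2col(p1, self.k)
        a2 = col2 @ self.p["C2"] + self.p["c2b"]
        r2 = np.maximum(a2, 0.0)
        emb = r2.mean(axis=(1, 2))
        if cache:
            return emb, (x0, col1, a1, blocks, p1, col2, a2, r2.shape)
        return emb

    def backward(self, demb: np.ndarray, cache) -> dict[str, np.ndarray]:
        x0, col1, a1, blocks, p1, col2, a2, r2_shape = cache
        demb = np.asarray(demb, dtype=np.float32)
        f, oh2, ow2, ch2 = r2_shape
        dr2 = np.broadcast_to(
            demb[:, None, None, :] / (oh2 * ow2), r2_shape).copy()
        da2 = dr2 * (a2 > 0)
        g = {}
        g["C2"] = col2.reshape(-1, col2.shape[-1]).T @ da2.reshape(
            -1, da2.shape[-1])
        g["c2b"] = da2.sum(axis=(0, 1, 2))
        dcol2 = da2 @ self.p["C2"].T
        dp1 = _col2im(dcol2, p1.shape, self.k)
        # back through 2x2 max pool
        f_, po, _, pw, _, ch = blocks.shape
        maxval = blocks.max(axis=(2, 4), keepdims=True)
        is_max = blocks == maxval
        # distribute over ties equally to keep gradient well-defined
        n_max = is_max.sum(axis=(2, 4), keepdims=True)
        dblocks = (is_max / n_max) * dp1[:, :, None, :, None, :]
        dr1 = np.zeros(a1.shape, dtype=dp1.dtype)
        dr1[:, :po * 2, :pw * 2, :] = dblocks.reshape(f_, po * 2, pw * 2, ch)
        da1 = dr1 * (a1 > 0)
        g["C1"] = col1.reshape(-1, col1.shape[-1]).T @ da1.reshape(
            -1, da1.shape[-1])
        g["c1b"] = da1.sum(axis=(0, 1, 2))
        return g


# --------------------------------------------------------------- trainers

@dataclass
class TrainLog:
    epoch_val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1


class GRUClassifier:
    """GRU over padded scalar sequences with validation-based selection."""

    def __init__(self, n_channels: int, units: int = 24, lr: float = 1e-2,
                 epochs: int = 175, batch_size: int = 64, seed: int = 0):
        self.units, self.lr = units, lr
        self.epochs, self.batch_size, self.seed = epochs, batch_size, seed
        self.n_channels = n_channels
        self.core: GRUCore | None = None
        self.log = TrainLog()

    def fit(self, x, valid, y, x_val=None, valid_val=None, y_val=None):
        rng = np.random.default_rng(self.seed)
        self.core = GRUCore(self.n_channels, self.units, rng)
        opt = Adam(self.core.p, lr=self.lr)
        n = x.shape[0]
        best_acc, best_params = -1.0, None
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                prob, cache = self.core.forward(x[idx], valid[idx],
                                                cache=True)
                grads, _ = self.core.backward(x[idx], valid[idx], y[idx],
                                              prob, cache)
                opt.step(grads)
            if x_val is not None and len(y_val):
                acc = float((self.predict(x_val, valid_val) == y_val).mean())
                self.log.epoch_val_accuracy.append(acc)
                if acc >= best_acc:
                    best_acc = acc
                    best_params = {k: v.copy()
                                   for k, v in self.core.p.items()}
                    self.log.best_epoch = epoch
        if best_params is not None:
            self.core.p = best_params
        return self

    def predict_proba(self, x, valid) -> np.ndarray:
        return self.core.forward(x, valid)

    def predict(self, x, valid) -> np.ndarray:
        return (self.predict_proba(x, valid) >= 0.5).astype(int)


class CNNGRUClassifier:
    """Per-frame conv encoder (weights shared across time) + GRU."""

    def __init__(self, units: int = 24, filters1: int = 8,
                 filters2: int = 16, lr: float = 3e-3, epochs: int = 30,
                 batch_size: int = 32, seed: int = 0, input_pool: int = 4):
        self.units = units
        self.filters = (filters1, filters2)
        self.lr, self.epochs, self.batch_size = lr, epochs, batch_size
        self.seed = seed
        self.input_pool = input_pool
        self.encoder: ConvEncoder | None = None
        self.core: GRUCore | None = None
        self.log = TrainLog()

    def _pool_sequences(self, x: np.ndarray) -> np.ndarray:
        """Apply the parameter-free input pooling to a whole set once."""
        n, t_len = x.shape[:2]
        pooled = self.encoder.pool_input(
            x.reshape(n * t_len, *x.shape[2:]))
        return pooled.reshape(n, t_len, *pooled.shape[1:])

    def _embed(self, x_pooled, valid, cache: bool = False):
        """Encode only the valid frames; padded steps embed to zero."""
        n, t_len = valid.shape
        flat_idx = np.nonzero(valid.reshape(-1))[0]
        enc_in = x_pooled.reshape(n * t_len, *x_pooled.shape[2:])[flat_idx]
        if cache:
            emb_flat, enc_cache = self.encoder.forward(enc_in, cache=True,
                                                       prepooled=True)
        else:
            emb_flat = self.encoder.forward(enc_in, prepooled=True)
            enc_cache = None
        emb = np.zeros((n * t_len, self.encoder.emb))
        emb[flat_idx] = emb_flat
        return emb.reshape(n, t_len, -1), flat_idx, enc_cache

    def fit(self, x, valid, y, x_val=None, valid_val=None, y_val=None):
        rng = np.random.default_rng(self.seed)
        self.encoder = ConvEncoder(*self.filters, rng,
                                   in_channels=x.shape[-1],
                                   input_pool=self.input_pool)
        self.core = GRUCore(self.encoder.emb, self.units, rng)
        params = {**{f"enc_{k}": v for k, v in self.encoder.p.items()},
                  **{f"gru_{k}": v for k, v in self.core.p.items()}}
        opt = Adam(params, lr=self.lr)
        n = x.shape[0]
        x_pooled = self._pool_sequences(x)
        if x_val is not None:
            x_val = self._pool_sequences(x_val)
        best_acc, best = -1.0, None
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, vb, yb = x_pooled[idx], valid[idx], y[idx]
                emb, flat_idx, enc_cache = self._embed(xb, vb, cache=True)
                prob, gru_cache = self.core.forward(emb, vb, cache=True)
                gru_grads, demb = self.core.backward(emb, vb, yb, prob,
                                                     gru_cache)
                demb_flat = demb.reshape(-1, self.encoder.emb)[flat_idx]
                enc_grads = self.encoder.backward(demb_flat, enc_cache)
                opt.step({**{f"enc_{k}": v for k, v in enc_grads.items()},
                          **{f"gru_{k}": v for k, v in gru_grads.items()}})
            if x_val is not None and len(y_val):
                pred = (self._predict_pooled(x_val, valid_val) >= 0.5)
                acc = float((pred.astype(int) == y_val).mean())
                self.log.epoch_val_accuracy.append(acc)
                if acc >= best_acc:
                    best_acc = acc
                    best = ({k: v.copy() for k, v in self.encoder.p.items()},
                            {k: v.copy() for k, v in self.core.p.items()})
                    self.log.best_epoch = epoch
        if best is not None:
            self.encoder.p, self.core.p = best
        return self

    def _predict_pooled(self, x_pooled, valid, chunk: int = 64
                        ) -> np.ndarray:
        out = np.empty(x_pooled.shape[0])
        for start in range(0, x_pooled.shape[0], chunk):
            sl = slice(start, start + chunk)
            emb, _, _ = self._embed(x_pooled[sl], valid[sl])
            out[sl] = self.core.forward(emb, valid[sl])
        return out

    def predict_proba(self, x, valid, chunk: int = 64) -> np.ndarray:
        # chunked to bound the float32 frame buffer
        out = np.empty(x.shape[0])
        for start in range(0, x.shape[0], chunk):
            sl = slice(start, start + chunk)
            out[sl] = self._predict_pooled(self._pool_sequences(x[sl]),
                                           valid[sl])
        return out

    def predict(self, x, valid) -> np.ndarray:
        return (self.predict_proba(x, valid) >= 0.5).astype(int)


class MaskCNNClassifier:
    """Static conv encoder + logistic head on single mask images.

    Used as the morphology-only control: classify cells from their
    undeformed cavity mask alone, with no access to dynamics.
    """

    def __init__(self, filters1: int = 8, filters2: int = 16,
                 lr: float = 3e-3, epochs: int = 30, batch_size: int = 32,
                 seed: int = 0, input_pool: int = 4):
        self.filters = (filters1, filters2)
        self.lr, self.epochs, self.batch_size = lr, epochs, batch_size
        self.seed = seed
        self.input_pool = input_pool
        self.encoder: ConvEncoder | None = None
        self.head: dict[str, np.ndarray] | None = None
        self.log = TrainLog()

    def fit(self, x, y, x_val=None, y_val=None):
        rng = np.random.default_rng(self.seed)
        self.encoder = ConvEncoder(*self.filters, rng,
                                   in_channels=x.shape[-1],
                                   input_pool=self.input_pool)
        self.head = {"w": rng.normal(0, 0.1, self.encoder.emb),
                     "b": np.zeros(1)}
        params = {**{f"enc_{k}": v for k, v in self.encoder.p.items()},
                  **{f"head_{k}": v for k, v in self.head.items()}}
        opt = Adam(params, lr=self.lr)
        n = x.shape[0]
        best_acc, best = -1.0, None
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = x[idx].astype(np.float64)
                emb, cache = self.encoder.forward(xb, cache=True)
                logits = emb @ self.head["w"] + self.head["b"][0]
                prob = _sigmoid(logits)
                dlog = (prob - y[idx]) / len(idx)
                head_grads = {"w": emb.T @ dlog,
                              "b": np.array([dlog.sum()])}
                demb = np.outer(dlog, self.head["w"])
                enc_grads = self.encoder.backward(demb, cache)
                opt.step({**{f"enc_{k}": v for k, v in enc_grads.items()},
                          **{f"head_{k}": v
                             for k, v in head_grads.items()}})
            if x_val is not None and len(y_val):
                acc = float((self.predict(x_val) == y_val).mean())
                self.log.epoch_val_accuracy.append(acc)
                if acc >= best_acc:
                    best_acc = acc
                    best = ({k: v.copy() for k, v in self.encoder.p.items()},
                            {k: v.copy() for k, v in self.head.items()})
                    self.log.best_epoch = epoch
        if best is not None:
            self.encoder.p, self.head = best
        return self

    def predict_proba(self, x) -> np.ndarray:
        emb = self.encoder.forward(x.astype(np.float64))
        return _sigmoid(emb @ self.head["w"] + self.head["b"][0])

    def predict(self, x) -> np.ndarray:
        return (self.predict_proba(x) >= 0.5).astype(int)
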