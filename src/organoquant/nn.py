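"""A compact, dependency-free convolutional network for binary crop classification.

Three 3x3 convolution blocks (8, 16, 32 filters) with ReLU and 2x2 max
pooling, preceded by a 2x2 average-pool downsampling of the input crop and
followed by global average pooling and a dense softmax head. Written in
plain NumPy (im2col convolutions, Adam updates) so training is fully
seeded and bit-reproducible on a fixed platform, and small enough to
train on a single CPU in well under a minute per thousand 128x128 crops.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patches with 'same' zero padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k) -> (N, H*W, C*k*k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * k * k)


def _col2im(dcols: np.ndarray, shape: tuple, k: int = 3) -> np.ndarray:
    """Adjoint of _im2col: scatter patch gradients back to (N, C, H, W)."""
    n, c, h, w = shape
    p = k // 2
    d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += d[..., i, j]
    return dxp[:, :, p:p + h, p:p + w]


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x):
        n, _, h, w = x.shape
        self.cols = _im2col(x, 3)
        self.in_shape = x.shape
        out = self.cols @ self.w.T + self.b
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, dout):
        n, c_out, h, w = dout.shape
        dflat = dout.reshape(n, c_out, h * w).transpose(0, 2, 1)
        self.dw = np.einsum("npo,npk->ok", dflat, self.cols).astype(np.float32)
        self.db = dflat.sum(axis=(0, 1)).astype(np.float32)
        dcols = dflat @ self.w
        return _col2im(dcols, self.in_shape, 3)


def _maxpool2(x):
    n, c, h, w = x.shape
    r = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))
    mask = r == out[:, :, :, None, :, None]
    return out, (mask, x.shape)


def _maxpool2_back(dout, cache):
    mask, shape = cache
    n, c, h, w = shape
    d = mask * dout[:, :, :, None, :, None]
    return d.reshape(n, c, h, w)


def _avgpool2(x):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


class SmallCNN:
    """Seeded binary classifier over square single-channel crops in [0, 1]."""

    def __init__(self, side: int = 128, seed: int = 0):
        if side % 8 != 0:
            raise ValueError("crop side must be divisible by 8")
        self.side = side
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.conv1 = _Conv(1, 8, rng)
        self.conv2 = _Conv(8, 16, rng)
        self.conv3 = _Conv(16, 32, rng)
        self.w_fc = rng.normal(0, np.sqrt(2.0 / 32), (32, 2)).astype(np.float32)
        self.b_fc = np.zeros(2, dtype=np.float32)

    # ------------------------------------------------------------------
    def _forward(self, x, train=False):
        x = x[:, None].astype(np.float32)
        x = _avgpool2(x)
        a1 = self.conv1.forward(x)
        r1 = np.maximum(a1, 0)
        p1, c1 = _maxpool2(r1)
        a2 = self.conv2.forward(p1)
        r2 = np.maximum(a2, 0)
        p2, c2 = _maxpool2(r2)
        a3 = self.conv3.forward(p2)
        r3 = np.maximum(a3, 0)
        feat = r3.mean(axis=(2, 3))
        logits = feat @ self.w_fc + self.b_fc
        if train:
            self._cache = (a1, c1, a2, c2, a3, r3.shape, feat)
        return logits

    def _backward(self, dlogits):
        a1, c1, a2, c2, a3, r3_shape, feat = self._cache
        self.dw_fc = feat.T @ dlogits
        self.db_fc = dlogits.sum(axis=0)
        dfeat = dlogits @ self.w_fc.T
        n, c, h, w = r3_shape
        dr3 = np.broadcast_to(dfeat[:, :, None, None] / (h * w), r3_shape).copy()
        da3 = dr3 * (a3 > 0)
        dp2 = self.conv3.backward(da3)
        dr2 = _maxpool2_back(dp2, c2)
        da2 = dr2 * (a2 > 0)
        dp1 = self.conv2.backward(da2)
        dr1 = _maxpool2_back(dp1, c1)
        da1 = dr1 * (a1 > 0)
        self.conv1.backward(da1)

    # ------------------------------------------------------------------
    def _params_and_grads(self):
        return [
            (self.conv1, "w", "dw"), (self.conv1, "b", "db"),
            (self.conv2, "w", "dw"), (self.conv2, "b", "db"),
            (self.conv3, "w", "dw"), (self.conv3, "b", "db"),
            (self, "w_fc", "dw_fc"), (self, "b_fc", "db_fc"),
        ]

    def fit(self, x, y, epochs: int = 12, batch_size: int = 32,
            learning_rate: float = 1e-3, x_val=None, y_val=None):
        """Adam + softmax cross-entropy. ``y`` holds class indices {0, 1}.
        Returns the per-epoch history (loss, validation accuracy)."""
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        rng = np.random.default_rng(self.seed + 1)
        slots = self._params_and_grads()
        m = [np.zeros_like(getattr(o, p)) for o, p, _ in slots]
        v = [np.zeros_like(getattr(o, p)) for o, p, _ in slots]
        b1, b2, eps, t = 0.9, 0.999, 1e-8, 0
        history = []
        for epoch in range(epochs):
            order = rng.permutation(len(x))
            losses = []
            for start in range(0, len(x), batch_size):
                idx = order[start:start + batch_size]
                logits = self._forward(x[idx], train=True)
                z = logits - logits.max(axis=1, keepdims=True)
                ez = np.exp(z)
                probs = ez / ez.sum(axis=1, keepdims=True)
                losses.append(float(-np.mean(np.log(probs[np.arange(len(idx)), y[idx]]
                                                    + 1e-12))))
                dlogits = probs
                dlogits[np.arange(len(idx)), y[idx]] -= 1
                dlogits /= len(idx)
                self._backward(dlogits.astype(np.float32))
                t += 1
                for i, (obj, pname, gname) in enumerate(slots):
                    g = getattr(obj, gname)
                    m[i] = b1 * m[i] + (1 - b1) * g
                    v[i] = b2 * v[i] + (1 - b2) * g * g
                    mh = m[i] / (1 - b1**t)
                    vh = v[i] / (1 - b2**t)
                    setattr(obj, pname,
                            getattr(obj, pname) - learning_rate * mh / (np.sqrt(vh) + eps))
            entry = {"epoch": epoch, "loss": float(np.mean(losses))}
            if x_val is not None and len(x_val):
                entry["val_accuracy"] = float(
                    np.mean(self.predict(x_val) == np.asarray(y_val)))
            history.append(entry)
        return history

    def predict_proba(self, x, batch_size: int = 64):
        x = np.asarray(x, dtype=np.float32)
        out = []
        for start in range(0, len(x), batch_size):
            logits = self._forward(x[start:start + batch_size])
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z)
            out.append(ez / ez.sum(axis=1, keepdims=True))
        return np.concatenate(out) if out else np.zeros((0, 2))

    def predict(self, x):
        return self.predict_proba(x).argmax(axis=1)

    # ------------------------------------------------------------------
    def save(self, path):
        np.savez(
            Path(path),
            meta=np.frombuffer(json.dumps({"side": self.side, "seed": self.seed})
                               .encode(), dtype=np.uint8),
            c1w=self.conv1.w, c1b=self.conv1.b,
            c2w=self.conv2.w, c2b=self.conv2.b,
            c3w=self.conv3.w, c3b=self.conv3.b,
            fcw=self.w_fc, fcb=self.b_fc,
        )

    @classmethod
    def load(cls, path):
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            net = cls(side=meta["side"], seed=meta["seed"])
            net.conv1.w, net.conv1.b = data["c1w"], data["c1b"]
            net.conv2.w, net.conv2.b = data["c2w"], data["c2b"]
            net.conv3.w, net.conv3.b = data["c3w"], data["c3b"]
            net.w_fc, net.b_fc = data["fcw"], data["fcb"]
        return net
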