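"""A compact 2D U-net with explicit forward/backward passes in numpy.

The segmentation network is deliberately small — a few encoder/decoder
levels of 3×3 convolutions with ReLU, 2×2 max-pooling, nearest-neighbour
upsampling with skip concatenation, and a 1×1 classification head — sized to
train on a CPU in minutes.  The implementation is plain numpy (im2col
convolutions, hand-derived gradients, Adam), channels-last, float32, and
fully deterministic given a seed.

Arrays are (batch, height, width, channels); inputs must have height and
width divisible by 2**depth (callers pad symmetrically).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


# ---------------------------------------------------------------------------
# primitive ops (functional, each returns output + cache for backward)


def _conv3x3_forward(x, W, b):
    n, h, w, cin = x.shape
    cout = W.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (n,h,w,cin,3,3)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, 9 * cin
    )
    out = cols @ W.reshape(9 * cin, cout) + b
    return out.reshape(n, h, w, cout), cols


def _conv3x3_backward(dout, cols, x_shape, W):
    n, h, w, cin = x_shape
    cout = W.shape[-1]
    dflat = dout.reshape(n * h * w, cout)
    dW = (cols.T @ dflat).reshape(W.shape)
    db = dflat.sum(axis=0)
    dcols = (dflat @ W.reshape(9 * cin, cout).T).reshape(n, h, w, 3, 3, cin)
    dxp = np.zeros((n, h + 2, w + 2, cin), dtype=dout.dtype)
    for ki in range(3):
        for kj in range(3):
            dxp[:, ki : ki + h, kj : kj + w, :] += dcols[:, :, :, ki, kj, :]
    return dxp[:, 1 : 1 + h, 1 : 1 + w, :], dW, db


def _conv1x1_forward(x, W, b):
    return x @ W + b


def _conv1x1_backward(dout, x, W):
    n, h, w, cin = x.shape
    dflat = dout.reshape(-1, W.shape[-1])
    dW = x.reshape(-1, cin).T @ dflat
    db = dflat.sum(axis=0)
    dx = (dflat @ W.T).reshape(x.shape)
    return dx, dW, db


def _maxpool2(x):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    # distribute gradient equally over ties (rare with float activations)
    mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
    return out, mask.astype(x.dtype)


def _maxpool2_backward(dout, mask):
    n, h2, w2, c = dout.shape
    d = dout[:, :, None, :, None, :] * mask
    return d.reshape(n, h2 * 2, w2 * 2, c)


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_backward(dout):
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits, labels, class_weights):
    """Mean class-weighted cross-entropy over all pixels.

    Returns (loss, dlogits).  labels: integer array matching logits[..., 0];
    class_weights: (n_classes,) array.
    """
    p = softmax(logits.astype(np.float64))
    w = np.asarray(class_weights, dtype=np.float64)[labels]
    wsum = w.sum()
    py = np.take_along_axis(p, labels[..., None], axis=-1)[..., 0]
    loss = float(-(w * np.log(np.maximum(py, 1e-12))).sum() / wsum)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    dlogits = ((p - onehot) * w[..., None] / wsum).astype(logits.dtype)
    return loss, dlogits


# ---------------------------------------------------------------------------
# the network


@dataclass
class _ConvParam:
    W: np.ndarray
    b: np.ndarray


class UNet2D:
    """Small U-net: ``depth`` poolings, channels doubling from ``base_channels``."""

    def __init__(self, depth=3, base_channels=8, n_classes=5, in_channels=1, seed=0):
        if depth < 1 or base_channels < 4:
            raise ValueError("depth ≥ 1 and base_channels ≥ 4 required")
        self.depth = depth
        self.base_channels = base_channels
        self.n_classes = n_classes
        self.in_channels = in_channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, _ConvParam] = {}

        def conv(name, cin, cout, k=3):
            std = np.sqrt(2.0 / (k * k * cin))
            W = rng.normal(0, std, size=(k, k, cin, cout)).astype(np.float32)
            if k == 1:
                W = W[0, 0]
            self.params[name] = _ConvParam(W, np.zeros(cout, dtype=np.float32))

        ch = [base_channels * 2**l for l in range(depth + 1)]
        cin = in_channels
        for l in range(depth):
            conv(f"enc{l}a", cin, ch[l])
            conv(f"enc{l}b", ch[l], ch[l])
            cin = ch[l]
        conv(f"bot_a", cin, ch[depth])
        conv(f"bot_b", ch[depth], ch[depth])
        for l in reversed(range(depth)):
            conv(f"up{l}", ch[l + 1], ch[l])  # after nearest-upsample
            conv(f"dec{l}a", 2 * ch[l], ch[l])  # skip concat
            conv(f"dec{l}b", ch[l], ch[l])
        conv("head", ch[0], n_classes, k=1)
        self._adam = {}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def astype(self, dtype):
        """Convert all parameters in place (float64 useful for gradient checks)."""
        for p in self.params.values():
            p.W = p.W.astype(dtype)
            p.b = p.b.astype(dtype)
        return self

    @property
    def dtype(self):
        return self.params["head"].W.dtype

    def forward(self, x, want_cache=False):
        """Logits for a batch (n, h, w, in_channels); h, w divisible by 2**depth."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[..., None]
        h, w = x.shape[1:3]
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(f"input {h}×{w} not divisible by 2^{self.depth}")
        cache = {"x": x}
        skips = []
        cur = x
        for l in range(self.depth):
            for part in "ab":
                p = self.params[f"enc{l}{part}"]
                pre, cols = _conv3x3_forward(cur, p.W, p.b)
                act = np.maximum(pre, 0)
                cache[f"enc{l}{part}"] = (cur.shape, cols, pre > 0)
                cur = act
            skips.append(cur)
            cur, mask = _maxpool2(cur)
            cache[f"pool{l}"] = mask
        for name in ("bot_a", "bot_b"):
            p = self.params[name]
            pre, cols = _conv3x3_forward(cur, p.W, p.b)
            cache[name] = (cur.shape, cols, pre > 0)
            cur = np.maximum(pre, 0)
        for l in reversed(range(self.depth)):
            up = _upsample2(cur)
            p = self.params[f"up{l}"]
            pre, cols = _conv3x3_forward(up, p.W, p.b)
            cache[f"up{l}"] = (up.shape, cols, pre > 0)
            upc = np.maximum(pre, 0)
            cur = np.concatenate([skips[l], upc], axis=-1)
            cache[f"cat{l}"] = skips[l].shape[-1]
            for part in "ab":
                p = self.params[f"dec{l}{part}"]
                pre, cols = _conv3x3_forward(cur, p.W, p.b)
                cache[f"dec{l}{part}"] = (cur.shape, cols, pre > 0)
                cur = np.maximum(pre, 0)
        ph = self.params["head"]
        logits = _conv1x1_forward(cur, ph.W, ph.b)
        cache["head_in"] = cur
        if want_cache:
            return logits, cache
        return logits

    def predict_proba(self, x):
        return softmax(self.forward(x))

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits, cache):
        grads = {}
        d, dW, db = _conv1x1_backward(dlogits, cache["head_in"], self.params["head"].W)
        grads["head"] = (dW, db)

        def back_conv(name, d):
            shape, cols, relu_mask = cache[name]
            d = d * relu_mask
            dx, dW, db = _conv3x3_backward(d, cols, shape, self.params[name].W)
            grads[name] = (dW, db)
            return dx

        for l in range(self.depth):
            d = back_conv(f"dec{l}b", d)
            d = back_conv(f"dec{l}a", d)
            nskip = cache[f"cat{l}"]
            d_skip, d_up = d[..., :nskip], d[..., nskip:]
            d = back_conv(f"up{l}", d_up)
            d = _upsample2_backward(d)
            cache[f"skip_grad{l}"] = d_skip
        d = back_conv("bot_b", d)
        d = back_conv("bot_a", d)
        for l in reversed(range(self.depth)):
            d = _maxpool2_backward(d, cache[f"pool{l}"])
            d = d + cache[f"skip_grad{l}"]
            d = back_conv(f"enc{l}b", d)
            d = back_conv(f"enc{l}a", d)
        return grads

    # -- optimisation ------------------------------------------------------

    def adam_step(self, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for name, (dW, db) in grads.items():
            p = self.params[name]
            for key, g, arr in (("W", dW, p.W), ("b", db, p.b)):
                g = g.astype(arr.dtype)
                mkey = (name, key)
                m, v = self._adam.get(mkey, (np.zeros_like(arr), np.zeros_like(arr)))
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                self._adam[mkey] = (m, v)
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                arr -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_step(self, x, labels, class_weights, lr=1e-3):
        logits, cache = self.forward(x, want_cache=True)
        loss, dlogits = weighted_cross_entropy(logits, labels, class_weights)
        grads = self.backward(dlogits, cache)
        self.adam_step(grads, lr=lr)
        return loss

    # -- persistence -------------------------------------------------------

    def save(self, path):
        meta = dict(
            depth=self.depth,
            base_channels=self.base_channels,
            n_classes=self.n_classes,
            in_channels=self.in_channels,
            seed=self.seed,
        )
        arrays = {}
        for name, p in self.params.items():
            arrays[f"{name}__W"] = p.W
            arrays[f"{name}__b"] = p.b
        np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            net = cls(**meta)
            for name, p in net.params.items():
                p.W = z[f"{name}__W"]
                p.b = z[f"{name}__b"]
        return net
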