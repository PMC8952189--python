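"""A compact NumPy engine for the shallow phase CNNs.

The phase classifiers are small enough (four 3x3 valid-convolution
blocks with 2x2 max-pooling, two fully connected layers, a 2-class
soft-max head) that a vectorized im2col implementation trains them on
one CPU in seconds to minutes at the patch sizes this package uses.
Forward, backward and the Adam update are all plain NumPy on NHWC
tensors, and every source of randomness (weight init, shuffling,
dropout masks) flows from one seeded Generator, so training is
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ShallowCNN", "softmax", "cross_entropy_loss"]

_EPS_LOG = 1e-12


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(truth_onehot: np.ndarray, probs: np.ndarray) -> float:
    """Mean over observations of -sum_i y_i log p_i, with a clamped log.

    ``truth_onehot`` must be one-hot rows; ``probs`` rows must sum to 1
    (within 1e-6).
    """
    y = np.asarray(truth_onehot, dtype=np.float64)
    p = np.asarray(probs, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {y.shape} vs probs {p.shape}")
    if not np.allclose(y.sum(axis=1), 1.0) or not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("truth must be one-hot")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    return float(-(y * np.log(np.clip(p, _EPS_LOG, None))).sum(axis=1).mean())


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid 3x3 convolution, stride 1, NHWC; returns (out, cols cache)."""
    n, h, wd, cin = x.shape
    k = w.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # win: (n, h-k+1, w-k+1, cin, k, k) -> cols (n*oh*ow, k*k*cin)
    oh, ow = h - k + 1, wd - k + 1
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, k * k * cin)
    wm = w.reshape(k * k * cin, -1)
    out = cols @ wm + b
    return out.reshape(n, oh, ow, -1), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, x_shape, w: np.ndarray):
    n, h, wd, cin = x_shape
    k = w.shape[0]
    oh, ow = h - k + 1, wd - k + 1
    cout = dout.shape[-1]
    dflat = dout.reshape(n * oh * ow, cout)
    dw = (cols.T @ dflat).reshape(k, k, cin, cout)
    db = dflat.sum(axis=0)
    dcols = (dflat @ w.reshape(k * k * cin, cout).T).reshape(n, oh, ow, k, k, cin)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    for a in range(k):
        for bb in range(k):
            dx[:, a : a + oh, bb : bb + ow, :] += dcols[:, :, :, a, bb, :]
    return dx, dw, db


def _pool_forward(x: np.ndarray):
    """2x2 max pool, stride 2, floor division (odd trailing row/col dropped)."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : h2 * 2, : w2 * 2, :]
    blocks = xc.reshape(n, h2, 2, w2, 2, c)
    out = blocks.max(axis=(2, 4))
    mask = blocks == out[:, :, None, :, None, :]
    return out, (mask, x.shape)


def _pool_backward(dout: np.ndarray, cache):
    mask, x_shape = cache
    n, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    d = mask * dout[:, :, None, :, None, :]
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : h2 * 2, : w2 * 2, :] = d.reshape(n, h2 * 2, w2 * 2, c)
    return dx


class ShallowCNN:
    """Conv(3x3 valid)+ReLU blocks with 2x2 max-pool, then FC head.

    ``conv_filters`` gives the per-block output channels (one or two
    conv layers per block via ``convs_per_block``); ``fc_widths`` the
    hidden fully connected sizes.  Dropout (inverted scaling) is
    applied after every pooling stage and FC ReLU during training.
    """

    def __init__(
        self,
        input_side: int,
        in_channels: int = 3,
        conv_filters: tuple[int, ...] = (16, 32, 64, 128),
        fc_widths: tuple[int, ...] = (128, 128),
        n_classes: int = 2,
        dropout_rate: float = 0.2,
        convs_per_block: int = 1,
        seed: int = 0,
    ):
        self.input_side = input_side
        self.in_channels = in_channels
        self.conv_filters = tuple(conv_filters)
        self.fc_widths = tuple(fc_widths)
        self.n_classes = n_classes
        self.dropout_rate = float(dropout_rate)
        self.convs_per_block = convs_per_block
        self.seed = seed
        self.rng = np.random.default_rng(seed)

        side = input_side
        cin = in_channels
        self.params: dict[str, np.ndarray] = {}
        self.conv_names: list[str] = []
        idx = 0
        for f in self.conv_filters:
            for _ in range(convs_per_block):
                side = side - 2
                if side < 1:
                    raise ValueError(
                        f"input_side {input_side} too small: conv {idx} leaves side {side}"
                    )
                name = f"conv{idx}"
                fan_in = 9 * cin
                self.params[f"{name}_w"] = self.rng.normal(
                    0.0, np.sqrt(2.0 / fan_in), (3, 3, cin, f)
                )
                self.params[f"{name}_b"] = np.zeros(f)
                self.conv_names.append(name)
                cin = f
                idx += 1
            side = side // 2
            if side < 1:
                raise ValueError(f"input_side {input_side} too small after pooling")
        self.final_side = side
        self.flat_len = side * side * cin
        self.fc_names: list[str] = []
        width_in = self.flat_len
        for i, wdt in enumerate(list(self.fc_widths) + [n_classes]):
            name = f"fc{i}"
            self.params[f"{name}_w"] = self.rng.normal(
                0.0, np.sqrt(2.0 / width_in), (width_in, wdt)
            )
            self.params[f"{name}_b"] = np.zeros(wdt)
            self.fc_names.append(name)
            width_in = wdt

        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Returns (probs, cache).  ``train=True`` activates dropout."""
        cache: list = []
        a = np.asarray(x, dtype=np.float64)
        ci = 0
        for _f in self.conv_filters:
            for _ in range(self.convs_per_block):
                name = self.conv_names[ci]
                out, cols = _conv_forward(a, self.params[f"{name}_w"], self.params[f"{name}_b"])
                relu_mask = out > 0
                out = out * relu_mask
                cache.append(("conv", name, cols, a.shape, relu_mask))
                a = out
                ci += 1
            a, pcache = _pool_forward(a)
            cache.append(("pool", pcache))
            a = self._dropout(a, train, rng, cache)
        a = a.reshape(a.shape[0], -1)
        cache.append(("flatten", None))
        for i, name in enumerate(self.fc_names):
            z = a @ self.params[f"{name}_w"] + self.params[f"{name}_b"]
            if i < len(self.fc_names) - 1:
                relu_mask = z > 0
                z = z * relu_mask
                cache.append(("fc", name, a, relu_mask))
                a = self._dropout(z, train, rng, cache)
            else:
                cache.append(("fc", name, a, None))
                a = z
        probs = softmax(a)
        return probs, cache

    def _dropout(self, a, train, rng, cache):
        if train and self.dropout_rate > 0:
            r = rng if rng is not None else self.rng
            mask = (r.random(a.shape) >= self.dropout_rate) / (1.0 - self.dropout_rate)
            cache.append(("dropout", mask))
            return a * mask
        cache.append(("dropout", None))
        return a

    def backward(self, probs: np.ndarray, y_onehot: np.ndarray, cache: list):
        """Gradients of mean cross-entropy wrt all parameters."""
        n = probs.shape[0]
        grads: dict[str, np.ndarray] = {}
        d = (probs - y_onehot) / n  # softmax + CE fused gradient
        for entry in reversed(cache):
            kind = entry[0]
            if kind == "dropout":
                if entry[1] is not None:
                    d = d * entry[1]
            elif kind == "fc":
                _, name, a_in, relu_mask = entry
                if relu_mask is not None:  # hidden layer: out = relu(z)
                    d = d * relu_mask
                grads[f"{name}_w"] = a_in.T @ d
                grads[f"{name}_b"] = d.sum(axis=0)
                d = d @ self.params[f"{name}_w"].T
            elif kind == "flatten":
                side, c = self.final_side, self.conv_filters[-1]
                d = d.reshape(-1, side, side, c)
            elif kind == "pool":
                d = _pool_backward(d, entry[1])
            elif kind == "conv":
                _, name, cols, x_shape, relu_mask = entry
                d = d * relu_mask
                d, dw, db = _conv_backward(d, cols, x_shape, self.params[f"{name}_w"])
                grads[f"{name}_w"] = dw
                grads[f"{name}_b"] = db
        return grads

    def adam_step(self, grads: dict[str, np.ndarray], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            p, _ = self.forward(x[i : i + batch_size], train=False)
            out.append(p)
        return np.concatenate(out, axis=0)

    def n_weight_params(self) -> int:
        return int(sum(v.size for k, v in self.params.items() if k.endswith("_w")))

    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))
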