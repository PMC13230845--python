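"""Lightweight interaction-map CNN with squeeze-and-excitation attention.

Architecture (for the default 21-channel input):

* Block 1: conv 64 @ 5x5, stride 1, pad 2 -> batch norm -> ReLU -> SE -> 2x2 max pool
* Block 2: conv 128 @ 3x3, stride 1, pad 1 -> batch norm -> ReLU -> SE -> 2x2 max pool
* Block 3: conv 256 @ 3x3, stride 1, pad 1 -> batch norm -> ReLU -> SE
* head: global max pool -> dense 256 -> 128 -> ReLU -> dropout 0.5 -> dense 128 -> 1

The single output is a logit; the binding probability is its logistic
transform.  SE blocks use reduction ratio 8: a global-average "squeeze"
summarizes each channel, a two-layer gating network (C -> C/r -> C, ReLU
then logistic) produces per-channel weights in (0, 1) that rescale the
feature maps.

Every layer implements ``forward`` and ``backward`` by hand on NumPy
arrays (there is no autodiff framework underneath), so the same backward
pass that trains the network also yields input gradients for saliency and
feature-map gradients for Grad-CAM.  Convolution is cross-correlation via
im2col and a single BLAS matmul; col2im in the backward pass is a sum of
k^2 array slices.  The numerics are validated against finite differences
in the test suite.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setup)."""

    in_channels: int = 21
    conv_channels: tuple[int, int, int] = (64, 128, 256)
    kernel_sizes: tuple[int, int, int] = (5, 3, 3)
    paddings: tuple[int, int, int] = (2, 1, 1)
    se_reduction: int = 8
    hidden: int = 128
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        for c in self.conv_channels:
            if c % self.se_reduction != 0:
                raise ValueError(
                    f"se_reduction {self.se_reduction} must divide channel count {c}")

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "conv_channels": list(self.conv_channels),
            "kernel_sizes": list(self.kernel_sizes),
            "paddings": list(self.paddings),
            "se_reduction": self.se_reduction,
            "hidden": self.hidden,
            "dropout": self.dropout,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            in_channels=int(d["in_channels"]),
            conv_channels=tuple(d["conv_channels"]),
            kernel_sizes=tuple(d["kernel_sizes"]),
            paddings=tuple(d["paddings"]),
            se_reduction=int(d["se_reduction"]),
            hidden=int(d.get("hidden", 128)),
            dropout=float(d.get("dropout", 0.5)),
        )


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int,
                     dtype) -> np.ndarray:
    """Fan-based uniform init (the usual framework default for conv/linear)."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    """Base class: parameters live in ``params``; gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def astype(self, dtype) -> None:
        for k in self.params:
            self.params[k] = self.params[k].astype(dtype)


class Conv2d(Layer):
    """Same-padding stride-1 cross-correlation via im2col."""

    def __init__(self, cin: int, cout: int, k: int, pad: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.k, self.pad = k, pad
        fan_in = cin * k * k
        self.params["W"] = _kaiming_uniform(rng, (cout, cin, k, k), fan_in, dtype)
        bound = 1.0 / np.sqrt(fan_in)
        self.params["b"] = rng.uniform(-bound, bound, size=cout).astype(dtype)

    def _im2col(self, xp: np.ndarray, H: int, W: int) -> np.ndarray:
        N, C = xp.shape[:2]
        k = self.k
        cols = np.empty((N, C, k, k, H, W), dtype=xp.dtype)
        for di in range(k):
            for dj in range(k):
                cols[:, :, di, dj] = xp[:, :, di:di + H, dj:dj + W]
        return cols

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = self._im2col(xp, H, W)  # same padding keeps H, W
        self._cols = cols.transpose(0, 4, 5, 1, 2, 3).reshape(N * H * W, -1)
        Wm = self.params["W"].reshape(self.params["W"].shape[0], -1)
        out = self._cols @ Wm.T + self.params["b"]
        self._shape = (N, C, H, W)
        return out.reshape(N, H, W, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        cout = dout.shape[1]
        dmat = dout.transpose(0, 2, 3, 1).reshape(N * H * W, cout)
        Wm = self.params["W"].reshape(cout, -1)
        self.grads["W"] = (dmat.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        dcols = (dmat @ Wm).reshape(N, H, W, C, self.k, self.k)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # N,C,k,k,H,W
        dxp = np.zeros((N, C, H + 2 * self.pad, W + 2 * self.pad),
                       dtype=dout.dtype)
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di:di + H, dj:dj + W] += dcols[:, :, di, dj]
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.astype(np.float64)
            self.running_var = (1 - m) * self.running_var + m * var.astype(np.float64)
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mu[None, :, None, None]) / self._std[None, :, None, None]
            self._train = True
            return g * self._xhat + b
        self._train = False
        rm = self.running_mean.astype(x.dtype)[None, :, None, None]
        rstd = np.sqrt(self.running_var + self.eps).astype(x.dtype)
        self._rstd = rstd
        self._xhat = (x - rm) / rstd[None, :, None, None]
        return g * self._xhat + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = self.params["gamma"]
        if not self._train:
            self.grads["gamma"] = (dout * self._xhat).sum(axis=(0, 2, 3))
            self.grads["beta"] = dout.sum(axis=(0, 2, 3))
            return dout * (g / self._rstd)[None, :, None, None]
        xhat = self._xhat
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g[None, :, None, None]
        mean_d = dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dx = (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return (dxhat - mean_d - xhat * mean_dx) / self._std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class SqueezeExcite(Layer):
    """Channel attention: GAP squeeze, two-layer gate, per-channel rescale."""

    def __init__(self, c: int, r: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if c % r != 0:
            raise ValueError(f"reduction {r} must divide channel count {c}")
        h = c // r
        self.params["W1"] = _kaiming_uniform(rng, (h, c), c, dtype)
        self.params["b1"] = np.zeros(h, dtype=dtype)
        self.params["W2"] = _kaiming_uniform(rng, (c, h), h, dtype)
        self.params["b2"] = np.zeros(c, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x.mean(axis=(2, 3))                       # N,C squeeze
        self._z = z
        a = z @ self.params["W1"].T + self.params["b1"]
        self._relu_mask = a > 0
        h = a * self._relu_mask
        self._h = h
        s = sigmoid(h @ self.params["W2"].T + self.params["b2"])
        self._s = s
        return x * s[:, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, s, h, z = self._x, self._s, self._h, self._z
        dx = dout * s[:, :, None, None]
        ds = (dout * x).sum(axis=(2, 3))
        da2 = ds * s * (1 - s)
        self.grads["W2"] = da2.T @ h
        self.grads["b2"] = da2.sum(axis=0)
        dh = (da2 @ self.params["W2"]) * self._relu_mask
        self.grads["W1"] = dh.T @ z
        self.grads["b1"] = dh.sum(axis=0)
        dz = dh @ self.params["W1"]
        hw = x.shape[2] * x.shape[3]
        dx += dz[:, :, None, None] / hw
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        if H2 < 1 or W2 < 1:
            raise ValueError(f"spatial dims too small for 2x2 pooling: {H}x{W}")
        xt = x[:, :, :H2 * 2, :W2 * 2].reshape(N, C, H2, 2, W2, 2)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H2, W2, 4)
        self._arg = xt.argmax(axis=-1)
        self._shape = (N, C, H, W)
        return np.take_along_axis(xt, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        H2, W2 = H // 2, W // 2
        dwin = np.zeros((N, C, H2, W2, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((N, C, H, W), dtype=dout.dtype)
        dx[:, :, :H2 * 2, :W2 * 2] = dwin.reshape(N, C, H2 * 2, W2 * 2)
        return dx


class GlobalMaxPool(Layer):
    """N,C,H,W -> N,C by spatial max; gradient routes to the arg max."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        flat = x.reshape(N, C, H * W)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        dflat = np.zeros((N, C, H * W), dtype=dout.dtype)
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        return dflat.reshape(self._shape)


class Dense(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.params["W"] = _kaiming_uniform(rng, (fout, fin), fin, dtype)
        bound = 1.0 / np.sqrt(fin)
        self.params["b"] = rng.uniform(-bound, bound, size=fout).astype(dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class InteractionCNN:
    """The full classifier; layers are kept in execution order.

    ``feature_layer_index`` marks the output of the last convolutional
    block (post-SE), which Grad-CAM differentiates against.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 42,
                 dtype=np.float32):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.cfg = cfg
        self.dtype = dtype
        c1, c2, c3 = cfg.conv_channels
        k1, k2, k3 = cfg.kernel_sizes
        p1, p2, p3 = cfg.paddings
        r = cfg.se_reduction
        self.layers: list[Layer] = [
            Conv2d(cfg.in_channels, c1, k1, p1, rng, dtype),
            BatchNorm2d(c1, dtype=dtype), ReLU(), SqueezeExcite(c1, r, rng, dtype),
            MaxPool2(),
            Conv2d(c1, c2, k2, p2, rng, dtype),
            BatchNorm2d(c2, dtype=dtype), ReLU(), SqueezeExcite(c2, r, rng, dtype),
            MaxPool2(),
            Conv2d(c2, c3, k3, p3, rng, dtype),
            BatchNorm2d(c3, dtype=dtype), ReLU(), SqueezeExcite(c3, r, rng, dtype),
            GlobalMaxPool(),
            Dense(c3, cfg.hidden, rng, dtype),
            ReLU(),
            Dropout(cfg.dropout, rng),
            Dense(cfg.hidden, 1, rng, dtype),
        ]
        # index of the layer whose OUTPUT is the last conv feature map
        self.feature_layer_index = len(self.layers) - 6  # last SqueezeExcite

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch (N, C, H, W) -> (N,)."""
        if X.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {X.shape[1]}")
        h = np.ascontiguousarray(X, dtype=self.dtype)
        self._feature_map = None
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, train)
            if i == self.feature_layer_index:
                self._feature_map = h
        return h[:, 0]

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for s in range(0, len(X), batch_size):
            probs.append(sigmoid(self.forward(X[s:s + batch_size], train=False)))
        return np.concatenate(probs) if probs else np.empty(0)

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(logit); returns d(loss)/d(input).

        Also stores ``feature_grad``, the gradient at the last conv block's
        output, for Grad-CAM.
        """
        dout = dlogit[:, None].astype(self.dtype)
        self.feature_grad = None
        for i in reversed(range(len(self.layers))):
            dout = self.layers[i].backward(dout)
            if i == self.feature_layer_index + 1:
                self.feature_grad = dout
        return dout

    @property
    def feature_map(self) -> np.ndarray:
        return self._feature_map

    # -- parameter plumbing -------------------------------------------------

    def named_params(self):
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"layer{i}.{name}", layer, name

    def n_parameters(self) -> int:
        return sum(p.size for _, layer, name in self.named_params()
                   for p in [layer.params[name]])

    def get_state(self) -> dict[str, np.ndarray]:
        state = {key: layer.params[name].copy()
                 for key, layer, name in self.named_params()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.named_params():
            layer.params[name] = state[key].astype(layer.params[name].dtype).copy()
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = state[f"layer{i}.running_mean"].copy()
                layer.running_var = state[f"layer{i}.running_var"].copy()

    def astype(self, dtype) -> "InteractionCNN":
        self.dtype = dtype
        for layer in self.layers:
            layer.astype(dtype)
        return self


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient (stable form)."""
    y = labels.astype(np.float64)
    z = logits.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / len(z)
    return float(loss.mean()), grad


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, model: InteractionCNN, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {key: np.zeros_like(layer.params[name], dtype=np.float64)
                  for key, layer, name in model.named_params()}
        self.v = {key: np.zeros_like(layer.params[name], dtype=np.float64)
                  for key, layer, name in model.named_params()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for key, layer, name in self.model.named_params():
            g = layer.grads[name].astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * layer.params[name]
            m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            layer.params[name] = (layer.params[name] - update).astype(
                layer.params[name].dtype)


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(path, model: InteractionCNN, extra: dict | None = None) -> None:
    """Weights + model config (+ featurizer/length metadata) in one file."""
    meta = {"model_config": model.cfg.to_dict()}
    if extra:
        meta.update(extra)
    state = model.get_state()
    buf = io.BytesIO()
    np.savez(buf, **state)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("state.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[InteractionCNN, dict]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("state.npz") as fh:
            state = dict(np.load(io.BytesIO(fh.read())))
    cfg = ModelConfig.from_dict(meta["model_config"])
    model = InteractionCNN(cfg, rng=0)
    model.set_state(state)
    return model, meta
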