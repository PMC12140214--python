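"""Minimal numpy neural-network layers with manual backprop and Adam.

The default offline backbone is a tiny two-layer convolutional network; the
classification head is always ``linear -> tanh -> softmax`` so pre-softmax
activations are constrained to [-1, 1] and no predicted probability can
reach exactly 0 or 1.

Arrays are NHWC; gradients flow with the 1/batch factor already applied by
the loss, so layer backward passes are pure chain rule.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np


class Param:
    """A trainable tensor with gradient and per-parameter Adam state."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)
        self.step_count = 0

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps

    def step(self, params: list[Param]) -> None:
        for p in params:
            p.step_count += 1
            p.m = self.beta1 * p.m + (1 - self.beta1) * p.grad
            p.v = self.beta2 * p.v + (1 - self.beta2) * p.grad ** 2
            m_hat = p.m / (1 - self.beta1 ** p.step_count)
            v_hat = p.v / (1 - self.beta2 ** p.step_count)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class AvgPool:
    """Non-overlapping average pooling by an integer factor."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.factor == 1:
            return x
        b, h, w, c = x.shape
        f = self.factor
        self._in_shape = x.shape
        return x.reshape(b, h // f, f, w // f, f, c).mean(axis=(2, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.factor == 1:
            return dy
        f = self.factor
        b, h, w, c = self._in_shape
        dx = np.repeat(np.repeat(dy, f, axis=1), f, axis=2) / (f * f)
        return dx

    params: list[Param] = []


class Conv2d:
    """3x3-style convolution via im2col; weight shape (k, k, C_in, C_out)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(k, k, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, pad

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        b, hp, wp, c = xp.shape
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        cols = np.empty((b, oh, ow, k, k, c))
        for dy in range(k):
            for dx in range(k):
                cols[:, :, :, dy, dx, :] = xp[
                    :, dy:dy + s * oh:s, dx:dx + s * ow:s, :
                ]
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        self._cols = self._im2col(x)
        return np.tensordot(self._cols, self.W.value, axes=3) + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        self.W.grad += np.tensordot(self._cols, dy, axes=([0, 1, 2], [0, 1, 2]))
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dcols = np.tensordot(dy, self.W.value, axes=([3], [3]))
        b, h, w, c = self._in_shape
        oh, ow = dy.shape[1], dy.shape[2]
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c))
        for ddy in range(k):
            for ddx in range(k):
                dxp[:, ddy:ddy + s * oh:s, ddx:ddx + s * ow:s, :] += dcols[
                    :, :, :, ddy, ddx, :
                ]
        return dxp[:, p:p + h, p:p + w, :]


class ReLU:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Flatten:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class Linear:
    def __init__(self, in_dim: int, out_dim: int,
                 rng: Optional[np.random.Generator] = None,
                 scale: float = 0.01):
        if rng is None:
            w = np.zeros((in_dim, out_dim))
        else:
            w = rng.normal(0.0, scale, size=(in_dim, out_dim))
        self.W = Param(w)
        self.b = Param(np.zeros(out_dim))

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def softmax(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# backbone and head
# ---------------------------------------------------------------------------


class TinyCNNBackbone:
    """Two 3x3 stride-2 conv layers on a 32x32 working resolution.

    Inputs of size ``input_size`` (a multiple of 32) are first
    average-pooled down to 32x32, so the backbone is resolution-agnostic
    and cheap enough to train on one CPU.
    """

    WORK_SIZE = 32

    def __init__(self, rng: np.random.Generator, input_size: int = 32):
        if input_size % self.WORK_SIZE != 0:
            raise ValueError(
                f"input_size must be a multiple of {self.WORK_SIZE}"
            )
        self.input_size = input_size
        self.layers = [
            AvgPool(input_size // self.WORK_SIZE),
            Conv2d(3, 8, k=3, stride=2, pad=1, rng=rng),
            ReLU(),
            Conv2d(8, 16, k=3, stride=2, pad=1, rng=rng),
            ReLU(),
            Flatten(),
        ]
        self.feature_dim = (self.WORK_SIZE // 4) ** 2 * 16  # 8*8*16 = 1024

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class TanhSoftmaxHead:
    """linear -> tanh -> softmax; one output node per class."""

    def __init__(self, feature_dim: int, n_classes: int,
                 rng: Optional[np.random.Generator] = None):
        if feature_dim < 1 or n_classes < 2:
            raise ValueError("feature_dim >= 1 and n_classes >= 2 required")
        self.linear = Linear(feature_dim, n_classes, rng=rng)
        self.n_classes = n_classes
        self.feature_dim = feature_dim

    @property
    def params(self) -> list[Param]:
        return self.linear.params

    @property
    def n_parameters(self) -> int:
        return self.feature_dim * self.n_classes + self.n_classes

    def forward(self, features: np.ndarray) -> np.ndarray:
        z = self.linear.forward(features)
        self._a = np.tanh(z)
        return softmax(self._a)

    def backward(self, dprob_pre: np.ndarray) -> np.ndarray:
        """Backprop from d(loss)/d(pre-softmax activation) = (p - q)/B."""
        dz = dprob_pre * (1.0 - self._a ** 2)
        return self.linear.backward(dz)


class ClassifierModel:
    """Backbone + tanh-softmax head + class names."""

    def __init__(self, backbone: TinyCNNBackbone, head: TanhSoftmaxHead,
                 class_names: list[str]):
        if head.n_classes != len(class_names):
            raise ValueError("head width must match class_names")
        self.backbone = backbone
        self.head = head
        self.class_names = list(class_names)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.backbone.forward(x))

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(images), batch_size):
            out.append(self.forward(np.asarray(images[i:i + batch_size])))
        return np.concatenate(out, axis=0)

    # -- persistence ----------------------------------------------------

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, p in enumerate(self.backbone.params):
            arrays[f"backbone_{i}"] = p.value
        for i, p in enumerate(self.head.params):
            arrays[f"head_{i}"] = p.value
        np.savez(model_dir / "weights.npz", **arrays)
        meta = {
            "class_names": self.class_names,
            "input_size": self.backbone.input_size,
            "feature_dim": self.head.feature_dim,
        }
        (model_dir / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> "ClassifierModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "meta.json").read_text())
        rng = np.random.default_rng(0)
        backbone = TinyCNNBackbone(rng, input_size=meta["input_size"])
        head = TanhSoftmaxHead(meta["feature_dim"], len(meta["class_names"]), rng)
        model = cls(backbone, head, meta["class_names"])
        with np.load(model_dir / "weights.npz") as data:
            for i, p in enumerate(model.backbone.params):
                p.value[...] = data[f"backbone_{i}"]
            for i, p in enumerate(model.head.params):
                p.value[...] = data[f"head_{i}"]
        return model
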