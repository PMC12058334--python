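"""Minimal 3D convolutional network engine in numpy.

Implements exactly the layer vocabulary needed by the flow-state classifier:
3D convolution (stride 1, symmetric padding), batch normalisation, ReLU,
2x2x2 max pooling, global average pooling and dense layers, together with
softmax / categorical cross-entropy and the Adam optimiser.  Convolutions are
lowered to im2col slice copies plus a single GEMM per sample so the heavy
lifting happens in BLAS.  Everything is deterministic given the
seeded ``numpy.random.Generator`` used for initialisation and shuffling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv3d", "BatchNorm3d", "ReLU", "MaxPool3d",
    "GlobalAvgPool3d", "Flatten", "Linear", "Sequential",
    "softmax", "cross_entropy", "Adam",
]

PROB_FLOOR = 1e-12  # floor on predicted probabilities inside the CE log


class Layer:
    """Base layer: subclasses define forward/backward and expose params/grads."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' padding, He-initialised.

    Input (B, C_in, D, H, W) -> output (B, C_out, D, H, W).  The batch is
    processed sample by sample: the im2col buffer is built with 27 contiguous
    slice copies (fast on strided memory), the convolution itself is one
    GEMM, and the input gradient is scattered back with the transposed GEMM
    plus 27 slice adds (col2im).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = c_in * kernel**3
        self.w = (rng.standard_normal((c_out, c_in, kernel, kernel, kernel))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}

    def _im2col(self, x1: np.ndarray) -> np.ndarray:
        """(C, D, H, W) -> (C*k^3, D*H*W) patch matrix."""
        C, D, H, W = x1.shape
        p, k = self.pad, self.k
        xp = np.pad(x1, ((0, 0), (p, p), (p, p), (p, p)))
        col = np.empty((C, k, k, k, D, H, W), dtype=x1.dtype)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    col[:, dz, dy, dx] = xp[:, dz:dz + D, dy:dy + H, dx:dx + W]
        return col.reshape(C * k**3, D * H * W)

    def _col2im(self, gcol: np.ndarray, shape: tuple) -> np.ndarray:
        """Transpose of _im2col: scatter-add patch gradients back to a volume."""
        C, D, H, W = shape
        p, k = self.pad, self.k
        g = gcol.reshape(C, k, k, k, D, H, W)
        gxp = np.zeros((C, D + 2 * p, H + 2 * p, W + 2 * p), dtype=gcol.dtype)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    gxp[:, dz:dz + D, dy:dy + H, dx:dx + W] += g[:, dz, dy, dx]
        return gxp[:, p:p + D, p:p + H, p:p + W] if p else gxp

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        B, C, D, H, W = x.shape
        wmat = self.w.reshape(self.c_out, -1)
        out = np.empty((B, self.c_out, D, H, W), dtype=x.dtype)
        for i in range(B):
            out[i] = (wmat @ self._im2col(x[i])).reshape(self.c_out, D, H, W)
        return out + self.b[None, :, None, None, None]

    #: set True on the network's first layer: no upstream layer consumes the
    #: input gradient, and skipping col2im there saves most of the step cost.
    skip_input_grad: bool = False

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        x = self._x
        B, C, D, H, W = x.shape
        wmat = self.w.reshape(self.c_out, -1)
        gwmat = np.zeros_like(wmat)
        self.gb[...] = grad.sum(axis=(0, 2, 3, 4))
        gx = None if self.skip_input_grad else np.empty_like(x)
        for i in range(B):
            col = self._im2col(x[i])
            gout = grad[i].reshape(self.c_out, -1)
            gwmat += gout @ col.T
            if gx is not None:
                gx[i] = self._col2im(wmat.T @ gout, (C, D, H, W))
        self.gw[...] = gwmat.reshape(self.gw.shape)
        return gx


class BatchNorm3d(Layer):
    """Per-channel batch normalisation over (batch, D, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros(c, dtype=np.float32)
        self.gbeta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}

    @staticmethod
    def _shape(v):
        return v[None, :, None, None, None]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = x - self._shape(mean.astype(x.dtype))
        xhat *= self._shape(inv)
        if training:
            self._xhat, self._inv, self._n = xhat, inv, x.size // x.shape[1]
        out = xhat * self._shape(self.gamma)
        out += self._shape(self.beta)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # operates in place on ``grad`` to limit full-size temporaries
        axes = (0, 2, 3, 4)
        xhat, inv, n = self._xhat, self._inv, self._n
        self.ggamma[...] = np.einsum("bczyx,bczyx->c", grad, xhat)
        self.gbeta[...] = grad.sum(axis=axes)
        grad *= self._shape(self.gamma)
        mean_g = grad.sum(axis=axes) / n
        mean_gx = np.einsum("bczyx,bczyx->c", grad, xhat) / n
        xhat *= self._shape(mean_gx.astype(grad.dtype))
        grad -= xhat
        grad -= self._shape(mean_g.astype(grad.dtype))
        grad *= self._shape(inv)
        return grad


class ReLU(Layer):
    """Rectifier, applied in place (its input is never reused upstream)."""

    def forward(self, x, training):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0, out=x)

    def backward(self, grad):
        grad *= self._mask
        return grad


class MaxPool3d(Layer):
    """2x2x2 max pooling; ties share the gradient equally."""

    def __init__(self, size: int = 2):
        self.s = size

    def forward(self, x, training):
        s = self.s
        B, C, D, H, W = x.shape
        if D % s or H % s or W % s:
            raise ValueError(f"spatial dims {(D, H, W)} not divisible by pool size {s}")
        xr = x.reshape(B, C, D // s, s, H // s, s, W // s, s)
        out = xr.max(axis=(3, 5, 7))
        self._xr, self._out = xr, out
        return out

    def backward(self, grad):
        xr, out = self._xr, self._out
        mask = xr == out[:, :, :, None, :, None, :, None]
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        g = mask * (grad[:, :, :, None, :, None, :, None] / counts)
        B, C = xr.shape[:2]
        s = self.s
        return g.reshape(B, C, xr.shape[2] * s, xr.shape[4] * s, xr.shape[6] * s)


class GlobalAvgPool3d(Layer):
    def forward(self, x, training):
        self._shape_in = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, grad):
        B, C, D, H, W = self._shape_in
        return np.broadcast_to(
            grad[:, :, None, None, None] / (D * H * W), self._shape_in
        ).astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x, training):
        self._shape_in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape_in)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def named_params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out[f"{i}.{name}"] = p
        return out

    def named_grads(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, g in layer.grads().items():
                out[f"{i}.{name}"] = g
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax; accepts a vector or a (B, n) batch."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(truth: np.ndarray, probs: np.ndarray) -> float:
    """Categorical cross-entropy L = -sum_i t_i log p_i.

    ``truth`` is one-hot and ``probs`` a probability vector; batched inputs
    (B, n) return the mean loss.  Probabilities are floored at 1e-12 inside
    the log for numerical safety.
    """
    t = np.atleast_2d(np.asarray(truth, dtype=np.float64))
    p = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {t.shape} vs probs {p.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-3):
        raise ValueError("probs rows must sum to 1")
    losses = -(t * np.log(np.maximum(p, PROB_FLOOR))).sum(axis=1)
    return float(losses.mean())


def cross_entropy_grad(truth: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Analytic gradient of cross_entropy w.r.t. probs: -t_i / max(p_i, floor)."""
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(probs, dtype=np.float64)
    g = -t / np.maximum(p, PROB_FLOOR)
    g[(p < PROB_FLOOR) & (t == 0)] = 0.0
    return g


class Adam:
    """Adam optimiser over a model's named parameters."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.named_params().items()}
        self.v = {k: np.zeros_like(v) for k, v in model.named_params().items()}

    def step(self):
        self.t += 1
        params = self.model.named_params()
        grads = self.model.named_grads()
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
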