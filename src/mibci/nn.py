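"""Minimal feed-forward network machinery for the EEG window classifiers.

Implements exactly the layer set the two CNN families need — a full-channel
spatial convolution, dense (all-feature) and depthwise temporal convolutions,
batch normalization, ELU, average pooling, dropout and a softmax readout —
plus Adam and accuracy-based early stopping. Parameters are float32 (training casts inputs to match); layer gradients
are verified against finite differences in the test suite.

Conventions: inputs are ``(N, F, T)`` (batch, feature maps, time). Temporal
convolutions use 'same' zero padding so pooling arithmetic stays simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; empty for stateless layers."""
        return []


class SpatialConv(Layer):
    """Learned spatial filter: kernel spans ALL input channels (extent C×1).

    Maps (N, C, T) → (N, F, T) by ``y[n,f,t] = Σ_c W[f,c] x[n,c,t] + b[f]`` —
    each output map is a fixed linear combination of the electrodes, i.e. a
    virtual channel re-referencing/mixing the montage.
    """

    def __init__(self, in_ch: int, out_f: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_ch)
        self.W = (rng.standard_normal((out_f, in_ch)) * scale).astype(np.float32)
        self.b = np.zeros(out_f, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        self._x = x
        return np.einsum("fc,nct->nft", self.W, x) + self.b[None, :, None]

    def backward(self, grad):
        self.dW = np.einsum("nft,nct->fc", grad, self._x)
        self.db = grad.sum(axis=(0, 2))
        return np.einsum("fc,nft->nct", self.W, grad, optimize=True)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class TemporalConv(Layer):
    """Temporal convolution across all feature maps, 'same' zero padding.

    Kernel (G, F, k): each output map pools every input map over a k-sample
    window — temporal extent k, spatial (map) extent F.
    """

    def __init__(self, in_f: int, out_f: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_f * k))
        self.W = (rng.standard_normal((out_f, in_f, k)) * scale).astype(np.float32)
        self.b = np.zeros(out_f, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k

    def _pad(self, x):
        k = self.k
        return np.pad(x, ((0, 0), (0, 0), (k // 2, k - 1 - k // 2)))

    def forward(self, x, train, rng):
        n, f, t = x.shape
        xp = self._pad(x)
        # im2col: (N, T, F, k) view, flattened for one GEMM
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        # cols: (N, F, T, k) -> (N*T, F*k)
        self._cols = cols.transpose(0, 2, 1, 3).reshape(n * t, f * self.k)
        g = self.W.shape[0]
        y = self._cols @ self.W.reshape(g, f * self.k).T + self.b
        self._shape = (n, f, t)
        return y.reshape(n, t, g).transpose(0, 2, 1)

    def backward(self, grad):
        n, f, t = self._shape
        g = self.W.shape[0]
        gy = grad.transpose(0, 2, 1).reshape(n * t, g)
        self.dW = (gy.T @ self._cols).reshape(self.W.shape)
        self.db = gy.sum(axis=0)
        k = self.k
        dxp = np.zeros((n, f, t + k - 1), dtype=grad.dtype)
        # scatter grad back through each kernel tap (k is small)
        for j in range(k):
            dxp[:, :, j : j + t] += np.einsum(
                "ngt,gf->nft", grad, self.W[:, :, j], optimize=True
            )
        lo = k // 2
        return dxp[:, :, lo : lo + t]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class DepthwiseTemporalConv(Layer):
    """Per-channel temporal filters: spatial extent 1 (no channel mixing).

    Kernel (C, m, k): channel c produces m output maps from its own samples
    only; output is (N, C*m, T). This is the layer-1 contrast to
    :class:`SpatialConv` — it cannot form cross-channel combinations.
    """

    def __init__(self, in_ch: int, mult: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / k)
        self.W = (rng.standard_normal((in_ch, mult, k)) * scale).astype(np.float32)
        self.b = np.zeros(in_ch * mult, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k

    def forward(self, x, train, rng):
        n, c, t = x.shape
        k = self.k
        xp = np.pad(x, ((0, 0), (0, 0), (k // 2, k - 1 - k // 2)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N,C,T,k)
        self._cols = cols
        self._shape = (n, c, t)
        y = np.einsum("nctk,cmk->ncmt", cols, self.W)
        m = self.W.shape[1]
        return y.reshape(n, c * m, t) + self.b[None, :, None]

    def backward(self, grad):
        n, c, t = self._shape
        m = self.W.shape[1]
        g = grad.reshape(n, c, m, t)
        self.dW = np.einsum("nctk,ncmt->cmk", self._cols, g)
        self.db = grad.sum(axis=(0, 2))
        k = self.k
        dxp = np.zeros((n, c, t + k - 1), dtype=grad.dtype)
        for j in range(k):
            dxp[:, :, j : j + t] += np.einsum("ncmt,cm->nct", g, self.W[:, :, j])
        lo = k // 2
        return dxp[:, :, lo : lo + t]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm(Layer):
    """Per-feature-map normalization over (batch, time)."""

    def __init__(self, n_f: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_f, dtype=np.float32)
        self.beta = np.zeros(n_f, dtype=np.float32)
        self.dgamma = np.zeros(n_f)
        self.dbeta = np.zeros(n_f)
        self.running_mean = np.zeros(n_f, dtype=np.float32)
        self.running_var = np.ones(n_f, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train, rng):
        if train:
            mean = x.mean(axis=(0, 2), dtype=x.dtype)
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        self._train = train
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad):
        self.dgamma = (grad * self._xhat).sum(axis=(0, 2))
        self.dbeta = grad.sum(axis=(0, 2))
        gs = self.gamma[None, :, None] / self._std[None, :, None]
        if not self._train:
            return grad * gs
        n = grad.shape[0] * grad.shape[2]
        gh = grad * self.gamma[None, :, None]
        mean_gh = gh.mean(axis=(0, 2))[None, :, None]
        mean_ghx = (gh * self._xhat).mean(axis=(0, 2))[None, :, None]
        return (gh - mean_gh - self._xhat * mean_ghx) / self._std[None, :, None]

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train, rng):
        self._neg = x < 0
        self._expm = np.where(self._neg, np.exp(np.minimum(x, 0.0)), 1.0)
        return np.where(self._neg, self.alpha * (self._expm - 1.0), x)

    def backward(self, grad):
        return grad * np.where(self._neg, self.alpha * self._expm, 1.0)


class Square(Layer):
    """x → x²; after a band-forming convolution this yields instantaneous
    band power, the quantity ERD/ERS modulates."""

    def forward(self, x, train, rng):
        self._x = x
        return x * x

    def backward(self, grad):
        return 2.0 * self._x * grad


class Log(Layer):
    """Safe log for power features (compresses the heavy-tailed power scale)."""

    def __init__(self, floor: float = 1e-6):
        self.floor = floor

    def forward(self, x, train, rng):
        self._x = np.maximum(x, self.floor)
        self._clipped = x < self.floor
        return np.log(self._x)

    def backward(self, grad):
        return np.where(self._clipped, 0.0, grad / self._x)


class AvgPool(Layer):
    """Non-overlapping temporal average pooling; trailing remainder dropped."""

    def __init__(self, p: int):
        self.p = p

    def forward(self, x, train, rng):
        n, f, t = x.shape
        tt = (t // self.p) * self.p
        self._t_in = t
        return x[:, :, :tt].reshape(n, f, tt // self.p, self.p).mean(axis=-1)

    def backward(self, grad):
        n, f, to = grad.shape
        out = np.zeros((n, f, self._t_in), dtype=grad.dtype)
        out[:, :, : to * self.p] = np.repeat(grad / self.p, self.p, axis=-1)
        return out


class Dropout(Layer):
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    return float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())


class Adam:
    def __init__(self, lr: float = 1e-3, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(params):
            m, v = self.state.get(i, (np.zeros_like(p), np.zeros_like(p)))
            m = self.b1 * m + (1 - self.b1) * g
            v = self.b2 * v + (1 - self.b2) * g * g
            self.state[i] = (m, v)
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


@dataclass
class FitResult:
    history: list[float] = field(default_factory=list)  # per-epoch val accuracy
    best_epoch: int = -1
    best_val_acc: float = 0.0
    stopped_epoch: int = -1


class Network:
    """A plain layer stack with softmax cross-entropy readout."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        rng = np.random.default_rng(0)  # unused in eval mode
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, len(x), batch):
            out.append(softmax(self.forward(x[i : i + batch], False, rng)))
        return np.concatenate(out) if out else np.empty((0, 0))

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p, _ in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for (p, _), s in zip(ps, state[: len(ps)]):
            p[...] = s
        rest = iter(state[len(ps) :])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(rest)
                layer.running_var[...] = next(rest)

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        batch_size: int = 64,
        max_epochs: int = 200,
        patience: int = 20,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> FitResult:
        """Mini-batch Adam with accuracy-based early stopping.

        Stops after ``max_epochs`` or once validation accuracy has not
        improved for ``patience`` consecutive epochs; the parameters of the
        best validation epoch are restored before returning.
        """
        rng = np.random.default_rng(seed)
        # single-precision is ample for SGD and roughly halves BLAS time
        x_train = np.asarray(x_train, dtype=np.float32)
        x_val = np.asarray(x_val, dtype=np.float32)
        opt = Adam(lr=lr)
        res = FitResult()
        best_state = self.get_state()
        since_best = 0
        n = len(x_train)
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                logits = self.forward(x_train[idx], True, rng)
                probs = softmax(logits)
                grad = probs.copy()
                grad[np.arange(len(idx)), y_train[idx]] -= 1.0
                grad /= len(idx)
                self.backward(grad)
                opt.step(self.params())
            val_probs = self.predict_proba(x_val)
            val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
            res.history.append(val_acc)
            if val_acc > res.best_val_acc:
                res.best_val_acc = val_acc
                res.best_epoch = epoch
                best_state = self.get_state()
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        res.stopped_epoch = len(res.history) - 1
        self.set_state(best_state)
        return res
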