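"""Minimal CPU neural-network engine for 1-D fully convolutional models.

Layers operate on arrays of shape ``(batch, channels, length)`` in float32
and implement explicit forward/backward passes; gradients are accumulated
into ``d<param>`` attributes.  The set of operations is exactly what the
segmentation network needs: stride-1 convolution, ELU, batch
normalization, width-2 max-pooling with edge-replication padding for odd
lengths, nearest-neighbour upsampling, right-cropping, segment mean
pooling, and a fused softmax + masked cross-entropy head.  Adam is the
only optimizer.

Every layer caches what its backward pass needs during forward; a layer
instance therefore appears exactly once in a network graph.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class; trainable layers override ``param_names``."""

    param_names: tuple[str, ...] = ()

    def params(self):
        return [(self, n) for n in self.param_names]

    def zero_grad(self):
        for n in self.param_names:
            setattr(self, "d" + n, np.zeros_like(getattr(self, n)))


class Conv1d(Layer):
    """Stride-1 cross-correlation with explicit (left, right) zero padding.

    ``pad=None`` keeps the input length: symmetric for odd kernels, one
    left zero for kernel 2.
    """

    param_names = ("W", "b")

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, pad: tuple[int, int] | None = None):
        fan_in = in_channels * kernel
        fan_out = out_channels * kernel
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, (out_channels, in_channels, kernel)).astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        if pad is None:
            pad = ((kernel - 1) // 2, kernel // 2) if kernel % 2 else (kernel - 1, 0)
        self.pad = pad
        self.kernel = kernel
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        pl, pr = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        self._xp = xp
        L_out = xp.shape[-1] - self.kernel + 1
        y = np.empty((x.shape[0], self.W.shape[0], L_out), dtype=DTYPE)
        y[:] = self.b[:, None]
        for j in range(self.kernel):
            y += np.matmul(self.W[:, :, j], xp[:, :, j : j + L_out])
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        L_out = dy.shape[-1]
        self.db += dy.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        for j in range(self.kernel):
            self.dW[:, :, j] += np.einsum("bol,bil->oi", dy, xp[:, :, j : j + L_out])
            dxp[:, :, j : j + L_out] += np.matmul(self.W[:, :, j].T, dy)
        pl, pr = self.pad
        return dxp[:, :, pl : dxp.shape[-1] - pr] if (pl or pr) else dxp


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._x, self._y = x, y
        return y.astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * np.where(self._x > 0, 1.0, self._y + self.alpha).astype(DTYPE)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    param_names = ("gamma", "beta")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.eps, self.momentum = eps, momentum
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv_std[:, None]
        self._xhat, self._inv_std, self._train = xhat.astype(DTYPE), inv_std.astype(DTYPE), train
        return self.gamma[:, None] * self._xhat + self.beta[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.dgamma += (dy * xhat).sum(axis=(0, 2))
        self.dbeta += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[:, None]
        if not self._train:
            return dxhat * inv_std[:, None]
        n = dy.shape[0] * dy.shape[2]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[:, None] / n) * (n * dxhat - s1 - xhat * s2)


class MaxPool2(Layer):
    """Width-2, stride-2 max pooling; odd lengths are right-padded by edge
    replication before pooling (the padded sample routes its gradient back
    to the true last sample)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._L = L = x.shape[-1]
        if L % 2:
            x = np.concatenate([x, x[:, :, -1:]], axis=-1)
        v = x.reshape(*x.shape[:2], -1, 2)
        self._idx = v.argmax(axis=-1)
        return np.take_along_axis(v, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, T = dy.shape
        dv = np.zeros((B, C, T, 2), dtype=DTYPE)
        np.put_along_axis(dv, self._idx[..., None], dy[..., None], axis=-1)
        dxp = dv.reshape(B, C, 2 * T)
        if self._L % 2:
            dx = dxp[:, :, : self._L].copy()
            dx[:, :, -1] += dxp[:, :, self._L]
            return dx
        return dxp


class UpsampleNearest2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, 2, axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy[:, :, 0::2] + dy[:, :, 1::2]


class CropRight(Layer):
    """Crop the temporal axis to a target length (decoder/skip alignment)."""

    def forward(self, x: np.ndarray, length: int) -> np.ndarray:
        self._orig = x.shape[-1]
        return x[:, :, :length]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        deficit = self._orig - dy.shape[-1]
        if deficit:
            return np.pad(dy, ((0, 0), (0, 0), (0, deficit)))
        return dy


class SegmentMeanPool(Layer):
    """Mean over non-overlapping windows of width i (kernel i, stride i)."""

    def forward(self, x: np.ndarray, i: int) -> np.ndarray:
        B, C, L = x.shape
        if L % i:
            raise ValueError(f"length {L} is not a multiple of the segment width {i}")
        self._i = i
        return x.reshape(B, C, L // i, i).mean(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy / self._i, self._i, axis=-1)


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax_xent(logits: np.ndarray, labels: np.ndarray, mask_code: int):
    """Fused softmax + cross-entropy with label masking.

    Parameters
    ----------
    logits : (B, K, T) pre-softmax segment scores.
    labels : (B, T) integer stage codes; positions equal to ``mask_code``
        contribute neither to the loss value nor to the gradient.

    Returns
    -------
    loss : float — mean negative log-likelihood over unmasked positions
        (0.0 when everything is masked).
    dlogits : (B, K, T) gradient of the mean loss w.r.t. the logits.
    """
    B, K, T = logits.shape
    p = softmax(logits.astype(np.float64), axis=1)
    valid = labels != mask_code
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(logits)
    safe = np.where(valid, labels, 0)
    picked = np.take_along_axis(p, safe[:, None, :], axis=1)[:, 0, :]
    loss = -np.log(np.maximum(picked[valid], 1e-12)).mean()
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, safe[:, None, :], 1.0, axis=1)
    d = (p - onehot) * valid[:, None, :] / n_valid
    return float(loss), d.astype(DTYPE)


class Adam:
    """Adam over a list of (layer, attribute-name) parameter handles."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.handles = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(l, n)) for l, n in self.handles]
        self.v = [np.zeros_like(getattr(l, n)) for l, n in self.handles]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, (layer, name) in enumerate(self.handles):
            g = getattr(layer, "d" + name)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.lr / bc1) * self.m[k] / (np.sqrt(self.v[k] / bc2) + self.eps)
            setattr(layer, name, getattr(layer, name) - update.astype(DTYPE))

    def zero_grad(self):
        for layer, name in self.handles:
            setattr(layer, "d" + name, np.zeros_like(getattr(layer, name)))
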