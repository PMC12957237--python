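"""Minimal NumPy neural-network core for the attention classifier.

Implements exactly the layers the sandwich-CBAM architectures need —
2D convolution (same padding), the two CBAM attention blocks, max
pooling, dense layers, dropout — with hand-written backward passes and
an Adam optimizer. Everything is float64 and deterministic given the
seeds supplied at build/training time; evaluation-mode forward passes
involve no randomness.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "Conv2D", "ReLU", "FilterAttention", "SpatialAttention", "MaxPool2D",
    "Flatten", "Dense", "Dropout", "Network", "Adam",
    "softmax", "softmax_cross_entropy",
]


def _he_uniform(rng, shape, fan_in):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    name = "layer"

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init_params(self, rng):  # pragma: no cover - stateless layers
        pass

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _im2col(xp, kh, kw, out_h, out_w):
    b, c = xp.shape[:2]
    cols = np.empty((b, c, kh, kw, out_h, out_w), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + out_h, j:j + out_w]
    return cols.reshape(b, c * kh * kw, out_h * out_w)


def _col2im(dcols, b, c, h, w, kh, kw, ph, pw):
    dxp = np.zeros((b, c, h + 2 * ph, w + 2 * pw), dtype=dcols.dtype)
    d = dcols.reshape(b, c, kh, kw, h, w)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + h, j:j + w] += d[:, :, i, j]
    return dxp[:, :, ph:ph + h, pw:pw + w]


class Conv2D(Layer):
    """2D convolution with stride 1 and 'same' zero padding."""

    def __init__(self, in_channels, out_channels, kernel, name="conv"):
        super().__init__()
        kh, kw = kernel
        if kh < 1 or kw < 1 or kh % 2 == 0 or kw % 2 == 0:
            raise InvalidArgumentError("kernel dims must be odd and >= 1")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kh, self.kw = kh, kw
        self.name = name

    def init_params(self, rng):
        fan_in = self.in_channels * self.kh * self.kw
        self.params["W"] = _he_uniform(
            rng, (self.out_channels, self.in_channels, self.kh, self.kw), fan_in)
        self.params["b"] = np.zeros(self.out_channels)

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols = _im2col(xp, self.kh, self.kw, h, w)
        wm = self.params["W"].reshape(self.out_channels, -1)
        y = np.einsum("of,bfp->bop", wm, cols) + self.params["b"][None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(b, self.out_channels, h, w)

    def backward(self, dy):
        cols, (b, c, h, w) = self._cache
        dyf = dy.reshape(b, self.out_channels, h * w)
        wm = self.params["W"].reshape(self.out_channels, -1)
        self.grads["W"] = np.einsum("bop,bfp->of", dyf, cols).reshape(
            self.params["W"].shape)
        self.grads["b"] = dyf.sum(axis=(0, 2))
        dcols = np.einsum("of,bop->bfp", wm, dyf)
        return _col2im(dcols, b, c, h, w, self.kh, self.kw,
                       self.kh // 2, self.kw // 2)


class ReLU(Layer):
    name = "relu"

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class FilterAttention(Layer):
    """CBAM channel ('filter') attention.

    A 1D attention map over the F filter maps: global average pooling and
    max pooling over the spatial plane each pass through a shared
    two-layer MLP (F -> F/r -> F, ReLU hidden), the two outputs are
    summed and squashed with a sigmoid, and the input is rescaled
    filter-wise. The reduction ratio r must divide F.
    """

    def __init__(self, n_filters, reduction_ratio=16, name="filter_attention"):
        super().__init__()
        if n_filters % reduction_ratio != 0:
            raise InvalidArgumentError(
                f"reduction ratio {reduction_ratio} does not divide "
                f"filter count {n_filters}"
            )
        self.n_filters = n_filters
        self.reduction_ratio = reduction_ratio
        self.hidden_width = n_filters // reduction_ratio
        self.name = name

    def init_params(self, rng):
        f, h = self.n_filters, self.hidden_width
        self.params["W0"] = _he_uniform(rng, (h, f), f)
        self.params["b0"] = np.zeros(h)
        self.params["W1"] = _he_uniform(rng, (f, h), h)
        self.params["b1"] = np.zeros(f)

    def _mlp_forward(self, v):
        h_pre = v @ self.params["W0"].T + self.params["b0"]
        h = np.maximum(h_pre, 0.0)
        return (h_pre, h, h @ self.params["W1"].T + self.params["b1"])

    def forward(self, x, train=False):
        b, f, hh, ww = x.shape
        gap = x.mean(axis=(2, 3))
        flat = x.reshape(b, f, hh * ww)
        argmax = flat.argmax(axis=2)
        mp = np.take_along_axis(flat, argmax[:, :, None], axis=2)[:, :, 0]
        br_g = self._mlp_forward(gap)
        br_m = self._mlp_forward(mp)
        a = 1.0 / (1.0 + np.exp(-(br_g[2] + br_m[2])))
        self._cache = (x, gap, mp, br_g, br_m, a, argmax)
        return x * a[:, :, None, None]

    def attention_map(self, x):
        """Evaluation helper: the (B, F) filter attention map for x."""
        self.forward(x)
        return self._cache[5]

    def _mlp_backward(self, ds, v, h_pre, h):
        dW1 = ds.T @ h
        db1 = ds.sum(axis=0)
        dh = (ds @ self.params["W1"]) * (h_pre > 0)
        dW0 = dh.T @ v
        db0 = dh.sum(axis=0)
        dv = dh @ self.params["W0"]
        return dv, dW0, db0, dW1, db1

    def backward(self, dy):
        x, gap, mp, br_g, br_m, a, argmax = self._cache
        b, f, hh, ww = x.shape
        da = (dy * x).sum(axis=(2, 3))
        dx = dy * a[:, :, None, None]
        ds = da * a * (1.0 - a)  # sigmoid'; shared by both MLP branches
        dgap, dW0g, db0g, dW1g, db1g = self._mlp_backward(ds, gap, br_g[0], br_g[1])
        dmp, dW0m, db0m, dW1m, db1m = self._mlp_backward(ds, mp, br_m[0], br_m[1])
        self.grads["W0"] = dW0g + dW0m
        self.grads["b0"] = db0g + db0m
        self.grads["W1"] = dW1g + dW1m
        self.grads["b1"] = db1g + db1m
        dx += dgap[:, :, None, None] / (hh * ww)
        dflat = np.zeros((b, f, hh * ww))
        np.put_along_axis(dflat, argmax[:, :, None], dmp[:, :, None], axis=2)
        dx += dflat.reshape(b, f, hh, ww)
        return dx


class SpatialAttention(Layer):
    """CBAM spatial attention over the component x rhythm plane.

    Average- and max-pooling across the filter axis are concatenated into
    a 2-channel descriptor, convolved with a single 3x3 kernel to one 2D
    map, and squashed with a sigmoid; the input is rescaled pointwise.
    """

    def __init__(self, kernel=(3, 3), name="spatial_attention"):
        super().__init__()
        self.conv = Conv2D(2, 1, kernel, name=name + "_conv")
        self.name = name

    def init_params(self, rng):
        self.conv.init_params(rng)
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x, train=False):
        b, f, hh, ww = x.shape
        avg = x.mean(axis=1)
        argmax = x.argmax(axis=1)
        mx = np.take_along_axis(x, argmax[:, None], axis=1)[:, 0]
        pooled = np.stack([avg, mx], axis=1)
        s = self.conv.forward(pooled, train=train)[:, 0]
        a = 1.0 / (1.0 + np.exp(-s))
        self._cache = (x, a, argmax)
        return x * a[:, None, :, :]

    def attention_map(self, x):
        """Evaluation helper: the (B, H, W) spatial attention map for x."""
        self.forward(x)
        return self._cache[1]

    def backward(self, dy):
        x, a, argmax = self._cache
        b, f, hh, ww = x.shape
        da = (dy * x).sum(axis=1)
        dx = dy * a[:, None, :, :]
        ds = da * a * (1.0 - a)
        dpooled = self.conv.backward(ds[:, None])
        self.grads = self.conv.grads
        dx += dpooled[:, 0][:, None] / f  # average-pool branch
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, argmax[:, None], dpooled[:, 1][:, None], axis=1)
        return dx + dmax


class MaxPool2D(Layer):
    name = "maxpool"

    def __init__(self, pool=(2, 2)):
        super().__init__()
        self.ph, self.pw = pool

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        oh, ow = h // self.ph, w // self.pw
        xt = x[:, :, :oh * self.ph, :ow * self.pw].reshape(
            b, c, oh, self.ph, ow, self.pw)
        y = xt.max(axis=(3, 5))
        self._cache = (x.shape, xt == y[:, :, :, None, :, None])
        return y

    def backward(self, dy):
        shape, mask = self._cache
        b, c, h, w = shape
        oh, ow = mask.shape[2], mask.shape[4]
        # split gradient among ties (ties are measure-zero for real data)
        counts = mask.sum(axis=(3, 5), keepdims=True)
        d = mask * (dy[:, :, :, None, :, None] / counts)
        dx = np.zeros(shape, dtype=dy.dtype)
        dx[:, :, :oh * self.ph, :ow * self.pw] = d.reshape(
            b, c, oh * self.ph, ow * self.pw)
        return dx


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, name="dense"):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.name = name

    def init_params(self, rng):
        self.params["W"] = _he_uniform(
            rng, (self.out_features, self.in_features), self.in_features)
        self.params["b"] = np.zeros(self.out_features)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"]


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    name = "dropout"

    def __init__(self, rate=0.3, rng=None):
        super().__init__()
        if not 0 <= rate < 1:
            raise InvalidArgumentError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(rng)

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Network:
    """Plain sequential container with softmax classification head."""

    def __init__(self, layers, input_shape):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape)

    def init_params(self, seed):
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init_params(rng)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def predict_proba(self, x):
        return softmax(self.forward(x, train=False))

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for key, value in layer.params.items():
                yield f"{li}:{layer.name}:{key}", layer, key

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def summary(self):
        """Layer-by-layer (name, output shape, parameter count) table."""
        x = np.zeros((1,) + self.input_shape)
        rows = []
        for layer in self.layers:
            x = layer.forward(x, train=False)
            rows.append({
                "layer": layer.name,
                "output_shape": tuple(x.shape[1:]),
                "n_params": layer.n_params(),
            })
        return rows


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, network: Network, learning_rate=0.001,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = network
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {pid: np.zeros_like(layer.params[key])
                  for pid, layer, key in network.parameters()}
        self.v = {pid: np.zeros_like(layer.params[key])
                  for pid, layer, key in network.parameters()}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for pid, layer, key in self.net.parameters():
            g = layer.grads.get(key)
            if g is None:
                continue
            self.m[pid] = self.beta1 * self.m[pid] + (1 - self.beta1) * g
            self.v[pid] = self.beta2 * self.v[pid] + (1 - self.beta2) * g * g
            m_hat = self.m[pid] / b1t
            v_hat = self.v[pid] / b2t
            layer.params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
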