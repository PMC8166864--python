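"""A small, self-contained convolutional network engine (numpy).

The engine implements exactly what the classifier needs and nothing
more: channels-last 2-D convolution (im2col), ReLU, max/average pooling,
dense layers, inverted dropout, a softmax cross-entropy head with L2
weight decay, and Adam.  All randomness flows through an explicit
``numpy.random.Generator``, so a seed fully determines initial weights,
dropout masks and batch order.

Layers are named (``conv1``, ``dense2``, ...) so intermediate
activations can be pulled out for feature-map inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: forward/backward over (N, H, W, C) or (N, F) arrays."""

    name: str = ""
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3-style convolution, stride 1, 'same' zero padding, He init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, name: str):
        super().__init__()
        self.name = name
        self.kernel = kernel
        fan_in = kernel * kernel * in_ch
        # weight rows follow the natural im2col window order (C, kr, kc)
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (kernel * kernel * in_ch, out_ch)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self.in_ch, self.out_ch = in_ch, out_ch

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
        return win.reshape(x.shape[0], x.shape[1], x.shape[2], x.shape[3] * k * k)

    def forward(self, x, train, rng):
        self._x_shape = x.shape
        cols = self._im2col(np.ascontiguousarray(x))
        self._cols = cols
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dy, need_dx=True):
        n, h, w, _ = dy.shape
        cols2d = self._cols.reshape(-1, self._cols.shape[-1])
        dy2d = np.ascontiguousarray(dy, dtype=np.float32).reshape(-1, self.out_ch)
        self.grads["W"] = cols2d.T @ dy2d
        self.grads["b"] = dy2d.sum(axis=0)
        if not need_dx:
            return None
        dcols = (dy2d @ self.params["W"].T).reshape(
            n, h, w, self.in_ch, self.kernel, self.kernel
        )
        k, p = self.kernel, self.kernel // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.in_ch), dtype=np.float32)
        for dr in range(k):
            for dc in range(k):
                dxp[:, dr : dr + h, dc : dc + w] += dcols[:, :, :, :, dr, dc]
        return dxp[:, p : p + h, p : p + w, :]


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        super().__init__()
        self.name = name

    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy, need_dx=True):
        return dy * self._mask if need_dx else None


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (trailing row/col dropped if odd)."""

    def __init__(self, name: str = "pool"):
        super().__init__()
        self.name = name

    def forward(self, x, train, rng):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._full_shape = x.shape
        x = x[:, : 2 * h2, : 2 * w2, :]
        self._x_shape = x.shape
        xr = x.reshape(n, h2, 2, w2, 2, c)
        self._xr = xr
        out = xr.max(axis=(2, 4))
        self._out = out
        return out

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        mask = self._xr == self._out[:, :, None, :, None, :]
        dyb = (dy[:, :, None, :, None, :] * mask).reshape(self._x_shape)
        if self._x_shape != self._full_shape:
            dx = np.zeros(self._full_shape)
            dx[:, : self._x_shape[1], : self._x_shape[2], :] = dyb
            return dx
        return dyb


class AvgPool(Layer):
    """k x k average pooling, stride k — used as a downsampling stem."""

    def __init__(self, k: int, name: str = "avgpool"):
        super().__init__()
        self.name = name
        self.k = k

    def forward(self, x, train, rng):
        k = self.k
        n, h, w, c = x.shape
        h2, w2 = h // k, w // k
        self._in_shape = x.shape
        xr = x[:, : h2 * k, : w2 * k, :].reshape(n, h2, k, w2, k, c)
        return xr.mean(axis=(2, 4))

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        k = self.k
        _, h, w, _ = self._in_shape
        h2, w2 = h // k, w // k
        dx = np.zeros(self._in_shape)
        dx[:, : h2 * k, : w2 * k, :] = np.repeat(np.repeat(dy, k, axis=1), k, axis=2) / (k * k)
        return dx


class Center(Layer):
    """Subtract a fixed offset (input centering; parameter-free)."""

    def __init__(self, offset: float, name: str = "center"):
        super().__init__()
        self.name = name
        self.offset = offset

    def forward(self, x, train, rng):
        return x - self.offset

    def backward(self, dy, need_dx=True):
        return dy if need_dx else None


class InstanceNorm(Layer):
    """Per-image, per-channel standardisation over the spatial axes.

    Parameter-free contrast normalisation: (x - mean) / (std + eps).
    Placed at the input it cancels global brightness scaling exactly,
    which matches the augmentation model (one multiplicative factor per
    image).
    """

    def __init__(self, eps: float = 1e-6, name: str = "instancenorm"):
        super().__init__()
        self.name = name
        self.eps = eps

    def forward(self, x, train, rng):
        mu = x.mean(axis=(1, 2), keepdims=True)
        sd = x.std(axis=(1, 2), keepdims=True)
        self._sd = sd
        self._xhat = (x - mu) / (sd + self.eps)
        return self._xhat

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        n_px = dy.shape[1] * dy.shape[2]
        xhat, sd = self._xhat, self._sd
        dmean = dy.mean(axis=(1, 2), keepdims=True)
        dvar = (dy * xhat).mean(axis=(1, 2), keepdims=True)
        return (dy - dmean - xhat * dvar * (sd / (sd + self.eps))) / (sd + self.eps)


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        super().__init__()
        self.name = name

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy, need_dx=True):
        return dy.reshape(self._shape) if need_dx else None


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str):
        super().__init__()
        self.name = name
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy, need_dx=True):
        dy = np.asarray(dy, dtype=np.float32)
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T if need_dx else None


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, name: str = "dropout"):
        super().__init__()
        self.name = name
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        return dy if self._mask is None else dy * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


@dataclass
class Network:
    """A sequential network with a softmax cross-entropy head."""

    layers: list[Layer]
    n_classes: int
    l2_weight: float = 0.0
    _adam_state: dict = field(default_factory=dict, repr=False)

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng(0)
        x = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out) if out else np.empty((0, self.n_classes))

    def activations(self, x: np.ndarray, layer_name: str) -> np.ndarray:
        """Forward pass returning the output of the named layer."""
        names = [layer.name for layer in self.layers]
        if layer_name not in names:
            raise KeyError(f"no layer named {layer_name!r}; layers: {names}")
        for layer in self.layers:
            x = layer.forward(x, False, np.random.default_rng(0))
            if layer.name == layer_name:
                return x
        raise AssertionError("unreachable")

    # -- training ----------------------------------------------------------

    def _loss_and_backward(self, x, y_onehot, rng) -> float:
        logits = self.forward(x, train=True, rng=rng)
        probs = softmax(logits)
        n = len(x)
        loss = -np.sum(y_onehot * np.log(np.clip(probs, 1e-12, None))) / n
        if self.l2_weight:
            loss += self.l2_weight * sum(
                float(np.sum(l.params["W"] ** 2)) for l in self.layers if "W" in l.params
            )
        dy = (probs - y_onehot) / n
        # gradients are not needed below the first trainable layer
        first_trainable = next(
            (i for i, l in enumerate(self.layers) if l.params), len(self.layers)
        )
        for i in range(len(self.layers) - 1, -1, -1):
            dy = self.layers[i].backward(dy, need_dx=i > first_trainable)
            if dy is None:
                break
        if self.l2_weight:
            for layer in self.layers:
                if "W" in layer.params:
                    layer.grads["W"] += 2 * self.l2_weight * layer.params["W"]
        return float(loss)

    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        st = self._adam_state
        st["t"] = st.get("t", 0) + 1
        t = st["t"]
        for li, layer in enumerate(self.layers):
            for key, p in layer.params.items():
                g = layer.grads[key]
                mk, vk = f"m{li}{key}", f"v{li}{key}"
                st[mk] = beta1 * st.get(mk, 0.0) + (1 - beta1) * g
                st[vk] = beta2 * st.get(vk, 0.0) + (1 - beta2) * g**2
                mhat = st[mk] / (1 - beta1**t)
                vhat = st[vk] / (1 - beta2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        rng: np.random.Generator,
        augment_fn=None,
        verbose: bool = False,
    ) -> list[float]:
        """Mini-batch Adam training; returns per-epoch mean losses.

        ``augment_fn(batch, rng) -> batch`` is applied to training
        batches only (online augmentation, fresh draws every epoch).
        """
        n = len(x)
        y_onehot = np.eye(self.n_classes)[y]
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb = x[idx]
                if augment_fn is not None:
                    xb = augment_fn(xb, rng)
                losses.append(self._loss_and_backward(xb, y_onehot[idx], rng))
                self._adam_step(learning_rate)
            history.append(float(np.mean(losses)))
        return history

    # -- persistence -------------------------------------------------------

    def save_weights(self, path) -> None:
        arrays = {}
        for li, layer in enumerate(self.layers):
            for key, p in layer.params.items():
                arrays[f"{li}:{layer.name}:{key}"] = p
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for li, layer in enumerate(self.layers):
                for key in layer.params:
                    tag = f"{li}:{layer.name}:{key}"
                    if tag not in data:
                        raise KeyError(f"weight file lacks parameter {tag}")
                    if data[tag].shape != layer.params[key].shape:
                        raise ValueError(
                            f"shape mismatch for {tag}: file {data[tag].shape}, "
                            f"model {layer.params[key].shape}"
                        )
                    layer.params[key] = data[tag]
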