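"""A compact, deterministic CNN toolkit on numpy.

Layers cache their forward inputs and implement explicit backward passes, so
gradients with respect to intermediate activations are available — which is
what gradient-weighted class-activation mapping needs.  Everything is seeded
through ``numpy.random.Generator``, making training runs bit-reproducible on
one CPU.

Image tensors are ``(B, C, H, W)`` float32.  Convolutions are 3x3, stride 1,
zero-padded ('same'); spatial reduction is done by pooling layers.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: optional parameters, cached forward state, backward pass."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 same-padding convolution, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k = k
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.params["W"] = rng.normal(0.0, scale, size=(out_ch, in_ch, k, k)).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        self._xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        B, _, H, W = x.shape
        Wt = self.params["W"]
        y = np.zeros((B, Wt.shape[0], H, W), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                y += np.einsum(
                    "oc,bchw->bohw", Wt[:, :, di, dj], self._xp[:, :, di : di + H, dj : dj + W],
                    optimize=True,
                )
        y += self.params["b"][None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        B, _, H, W = dy.shape
        Wt = self.params["W"]
        dW = np.zeros_like(Wt)
        dxp = np.zeros_like(self._xp)
        for di in range(k):
            for dj in range(k):
                xs = self._xp[:, :, di : di + H, dj : dj + W]
                dW[:, :, di, dj] = np.einsum("bohw,bchw->oc", dy, xs, optimize=True)
                dxp[:, :, di : di + H, dj : dj + W] += np.einsum(
                    "oc,bohw->bchw", Wt[:, :, di, dj], dy, optimize=True
                )
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        p = k // 2
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool2d(Layer):
    """Non-overlapping k x k average pooling (trailing rows/cols dropped)."""

    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        B, C, H, W = x.shape
        Ho, Wo = H // k, W // k
        self._in_shape = x.shape
        xr = x[:, :, : Ho * k, : Wo * k].reshape(B, C, Ho, k, Wo, k)
        return xr.mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        B, C, H, W = self._in_shape
        Ho, Wo = H // k, W // k
        dx = np.zeros(self._in_shape, dtype=np.float32)
        expanded = np.repeat(np.repeat(dy, k, axis=2), k, axis=3) / (k * k)
        dx[:, :, : Ho * k, : Wo * k] = expanded
        return dx


class MaxPool2d(Layer):
    """Non-overlapping k x k max pooling (trailing rows/cols dropped)."""

    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        B, C, H, W = x.shape
        Ho, Wo = H // k, W // k
        self._in_shape = x.shape
        xr = x[:, :, : Ho * k, : Wo * k].reshape(B, C, Ho, k, Wo, k)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, k * k)
        self._arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        B, C, H, W = self._in_shape
        Ho, Wo = H // k, W // k
        dflat = np.zeros((B, C, Ho, Wo, k * k), dtype=np.float32)
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, : Ho * k, : Wo * k] = (
            dflat.reshape(B, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho * k, Wo * k)
        )
        return dx


class Flatten(Layer):
    """(B, C, H, W) -> (B, C*H*W), preserving spatial layout for the head."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        return np.broadcast_to(dy[:, :, None, None], self._in_shape).copy() / (H * W)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_dim)
        self.params["W"] = rng.normal(0.0, scale, size=(in_dim, out_dim)).astype(np.float32)
        self.params["b"] = np.zeros(out_dim, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def forward_collect(self, x: np.ndarray) -> list[np.ndarray]:
        """Forward pass returning every layer's output (for activation maps)."""
        outs = []
        for layer in self.layers:
            x = layer.forward(x)
            outs.append(x)
        return outs

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.backward_to(dy, -1)

    def backward_to(self, dy: np.ndarray, stop_index: int) -> np.ndarray:
        """Backpropagate down to (exclusive) layer ``stop_index``.

        With ``stop_index = -1`` this is a full backward pass returning the
        input gradient; with ``stop_index = i >= 0`` it returns the gradient
        with respect to layer ``i``'s *output*.
        """
        if stop_index < -1:
            stop_index += len(self.layers)
        for idx in range(len(self.layers) - 1, stop_index, -1):
            dy = self.layers[idx].backward(dy)
        return dy

    def parameters(self) -> list[tuple[str, Layer, str]]:
        out = []
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                for name, sub, key in layer.parameters():
                    out.append((f"{i}.{name}", sub, key))
            else:
                for key in layer.params:
                    out.append((f"{i}.{key}", layer, key))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: layer.params[key].copy() for name, layer, key in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.parameters():
            layer.params[key] = state[name].astype(np.float32).copy()


class Adam:
    """Adaptive-moment optimizer over a Sequential's parameters."""

    def __init__(self, model: Sequential, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {name: np.zeros_like(layer.params[key]) for name, layer, key in model.parameters()}
        self._v = {name: np.zeros_like(layer.params[key]) for name, layer, key in model.parameters()}

    def step(self) -> None:
        self.t += 1
        for name, layer, key in self.model.parameters():
            g = layer.grads.get(key)
            if g is None:
                continue
            m = self._m[name] = self.b1 * self._m[name] + (1 - self.b1) * g
            v = self._v[name] = self.b2 * self._v[name] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def focal_loss_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    gamma: float = 0.0,
    class_weights: np.ndarray | None = None,
    floor: float = 1e-7,
) -> tuple[float, np.ndarray]:
    """Mean focal loss over a batch and its gradient w.r.t. the logits.

    With ``p`` the softmax probability of the true class, each sample
    contributes ``-w (1-p)^gamma log p``; the analytic gradient is chained
    through the softmax.  Returns ``(loss, dlogits)``.
    """
    B, L = logits.shape
    y = softmax(logits.astype(np.float64))
    idx = np.arange(B)
    p = y[idx, labels]
    pc = np.clip(p, floor, 1.0)
    w = np.ones(B) if class_weights is None else np.asarray(class_weights, dtype=float)[labels]
    one_minus = 1.0 - pc
    loss = float(np.mean(-w * one_minus**gamma * np.log(pc)))
    # dL/dp for one sample (using the floored p), then dp/dz = p*(e_c - y)
    if gamma == 0.0:
        dLdp = -w / pc
    else:
        dLdp = -w * (one_minus**gamma / pc - gamma * one_minus ** (gamma - 1.0) * np.log(pc))
    ec = np.zeros_like(y)
    ec[idx, labels] = 1.0
    dlogits = (dLdp * p)[:, None] * (ec - y) / B
    return loss, dlogits.astype(np.float32)
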