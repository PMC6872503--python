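"""Sequential container, Adam optimizer, and classification losses."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad, need_input_grad=False):
        for i in range(len(self.layers) - 1, -1, -1):
            need = need_input_grad or i > 0
            grad = self.layers[i].backward(grad, need_input_grad=need)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (p, _), s in zip(self.params(), state):
            p[...] = s


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def bce_logits_grad(logits: np.ndarray, targets: np.ndarray):
    """Mean sigmoid binary cross-entropy and gradient w.r.t. logits.

    ``logits`` and ``targets`` are flat arrays; numerically stable log1p form.
    """
    z = logits.ravel()
    t = targets.ravel()
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = (sig - t) / z.size
    return loss, grad.reshape(logits.shape)
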