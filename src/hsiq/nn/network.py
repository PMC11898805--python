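"""Sequential container, losses, and the Adam optimiser."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads:
                g[...] = 0.0

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for layer in self.layers:
            pairs.extend(zip(layer.params, layer.grads))
        return pairs


class SoftmaxCrossEntropy:
    """Cross-entropy on logits with integer class labels."""

    def loss_and_grad(self, logits: np.ndarray, labels: np.ndarray):
        z = logits - logits.max(axis=1, keepdims=True)
        log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        n = logits.shape[0]
        loss = -log_probs[np.arange(n), labels].mean()
        probs = np.exp(log_probs)
        grad = probs
        grad[np.arange(n), labels] -= 1.0
        return loss, grad / n

    @staticmethod
    def probabilities(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


class MSELoss:
    def loss_and_grad(self, pred: np.ndarray, target: np.ndarray):
        target = target.reshape(pred.shape)
        diff = pred - target
        loss = float(np.mean(diff**2))
        return loss, 2.0 * diff / diff.size


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, (p, g) in enumerate(self.params):
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
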