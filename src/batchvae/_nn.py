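"""Minimal feed-forward neural-network kernel: dense layers, SELU/ReLU,
softmax cross-entropy, and Adam, all in NumPy with hand-written backprop.

Everything here is deterministic given a ``numpy.random.Generator`` for
initialisation; forward/backward passes consume no randomness. Gradients
are accumulated on the layers (``gW``, ``gb``) and applied by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np

# SELU constants (self-normalising networks)
_SELU_LAMBDA = 1.0507009873554804934193349852946
_SELU_ALPHA = 1.6732632423543772848170429916717

LOGVAR_MIN, LOGVAR_MAX = -20.0, 20.0
EPS_PROB = 1e-12  # clamp for log-probabilities


class Dense:
    """Affine layer ``y = x W + b`` with LeCun-normal init (SELU-friendly)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ gy
        self.gb += gy.sum(axis=0)
        return gy @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]


class SELU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        neg = np.minimum(x, 0.0)  # keep exp off the positive branch
        return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * np.expm1(neg))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        neg = np.minimum(x, 0.0)
        return gy * _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(neg))

    params: list = []
    grads: list = []


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.maximum(x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * (self._x > 0)

    params: list = []
    grads: list = []


class MLP:
    """A stack of layers with shared forward/backward plumbing."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


def dense_stack(sizes, rng, hidden_act=SELU, final_act=None) -> MLP:
    """Build Dense layers for consecutive ``sizes`` with ``hidden_act``
    between them and an optional activation after the last layer."""
    layers = []
    for i in range(len(sizes) - 1):
        layers.append(Dense(sizes[i], sizes[i + 1], rng))
        if i < len(sizes) - 2:
            layers.append(hidden_act())
    if final_act is not None:
        layers.append(final_act())
    return MLP(layers)


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def nll_from_logits(logits: np.ndarray, labels: np.ndarray):
    """Mean negative log-likelihood of integer ``labels`` under softmax
    ``logits``; returns ``(nll, grad_wrt_logits, probs)``.

    Probabilities are clamped at ``EPS_PROB`` before the log so a saturated
    softmax cannot produce infinities.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    p_true = np.clip(probs[np.arange(n), labels], EPS_PROB, None)
    nll = -np.log(p_true).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return nll, grad, probs


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clip_global_norm(grads, max_norm: float) -> None:
    """Rescale a list of gradient arrays in place so their joint L2 norm is
    at most ``max_norm`` (no-op when already within)."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale


def clamp_logvar(logvar: np.ndarray):
    """Clip log-variances to a numerically safe range; returns the clipped
    array and the pass-through gradient mask."""
    mask = (logvar > LOGVAR_MIN) & (logvar < LOGVAR_MAX)
    return np.clip(logvar, LOGVAR_MIN, LOGVAR_MAX), mask
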