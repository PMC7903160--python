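"""Neural-network building blocks on top of the autodiff engine.

Layers hold :class:`~unlearn.autodiff.Tensor` parameters; modules expose
``parameters()`` so that optimisers can be scoped to a parameter partition —
the mechanism the iterative unlearning scheme relies on to update the feature
extractor, label predictor and domain classifier independently.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, maxpool2d

__all__ = ["Dense", "Conv2d", "Sequential", "MLPHead", "Adam"]


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense:
    """Fully connected layer, optionally followed by a ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu: bool = False):
        self.weight = Tensor(_he_init(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)
        self.relu = relu

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight + self.bias
        return out.relu() if self.relu else out

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Conv2d:
    """3x3 (default) stride-1 convolution with same padding, optional ReLU/pool."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        relu: bool = True,
        pool: bool = False,
    ):
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(
            _he_init(rng, (c_out, c_in, kernel, kernel), fan_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.pad = kernel // 2
        self.relu = relu
        self.pool = pool

    def __call__(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.bias, pad=self.pad)
        if self.relu:
            out = out.relu()
        if self.pool:
            out = maxpool2d(out)
        return out

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


class MLPHead(Sequential):
    """Two-layer fully connected head (the domain/confound classifier shape)."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        super().__init__(Dense(n_in, n_hidden, rng, relu=True), Dense(n_hidden, n_out, rng))


class SGD:
    """Plain gradient descent scoped to one parameter group.

    Used by default for the confusion stage: its steps shrink with the
    gradient as the domain classifier approaches uniformity, annealing the
    adversarial game instead of stepping at constant size the way adaptive
    optimisers do."""

    def __init__(self, params: list, lr: float = 1e-2, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad
                if self.weight_decay:
                    # decoupled decay: fixed shrink per step
                    p.data *= 1.0 - self.weight_decay


class Adam:
    """Adam optimiser scoped to one parameter group."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
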