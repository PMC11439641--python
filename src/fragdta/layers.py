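"""Neural building blocks: dense layers, GIN message passing, Adam.

Parameters are plain :class:`~fragdta.autograd.Tensor` objects with
``requires_grad=True``; every module exposes ``params()`` so optimizers and
checkpoints can enumerate them in a stable order.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, gather_rows, matmul, relu, scatter_sum

_ACTIVATIONS = {"relu": relu, "identity": lambda t: t}


def get_activation(name: str):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; known: {sorted(_ACTIVATIONS)}")


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    def params(self) -> list[Tensor]:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.params()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.params()
        if len(arrays) != len(own):
            raise ValueError(f"expected {len(own)} arrays, got {len(arrays)}")
        for p, a in zip(own, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32, copy=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.W) + self.b

    def params(self):
        return [self.W, self.b]


class MLP(Module):
    """Fully connected stack; activation between layers, linear final layer."""

    def __init__(self, sizes: list[int], rng: np.random.Generator, activation: str = "relu"):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.act = get_activation(activation)
        self.sizes = list(sizes)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = self.act(layer(x))
        return self.layers[-1](x)

    def params(self):
        return [p for l in self.layers for p in l.params()]


class GINLayer(Module):
    """One graph isomorphism network update.

    h'_v = MLP((1 + eps) * h_v + sum_{u in N(v)} h_u); the sum aggregator is a
    segment scatter over the directed edge list.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, epsilon: float = 0.0):
        self.mlp = MLP([n_in, n_out, n_out], rng)
        self.epsilon = float(epsilon)

    def __call__(self, h: Tensor, src: np.ndarray, dst: np.ndarray) -> Tensor:
        n = h.shape[0]
        if len(src):
            agg = scatter_sum(gather_rows(h, src), dst, n)
            z = h * (1.0 + self.epsilon) + agg
        else:
            z = h * (1.0 + self.epsilon)
        return self.mlp(z)

    def params(self):
        return self.mlp.params()


class Bilinear(Module):
    """Bilinear score T(h, H) = h^T W H for (node, graph) discriminator pairs."""

    def __init__(self, n_left: int, n_right: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, (n_left, n_right)), requires_grad=True)

    def __call__(self, H: Tensor, G: Tensor) -> Tensor:
        """All-pairs scores: H (N, d_n), G (B, d_g) -> (N, B)."""
        return matmul(matmul(H, self.W), G.transpose())

    def params(self):
        return [self.W]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
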