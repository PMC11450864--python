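"""Neural layers used by the response-prediction model.

Layers are thin modules over :mod:`dgdrp.autograd`: fully connected stacks,
a dense single-head graph attention layer, top-k graph pooling, the
straight-through top-k gene gate, and an Adam optimizer. Graphs here are
small (tens of nodes), so attention is computed densely over an adjacency
mask; batching is over cell lines sharing one drug's graph.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd
from .autograd import Tensor, astensor, gather_rows, masked_softmax


class Module:
    """Minimal parameter container with recursive discovery."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch on parameters: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for parameter {name}")
            p.data = np.array(state[name], dtype=autograd.DTYPE)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Fully connected stack with ReLU between layers (linear output)."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 final_activation: bool = False):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_activation:
                x = x.relu()
        return x


class GATLayer(Module):
    """Single-head graph attention over a dense adjacency mask.

    Input ``h`` has shape (B, n, in_dim); ``adj`` is an (n, n) or (B, n, n)
    boolean mask that must include self-loops. Attention coefficients are
    leaky-ReLU additive scores normalized over each node's neighborhood;
    the aggregated output passes through an ELU.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 negative_slope: float = 0.2):
        self.W = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.a_src = Tensor(_glorot(rng, out_dim, 1), requires_grad=True)
        self.a_dst = Tensor(_glorot(rng, out_dim, 1), requires_grad=True)
        self.negative_slope = negative_slope

    def __call__(self, h: Tensor, adj: np.ndarray) -> Tensor:
        wh = h @ self.W                                   # (B, n, d)
        s_src = wh @ self.a_src                           # (B, n, 1)
        s_dst = wh @ self.a_dst                           # (B, n, 1)
        scores = (s_src + s_dst.swapaxes(-1, -2)).leaky_relu(self.negative_slope)
        att = masked_softmax(scores, adj, axis=-1)        # (B, n, n)
        return (att @ wh).elu()


class TopKPool(Module):
    """Top-k graph pooling (projection-score node selection).

    Nodes are scored by a learned projection; the top ``ceil(ratio * n)``
    nodes survive, their features scaled by tanh(score) so the selection
    receives gradient. Returns pooled features, the induced adjacency and
    the kept indices. Ties break toward the lower node index; kept nodes
    stay in original order.
    """

    def __init__(self, dim: int, rng: np.random.Generator, ratio: float = 0.5):
        if not 0 < ratio <= 1:
            raise ValueError("pooling ratio must be in (0, 1]")
        self.p = Tensor(_glorot(rng, dim, 1), requires_grad=True)
        self.ratio = ratio

    def __call__(self, h: Tensor, adj: np.ndarray):
        B, n, _ = h.shape
        norm = ((self.p * self.p).sum() + 1e-12) ** 0.5
        score = (h @ self.p) / norm                        # (B, n, 1)
        score2 = score.reshape(B, n)
        k = max(1, math.ceil(self.ratio * n))
        order = np.argsort(-score2.data, axis=1, kind="stable")[:, :k]
        idx = np.sort(order, axis=1)                       # keep node order
        h_sel = gather_rows(h, idx)                        # (B, k, d)
        gate = gather_rows(score, idx).tanh()              # (B, k, 1)
        pooled = h_sel * gate
        if adj.ndim == 2:
            adj = np.broadcast_to(adj, (B, n, n))
        b = np.arange(B)[:, None, None]
        adj_sel = adj[b, idx[:, :, None], idx[:, None, :]]
        return pooled, adj_sel, idx


def topk_gate(expression: Tensor, scores: Tensor, k: int,
              mode: str = "straight_through") -> tuple[Tensor, np.ndarray]:
    """Select the top-k scoring genes and mask the expression vector.

    ``expression`` and ``scores`` have shape (B, g). The hard mask puts 1 at
    the k highest scores per row (ties to the lower gene index) and 0
    elsewhere. Gating modes:

    - ``hard``: forward and backward use the hard mask; score gradients are 0.
    - ``straight_through``: hard mask forward; the backward pass treats the
      mask as if it were the score vector, so every gene's score receives
      the gradient of its (masked) expression contribution.
    - ``soft_topk``: selected entries are additionally weighted by the
      softmax-normalized scores (fully differentiable through the weights).

    Returns the masked expression and the hard mask as an int array.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    x, s = astensor(expression), astensor(scores)
    if x.shape != s.shape:
        raise ValueError(f"expression {x.shape} and scores {s.shape} differ")
    g = x.shape[-1]
    if k > g:
        raise ValueError(f"k={k} exceeds gene count {g}")
    order = np.argsort(-s.data, axis=-1, kind="stable")[..., :k]
    mask = np.zeros_like(s.data)
    np.put_along_axis(mask, order, 1.0, axis=-1)

    if mode == "soft_topk":
        shifted = s - Tensor(s.data.max(axis=-1, keepdims=True))
        e = shifted.exp()
        soft = e / e.sum(axis=-1, keepdims=True)
        masked = x * Tensor(mask) * soft * float(g)
        return masked, mask.astype(int)
    if mode not in ("hard", "straight_through"):
        raise ValueError(f"unknown gating mode {mode!r}")

    out_data = x.data * mask

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * mask)
        if s.requires_grad and mode == "straight_through":
            s._accumulate(grad * x.data)

    masked = Tensor._from_op(out_data, (x, s), backward)
    return masked, mask.astype(int)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
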