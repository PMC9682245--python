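"""Neural-network building blocks on top of :mod:`ehrformer.nn.autograd`."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Dropout",
    "GRUCell",
    "MLP",
]


class Module:
    """Container with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            for sub, p in _collect_named(value):
                out[f"{name}{sub}"] = p
        return out

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for value in vars(self).values():
            for m in _collect_modules(value):
                m.training = training
                m._set_mode(training)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_named(value, prefix=""):
    if isinstance(value, Tensor) and value.requires_grad:
        yield prefix, value
    elif isinstance(value, Module):
        for name, p in value.named_parameters().items():
            yield f"{prefix}.{name}", p
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _collect_named(v, f"{prefix}.{i}")


def _collect_modules(value):
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.weight = Tensor(
            (rng.standard_normal((num_embeddings, dim)) * 0.02).astype(dtype),
            requires_grad=True,
        )

    def __call__(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids)
        if ids.min(initial=0) < 0 or (ids.size and ids.max() >= self.weight.data.shape[0]):
            raise IndexError("token id outside the embedding table")
        return self.weight[ids]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.eps) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Randomness comes from the
    generator handed in at construction so runs are reproducible."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        u = self.rng.random(x.shape, dtype=np.float32)
        mask = (u < keep).astype(x.dtype) / keep
        return x * mask


class MLP(Module):
    """Fully-connected stack with tanh hidden activations."""

    def __init__(self, widths: list[int], rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.layers = [Linear(a, b, rng, dtype) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.tanh()
        return x


class GRUCell(Module):
    """Standard gated recurrent unit update."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.hidden_size = hidden_size
        self.x2g = Linear(input_size, 3 * hidden_size, rng, dtype)
        self.h2g = Linear(hidden_size, 3 * hidden_size, rng, dtype)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden_size
        gx = self.x2g(x)
        gh = self.h2g(h)
        z = (gx[..., :H] + gh[..., :H]).sigmoid()
        r = (gx[..., H:2 * H] + gh[..., H:2 * H]).sigmoid()
        n = (gx[..., 2 * H:] + r * gh[..., 2 * H:]).tanh()
        return (1.0 - z) * n + z * h


def stack_time(tensors: list[Tensor]) -> Tensor:
    """Stack per-step (B, H) tensors into (B, T, H)."""
    expanded = [t.reshape(t.shape[0], 1, t.shape[1]) for t in tensors]
    return concatenate(expanded, axis=1)
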