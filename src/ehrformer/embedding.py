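"""Joint event embedding: value/time projection + id lookup + sinusoids.

Each token's embedding is the elementwise sum of three components:

1. a single (linear) fully-connected projection of ``[time, value features]``,
2. a lookup embedding of the integer variable id,
3. a parameter-free sinusoidal encoding of the dense-rank position.

Special tokens (the static slot and task tokens) receive a zero positional
component: their temporality is carried entirely by the time feature.  The
static slot's embedding is produced by a separate fully-connected network
over the static vector and is substituted in by the encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Linear, MLP, Module, Tensor
from .nn.layers import Embedding as LookupEmbedding


@dataclass
class EmbeddingConfig:
    hidden: int = 128
    vocab_size: int = 0
    static_width: int = 0
    static_hidden: list = field(default_factory=lambda: [64])
    discrete_only: bool = False
    dtype: type = np.float32

    def __post_init__(self):
        if self.hidden % 2 != 0:
            raise ValueError("hidden size must be even for sin/cos pairing")


def sinusoidal_encoding(positions, d: int, dtype=np.float64) -> np.ndarray:
    """Standard interleaved sin/cos positional table rows.

    ``PE[p, 2i] = sin(p / 10000^(2i/d))`` and ``PE[p, 2i+1]`` the matching
    cosine.  Accepts a scalar or an integer array; positions must be >= 0.
    """
    pos = np.asarray(positions)
    scalar = pos.ndim == 0
    pos = np.atleast_1d(pos).astype(np.float64)
    if (pos < 0).any():
        raise ValueError("positions must be non-negative")
    i = np.arange(d // 2, dtype=np.float64)
    freqs = np.power(10000.0, -2.0 * i / d)
    angles = pos[:, None] * freqs[None, :]
    enc = np.zeros((pos.size, d))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    enc = enc.astype(dtype)
    return enc[0] if scalar else enc


class TokenEmbedder(Module):
    """Sum of value-FC, id-lookup, and positional components.

    With ``discrete_only`` the nine value-derived features are omitted from
    the fully-connected input (elapsed time is retained), reproducing the
    discrete-code-only model variant.
    """

    def __init__(self, config: EmbeddingConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        n_cont = 1 if config.discrete_only else 10  # time (+ 9 value features)
        self.value_fc = Linear(n_cont, config.hidden, rng, config.dtype)
        self.id_embedding = LookupEmbedding(config.vocab_size, config.hidden,
                                            rng, config.dtype)
        self.n_continuous = n_cont

    def __call__(self, tokens: np.ndarray, special_mask: np.ndarray) -> Tensor:
        """tokens: (B, L, 12) -> embeddings (B, L, d)."""
        cont = tokens[..., 2:3] if self.config.discrete_only else tokens[..., 2:12]
        cont = np.ascontiguousarray(cont, dtype=self.config.dtype)
        ids = tokens[..., 1].astype(np.int64)
        positions = tokens[..., 0].astype(np.int64)
        value_part = self.value_fc(Tensor(cont))
        id_part = self.id_embedding(ids)
        pos = sinusoidal_encoding(positions.reshape(-1), self.config.hidden,
                                  self.config.dtype).reshape(*positions.shape, -1)
        pos = pos * (~special_mask[..., None])  # specials: no positional part
        return value_part + id_part + Tensor(pos)


class StaticEncoder(Module):
    """Fully-connected network mapping the static vector to the hidden size."""

    def __init__(self, config: EmbeddingConfig, rng: np.random.Generator):
        super().__init__()
        widths = [config.static_width, *config.static_hidden, config.hidden]
        self.net = MLP(widths, rng, config.dtype)
        self.width = config.static_width
        self.dtype = config.dtype

    def __call__(self, static: np.ndarray) -> Tensor:
        if static.shape[-1] != self.width:
            raise ValueError(f"static vector width {static.shape[-1]} != "
                             f"fitted width {self.width}")
        return self.net(Tensor(np.ascontiguousarray(static, dtype=self.dtype)))
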