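"""Sliding-window / global-attention transformer encoder with per-task heads.

Non-global tokens attend within a fixed-width window around their sequence
index plus all global tokens; global tokens (the static slot and the task
tokens) attend to every non-padding position.  Each prediction head reads
the concatenation of its task token's representation from every encoder
layer.  Attention is computed densely under a boolean mask, which is exact
at the sequence lengths this package targets; a banded kernel would be an
optimization, not a behavioral change.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field

import numpy as np

from .embedding import EmbeddingConfig, StaticEncoder, TokenEmbedder
from .nn import Dropout, LayerNorm, Linear, Module, Tensor, concatenate
from .sequence import Batch

NEG_INF = -1.0e9


@dataclass
class ModelConfig:
    layers: int = 8
    hidden: int = 128
    feedforward: int = 512
    heads: int = 8
    window: int = 128        # total width; half on each side
    dropout: float = 0.1
    n_tasks: int = 7
    vocab_size: int = 0
    static_width: int = 0
    static_hidden: list = field(default_factory=lambda: [64])
    discrete_only: bool = False
    ln_eps: float = 1e-5
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.hidden % self.heads != 0:
            raise ValueError("hidden size must be divisible by the head count")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64


def attention_bias(window: int, global_mask: np.ndarray,
                   pad_mask: np.ndarray, dtype=np.float32) -> np.ndarray:
    """Additive (B, 1, L, L) bias encoding the sliding-window + global
    pattern: 0 where attention is allowed, a large negative constant where
    masked.  Padding positions are excluded as both queries and keys."""
    B, L = pad_mask.shape
    idx = np.arange(L)
    band = np.abs(idx[:, None] - idx[None, :]) <= window // 2
    allowed = np.broadcast_to(band, (B, L, L)).copy()
    allowed |= global_mask[:, :, None]   # global queries see everything
    allowed |= global_mask[:, None, :]   # everyone sees global keys
    allowed &= pad_mask[:, None, :]
    allowed &= pad_mask[:, :, None]
    bias = np.where(allowed, 0.0, NEG_INF).astype(dtype)
    return bias[:, None, :, :]


class MultiHeadAttention(Module):
    def __init__(self, hidden: int, heads: int, dropout: float,
                 rng: np.random.Generator, drop_rng: np.random.Generator, dtype):
        super().__init__()
        self.heads = heads
        self.head_dim = hidden // heads
        self.q = Linear(hidden, hidden, rng, dtype)
        self.k = Linear(hidden, hidden, rng, dtype)
        self.v = Linear(hidden, hidden, rng, dtype)
        self.out = Linear(hidden, hidden, rng, dtype)
        self.drop = Dropout(dropout, drop_rng)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.heads, self.head_dim).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor, bias: np.ndarray) -> Tensor:
        B, L, d = x.shape
        q = self._split(self.q(x), B, L)
        k = self._split(self.k(x), B, L)
        v = self._split(self.v(x), B, L)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.head_dim)) + Tensor(bias)
        attn = self.drop(scores.softmax(axis=-1))
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, L, d)
        return self.out(ctx)


class EncoderLayer(Module):
    """Pre-norm residual layer: attention sublayer + GELU feedforward."""

    def __init__(self, config: ModelConfig, rng, drop_rng):
        super().__init__()
        dt = config.np_dtype
        self.ln1 = LayerNorm(config.hidden, config.ln_eps, dt)
        self.attn = MultiHeadAttention(config.hidden, config.heads,
                                       config.dropout, rng, drop_rng, dt)
        self.ln2 = LayerNorm(config.hidden, config.ln_eps, dt)
        self.ff1 = Linear(config.hidden, config.feedforward, rng, dt)
        self.ff2 = Linear(config.feedforward, config.hidden, rng, dt)
        self.drop = Dropout(config.dropout, drop_rng)

    def __call__(self, x: Tensor, bias: np.ndarray) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x), bias))
        return x + self.drop(self.ff2(self.ff1(self.ln2(x)).gelu()))


class AcuityTransformer(Module):
    """Multi-task ICU acuity estimator.

    Sequence layout is ``[static slot][task tokens][event tokens]``; task
    token ``k`` (sequence position ``1 + k``) feeds head ``k`` through the
    concatenation of that position's representation at every layer.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.drop_rng = np.random.default_rng(config.seed + 1)
        dt = config.np_dtype
        emb_cfg = EmbeddingConfig(
            hidden=config.hidden, vocab_size=config.vocab_size,
            static_width=config.static_width, static_hidden=list(config.static_hidden),
            discrete_only=config.discrete_only, dtype=dt,
        )
        self.embedder = TokenEmbedder(emb_cfg, rng)
        self.static_encoder = StaticEncoder(emb_cfg, rng)
        self.embed_drop = Dropout(config.dropout, self.drop_rng)
        self.layers = [EncoderLayer(config, rng, self.drop_rng)
                       for _ in range(config.layers)]
        head_in = config.layers * config.hidden
        self.heads = [Linear(head_in, 1, rng, dt) for _ in range(config.n_tasks)]

    def forward(self, batch: Batch) -> Tensor:
        """Per-task logits, shape (B, n_tasks)."""
        cfg = self.config
        if batch.labels.shape[1] != cfg.n_tasks:
            raise ValueError("batch task count does not match the model config")
        x = self.embedder(batch.tokens, batch.special_mask)
        static_emb = self.static_encoder(batch.static)
        B, L, d = x.shape
        # substitute the static network's output into the static slot
        x = concatenate([static_emb.reshape(B, 1, d), x[:, 1:, :]], axis=1)
        x = self.embed_drop(x)
        bias = attention_bias(cfg.window, batch.global_mask, batch.pad_mask,
                              cfg.np_dtype)
        task_slices = []
        for layer in self.layers:
            x = layer(x, bias)
            task_slices.append(x[:, 1:1 + cfg.n_tasks, :])
        # (B, n_tasks, layers * hidden)
        stacked = concatenate(task_slices, axis=2)
        logits = [head(stacked[:, k, :]) for k, head in enumerate(self.heads)]
        return concatenate(logits, axis=1)

    __call__ = forward

    # -- persistence -------------------------------------------------------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "weights.npz"), **self.state_dict())
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)

    @classmethod
    def load(cls, directory: str) -> "AcuityTransformer":
        with open(os.path.join(directory, "config.json")) as fh:
            config = ModelConfig(**json.load(fh))
        model = cls(config)
        with np.load(os.path.join(directory, "weights.npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def sliding_global_attention(attn: MultiHeadAttention, states: Tensor,
                             window: int, global_mask: np.ndarray,
                             pad_mask: np.ndarray) -> Tensor:
    """Apply one multi-head attention block under the sliding+global mask."""
    bias = attention_bias(window, global_mask, pad_mask, states.dtype)
    return attn(states, bias)
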