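"""Comparison models: hourly-resampled GRUs, a tokenized attentional GRU
reusing the event embedding, and gradient-boosted-tree adapters.

All baselines emit the same seven-task logit/score schema as the
transformer so a single split/train/evaluate path serves every family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingConfig, TokenEmbedder
from .nn import GRUCell, Linear, MLP, Module, Tensor, concatenate
from .nn.layers import stack_time
from .sequence import Batch
from .tokenizer import FitArtifacts, TokenizedStay, VocabMap

NEG_INF = -1.0e9


# ---------------------------------------------------------------------------
# hourly resampling


@dataclass
class ResampledSeries:
    values: np.ndarray   # (hours, n_variables), standardized, no missing cells
    static_vector: np.ndarray
    labels: np.ndarray
    stay_id: str = ""


def resample_hourly(events, variables: list[str], artifacts: FitArtifacts,
                    los_hours: float) -> np.ndarray:
    """Aggregate one stay's events into 1-hour bins.

    Half-open bins ``[k, k+1)``; within-bin mean; empty bins forward-filled
    from the last observed bin; leading bins (before the first observation)
    imputed with the training-set median of the variable.  Values are then
    standardized with the per-variable value transform.
    """
    n_bins = max(int(np.ceil(los_hours)), 1)
    out = np.zeros((n_bins, len(variables)))
    for j, name in enumerate(variables):
        med = artifacts.value_medians.get(name, 0.0)
        rows = events[events["variable"] == name]
        col = np.full(n_bins, np.nan)
        if len(rows):
            bins = np.minimum(rows["time_hours"].to_numpy(dtype=float).astype(int),
                              n_bins - 1)
            vals = rows["value"].to_numpy(dtype=float)
            sums = np.bincount(bins, weights=vals, minlength=n_bins)
            counts = np.bincount(bins, minlength=n_bins)
            observed = counts > 0
            col[observed] = sums[observed] / counts[observed]
            # forward fill, then training-median for leading gaps
            last = np.nan
            for k in range(n_bins):
                if np.isnan(col[k]):
                    col[k] = last
                else:
                    last = col[k]
        col = np.where(np.isnan(col), med, col)
        stats = artifacts.value_stats.get(name)
        if stats is not None:
            col = (col - stats[0, 0]) / stats[0, 1]  # 'value' column transform
        out[:, j] = col
    return out


def build_resampled_series(stays: list, tokenized: list[TokenizedStay],
                           vocab: VocabMap, artifacts: FitArtifacts) -> list[ResampledSeries]:
    variables = sorted(vocab.name_to_id)
    out = []
    for raw, tok in zip(stays, tokenized):
        out.append(ResampledSeries(
            values=resample_hourly(raw.events, variables, artifacts, raw.los_hours),
            static_vector=tok.static_vector,
            labels=tok.labels,
            stay_id=tok.stay_id,
        ))
    return out


@dataclass
class SeriesBatch:
    values: np.ndarray   # (B, H, V) right-padded
    mask: np.ndarray     # (B, H) True on real steps
    static: np.ndarray
    labels: np.ndarray
    lengths: np.ndarray


def batch_series(series: list[ResampledSeries]) -> SeriesBatch:
    lengths = np.array([s.values.shape[0] for s in series])
    H = int(lengths.max())
    B = len(series)
    V = series[0].values.shape[1]
    values = np.zeros((B, H, V))
    mask = np.zeros((B, H), dtype=bool)
    for i, s in enumerate(series):
        n = s.values.shape[0]
        values[i, :n] = s.values
        mask[i, :n] = True
    return SeriesBatch(values=values, mask=mask,
                       static=np.stack([s.static_vector for s in series]),
                       labels=np.stack([s.labels for s in series]),
                       lengths=lengths)


# ---------------------------------------------------------------------------
# recurrent baselines


class _GRUBase(Module):
    def __init__(self, input_size: int, static_width: int, hidden: int,
                 n_tasks: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.hidden = hidden
        self.cell = GRUCell(input_size, hidden, rng, dtype)
        self.readout = MLP([hidden + static_width, hidden, n_tasks], rng, dtype)
        self.dtype = dtype

    def _run(self, values: np.ndarray) -> list[Tensor]:
        B, H, _ = values.shape
        h = Tensor(np.zeros((B, self.hidden), dtype=self.dtype))
        states = []
        for t in range(H):
            x = Tensor(np.ascontiguousarray(values[:, t, :], dtype=self.dtype))
            h = self.cell(x, h)
            states.append(h)
        return states

    @staticmethod
    def _final_state(states: list[Tensor], lengths: np.ndarray) -> Tensor:
        stacked = stack_time(states)  # (B, H, hid)
        idx = (np.arange(len(lengths)), lengths - 1)
        return stacked[idx]


class GRUBaseline(_GRUBase):
    """Multivariate-series GRU; predictions from the final hidden state
    concatenated with the static vector."""

    def forward(self, batch: SeriesBatch) -> Tensor:
        states = self._run(batch.values)
        final = self._final_state(states, batch.lengths)
        static = Tensor(np.ascontiguousarray(batch.static, dtype=self.dtype))
        return self.readout(concatenate([final, static], axis=1))

    __call__ = forward


class AdditiveAttention(Module):
    """Alignment scores over hidden states, softmax-normalized."""

    def __init__(self, hidden: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.proj = Linear(hidden, hidden, rng, dtype)
        self.score = Linear(hidden, 1, rng, dtype)

    def __call__(self, states: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        scores = self.score(self.proj(states).tanh())[..., 0]  # (B, H)
        bias = np.where(mask, 0.0, NEG_INF).astype(states.dtype)
        weights = (scores + Tensor(bias)).softmax(axis=-1)
        context = (weights.reshape(*weights.shape, 1) * states).sum(axis=1)
        return context, weights


class GRUAttentionBaseline(_GRUBase):
    """GRU whose readout is the attention-weighted sum of hidden states."""

    def __init__(self, input_size, static_width, hidden, n_tasks, rng,
                 dtype=np.float32):
        super().__init__(input_size, static_width, hidden, n_tasks, rng, dtype)
        self.attention = AdditiveAttention(hidden, rng, dtype)

    def forward(self, batch: SeriesBatch) -> Tensor:
        states = stack_time(self._run(batch.values))
        context, _ = self.attention(states, batch.mask)
        static = Tensor(np.ascontiguousarray(batch.static, dtype=self.dtype))
        return self.readout(concatenate([context, static], axis=1))

    __call__ = forward


class TokenizedGRUAttention(Module):
    """Attentional GRU over the transformer's own token embeddings.

    Consumes assembled batches; the static slot and task tokens are skipped
    (positions after the specials), and the static vector joins at readout
    as in the other recurrent baselines.
    """

    def __init__(self, embed_config: EmbeddingConfig, static_width: int,
                 hidden: int, n_tasks: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        dt = embed_config.dtype
        self.embedder = TokenEmbedder(embed_config, rng)
        self.cell = GRUCell(embed_config.hidden, hidden, rng, dt)
        self.attention = AdditiveAttention(hidden, rng, dt)
        self.readout = MLP([hidden + static_width, hidden, n_tasks], rng, dt)
        self.hidden = hidden
        self.n_specials = 1 + n_tasks
        self.dtype = dt

    def forward(self, batch: Batch) -> Tensor:
        emb = self.embedder(batch.tokens, batch.special_mask)  # (B, L, d)
        events = emb[:, self.n_specials:, :]
        mask = batch.pad_mask[:, self.n_specials:]
        B, H, _ = events.shape
        h = Tensor(np.zeros((B, self.hidden), dtype=self.dtype))
        states = []
        for t in range(H):
            h = self.cell(events[:, t, :], h)
            states.append(h)
        if mask.shape[1] == 0:  # zero-event degenerate batch
            context = Tensor(np.zeros((B, self.hidden), dtype=self.dtype))
        else:
            context, _ = self.attention(stack_time(states), mask)
        static = Tensor(np.ascontiguousarray(batch.static, dtype=self.dtype))
        return self.readout(concatenate([context, static], axis=1))

    __call__ = forward


# ---------------------------------------------------------------------------
# gradient-boosted trees on flattened features


def flatten_for_trees(stay: TokenizedStay, vocab: VocabMap) -> np.ndarray:
    """Fixed-width feature vector: static block, then per vocabulary
    variable the final cumulative 8-vector + last value + presence flag
    (zeros and flag 0 for variables absent from the stay)."""
    variables = sorted(vocab.name_to_id)
    id_to_slot = {vocab.name_to_id[name]: i for i, name in enumerate(variables)}
    blocks = np.zeros((len(variables), 10))
    if stay.tokens.shape[0]:
        ids = stay.tokens[:, 1].astype(int)
        for row, vid in enumerate(ids):  # later rows overwrite: final features win
            slot = id_to_slot.get(vid)
            if slot is None:
                continue
            feats = stay.tokens[row, 3:]  # value + 8 cumulative
            blocks[slot, 0] = feats[0]                 # last value
            blocks[slot, 1:9] = feats[1:]              # final cumulative stats
            blocks[slot, 9] = 1.0                      # presence
    return np.concatenate([stay.static_vector, blocks.reshape(-1)])


def flatten_cohort(stays: list[TokenizedStay], vocab: VocabMap) -> np.ndarray:
    return np.stack([flatten_for_trees(s, vocab) for s in stays])


class TreeBaseline:
    """One independent booster per outcome over the flattened features."""

    def __init__(self, family: str = "xgboost", n_tasks: int = 7, seed: int = 0,
                 n_estimators: int = 200, max_depth: int = 4,
                 learning_rate: float = 0.1):
        self.family = family
        self.n_tasks = n_tasks
        self.seed = seed
        self.params = dict(n_estimators=n_estimators, max_depth=max_depth,
                           learning_rate=learning_rate)
        self.models: list = []

    def _new_model(self):
        if self.family == "xgboost":
            from xgboost import XGBClassifier
            return XGBClassifier(random_state=self.seed, verbosity=0,
                                 eval_metric="logloss", **self.params)
        if self.family == "lightgbm":
            from lightgbm import LGBMClassifier
            return LGBMClassifier(random_state=self.seed, verbose=-1,
                                  **self.params)
        raise ValueError(f"unknown tree family {self.family!r}")

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "TreeBaseline":
        self.models = []
        for k in range(self.n_tasks):
            y = labels[:, k]
            model = self._new_model()
            if len(np.unique(y)) < 2:
                self.models.append(float(y.mean()))  # degenerate constant task
            else:
                model.fit(features, y)
                self.models.append(model)
        return self

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        scores = np.zeros((features.shape[0], self.n_tasks))
        for k, model in enumerate(self.models):
            if isinstance(model, float):
                scores[:, k] = model
            else:
                scores[:, k] = model.predict_proba(features)[:, 1]
        return scores
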