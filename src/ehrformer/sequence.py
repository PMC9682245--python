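"""Assembly of model-ready sequences and padded batches.

Layout per stay: ``[static slot][task tokens][event tokens]``.  The static
slot bypasses the token embedder (its embedding comes from the static
network); the task tokens carry reserved variable ids, time equal to the
standardized length of stay, and exactly-zero value features.  The static
slot and all task tokens receive global attention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tokenizer import FitArtifacts, TokenizedStay, TOKEN_WIDTH, VocabMap


@dataclass
class AssembledSequence:
    tokens: np.ndarray        # (1 + n_tasks + T, 12)
    global_mask: np.ndarray   # bool, True on the specials
    special_mask: np.ndarray  # bool, True on static slot + task tokens
    static_vector: np.ndarray
    labels: np.ndarray
    los_hours: float
    stay_id: str = ""

    @property
    def length(self) -> int:
        return self.tokens.shape[0]


@dataclass
class Batch:
    tokens: np.ndarray        # (B, L, 12)
    pad_mask: np.ndarray      # bool (B, L), True on real positions
    global_mask: np.ndarray   # bool (B, L)
    special_mask: np.ndarray  # bool (B, L)
    static: np.ndarray        # (B, S)
    labels: np.ndarray        # (B, n_tasks)
    lengths: np.ndarray       # (B,)
    stay_ids: list

    @property
    def size(self) -> int:
        return self.tokens.shape[0]


def assemble_sequence(stay: TokenizedStay, vocab: VocabMap,
                      artifacts: FitArtifacts, n_tasks: int = 7) -> AssembledSequence:
    """Prepend the static slot and per-task tokens to a tokenized stay."""
    if n_tasks != vocab.n_tasks:
        raise ValueError(f"n_tasks={n_tasks} does not match vocabulary "
                         f"({vocab.n_tasks} task ids reserved)")
    if stay.labels.shape[0] != n_tasks:
        raise ValueError("label vector width does not match the task count")
    n_special = 1 + n_tasks
    specials = np.zeros((n_special, TOKEN_WIDTH))
    specials[0, 1] = vocab.STATIC
    std_los = float(artifacts.standardize_time(stay.los_hours))
    for k, task_id in enumerate(vocab.task_ids):
        specials[1 + k, 1] = task_id
        specials[1 + k, 2] = std_los  # prediction-time feature; values stay 0
    if stay.tokens.shape[0] == 0:
        warnings.warn(f"stay {stay.stay_id or '?'} has no event tokens; "
                      "sequence contains specials only")
        tokens = specials
    else:
        tokens = np.vstack([specials, stay.tokens])
    length = tokens.shape[0]
    global_mask = np.zeros(length, dtype=bool)
    global_mask[:n_special] = True
    return AssembledSequence(
        tokens=tokens,
        global_mask=global_mask,
        special_mask=global_mask.copy(),
        static_vector=stay.static_vector,
        labels=stay.labels,
        los_hours=stay.los_hours,
        stay_id=stay.stay_id,
    )


def pad_and_batch(sequences: list[AssembledSequence],
                  max_len: int | None = None) -> Batch:
    """Right-pad sequences to a common length and stack into batch arrays."""
    if not sequences:
        raise ValueError("cannot batch zero sequences")
    lengths = np.array([s.length for s in sequences])
    if max_len is not None and lengths.max() > max_len:
        raise ValueError(f"sequence of length {lengths.max()} exceeds "
                         f"max_len={max_len}; filter stays first")
    L = int(lengths.max())
    B = len(sequences)
    tokens = np.zeros((B, L, TOKEN_WIDTH))
    pad_mask = np.zeros((B, L), dtype=bool)
    global_mask = np.zeros((B, L), dtype=bool)
    special_mask = np.zeros((B, L), dtype=bool)
    static = np.stack([s.static_vector for s in sequences])
    labels = np.stack([s.labels for s in sequences])
    for i, s in enumerate(sequences):
        n = s.length
        tokens[i, :n] = s.tokens
        pad_mask[i, :n] = True
        global_mask[i, :n] = s.global_mask
        special_mask[i, :n] = s.special_mask
    return Batch(tokens=tokens, pad_mask=pad_mask, global_mask=global_mask,
                 special_mask=special_mask, static=static, labels=labels,
                 lengths=lengths, stay_ids=[s.stay_id for s in sequences])
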