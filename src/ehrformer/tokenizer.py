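"""Tokenization of irregular ICU event streams into 12-feature event tokens.

Every clinical event (one timestamped measurement of one variable) becomes a
token with twelve entries::

    [position, variable_id, time,
     value, mean, median, count, min, max, std, first, gap]

``position`` is the dense rank of the event's timestamp within the stay
(simultaneous events share a position), ``variable_id`` indexes a vocabulary
fitted on the training cohort, ``time`` is elapsed hours from ICU admission,
and the nine trailing columns are the current value plus running statistics
of the same variable's history within the stay, inclusive of the current
measurement.  All continuous columns are standardized with training-set
statistics held in :class:`FitArtifacts`.

Static (pre-ICU) records are encoded as one-hot categorical blocks,
median-imputed standardized numerics, and binary missingness masks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("vital", "lab", "medication", "assessment")
#: categories subject to the prevalence filter at vocabulary build time
FILTERED_CATEGORIES = ("lab", "medication")

TOKEN_COLUMNS = [
    "position", "variable_id", "time",
    "value", "mean", "median", "count", "min", "max", "std", "first", "gap",
]
VALUE_COLUMNS = TOKEN_COLUMNS[3:]  # the nine value-derived columns
TOKEN_WIDTH = len(TOKEN_COLUMNS)

# length-of-stay inclusion window (hours) and token budget
MIN_LOS_HOURS = 1.0
MAX_LOS_HOURS = 240.0
MAX_TOKENS = 12_000


@dataclass(frozen=True)
class ClinicalEvent:
    """One raw measurement."""

    stay_id: str
    variable: str
    category: str
    time_hours: float
    value: float


@dataclass
class VocabMap:
    """Variable name <-> id map with reserved special ids.

    Ids are contiguous from zero: pad, static slot, one id per prediction
    task, an optional unknown id, then variables in sorted-name order.
    """

    name_to_id: dict[str, int]
    categories: dict[str, str]
    prevalence: dict[str, float]
    n_tasks: int = 7
    use_unknown: bool = False

    PAD = 0
    STATIC = 1

    @property
    def task_ids(self) -> list[int]:
        return list(range(2, 2 + self.n_tasks))

    @property
    def unknown_id(self) -> int | None:
        return 2 + self.n_tasks if self.use_unknown else None

    @property
    def first_variable_id(self) -> int:
        return 2 + self.n_tasks + (1 if self.use_unknown else 0)

    @property
    def size(self) -> int:
        return self.first_variable_id + len(self.name_to_id)

    def lookup(self, name: str) -> int | None:
        vid = self.name_to_id.get(name)
        if vid is None and self.use_unknown:
            return self.unknown_id
        return vid

    def to_json(self) -> str:
        return json.dumps({
            "name_to_id": self.name_to_id,
            "categories": self.categories,
            "prevalence": self.prevalence,
            "n_tasks": self.n_tasks,
            "use_unknown": self.use_unknown,
        })

    @classmethod
    def from_json(cls, text: str) -> "VocabMap":
        d = json.loads(text)
        return cls(d["name_to_id"], d["categories"], d["prevalence"],
                   d["n_tasks"], d["use_unknown"])


@dataclass
class FitArtifacts:
    """Training-set statistics needed to transform new stays."""

    static_numeric_columns: list[str]
    static_categorical_levels: dict[str, list[str]]  # frozen level catalogs
    static_medians: dict[str, float]
    static_means: dict[str, float]
    static_scales: dict[str, float]
    # per variable: (9, 2) array of [mean, scale] rows for VALUE_COLUMNS
    value_stats: dict[str, np.ndarray]
    time_mean: float
    time_scale: float
    value_medians: dict[str, float] = field(default_factory=dict)
    zero_variance: list[str] = field(default_factory=list)

    @property
    def static_width(self) -> int:
        onehot = sum(len(v) for v in self.static_categorical_levels.values())
        return onehot + 2 * len(self.static_numeric_columns)

    def standardize_time(self, t):
        return (np.asarray(t, dtype=float) - self.time_mean) / self.time_scale

    def to_json(self) -> str:
        return json.dumps({
            "static_numeric_columns": self.static_numeric_columns,
            "static_categorical_levels": self.static_categorical_levels,
            "static_medians": self.static_medians,
            "static_means": self.static_means,
            "static_scales": self.static_scales,
            "value_stats": {k: v.tolist() for k, v in self.value_stats.items()},
            "time_mean": self.time_mean,
            "time_scale": self.time_scale,
            "value_medians": self.value_medians,
            "zero_variance": self.zero_variance,
        })

    @classmethod
    def from_json(cls, text: str) -> "FitArtifacts":
        d = json.loads(text)
        d["value_stats"] = {k: np.asarray(v) for k, v in d["value_stats"].items()}
        return cls(**d)


@dataclass
class TokenizedStay:
    stay_id: str
    patient_id: str
    admit_time: float
    los_hours: float
    static_vector: np.ndarray
    tokens: np.ndarray  # (T, 12), standardized
    labels: np.ndarray  # (7,) six outcomes + auxiliary readmission

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[0]


# ---------------------------------------------------------------------------
# vocabulary


def build_vocab(event_frames, min_prevalence: float = 0.01, n_tasks: int = 7,
                use_unknown: bool = False) -> VocabMap:
    """Fit the variable vocabulary on training stays.

    ``event_frames`` is an iterable of per-stay DataFrames with columns
    ``variable``, ``category``, ``time_hours``, ``value``.  Laboratory tests
    and medications are retained only when present in at least
    ``min_prevalence`` of training stays (boundary inclusive); vitals and
    assessment components are always retained.
    """
    frames = list(event_frames)
    if not frames:
        raise ValueError("cannot build a vocabulary from an empty training set")
    n_stays = len(frames)
    seen_in: dict[str, int] = {}
    categories: dict[str, str] = {}
    for frame in frames:
        if len(frame) == 0:
            continue
        pairs = frame[["variable", "category"]].drop_duplicates()
        for name, cat in zip(pairs["variable"], pairs["category"]):
            if cat not in CATEGORIES:
                raise ValueError(f"unknown event category {cat!r} for variable {name!r}")
            seen_in[name] = seen_in.get(name, 0) + 1
            categories[name] = cat
    prevalence = {name: count / n_stays for name, count in seen_in.items()}
    kept = sorted(
        name for name, prev in prevalence.items()
        if categories[name] not in FILTERED_CATEGORIES or prev >= min_prevalence
    )
    vocab = VocabMap({}, {}, {}, n_tasks=n_tasks, use_unknown=use_unknown)
    base = vocab.first_variable_id
    vocab.name_to_id = {name: base + i for i, name in enumerate(kept)}
    vocab.categories = {name: categories[name] for name in kept}
    vocab.prevalence = {name: prevalence[name] for name in kept}
    return vocab


# ---------------------------------------------------------------------------
# positions and cumulative features


def assign_positions(times) -> np.ndarray:
    """Dense rank of timestamps: equal times share an index, each new unique
    time increments the index by exactly one, starting at zero."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return np.zeros(0, dtype=np.int64)
    d = np.diff(t)
    if (d < 0).any():
        raise ValueError("times must be sorted non-decreasing")
    return np.concatenate([[0], np.cumsum((d > 0).astype(np.int64))])


def compute_cumulative_features(values, times) -> np.ndarray:
    """Running statistics of one variable's measurements within a stay.

    Returns an (n, 9) array in VALUE_COLUMNS order: current value, then
    inclusive-prefix mean, median, count, min, max, population std, first
    value, and the gap since the variable's previous measurement (zero for
    the first occurrence).
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.size == 0:
        return np.zeros((0, 9))
    if (np.diff(t) < 0).any():
        raise ValueError("events must be sorted by time")
    n = v.size
    count = np.arange(1, n + 1, dtype=float)
    csum = np.cumsum(v)
    mean = csum / count
    csum2 = np.cumsum(v * v)
    var = np.maximum(csum2 / count - mean ** 2, 0.0)
    std = np.sqrt(var)
    running_min = np.minimum.accumulate(v)
    running_max = np.maximum.accumulate(v)
    median = np.array([np.median(v[: i + 1]) for i in range(n)])
    first = np.full(n, v[0])
    gap = np.concatenate([[0.0], np.diff(t)])
    return np.column_stack([v, mean, median, count, running_min, running_max,
                            std, first, gap])


# ---------------------------------------------------------------------------
# fitting transforms


def _sorted_events(frame: pd.DataFrame) -> pd.DataFrame:
    # stable sort: time, then variable name — tie order never changes positions
    return frame.sort_values(["time_hours", "variable"], kind="stable")


def _raw_token_features(frame: pd.DataFrame, vocab: VocabMap) -> tuple[np.ndarray, pd.DataFrame]:
    """Sort, drop out-of-vocabulary events, and build the raw (unstandardized)
    token matrix.  Returns (matrix, retained sorted frame)."""
    if len(frame) == 0:
        return np.zeros((0, TOKEN_WIDTH)), frame
    frame = _sorted_events(frame)
    ids = np.array([vocab.lookup(name) if vocab.lookup(name) is not None else -1
                    for name in frame["variable"]])
    keep = ids >= 0
    frame = frame.iloc[keep]
    ids = ids[keep]
    if len(frame) == 0:
        return np.zeros((0, TOKEN_WIDTH)), frame
    times = frame["time_hours"].to_numpy(dtype=float)
    positions = assign_positions(times)
    mat = np.zeros((len(frame), TOKEN_WIDTH))
    mat[:, 0] = positions
    mat[:, 1] = ids
    mat[:, 2] = times
    values = frame["value"].to_numpy(dtype=float)
    # cumulative statistics per variable, scattered back to sequence order
    codes, _ = pd.factorize(frame["variable"].to_numpy())
    for code in np.unique(codes):
        idx = np.nonzero(codes == code)[0]
        mat[idx, 3:] = compute_cumulative_features(values[idx], times[idx])
    return mat, frame


def fit_transforms(stays, vocab: VocabMap) -> FitArtifacts:
    """Fit standardization statistics on training stays.

    ``stays`` is an iterable of objects with ``events`` (DataFrame) and
    ``static_record`` (dict) attributes — e.g. the synthetic cohort's stays.
    Statistics are per static numeric column, per (variable, value-feature
    column), plus a global elapsed-time transform.
    """
    stays = list(stays)
    if not stays:
        raise ValueError("cannot fit transforms on an empty training set")

    # -- static side -------------------------------------------------------
    static_rows = [s.static_record for s in stays]
    columns = sorted({k for row in static_rows for k in row})
    numeric_cols, cat_cols = [], []
    for col in columns:
        vals = [row.get(col) for row in static_rows]
        non_missing = [v for v in vals if v is not None]
        if non_missing and all(isinstance(v, str) for v in non_missing):
            cat_cols.append(col)
        else:
            numeric_cols.append(col)
    zero_variance: list[str] = []
    medians, means, scales = {}, {}, {}
    for col in numeric_cols:
        vals = np.array([row.get(col) for row in static_rows
                         if row.get(col) is not None], dtype=float)
        if vals.size == 0:
            vals = np.zeros(1)
        medians[col] = float(np.median(vals))
        means[col] = float(vals.mean())
        sd = float(vals.std())
        if sd < 1e-12:
            zero_variance.append(f"static:{col}")
            sd = 1.0
        scales[col] = sd
    catalogs = {
        col: sorted({row[col] for row in static_rows
                     if isinstance(row.get(col), str)})
        for col in cat_cols
    }

    # -- temporal side -----------------------------------------------------
    per_var: dict[str, list[np.ndarray]] = {}
    all_times: list[np.ndarray] = []
    raw_values: dict[str, list[np.ndarray]] = {}
    for stay in stays:
        mat, frame = _raw_token_features(stay.events, vocab)
        if mat.shape[0] == 0:
            continue
        all_times.append(mat[:, 2])
        for name in frame["variable"].unique():
            rows = mat[frame["variable"].to_numpy() == name, 3:]
            per_var.setdefault(name, []).append(rows)
            raw_values.setdefault(name, []).append(rows[:, 0])
    value_stats: dict[str, np.ndarray] = {}
    value_medians: dict[str, float] = {}
    for name, chunks in per_var.items():
        block = np.vstack(chunks)
        mean = block.mean(axis=0)
        sd = block.std(axis=0)
        flat = sd < 1e-12
        if flat.any():
            zero_variance.extend(f"{name}:{VALUE_COLUMNS[i]}" for i in np.nonzero(flat)[0])
            sd = np.where(flat, 1.0, sd)
        value_stats[name] = np.column_stack([mean, sd])
        value_medians[name] = float(np.median(np.concatenate(raw_values[name])))
    times = np.concatenate(all_times) if all_times else np.zeros(1)
    time_mean = float(times.mean())
    time_scale = float(times.std())
    if time_scale < 1e-12:
        zero_variance.append("time")
        time_scale = 1.0

    return FitArtifacts(
        static_numeric_columns=numeric_cols,
        static_categorical_levels=catalogs,
        static_medians=medians,
        static_means=means,
        static_scales=scales,
        value_stats=value_stats,
        time_mean=time_mean,
        time_scale=time_scale,
        value_medians=value_medians,
        zero_variance=zero_variance,
    )


def process_static(record: dict, artifacts: FitArtifacts) -> np.ndarray:
    """Encode one static record as [one-hot blocks | standardized numerics |
    missingness masks] with a width fixed by the training catalogs."""
    known = set(artifacts.static_numeric_columns) | set(artifacts.static_categorical_levels)
    unknown = set(record) - known
    if unknown:
        raise KeyError(f"unknown static columns: {sorted(unknown)}")
    onehots = []
    for col in sorted(artifacts.static_categorical_levels):
        levels = artifacts.static_categorical_levels[col]
        block = np.zeros(len(levels))
        val = record.get(col)
        if isinstance(val, str) and val in levels:
            block[levels.index(val)] = 1.0
        # missing or unseen level -> all-zero block
        onehots.append(block)
    numerics = np.zeros(len(artifacts.static_numeric_columns))
    masks = np.zeros(len(artifacts.static_numeric_columns))
    for i, col in enumerate(artifacts.static_numeric_columns):
        val = record.get(col)
        if val is None:
            val = artifacts.static_medians[col]
            masks[i] = 1.0
        numerics[i] = (float(val) - artifacts.static_means[col]) / artifacts.static_scales[col]
    parts = onehots + [numerics, masks]
    return np.concatenate(parts) if parts else np.zeros(0)


def tokenize_stay(events: pd.DataFrame, vocab: VocabMap,
                  artifacts: FitArtifacts) -> np.ndarray:
    """Standardized (T, 12) token matrix for one stay.

    Out-of-vocabulary events are dropped (or mapped to the unknown id when
    the vocabulary was built with one); cumulative features are computed on
    raw values and then standardized per (variable, column); elapsed time is
    standardized globally.
    """
    mat, frame = _raw_token_features(events, vocab)
    if mat.shape[0] == 0:
        if len(events) > 0:
            warnings.warn("stay has no in-vocabulary events; emitting an empty token matrix")
        return mat
    names = frame["variable"].to_numpy()
    for name in np.unique(names):
        stats = artifacts.value_stats.get(name)
        if stats is None:  # variable never seen in training (unknown mode)
            continue
        rows = names == name
        mat[rows, 3:] = (mat[rows, 3:] - stats[:, 0]) / stats[:, 1]
    mat[:, 2] = artifacts.standardize_time(mat[:, 2])
    return mat


def filter_stays(stays, token_counts=None, min_los: float = MIN_LOS_HOURS,
                 max_los: float = MAX_LOS_HOURS, max_tokens: int = MAX_TOKENS):
    """Apply the stay-level inclusion rules.

    Retains stays with length of stay in [min_los, max_los] hours and at most
    ``max_tokens`` tokens.  ``stays`` items need ``los_hours`` and ``stay_id``
    attributes; token counts come from ``token_counts`` (parallel sequence)
    or an ``n_tokens`` attribute.  Returns (retained, exclusion_log) where the
    log holds (stay_id, reason) pairs.
    """
    stays = list(stays)
    if token_counts is None:
        token_counts = [s.n_tokens for s in stays]
    retained, log = [], []
    for stay, n_tok in zip(stays, token_counts):
        if stay.los_hours < min_los:
            log.append((stay.stay_id, "los_too_short"))
        elif stay.los_hours > max_los:
            log.append((stay.stay_id, "los_too_long"))
        elif n_tok > max_tokens:
            log.append((stay.stay_id, "too_many_tokens"))
        else:
            retained.append(stay)
    return retained, log


def tokenize_cohort(stays, vocab: VocabMap, artifacts: FitArtifacts) -> list[TokenizedStay]:
    """Tokenize every stay of a cohort (no filtering)."""
    out = []
    for stay in stays:
        out.append(TokenizedStay(
            stay_id=stay.stay_id,
            patient_id=stay.patient_id,
            admit_time=stay.admit_time,
            los_hours=stay.los_hours,
            static_vector=process_static(stay.static_record, artifacts),
            tokens=tokenize_stay(stay.events, vocab, artifacts),
            labels=np.asarray(stay.labels, dtype=float),
        ))
    return out
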