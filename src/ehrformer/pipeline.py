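"""End-to-end experiment pipeline: simulate -> tokenize -> split -> train ->
evaluate, for the transformer variants and every baseline family.

The reduced-scale synthetic benchmark (small hidden size, two encoder
layers, short sequences) is defined here once so the command-line
``benchmark`` subcommand, the test suite, and the acceptance script all run
the same computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import baselines as bl
from .harness import (SplitSpec, TrainSpec, chronological_split, evaluate,
                      evaluate_scores, results_table, train)
from .model import AcuityTransformer, ModelConfig
from .sequence import assemble_sequence, pad_and_batch
from .synthetic import N_TASKS, SimConfig, generate_cohort
from .tokenizer import (build_vocab, filter_stays, fit_transforms,
                        tokenize_cohort)

#: sequence cap for the reduced benchmark (1 static + 7 task + 248 events)
BENCHMARK_MAX_TOKENS = 248
BENCHMARK_MAX_LEN = 256


@dataclass
class PreparedSplit:
    """One split's stays in every model-family view."""

    raw: list
    tokenized: list
    batches: list            # assembled transformer batches
    series_batches: list     # hourly-resampled batches
    features: np.ndarray     # flattened tree features
    labels: np.ndarray


@dataclass
class PreparedCohort:
    vocab: object
    artifacts: object
    train: PreparedSplit
    val: PreparedSplit
    heldout: PreparedSplit
    exclusion_log: list
    static_width: int = 0


def _batch_sorted(seqs, batch_size):
    """Batch sequences grouped by similar length to limit padding waste."""
    order = np.argsort([s.length for s in seqs], kind="stable")
    seqs = [seqs[i] for i in order]
    return [pad_and_batch(seqs[i:i + batch_size], BENCHMARK_MAX_LEN * 64)
            for i in range(0, len(seqs), batch_size)]


def prepare_cohort(stays, split_spec: SplitSpec | None = None,
                   batch_size: int = 21, max_tokens: int = BENCHMARK_MAX_TOKENS,
                   build_series: bool = True, build_trees: bool = True) -> PreparedCohort:
    """Fit tokenization on the training side only, then materialize every
    split in transformer, resampled-series, and flattened-tree form."""
    split_spec = split_spec or SplitSpec()
    train_raw, val_raw, held_raw = chronological_split(stays, split_spec)

    vocab = build_vocab([s.events for s in train_raw])
    artifacts = fit_transforms(train_raw, vocab)

    def build(split_raw) -> PreparedSplit:
        tokenized = tokenize_cohort(split_raw, vocab, artifacts)
        keep, log = filter_stays(tokenized, max_tokens=max_tokens)
        kept_ids = {t.stay_id for t in keep}
        raw = [s for s in split_raw if s.stay_id in kept_ids]
        build.exclusions.extend(log)
        seqs = [assemble_sequence(t, vocab, artifacts) for t in keep]
        batches = _batch_sorted(seqs, batch_size)
        series_batches = []
        if build_series:
            series = bl.build_resampled_series(raw, keep, vocab, artifacts)
            order = np.argsort([s.values.shape[0] for s in series], kind="stable")
            series = [series[i] for i in order]
            series_batches = [bl.batch_series(series[i:i + batch_size])
                              for i in range(0, len(series), batch_size)]
        features = (bl.flatten_cohort(keep, vocab) if build_trees
                    else np.zeros((len(keep), 0)))
        labels = np.stack([t.labels for t in keep])
        return PreparedSplit(raw=raw, tokenized=keep, batches=batches,
                             series_batches=series_batches, features=features,
                             labels=labels)

    build.exclusions = []
    prepared = PreparedCohort(
        vocab=vocab, artifacts=artifacts,
        train=build(train_raw), val=build(val_raw), heldout=build(held_raw),
        exclusion_log=build.exclusions,
        static_width=artifacts.static_width,
    )
    return prepared


# ---------------------------------------------------------------------------
# reduced-scale benchmark configuration


def benchmark_sim_config(seed: int, n_patients: int = 1800) -> SimConfig:
    """Planted-signal cohort of ~2,000 stays (multi-stay patients included)."""
    return SimConfig(n_patients=n_patients, seed=seed)


def benchmark_model_config(vocab_size: int, static_width: int, seed: int,
                           discrete_only: bool = False) -> ModelConfig:
    return ModelConfig(layers=2, hidden=32, feedforward=128, heads=4,
                       window=32, dropout=0.1, n_tasks=N_TASKS,
                       vocab_size=vocab_size, static_width=static_width,
                       static_hidden=[32], discrete_only=discrete_only,
                       seed=seed)


def benchmark_train_spec(seed: int, max_epochs: int = 18) -> TrainSpec:
    # larger step than the full-scale default: small model, small cohort
    return TrainSpec(lr=1e-3, max_epochs=max_epochs, patience=4, seed=seed)


def train_transformer(prepared: PreparedCohort, seed: int,
                      discrete_only: bool = False, max_epochs: int = 18):
    config = benchmark_model_config(prepared.vocab.size, prepared.static_width,
                                    seed, discrete_only)
    model = AcuityTransformer(config)
    spec = benchmark_train_spec(seed, max_epochs)
    model, info = train(model, prepared.train.batches, prepared.val.batches, spec)
    return model, info


def run_reduced_benchmark(seed: int, n_patients: int = 1800,
                          max_epochs: int = 18) -> dict:
    """Train the full and discrete-only transformer variants on the planted-
    signal cohort; report validation and held-out AUROC tables."""
    stays = generate_cohort(benchmark_sim_config(seed, n_patients))
    prepared = prepare_cohort(stays, SplitSpec(seed=seed),
                              build_series=False, build_trees=False)
    out = {"n_stays": sum(len(p.tokenized) for p in
                          (prepared.train, prepared.val, prepared.heldout))}
    for variant, discrete in (("full", False), ("discrete_only", True)):
        model, info = train_transformer(prepared, seed, discrete, max_epochs)
        out[variant] = {
            "val": {"mean": info["best_val_mean_auroc"],
                    **evaluate(model, prepared.val.batches)},
            "heldout": evaluate(model, prepared.heldout.batches),
            "best_epoch": info["best_epoch"],
            "epochs_run": len(info["history"]),
        }
    out["val_mean_gap"] = (out["full"]["val"]["mean"]
                           - out["discrete_only"]["val"]["mean"])
    return out


# ---------------------------------------------------------------------------
# full model grid (the benchmark subcommand)

GRID_FAMILIES = [
    "transformer_discrete_only",
    "transformer_full",
    "gru_resampled",
    "gru_attention_resampled",
    "gru_attention_tokenized",
    "lightgbm",
    "xgboost",
]


def run_model_grid(prepared: PreparedCohort, seed: int, max_epochs: int = 10,
                   gru_hidden: int = 32, families: list[str] | None = None):
    """Run every model family through the shared split/train/evaluate path
    and return {family: heldout AUROC table} plus a printable grid."""
    from .embedding import EmbeddingConfig

    families = families or GRID_FAMILIES
    spec = benchmark_train_spec(seed, max_epochs)
    n_vars = len(prepared.vocab.name_to_id)
    results: dict[str, dict[str, float]] = {}
    for family in families:
        rng_seed = seed
        if family in ("transformer_full", "transformer_discrete_only"):
            model, _ = train_transformer(prepared, rng_seed,
                                         family.endswith("discrete_only"),
                                         max_epochs)
            results[family] = evaluate(model, prepared.heldout.batches)
        elif family == "gru_resampled":
            model = bl.GRUBaseline(n_vars, prepared.static_width, gru_hidden,
                                   N_TASKS, np.random.default_rng(rng_seed))
            model, _ = train(model, prepared.train.series_batches,
                             prepared.val.series_batches, spec)
            results[family] = evaluate(model, prepared.heldout.series_batches)
        elif family == "gru_attention_resampled":
            model = bl.GRUAttentionBaseline(n_vars, prepared.static_width,
                                            gru_hidden, N_TASKS,
                                            np.random.default_rng(rng_seed))
            model, _ = train(model, prepared.train.series_batches,
                             prepared.val.series_batches, spec)
            results[family] = evaluate(model, prepared.heldout.series_batches)
        elif family == "gru_attention_tokenized":
            emb_cfg = EmbeddingConfig(hidden=32, vocab_size=prepared.vocab.size,
                                      static_width=prepared.static_width,
                                      static_hidden=[32])
            model = bl.TokenizedGRUAttention(emb_cfg, prepared.static_width,
                                             gru_hidden, N_TASKS, rng_seed)
            model, _ = train(model, prepared.train.batches,
                             prepared.val.batches, spec)
            results[family] = evaluate(model, prepared.heldout.batches)
        elif family in ("xgboost", "lightgbm"):
            tree = bl.TreeBaseline(family, N_TASKS, seed=rng_seed)
            tree.fit(prepared.train.features, prepared.train.labels)
            scores = tree.predict_scores(prepared.heldout.features)
            results[family] = evaluate_scores(scores, prepared.heldout.labels)
        else:
            raise ValueError(f"unknown model family {family!r}")
    return results, results_table(results)
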