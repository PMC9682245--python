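"""Cohort splitting, multi-task training with early stopping, and AUROC
evaluation shared by every model family."""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .nn import Adam
from .synthetic import ACUITY_TASKS, LABEL_NAMES

TASK_DISPLAY = {
    "icu_readmission": "Readmission",
    "inpatient_mortality": "Inpatient",
    "mortality_7d": "7-Day",
    "mortality_30d": "30-Day",
    "mortality_90d": "90-Day",
    "mortality_1y": "1-Year",
}


@dataclass
class SplitSpec:
    dev_fraction: float = 0.8
    val_fraction: float = 0.1   # within the development set
    seed: int = 0


@dataclass
class TrainSpec:
    """Optimizer family and learning rate are not pinned down by the problem
    definition; the adaptive-moment default below is logged with every run."""

    lr: float = 1e-4
    max_epochs: int = 50
    patience: int = 4
    batch_size: int = 21
    seed: int = 0
    grad_clip: float = 5.0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def chronological_split(stays, spec: SplitSpec):
    """Chronological grouped 80/20 split plus a patient-grouped validation
    sample inside the development set.

    Stays are ordered by admission time; the earliest ``dev_fraction`` form
    the development set, and any later stay whose patient already appears in
    development is pulled into development so no patient spans the boundary.
    Returns (train, validation, heldout) index-free stay lists.
    """
    stays = list(stays)
    if len(stays) < 10:
        raise ValueError("need at least 10 stays to split")
    order = np.argsort([s.admit_time for s in stays], kind="stable")
    ordered = [stays[i] for i in order]
    n_dev = int(round(spec.dev_fraction * len(ordered)))
    dev = ordered[:n_dev]
    rest = ordered[n_dev:]
    dev_patients = {s.patient_id for s in dev}
    heldout = [s for s in rest if s.patient_id not in dev_patients]
    dev = dev + [s for s in rest if s.patient_id in dev_patients]

    rng = np.random.default_rng(spec.seed)
    patients = sorted({s.patient_id for s in dev})
    rng.shuffle(patients)
    target = spec.val_fraction * len(dev)
    by_patient: dict[str, list] = {}
    for s in dev:
        by_patient.setdefault(s.patient_id, []).append(s)
    val_patients: set[str] = set()
    n_val = 0
    for pid in patients:
        if n_val >= target:
            break
        val_patients.add(pid)
        n_val += len(by_patient[pid])
    val = [s for s in dev if s.patient_id in val_patients]
    train = [s for s in dev if s.patient_id not in val_patients]
    _assert_disjoint(train, val, heldout)
    return train, val, heldout


def _assert_disjoint(train, val, heldout):
    t = {s.stay_id for s in train}
    v = {s.stay_id for s in val}
    h = {s.stay_id for s in heldout}
    if t & v or t & h or v & h:
        raise AssertionError("split stay sets overlap")
    dev_patients = {s.patient_id for s in train} | {s.patient_id for s in val}
    if dev_patients & {s.patient_id for s in heldout}:
        raise AssertionError("a patient spans the development/held-out boundary")


def auroc(scores, labels) -> float:
    """Rank-based (Mann-Whitney, midrank ties) AUROC.  Returns NaN with a
    warning when only one class is present."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        warnings.warn("AUROC undefined for single-class labels; reporting NaN")
        return float("nan")
    return float(roc_auc_score(labels, scores))


def task_aurocs(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Per-task AUROC table plus the mean over the six acuity outcomes (the
    auxiliary target is reported separately, never averaged in)."""
    out: dict[str, float] = {}
    for i, name in enumerate(LABEL_NAMES):
        out[name] = auroc(scores[:, i], labels[:, i])
    acuity = [out[name] for name in ACUITY_TASKS if np.isfinite(out[name])]
    out["mean"] = float(np.mean(acuity)) if acuity else float("nan")
    return out


# ---------------------------------------------------------------------------
# training


def _score_batches(model, batches) -> tuple[np.ndarray, np.ndarray]:
    was_training = model.training
    model.eval()
    scores, labels = [], []
    for batch in batches:
        logits = model.forward(batch)
        scores.append(logits.data.copy())
        labels.append(batch.labels)
    if was_training:
        model.train()
    return np.vstack(scores), np.vstack(labels)


def train(model, train_batches: list, val_batches: list, spec: TrainSpec):
    """Optimize the mean per-task binary cross-entropy with early stopping
    on the validation mean AUROC over the six acuity outcomes.

    Stops after ``patience`` consecutive epochs without improvement and
    restores the best checkpoint.  Returns (model, history) where history
    has one record per epoch."""
    optimizer = Adam(model.parameters(), lr=spec.lr, grad_clip=spec.grad_clip)
    rng = np.random.default_rng(spec.seed)
    best_metric = -np.inf
    best_state = None
    best_epoch = -1
    bad_epochs = 0
    history: list[dict] = []
    model.train()
    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(train_batches))
        total_loss = 0.0
        for bi in order:
            batch = train_batches[bi]
            optimizer.zero_grad()
            logits = model.forward(batch)
            loss = logits.bce_with_logits(batch.labels).mean()
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {value}")
            loss.backward()
            optimizer.step()
            total_loss += value
        scores, labels = _score_batches(model, val_batches)
        metrics = task_aurocs(scores, labels)
        record = {"epoch": epoch, "train_loss": total_loss / max(len(train_batches), 1),
                  "val_mean_auroc": metrics["mean"],
                  **{f"val_{k}": v for k, v in metrics.items() if k != "mean"}}
        history.append(record)
        if metrics["mean"] > best_metric:
            best_metric = metrics["mean"]
            best_state = copy.deepcopy(model.state_dict())
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= spec.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, {"history": history, "best_epoch": best_epoch,
                   "best_val_mean_auroc": best_metric}


def evaluate(model, batches) -> dict[str, float]:
    """Per-task AUROC table + mean for a fitted logit-emitting model."""
    scores, labels = _score_batches(model, batches)
    return task_aurocs(scores, labels)


def evaluate_scores(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    return task_aurocs(scores, labels)


def results_table(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Model-by-task AUROC grid in the canonical column order."""
    columns = ["mean"] + list(TASK_DISPLAY)
    table = pd.DataFrame.from_dict(
        {model: {col: metrics.get(col, float("nan")) for col in columns}
         for model, metrics in rows.items()},
        orient="index", columns=columns)
    table.columns = ["Mean"] + [TASK_DISPLAY[c] for c in columns[1:]]
    return table
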