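"""Training protocol and patient-level 5-fold cross-validation.

Training follows the reference recipe: cross-entropy loss, SGD with
momentum 0.9, initial learning rate 1e-3 reduced by a factor of 10 after
every 6 epochs, 30 epochs, batch size 1 (inputs have heterogeneous sizes,
so subjects are processed one at a time).

Cross-validation is at patient level.  The cohort is split into five
disjoint subsets whose sizes are drawn from a seeded range — [65, 70] for
the 333-subject reference cohort, scaled proportionally for other cohort
sizes — so that each round trains on ~80% and tests on ~20% of patients.
Augmentation, when enabled, is applied to the training split only, after
fold assignment, and a leakage guard asserts that no (augmented) variant of
a test patient ever enters training.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .cohort import SubjectRecord
from .evaluation import ConfusionCounts, MetricSet, confusion, metrics
from .model import ModelConfig, OSFPNet, build_model
from .pipeline import AugmentationSpec, augment, base_subject_id

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "make_folds",
    "lr_at_epoch",
    "train_one_fold",
    "run_cross_validation",
    "predict",
    "TrainResult",
    "CVResult",
    "ProtocolError",
]

REFERENCE_N = 333
REFERENCE_FOLD_RANGE = (65, 70)
N_FOLDS = 5


class ProtocolError(RuntimeError):
    """Raised when the train/test protocol is violated (e.g. subject leakage)."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    momentum: float = 0.9
    lr0: float = 1e-3
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 6
    batch_size: int = 1
    seed: int = 0
    early_stop_train_acc: float | None = None  # optional stop once reached

    def __post_init__(self):
        if self.batch_size != 1:
            raise ValueError(
                "batch_size must be 1: input images have heterogeneous sizes"
            )
        if self.epochs < 0 or self.lr0 <= 0 or self.lr_decay_every < 1:
            raise ValueError("invalid training configuration")


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """lr0 / factor^floor(epoch / every): 1e-3, dropping 10x every 6 epochs."""
    if not 0 <= epoch < max(cfg.epochs, 1):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    return cfg.lr0 / cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


@dataclass(frozen=True)
class FoldAssignment:
    fold_of: dict  # subject_id -> fold index in 1..5
    sizes: tuple[int, ...]

    def fold_ids(self, k: int) -> list[str]:
        return [sid for sid, f in self.fold_of.items() if f == k]


def _scaled_fold_range(n: int) -> tuple[int, int]:
    lo = max(1, (REFERENCE_FOLD_RANGE[0] * n) // REFERENCE_N)
    hi = -((-REFERENCE_FOLD_RANGE[1] * n) // REFERENCE_N)  # ceil
    return lo, hi


def make_folds(subject_ids, seed: int) -> FoldAssignment:
    """Patient-level 5-fold partition with seeded random subset sizes.

    Subset sizes are drawn uniformly from the (scaled) [65, 70] range until
    they sum to n; if the constraint is infeasible or the draw does not
    converge, a near-equal split is used with a warning.
    """
    ids = list(subject_ids)
    n = len(ids)
    if n < N_FOLDS:
        raise ValueError(f"need at least {N_FOLDS} subjects, got {n}")
    if len(set(ids)) != n:
        raise ValueError("subject ids must be unique")
    rng = np.random.default_rng(seed)
    lo, hi = _scaled_fold_range(n)
    sizes = None
    if N_FOLDS * lo <= n <= N_FOLDS * hi:
        for _ in range(20000):
            draw = rng.integers(lo, hi + 1, size=N_FOLDS)
            if draw.sum() == n:
                sizes = tuple(int(s) for s in draw)
                break
    if sizes is None:
        warnings.warn(
            f"fold sizes in [{lo}, {hi}] summing to {n} not found; "
            "falling back to a near-equal split"
        )
        base, rem = divmod(n, N_FOLDS)
        sizes = tuple(base + (1 if i < rem else 0) for i in range(N_FOLDS))
    order = rng.permutation(n)
    fold_of, start = {}, 0
    for k, size in enumerate(sizes, start=1):
        for i in order[start: start + size]:
            fold_of[ids[i]] = k
        start += size
    return FoldAssignment(fold_of, sizes)


@dataclass
class TrainResult:
    model: OSFPNet
    log: pd.DataFrame  # per-epoch: epoch, lr, train_loss, train_acc, val_acc
    best_epoch: int | None
    best_val_acc: float | None
    best_state: list | None  # weights at the best-validation epoch


def _check_disjoint(train_records, val_records):
    train_ids = {base_subject_id(r.subject_id) for r in train_records}
    val_ids = {base_subject_id(r.subject_id) for r in val_records}
    overlap = train_ids & val_ids
    if overlap:
        raise ProtocolError(
            f"train and validation/test share subjects: {sorted(overlap)[:5]}"
        )


def predict(model: OSFPNet, records) -> pd.DataFrame:
    """Inference-mode predictions: one row per record with the symptomatic
    probability and the argmax label."""
    rows = []
    for rec in records:
        p = model.predict_proba(rec.quadruple())
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "score_symptomatic": float(p[1]),
                "prediction": int(p.argmax()),
            }
        )
    return pd.DataFrame(rows)


def _accuracy(model: OSFPNet, records) -> float:
    if not records:
        return math.nan
    df = predict(model, records)
    return float((df["label"] == df["prediction"]).mean())


def train_one_fold(model_cfg: ModelConfig, train_records, val_records,
                   train_cfg: TrainConfig, dtype=np.float32) -> TrainResult:
    """Train one model on a training split, logging per-epoch loss/accuracy.

    Training accuracy is tracked from the training-pass predictions; the
    validation split (the held-out fold) is scored in inference mode each
    epoch, and the best-validation weights are snapshotted.
    """
    if val_records:
        _check_disjoint(train_records, val_records)
    model = build_model(model_cfg, seed=train_cfg.seed, dtype=dtype)
    opt = nn.SGD(model.parameters(), momentum=train_cfg.momentum)
    rng = np.random.default_rng(train_cfg.seed + 1)

    rows = []
    best_epoch, best_val, best_state = None, None, None
    for epoch in range(train_cfg.epochs):
        lr = lr_at_epoch(train_cfg, epoch)
        order = rng.permutation(len(train_records))
        losses, correct = [], 0
        for i in order:
            rec = train_records[i]
            logits = model.forward(rec.quadruple(), train=True, rng=rng)
            loss, dlogits, probs = nn.cross_entropy(logits, rec.label)
            correct += int(probs.argmax() == rec.label)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
        train_acc = correct / len(train_records)
        val_acc = _accuracy(model, val_records) if val_records else math.nan
        rows.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(losses)),
                "train_acc": train_acc,
                "val_acc": val_acc,
            }
        )
        if val_records and (best_val is None or val_acc > best_val):
            best_epoch, best_val, best_state = epoch, val_acc, model.state()
        if (
            train_cfg.early_stop_train_acc is not None
            and train_acc >= train_cfg.early_stop_train_acc
        ):
            break
    log = pd.DataFrame(
        rows, columns=["epoch", "lr", "train_loss", "train_acc", "val_acc"]
    )
    return TrainResult(model, log, best_epoch, best_val, best_state)


@dataclass
class CVResult:
    folds: FoldAssignment
    fold_metrics: list[MetricSet]
    fold_counts: list[ConfusionCounts]
    predictions: list[pd.DataFrame]  # per-fold test predictions
    logs: list[pd.DataFrame]

    @property
    def mean_metrics(self) -> dict:
        """Fold-mean of each metric, ignoring undefined (None) entries."""
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
            vals = [m.as_dict()[name] for m in self.fold_metrics]
            vals = [v for v in vals if v is not None]
            out[name] = float(np.mean(vals)) if vals else None
        return out


def run_cross_validation(
    records,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    augment_spec: AugmentationSpec | None = None,
    fold_seed: int = 0,
    out_dir=None,
    selection: str = "final",
    dtype=np.float32,
) -> CVResult:
    """5-fold patient-level cross-validation.

    Each round trains on four subsets (augmented if requested — the test
    subset is never augmented) and evaluates on the held-out subset.
    ``selection='final'`` scores the final-epoch model; ``'best'`` restores
    the epoch with the highest held-out accuracy (optimistic: the protocol
    has no nested validation split).
    """
    if selection not in ("final", "best"):
        raise ValueError(f"selection must be 'final' or 'best', got {selection!r}")
    ids = [r.subject_id for r in records]
    if any("__" in sid for sid in ids):
        raise ProtocolError("run_cross_validation expects unaugmented records")
    folds = make_folds(ids, fold_seed)
    by_id = {r.subject_id: r for r in records}

    fold_metrics, fold_counts, preds, logs = [], [], [], []
    for k in range(1, N_FOLDS + 1):
        test = [by_id[s] for s in ids if folds.fold_of[s] == k]
        train = [by_id[s] for s in ids if folds.fold_of[s] != k]
        if augment_spec is not None:
            train = augment(train, augment_spec)
        _check_disjoint(train, test)  # leakage guard, every round
        result = train_one_fold(model_cfg, train, test, train_cfg, dtype=dtype)
        model = result.model
        if selection == "best" and result.best_state is not None:
            model.set_state(result.best_state)
        df = predict(model, test)
        counts = confusion(df["label"].to_numpy(), df["prediction"].to_numpy())
        fold_counts.append(counts)
        fold_metrics.append(metrics(counts))
        preds.append(df)
        logs.append(result.log)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            df.to_csv(out_dir / f"fold_{k}.csv", index=False)
            result.log.to_csv(out_dir / f"fold_{k}_log.csv", index=False)
    return CVResult(folds, fold_metrics, fold_counts, preds, logs)
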