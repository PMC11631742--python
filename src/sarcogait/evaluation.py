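"""Subject-stratified 4-fold cross-validation and accuracy aggregation.

Folds are assigned at the participant level (all of a person's sequences
share one fold) with class stratification, so a 20-sarcopenia /
80-normal cohort yields four folds of 25 participants (5 + 20).  Within
each training round, 20% of the training participants — again per class,
rounded to the nearest integer — are held out for validation; the epoch
with the best validation accuracy supplies the tested parameters.
Accuracy is computed per sequence; per-participant majority voting is
available via ``TrainConfig.unit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Callable, Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .cohort_labeling import CohortTable, Label
from .models.training import predict_proba, train_classifier

__all__ = [
    "CLASS_INDEX",
    "FoldSplit",
    "TrainConfig",
    "EvalResult",
    "SequenceDataset",
    "make_folds",
    "make_validation_split",
    "train_and_eval",
    "average_accuracy",
    "permute_participant_labels",
    "write_fold_csv",
]

#: class index convention used throughout: 0 = normal, 1 = sarcopenia
CLASS_INDEX = {Label.NORMAL: 0, Label.SARCOPENIA: 1}


@dataclass(frozen=True)
class FoldSplit:
    """Participant-level partition into folds, plus per-fold class counts."""

    folds: tuple[tuple[str, ...], ...]
    class_counts: tuple[dict[str, int], ...]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def all_ids(self) -> set[str]:
        return {pid for fold in self.folds for pid in fold}

    def training_ids(self, test_fold: int) -> list[str]:
        return [pid for k, fold in enumerate(self.folds)
                if k != test_fold for pid in fold]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; presets mirror the two study configurations."""

    model: str = "cnn"  # "cnn" | "stgcn"
    lr: float = 0.001
    optimizer: str = "adam"
    momentum: float = 0.9
    weight_decay: float = 0.0
    schedule: str = "none"
    epochs: int = 100
    loss: str = "cross_entropy"
    batch_size: int = 16
    seed: int = 0
    validation_fraction: float = 0.20
    unit: str = "sequence"  # "sequence" | "participant"

    def __post_init__(self) -> None:
        if self.model not in ("cnn", "stgcn"):
            raise ValueError(f"unknown model kind {self.model!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.schedule not in ("none", "cosine_annealing"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")
        if self.unit not in ("sequence", "participant"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @classmethod
    def cnn_preset(cls, **overrides) -> "TrainConfig":
        """Pressure-image configuration: Adam, lr 0.001, 100 epochs."""
        base = dict(model="cnn", lr=0.001, optimizer="adam", epochs=100)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def stgcn_preset(cls, **overrides) -> "TrainConfig":
        """Skeleton configuration: SGD momentum 0.9, lr 0.1, cosine
        annealing, weight decay 0.001, 200 epochs."""
        base = dict(model="stgcn", lr=0.1, optimizer="sgd", momentum=0.9,
                    weight_decay=0.001, schedule="cosine_annealing", epochs=200)
        base.update(overrides)
        return cls(**base)


class AverageAccuracy(NamedTuple):
    value: float  # rounded half-to-even to 2 decimals
    raw: float


@dataclass
class EvalResult:
    fold_accuracies: list[float]          # percent, one per fold
    average: float                         # percent, 2-decimal reporting value
    average_raw: float
    confusions: list[np.ndarray]           # 2x2 [true, predicted] counts
    validation_ids: list[list[str]] = field(default_factory=list)
    config: TrainConfig | None = None

    def to_dict(self) -> dict:
        return {
            "fold_accuracies_percent": [float(a) for a in self.fold_accuracies],
            "average_percent": self.average,
            "average_percent_raw": self.average_raw,
            "confusions": [c.tolist() for c in self.confusions],
            "validation_participants": self.validation_ids,
            "config": None if self.config is None else vars(self.config) | {},
        }


# ---------------------------------------------------------------------------
# splitting


def make_folds(cohort: CohortTable, n_folds: int = 4, seed: int = 0) -> FoldSplit:
    """Class-stratified, subject-level partition into ``n_folds`` folds.

    Members of each class are dealt round-robin after a seeded shuffle, so
    class counts per fold differ by at most one; a 20 + 80 cohort gives
    every fold exactly 5 sarcopenia + 20 normal participants.
    """
    rng = np.random.default_rng(seed)
    by_label = cohort.ids_by_label()
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    counts: list[dict[str, int]] = [
        {lbl.value: 0 for lbl in CLASS_INDEX} for _ in range(n_folds)]
    for label in (Label.SARCOPENIA, Label.NORMAL):
        ids = sorted(by_label[label])
        if len(ids) < n_folds:
            raise ValueError(
                f"class {label.value!r} has {len(ids)} members, fewer than "
                f"n_folds={n_folds}")
        perm = rng.permutation(len(ids))
        for k, idx in enumerate(perm):
            folds[k % n_folds].append(ids[idx])
            counts[k % n_folds][label.value] += 1
    return FoldSplit(
        folds=tuple(tuple(f) for f in folds),
        class_counts=tuple(counts),
        seed=seed,
    )


def make_validation_split(
    participants: Mapping[str, Label] | Iterable[tuple[str, Label]],
    fraction: float = 0.20,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Hold out ``fraction`` of participants per class for validation.

    Per-class validation counts are ``round(fraction * class_size)``; a
    15 + 60 training set yields 3 sarcopenia + 12 normal validation
    participants.  Returns ``(train_ids, validation_ids)``.
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    items = dict(participants)
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for label in (Label.SARCOPENIA, Label.NORMAL):
        ids = sorted(pid for pid, lbl in items.items() if lbl == label)
        n_val = int(round(fraction * len(ids)))
        perm = rng.permutation(len(ids))
        chosen = {ids[i] for i in perm[:n_val]}
        val_ids.extend(sorted(chosen))
        train_ids.extend(sorted(set(ids) - chosen))
    return train_ids, val_ids


def write_fold_csv(split: FoldSplit, path: str | Path) -> None:
    rows = [{"participant_id": pid, "fold": k}
            for k, fold in enumerate(split.folds) for pid in fold]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# datasets


@dataclass
class SequenceDataset:
    """Feature array plus labels and participant ownership per sequence.

    Entries are sorted by (participant_id, sequence_id) at construction so
    downstream seeded operations are invariant to input order.
    """

    x: np.ndarray
    y: np.ndarray
    participant_ids: np.ndarray
    sequence_ids: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y, dtype=int)
        self.participant_ids = np.asarray(self.participant_ids, dtype=object)
        self.sequence_ids = np.asarray(self.sequence_ids, dtype=object)
        n = len(self.x)
        if not (len(self.y) == len(self.participant_ids) == len(self.sequence_ids) == n):
            raise ValueError("dataset arrays must have equal length")
        order = np.lexsort((self.sequence_ids.astype(str),
                            self.participant_ids.astype(str)))
        for name in ("x", "y", "participant_ids", "sequence_ids"):
            setattr(self, name, getattr(self, name)[order])

    def __len__(self) -> int:
        return len(self.x)

    def participant_labels(self) -> dict[str, Label]:
        out: dict[str, Label] = {}
        inv = {v: k for k, v in CLASS_INDEX.items()}
        for pid, yi in zip(self.participant_ids, self.y):
            lbl = inv[int(yi)]
            if out.setdefault(pid, lbl) != lbl:
                raise ValueError(f"participant {pid} has inconsistent labels")
        return out

    def select(self, ids: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        wanted = set(ids)
        mask = np.array([pid in wanted for pid in self.participant_ids])
        return self.x[mask], self.y[mask]

    def select_with_ids(self, ids: Iterable[str]):
        wanted = set(ids)
        mask = np.array([pid in wanted for pid in self.participant_ids])
        return self.x[mask], self.y[mask], self.participant_ids[mask]


def permute_participant_labels(dataset: SequenceDataset, seed: int = 0) -> SequenceDataset:
    """Shuffle class labels among participants (null-model control)."""
    rng = np.random.default_rng(seed)
    pids = sorted(set(dataset.participant_ids))
    labels = dataset.participant_labels()
    permuted = rng.permutation([CLASS_INDEX[labels[p]] for p in pids])
    new_label = dict(zip(pids, permuted))
    y = np.array([new_label[p] for p in dataset.participant_ids])
    return SequenceDataset(dataset.x, y, dataset.participant_ids.copy(),
                           dataset.sequence_ids.copy())


# ---------------------------------------------------------------------------
# training / evaluation


def average_accuracy(per_fold: Iterable[float]) -> AverageAccuracy:
    """Arithmetic mean of the four fold accuracies, reported to 2 decimals.

    Reporting uses round-half-to-even; the raw mean is also returned.
    """
    vals = [float(v) for v in per_fold]
    if len(vals) != 4:
        raise ValueError(f"expected exactly 4 fold accuracies, got {len(vals)}")
    if any(not (0 <= v <= 100) for v in vals):
        raise ValueError("accuracies must lie in [0, 100]")
    raw = sum(vals) / 4.0
    rounded = float(Decimal(repr(raw)).quantize(Decimal("0.01"),
                                                rounding=ROUND_HALF_EVEN))
    return AverageAccuracy(value=rounded, raw=raw)


def _score(model, x, y, pids, unit: str) -> tuple[float, np.ndarray]:
    probs = predict_proba(model, x)
    pred = probs.argmax(axis=1)
    if unit == "participant":
        pids = np.asarray(pids)
        u_pred, u_true = [], []
        for pid in sorted(set(pids)):
            m = pids == pid
            u_pred.append(int(np.bincount(pred[m], minlength=2).argmax()))
            u_true.append(int(y[m][0]))
        pred, y = np.array(u_pred), np.array(u_true)
    conf = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, pred):
        conf[t, p] += 1
    return 100.0 * float(np.mean(pred == y)), conf


def train_and_eval(
    dataset: SequenceDataset,
    folds: FoldSplit,
    config: TrainConfig,
    model_factory: Callable[[int], object],
    augment_fn: Callable | None = None,
) -> EvalResult:
    """Run the full cross-validation protocol.

    For each fold ``k``: train on the remaining folds minus a per-class 20%
    validation holdout, keep the epoch with the best validation accuracy,
    and score fold ``k``.  A leakage assertion guarantees no participant
    appears in more than one of train/validation/test within a round.
    """
    labels = dataset.participant_labels()
    missing = folds.all_ids() - set(labels)
    if missing:
        raise ValueError(f"folds reference participants without sequences: "
                         f"{sorted(missing)[:5]}")
    fold_accs: list[float] = []
    confusions: list[np.ndarray] = []
    val_record: list[list[str]] = []
    for k in range(folds.n_folds):
        test_ids = list(folds.folds[k])
        if not test_ids:
            raise ValueError(f"fold {k} is empty")
        pool = folds.training_ids(k)
        train_ids, val_ids = make_validation_split(
            {pid: labels[pid] for pid in pool},
            fraction=config.validation_fraction,
            seed=config.seed + 1000 * (k + 1),
        )
        # leakage check: train / validation / test are pairwise disjoint
        tr, va, te = set(train_ids), set(val_ids), set(test_ids)
        assert not (tr & va) and not (tr & te) and not (va & te), \
            "participant leakage across train/validation/test"
        x_tr, y_tr = dataset.select(train_ids)
        x_va, y_va = dataset.select(val_ids)
        x_te, y_te, pids_te = dataset.select_with_ids(test_ids)
        if len(x_tr) == 0 or len(x_te) == 0:
            raise ValueError(f"fold {k}: empty train or test set")
        model = model_factory(config.seed + k)
        train_classifier(
            model, x_tr, y_tr, x_va if len(x_va) else None,
            y_va if len(x_va) else None,
            epochs=config.epochs, lr=config.lr, optimizer=config.optimizer,
            momentum=config.momentum, weight_decay=config.weight_decay,
            schedule=config.schedule, batch_size=config.batch_size,
            seed=config.seed + 7000 * (k + 1),
            augment_fn=augment_fn,
        )
        acc, conf = _score(model, x_te, y_te, pids_te, config.unit)
        fold_accs.append(acc)
        confusions.append(conf)
        val_record.append(list(val_ids))
    if folds.n_folds == 4:
        avg = average_accuracy(fold_accs)
        average, average_raw = avg.value, avg.raw
    else:
        average_raw = float(np.mean(fold_accs))
        average = round(average_raw, 2)
    return EvalResult(
        fold_accuracies=fold_accs, average=average, average_raw=average_raw,
        confusions=confusions, validation_ids=val_record, config=config,
    )
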