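"""End-to-end orchestration: normalize -> rank -> swarm-select -> evaluate.

The pipeline enforces a strict train/test separation: z-score statistics,
the mRMR ranking, and every fitness evaluation see training rows only; the
held-out partition is touched exactly once, by the final retrained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GroupShuffleSplit, train_test_split as _sk_split
from sklearn.svm import SVC

from .errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    LeakageError,
)
from .features import FeatureTable, Standardizer
from .mrmr import mrmr_rank
from .pso import SelectionResult, SwarmConfig, run_pso

__all__ = [
    "Metrics",
    "PipelineConfig",
    "classification_metrics",
    "label_valence_arousal",
    "train_test_split",
    "mrmr_pso_svm",
]


@dataclass(frozen=True)
class Metrics:
    """Confusion-matrix counts and the derived scores.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    F = 2 P R / (P + R), accuracy = (TP+TN)/total; a zero denominator
    yields 0 and sets ``degenerate``.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    precision: float
    recall: float
    f_measure: float
    accuracy: float
    degenerate: bool = False

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Counts and scores for a binary prediction (positive class = 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    return Metrics(tp, fp, tn, fn, precision, recall, f, accuracy, degenerate)


def label_valence_arousal(arousal: float, valence: float) -> str:
    """Map 1-9 self-report scores to ``calm`` / ``stress`` / ``unlabeled``.

    calm  iff arousal < 4 and 4 < valence < 6;
    stress iff arousal > 5 and valence < 3; anything else is unlabeled
    (such rows are excluded from analysis).
    """
    for name, v in (("arousal", arousal), ("valence", valence)):
        if not 1.0 <= v <= 9.0:
            raise ValueError(f"{name} score {v} outside the 1-9 scale")
    if arousal < 4 and 4 < valence < 6:
        return "calm"
    if arousal > 5 and valence < 3:
        return "stress"
    return "unlabeled"


def _split_indices(
    y: np.ndarray, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    if not 0.0 < train_fraction < 1.0:
        raise InsufficientDataError(
            f"train_fraction must lie strictly in (0, 1), got {train_fraction}"
        )
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise DegenerateLabelsError(f"need two classes, got {classes.tolist()}")
    if counts.min() < 2:
        raise InsufficientDataError(
            f"each class needs >= 2 rows for a stratified split, got {counts.tolist()}"
        )
    idx = np.arange(y.size)
    tr, te = _sk_split(
        idx,
        train_size=train_fraction,
        stratify=y,
        random_state=seed % 2**31,
        shuffle=True,
    )
    return np.sort(tr), np.sort(te)


def train_test_split(
    table: FeatureTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified, disjoint, seed-reproducible row split."""
    if table.y is None:
        raise DegenerateLabelsError("train_test_split needs a labeled table")
    tr, te = _split_indices(table.y, train_fraction, seed)
    return table.subset_rows(tr), table.subset_rows(te)


def _group_split_indices(y, groups, train_fraction, seed):
    """Subject-independent split: whole subjects go to one side."""
    gss = GroupShuffleSplit(n_splits=1, train_size=train_fraction, random_state=seed % 2**31)
    tr, te = next(gss.split(np.zeros_like(y), y, groups=np.asarray(groups)))
    for part, name in ((tr, "train"), (te, "test")):
        if np.unique(y[part]).size != 2:
            raise InsufficientDataError(
                f"subject-level split left a single class in the {name} partition"
            )
    return np.sort(tr), np.sort(te)


@dataclass
class PipelineConfig:
    """Configuration of the full selection + evaluation pipeline."""

    train_fraction: float = 0.8
    pool_size: int | None = None
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    seed: int = 0
    #: optional per-row subject ids; if given the split is subject-independent
    groups: np.ndarray | None = None
    #: optional explicit (train_idx, test_idx); overrides the seeded split
    split: tuple[np.ndarray, np.ndarray] | None = None


def mrmr_pso_svm(table: FeatureTable, config: PipelineConfig | None = None) -> SelectionResult:
    """Run the hybrid selector end-to-end and evaluate once on held-out rows.

    Order of operations: stratified 80/20 split -> z-score fitted on train
    -> mRMR ranking on train -> binary PSO with SVM (C, gamma)
    co-optimization on train -> final RBF-SVM retrained on the full
    training partition with the best mask -> single evaluation on the
    untouched test rows.  Test rows never influence normalization, ranking
    or fitness.
    """
    config = config or PipelineConfig()
    if table.y is None:
        raise DegenerateLabelsError("the pipeline needs a labeled table")
    classes, counts = np.unique(table.y, return_counts=True)
    if classes.size != 2:
        raise DegenerateLabelsError(f"need two classes, got {classes.tolist()}")
    if counts.min() < 10:
        raise InsufficientDataError(
            f"need >= 10 rows per class, got counts {counts.tolist()}"
        )

    ss = np.random.SeedSequence(config.seed)
    split_seed, swarm_seed = (int(s) % 2**31 for s in ss.generate_state(2))

    if config.split is not None:
        tr_idx, te_idx = (np.asarray(i, dtype=int) for i in config.split)
    elif config.groups is not None:
        tr_idx, te_idx = _group_split_indices(
            table.y, config.groups, config.train_fraction, split_seed
        )
    else:
        tr_idx, te_idx = _split_indices(table.y, config.train_fraction, split_seed)
    if np.intersect1d(tr_idx, te_idx).size:
        raise LeakageError("train and test partitions overlap")

    train = table.subset_rows(tr_idx)
    test = table.subset_rows(te_idx)

    std = Standardizer().fit(train)
    train_n = std.transform(train)
    test_n = std.transform(test)

    ranking = mrmr_rank(train_n, pool_size=config.pool_size)

    swarm_cfg = SwarmConfig(**{**config.swarm.__dict__, "seed": swarm_seed})
    result = run_pso(train_n, ranking, swarm_cfg)

    clf = SVC(kernel="rbf", C=result.C, gamma=result.gamma)
    clf.fit(train_n.X[:, result.mask], train_n.y)
    y_pred = clf.predict(test_n.X[:, result.mask])
    result.metrics = classification_metrics(test_n.y, y_pred)
    return result
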