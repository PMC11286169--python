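"""Subject-disjoint splits, training-set balancing and the RF classifier.

Cross-subject evaluation is the point: in subject-wise 5-fold and
leave-one-out modes no subject's segments ever appear in both train and
test of a fold, which removes subjective data leakage.  A random-segment
80:20 mode is provided as the leaky baseline for comparison.

Training data is balanced by undersampling (all ictal rows kept, an
equal-size random subset of interictal rows); test folds stay at their
natural imbalance.  The segment classifier is a random forest whose
``n_estimators`` is grid-searched over {15, 21, 30, 50, 75} on a
held-out 30% of training *subjects*, objective = validation sensitivity
(ties going to the smaller forest), then refit on the full balanced
training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import ValidationError

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "SegmentMetrics",
    "make_split",
    "undersample",
    "train_segment_classifier",
    "segment_metrics",
    "run_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    mode: str  # sw_kfold | loo | random_segment
    folds: list[tuple[list, list]]  # (train subjects/rows, test subjects/rows)
    seed: int


@dataclass
class TrainConfig:
    n_estimators_grid: tuple[int, ...] = (15, 21, 30, 50, 75)
    validation_fraction: float = 0.30  # of training *subjects*
    objective: str = "sensitivity"     # or "f1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_estimators_grid:
            raise ValidationError("n_estimators grid must be non-empty")
        if not (0 < self.validation_fraction < 1):
            raise ValidationError("validation fraction must be in (0, 1)")


@dataclass
class SegmentMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float


def make_split(
    subjects_or_n: list[str] | int,
    mode: str,
    seed: int = 0,
    k: int = 5,
    test_fraction: float = 0.20,
) -> SplitPlan:
    """Build a deterministic split plan.

    ``sw_kfold``: subjects shuffled then cut into k groups whose sizes
    differ by at most 1; each fold tests one group.  ``loo``: one fold
    per subject.  ``random_segment``: pass the row count; rows are
    shuffled and split (1 - test_fraction) : test_fraction.
    """
    rng = np.random.default_rng(seed)
    if mode == "random_segment":
        if not isinstance(subjects_or_n, int):
            raise ValidationError("random_segment mode needs a row count")
        idx = rng.permutation(subjects_or_n)
        n_test = int(round(subjects_or_n * test_fraction))
        folds = [(sorted(idx[n_test:].tolist()), sorted(idx[:n_test].tolist()))]
        return SplitPlan(mode=mode, folds=folds, seed=seed)

    subjects = list(subjects_or_n)
    if mode == "sw_kfold":
        if len(subjects) < k:
            raise ValidationError(f"need >= {k} subjects for {k}-fold")
        perm = [subjects[i] for i in rng.permutation(len(subjects))]
        groups = [sorted(g.tolist()) for g in np.array_split(np.array(perm), k)]
        folds = [
            (sorted(s for g2 in groups if g2 is not g for s in g2), g) for g in groups
        ]
    elif mode == "loo":
        folds = [
            (sorted(s for s in subjects if s != t), [t]) for t in sorted(subjects)
        ]
    else:
        raise ValidationError(f"unknown split mode {mode!r}")
    return SplitPlan(mode=mode, folds=folds, seed=seed)


def undersample(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Balance a training table by majority-class undersampling.

    All minority rows are kept; majority rows are sampled without
    replacement down to the minority count.  Row order follows the
    original table.  Never applied to test data.
    """
    y = table["label"].to_numpy()
    counts = pd.Series(y).value_counts()
    if len(counts) < 2:
        raise ValidationError("undersample needs both classes present")
    minority = counts.idxmin()
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    keep = np.concatenate([keep, rng.choice(maj_idx, size=n_min, replace=False)])
    return table.iloc[np.sort(keep)]


def segment_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> SegmentMetrics:
    """Confusion counts and the usual ratios; 0/0 ratios resolve to 0."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred lengths differ")

    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())

    def ratio(num: int, den: int) -> float:
        if den == 0:
            logger.debug("0/0 metric resolved to 0")
            return 0.0
        return num / den

    prec = ratio(tp, tp + fp)
    sen = ratio(tp, tp + fn)
    return SegmentMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=ratio(tp + tn, len(y_true)),
        sensitivity=sen,
        specificity=ratio(tn, tn + fp),
        precision=prec,
        f1=2 * prec * sen / (prec + sen) if prec + sen > 0 else 0.0,
    )


def _fit_rf(X: np.ndarray, y: np.ndarray, n_estimators: int, seed: int):
    return RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    ).fit(X, y)


def train_segment_classifier(
    train: pd.DataFrame,
    feature_cols: list[str],
    config: TrainConfig = TrainConfig(),
) -> tuple[RandomForestClassifier, int]:
    """Grid-search the forest size on held-out subjects, then refit.

    30% of the training subjects (at least one, never all) are held out;
    each grid value is fit on the remainder and scored on the held-out
    segments by the configured objective; ties prefer the smaller
    forest.  The winner is refit on the full balanced training table.
    """
    subjects = sorted(train["subject"].unique())
    if len(subjects) < 2:
        raise ValidationError("subject-level validation needs >= 2 training subjects")
    rng = np.random.default_rng(config.seed)
    n_val = max(1, int(round(config.validation_fraction * len(subjects))))
    n_val = min(n_val, len(subjects) - 1)
    val_subjects = set(
        np.asarray(subjects, dtype=object)[
            rng.permutation(len(subjects))[:n_val]
        ].tolist()
    )
    val_mask = train["subject"].isin(val_subjects).to_numpy()
    X = train[feature_cols].to_numpy()
    y = train["label"].to_numpy().astype(int)

    best_n, best_score = None, -1.0
    if len(config.n_estimators_grid) == 1:
        best_n = config.n_estimators_grid[0]
    else:
        for n_est in sorted(config.n_estimators_grid):
            model = _fit_rf(X[~val_mask], y[~val_mask], n_est, config.seed)
            m = segment_metrics(y[val_mask], model.predict(X[val_mask]))
            score = m.sensitivity if config.objective == "sensitivity" else m.f1
            logger.debug("grid n_estimators=%d -> %s=%.4f", n_est, config.objective, score)
            if score > best_score + 1e-12:  # strict: ties keep the smaller forest
                best_n, best_score = n_est, score
    model = _fit_rf(X, y, best_n, config.seed)
    return model, best_n


def run_experiment(
    table: pd.DataFrame,
    mode: str,
    feature_cols: list[str],
    config: TrainConfig = TrainConfig(),
    k: int = 5,
) -> tuple[pd.DataFrame, list[SegmentMetrics]]:
    """Cross-validated segment classification over a feature table.

    For every fold: balance the training rows by undersampling, fit the
    grid-searched forest, and predict *every* test segment (test rows
    stay imbalanced).  Returns all predictions keyed
    (subject, record, index, y_true, y_pred, fold) plus per-fold
    metrics.  Subject-wise folds are leakage-checked by construction.
    """
    root = np.random.SeedSequence(config.seed)
    if mode == "random_segment":
        plan = make_split(len(table), mode, seed=config.seed, k=k)
    else:
        plan = make_split(sorted(table["subject"].unique()), mode, seed=config.seed, k=k)

    predictions = []
    fold_metrics = []
    for fold_id, ((train_key, test_key), ss) in enumerate(
        zip(plan.folds, root.spawn(len(plan.folds)))
    ):
        s_under, s_train = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(2))
        if mode == "random_segment":
            train_rows = table.iloc[list(train_key)]
            test_rows = table.iloc[list(test_key)]
        else:
            assert not set(train_key) & set(test_key), "subject leakage in fold"
            train_rows = table[table["subject"].isin(train_key)]
            test_rows = table[table["subject"].isin(test_key)]

        balanced = undersample(train_rows, seed=s_under)
        model, chosen_n = train_segment_classifier(
            balanced, feature_cols, TrainConfig(
                n_estimators_grid=config.n_estimators_grid,
                validation_fraction=config.validation_fraction,
                objective=config.objective,
                seed=s_train,
            ),
        )
        y_pred = model.predict(test_rows[feature_cols].to_numpy())
        y_true = test_rows["label"].to_numpy().astype(int)
        fold_metrics.append(segment_metrics(y_true, y_pred))
        out = test_rows[["subject", "record", "index"]].copy()
        out["y_true"] = y_true
        out["y_pred"] = y_pred.astype(int)
        out["fold"] = fold_id
        out["n_estimators"] = chosen_n
        predictions.append(out)
        logger.info(
            "fold %d: n_estimators=%d test_sensitivity=%.3f",
            fold_id, chosen_n, fold_metrics[-1].sensitivity,
        )
    return pd.concat(predictions, ignore_index=True), fold_metrics
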