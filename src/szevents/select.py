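"""Feature scoring and cumulative-importance selection.

Four scorers are available — chi-squared, absolute Pearson correlation
with the target, decision-tree impurity importance and random-forest
permutation importance.  Scores are normalized to weights summing to 1;
selection takes the minimal descending-weight prefix whose cumulative
weight reaches a cutoff (default 0.9), ties broken by catalog order.

The comparison protocol mirrors a small-sample design: segments from
one channel of five random subjects, repeated over five random
channels, averaging each feature's weight across channels per method.
The chi-squared ranking is then applied identically to every channel;
the per-channel selected count defaults to 34 (748 classifier columns
over 22 channels) so the classifier dimension is reproducible run to
run, while the protocol also reports what the cutoff itself would give.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import catalog_names
from .io import ValidationError

__all__ = [
    "DEFAULT_PER_CHANNEL_K",
    "ImportanceScores",
    "SelectionResult",
    "chi2_scores",
    "correlation_scores",
    "tree_importance_scores",
    "cumulative_select",
    "selection_protocol",
    "select_per_channel",
    "apply_selection",
]

DEFAULT_PER_CHANNEL_K = 34  # selected features per channel; 22 * 34 = 748


@dataclass
class ImportanceScores:
    method: str
    feature_names: list[str]
    scores: np.ndarray   # raw scores >= 0
    weights: np.ndarray  # scores / sum(scores)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < 0).any():
            raise ValidationError("importance scores must be non-negative")
        total = self.scores.sum()
        self.weights = self.scores / total if total > 0 else np.zeros_like(self.scores)


@dataclass
class SelectionResult:
    method: str
    cutoff: float
    selected: list[str]        # ordered by descending weight
    cumulative_weight: float


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValidationError("X must be 2-D with one row per label")
    if len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes")
    return X, y


def chi2_scores(
    X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None
) -> ImportanceScores:
    """Chi-squared statistic of per-class feature mass.

    Each feature is first min-max rescaled to [0, 1] on the scoring
    sample (the statistic requires non-negative input).  For feature f
    with class-c observed mass O_c = sum of f over class-c rows and
    expected mass E_c = (total mass) * N_c / N, the score is
    sum_c (O_c - E_c)^2 / E_c; all-constant (zero-mass) features score 0.
    """
    X, y = _check_xy(X, y)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span_safe = np.where(span > 0, span, 1.0)
    Xs = (X - lo) / span_safe

    classes = np.unique(y)
    n = len(y)
    total = Xs.sum(axis=0)
    chi2 = np.zeros(X.shape[1])
    for c in classes:
        mask = y == c
        observed = Xs[mask].sum(axis=0)
        expected = total * (mask.sum() / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (observed - expected) ** 2 / expected
        chi2 += np.where(expected > 0, term, 0.0)
    chi2[total <= 0] = 0.0
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return ImportanceScores("chi2", list(names), chi2, chi2)


def correlation_scores(
    X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None
) -> ImportanceScores:
    """Absolute Pearson correlation with the binary target."""
    X, y = _check_xy(X, y)
    yc = y.astype(float) - y.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    score = np.where(denom > 0, np.abs(r), 0.0)
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return ImportanceScores("correlation", list(names), score, score)


def tree_importance_scores(
    X: np.ndarray,
    y: np.ndarray,
    kind: str = "decision_tree",
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> ImportanceScores:
    """Library-backed tree importances (impurity or RF permutation)."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance
    from sklearn.tree import DecisionTreeClassifier

    X, y = _check_xy(X, y)
    if kind == "decision_tree":
        model = DecisionTreeClassifier(random_state=seed).fit(X, y)
        raw = model.feature_importances_
    elif kind == "rf_permutation":
        model = RandomForestClassifier(
            n_estimators=30, random_state=seed, n_jobs=1
        ).fit(X, y)
        pi = permutation_importance(
            model, X, y, n_repeats=5, random_state=seed, n_jobs=1
        )
        raw = np.clip(pi.importances_mean, 0.0, None)
    else:
        raise ValidationError(f"unknown importance kind {kind!r}")
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return ImportanceScores(kind, list(names), raw, raw)


def cumulative_select(scores: ImportanceScores, cutoff: float = 0.9) -> SelectionResult:
    """Minimal descending-weight prefix reaching the cumulative cutoff.

    Ties are broken by catalog (input) order, which makes the selection
    deterministic.  With all-zero weights nothing can reach the cutoff
    and every feature is returned.
    """
    if not (0 < cutoff <= 1):
        raise ValidationError("cutoff must be in (0, 1]")
    order = np.argsort(-scores.weights, kind="stable")
    cum = np.cumsum(scores.weights[order])
    reached = np.flatnonzero(cum >= cutoff - 1e-12)
    k = int(reached[0]) + 1 if len(reached) else len(order)
    sel = [scores.feature_names[i] for i in order[:k]]
    return SelectionResult(
        method=scores.method,
        cutoff=cutoff,
        selected=sel,
        cumulative_weight=float(cum[k - 1]),
    )


_METHOD_FUNCS = {
    "chi2": chi2_scores,
    "correlation": correlation_scores,
    "decision_tree": lambda X, y, names=None, seed=0: tree_importance_scores(
        X, y, "decision_tree", seed, names
    ),
    "rf_permutation": lambda X, y, names=None, seed=0: tree_importance_scores(
        X, y, "rf_permutation", seed, names
    ),
}


def selection_protocol(
    table: pd.DataFrame,
    channel_labels: list[str],
    n_subjects: int = 5,
    n_channels: int = 5,
    methods: tuple[str, ...] = ("chi2", "correlation", "decision_tree", "rf_permutation"),
    cutoff: float = 0.9,
    seed: int = 0,
) -> dict[str, dict]:
    """Small-sample method comparison and averaged chi-squared ranking.

    Samples ``n_subjects`` random subjects and ``n_channels`` random
    channels from the feature table; scores each channel's 92 features
    with every method on the raw (imbalanced) sample; averages weights
    across channels per method; and reports each method's
    cumulative-cutoff selection plus its minimum feature count.
    """
    rng = np.random.default_rng(seed)
    subjects = sorted(table["subject"].unique())
    if len(subjects) < n_subjects:
        raise ValidationError(f"need >= {n_subjects} subjects, have {len(subjects)}")
    if len(channel_labels) < n_channels:
        raise ValidationError(f"need >= {n_channels} channels")
    pick_subj = list(rng.choice(subjects, size=n_subjects, replace=False))
    pick_ch = list(rng.choice(channel_labels, size=n_channels, replace=False))
    sample = table[table["subject"].isin(pick_subj)]
    names = catalog_names()
    y = sample["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("sampled subjects contain a single class")

    report: dict[str, dict] = {}
    for method in methods:
        func = _METHOD_FUNCS[method]
        wsum = np.zeros(len(names))
        for ch in pick_ch:
            X = sample[[f"{ch}/{n}" for n in names]].to_numpy()
            if method in ("decision_tree", "rf_permutation"):
                s = func(X, y, names, int(rng.integers(2**31)))
            else:
                s = func(X, y, names)
            wsum += s.weights
        avg = ImportanceScores(method, names, wsum / n_channels, wsum)
        sel = cumulative_select(avg, cutoff)
        report[method] = {
            "scores": avg,
            "selection": sel,
            "min_count": len(sel.selected),
        }
    report["_protocol"] = {"subjects": pick_subj, "channels": pick_ch, "cutoff": cutoff}
    return report


def select_per_channel(
    table: pd.DataFrame,
    channel_labels: list[str],
    k: int = DEFAULT_PER_CHANNEL_K,
    seed: int = 0,
    n_subjects: int = 5,
    n_channels: int = 5,
) -> list[str]:
    """Top-k feature names by channel-averaged chi-squared weight.

    The same k names are applied to every channel, fixing the classifier
    dimension at ``k * n_channels_total`` columns.
    """
    report = selection_protocol(
        table, channel_labels, n_subjects=n_subjects, n_channels=n_channels,
        methods=("chi2",), seed=seed,
    )
    scores: ImportanceScores = report["chi2"]["scores"]
    order = np.argsort(-scores.weights, kind="stable")[:k]
    return [scores.feature_names[i] for i in order]


def apply_selection(feature_names: list[str], channel_labels: list[str]) -> list[str]:
    """Expand per-channel feature names into table column names."""
    return [f"{ch}/{n}" for ch in channel_labels for n in feature_names]
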