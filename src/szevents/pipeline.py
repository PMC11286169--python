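"""End-to-end glue: timelines -> features -> selection -> CV -> event scores.

This is the one-call version of the full detection experiment used by
the command line and by evaluation scripts; every stage is the public
API of its own module.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .events import PostprocessParams, score_table
from .experiment import TrainConfig, run_experiment
from .features import extract_table
from .io import SubjectTimeline
from .select import DEFAULT_PER_CHANNEL_K, apply_selection, select_per_channel

__all__ = ["DetectionResult", "run_event_detection"]


@dataclass
class DetectionResult:
    scores: pd.DataFrame          # per-subject + overall event scores
    predictions: pd.DataFrame     # per-segment predictions, all folds
    selected_features: list[str]  # per-channel feature names
    segment_sensitivity: float    # pooled over all test segments


def run_event_detection(
    timelines: list[SubjectTimeline],
    mode: str = "loo",
    seed: int = 0,
    per_channel_k: int = DEFAULT_PER_CHANNEL_K,
    entropy_stride: int = 1,
    params: PostprocessParams = PostprocessParams(),
    train_config: TrainConfig | None = None,
    feature_table: pd.DataFrame | None = None,
) -> DetectionResult:
    """Run the whole detection experiment on subject timelines.

    Feature selection is performed once, globally, before splitting (the
    classifier dimension is per_channel_k * 22); pass ``feature_table``
    to reuse a precomputed table.
    """
    channel_labels = list(timelines[0].records[0].channels.labels)
    table = (
        feature_table
        if feature_table is not None
        else extract_table(timelines, entropy_stride=entropy_stride)
    )
    n_subj = table["subject"].nunique()
    selected = select_per_channel(
        table, channel_labels, k=per_channel_k, seed=seed,
        n_subjects=min(5, n_subj), n_channels=5,
    )
    cols = apply_selection(selected, channel_labels)
    cfg = train_config or TrainConfig(seed=seed)
    predictions, _fold_metrics = run_experiment(table, mode, cols, cfg)
    scores = score_table(predictions, timelines, params)
    pooled = predictions["y_true"].to_numpy(), predictions["y_pred"].to_numpy()
    from .experiment import segment_metrics

    seg_sen = segment_metrics(*pooled).sensitivity
    return DetectionResult(
        scores=scores,
        predictions=predictions,
        selected_features=selected,
        segment_sensitivity=seg_sen,
    )
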