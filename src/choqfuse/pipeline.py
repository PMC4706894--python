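"""End-to-end convenience layer: train a fusion model from raw scores and
evaluate it against its base classifiers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision import FrameworkModel, decide_batch, search_threshold
from .learning import DEFAULT_RIDGE, learn_all
from .metrics import (
    ConfusionTable,
    confusion_with_abstention,
    efficiency,
    nykopp_itr,
)
from .normalization import BeliefMatrix, NormalizationConfig, ScoreMatrix, \
    normalize_scores
from .simulate import accuracy_by_classifier

__all__ = [
    "train_model",
    "tune_model_threshold",
    "evaluate_model",
    "EvaluationReport",
]


def _normalize_all(
    matrices: list[ScoreMatrix], config: NormalizationConfig
) -> list[BeliefMatrix]:
    return [normalize_scores(m, config) for m in matrices]


def train_model(
    score_matrices: list[ScoreMatrix],
    true_labels: np.ndarray,
    normalization: NormalizationConfig | None = None,
    ensemble_size: int = 4,
    global_order: int = 4,
    class_order: int | None = None,
    ridge: float = DEFAULT_RIDGE,
    threshold: float = 0.0,
) -> FrameworkModel:
    """Train the full fusion model on labeled score matrices.

    Normalizes scores to beliefs, learns one-vs-rest global capacities,
    builds class ensembles by greedy interaction, learns ensemble
    capacities, and installs the given abstention threshold (tune it
    afterwards with :func:`choqfuse.decision.search_threshold`).
    """
    if normalization is None:
        normalization = NormalizationConfig()
    k, n = score_matrices[0].scores.shape
    beliefs = _normalize_all(score_matrices, normalization)
    size = min(ensemble_size, k)
    global_caps, ensembles, class_caps = learn_all(
        beliefs,
        true_labels,
        class_order=class_order,
        global_order=min(global_order, k),
        ridge=ridge,
        ensemble_size=size,
    )
    return FrameworkModel(
        k=k,
        n=n,
        normalization=normalization,
        ensembles=ensembles,
        class_capacities=class_caps,
        global_capacities=global_caps,
        abstention_threshold=threshold,
    )


def tune_model_threshold(
    model: FrameworkModel,
    score_matrices: list[ScoreMatrix],
    true_labels: np.ndarray,
    metric: str = "efficiency",
    grid: np.ndarray | None = None,
) -> FrameworkModel:
    """Return the model with its threshold replaced by the grid-search
    optimum on the given validation data (falls back to ITR when the
    efficiency is undefined on the whole grid)."""
    from .decision import ThresholdSearchError

    beliefs = _normalize_all(score_matrices, model.normalization)
    try:
        best = search_threshold(model, beliefs, true_labels, metric, grid)
    except ThresholdSearchError:
        if metric != "itr":
            best = search_threshold(model, beliefs, true_labels, "itr", grid)
        else:
            raise
    model.abstention_threshold = best
    return model


@dataclass
class EvaluationReport:
    """Framework and per-base-classifier metrics on one test set."""

    framework_table: ConfusionTable
    framework_efficiency: float | None
    framework_itr: float
    base_efficiencies: list[float | None]
    base_itrs: list[float]
    base_accuracies: np.ndarray


def evaluate_model(
    model: FrameworkModel,
    score_matrices: list[ScoreMatrix],
    true_labels: np.ndarray,
) -> EvaluationReport:
    """Evaluate the fusion model and each base classifier on a test set.

    Base classifiers decide by per-classifier argmax over raw scores (no
    abstention); the framework decides by Choquet fusion with its margin
    rule.
    """
    true_labels = np.asarray(true_labels)
    class_ids = list(range(model.n))
    beliefs = _normalize_all(score_matrices, model.normalization)
    decisions = decide_batch(model, beliefs)
    framework_table = confusion_with_abstention(
        true_labels, [d.label for d in decisions], class_ids=class_ids
    )

    base_eff: list[float | None] = []
    base_itr: list[float] = []
    scores = np.stack([m.scores for m in score_matrices])
    for j in range(model.k):
        predictions = scores[:, j, :].argmax(axis=1)
        table = confusion_with_abstention(
            true_labels, predictions, class_ids=class_ids
        )
        base_eff.append(efficiency(table))
        base_itr.append(nykopp_itr(table))

    return EvaluationReport(
        framework_table=framework_table,
        framework_efficiency=efficiency(framework_table),
        framework_itr=nykopp_itr(framework_table),
        base_efficiencies=base_eff,
        base_itrs=base_itr,
        base_accuracies=accuracy_by_classifier(score_matrices, true_labels),
    )
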