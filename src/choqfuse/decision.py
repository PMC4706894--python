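"""Choquet fusion, class decision, and the reject option.

For each class the beliefs of its ensemble members are fused by the Choquet
integral with respect to the class capacity, giving a vector of class
likelihoods in ``[0, 1]``.  The decision rule outputs the argmax class
unless the two top-rated classes are too close in likelihood: when the
margin ``top1 - top2`` falls strictly below the abstention threshold the
system abstains instead of risking a misclassification.  A threshold of 0
therefore means "never abstain" (exact ties go to the lowest class index),
and raising the threshold can only convert decisions into abstentions —
errors are non-increasing and abstentions non-decreasing in the threshold,
which is the trade-off the reject option exists to navigate.

The threshold itself is tuned by grid search on validation data,
maximizing a chosen metric (efficiency by default, information transfer
rate as an alternative); grid points where the metric is not defined are
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .capacity import Capacity, choquet_integral
from .ensembles import Ensemble
from .normalization import BeliefMatrix, NormalizationConfig

__all__ = [
    "ABSTAIN",
    "Decision",
    "FrameworkModel",
    "aggregate_class_likelihoods",
    "decide",
    "search_threshold",
    "ThresholdSearchError",
]

ABSTAIN = "ABSTAIN"


class ThresholdSearchError(RuntimeError):
    """Raised when the tuning metric is undefined on the whole grid."""


@dataclass
class Decision:
    """Outcome for one sample: a class label or abstention, with the full
    likelihood vector and the top-two margin that drove the choice."""

    label: object
    class_likelihoods: np.ndarray
    margin: float


@dataclass
class FrameworkModel:
    """Trained fusion model: per-class ensembles and capacities, the
    one-vs-rest global capacities that built them, the normalization
    configuration, and the abstention threshold."""

    k: int
    n: int
    normalization: NormalizationConfig
    ensembles: list[Ensemble]
    class_capacities: list[Capacity]
    global_capacities: list[Capacity] = field(default_factory=list)
    abstention_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.abstention_threshold < 0:
            raise ValueError("abstention threshold must be non-negative")
        if len(self.ensembles) != self.n or len(self.class_capacities) != self.n:
            raise ValueError("need one ensemble and one capacity per class")
        for ens, cap in zip(self.ensembles, self.class_capacities):
            if cap.n_elements != len(ens.members):
                raise ValueError(
                    f"capacity for class {ens.class_id} is on "
                    f"{cap.n_elements} elements but the ensemble has "
                    f"{len(ens.members)} members"
                )


def aggregate_class_likelihoods(
    model: FrameworkModel, beliefs: BeliefMatrix
) -> np.ndarray:
    """Per-class Choquet fusion of ensemble-member beliefs.

    ``likelihood[i]`` integrates column ``i`` of the belief matrix,
    restricted to the rows of ensemble ``i``, against the class capacity.
    """
    b = beliefs.beliefs
    if b.shape != (model.k, model.n):
        raise ValueError(
            f"belief matrix has shape {b.shape}, expected "
            f"({model.k}, {model.n})"
        )
    out = np.empty(model.n)
    for i, (ens, cap) in enumerate(zip(model.ensembles, model.class_capacities)):
        out[i] = choquet_integral(cap, b[list(ens.members), i])
    return out


def decide(model: FrameworkModel, beliefs: BeliefMatrix) -> Decision:
    """Argmax-with-reject decision on one belief matrix."""
    likelihoods = aggregate_class_likelihoods(model, beliefs)
    order = np.argsort(likelihoods, kind="stable")
    top1 = order[-1]
    # ties at the maximum break toward the lowest class index
    top_val = likelihoods[top1]
    top1 = int(np.flatnonzero(likelihoods == top_val)[0])
    second = order[-2] if model.n >= 2 else top1
    margin = float(top_val - likelihoods[second]) if model.n >= 2 else top_val
    if margin < model.abstention_threshold:
        label: object = ABSTAIN
    else:
        label = top1
    return Decision(label=label, class_likelihoods=likelihoods, margin=margin)


def decide_batch(
    model: FrameworkModel, beliefs_by_sample: list[BeliefMatrix]
) -> list[Decision]:
    """Decide every sample in a list."""
    return [decide(model, bm) for bm in beliefs_by_sample]


def _labels_at_threshold(
    margins: np.ndarray, argmaxes: np.ndarray, threshold: float
) -> list:
    return [
        ABSTAIN if m < threshold else int(a)
        for m, a in zip(margins, argmaxes)
    ]


def search_threshold(
    model: FrameworkModel,
    beliefs_by_sample: list[BeliefMatrix],
    true_labels: np.ndarray,
    metric: str = "efficiency",
    grid: np.ndarray | None = None,
) -> float:
    """Grid-search the abstention threshold maximizing a validation metric.

    The likelihoods are computed once; every grid point only re-applies the
    margin rule.  Grid points where the metric is not defined are skipped;
    ties break toward the smallest threshold.  Raises
    :class:`ThresholdSearchError` if the metric is undefined everywhere.
    """
    from .metrics import confusion_with_abstention, efficiency, nykopp_itr

    if grid is None:
        grid = np.arange(0.0, 1.0 + 1e-9, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if metric not in ("efficiency", "itr"):
        raise ValueError(f"unknown tuning metric {metric!r}")

    decisions = [decide(model, bm) for bm in beliefs_by_sample]
    margins = np.array([d.margin for d in decisions])
    argmaxes = np.array(
        [int(np.argmax(d.class_likelihoods)) for d in decisions]
    )
    true_labels = np.asarray(true_labels)

    best_t, best_val = None, -np.inf
    for t in grid:
        labels = _labels_at_threshold(margins, argmaxes, t)
        table = confusion_with_abstention(
            true_labels, labels, class_ids=list(range(model.n))
        )
        val = efficiency(table) if metric == "efficiency" else nykopp_itr(table)
        if val is None:
            continue
        if val > best_val + 1e-12:
            best_t, best_val = float(t), float(val)
    if best_t is None:
        raise ThresholdSearchError(
            f"metric {metric!r} not defined at any of the {grid.size} "
            "grid points"
        )
    return best_t
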