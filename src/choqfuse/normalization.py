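"""Mapping raw classifier scores into a common belief space.

Measurement-level classifiers emit scores on incommensurable scales (a
Bayesian classifier outputs posterior probabilities, a margin classifier
outputs signed distances), so scores must be projected into one
classifier-independent space before fusion.  The projection used here, per
classifier and per classification event, is:

1. affine min-max rescaling of the row of class scores onto ``[-1, 1]``
   (minimum score to -1, maximum to +1);
2. a logistic sigmoid into ``(0, 1)`` centered at the crossover point,
   by default the midpoint of the two highest rescaled values.

The result is read as a degree of belief in "the input belongs to this
class": 0 is certain rejection, 1 certain membership.  Centering between the
two top scores deliberately compresses both toward 0.5 when they are nearly
tied, so that genuine ambiguity in a classifier's decision surfaces as
lowered beliefs.  The map is strictly increasing, hence rank-preserving
within every row, and is invariant to positive affine changes of the raw
score scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizationConfig",
    "ScoreMatrix",
    "BeliefMatrix",
    "linear_rescale",
    "sigmoid_project",
    "normalize_scores",
]

_DEGENERATE_EPS = 1e-12


@dataclass
class NormalizationConfig:
    """Sigmoid projection parameters.

    slope:
        Sigmoid slope factor λ.  Capped by ``slope_max``: an unbounded slope
        degenerates the sigmoid into a step and destroys the graded-belief
        semantics.
    crossover_rule:
        ``"midpoint_top2"`` centers the sigmoid midway between the two
        highest rescaled scores.  ``"optimized"`` is an extension point for
        a learned crossover; it is accepted but currently resolves to the
        midpoint rule.
    degenerate_belief:
        Belief assigned to every class when a row carries no information
        (all scores equal); 0.5 encodes maximal uncertainty between
        membership and non-membership.
    """

    slope: float = 2.0
    slope_max: float = 10.0
    crossover_rule: str = "midpoint_top2"
    degenerate_belief: float = 0.5

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.slope_max <= 0:
            raise ValueError("slope and slope_max must be positive")
        if self.slope > self.slope_max:
            raise ValueError(
                f"slope {self.slope} exceeds slope_max {self.slope_max}"
            )
        if self.crossover_rule not in ("midpoint_top2", "optimized"):
            raise ValueError(f"unknown crossover_rule {self.crossover_rule!r}")
        if not 0.0 <= self.degenerate_belief <= 1.0:
            raise ValueError("degenerate_belief must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_max": self.slope_max,
            "crossover_rule": self.crossover_rule,
            "degenerate_belief": self.degenerate_belief,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "NormalizationConfig":
        return cls(**data)


@dataclass
class ScoreMatrix:
    """Raw ``k x n`` classifier-by-class score matrix for one sample."""

    scores: np.ndarray
    classifier_ids: list[str] | None = None
    class_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D (k x n) matrix")
        k, n = self.scores.shape
        if k < 1 or n < 2:
            raise ValueError("need at least 1 classifier and 2 classes")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.classifier_ids is None:
            self.classifier_ids = [f"D{j}" for j in range(k)]
        if self.class_ids is None:
            self.class_ids = [f"C{i}" for i in range(n)]

    @property
    def k(self) -> int:
        return self.scores.shape[0]

    @property
    def n(self) -> int:
        return self.scores.shape[1]


@dataclass
class BeliefMatrix:
    """``k x n`` matrix of per-classifier class beliefs in ``[0, 1]``."""

    beliefs: np.ndarray

    def __post_init__(self) -> None:
        self.beliefs = np.asarray(self.beliefs, dtype=float)
        if self.beliefs.ndim != 2:
            raise ValueError("beliefs must be a 2-D (k x n) matrix")
        if np.any(self.beliefs < 0) or np.any(self.beliefs > 1):
            raise ValueError("beliefs must lie in [0, 1]")


def linear_rescale(row: np.ndarray) -> np.ndarray:
    """Affine map of a score row onto ``[-1, 1]`` (min to -1, max to +1).

    A constant row maps to all zeros, deferring the degenerate case to the
    sigmoid stage.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise ValueError("row must be a 1-D vector of at least 2 scores")
    if not np.all(np.isfinite(row)):
        raise ValueError("scores must be finite")
    lo, hi = row.min(), row.max()
    if hi - lo < _DEGENERATE_EPS:
        return np.zeros_like(row)
    return 2.0 * (row - lo) / (hi - lo) - 1.0


def sigmoid_project(
    rescaled: np.ndarray, config: NormalizationConfig | None = None
) -> np.ndarray:
    """Project rescaled scores in ``[-1, 1]`` into beliefs in ``(0, 1)``.

    Applies ``x -> 1 / (1 + exp(-lambda (x - c)))`` with crossover ``c`` at
    the midpoint of the two largest entries.  All-equal rows (no ranking
    information) map to ``config.degenerate_belief`` exactly.
    """
    if config is None:
        config = NormalizationConfig()
    x = np.asarray(rescaled, dtype=float)
    if np.ptp(x) < _DEGENERATE_EPS:
        return np.full_like(x, config.degenerate_belief)
    top2 = np.partition(x, -2)[-2:]
    crossover = 0.5 * (top2[0] + top2[1])
    return 1.0 / (1.0 + np.exp(-config.slope * (x - crossover)))


def normalize_scores(
    matrix: ScoreMatrix, config: NormalizationConfig | None = None
) -> BeliefMatrix:
    """Normalize every classifier's score row independently into beliefs."""
    if config is None:
        config = NormalizationConfig()
    beliefs = np.vstack(
        [sigmoid_project(linear_rescale(row), config) for row in matrix.scores]
    )
    return BeliefMatrix(beliefs)
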