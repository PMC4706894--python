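"""Synthetic measurement-level classifier scores for an n-class symbol task.

Real first-level scores come from heterogeneous classifiers run on
event-related EEG; here they are emulated by a Gaussian signal-plus-noise
model with exactly the two knobs the fusion framework's behavior depends
on: per-classifier *skill* and inter-classifier *correlation*.

For sample ``t`` with true class ``c_t`` drawn uniformly, classifier ``j``
scores class ``i`` as

.. math:: s_{j,i} = \\alpha_j \\, [i = c_t]
          + \\sigma (\\sqrt{\\rho}\\, z_{t,i}
          + \\sqrt{1-\\rho}\\, \\varepsilon_{t,j,i}),

with ``z`` a noise term shared by all classifiers and ``ε`` independent
per classifier, both standard normal.  ``α_j`` controls classifier ``j``'s
accuracy (0 = chance); ``ρ`` controls how much the classifiers' mistakes
coincide — at ``ρ → 1`` with equal skills they agree almost everywhere and
an ensemble has no diversity left to exploit.

The ``paper_like`` preset mirrors a 6-symbol session decoded by six base
classifiers of heterogeneous skill with moderately correlated errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .normalization import ScoreMatrix

__all__ = [
    "SimulationConfig",
    "paper_like_config",
    "simulate_dataset",
    "accuracy_by_classifier",
]


@dataclass
class SimulationConfig:
    """Generator parameters; see the module docstring for the model."""

    n_classes: int = 6
    k_classifiers: int = 6
    skills: tuple[float, ...] = (0.8, 1.1, 1.5, 1.9, 2.4, 3.0)
    correlation: float = 0.3
    noise_sd: float = 1.0
    n_samples: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.k_classifiers < 1:
            raise ValueError("need at least 1 classifier")
        if len(self.skills) != self.k_classifiers:
            raise ValueError(
                f"{self.k_classifiers} classifiers but "
                f"{len(self.skills)} skills"
            )
        if any(a < 0 for a in self.skills):
            raise ValueError("skills must be non-negative")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


def paper_like_config(seed: int = 0, n_samples: int = 500) -> SimulationConfig:
    """Six classes, six base classifiers with skills spanning weak to
    strong, moderately correlated errors (rho = 0.3)."""
    return SimulationConfig(seed=seed, n_samples=n_samples)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[ScoreMatrix], np.ndarray]:
    """Draw a dataset of per-sample score matrices and true labels.

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_classes, config.k_classifiers
    labels = rng.integers(0, n, size=config.n_samples)
    alphas = np.asarray(config.skills, dtype=float)
    shared = rng.standard_normal((config.n_samples, n))
    private = rng.standard_normal((config.n_samples, k, n))
    noise = config.noise_sd * (
        np.sqrt(config.correlation) * shared[:, None, :]
        + np.sqrt(1.0 - config.correlation) * private
    )
    signal = alphas[:, None] * np.eye(n)[labels][:, None, :]
    scores = signal + noise
    matrices = [ScoreMatrix(scores[t]) for t in range(config.n_samples)]
    return matrices, labels


def accuracy_by_classifier(
    score_matrices: list[ScoreMatrix], labels: np.ndarray
) -> np.ndarray:
    """Per-classifier argmax accuracy over the dataset."""
    labels = np.asarray(labels)
    if len(score_matrices) != labels.shape[0]:
        raise ValueError("number of samples and labels differ")
    scores = np.stack([m.scores for m in score_matrices])  # T x k x n
    predictions = scores.argmax(axis=2)  # T x k
    return (predictions == labels[:, None]).mean(axis=0)
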