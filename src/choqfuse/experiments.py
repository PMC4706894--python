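"""Replicated synthetic studies of fusion versus base classifiers.

The central empirical claim for the fusion framework is comparative: on a
multi-class task served by heterogeneous base classifiers, the fused system
should perform clearly above the *average* base classifier (and near the
best one), because capacity learning concentrates weight on the classifiers
and coalitions that actually help.  This module runs that comparison as a
seeded replicate study on the synthetic score generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .metrics import nd_skipping_mean
from .pipeline import evaluate_model, train_model
from .simulate import paper_like_config, simulate_dataset

__all__ = ["ReplicateResult", "StudySummary", "fusion_vs_average_study"]

_TEST_SEED_OFFSET = 10_000  # keeps train/test streams disjoint per replicate


@dataclass
class ReplicateResult:
    seed: int
    framework_efficiency: float | None
    framework_itr: float
    mean_base_efficiency: float
    mean_base_itr: float
    best_base_efficiency: float
    best_base_itr: float


@dataclass
class StudySummary:
    replicates: list[ReplicateResult]

    @property
    def efficiency_win_fraction(self) -> float:
        """Fraction of replicates with framework efficiency at or above the
        ND-skipping mean of the base classifiers'."""
        wins = [
            r.framework_efficiency is not None
            and r.framework_efficiency >= r.mean_base_efficiency
            for r in self.replicates
        ]
        return float(np.mean(wins))

    @property
    def itr_win_fraction(self) -> float:
        wins = [r.framework_itr >= r.mean_base_itr for r in self.replicates]
        return float(np.mean(wins))

    def mean_improvement_vs_average(self) -> tuple[float, float]:
        """Mean percent improvement (efficiency, ITR) over the average base
        classifier, across replicates where the framework efficiency is
        defined."""
        eff = [
            100.0
            * (r.framework_efficiency - r.mean_base_efficiency)
            / r.mean_base_efficiency
            for r in self.replicates
            if r.framework_efficiency is not None
        ]
        itr = [
            100.0 * (r.framework_itr - r.mean_base_itr) / r.mean_base_itr
            for r in self.replicates
        ]
        return float(np.mean(eff)), float(np.mean(itr))


def run_replicate(
    seed: int, n_train: int = 500, n_test: int = 500
) -> ReplicateResult:
    """Train on one synthetic draw, evaluate framework and bases on a
    disjoint draw."""
    config = paper_like_config(seed=seed, n_samples=n_train)
    train_matrices, train_labels = simulate_dataset(config)
    model = train_model(train_matrices, train_labels)
    test_config = replace(
        config, seed=seed + _TEST_SEED_OFFSET, n_samples=n_test
    )
    test_matrices, test_labels = simulate_dataset(test_config)
    report = evaluate_model(model, test_matrices, test_labels)
    return ReplicateResult(
        seed=seed,
        framework_efficiency=report.framework_efficiency,
        framework_itr=report.framework_itr,
        mean_base_efficiency=nd_skipping_mean(report.base_efficiencies),
        mean_base_itr=float(np.mean(report.base_itrs)),
        best_base_efficiency=max(
            v for v in report.base_efficiencies if v is not None
        ),
        best_base_itr=max(report.base_itrs),
    )


def fusion_vs_average_study(
    n_replicates: int = 20,
    base_seed: int = 0,
    n_train: int = 500,
    n_test: int = 500,
) -> StudySummary:
    """Run the seeded replicate study (default 20 replicates, 500 test
    samples each, six classes and six heterogeneous base classifiers)."""
    results = [
        run_replicate(base_seed + r, n_train=n_train, n_test=n_test)
        for r in range(n_replicates)
    ]
    return StudySummary(results)
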