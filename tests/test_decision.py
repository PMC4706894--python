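"""Choquet fusion, margin-based abstention, and threshold tuning."""

import numpy as np
import pytest

from choqfuse.capacity import Capacity, choquet_integral
from choqfuse.decision import (
    ABSTAIN,
    FrameworkModel,
    ThresholdSearchError,
    aggregate_class_likelihoods,
    decide,
    search_threshold,
)
from choqfuse.ensembles import Ensemble
from choqfuse.metrics import confusion_with_abstention, efficiency
from choqfuse.normalization import BeliefMatrix, NormalizationConfig

from conftest import random_monotone_capacity


def _model(ensembles, capacities, k, n, threshold=0.0):
    return FrameworkModel(
        k=k,
        n=n,
        normalization=NormalizationConfig(),
        ensembles=ensembles,
        class_capacities=capacities,
        abstention_threshold=threshold,
    )


def _singleton_model(k, n, threshold=0.0):
    ensembles = [
        Ensemble(class_id=i, members=[i % k], s=1) for i in range(n)
    ]
    capacities = [Capacity.additive([1.0]) for _ in range(n)]
    return _model(ensembles, capacities, k, n, threshold)


class TestAggregate:
    def test_singleton_identity_pass_through(self, rng):
        model = _singleton_model(3, 3)
        beliefs = BeliefMatrix(rng.uniform(0, 1, (3, 3)))
        out = aggregate_class_likelihoods(model, beliefs)
        assert out == pytest.approx(np.diag(beliefs.beliefs))

    def test_uniform_pair_is_mean(self, rng):
        ensembles = [Ensemble(class_id=0, members=[0, 2], s=2)]
        capacities = [Capacity.additive([0.5, 0.5])]
        model = _model(ensembles, capacities, k=3, n=1)
        beliefs = BeliefMatrix(rng.uniform(0, 1, (3, 1)))
        out = aggregate_class_likelihoods(model, beliefs)
        expected = 0.5 * (beliefs.beliefs[0, 0] + beliefs.beliefs[2, 0])
        assert out[0] == pytest.approx(expected)

    def test_matches_per_class_choquet_oracle(self, rng):
        k, n = 4, 3
        ensembles, capacities = [], []
        for i in range(n):
            members = sorted(
                rng.choice(k, size=int(rng.integers(1, 4)), replace=False)
            )
            ensembles.append(
                Ensemble(class_id=i, members=[int(m) for m in members],
                         s=len(members))
            )
            capacities.append(random_monotone_capacity(rng, len(members)))
        model = _model(ensembles, capacities, k, n)
        beliefs = BeliefMatrix(rng.uniform(0, 1, (k, n)))
        out = aggregate_class_likelihoods(model, beliefs)
        for i in range(n):
            expected = choquet_integral(
                capacities[i], beliefs.beliefs[ensembles[i].members, i]
            )
            assert out[i] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        model = _singleton_model(3, 3)
        with pytest.raises(ValueError):
            aggregate_class_likelihoods(
                model, BeliefMatrix(rng.uniform(0, 1, (2, 3)))
            )


class TestDecide:
    def test_clear_winner(self):
        model = _singleton_model(3, 3, threshold=0.1)
        beliefs = BeliefMatrix(np.diag([0.9, 0.2, 0.1]))
        decision = decide(model, beliefs)
        assert decision.label == 0
        assert decision.margin == pytest.approx(0.7)

    def test_close_race_abstains(self):
        model = _singleton_model(2, 2, threshold=0.1)
        beliefs = BeliefMatrix(np.diag([0.55, 0.50]))
        decision = decide(model, beliefs)
        assert decision.label == ABSTAIN
        assert decision.margin == pytest.approx(0.05)

    def test_threshold_above_one_always_abstains(self, rng):
        model = _singleton_model(3, 3, threshold=1.01)
        for _ in range(10):
            beliefs = BeliefMatrix(rng.uniform(0, 1, (3, 3)))
            assert decide(model, beliefs).label == ABSTAIN

    def test_exact_tie_goes_to_lowest_class(self):
        model = _singleton_model(2, 2, threshold=0.0)
        beliefs = BeliefMatrix(np.diag([0.7, 0.7]))
        decision = decide(model, beliefs)
        assert decision.label == 0
        assert decision.margin == 0.0


class TestSearchThreshold:
    @staticmethod
    def _validation(rng, model, T=120):
        # informative beliefs: the true class's diagonal entry is boosted,
        # so correct decisions dominate and the efficiency is defined
        labels = rng.integers(0, 2, T)
        beliefs = []
        for y in labels:
            b = rng.uniform(0, 0.6, (2, 2))
            b[y, y] = rng.uniform(0.6, 1.0)
            beliefs.append(BeliefMatrix(b))
        return beliefs, labels

    def test_single_point_grid(self, rng):
        model = _singleton_model(2, 2)
        beliefs, labels = self._validation(rng, model)
        assert search_threshold(
            model, beliefs, labels, grid=np.array([0.2])
        ) == pytest.approx(0.2)

    def test_argmax_matches_brute_force_recomputation(self, rng):
        model = _singleton_model(2, 2)
        beliefs, labels = self._validation(rng, model)
        grid = np.arange(0, 1.001, 0.05)
        best = search_threshold(model, beliefs, labels, "efficiency", grid)

        # independent recomputation: re-decide at every grid point
        scored = []
        for t in grid:
            model.abstention_threshold = float(t)
            outs = [decide(model, bm).label for bm in beliefs]
            table = confusion_with_abstention(labels, outs, class_ids=[0, 1])
            val = efficiency(table)
            if val is not None:
                scored.append((val, -t))
        model.abstention_threshold = 0.0
        expected = -max(scored)[1]
        assert best == pytest.approx(expected)

    def test_error_and_abstention_curves_monotone(self, rng):
        model = _singleton_model(3, 3)
        beliefs = [BeliefMatrix(rng.uniform(0, 1, (3, 3))) for _ in range(200)]
        labels = rng.integers(0, 3, 200)
        errors, abstentions = [], []
        for t in np.arange(0, 1.001, 0.02):
            model.abstention_threshold = float(t)
            outs = [decide(model, bm).label for bm in beliefs]
            n_abstain = sum(1 for o in outs if o == ABSTAIN)
            n_err = sum(
                1 for o, y in zip(outs, labels) if o != ABSTAIN and o != y
            )
            errors.append(n_err)
            abstentions.append(n_abstain)
        assert all(e2 <= e1 for e1, e2 in zip(errors, errors[1:]))
        assert all(a2 >= a1 for a1, a2 in zip(abstentions, abstentions[1:]))

    def test_all_nd_grid_raises(self):
        model = _singleton_model(2, 2)
        # every decision wrong -> efficiency ND at every threshold
        beliefs = [BeliefMatrix(np.array([[0.9, 0.1], [0.9, 0.1]]))] * 10
        labels = np.ones(10, dtype=int)
        with pytest.raises(ThresholdSearchError):
            search_threshold(
                model, beliefs, labels, "efficiency", np.array([0.0])
            )
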