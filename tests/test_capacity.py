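"""Capacity representation and the three set-function operators, certified
against literal brute-force evaluation of their definitions."""

import numpy as np
import pytest

from choqfuse.capacity import (
    Capacity,
    check_monotonicity,
    choquet_integral,
    extended_interaction_index,
    measure_value,
    mobius_support_size,
    shapley_values,
)

from conftest import (
    choquet_literal,
    interaction_literal,
    mu_table_from_mobius,
    murofushi_soneda_pairwise,
    random_2additive_capacity,
    random_monotone_capacity,
    shapley_literal,
    subsets,
)

TOL = 1e-12


class TestMeasureValue:
    def test_additive_sum(self):
        cap = Capacity(2, 1, {(0,): 0.5, (1,): 0.5})
        assert measure_value(cap, (0, 1)) == pytest.approx(1.0, abs=TOL)

    def test_empty_set_is_zero(self, rng):
        cap = random_monotone_capacity(rng, 4)
        assert measure_value(cap, ()) == 0.0

    def test_out_of_range_element(self):
        cap = Capacity.additive([0.5, 0.5])
        with pytest.raises(IndexError):
            measure_value(cap, (0, 2))

    def test_matches_direct_tabulation(self, rng):
        for _ in range(10):
            cap = random_2additive_capacity(rng, 4)
            table = mu_table_from_mobius(cap.mobius, 4)
            for a in subsets(range(4)):
                assert measure_value(cap, a) == pytest.approx(
                    table[a], abs=TOL
                )

    def test_monotone_in_inclusion(self, rng):
        cap = random_monotone_capacity(rng, 4)
        for a in subsets(range(4)):
            for b in subsets(range(4)):
                if set(a) <= set(b):
                    assert (
                        measure_value(cap, a)
                        <= measure_value(cap, b) + TOL
                    )


class TestChoquetIntegral:
    def test_additive_reduces_to_weighted_mean(self):
        cap = Capacity.additive([0.5, 0.5])
        assert choquet_integral(cap, [0.2, 0.8]) == pytest.approx(0.5, abs=TOL)

    def test_max_and_min_limit_capacities(self):
        # build from explicit mu tables via the conftest inverse transform
        from conftest import mobius_from_mu

        mu_max = {c: (1.0 if c else 0.0) for c in subsets(range(3))}
        mu_min = {c: (1.0 if len(c) == 3 else 0.0) for c in subsets(range(3))}
        max_cap = Capacity(3, 3, mobius_from_mu(mu_max, 3), normalized=True)
        min_cap = Capacity(3, 3, mobius_from_mu(mu_min, 3), normalized=True)
        f = [0.3, 0.7, 0.1]
        assert choquet_integral(max_cap, f) == pytest.approx(0.7, abs=TOL)
        assert choquet_integral(min_cap, f) == pytest.approx(0.1, abs=TOL)

    def test_matches_literal_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 6))
            cap = (
                random_monotone_capacity(rng, n)
                if rng.uniform() < 0.5
                else random_2additive_capacity(rng, n)
            )
            f = rng.uniform(0, 1, n)
            table = mu_table_from_mobius(cap.mobius, n)
            assert choquet_integral(cap, f) == pytest.approx(
                choquet_literal(table, f), abs=TOL
            )

    def test_bounded_and_idempotent(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 6))
            cap = random_monotone_capacity(rng, n)
            f = rng.uniform(0, 1, n)
            value = choquet_integral(cap, f)
            assert f.min() - TOL <= value <= f.max() + TOL
            c = float(rng.uniform(0, 1))
            assert choquet_integral(cap, np.full(n, c)) == pytest.approx(
                c, abs=TOL
            )

    def test_comonotone_pointwise_monotone(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 6))
            cap = random_monotone_capacity(rng, n)
            f = rng.uniform(0, 1, n)
            g = f + rng.uniform(0, 0.5, n)
            assert choquet_integral(cap, f) <= choquet_integral(cap, g) + TOL

    def test_tie_value_invariance(self, rng):
        # equal entries contribute zero increments, so the sorted-order tie
        # rule cannot change the value: permuting a constant block is a no-op
        cap = random_monotone_capacity(rng, 4)
        f = np.array([0.4, 0.4, 0.4, 0.9])
        table = mu_table_from_mobius(cap.mobius, 4)
        assert choquet_integral(cap, f) == pytest.approx(
            choquet_literal(table, f), abs=TOL
        )

    def test_rejects_negative_and_misshaped_integrands(self):
        cap = Capacity.additive([0.5, 0.5])
        with pytest.raises(ValueError):
            choquet_integral(cap, [-0.1, 0.5])
        with pytest.raises(ValueError):
            choquet_integral(cap, [0.1, 0.5, 0.7])


class TestShapley:
    def test_additive_weights_recovered(self):
        cap = Capacity.additive([0.2, 0.3, 0.5])
        assert shapley_values(cap) == pytest.approx([0.2, 0.3, 0.5], abs=TOL)

    def test_symmetric_capacity_uniform(self):
        from conftest import mobius_from_mu

        mu = {c: (len(c) / 3) ** 2 for c in subsets(range(3))}
        cap = Capacity(3, 3, mobius_from_mu(mu, 3), normalized=True)
        assert shapley_values(cap) == pytest.approx([1 / 3] * 3, abs=TOL)

    def test_matches_literal_oracle_and_efficiency(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 6))
            cap = random_monotone_capacity(rng, n)
            table = mu_table_from_mobius(cap.mobius, n)
            v = shapley_values(cap)
            assert v == pytest.approx(shapley_literal(table, n), abs=TOL)
            assert v.sum() == pytest.approx(
                measure_value(cap, tuple(range(n))), abs=TOL
            )


class TestInteractionIndex:
    def test_singleton_equals_shapley(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 6))
            cap = random_monotone_capacity(rng, n)
            v = shapley_values(cap)
            for i in range(n):
                assert extended_interaction_index(cap, (i,)) == pytest.approx(
                    v[i], abs=TOL
                )

    def test_additive_pairs_have_zero_synergy(self):
        cap = Capacity.additive([0.2, 0.3, 0.5])
        assert extended_interaction_index(cap, (0, 1)) == pytest.approx(
            0.0, abs=TOL
        )

    def test_matches_literal_oracle_and_pairwise_index(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 6))
            cap = random_monotone_capacity(rng, n)
            table = mu_table_from_mobius(cap.mobius, n)
            pair = tuple(
                sorted(rng.choice(n, size=2, replace=False).tolist())
            )
            value = extended_interaction_index(cap, pair)
            assert value == pytest.approx(
                interaction_literal(table, n, pair), abs=TOL
            )
            assert value == pytest.approx(
                murofushi_soneda_pairwise(table, n, *pair), abs=TOL
            )

    def test_triple_coalition_against_literal(self, rng):
        cap = random_monotone_capacity(rng, 5)
        table = mu_table_from_mobius(cap.mobius, 5)
        assert extended_interaction_index(cap, (0, 2, 4)) == pytest.approx(
            interaction_literal(table, 5, (0, 2, 4)), abs=TOL
        )

    def test_empty_coalition_rejected(self):
        cap = Capacity.additive([0.5, 0.5])
        with pytest.raises(ValueError):
            extended_interaction_index(cap, ())


class TestMobiusSupportSize:
    @pytest.mark.parametrize(
        "n,k,expected",
        [(6, 2, 21), (6, 6, 63), (4, 4, 15), (6, 1, 6), (5, 5, 31)],
    )
    def test_counts(self, n, k, expected):
        assert mobius_support_size(n, k) == expected

    def test_out_of_range_order(self):
        with pytest.raises(ValueError):
            mobius_support_size(4, 5)
        with pytest.raises(ValueError):
            mobius_support_size(4, 0)


class TestCheckMonotonicity:
    def test_additive_positive_weights_clean(self):
        assert check_monotonicity(Capacity.additive([0.3, 0.7])) == []

    def test_reports_negative_marginal(self):
        cap = Capacity(2, 2, {(0,): 0.8, (1,): 0.8, (0, 1): -0.9})
        violations = check_monotonicity(cap)
        assert ((0, (1,)) in [(v[0], v[1]) for v in violations])
        margins = {(v[0], v[1]): v[2] for v in violations}
        assert margins[(0, (1,))] == pytest.approx(-0.1, abs=TOL)

    def test_random_monotone_capacities_clean(self, rng):
        for _ in range(10):
            cap = random_monotone_capacity(rng, 4)
            assert check_monotonicity(cap, tolerance=1e-10) == []


class TestSerialization:
    def test_round_trip(self, rng):
        cap = random_2additive_capacity(rng, 4)
        restored = Capacity.from_json(cap.to_json())
        assert restored.n_elements == cap.n_elements
        assert restored.order == cap.order
        assert restored.normalized == cap.normalized
        assert restored.mobius == cap.mobius

    def test_canonical_keys(self):
        cap = Capacity(3, 2, {(2, 0): 0.4, (1,): 0.6})
        assert "0,2" in cap.to_dict()["mobius"]
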