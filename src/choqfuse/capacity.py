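"""Fuzzy measures (capacities) in Möbius representation and their operators.

A capacity is a monotone set function :math:`\\mu` on a finite ground set
``X = {0, ..., n-1}`` with :math:`\\mu(\\emptyset) = 0`.  In classifier
fusion the ground set indexes the base classifiers and :math:`\\mu(A)`
expresses the worth of coalition ``A``, including positive or negative
synergy that an additive weight vector cannot represent.

The representation here is Möbius-first: a capacity is stored as its Möbius
coefficients ``m(B)`` over nonempty coalitions, so that

.. math:: \\mu(A) = \\sum_{B \\subseteq A} m(B).

``k``-additivity — the standard complexity-control device for capacities —
then becomes a plain storage truncation: coefficients vanish on coalitions
larger than ``k``, leaving :math:`\\sum_{i=1}^{k} \\binom{n}{i}` free
parameters instead of :math:`2^n - 1`.

The three classical set-function operators are provided:

* the **Choquet integral**, the aggregation operator that integrates a
  non-negative score vector against the capacity via sorted level sets;
* the **Shapley value**, the average marginal contribution of each element
  (importance index), which sums to :math:`\\mu(X)`;
* the **extended interaction index**, a signed measure of the synergy of a
  coalition that generalizes the Shapley value (singletons) and the
  Murofushi–Soneda pairwise index (pairs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Capacity",
    "all_coalitions",
    "measure_value",
    "choquet_integral",
    "shapley_values",
    "extended_interaction_index",
    "mobius_support_size",
    "check_monotonicity",
]

Coalition = tuple[int, ...]


def _canon(members: Iterable[int]) -> Coalition:
    """Canonical (sorted, duplicate-free) form of a coalition."""
    out = tuple(sorted(set(int(i) for i in members)))
    return out


def all_coalitions(n: int, max_size: int) -> list[Coalition]:
    """All nonempty coalitions of ``{0,...,n-1}`` up to ``max_size``.

    Ordered by size then lexicographically, which is the canonical column
    order used throughout learning and serialization.
    """
    out: list[Coalition] = []
    for size in range(1, max_size + 1):
        out.extend(combinations(range(n), size))
    return out


def mobius_support_size(n: int, k: int) -> int:
    """Number of Möbius coefficients of a ``k``-additive capacity on ``n``
    elements: :math:`\\sum_{i=1}^{k} \\binom{n}{i}`; ``k = n`` gives the
    unrestricted count :math:`2^n - 1`.
    """
    if not 1 <= k <= n:
        raise ValueError(f"additivity order k={k} must lie in [1, {n}]")
    return sum(math.comb(n, i) for i in range(1, k + 1))


@dataclass
class Capacity:
    """A (possibly ``k``-additive) capacity stored by Möbius coefficients.

    Parameters
    ----------
    n_elements:
        Size of the ground set.
    order:
        Additivity order ``k``; coefficients exist only for coalitions of
        size at most ``k``.  ``order == n_elements`` means unrestricted.
    mobius:
        Mapping from canonical coalition tuples to coefficients ``m(B)``.
        Missing coalitions have coefficient zero; the empty set has no
        coefficient, so :math:`\\mu(\\emptyset) = 0` by construction.
    normalized:
        Declares :math:`\\sum_B m(B) = \\mu(X) = 1`.
    """

    n_elements: int
    order: int
    mobius: dict[Coalition, float] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be positive")
        if not 1 <= self.order <= self.n_elements:
            raise ValueError(
                f"order {self.order} outside [1, {self.n_elements}]"
            )
        canon: dict[Coalition, float] = {}
        for coal, coeff in self.mobius.items():
            c = _canon(coal)
            if not c:
                raise ValueError("empty coalition has no Möbius coefficient")
            if c[-1] >= self.n_elements or c[0] < 0:
                raise IndexError(f"coalition {c} outside ground set")
            if len(c) > self.order:
                raise ValueError(
                    f"coalition {c} exceeds additivity order {self.order}"
                )
            canon[c] = canon.get(c, 0.0) + float(coeff)
        self.mobius = canon

    # -- construction helpers -------------------------------------------------

    @classmethod
    def additive(cls, weights: Iterable[float]) -> "Capacity":
        """1-additive capacity from singleton weights."""
        w = [float(x) for x in weights]
        mob = {(i,): wi for i, wi in enumerate(w)}
        return cls(
            n_elements=len(w),
            order=1,
            mobius=mob,
            normalized=abs(sum(w) - 1.0) < 1e-12,
        )

    @classmethod
    def from_vector(
        cls,
        n_elements: int,
        order: int,
        coeffs: np.ndarray,
        normalized: bool = False,
    ) -> "Capacity":
        """Capacity from a coefficient vector in canonical coalition order."""
        coals = all_coalitions(n_elements, order)
        if len(coeffs) != len(coals):
            raise ValueError(
                f"expected {len(coals)} coefficients, got {len(coeffs)}"
            )
        mob = {c: float(v) for c, v in zip(coals, coeffs)}
        return cls(n_elements, order, mob, normalized)

    def to_vector(self) -> np.ndarray:
        """Coefficient vector in canonical coalition order."""
        coals = all_coalitions(self.n_elements, self.order)
        return np.array([self.mobius.get(c, 0.0) for c in coals])

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        mob = {
            ",".join(str(i) for i in c): self.mobius[c]
            for c in sorted(self.mobius, key=lambda c: (len(c), c))
        }
        return {
            "n": self.n_elements,
            "k": self.order,
            "normalized": self.normalized,
            "mobius": mob,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Capacity":
        mob = {
            tuple(int(i) for i in key.split(",")): float(v)
            for key, v in data["mobius"].items()
        }
        return cls(
            n_elements=int(data["n"]),
            order=int(data["k"]),
            mobius=mob,
            normalized=bool(data["normalized"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "Capacity":
        return cls.from_dict(json.loads(text))


def measure_value(capacity: Capacity, subset: Iterable[int]) -> float:
    """Evaluate :math:`\\mu(A) = \\sum_{B \\subseteq A} m(B)`."""
    members = _canon(subset)
    if members and members[-1] >= capacity.n_elements:
        raise IndexError(
            f"element {members[-1]} outside ground set of size "
            f"{capacity.n_elements}"
        )
    s = set(members)
    return sum(
        coeff for coal, coeff in capacity.mobius.items() if s.issuperset(coal)
    )


def choquet_integral(capacity: Capacity, f: Iterable[float]) -> float:
    """Choquet integral of a non-negative integrand ``f`` w.r.t. the capacity.

    Sorting the elements so that ``f`` is ascending (ties broken by ascending
    element index; the value is invariant to the tie rule since equal
    increments contribute zero), with :math:`f(x_{(0)}) = 0` and
    :math:`A_i = \\{x_{(i)}, \\ldots, x_{(n)}\\}` the upper-level set:

    .. math:: (C)\\!\\int f \\, d\\mu
              = \\sum_i (f(x_{(i)}) - f(x_{(i-1)})) \\, \\mu(A_i).

    For an additive capacity this reduces to the weighted arithmetic mean.
    """
    values = np.asarray(list(f), dtype=float)
    if values.shape != (capacity.n_elements,):
        raise ValueError(
            f"integrand has shape {values.shape}, expected "
            f"({capacity.n_elements},)"
        )
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise ValueError("integrand entries must be finite and non-negative")
    order = np.lexsort((np.arange(len(values)), values))
    total = 0.0
    prev = 0.0
    for pos, idx in enumerate(order):
        fi = values[idx]
        if fi > prev:
            total += (fi - prev) * measure_value(capacity, order[pos:])
            prev = fi
    return total


def shapley_values(capacity: Capacity) -> np.ndarray:
    """Shapley importance of every element: :math:`v_i = \\sum_{B \\ni i}
    m(B) / |B|`.  Efficiency holds by construction:
    :math:`\\sum_i v_i = \\sum_B m(B) = \\mu(X)`.
    """
    v = np.zeros(capacity.n_elements)
    for coal, coeff in capacity.mobius.items():
        share = coeff / len(coal)
        for i in coal:
            v[i] += share
    return v


def extended_interaction_index(
    capacity: Capacity, s_coalition: Iterable[int]
) -> float:
    """Extended (generalized) interaction index of a coalition ``S``.

    In Möbius form :math:`I_S = \\sum_{B \\supseteq S} m(B) / (|B| - |S| + 1)`.
    For ``|S| = 1`` this is the Shapley value of the element; for ``|S| = 2``
    it is the Murofushi–Soneda pairwise interaction index; it vanishes for
    coalitions of two or more elements under an additive capacity.
    """
    s = set(_canon(s_coalition))
    if not s:
        raise ValueError("interaction index of the empty coalition is undefined")
    if max(s) >= capacity.n_elements:
        raise IndexError("coalition outside ground set")
    total = 0.0
    for coal, coeff in capacity.mobius.items():
        if s.issubset(coal):
            total += coeff / (len(coal) - len(s) + 1)
    return total


def check_monotonicity(
    capacity: Capacity, tolerance: float = 1e-8
) -> list[tuple[int, Coalition, float]]:
    """List monotonicity violations ``(element, subset, margin)``.

    For every element ``x`` and every ``A ⊆ X∖{x}`` the marginal
    :math:`\\mu(A \\cup \\{x\\}) - \\mu(A) = \\sum_{B \\subseteq A}
    m(B \\cup \\{x\\})` must be non-negative.  A triple is reported whenever
    the margin falls below ``-tolerance``; an empty list certifies the
    capacity monotone within tolerance.
    """
    n = capacity.n_elements
    violations: list[tuple[int, Coalition, float]] = []
    for x in range(n):
        rest = [i for i in range(n) if i != x]
        for size in range(len(rest) + 1):
            for a in combinations(rest, size):
                a_set = set(a)
                margin = sum(
                    coeff
                    for coal, coeff in capacity.mobius.items()
                    if x in coal and a_set.issuperset(c for c in coal if c != x)
                )
                if margin < -tolerance:
                    violations.append((x, tuple(a), margin))
    return violations
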