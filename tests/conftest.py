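"""Shared fixtures and independent brute-force oracles.

The oracles evaluate the textbook definitions of the set-function operators
literally over explicit mu tables, with no reliance on the package's Möbius
machinery, so they can certify the implementation.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from choqfuse.capacity import Capacity


# ---------------------------------------------------------------------------
# mu-table construction (independent of Capacity internals)

def subsets(elements):
    for size in range(len(elements) + 1):
        yield from combinations(elements, size)


def mu_table_from_mobius(mobius: dict, n: int) -> dict:
    """Tabulate mu over all subsets by summing Möbius terms directly."""
    table = {}
    for a in subsets(range(n)):
        s = set(a)
        table[a] = sum(
            coeff for coal, coeff in mobius.items() if s.issuperset(coal)
        )
    return table


def mobius_from_mu(mu: dict, n: int) -> dict:
    """Inverse Möbius transform: m(B) = sum_{C<=B} (-1)^{|B\\C|} mu(C)."""
    mob = {}
    for b in subsets(range(n)):
        if not b:
            continue
        total = 0.0
        for c in subsets(b):
            total += (-1) ** (len(b) - len(c)) * mu[c]
        mob[b] = total
    return mob


def random_monotone_capacity(rng: np.random.Generator, n: int) -> Capacity:
    """Random normalized monotone capacity via cumulative-max construction.

    mu(A) = max_{B subseteq A} u_B with independent uniforms u is monotone
    by construction; dividing by mu(X) normalizes it.
    """
    u = {a: rng.uniform(0, 1) for a in subsets(range(n)) if a}
    mu = {(): 0.0}
    for a in subsets(range(n)):
        if a:
            mu[a] = max(u[b] for b in subsets(a) if b)
    top = mu[tuple(range(n))]
    mu = {a: v / top for a, v in mu.items()}
    return Capacity(n, n, mobius_from_mu(mu, n), normalized=True)


def random_2additive_capacity(rng: np.random.Generator, n: int) -> Capacity:
    """Random normalized monotone 2-additive capacity (non-negative Möbius
    coefficients on singletons and pairs are sufficient for monotonicity)."""
    mob = {}
    for i in range(n):
        mob[(i,)] = rng.uniform(0.05, 1.0)
    for pair in combinations(range(n), 2):
        mob[pair] = rng.uniform(0.0, 0.5)
    total = sum(mob.values())
    mob = {c: v / total for c, v in mob.items()}
    return Capacity(n, 2, mob, normalized=True)


# ---------------------------------------------------------------------------
# literal definitional oracles over a mu table

def choquet_literal(mu: dict, f: np.ndarray) -> float:
    """Sorted-level-set evaluation of the Choquet integral."""
    n = len(f)
    order = sorted(range(n), key=lambda i: (f[i], i))
    total, prev = 0.0, 0.0
    for pos in range(n):
        fi = f[order[pos]]
        upper = tuple(sorted(order[pos:]))
        total += (fi - prev) * mu[upper]
        prev = fi
    return total


def shapley_literal(mu: dict, n: int) -> np.ndarray:
    """Average-marginal-contribution evaluation of the Shapley value."""
    v = np.zeros(n)
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        for a in subsets(rest):
            weight = (
                math.factorial(n - len(a) - 1)
                * math.factorial(len(a))
                / math.factorial(n)
            )
            with_i = tuple(sorted(a + (i,)))
            v[i] += weight * (mu[with_i] - mu[a])
    return v


def interaction_literal(mu: dict, n: int, s: tuple) -> float:
    """Double-sum evaluation of the extended interaction index."""
    s = tuple(sorted(s))
    rest = [j for j in range(n) if j not in s]
    total = 0.0
    for a in subsets(rest):
        weight = (
            math.factorial(n - len(a) - len(s))
            * math.factorial(len(a))
            / math.factorial(n - len(s) + 1)
        )
        inner = 0.0
        for b in subsets(s):
            inner += (-1) ** (len(s) - len(b)) * mu[tuple(sorted(a + b))]
        total += weight * inner
    return total


def murofushi_soneda_pairwise(mu: dict, n: int, x: int, y: int) -> float:
    """Pairwise interaction index of two elements, computed directly."""
    rest = [j for j in range(n) if j not in (x, y)]
    total = 0.0
    for a in subsets(rest):
        weight = (
            math.factorial(n - len(a) - 2)
            * math.factorial(len(a))
            / math.factorial(n - 1)
        )
        axy = tuple(sorted(a + (x, y)))
        ax = tuple(sorted(a + (x,)))
        ay = tuple(sorted(a + (y,)))
        total += weight * (mu[axy] - mu[ax] - mu[ay] + mu[a])
    return total


# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
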