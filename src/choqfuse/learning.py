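"""Capacity identification by constrained least squares.

The Choquet integral is linear in the Möbius coefficients:

.. math:: (C)\\!\\int f \\, d\\mu = \\sum_B m(B) \\min_{i \\in B} f_i,

so fitting a capacity to (belief vector, target) pairs is a least-squares
problem in ``m`` subject to linear constraints — monotonicity of the induced
measure and normalization :math:`\\sum_B m(B) = 1` — i.e. a convex quadratic
program.  Targets are one-vs-rest class indicators: 1 when the sample's true
class is the proposition's class, 0 otherwise, so the fitted integral output
behaves as a class-likelihood score.

A small ridge term (default 1e-6) keeps the Hessian positive definite when
the design is rank-deficient (small training sets, collinear classifiers),
guaranteeing a unique solution.  The QP is solved with SLSQP using analytic
gradients, with a trust-constr fallback; the returned coefficients are
rescaled by their sum, which enforces the normalization equality exactly and
preserves every monotonicity inequality (they are homogeneous in ``m``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from .capacity import Capacity, all_coalitions, check_monotonicity
from .ensembles import Ensemble, build_all_ensembles
from .normalization import BeliefMatrix

__all__ = [
    "TrainingSet",
    "OptimizationError",
    "build_design_row",
    "build_design_matrix",
    "monotonicity_matrix",
    "learn_capacity",
    "learn_all",
]

DEFAULT_RIDGE = 1e-6
CONSTRAINT_TOL = 1e-8


class OptimizationError(RuntimeError):
    """Raised when the capacity QP cannot be solved to feasibility."""


@dataclass
class TrainingSet:
    """Per-sample classifier beliefs and binary targets for one class
    proposition."""

    beliefs: np.ndarray  # T x k, entries in [0, 1]
    targets: np.ndarray  # T, entries in [0, 1]; {0,1} in one-vs-rest use
    sample_ids: list | None = None

    def __post_init__(self) -> None:
        self.beliefs = np.asarray(self.beliefs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.beliefs.ndim != 2:
            raise ValueError("beliefs must be T x k")
        if self.targets.shape != (self.beliefs.shape[0],):
            raise ValueError("targets length must match beliefs rows")
        if self.beliefs.shape[0] < 1:
            raise ValueError("training set must contain at least one sample")
        if np.any(self.targets < 0) or np.any(self.targets > 1):
            raise ValueError("targets must lie in [0, 1]")
        if np.any(self.beliefs < 0) or np.any(self.beliefs > 1):
            raise ValueError("beliefs must lie in [0, 1]")


def build_design_row(beliefs: np.ndarray, order: int) -> np.ndarray:
    """Design-row linearization of the Choquet integral.

    Entry for coalition ``B`` (canonical order) is ``min_{i in B}``
    of the beliefs, so the dot product with any Möbius vector of the same
    order equals the Choquet integral of that capacity at these beliefs.
    """
    beliefs = np.asarray(beliefs, dtype=float)
    k = beliefs.shape[0]
    if not 1 <= order <= k:
        raise ValueError(f"order {order} outside [1, {k}]")
    return np.array(
        [beliefs[list(c)].min() for c in all_coalitions(k, order)]
    )


def build_design_matrix(beliefs: np.ndarray, order: int) -> np.ndarray:
    """Stack design rows for a T x k belief matrix."""
    return np.vstack([build_design_row(row, order) for row in beliefs])


def monotonicity_matrix(k: int, order: int) -> np.ndarray:
    """Linear monotonicity constraints ``G m >= 0`` in canonical column order.

    One row per (element x, subset A of the rest): the marginal
    :math:`\\mu(A \\cup \\{x\\}) - \\mu(A) = \\sum_{B \\subseteq A}
    m(B \\cup \\{x\\})` must be non-negative.
    """
    from itertools import combinations

    coals = all_coalitions(k, order)
    col = {c: j for j, c in enumerate(coals)}
    rows = []
    for x in range(k):
        rest = [i for i in range(k) if i != x]
        for size in range(k):
            for a in combinations(rest, size):
                row = np.zeros(len(coals))
                a_set = set(a)
                for c, j in col.items():
                    if x in c and a_set.issuperset(i for i in c if i != x):
                        row[j] = 1.0
                rows.append(row)
    return np.vstack(rows)


def _solve_qp(
    H: np.ndarray,
    g: np.ndarray,
    G: np.ndarray,
    x0: np.ndarray,
) -> np.ndarray:
    """Minimize ``0.5 x'Hx + g'x`` s.t. ``Gx >= 0`` and ``sum(x) = 1``."""

    def fun(x: np.ndarray) -> float:
        return 0.5 * x @ H @ x + g @ x

    def jac(x: np.ndarray) -> np.ndarray:
        return H @ x + g

    ones = np.ones_like(x0)
    constraints = [
        {"type": "ineq", "fun": lambda x: G @ x, "jac": lambda x: G},
        {"type": "eq", "fun": lambda x: ones @ x - 1.0, "jac": lambda x: ones},
    ]
    res = minimize(
        fun,
        x0,
        jac=jac,
        method="SLSQP",
        constraints=constraints,
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    sol = res.x
    feasible = (
        res.success
        and G @ sol >= -CONSTRAINT_TOL
    )
    if not np.all(feasible) or abs(sol.sum() - 1.0) > 1e-6:
        res2 = minimize(
            fun,
            x0,
            jac=jac,
            method="trust-constr",
            constraints=[
                LinearConstraint(G, 0.0, np.inf),
                LinearConstraint(ones[None, :], 1.0, 1.0),
            ],
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000},
        )
        if res2.constr_violation < CONSTRAINT_TOL:
            sol = res2.x
        elif not res.success:
            raise OptimizationError(
                f"capacity QP failed: SLSQP status {res.status} "
                f"({res.message}); trust-constr violation "
                f"{res2.constr_violation:.2e}"
            )
    return sol


def learn_capacity(
    data: TrainingSet, order: int, ridge: float = DEFAULT_RIDGE
) -> Capacity:
    """Fit a normalized ``order``-additive capacity by constrained least
    squares.

    Minimizes :math:`\\sum_t (d_t \\cdot m - y_t)^2 + \\text{ridge}\\,
    \\lVert m \\rVert^2` over Möbius vectors subject to monotonicity and
    :math:`\\sum m = 1`.  The returned capacity is monotone within 1e-8 and
    normalized exactly.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    k = data.beliefs.shape[1]
    X = build_design_matrix(data.beliefs, order)
    y = data.targets
    T, p = X.shape
    # 1/T scaling keeps the objective O(1) so SLSQP's ftol is meaningful
    # regardless of training-set size
    H = 2.0 * (X.T @ X + ridge * np.eye(p)) / T
    g = -2.0 * X.T @ y / T
    G = monotonicity_matrix(k, order)

    x0 = np.zeros(p)
    x0[:k] = 1.0 / k  # uniform additive capacity: always feasible
    sol = _solve_qp(H, g, G, x0)
    # positive rescale: exact normalization, monotonicity preserved
    sol = sol / sol.sum()
    cap = Capacity.from_vector(k, order, sol, normalized=True)
    if check_monotonicity(cap, CONSTRAINT_TOL):
        raise OptimizationError("solver returned a non-monotone capacity")
    return cap


def learn_all(
    beliefs_by_sample: list[BeliefMatrix],
    true_classes: np.ndarray,
    class_order: int | None = None,
    global_order: int = 4,
    ridge: float = DEFAULT_RIDGE,
    ensemble_size: int | None = None,
) -> tuple[list[Capacity], list[Ensemble], list[Capacity]]:
    """Learn the full capacity hierarchy from training beliefs.

    For each class proposition, a one-vs-rest ``global_order``-additive
    capacity on all ``k`` classifiers is learned first; the class ensemble
    of ``ensemble_size`` classifiers is then built greedily from its
    interaction indices; finally a class capacity is learned on the
    ensemble members only (order ``class_order``, default unrestricted on
    the ensemble).

    Returns ``(global_capacities, ensembles, class_capacities)``, one entry
    per class.
    """
    if not beliefs_by_sample:
        raise ValueError("no training samples")
    true_classes = np.asarray(true_classes, dtype=int)
    k, n = beliefs_by_sample[0].beliefs.shape
    if ensemble_size is None:
        ensemble_size = min(4, k)
    g_order = min(global_order, k)

    stacked = np.stack([bm.beliefs for bm in beliefs_by_sample])  # T x k x n
    global_caps: list[Capacity] = []
    for cls in range(n):
        data = TrainingSet(
            beliefs=stacked[:, :, cls],
            targets=(true_classes == cls).astype(float),
        )
        global_caps.append(learn_capacity(data, g_order, ridge))

    ensembles = build_all_ensembles(
        global_caps, ensemble_size, class_ids=list(range(n))
    )

    class_caps: list[Capacity] = []
    for cls, ens in enumerate(ensembles):
        members = list(ens.members)
        order = len(members) if class_order is None else min(
            class_order, len(members)
        )
        data = TrainingSet(
            beliefs=stacked[:, members, cls],
            targets=(true_classes == cls).astype(float),
        )
        class_caps.append(learn_capacity(data, order, ridge))
    return global_caps, ensembles, class_caps
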