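"""Evaluation metrics for symbol-communication interfaces with a reject
option.

Two complementary metrics are provided on top of an (n classes) x (n + 1
outputs) confusion table whose last column counts abstentions.

**Efficiency** measures net progress in a copy-spelling task where every
error must be undone: with correct/error/abstention rates ``p_c, p_e, p_a``
(summing to 1) it is ``p_c - p_e``, the expected number of correctly
communicated symbols per emission.  When ``p_c <= p_e`` the user cannot make
net progress and the metric is *not defined* (ND, returned as ``None``);
ND entries are skipped when averaging across classifiers.  Abstentions cost
time but never require an undo, so they only drain probability mass from
``p_c + p_e``.

**Nykopp's information transfer rate** treats the confusion table as a
discrete memoryless channel from intended to decoded symbols, with
abstention as an (n+1)-th output symbol, and reports the channel capacity in
bits per symbol: the maximum of the mutual information over input
distributions, computed by Blahut–Arimoto alternating maximization.  Unlike
accuracy-based rates it credits a system for converting errors into
abstentions, which carry less misinformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision import ABSTAIN

__all__ = [
    "ConfusionTable",
    "confusion_with_abstention",
    "nykopp_itr",
    "efficiency",
    "percentage_improvement",
    "nd_skipping_mean",
]


@dataclass
class ConfusionTable:
    """``n x (n+1)`` counts of (true class, decided class-or-abstain)."""

    counts: np.ndarray
    class_ids: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.class_ids)
        if self.counts.shape != (n, n + 1):
            raise ValueError(
                f"counts must be {n} x {n + 1}, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def rates(self) -> tuple[float, float, float]:
        """Correct, error and abstention rates ``(p_c, p_e, p_a)``."""
        total = self.total
        if total == 0:
            raise ValueError("empty confusion table")
        n = len(self.class_ids)
        p_c = float(np.trace(self.counts[:, :n])) / total
        p_a = float(self.counts[:, n].sum()) / total
        return p_c, 1.0 - p_c - p_a, p_a


def confusion_with_abstention(
    true_labels, decisions, class_ids: list | None = None
) -> ConfusionTable:
    """Tally decisions (class ids or ``ABSTAIN``) against true labels."""
    true_labels = list(true_labels)
    decisions = list(decisions)
    if len(true_labels) != len(decisions):
        raise ValueError("true_labels and decisions differ in length")
    if class_ids is None:
        class_ids = sorted(set(true_labels))
    index = {c: i for i, c in enumerate(class_ids)}
    n = len(class_ids)
    counts = np.zeros((n, n + 1), dtype=int)
    for t, d in zip(true_labels, decisions):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if d == ABSTAIN:
            counts[index[t], n] += 1
        elif d in index:
            counts[index[t], index[d]] += 1
        else:
            raise ValueError(f"unknown decision label {d!r}")
    return ConfusionTable(counts=counts, class_ids=list(class_ids))


def _channel_capacity(P: np.ndarray, rel_tol: float = 1e-9,
                      max_iter: int = 200000) -> float:
    """Capacity (bits/use) of a row-stochastic channel by Blahut–Arimoto.

    Alternates between the optimal input distribution and the induced
    output distribution; the duality gap ``max_i c_i - I`` bounds the
    distance to capacity and drives the stopping rule.
    """
    m = P.shape[0]
    p = np.full(m, 1.0 / m)
    nz = P > 0
    logP = np.zeros_like(P)
    logP[nz] = np.log2(P[nz])
    capacity = 0.0
    for _ in range(max_iter):
        q = p @ P
        with np.errstate(divide="ignore"):
            logq = np.where(q > 0, np.log2(np.maximum(q, 1e-300)), 0.0)
        # c_i = D(P_i || q), the per-input information contribution
        c = np.einsum("ij,ij->i", P, np.where(nz, logP - logq[None, :], 0.0))
        lower = float(p @ c)
        upper = float(c.max())
        capacity = lower
        if upper - lower <= rel_tol * max(1.0, abs(upper)):
            break
        p = p * np.exp2(c - c.max())
        p /= p.sum()
    return max(capacity, 0.0)


def nykopp_itr(table: ConfusionTable) -> float:
    """Information transfer rate (bits/symbol): the capacity of the
    row-normalized confusion channel, abstention included as an output.

    Classes with no evaluated samples are dropped from the input alphabet.
    The result lies in ``[0, log2(n)]``.
    """
    counts = np.asarray(table.counts, dtype=float)
    row_sums = counts.sum(axis=1)
    used = row_sums > 0
    if not used.any():
        raise ValueError("empty confusion table")
    P = counts[used] / row_sums[used, None]
    return _channel_capacity(P)


def efficiency(table: ConfusionTable) -> float | None:
    """Copy-spelling efficiency ``p_c - p_e``; ``None`` (ND) when errors
    match or outweigh correct decisions and no effective communication is
    possible."""
    p_c, p_e, _ = table.rates()
    value = p_c - p_e
    return value if value > 0 else None


def percentage_improvement(value: float, reference: float) -> float:
    """Relative improvement of ``value`` over ``reference`` in percent."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (value - reference) / reference


def nd_skipping_mean(values) -> float:
    """Mean over a sequence where ND entries (``None``) are skipped."""
    kept = [v for v in values if v is not None]
    if not kept:
        raise ValueError("all entries are ND")
    return float(np.mean(kept))
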