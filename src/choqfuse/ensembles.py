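"""Greedy construction of class-specific classifier coalitions.

Each class gets an ensemble of at most ``s`` classifiers chosen from the
``k`` available, built on the principle that a good team is made of good
players that collaborate.  Selection is greedy on the extended interaction
index of the augmented coalition: starting from the empty ensemble, the
classifier maximizing :math:`I_{E \\cup \\{D\\}}` under the class's
one-vs-rest capacity is appended until the ensemble is full.  Because the
interaction index of a singleton is the Shapley value, the first member is
always the most important classifier for that class; for additive
(zero-interaction) capacities the whole ensemble reduces to the top-``s``
Shapley ranking.  Ties break toward the lowest classifier index so the
construction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .capacity import Capacity, extended_interaction_index

__all__ = ["Ensemble", "build_class_ensemble", "build_all_ensembles"]


@dataclass
class Ensemble:
    """Ordered coalition of classifiers attached to one class.

    ``members`` preserves selection order: the first entry is the Shapley
    maximizer for the class.
    """

    class_id: object
    members: list[int] = field(default_factory=list)
    s: int = 4

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("ensemble members must be distinct")
        if not 1 <= len(self.members) <= self.s:
            raise ValueError(
                f"ensemble size {len(self.members)} outside [1, {self.s}]"
            )

    def to_dict(self) -> dict:
        return {"class": self.class_id, "members": list(self.members)}


def build_class_ensemble(
    global_capacity: Capacity, s: int, class_id: object = None
) -> Ensemble:
    """Greedily select ``s`` classifiers by maximal augmented interaction.

    At each step the classifier ``D`` outside the current ensemble ``E``
    maximizing ``extended_interaction_index(capacity, E + [D])`` is
    appended.  Ensembles are always filled to ``s`` even if the marginal
    interaction is negative.
    """
    k = global_capacity.n_elements
    if not 1 <= s <= k:
        raise ValueError(f"ensemble size {s} outside [1, {k}]")
    members: list[int] = []
    while len(members) < s:
        best_idx, best_val = None, -np.inf
        for d in range(k):
            if d in members:
                continue
            val = extended_interaction_index(global_capacity, members + [d])
            if val > best_val + 1e-15 or best_idx is None:
                best_idx, best_val = d, val
        members.append(best_idx)
    return Ensemble(class_id=class_id, members=members, s=s)


def build_all_ensembles(
    global_capacities_per_class: list[Capacity],
    s: int,
    class_ids: list | None = None,
) -> list[Ensemble]:
    """One ensemble per class, each driven by that class's one-vs-rest
    capacity on the full classifier set."""
    if class_ids is None:
        class_ids = list(range(len(global_capacities_per_class)))
    return [
        build_class_ensemble(cap, s, class_id=cid)
        for cap, cid in zip(global_capacities_per_class, class_ids)
    ]
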