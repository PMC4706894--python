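"""Published benchmark results for a five-subject visual P300 speller study.

Offline efficiency and information-transfer-rate values for a BCI system
driven by each of six standard first-level classifiers (Bayesian LDA,
artificial neural network, shrunken regularized LDA, stepwise LDA, and
linear/RBF support vector machines) and by the Choquet-fusion framework,
for five healthy subjects (A–E).  ``None`` marks entries where the
classifier's error rate precluded effective communication, so the
efficiency is not defined (ND).

These tables serve as reference inputs for the improvement summaries:
the framework's percentage improvement over the ND-skipping average and
over the best first-level classifier, per subject and metric.
"""

from __future__ import annotations

from .metrics import nd_skipping_mean, percentage_improvement

__all__ = [
    "CLASSIFIERS",
    "SUBJECTS",
    "EFFICIENCY_BASE",
    "EFFICIENCY_FRAMEWORK",
    "ITR_BASE",
    "ITR_FRAMEWORK",
    "improvement_summary",
]

CLASSIFIERS = ("BLDA", "ANN", "SRLDA", "SWLDA", "SVM-LIN", "SVM-RBF")
SUBJECTS = ("A", "B", "C", "D", "E")

# Efficiency of the BCI system per first-level classifier; None = ND.
EFFICIENCY_BASE = {
    "A": (0.6821, 0.6690, 0.3277, 0.3392, 0.6986, 0.6519),
    "B": (0.5320, None, None, 0.3283, 0.2019, 0.3874),
    "C": (0.4194, 0.2131, 0.3235, 0.3166, 0.4559, 0.2084),
    "D": (0.4619, 0.4837, 0.2358, 0.2774, 0.5145, 0.4143),
    "E": (0.8272, 0.7979, 0.5948, 0.7873, 0.8046, 0.7729),
}
EFFICIENCY_FRAMEWORK = {
    "A": 0.6964,
    "B": 0.5121,
    "C": 0.3798,
    "D": 0.5789,
    "E": 0.8736,
}

# Nykopp ITR (bits/symbol) of the BCI system per first-level classifier.
ITR_BASE = {
    "A": (1.8800, 1.8885, 1.6434, 1.7259, 1.8424, 1.8341),
    "B": (1.5703, 1.1351, 0.9654, 1.2729, 1.0330, 1.3857),
    "C": (1.1983, 1.0374, 1.0845, 1.0617, 1.2053, 0.9610),
    "D": (1.5542, 1.4622, 1.4282, 1.2773, 1.4989, 1.4819),
    "E": (2.1422, 2.0673, 1.7038, 2.1059, 2.0801, 2.0202),
}
ITR_FRAMEWORK = {
    "A": 1.9133,
    "B": 1.5010,
    "C": 1.1899,
    "D": 1.5764,
    "E": 2.2532,
}


def improvement_summary() -> dict[str, dict[str, float]]:
    """Per-subject percentage improvement of the framework over the
    ND-skipping average and over the best first-level classifier, for both
    metrics, plus the min/max range across subjects.

    Returns a dict with keys ``efficiency_vs_average``,
    ``efficiency_vs_best``, ``itr_vs_average``, ``itr_vs_best``; each maps
    subject -> percent plus ``"min"``/``"max"`` entries.
    """
    out: dict[str, dict[str, float]] = {}
    for name, base_tbl, framework_tbl in (
        ("efficiency", EFFICIENCY_BASE, EFFICIENCY_FRAMEWORK),
        ("itr", ITR_BASE, ITR_FRAMEWORK),
    ):
        for ref_name, ref_fn in (
            ("average", nd_skipping_mean),
            ("best", lambda vals: max(v for v in vals if v is not None)),
        ):
            entry: dict[str, float] = {}
            for subject in SUBJECTS:
                reference = ref_fn(base_tbl[subject])
                entry[subject] = percentage_improvement(
                    framework_tbl[subject], reference
                )
            entry["min"] = min(entry[s] for s in SUBJECTS)
            entry["max"] = max(entry[s] for s in SUBJECTS)
            out[f"{name}_vs_{ref_name}"] = entry
    return out
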