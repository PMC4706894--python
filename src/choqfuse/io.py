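"""File formats: long-format score CSV, model JSON, decisions CSV, YAML
run configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .capacity import Capacity
from .decision import Decision, FrameworkModel
from .ensembles import Ensemble
from .normalization import NormalizationConfig, ScoreMatrix

__all__ = [
    "FormatError",
    "read_scores",
    "write_scores",
    "write_model",
    "read_model",
    "write_decisions",
    "read_decisions",
    "load_run_config",
]

MODEL_SCHEMA_VERSION = 1

SCORE_COLUMNS = ["sample_id", "true_class", "classifier", "class", "score"]


class FormatError(ValueError):
    """Malformed input file (missing columns, ragged samples, bad schema)."""


def read_scores(path) -> tuple[list[ScoreMatrix], np.ndarray | None]:
    """Read a long-format score CSV into per-sample ``k x n`` matrices.

    Expected header: ``sample_id,true_class,classifier,class,score`` — one
    score per row.  Samples are grouped by ``sample_id`` in first-appearance
    order; every sample must carry the same full classifier x class grid.
    True labels are returned only when the ``true_class`` column is
    populated.
    """
    df = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["score"].isna().any():
        row = int(df.index[df["score"].isna()][0])
        raise FormatError(f"{path}: non-numeric or missing score at row {row}")

    classifier_ids = list(dict.fromkeys(df["classifier"]))
    class_ids = list(dict.fromkeys(df["class"]))
    c_index = {c: i for i, c in enumerate(classifier_ids)}
    k_index = {c: i for i, c in enumerate(class_ids)}
    k, n = len(classifier_ids), len(class_ids)

    matrices: list[ScoreMatrix] = []
    labels: list = []
    have_labels = df["true_class"].notna().all()
    for sample_id, group in df.groupby("sample_id", sort=False):
        if len(group) != k * n:
            raise FormatError(
                f"{path}: sample {sample_id!r} has {len(group)} rows, "
                f"expected {k * n} (k={k} classifiers x n={n} classes)"
            )
        scores = np.full((k, n), np.nan)
        for _, row in group.iterrows():
            scores[c_index[row["classifier"]], k_index[row["class"]]] = row[
                "score"
            ]
        if np.isnan(scores).any():
            raise FormatError(
                f"{path}: sample {sample_id!r} misses a classifier/class "
                "combination"
            )
        matrices.append(
            ScoreMatrix(
                scores,
                classifier_ids=[str(c) for c in classifier_ids],
                class_ids=[str(c) for c in class_ids],
            )
        )
        if have_labels:
            labels.append(group["true_class"].iloc[0])
    return matrices, (np.asarray(labels) if have_labels else None)


def write_scores(
    path,
    matrices: list[ScoreMatrix],
    labels=None,
    sample_ids=None,
) -> None:
    """Write per-sample score matrices as a long-format CSV."""
    rows = []
    if sample_ids is None:
        sample_ids = list(range(len(matrices)))
    for t, matrix in enumerate(matrices):
        true_class = "" if labels is None else labels[t]
        for j, cid in enumerate(matrix.classifier_ids):
            for i, kid in enumerate(matrix.class_ids):
                rows.append(
                    (sample_ids[t], true_class, cid, kid, matrix.scores[j, i])
                )
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, index=False)


def write_model(model: FrameworkModel, path) -> None:
    """Serialize a trained model to JSON at full float precision."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "k": model.k,
        "n": model.n,
        "normalization": model.normalization.to_dict(),
        "ensembles": [e.to_dict() for e in model.ensembles],
        "class_capacities": [c.to_dict() for c in model.class_capacities],
        "global_capacities": [c.to_dict() for c in model.global_capacities],
        "abstention_threshold": model.abstention_threshold,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path) -> FrameworkModel:
    """Load a model JSON written by :func:`write_model`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: corrupt model JSON ({exc})") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: model schema version {version!r}, expected "
            f"{MODEL_SCHEMA_VERSION}"
        )
    ensembles = [
        Ensemble(
            class_id=e["class"],
            members=list(e["members"]),
            s=len(e["members"]),
        )
        for e in payload["ensembles"]
    ]
    return FrameworkModel(
        k=payload["k"],
        n=payload["n"],
        normalization=NormalizationConfig.from_dict(payload["normalization"]),
        ensembles=ensembles,
        class_capacities=[
            Capacity.from_dict(c) for c in payload["class_capacities"]
        ],
        global_capacities=[
            Capacity.from_dict(c) for c in payload["global_capacities"]
        ],
        abstention_threshold=payload["abstention_threshold"],
    )


def write_decisions(path, decisions: list[Decision], sample_ids=None) -> None:
    """Write decisions CSV: sample_id, decision, margin, per-class
    likelihoods."""
    if sample_ids is None:
        sample_ids = list(range(len(decisions)))
    n = len(decisions[0].class_likelihoods) if decisions else 0
    columns = ["sample_id", "decision", "margin"] + [
        f"likelihood_{i}" for i in range(n)
    ]
    rows = [
        (sid, d.label, d.margin, *d.class_likelihoods)
        for sid, d in zip(sample_ids, decisions)
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_decisions(path) -> pd.DataFrame:
    """Read a decisions CSV; decision labels stay strings, ``ABSTAIN``
    included."""
    df = pd.read_csv(path, dtype={"decision": str})
    if "decision" not in df.columns:
        raise FormatError(f"{path}: missing 'decision' column")
    return df


def load_run_config(path) -> dict:
    """Load the YAML run configuration (normalization, learning, ensemble,
    decision, simulation and seed blocks; all optional)."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise FormatError(f"{path}: run config must be a YAML mapping")
    return config
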