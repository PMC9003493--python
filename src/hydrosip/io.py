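"""File formats: accelerometer CSV, episode/feature CSV, model JSON.

The accelerometer reader is deliberately permissive: a plain numeric CSV
with either one column (value) or two (time, value), with or without a
header row. Timestamps are optional everywhere — the pipeline is
sample-indexed and only ``sample_rate_hz`` converts to seconds.

Models serialize to a single self-describing JSON document (layer sizes,
activation names, flat weight arrays, scaler mean/scale, decision
threshold), so a trained classifier is inspectable and diffable.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .nn import DenseNetModel, NetArchitecture
from .preprocessing import AccelStream, Episode
from .simulate import GroundTruth, SipInterval

MODEL_FORMAT_VERSION = 1


def read_accel_csv(path, config: Optional[PipelineConfig] = None) -> AccelStream:
    """Read a one-column (value) or two-column (time, value) numeric CSV.

    A header row is skipped if present. Non-numeric payload rows raise a
    ``ValueError`` naming the offending row (1-based, header excluded).
    """
    config = config or PipelineConfig()
    values: List[float] = []
    n_cols = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r and any(cell.strip() for cell in r)]
    if not rows:
        raise ValueError(f"{path}: empty file")
    start = 0
    try:
        [float(c) for c in rows[0]]
    except ValueError:
        start = 1  # header row
        if len(rows) == 1:
            # a lone non-numeric row is bad data, not a header
            raise ValueError(f"{path}: non-numeric data in row 1: {rows[0]!r}")
    for rownum, row in enumerate(rows[start:], start=1):
        try:
            nums = [float(c) for c in row]
        except ValueError:
            raise ValueError(f"{path}: non-numeric data in row {rownum}: {row!r}")
        if n_cols is None:
            n_cols = len(nums)
            if n_cols not in (1, 2):
                raise ValueError(f"{path}: expected 1 or 2 columns, got {n_cols}")
        elif len(nums) != n_cols:
            raise ValueError(f"{path}: row {rownum} has {len(nums)} columns, expected {n_cols}")
        values.append(nums[-1])
    return AccelStream(np.asarray(values), config.sample_rate_hz)


def write_accel_csv(path, stream: AccelStream, include_time: bool = True) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if include_time:
            writer.writerow(["time", "value"])
            for t, v in zip(stream.times, stream.values):
                writer.writerow([f"{t:.6g}", f"{v:.10g}"])
        else:
            writer.writerow(["value"])
            for v in stream.values:
                writer.writerow([f"{v:.10g}"])


def write_episodes_csv(path, episodes: List[Episode],
                       labels: Optional[List[int]] = None) -> None:
    """Episodes as CSV: 120 value columns + raw_max + original_len (+ label)."""
    if not episodes:
        cols: List[str] = []
    else:
        cols = [f"v{i}" for i in range(len(episodes[0].norm_values))]
    records = []
    for i, ep in enumerate(episodes):
        rec = {c: ep.norm_values[j] for j, c in enumerate(cols)}
        rec["raw_max"] = ep.raw_max
        rec["original_len"] = ep.original_len
        rec["start_index"] = ep.start_index
        if labels is not None:
            rec["label"] = labels[i]
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def read_episodes_csv(path) -> Tuple[List[Episode], Optional[np.ndarray]]:
    df = pd.read_csv(path)
    vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    vcols.sort(key=lambda c: int(c[1:]))
    episodes = [
        Episode(
            norm_values=row[vcols].to_numpy(dtype=float),
            raw_max=float(row["raw_max"]),
            original_len=int(row["original_len"]),
            start_index=int(row.get("start_index", 0)),
        )
        for _, row in df.iterrows()
    ]
    labels = df["label"].to_numpy(dtype=int) if "label" in df.columns else None
    return episodes, labels


def write_features_csv(path, X: np.ndarray, feature_names,
                       labels: Optional[np.ndarray] = None) -> None:
    df = pd.DataFrame(np.atleast_2d(X), columns=list(feature_names))
    if labels is not None:
        df["label"] = labels
    df.to_csv(path, index=False)


def read_features_csv(path) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy(dtype=int) if "label" in df.columns else None
    return df.to_numpy(dtype=float), labels


def save_model(model: DenseNetModel, path) -> None:
    doc = {
        "format": "hydrosip-dense-net",
        "version": MODEL_FORMAT_VERSION,
        "architecture": {
            "n_inputs": model.architecture.n_inputs,
            "hidden_sizes": list(model.architecture.hidden_sizes),
            "n_outputs": model.architecture.n_outputs,
        },
        "hidden_activation": model.hidden_activation,
        "output_activation": "sigmoid",
        "n_parameters": model.n_parameters,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "decision_threshold": model.decision_threshold,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> DenseNetModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed model file ({exc})") from exc
    if doc.get("format") != "hydrosip-dense-net":
        raise ValueError(f"{path}: not a dense-net model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {doc.get('version')} != {MODEL_FORMAT_VERSION}"
        )
    arch = NetArchitecture(
        n_inputs=doc["architecture"]["n_inputs"],
        hidden_sizes=tuple(doc["architecture"]["hidden_sizes"]),
        n_outputs=doc["architecture"]["n_outputs"],
    )
    return DenseNetModel(
        architecture=arch,
        weights=[np.asarray(w, dtype=float) for w in doc["weights"]],
        biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
        hidden_activation=doc["hidden_activation"],
        scaler_mean=np.asarray(doc["scaler_mean"], dtype=float),
        scaler_scale=np.asarray(doc["scaler_scale"], dtype=float),
        decision_threshold=float(doc["decision_threshold"]),
    )


def write_ground_truth_json(path, truth: GroundTruth) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "v_bottle": truth.v_bottle,
                "refill_indices": truth.refill_indices,
                "sips": [asdict(s) for s in truth.sips],
                "nonsip_intervals": [list(iv) for iv in truth.nonsip_intervals],
            },
            fh, indent=1,
        )


def read_ground_truth_json(path) -> GroundTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return GroundTruth(
        sips=[SipInterval(**s) for s in doc["sips"]],
        nonsip_intervals=[tuple(iv) for iv in doc["nonsip_intervals"]],
        refill_indices=list(doc["refill_indices"]),
        v_bottle=float(doc["v_bottle"]),
    )
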