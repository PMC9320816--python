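"""Plain-text readers and writers binding the pipeline stages together.

Trials travel as a long-format CSV (one row per sample:
``subject, condition, sample_index, acc_ml, acc_vt, acc_ap`` plus optional
gold-standard columns ``com_ml, com_ml_velocity``) with a JSON sidecar
``<path>.meta.json`` carrying per-trial scalars and arrays that do not fit
the long format (sampling rate, leg length, BOS boundaries, planted truth)
as well as the provenance block (config hash, seed) every artifact embeds.
Floats are written with 17 significant digits, so a write/read round trip is
lossless.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .registry import FEATURE_NAMES, METADATA_COLUMNS, OUTCOME_NAMES
from .simulate import GroundTruth, TrialSignal

__all__ = [
    "config_hash",
    "write_trials",
    "read_trials",
    "write_ground_truth",
    "read_ground_truth",
    "write_feature_table",
    "read_feature_table",
    "write_json",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ("subject", "condition", "sample_index", "acc_ml", "acc_vt", "acc_ap")
OPTIONAL_TRIAL_COLUMNS = ("com_ml", "com_ml_velocity")
FLOAT_FMT = "%.17g"


def config_hash(config: Mapping | object) -> str:
    """SHA-256 of the canonical JSON form of a configuration object."""
    if hasattr(config, "__dataclass_fields__"):
        from dataclasses import asdict

        config = asdict(config)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(config, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_json(obj, path: str | Path) -> None:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=default))


def write_trials(
    trials: Sequence[TrialSignal],
    path: str | Path,
    provenance: Mapping | None = None,
) -> None:
    """Write a cohort as long CSV + JSON sidecar (lossless round trip)."""
    path = Path(path)
    frames = []
    meta_trials = []
    for t in trials:
        n = t.n_samples
        frame = {
            "subject": np.repeat(t.subject_id, n),
            "condition": np.repeat(t.condition, n),
            "sample_index": np.arange(n),
            "acc_ml": t.acc_ml,
            "acc_vt": t.acc_vt,
            "acc_ap": t.acc_ap,
        }
        if t.com_ml is not None:
            frame["com_ml"] = t.com_ml
            frame["com_ml_velocity"] = t.com_ml_velocity
        frames.append(pd.DataFrame(frame))
        meta_trials.append(
            {
                "subject": t.subject_id,
                "condition": t.condition,
                "sampling_rate": t.sampling_rate,
                "leg_length": t.leg_length,
                "right_bos_boundary": None
                if t.right_bos_boundary is None
                else t.right_bos_boundary.tolist(),
                "true_heel_strikes": None
                if t.true_heel_strikes is None
                else np.asarray(t.true_heel_strikes).tolist(),
                "true_side_labels": t.true_side_labels,
            }
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)
    write_json({"provenance": dict(provenance or {}), "trials": meta_trials}, _meta_path(path))


def read_trials(path: str | Path) -> list[TrialSignal]:
    """Read a trials CSV (+ sidecar) back into TrialSignal objects.

    Unknown extra columns are tolerated with a warning; missing required
    columns raise :class:`SchemaError` listing them.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty trials file") from exc
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed CSV: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    known = set(TRIAL_COLUMNS) | set(OPTIONAL_TRIAL_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    for col in ("acc_ml", "acc_vt", "acc_ap"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SchemaError(f"{path}: non-numeric or missing value in '{col}' at row {row}")

    meta_file = _meta_path(path)
    meta_by_key: dict[tuple, dict] = {}
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        for m in meta.get("trials", []):
            meta_by_key[(str(m["subject"]), float(m["condition"]))] = m

    trials = []
    for (subject, condition), g in df.groupby(["subject", "condition"], sort=False):
        g = g.sort_values("sample_index")
        m = meta_by_key.get((str(subject), float(condition)), {})
        trials.append(
            TrialSignal(
                subject_id=str(subject),
                condition=float(condition),
                sampling_rate=float(m.get("sampling_rate", 100.0)),
                acc_ml=g["acc_ml"].to_numpy(dtype=float),
                acc_vt=g["acc_vt"].to_numpy(dtype=float),
                acc_ap=g["acc_ap"].to_numpy(dtype=float),
                leg_length=float(m.get("leg_length", 0.9)),
                com_ml=g["com_ml"].to_numpy(dtype=float) if "com_ml" in g else None,
                com_ml_velocity=g["com_ml_velocity"].to_numpy(dtype=float)
                if "com_ml_velocity" in g
                else None,
                right_bos_boundary=None
                if m.get("right_bos_boundary") is None
                else np.asarray(m["right_bos_boundary"], dtype=float),
                true_heel_strikes=None
                if m.get("true_heel_strikes") is None
                else np.asarray(m["true_heel_strikes"], dtype=np.int64),
                true_side_labels=m.get("true_side_labels"),
            )
        )
    return trials


def write_ground_truth(
    truths: Sequence[GroundTruth],
    trials: Sequence[TrialSignal],
    path: str | Path,
    provenance: Mapping | None = None,
) -> None:
    records = []
    for t, gt in zip(trials, truths):
        records.append(
            {
                "subject": t.subject_id,
                "condition": t.condition,
                "heel_strike_indices": gt.heel_strike_indices.tolist(),
                "side_labels": gt.side_labels,
                "peak_com_excursion": gt.peak_com_excursion,
                "mos_values": np.asarray(gt.mos_values).tolist(),
                "mos_variability": gt.mos_variability,
                "true_outcome_coefficients": gt.true_outcome_coefficients,
                "clean_features": gt.clean_features,
            }
        )
    write_json({"provenance": dict(provenance or {}), "ground_truth": records}, path)


def read_ground_truth(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())["ground_truth"]


def write_feature_table(
    table: pd.DataFrame, path: str | Path, provenance: Mapping | None = None
) -> None:
    """Feature table as CSV in the documented fixed column order."""
    path = Path(path)
    order = [c for c in list(METADATA_COLUMNS) + list(FEATURE_NAMES) + list(OUTCOME_NAMES) if c in table.columns]
    table[order].to_csv(path, index=False, float_format=FLOAT_FMT)
    write_json({"provenance": dict(provenance or {}), "columns": order}, _meta_path(path))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty feature table") from exc
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing feature column(s) {missing[:5]}{'...' if len(missing) > 5 else ''}")
    return df
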