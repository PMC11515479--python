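"""Readers and writers for the pipeline's CSV/JSON/YAML dialects.

Channel time series are stored long-format (``animal_id, time_s, channel,
value, unit``) with times in seconds from recording start; blood gases
carry ISO-8601 minutes resolved against the recording's start time.
Models and selection traces are JSON with an explicit schema version, and
every artifact written by the command-line pipeline is accompanied by a
provenance block (tool version, seed, configuration hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementReport, MethodComparison
from .channels import BASE_UNITS, CHANNELS
from .errors import ParseError, SchemaError, UnitError
from .estimator import EstimateRecord
from .features import TRANSFORMS, CandidateDescriptor
from .preprocess import AveragedSample
from .records import DEFAULT_START_TIME, BloodGasRecord, TrialRecording
from .robust import FittedModel, SelectionTrace

MODEL_SCHEMA_VERSION = 1


def provenance(seed: int | None = None,
               config: Any | None = None) -> dict[str, Any]:
    """Provenance block embedded in written artifacts."""
    block: dict[str, Any] = {"tool": f"paco2est {__version__}"}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        if dataclasses.is_dataclass(config) and not isinstance(config, type):
            config = dataclasses.asdict(config)
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
        block["config_sha256"] = digest
    return block


# ---------------------------------------------------------------------------
# trials and blood gases

def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write one recording as long-format CSV."""
    rows = []
    for name, (t, v) in trial.channels.items():
        unit = CHANNELS[name].unit if name in CHANNELS else ""
        rows.append(pd.DataFrame({
            "animal_id": trial.animal_id,
            "time_s": np.round(t, 3),
            "channel": name, "value": v, "unit": unit,
        }))
    df = pd.concat(rows, ignore_index=True)
    df.sort_values(["channel", "time_s"], inplace=True, kind="stable")
    df.to_csv(path, index=False)


def load_trial(path: str | Path,
               start_time: str = DEFAULT_START_TIME) -> TrialRecording:
    """Load a single-animal recording written by :func:`write_trial`."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:                      # noqa: BLE001
        raise ParseError(f"cannot read trial CSV {path}: {exc}") from exc
    required = {"animal_id", "time_s", "channel", "value", "unit"}
    if not required.issubset(df.columns):
        raise ParseError(f"trial CSV {path} missing columns "
                         f"{sorted(required - set(df.columns))}")
    animals = df["animal_id"].unique()
    if len(animals) != 1:
        raise ParseError(f"trial CSV {path} must contain exactly one animal, "
                         f"found {list(animals)}")
    channels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, group in df.groupby("channel", sort=False):
        if name not in CHANNELS:
            raise ParseError(f"unknown channel {name!r} in {path}")
        units = group["unit"].unique()
        if len(units) != 1 or units[0] != CHANNELS[name].unit:
            raise UnitError(f"channel {name!r}: expected unit "
                            f"{CHANNELS[name].unit!r}, found {list(units)}")
        t = group["time_s"].to_numpy(dtype=float)
        v = group["value"].to_numpy(dtype=float)
        order = np.argsort(t, kind="stable")
        channels[name] = (t[order], v[order])
    return TrialRecording(animal_id=str(animals[0]), channels=channels,
                          start_time=start_time)


def write_bgas(bgas: Sequence[BloodGasRecord], path: str | Path,
               start_time: str = DEFAULT_START_TIME) -> None:
    start = pd.Timestamp(start_time)
    df = pd.DataFrame({
        "animal_id": [b.animal_id for b in bgas],
        "minute_iso8601": [
            (start + pd.Timedelta(seconds=b.documented_minute_s)).isoformat()
            for b in bgas],
        "paco2_mmHg": [b.paco2 for b in bgas],
        "ph": [b.ph for b in bgas],
        "pao2_mmHg": [b.pao2 for b in bgas],
    })
    df.to_csv(path, index=False)


def load_bgas(path: str | Path,
              start_time: str = DEFAULT_START_TIME) -> list[BloodGasRecord]:
    """Load blood gases; timestamps with a seconds component are
    normalised to their documented minute with a warning."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:                      # noqa: BLE001
        raise ParseError(f"cannot read blood-gas CSV {path}: {exc}") from exc
    required = {"animal_id", "minute_iso8601", "paco2_mmHg", "ph", "pao2_mmHg"}
    if not required.issubset(df.columns):
        raise ParseError(f"blood-gas CSV {path} missing columns "
                         f"{sorted(required - set(df.columns))}")
    start = pd.Timestamp(start_time)
    out: list[BloodGasRecord] = []
    for i, row in df.iterrows():
        try:
            seconds = (pd.Timestamp(row["minute_iso8601"]) - start).total_seconds()
        except Exception as exc:                  # noqa: BLE001
            raise ParseError(f"{path}, line {i + 2}: bad timestamp "
                             f"{row['minute_iso8601']!r}") from exc
        if seconds % 60 != 0:
            warnings.warn(f"{path}, line {i + 2}: timestamp has a seconds "
                          "component; truncated to the documented minute",
                          stacklevel=2)
            seconds = np.floor(seconds / 60.0) * 60.0
        out.append(BloodGasRecord(
            animal_id=str(row["animal_id"]), documented_minute_s=seconds,
            paco2=float(row["paco2_mmHg"]), ph=float(row["ph"]),
            pao2=float(row["pao2_mmHg"])))
    return out


# ---------------------------------------------------------------------------
# averaged samples

def write_samples(samples: Sequence[AveragedSample], path: str | Path,
                  kept_flags: Sequence[bool] | None = None) -> None:
    """One row per blood gas: averaged values, coverages and flags."""
    variables = sorted({name for s in samples for name in s.coverage})
    rows = []
    for i, s in enumerate(samples):
        row: dict[str, Any] = {
            "animal_id": s.animal_id, "reference_time_s": s.reference_time,
            "paco2_mmHg": s.paco2, "complete": s.complete,
        }
        if kept_flags is not None:
            row["kept"] = bool(kept_flags[i])
        for name in variables:
            row[name] = s.values.get(name)
            row[f"coverage_{name}"] = s.coverage.get(name, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_samples(path: str | Path) -> list[AveragedSample]:
    df = pd.read_csv(path)
    if "animal_id" not in df.columns or "paco2_mmHg" not in df.columns:
        raise ParseError(f"sample CSV {path} missing required columns")
    variables = [c for c in df.columns
                 if c in CHANNELS or c in ("O2diff", "O2quot")]
    out = []
    for _, row in df.iterrows():
        values = {name: float(row[name]) for name in variables
                  if pd.notna(row[name])}
        coverage = {name: float(row.get(f"coverage_{name}", 1.0))
                    for name in variables}
        paco2 = float(row["paco2_mmHg"]) if pd.notna(row["paco2_mmHg"]) else None
        out.append(AveragedSample(
            animal_id=str(row["animal_id"]),
            reference_time=float(row["reference_time_s"]),
            values=values, coverage=coverage,
            complete=bool(row.get("complete", True)), paco2=paco2))
    return out


# ---------------------------------------------------------------------------
# models and traces

def model_to_dict(model: FittedModel,
                  extra: dict[str, Any] | None = None) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "intercept": model.intercept,
        "terms": [{"base": d.base, "transform": d.transform,
                   "coefficient": c} for d, c in model.coefficients.items()],
        "scale": model.scale,
        "n_iter": model.n_iter,
        "converged": model.converged,
    }
    if extra:
        doc.update(extra)
    return doc


def model_from_dict(doc: dict[str, Any]) -> FittedModel:
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaError(f"unsupported model schema version {version!r} "
                          f"(expected {MODEL_SCHEMA_VERSION})")
    for key in ("intercept", "terms"):
        if key not in doc:
            raise SchemaError(f"model document missing {key!r}")
    coefficients = {}
    for term in doc["terms"]:
        if term.get("transform") not in TRANSFORMS:
            raise SchemaError(f"unknown transform {term.get('transform')!r}")
        coefficients[CandidateDescriptor(term["base"], term["transform"])] = \
            float(term["coefficient"])
    return FittedModel(intercept=float(doc["intercept"]),
                       coefficients=coefficients,
                       scale=float(doc.get("scale", 1.0)),
                       n_iter=int(doc.get("n_iter", 0)),
                       converged=bool(doc.get("converged", True)))


def save_model(model: FittedModel, path: str | Path,
               extra: dict[str, Any] | None = None) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model, extra), indent=2)
                          + "\n")


def load_model(path: str | Path) -> FittedModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"cannot parse model JSON {path}: {exc}") from exc
    return model_from_dict(doc)


def save_trace(trace: SelectionTrace, path: str | Path,
               extra: dict[str, Any] | None = None) -> None:
    doc: dict[str, Any] = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "stop_reason": trace.stop_reason,
        "steps": [{
            "index": s.index,
            "chosen": {"base": s.chosen.base, "transform": s.chosen.transform},
            "max_abs_r": s.max_abs_r,
            "model": model_to_dict(s.model),
        } for s in trace.steps],
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# estimate streams and comparisons

def write_estimates(streams: dict[str, Sequence[EstimateRecord]],
                    animal_id: str, path: str | Path) -> None:
    rows = []
    for method in sorted(streams):
        for e in streams[method]:
            rows.append({
                "animal_id": animal_id, "time_s": e.time, "method": e.method,
                "value_mmHg": e.value, "withheld_reason": e.withheld_reason,
                "out_of_validated_range": e.out_of_validated_range,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_estimates(path: str | Path
                   ) -> dict[str, dict[str, list[EstimateRecord]]]:
    """Load estimate streams, keyed by animal then method."""
    df = pd.read_csv(path)
    required = {"animal_id", "time_s", "method", "value_mmHg",
                "withheld_reason"}
    if not required.issubset(df.columns):
        raise ParseError(f"estimate CSV {path} missing columns "
                         f"{sorted(required - set(df.columns))}")
    out: dict[str, dict[str, list[EstimateRecord]]] = {}
    for _, row in df.iterrows():
        value = row["value_mmHg"]
        record = EstimateRecord(
            time=float(row["time_s"]), method=str(row["method"]),
            value=None if pd.isna(value) else float(value),
            withheld_reason=str(row["withheld_reason"]),
            out_of_validated_range=bool(row.get("out_of_validated_range",
                                                False)))
        out.setdefault(str(row["animal_id"]), {}) \
           .setdefault(record.method, []).append(record)
    return out


def comparison_to_dict(comparison: MethodComparison,
                       extra: dict[str, Any] | None = None) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "n_bgas_used": comparison.n_bgas_used,
        "n_bgas_dropped": comparison.n_bgas_dropped,
        "mae_reduction_abs": comparison.mae_reduction_abs,
        "mae_reduction_rel": comparison.mae_reduction_rel,
        "reports": {name: r.rounded()
                    for name, r in comparison.reports.items()},
    }
    if extra:
        doc.update(extra)
    return doc


def comparison_table(comparison: MethodComparison) -> pd.DataFrame:
    """Two-decimal result table, one column per method."""
    rows = {
        "Mean absolute error (MAE) [mmHg]": "mae",
        "Standard deviation (SD) [mmHg]": "sd",
        "Standard error (SE) [mmHg]": "se",
    }
    data = {name: [r.rounded()[field] for field in rows.values()]
            for name, r in comparison.reports.items()}
    return pd.DataFrame(data, index=list(rows))


def save_comparison(comparison: MethodComparison, path: str | Path,
                    extra: dict[str, Any] | None = None) -> None:
    Path(path).write_text(
        json.dumps(comparison_to_dict(comparison, extra), indent=2) + "\n")
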