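"""Table schemas, validated CSV readers/writers, and run manifests.

All interchange is comma-separated UTF-8 text with a header row and ISO-8601
dates/timestamps.  Column names are part of the public contract; see
``SCHEMAS``.  Validation errors carry row/column coordinates.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError


def _range_check(name, lo, hi):
    def check(series: pd.Series):
        bad = series[(series < lo) | (series > hi)]
        if len(bad):
            idx = bad.index[0]
            raise SchemaError(
                f"column {name!r} value {bad.iloc[0]!r} out of [{lo}, {hi}] "
                f"at row {idx}")
    return check


#: schema name -> {column: kind}; kinds: str, int, float, date, timestamp
SCHEMAS: dict[str, dict] = {
    "subjects": {
        "columns": {"subject_id": "str", "age": "float", "gender": "str",
                    "sleep_goal": "int", "bedtime_center_minutes": "float"},
        "checks": {},
    },
    "presence_intervals": {
        "columns": {"subject_id": "str", "start": "timestamp",
                    "end": "timestamp"},
        "checks": {},
    },
    "session_physiology": {
        "columns": {"subject_id": "str", "session_date": "date",
                    "sleep_duration": "float", "restful_duration": "float",
                    "time_to_fall_asleep": "float", "percent_motion": "float",
                    "heart_rate": "float", "breathing_rate": "float",
                    "hrv": "float", "quality_score": "float"},
        "checks": {"percent_motion": _range_check("percent_motion", 0.0, 1.0)},
    },
    "questionnaires": {
        "columns": {"subject_id": "str", "wave_index": "int",
                    "response_date": "date",
                    **{f"isi_q{j}": "int" for j in range(1, 8)},
                    "isi_total": "int"},
        "checks": {**{f"isi_q{j}": _range_check(f"isi_q{j}", 0, 4)
                      for j in range(1, 8)},
                   "isi_total": _range_check("isi_total", 0, 28)},
    },
    "sessions": {
        "columns": {"subject_id": "str", "session_date": "date",
                    "start": "timestamp", "end": "timestamp",
                    "age": "float", "bed_exits": "int",
                    "breathing_rate": "float", "gender_encoded": "float",
                    "heart_rate": "float", "hrv": "float",
                    "percent_motion": "float", "restful_duration": "float",
                    "session_duration": "float", "sleep_debt": "float",
                    "sleep_duration": "float", "quality_score": "float",
                    "sri": "float", "time_to_fall_asleep": "float"},
        "checks": {"sri": _range_check("sri", -100.0, 100.0)},
    },
    "labeled_sessions": {
        "columns": {"subject_id": "str", "session_date": "date",
                    "start": "timestamp", "end": "timestamp",
                    "age": "float", "bed_exits": "int",
                    "breathing_rate": "float", "gender_encoded": "float",
                    "heart_rate": "float", "hrv": "float",
                    "percent_motion": "float", "restful_duration": "float",
                    "session_duration": "float", "sleep_debt": "float",
                    "sleep_duration": "float", "quality_score": "float",
                    "sri": "float", "time_to_fall_asleep": "float",
                    "assigned_isi": "int", "source_wave": "int",
                    "label_ge_8": "int", "label_ge_10": "int",
                    "label_ge_15": "int"},
        "checks": {"assigned_isi": _range_check("assigned_isi", 0, 28)},
    },
    "inclusion_report": {
        "columns": {"stage": "str", "n_subjects": "int"},
        "checks": {},
    },
    "sweep_results": {
        "columns": {"threshold": "int", "interval": "int", "n_subjects": "int",
                    "accuracy_mean": "float", "accuracy_sd": "float",
                    "accuracy_n_defined": "int",
                    "precision_mean": "float", "precision_sd": "float",
                    "precision_n_defined": "int",
                    "recall_mean": "float", "recall_sd": "float",
                    "recall_n_defined": "int",
                    "auc_subject_mean": "float", "auc_subject_sd": "float",
                    "auc_subject_n_defined": "int",
                    "f1_pooled": "float", "auc_pooled": "float"},
        "checks": {},
    },
    "iauc": {
        "columns": {"threshold": "int", "interval": "int", "auc": "float",
                    "iauc": "float"},
        "checks": {},
    },
    "iauc_tests": {
        "columns": {"comparison": "str", "t_statistic": "float",
                    "p_value": "float"},
        "checks": {},
    },
}

_DATE_KINDS = {"date", "timestamp"}


def write_table(table: pd.DataFrame, path, schema_name: str) -> Path:
    """Validate ``table`` against a named schema and write it as CSV."""
    schema = SCHEMAS[schema_name]
    cols = list(schema["columns"])
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SchemaError(
            f"table for schema {schema_name!r} is missing columns {missing}")
    out = table[cols].copy()
    for c, kind in schema["columns"].items():
        if kind == "date":
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        elif kind == "timestamp":
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    for c, check in schema["checks"].items():
        check(pd.to_numeric(table[c]))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema (typed columns)."""
    schema = SCHEMAS[schema_name]
    path = Path(path)
    df = pd.read_csv(path)
    expected = list(schema["columns"])
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    if extra:
        raise SchemaError(f"{path.name}: unexpected columns {extra}")
    for c, kind in schema["columns"].items():
        try:
            if kind in _DATE_KINDS:
                df[c] = pd.to_datetime(df[c])
            elif kind == "int":
                df[c] = df[c].astype(np.int64)
            elif kind == "float":
                df[c] = df[c].astype(float)
            else:
                df[c] = df[c].astype(str)
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{path.name}: column {c!r} failed to parse as {kind}: {exc}"
            ) from exc
    for c, check in schema["checks"].items():
        check(df[c])
    return df


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run an experiment bit-identically."""

    master_seed: int
    cohort_config: dict
    sweep_config: dict
    package_version: str
    created_utc: str = ""
    inputs: dict[str, str] = field(default_factory=dict)    # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256

    def save(self, path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))


def new_manifest(master_seed, cohort_cfg_dict, sweep_cfg_dict,
                 package_version) -> RunManifest:
    return RunManifest(
        master_seed=int(master_seed),
        cohort_config=cohort_cfg_dict,
        sweep_config=sweep_cfg_dict,
        package_version=package_version,
        created_utc=dt.datetime.now(dt.timezone.utc).isoformat(),
    )
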