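"""Readers, writers, validation and configuration.

Canonical interchange is delimited text: CSV, UTF-8, header row, RFC-4180
quoting.  Units are fixed by the schema (potassium mEq/l, creatinine
mg/dl, urine output ml/kg/h); there is no unit auto-detection.  Extra
columns are accepted and kept available to the weight model.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("ccwdtr")

SCHEMA_VERSION = "1"

BASELINE_REQUIRED = [
    "patient_id",
    "age",
    "sex",
    "weight",
    "admission_category",
    "admission_sofa",
    "ckd_flag",
    "rrt_history_flag",
    "dnr_restriction_flag",
]
PERSON_DAY_REQUIRED = [
    "patient_id",
    "day",
    "creatinine",
    "potassium",
    "ph",
    "urine_output_rate",
    "sofa",
    "rrt_started_today",
    "rrt_active",
    "event_today",
]
_EVENT_VALUES = {"none", "death", "discharge"}


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ValidationError(ValueError):
    """Structural rules of the cohort tables are violated."""


@dataclass
class CohortBundle:
    """A validated pair of baseline and person-day tables."""

    baseline: pd.DataFrame
    person_days: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.info("%s table has extra columns (kept): %s", name, extra)


def validate_bundle(baseline: pd.DataFrame, person_days: pd.DataFrame) -> None:
    """Raise on structural violations; side-effect free."""
    _check_columns(baseline, BASELINE_REQUIRED, "baseline")
    _check_columns(person_days, PERSON_DAY_REQUIRED, "person-day")

    known = set(baseline["patient_id"])
    unknown = set(person_days["patient_id"]) - known
    if unknown:
        raise ValidationError(
            f"person-day rows reference unknown patient_id(s): {sorted(unknown)[:5]}"
        )
    bad_events = set(person_days["event_today"].unique()) - _EVENT_VALUES
    if bad_events:
        raise ValidationError(f"unknown event_today value(s): {sorted(bad_events)}")

    g = person_days.sort_values(["patient_id", "day"]).groupby("patient_id", sort=False)
    non_contig = []
    nonterminal = []
    for pid, grp in g:
        days = grp["day"].to_numpy()
        if days[0] != 0 or np.any(np.diff(days) != 1):
            non_contig.append(pid)
        ev = grp["event_today"].to_numpy()
        if np.any(ev[:-1] != "none"):
            nonterminal.append(pid)
    if non_contig:
        raise ValidationError(
            f"non-contiguous days (must run 0,1,2,... per patient) for: {non_contig[:5]}"
        )
    if nonterminal:
        raise ValidationError(f"event rows are not terminal for: {nonterminal[:5]}")


def forward_fill_labs(
    person_days: pd.DataFrame,
    columns: tuple[str, ...] = ("creatinine", "potassium", "ph", "urine_output_rate", "sofa"),
    max_gap_days: int = 1,
) -> pd.DataFrame:
    """Forward-fill missing lab values up to a configurable gap.

    Adds a ``<col>_missing`` indicator column for each filled column so the
    weight model can condition on missingness.
    """
    df = person_days.sort_values(["patient_id", "day"]).copy()
    g = df.groupby("patient_id", sort=False)
    for col in columns:
        if col not in df.columns:
            continue
        df[f"{col}_missing"] = df[col].isna().astype(int)
        df[col] = g[col].transform(lambda s: s.ffill(limit=max_gap_days))
    return df


def write_cohort(bundle: CohortBundle, directory: str | Path) -> tuple[Path, Path]:
    """Write baseline.csv and person_days.csv (UTF-8, RFC-4180)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bpath = directory / "baseline.csv"
    dpath = directory / "person_days.csv"
    bundle.baseline.to_csv(bpath, index=False)
    bundle.person_days.to_csv(dpath, index=False)
    with open(directory / "provenance.json", "w") as fh:
        json.dump(
            {"schema_version": bundle.schema_version, **bundle.provenance}, fh, indent=2, default=str
        )
    return bpath, dpath


def read_cohort(
    baseline_path: str | Path,
    person_days_path: str | Path,
    fill_missing: bool = True,
    max_gap_days: int = 1,
) -> CohortBundle:
    """Read and validate a cohort from delimited-text files."""
    baseline_path, person_days_path = Path(baseline_path), Path(person_days_path)
    for p in (baseline_path, person_days_path):
        if not p.exists():
            raise FileNotFoundError(p)
    baseline = pd.read_csv(baseline_path)
    person_days = pd.read_csv(person_days_path)
    for col in ("ckd_flag", "rrt_history_flag", "dnr_restriction_flag"):
        if col in baseline.columns:
            baseline[col] = baseline[col].astype(bool)
    for col in ("rrt_started_today", "rrt_active"):
        if col in person_days.columns:
            person_days[col] = person_days[col].astype(bool)
    validate_bundle(baseline, person_days)
    if fill_missing:
        person_days = forward_fill_labs(person_days, max_gap_days=max_gap_days)
    return CohortBundle(
        baseline=baseline,
        person_days=person_days,
        provenance={
            "baseline_path": str(baseline_path),
            "person_days_path": str(person_days_path),
        },
    )


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    """Load the structured run configuration (YAML).

    Recognised sections: scenario, regimes, weights, estimation, cv.
    Unknown sections are rejected to catch typos early.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    allowed = {"scenario", "regimes", "weights", "estimation", "cv", "output"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return cfg


def setup_run_log(directory: str | Path, config: dict, seed: int) -> Path:
    """Write a run log with seed, versions and the config hash."""
    import ccwdtr

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "run_log.json"
    payload = {
        "package_version": ccwdtr.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
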