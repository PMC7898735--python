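"""CSV ingestion, run configuration and report serialization.

Ingestion mirrors clinical cohort-construction practice: rows with missing
or unparseable measurement values are dropped and counted rather than
aborting the run, and the exclusion tallies travel with the results so
every report documents exactly what was analyzed.  CSV is comma-separated
UTF-8 with a required header and "." decimals; no locale handling.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortRecord
from .core import EnormsResult, ParameterError
from .strata import AgeBins, StratifiedReport

logger = logging.getLogger("enorms")

__all__ = [
    "ConfigurationError",
    "ColumnConfig",
    "IngestionResult",
    "read_cohort_csv",
    "read_value_column",
    "enorms_result_to_dict",
    "stratified_report_to_dict",
    "write_json_report",
]

_SEX_CODES = {
    "male": "male",
    "m": "male",
    "female": "female",
    "f": "female",
}


class ConfigurationError(ParameterError):
    """The run configuration does not match the input file."""


@dataclass(frozen=True)
class ColumnConfig:
    """Column names binding a CSV file to the cohort model.

    ``value_col`` names the precomputed measurement column.  Alternatively
    ``height_col``/``weight_col`` (metres and kilograms, or centimetres --
    heights above 3 are treated as cm) may be given and the value derived
    as weight / height^2, the BMI definition.
    """

    value_col: str = "value"
    age_col: str | None = "age"
    sex_col: str | None = "sex"
    condition_col: str | None = "condition"
    id_col: str | None = "subject_id"
    height_col: str | None = None
    weight_col: str | None = None


@dataclass(frozen=True)
class IngestionResult:
    """Parsed records plus exclusion bookkeeping."""

    records: list[CohortRecord]
    n_rows: int
    n_excluded_missing_value: int
    n_row_errors: int
    row_errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def _derive_bmi(height: float, width_kg: float) -> float:
    h = height / 100.0 if height > 3 else height  # heuristic: cm vs m
    return width_kg / (h * h)


def read_cohort_csv(path: str | Path, config: ColumnConfig | None = None) -> IngestionResult:
    """Read a cohort CSV into records, dropping and counting bad rows.

    Rows with a missing or non-finite measurement are excluded and counted;
    rows that fail to parse (bad age, unknown sex code) are collected as
    row-level errors and the run continues.  A missing required column is a
    configuration error (this also catches headerless files, whose first
    data row will not match any configured column name).
    """
    if config is None:
        config = ColumnConfig()
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    derive = config.height_col is not None and config.weight_col is not None
    needed = [config.height_col, config.weight_col] if derive else [config.value_col]
    missing = [col for col in needed if col not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: required column(s) {missing} not found in header "
            f"{list(frame.columns)}; is the header row present?"
        )
    records: list[CohortRecord] = []
    n_missing = 0
    errors: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header = line 1
        row_map = dict(zip(frame.columns, row))
        raw_fields = (
            [row_map[config.height_col], row_map[config.weight_col]]
            if derive
            else [row_map[config.value_col]]
        )
        if any(
            f is None or (isinstance(f, float) and np.isnan(f)) or str(f).strip() == ""
            for f in raw_fields
        ):
            n_missing += 1
            continue
        try:
            if derive:
                h, w = float(raw_fields[0]), float(raw_fields[1])
                if not (np.isfinite(h) and np.isfinite(w)) or h <= 0:
                    n_missing += 1
                    continue
                value = _derive_bmi(h, w)
            else:
                value = float(raw_fields[0])
                if not np.isfinite(value):
                    n_missing += 1
                    continue
        except (TypeError, ValueError) as exc:
            errors.append(f"line {i}: unparseable numeric cell ({exc})")
            continue
        try:
            age = 0
            if config.age_col and config.age_col in frame.columns:
                age_raw = row_map[config.age_col]
                age = int(float(age_raw)) if age_raw == age_raw and age_raw is not None else 0
            sex = "female"
            if config.sex_col and config.sex_col in frame.columns:
                sex_raw = str(row_map[config.sex_col]).strip().lower()
                if sex_raw not in _SEX_CODES:
                    raise ValueError(f"unknown sex code {sex_raw!r}")
                sex = _SEX_CODES[sex_raw]
            condition = False
            if config.condition_col and config.condition_col in frame.columns:
                cond_raw = str(row_map[config.condition_col]).strip().lower()
                condition = cond_raw in ("1", "true", "yes")
            subject_id = (
                str(row_map[config.id_col])
                if config.id_col and config.id_col in frame.columns
                else f"row{i}"
            )
            records.append(
                CohortRecord(
                    subject_id=subject_id,
                    age=age,
                    sex=sex,
                    value=value,
                    condition=condition,
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"line {i}: {exc}")
    if n_missing or errors:
        logger.info(
            "%s: %d rows excluded for missing/bad values, %d row errors",
            path,
            n_missing,
            len(errors),
        )
    return IngestionResult(
        records=records,
        n_rows=len(frame),
        n_excluded_missing_value=n_missing,
        n_row_errors=len(errors),
        row_errors=errors,
    )


def read_value_column(path: str | Path, value_col: str = "value") -> np.ndarray:
    """Read just the measurement column, dropping missing entries."""
    frame = pd.read_csv(path)
    if value_col not in frame.columns:
        raise ConfigurationError(
            f"{path}: column {value_col!r} not found in header {list(frame.columns)}"
        )
    vals = pd.to_numeric(frame[value_col], errors="coerce").to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def enorms_result_to_dict(result: EnormsResult, **extra: Any) -> dict[str, Any]:
    """Machine-readable report of a single-series run (plot omitted)."""
    rng = result.range
    out: dict[str, Any] = {
        "params": {
            "window": result.params.window,
            "k": result.params.k,
            "min_run": result.params.resolve_min_run(result.plot.n),
        },
        "n": result.plot.n,
        "bounds": {"a": result.bounds.a, "b": result.bounds.b},
        "normative_range": {
            "n_plateau": rng.n_plateau,
            "mean": rng.mean,
            "sd": rng.sd,
            "min": rng.min,
            "max": rng.max,
            "mean_minus_2sd": rng.mean_minus_2sd,
            "mean_plus_2sd": rng.mean_plus_2sd,
        },
    }
    if result.diagnostics is not None:
        out["diagnostics"] = _jsonable(result.diagnostics)
    out.update(extra)
    return _jsonable(out)


def stratified_report_to_dict(
    report: StratifiedReport, bins: AgeBins, **extra: Any
) -> dict[str, Any]:
    """Machine-readable report of a stratified run."""
    out: dict[str, Any] = {
        "bins": [list(edge) for edge in bins.edges],
        "n_excluded_age": report.n_excluded,
        "strata": [
            {
                "sex": res.key[0],
                "age_group": f"{res.key[1][0]}-{res.key[1][1]}",
                "n": res.n,
                "bounds": {"a": res.bounds.a, "b": res.bounds.b},
                "normative_range": {
                    "n_plateau": res.range.n_plateau,
                    "mean": res.range.mean,
                    "sd": res.range.sd,
                    "min": res.range.min,
                    "max": res.range.max,
                },
                "diagnostics": _jsonable(res.diagnostics)
                if res.diagnostics is not None
                else None,
            }
            for res in report.results
        ],
        "skipped": [
            {"sex": key[0], "age_group": f"{key[1][0]}-{key[1][1]}", "reason": reason}
            for key, reason in report.skipped
        ],
        "comparisons": [
            {
                "a": {"sex": c.key_a[0], "age_group": f"{c.key_a[1][0]}-{c.key_a[1][1]}"},
                "b": {"sex": c.key_b[0], "age_group": f"{c.key_b[1][0]}-{c.key_b[1][1]}"},
                "method": c.method,
                "statistic": c.statistic,
                "degrees_of_freedom": c.degrees_of_freedom,
                "p_value": c.p_value,
            }
            for c in report.comparisons
        ],
    }
    out.update(extra)
    return _jsonable(out)


def write_json_report(report: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")
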