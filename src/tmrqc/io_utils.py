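"""CSV layouts, schema validation and run manifests.

Dialect: UTF-8, comma-separated, period decimal separator, mandatory header
row.  European decimal commas are normalised at ingest.  Four table layouts
travel through the pipeline:

* spectra (wide): ``sample_id`` plus one column per wavelength in nm;
* reference analytics: chemistry + sieve fractions (+ derived particle columns);
* alley batch (long): ``point_id``, ``time`` in {fresh, 2h}, index-trait columns;
* farm records: one row per farm-visit, cohort schema.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import FARM_CATEGORICAL_COLUMNS, FARM_NUMERIC_COLUMNS
from .errors import InputValidationError
from .indexes import TRAIT_NAMES, AlleyBatch

SIEVE_COLUMNS = ("s1", "s2", "s3", "s4", "s5", "bottom")
CHEMISTRY_COLUMNS = ("dm", "cp", "andf", "adf", "starch")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputValidationError(f"file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputValidationError(f"empty file: {path}") from exc
    # normalise European decimal commas in object columns
    for col in df.columns:
        if df[col].dtype == object:
            converted = pd.to_numeric(
                df[col].astype(str).str.replace(",", ".", regex=False), errors="coerce"
            )
            if converted.notna().all():
                df[col] = converted
    return df


def _require_columns(df: pd.DataFrame, columns, report: list[str]) -> None:
    for col in columns:
        if col not in df.columns:
            report.append(f"missing column {col!r}")


def _require_numeric(df: pd.DataFrame, columns, report: list[str]) -> None:
    for col in columns:
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            report.append(f"column {col!r} contains non-numeric cells")


def _raise_if(report: list[str], path) -> None:
    if report:
        raise InputValidationError(
            f"{path}: {len(report)} validation problem(s)", report=report
        )


def validate_spectra_table(path) -> pd.DataFrame:
    """Wide spectra table: sample_id plus strictly increasing wavelength columns."""
    df = _read_csv(path)
    report: list[str] = []
    _require_columns(df, ["sample_id"], report)
    wl_cols = [c for c in df.columns if c != "sample_id"]
    if len(wl_cols) < 2:
        report.append("fewer than 2 wavelength columns")
    else:
        try:
            wl = np.array([float(c) for c in wl_cols])
            if np.any(np.diff(wl) <= 0):
                report.append("wavelength columns are not strictly increasing")
            if wl[0] < 902 - 1e-9 or wl[-1] > 1660 + 1e-9:
                report.append("wavelengths outside [902, 1660] nm")
        except ValueError:
            report.append("wavelength column headers are not numeric")
        _require_numeric(df, wl_cols, report)
        if not report and not np.all(np.isfinite(df[wl_cols].to_numpy(dtype=float))):
            report.append("non-finite absorbance values")
    _raise_if(report, path)
    return df


def validate_reference_table(path, fraction_sum_tol: float = 10.0) -> pd.DataFrame:
    """Reference analytics: chemistry %, sieve fractions roughly summing to 100."""
    df = _read_csv(path)
    report: list[str] = []
    _require_columns(df, ["sample_id", *CHEMISTRY_COLUMNS, *SIEVE_COLUMNS], report)
    _require_numeric(df, [*CHEMISTRY_COLUMNS, *SIEVE_COLUMNS], report)
    if not report:
        for col in (*CHEMISTRY_COLUMNS, *SIEVE_COLUMNS):
            bad = (df[col] < 0) | (df[col] > 100)
            if bad.any():
                report.append(f"column {col!r}: {int(bad.sum())} value(s) outside [0, 100] %")
        sums = df[list(SIEVE_COLUMNS)].sum(axis=1)
        bad = (sums - 100.0).abs() > fraction_sum_tol
        if bad.any():
            report.append(
                f"{int(bad.sum())} row(s) with sieve fractions summing far from 100%"
            )
    _raise_if(report, path)
    return df


def validate_alley_table(path) -> pd.DataFrame:
    """Long alley table: point_id, time in {fresh, 2h}, index-trait columns."""
    df = _read_csv(path)
    report: list[str] = []
    _require_columns(df, ["point_id", "time", *TRAIT_NAMES], report)
    _require_numeric(df, list(TRAIT_NAMES), report)
    if not report:
        times = set(df["time"].astype(str).unique())
        if not times <= {"fresh", "2h"}:
            report.append(f"unexpected time labels {sorted(times - {'fresh', '2h'})}")
        if "fresh" not in times:
            report.append("no fresh rows")
    _raise_if(report, path)
    return df


def validate_farm_table(path) -> pd.DataFrame:
    """Farm-cohort table: farm id plus the numeric/categorical record schema."""
    df = _read_csv(path)
    report: list[str] = []
    _require_columns(df, ["farm"], report)
    present_numeric = [c for c in FARM_NUMERIC_COLUMNS if c in df.columns]
    if not present_numeric:
        report.append("no recognised numeric farm columns")
    _require_numeric(df, present_numeric, report)
    for col in FARM_CATEGORICAL_COLUMNS:
        if col in df.columns and pd.api.types.is_numeric_dtype(df[col]):
            report.append(f"categorical column {col!r} is numeric")
    _raise_if(report, path)
    return df


def alley_batch_from_table(df: pd.DataFrame) -> AlleyBatch:
    """Assemble an AlleyBatch from a validated long-format table."""
    fresh = df[df["time"] == "fresh"].sort_values("point_id")[list(TRAIT_NAMES)]
    later_rows = df[df["time"] == "2h"]
    later = (
        later_rows.sort_values("point_id")[list(TRAIT_NAMES)] if len(later_rows) else None
    )
    return AlleyBatch(fresh=fresh.reset_index(drop=True),
                      later=None if later is None else later.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline invocation bit-identically."""

    seed: int
    config: dict
    version: str
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)   # path -> sha256
    failure: str | None = None

    def record_stage(self, name: str, seconds: float) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 4)})

    def record_output(self, path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


class StageTimer:
    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.record_stage(self.name, time.perf_counter() - self.t0)
        if exc is not None:
            self.manifest.failure = f"{self.name}: {exc}"
        return False
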