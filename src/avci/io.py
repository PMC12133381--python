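"""Trial-table CSV schemas, run configuration, and (de)serialization.

Trial tables are plain UTF-8 CSV with a documented header row; spatial
columns are degrees (positive rightward), temporal columns milliseconds
(positive = auditory first).  Binary responses are coded 0/1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["TASK_FILES", "SchemaError", "read_trials", "write_trials",
           "validate_trials", "RunConfig"]

# column -> (kind, lo, hi); kind "f" float, "i" integer code, "s" categorical
_SCHEMAS: dict[str, dict] = {
    "toj": {
        "soa_ms": ("f", -2000.0, 2000.0),
        "resp_afirst": ("i", 0, 1),
    },
    "disc": {
        "staircase_id": ("i", 0, 1000),
        "s_v_deg": ("f", -90.0, 90.0),
        "s_a_deg": ("f", -90.0, 90.0),
        "resp_aright": ("i", 0, 1),
    },
    "uniloc": {
        "modality": ("s", ("A", "V"), None),
        "s_deg": ("f", -90.0, 90.0),
        "resp_deg": ("f", -90.0, 90.0),
    },
    "bimodal": {
        "s_a_deg": ("f", -90.0, 90.0),
        "s_v_deg": ("f", -90.0, 90.0),
        "soa_ms": ("f", -2000.0, 2000.0),
        "resp_loc_deg": ("f", -90.0, 90.0),
        "resp_common": ("i", 0, 1),
    },
}

TASK_FILES = {"toj": "toj.csv", "disc": "disc.csv",
              "uniloc": "uniloc.csv", "bimodal": "bimodal.csv"}


class SchemaError(ValueError):
    """A trial table violates its task schema (names the row and column)."""


def validate_trials(table: pd.DataFrame, task: str) -> pd.DataFrame:
    """Validate (and coerce) a trial table against its task schema."""
    if task not in _SCHEMAS:
        raise SchemaError(f"unknown task id: {task!r}")
    schema = _SCHEMAS[task]
    missing = [c for c in schema if c not in table.columns]
    if missing:
        raise SchemaError(f"{task} table is missing column(s) {missing}")
    out = table.copy()
    for col, (kind, lo, hi) in schema.items():
        x = out[col]
        if kind == "s":
            bad = ~x.astype(str).isin(lo)
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise SchemaError(
                    f"{task} column '{col}', row {row}: value {x.iloc[row]!r} "
                    f"not in {lo}")
            out[col] = x.astype(str)
            continue
        vals = pd.to_numeric(x, errors="coerce")
        if vals.isna().any():
            row = int(np.argmax(vals.isna().to_numpy()))
            raise SchemaError(f"{task} column '{col}', row {row}: non-numeric value")
        if kind == "i":
            if not np.allclose(vals, np.round(vals)):
                row = int(np.argmax(~np.isclose(vals, np.round(vals))))
                raise SchemaError(f"{task} column '{col}', row {row}: not an integer")
            vals = vals.astype(int)
        bad = (vals < lo) | (vals > hi)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise SchemaError(
                f"{task} column '{col}', row {row}: value {vals.iloc[row]} "
                f"outside [{lo}, {hi}]")
        out[col] = vals.astype(float if kind == "f" else int)
    return out[list(schema)]


def read_trials(path: str | Path, task: str) -> pd.DataFrame:
    """Read and schema-check one task's trial table from CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_trials(pd.read_csv(path), task)


def write_trials(table: pd.DataFrame, path: str | Path, task: str) -> None:
    """Schema-check and write one task's trial table as CSV."""
    validate_trials(table, task).to_csv(path, index=False)


class QuadConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nodes: int = 61
    halfwidth: float = 4.0
    grid_spacing: float = 0.25
    grid_half: float = 60.0


class RunConfig(BaseModel):
    """Schema-validated run configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    reduced: bool = False
    n_starts: int = Field(default=20, ge=1)
    maxfev: int | None = None
    variants: list[str] = Field(
        default_factory=lambda: ["accurate", "temporal", "spatial", "both"])
    quad: QuadConfig = Field(default_factory=QuadConfig)
    params: dict = Field(default_factory=dict)       # generating-observer overrides
    bounds: dict = Field(default_factory=dict)       # ParamBounds overrides
    design: dict = Field(default_factory=dict)       # ExperimentDesign overrides

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))
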