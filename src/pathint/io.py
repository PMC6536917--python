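"""CSV / YAML schemas and lossless round-trips.

Files are UTF-8 CSV with '.' decimal separators and mandatory headers, all
lengths in metres.  ``trials.csv`` carries one row per trial (cone and
response coordinates plus the exclusion flag; the densely sampled return
path is not persisted).  Reads validate the schema and fail naming the file,
column and first offending row — a locale-style decimal comma is rejected,
never silently misparsed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ReturnCondition, Trial

__all__ = [
    "SchemaError",
    "trials_frame",
    "write_trials_csv",
    "read_trials_csv",
    "write_table",
    "read_table",
    "read_yaml",
    "write_yaml",
    "TRIALS_COLUMNS",
    "OUTCOMES_COLUMNS",
    "PARTICIPANTS_COLUMNS",
]

TRIALS_COLUMNS = {
    "participant_id": str,
    "environment": int,
    "trial_index": int,
    "condition": str,
    "c1_x": float, "c1_y": float,
    "c2_x": float, "c2_y": float,
    "c3_x": float, "c3_y": float,
    "resp_x": float, "resp_y": float,
    "excluded": bool,
}

OUTCOMES_COLUMNS = {
    "participant_id": str,
    "environment": int,
    "trial_index": int,
    "condition": str,
    "abs_error_m": float,
    "prop_angular": float,
    "prop_linear": float,
    "abs_dev_angular": float,
    "abs_dev_linear": float,
    "valid_angular": bool,
    "excluded": bool,
}

PARTICIPANTS_COLUMNS = {
    "participant_id": str,
    "group": str,
    "age": float,
    "sex": str,
    "education": float,
    "ace_r": float,
    "nart": float,
    "csf_abeta": float,
    "csf_tau": float,
    "csf_ptau": float,
    "biomarker_status": str,
    "icv": float,
    "n_viable": int,
    "mean_abs_error": float,
    "mean_prop_angular": float,
    "mean_prop_linear": float,
}


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def trials_frame(trials: list[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        resp = t.response if t.response is not None else (np.nan, np.nan)
        rows.append(
            {
                "participant_id": t.participant_id,
                "environment": t.environment,
                "trial_index": t.trial_index,
                "condition": t.condition.value,
                "c1_x": t.c1[0], "c1_y": t.c1[1],
                "c2_x": t.c2[0], "c2_y": t.c2[1],
                "c3_x": t.c3[0], "c3_y": t.c3[1],
                "resp_x": resp[0], "resp_y": resp[1],
                "excluded": t.excluded_out_of_border,
            }
        )
    return pd.DataFrame(rows)


def write_trials_csv(trials: list[Trial] | pd.DataFrame, path) -> None:
    frame = trials if isinstance(trials, pd.DataFrame) else trials_frame(trials)
    frame.to_csv(path, index=False)


def _validate(frame: pd.DataFrame, schema: dict, path) -> pd.DataFrame:
    name = Path(path).name
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    for col, typ in schema.items():
        if typ in (float, int):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna() & (frame[col].astype(str) != "")
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"{name}: column {col!r}, row {row}: "
                    f"unparseable value {frame[col][row]!r} (decimal commas are rejected)"
                )
            frame[col] = coerced
        elif typ is bool:
            mapped = frame[col].map(
                {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
            )
            if mapped.isna().any():
                row = int(mapped.isna().idxmax())
                raise SchemaError(f"{name}: column {col!r}, row {row}: not a boolean")
            frame[col] = mapped.astype(bool)
    return frame


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read and schema-validate a CSV table.

    Columns beyond the schema (e.g. per-ROI volume columns) are coerced to
    numeric when they parse cleanly and left as strings otherwise.
    """
    frame = pd.read_csv(path, dtype=object)
    frame = _validate(frame, schema, path)
    for col in frame.columns:
        if col not in schema:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            if not (coerced.isna() & frame[col].notna()).any():
                frame[col] = coerced
    return frame


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_trials_csv(path) -> list[Trial]:
    """Rebuild Trial objects from trials.csv (return paths are not stored)."""
    frame = read_table(path, TRIALS_COLUMNS)
    by_letter = {c.value: c for c in ReturnCondition}
    trials = []
    for i, row in frame.iterrows():
        if row["condition"] not in by_letter:
            raise SchemaError(
                f"{Path(path).name}: column 'condition', row {i}: "
                f"unknown condition {row['condition']!r}"
            )
        resp = None
        if np.isfinite(row["resp_x"]) and np.isfinite(row["resp_y"]):
            resp = np.array([row["resp_x"], row["resp_y"]])
        trials.append(
            Trial(
                participant_id=str(row["participant_id"]),
                environment=int(row["environment"]),
                trial_index=int(row["trial_index"]),
                c1=np.array([row["c1_x"], row["c1_y"]]),
                c2=np.array([row["c2_x"], row["c2_y"]]),
                c3=np.array([row["c3_x"], row["c3_y"]]),
                condition=by_letter[row["condition"]],
                response=resp,
                excluded_out_of_border=bool(row["excluded"]),
            )
        )
    return trials


def read_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{Path(path).name}: top level must be a mapping")
    return data


def write_yaml(data: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
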