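"""Trial CSV ingestion/validation and result serialization.

Input schema (header required): ``arm`` (0/1), ``time_death``,
``event_death`` (0/1), ``time_nonfatal``, ``event_nonfatal`` (0/1).
Remaining numeric columns — or an explicit list — are baseline covariates.
Times may be in any consistent unit.  Categorical covariates must arrive
pre-encoded as 0/1 indicator columns, and missing covariate values are
rejected rather than imputed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .comparison import SubjectRecord, TrialArrays

__all__ = [
    "REQUIRED_COLUMNS",
    "TrialValidationError",
    "read_trial_csv",
    "write_trial_csv",
    "frame_to_arrays",
    "arrays_to_frame",
    "results_to_frame",
    "write_results",
]

REQUIRED_COLUMNS = (
    "arm",
    "time_death",
    "event_death",
    "time_nonfatal",
    "event_nonfatal",
)
_ID_COLUMN = "subject_id"


class TrialValidationError(ValueError):
    """A row of the input violates the trial-data schema; the message
    names the offending row."""


def _fail_rows(mask: np.ndarray, frame: pd.DataFrame, what: str) -> None:
    if mask.any():
        rows = frame.index[mask].tolist()[:10]
        raise TrialValidationError(f"{what} (rows {rows})")


def frame_to_arrays(
    frame: pd.DataFrame, covariates: Sequence[str] | None = None
) -> tuple[TrialArrays, list[str]]:
    """Validate a trial DataFrame and convert it to :class:`TrialArrays`.

    Returns the arrays together with the covariate column names used (in
    order).  ``covariates=None`` takes every numeric column that is not
    part of the required schema (and not ``subject_id``).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialValidationError(f"missing required columns: {missing}")
    if covariates is None:
        covariates = [
            c
            for c in frame.columns
            if c not in REQUIRED_COLUMNS
            and c != _ID_COLUMN
            and pd.api.types.is_numeric_dtype(frame[c])
        ]
    else:
        covariates = list(covariates)
        absent = [c for c in covariates if c not in frame.columns]
        if absent:
            raise TrialValidationError(f"covariate columns not in input: {absent}")
        for c in covariates:
            if not pd.api.types.is_numeric_dtype(frame[c]):
                raise TrialValidationError(
                    f"covariate column {c!r} is not numeric; encode categorical "
                    "covariates as 0/1 indicator columns"
                )

    for c in REQUIRED_COLUMNS:
        vals = pd.to_numeric(frame[c], errors="coerce")
        _fail_rows(vals.isna().to_numpy(), frame, f"non-numeric or missing {c!r}")

    arm = frame["arm"].to_numpy()
    _fail_rows(~np.isin(arm, (0, 1)), frame, "arm must be 0 or 1")
    for c in ("event_death", "event_nonfatal"):
        _fail_rows(~np.isin(frame[c].to_numpy(), (0, 1)), frame, f"{c} must be 0 or 1")
    t1 = frame["time_death"].to_numpy(dtype=float)
    t2 = frame["time_nonfatal"].to_numpy(dtype=float)
    _fail_rows(~(t1 > 0) | ~(t2 > 0), frame, "times must be positive")
    _fail_rows(t2 > t1, frame, "time_nonfatal exceeds time_death")
    d2 = frame["event_nonfatal"].to_numpy(dtype=int)
    _fail_rows(
        (d2 == 0) & (t2 != t1),
        frame,
        "time_nonfatal must equal time_death when no nonfatal event observed",
    )
    if covariates:
        X = frame[covariates].to_numpy(dtype=float)
        _fail_rows(~np.isfinite(X).all(axis=1), frame, "missing/non-finite covariate values")
    else:
        X = np.empty((len(frame), 0))

    ids = (
        frame[_ID_COLUMN].to_numpy(dtype=object)
        if _ID_COLUMN in frame.columns
        else frame.index.to_numpy(dtype=object)
    )
    data = TrialArrays(
        arm=arm.astype(np.int64),
        terminal_time=t1,
        terminal_event=frame["event_death"].to_numpy(dtype=np.int64),
        nonfatal_time=t2,
        nonfatal_event=d2.astype(np.int64),
        covariates=X,
        subject_ids=ids,
    )
    return data, covariates


def read_trial_csv(
    path: str | Path, covariates: Sequence[str] | None = None
) -> tuple[list[SubjectRecord], list[str]]:
    """Read and validate a trial CSV; returns records and covariate names."""
    frame = pd.read_csv(path, float_precision="round_trip")
    data, names = frame_to_arrays(frame, covariates)
    return data.to_records(), names


def arrays_to_frame(
    data: TrialArrays, covariate_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Serialize trial arrays to the CSV schema at full float precision."""
    names = (
        list(covariate_names)
        if covariate_names is not None
        else [f"X{k + 1}" for k in range(data.p)]
    )
    frame = pd.DataFrame(
        {
            _ID_COLUMN: data.subject_ids,
            "arm": data.arm,
            "time_death": data.terminal_time,
            "event_death": data.terminal_event,
            "time_nonfatal": data.nonfatal_time,
            "event_nonfatal": data.nonfatal_event,
        }
    )
    for k, name in enumerate(names):
        frame[name] = data.covariates[:, k]
    return frame


def write_trial_csv(
    data: TrialArrays | list[SubjectRecord],
    path: str | Path,
    covariate_names: Sequence[str] | None = None,
) -> None:
    if not isinstance(data, TrialArrays):
        data = TrialArrays.from_records(data)
    arrays_to_frame(data, covariate_names).to_csv(path, index=False)


def results_to_frame(results: list[dict]) -> pd.DataFrame:
    """Flatten a list of result dicts (one per adjustment set) to a table."""
    return pd.DataFrame(results)


def write_results(
    results: list[dict],
    json_path: str | Path | None = None,
    csv_path: str | Path | None = None,
    provenance: dict | None = None,
) -> None:
    """Write analysis results as JSON and/or flat CSV.

    The JSON document echoes the configuration used (``provenance``) so a
    run can be reproduced from its output alone.
    """
    if json_path is not None:
        doc = {"results": results}
        if provenance:
            doc["config"] = provenance
        Path(json_path).write_text(json.dumps(doc, indent=2, default=str))
    if csv_path is not None:
        results_to_frame(results).to_csv(csv_path, index=False)
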