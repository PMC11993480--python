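"""Tabular input/output: cohort CSVs and validation reports.

CSV dialect is fixed: comma-separated, UTF-8, ``.`` decimal, header
required.  Lengths are millimetres and angles degrees, as documented
per column.  Reports are written with deterministic field ordering and
floats at 4 significant figures, so identical analyses produce
byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    MEASUREMENT_COLUMNS,
    REQUIRED_COHORT_COLUMNS,
    validate_cohort_frame,
)
from .errors import SchemaError

__all__ = ["read_cohort", "read_measurements", "write_cohort", "write_report"]

logger = logging.getLogger("tsscore")

_FLOAT_DIGITS = 4


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.read_json(path, orient="records")
    else:
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"{path}: empty input file") from exc
    if frame.empty:
        raise SchemaError(f"{path}: no data rows")
    return frame


def read_cohort(path: Union[str, Path]) -> Cohort:
    """Load a scored-cohort CSV (or records JSON) with row-level validation.

    Rows violating the score invariants (outcome not 0/1, sub-scores off
    their supports, total not equal to the sub-score sum) are dropped
    and logged with their row number and reason; the accepted/rejected
    counts are logged at INFO.  A missing required column raises
    :class:`SchemaError` naming it.
    """
    frame = _read_table(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    known = set(REQUIRED_COHORT_COLUMNS) | set(MEASUREMENT_COLUMNS) | {
        "id", "risk_band", "predicted_probability", "incomplete",
    }
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        logger.warning("%s: unknown columns carried as passthrough: %s", path, unknown)
    clean, rejections = validate_cohort_frame(frame)
    for row, reason in rejections:
        logger.warning("%s: rejected row %d: %s", path, row, reason)
    logger.info(
        "%s: accepted %d rows, rejected %d", path, len(clean), len(rejections)
    )
    if clean.empty:
        raise SchemaError(f"{path}: no valid rows after validation")
    return Cohort(clean, validate=False)


def read_measurements(path: Union[str, Path]) -> pd.DataFrame:
    """Load a raw-measurements table (one row per hip) for scoring.

    Unknown columns are kept as passthrough with a logged warning.
    """
    frame = _read_table(path)
    known = set(MEASUREMENT_COLUMNS) | {"id", "outcome"}
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        logger.warning("%s: unknown columns carried as passthrough: %s", path, unknown)
    return frame


def write_cohort(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort/measurement table as deterministic CSV."""
    frame.to_csv(path, index=False)


def _rounded(value):
    """Round floats to 4 significant figures; pass everything else through."""
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return None
        if np.isinf(value):
            return "inf" if value > 0 else "-inf"
        return float(f"{value:.{_FLOAT_DIGITS}g}")
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if isinstance(value, np.ndarray):
        return [_rounded(v) for v in value.tolist()]
    if isinstance(value, dict):
        return {str(k): _rounded(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_rounded(v) for v in value]
    return value


def _flatten(results: dict, prefix: str = "") -> List[Tuple[str, object]]:
    items: List[Tuple[str, object]] = []
    for key, value in results.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            items.extend(_flatten(value, prefix=f"{name}."))
        else:
            items.append((name, value))
    return items


def write_report(
    results: dict, path: Union[str, Path], format: str = "json"
) -> None:
    """Write a validation report as JSON, flat text, or CSV.

    JSON preserves the (deterministic) insertion order of ``results``
    and round-trips losslessly at the stored precision.  ``csv``
    expects a ``calibration_by_score`` entry (list of per-level rows)
    and renders one CSV row per score level.
    """
    path = Path(path)
    payload = _rounded(results)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    elif format == "text":
        lines = [f"{key} = {value}" for key, value in _flatten(payload)]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "csv":
        table = payload.get("calibration_by_score")
        if table is None:
            raise SchemaError("csv format requires a 'calibration_by_score' entry")
        pd.DataFrame(table).to_csv(path, index=False)
    else:
        raise SchemaError(f"unknown report format {format!r}")
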