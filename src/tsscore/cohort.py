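"""Patient-level containers and table-level scoring.

A :class:`Cohort` is a thin, validated wrapper around a pandas
DataFrame with one row per operated hip: the binary mechanical-
complication outcome, the six TSS sub-scores, the total, and any
passthrough covariates (raw measurements, demographics, ...).

:func:`score_frame` applies the scoring rules column-wise to a table of
raw radiographic measurements, which is what the ``tss score`` command
runs under the hood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import scoring
from .errors import DomainError
from .geometry import (
    CORTICAL_CATEGORIES,
    Quadrant,
    TadMeasurement,
    classify_cortical_support,
    tip_apex_distance,
)
from .scoring import SUBSCORE_FIELDS, SubScores

__all__ = [
    "REQUIRED_COHORT_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "PatientRecord",
    "Cohort",
    "validate_cohort_frame",
    "score_frame",
]

#: Columns a cohort table must carry for validation statistics.
REQUIRED_COHORT_COLUMNS: Tuple[str, ...] = ("outcome",) + SUBSCORE_FIELDS + ("tss_total",)

#: Raw measurement columns the scorer understands (per-hip, one row each).
MEASUREMENT_COLUMNS: Tuple[str, ...] = (
    "tad_mm",
    "x_ap",
    "x_lat",
    "d_ap",
    "d_lat",
    "d_true",
    "quadrant_ap",
    "quadrant_lat",
    "cda_diff_deg",
    "cda_fractured",
    "cda_intact",
    "lateral_angulation_deg",
    "mcs",
    "acs",
)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: outcome, sub-scores, total, and passthrough fields."""

    id: str
    outcome: int
    sub_scores: SubScores
    tss_total: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise DomainError(f"outcome must be 0 or 1, got {self.outcome!r}")
        if self.tss_total != self.sub_scores.total:
            raise DomainError(
                f"inconsistent total: tss_total={self.tss_total} but "
                f"sub-scores sum to {self.sub_scores.total}"
            )


def _row_error(row: pd.Series) -> Optional[str]:
    """Reason a cohort row is invalid, or None if it passes."""
    if row["outcome"] not in (0, 1):
        return f"outcome must be 0 or 1, got {row['outcome']!r}"
    for name in SUBSCORE_FIELDS:
        upper = 2 if name in ("tad_score", "quadrant_score") else 1
        value = row[name]
        try:
            ok = float(value).is_integer() and 0 <= float(value) <= upper
        except (TypeError, ValueError):
            ok = False
        if not ok:
            return f"{name} outside [0, {upper}]: {value!r}"
    if int(row["tss_total"]) != int(sum(row[name] for name in SUBSCORE_FIELDS)):
        return "inconsistent total: tss_total does not equal the sub-score sum"
    return None


def validate_cohort_frame(frame: pd.DataFrame) -> Tuple[pd.DataFrame, List[Tuple[int, str]]]:
    """Split a cohort table into valid rows and (row-number, reason) rejects.

    Row numbers are 0-based positions in the input frame.
    """
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise DomainError(f"cohort frame is missing required columns: {missing}")
    rejections: List[Tuple[int, str]] = []
    keep = np.ones(len(frame), dtype=bool)
    for pos, (_, row) in enumerate(frame.iterrows()):
        reason = _row_error(row)
        if reason is not None:
            keep[pos] = False
            rejections.append((pos, reason))
    clean = frame.iloc[keep].reset_index(drop=True)
    return clean, rejections


class Cohort:
    """Validated cohort of scored patients backed by a DataFrame."""

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        if validate:
            frame, rejections = validate_cohort_frame(frame)
            if rejections:
                raise DomainError(
                    f"{len(rejections)} invalid rows; first: row "
                    f"{rejections[0][0]}: {rejections[0][1]}"
                )
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def outcome(self) -> np.ndarray:
        return self.frame["outcome"].to_numpy(dtype=int)

    @property
    def tss_total(self) -> np.ndarray:
        return self.frame["tss_total"].to_numpy(dtype=int)

    @property
    def prevalence(self) -> float:
        return float(self.outcome.mean())

    @property
    def records(self) -> Iterator[PatientRecord]:
        known = set(REQUIRED_COHORT_COLUMNS) | {"id"}
        for i, row in self.frame.iterrows():
            yield PatientRecord(
                id=str(row.get("id", i)),
                outcome=int(row["outcome"]),
                sub_scores=SubScores(
                    **{name: int(row[name]) for name in SUBSCORE_FIELDS}
                ),
                tss_total=int(row["tss_total"]),
                extras={k: row[k] for k in self.frame.columns if k not in known},
            )

    def split_by_outcome(self) -> Tuple[pd.DataFrame, pd.DataFrame]:
        """(complication, non-complication) sub-frames."""
        mask = self.frame["outcome"].astype(int) == 1
        return self.frame[mask], self.frame[~mask]

    @classmethod
    def from_records(cls, records: Sequence[PatientRecord]) -> "Cohort":
        rows = []
        for r in records:
            row = {"id": r.id, "outcome": r.outcome, "tss_total": r.tss_total}
            row.update({name: getattr(r.sub_scores, name) for name in SUBSCORE_FIELDS})
            row.update(r.extras)
            rows.append(row)
        return cls(pd.DataFrame(rows))


def _score_row(
    row: pd.Series,
    cortical_tolerance: float,
    varus_tolerance: float,
) -> dict:
    """Score one measurement row; missing inputs leave NaN sub-scores."""
    out: dict = {name: np.nan for name in SUBSCORE_FIELDS}

    def has(*cols: str) -> bool:
        return all(c in row.index and pd.notna(row[c]) for c in cols)

    if has("tad_mm"):
        tad = float(row["tad_mm"])
        out["tad_score"] = scoring.score_tad(tad)
    elif has("x_ap", "x_lat", "d_ap", "d_lat", "d_true"):
        tad = tip_apex_distance(
            TadMeasurement(
                x_ap=float(row["x_ap"]),
                x_lat=float(row["x_lat"]),
                d_ap=float(row["d_ap"]),
                d_lat=float(row["d_lat"]),
                d_true=float(row["d_true"]),
            )
        )
        out["tad_mm"] = tad
        out["tad_score"] = scoring.score_tad(tad)

    if has("quadrant_ap", "quadrant_lat"):
        out["quadrant_score"] = scoring.score_quadrant(
            Quadrant(ap_band=str(row["quadrant_ap"]), lat_band=str(row["quadrant_lat"]))
        )

    if has("cda_diff_deg"):
        out["ap_alignment_score"] = scoring.score_ap_alignment(
            float(row["cda_diff_deg"]), varus_tolerance
        )
    elif has("cda_fractured", "cda_intact"):
        diff = float(row["cda_fractured"]) - float(row["cda_intact"])
        out["cda_diff_deg"] = diff
        out["ap_alignment_score"] = scoring.score_ap_alignment(diff, varus_tolerance)

    if has("lateral_angulation_deg"):
        out["lateral_alignment_score"] = scoring.score_lateral_alignment(
            float(row["lateral_angulation_deg"])
        )

    for col, key in (("mcs", "mcs_score"), ("acs", "acs_score")):
        if has(col):
            value = row[col]
            if isinstance(value, str) and value in CORTICAL_CATEGORIES:
                out[key] = scoring.score_cortical(value)
            else:
                # numeric offset in mm -> graded through the tolerance band
                out[key] = scoring.score_cortical(
                    classify_cortical_support(float(value), cortical_tolerance)
                )
    return out


def score_frame(
    frame: pd.DataFrame,
    cortical_tolerance: float = 1.0,
    varus_tolerance: float = 0.0,
    beta0: Optional[float] = None,
    beta1: Optional[float] = None,
) -> pd.DataFrame:
    """Score a table of raw measurements row by row.

    Accepts either derived quantities (``tad_mm``, ``cda_diff_deg``) or
    their raw components (TAD films, per-hip CDAs); cortical support as
    a category or a signed offset in mm.  Rows missing any of the six
    inputs are scored partially and flagged ``incomplete`` with a NaN
    total rather than imputed.  Unknown columns pass through untouched.
    """
    scored = frame.copy()
    results = [
        _score_row(row, cortical_tolerance, varus_tolerance)
        for _, row in frame.iterrows()
    ]
    result_frame = pd.DataFrame(results, index=frame.index)
    for col in result_frame.columns:
        scored[col] = result_frame[col]

    sub = scored[list(SUBSCORE_FIELDS)]
    complete = sub.notna().all(axis=1)
    scored["incomplete"] = ~complete
    scored["tss_total"] = np.where(complete, sub.sum(axis=1), np.nan)
    scored["risk_band"] = [
        scoring.assign_risk_band(int(t)) if ok else ""
        for t, ok in zip(scored["tss_total"].fillna(0), complete)
    ]
    if beta0 is not None and beta1 is not None:
        scored["predicted_probability"] = [
            scoring.predicted_probability(int(t), beta0, beta1) if ok else np.nan
            for t, ok in zip(scored["tss_total"].fillna(0), complete)
        ]
    return scored
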