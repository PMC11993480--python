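"""The Targeted Surgical Score (TSS) rules.

Six sub-scores grade the quality of implant placement and fracture
reduction after proximal femoral nailing:

===========================  ======  ==========================================
sub-score                    points  target
===========================  ======  ==========================================
tip-apex distance (TAD)      0-2     < 25 mm (2), 25-30 mm (1), >= 30 mm (0)
lag-screw quadrant           0-2     centre-centre / inferior-centre (2);
                                     superior-anterior / superior-posterior (0);
                                     the other five combinations (1)
AP alignment                 0-1     CDA difference neutral or < 10 deg valgus
lateral alignment            0-1     angulation < 20 deg
medial cortical support      0-1     neutral or positive MCS
anterior cortical support    0-1     neutral or positive ACS
===========================  ======  ==========================================

The total (0-8 points) maps to four clinical risk bands: 7-8 very low
(< 5% complication probability), 5-6 low (5-10%), 2-4 moderate
(10-50%), 0-1 high (> 50%).  A fitted per-point logistic model can
optionally decorate the result with a predicted complication
probability; scoring itself never requires one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

from .errors import DomainError, InvalidMeasurementError
from .geometry import Quadrant

__all__ = [
    "RISK_BANDS",
    "SUBSCORE_FIELDS",
    "SubScores",
    "TssResult",
    "score_tad",
    "score_quadrant",
    "score_ap_alignment",
    "score_lateral_alignment",
    "score_cortical",
    "total_tss",
    "assign_risk_band",
    "predicted_probability",
]

RISK_BANDS = ("very_low", "low", "moderate", "high")

#: Sub-score field names in canonical (tabular-output) order.
SUBSCORE_FIELDS = (
    "tad_score",
    "quadrant_score",
    "ap_alignment_score",
    "lateral_alignment_score",
    "mcs_score",
    "acs_score",
)

_TARGET_QUADRANTS = {("centre", "centre"), ("inferior", "centre")}
_UNDESIRABLE_QUADRANTS = {("superior", "anterior"), ("superior", "posterior")}


@dataclass(frozen=True)
class SubScores:
    """The six TSS sub-scores; TAD and quadrant carry up to 2 points."""

    tad_score: int
    quadrant_score: int
    ap_alignment_score: int
    lateral_alignment_score: int
    mcs_score: int
    acs_score: int

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            upper = 2 if f.name in ("tad_score", "quadrant_score") else 1
            if value not in range(upper + 1):
                raise DomainError(
                    f"{f.name} must be an integer in [0, {upper}], got {value!r}"
                )

    @property
    def total(self) -> int:
        return sum(getattr(self, name) for name in SUBSCORE_FIELDS)


@dataclass(frozen=True)
class TssResult:
    """Total TSS with its clinical risk band.

    ``predicted_probability`` is optional decoration from a fitted
    logistic model; it is ``None`` unless a fit was supplied.
    """

    total: int
    risk_band: str
    predicted_probability: Optional[float] = field(default=None)


def score_tad(tad: float) -> int:
    """TAD sub-score: < 25 mm -> 2, [25, 30) mm -> 1, >= 30 mm -> 0."""
    if tad < 0:
        raise InvalidMeasurementError(f"TAD must be non-negative, got {tad}")
    if tad < 25.0:
        return 2
    if tad < 30.0:
        return 1
    return 0


def score_quadrant(q: Quadrant) -> int:
    """Quadrant sub-score: central/inferior-central placement is the target.

    centre-centre and inferior-centre earn 2 points; the superior-anterior
    and superior-posterior quadrants (the cut-out-prone placements) earn 0;
    every other combination is acceptable at 1 point.
    """
    combo = (q.ap_band, q.lat_band)
    if combo in _TARGET_QUADRANTS:
        return 2
    if combo in _UNDESIRABLE_QUADRANTS:
        return 0
    return 1


def score_ap_alignment(cda_diff: float, varus_tolerance: float = 0.0) -> int:
    """AP alignment sub-score from the signed CDA difference (degrees).

    The favourable window is neutral up to (but excluding) 10 deg of
    valgus.  Any varus beyond ``varus_tolerance`` (0 deg by default,
    i.e. strictly no varus) scores 0, as does valgus of 10 deg or more.
    """
    if varus_tolerance < 0:
        raise DomainError(
            f"varus_tolerance must be non-negative, got {varus_tolerance}"
        )
    return 1 if -varus_tolerance <= cda_diff < 10.0 else 0


def score_lateral_alignment(ang: float) -> int:
    """Lateral alignment sub-score: angulation strictly below 20 deg -> 1."""
    if ang < 0:
        raise InvalidMeasurementError(
            f"lateral angulation must be non-negative, got {ang}"
        )
    return 1 if ang < 20.0 else 0


def score_cortical(category: str) -> int:
    """Cortical-support sub-score: neutral or positive -> 1, negative -> 0."""
    if category in ("neutral", "positive"):
        return 1
    if category == "negative":
        return 0
    raise DomainError(
        f"cortical support must be negative/neutral/positive, got {category!r}"
    )


def assign_risk_band(total: int) -> str:
    """Clinical risk band for a total TSS: 7-8 very_low, 5-6 low, 2-4 moderate, 0-1 high."""
    if total not in range(9):
        raise DomainError(f"total TSS must be an integer in [0, 8], got {total!r}")
    if total >= 7:
        return "very_low"
    if total >= 5:
        return "low"
    if total >= 2:
        return "moderate"
    return "high"


def total_tss(
    s: SubScores,
    beta0: Optional[float] = None,
    beta1: Optional[float] = None,
) -> TssResult:
    """Sum the sub-scores into the 0-8 total and attach the risk band.

    If both logistic coefficients are given, the result also carries the
    model-predicted complication probability at that total.
    """
    total = s.total
    prob = None
    if beta0 is not None and beta1 is not None:
        prob = predicted_probability(total, beta0, beta1)
    return TssResult(total=total, risk_band=assign_risk_band(total), predicted_probability=prob)


def predicted_probability(total: int, beta0: float, beta1: float) -> float:
    """Logistic complication probability at a given total score.

    ``beta1`` is the per-point change in log-odds (negative for a
    protective score), ``beta0`` the intercept; returns
    1 / (1 + exp(-(beta0 + beta1 * total))).
    """
    if not 0 <= total <= 8:
        raise DomainError(f"total TSS must lie in [0, 8], got {total!r}")
    return 1.0 / (1.0 + math.exp(-(beta0 + beta1 * total)))
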