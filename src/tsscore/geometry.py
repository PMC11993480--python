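"""Radiographic geometry for proximal femoral nailing.

Quantities measured on paired AP (antero-posterior) and lateral hip
radiographs that feed the Targeted Surgical Score: the magnification-
corrected tip-apex distance (TAD), the lag-screw quadrant within the
femoral head (superior/centre/inferior x anterior/centre/posterior),
the collo-diaphyseal angle (CDA) difference between the operated and
intact hips, lateral angulation of the proximal fragment, and the
medial/anterior cortical-support categories (MCS/ACS).

Image coordinates are abstract planar units: every formula uses only
ratios or normalised positions, so no pixel-spacing metadata is needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

from .errors import InvalidMeasurementError, OutOfHeadError, DomainError

__all__ = [
    "AP_BANDS",
    "LAT_BANDS",
    "CORTICAL_CATEGORIES",
    "TadMeasurement",
    "Quadrant",
    "HeadProjection",
    "AlignmentMeasures",
    "CorticalSupport",
    "tip_apex_distance",
    "assign_band",
    "quadrant_from_projections",
    "cda_difference",
    "classify_cortical_support",
]

#: Band labels per plane, ordered from the s=0 edge to the s=1 edge.
AP_BANDS: Tuple[str, str, str] = ("superior", "centre", "inferior")
LAT_BANDS: Tuple[str, str, str] = ("anterior", "centre", "posterior")

#: Cortical-support grades (fragment cortex vs shaft cortex contact).
CORTICAL_CATEGORIES: Tuple[str, str, str] = ("negative", "neutral", "positive")

# Manufactured lag-screw diameters fall in a narrow range; values outside
# it are almost certainly data-entry mistakes, but measurement units are
# the caller's responsibility, so this is only a warning band (mm).
_PLAUSIBLE_SCREW_DIAMETER = (5.0, 16.0)


@dataclass(frozen=True)
class TadMeasurement:
    """Raw tip-apex distance components from the two films.

    ``x_ap``/``x_lat`` are the apparent tip-to-apex lengths measured on
    the AP and lateral films; ``d_ap``/``d_lat`` the apparent lag-screw
    diameters on those films; ``d_true`` the manufactured screw diameter.
    All in millimetres.  The apparent diameters calibrate away the
    radiographic magnification of each film.
    """

    x_ap: float
    x_lat: float
    d_ap: float
    d_lat: float
    d_true: float

    def __post_init__(self) -> None:
        for name in ("x_ap", "x_lat"):
            if getattr(self, name) < 0:
                raise InvalidMeasurementError(
                    f"{name} must be non-negative, got {getattr(self, name)}"
                )
        for name in ("d_ap", "d_lat", "d_true"):
            if getattr(self, name) <= 0:
                raise InvalidMeasurementError(
                    f"{name} must be positive, got {getattr(self, name)}"
                )
        lo, hi = _PLAUSIBLE_SCREW_DIAMETER
        if not lo <= self.d_true <= hi:
            warnings.warn(
                f"d_true={self.d_true} mm is outside the plausible lag-screw "
                f"diameter range [{lo}, {hi}] mm",
                stacklevel=3,
            )


@dataclass(frozen=True)
class Quadrant:
    """Lag-screw position in the 3x3 femoral-head grid."""

    ap_band: str
    lat_band: str

    def __post_init__(self) -> None:
        if self.ap_band not in AP_BANDS:
            raise DomainError(
                f"ap_band must be one of {AP_BANDS}, got {self.ap_band!r}"
            )
        if self.lat_band not in LAT_BANDS:
            raise DomainError(
                f"lat_band must be one of {LAT_BANDS}, got {self.lat_band!r}"
            )


@dataclass(frozen=True)
class HeadProjection:
    """Planar projection of the femoral head and lag-screw centre.

    ``neck_axis_direction`` is normalised on construction; the head is
    split into three equal bands perpendicular to it.  The first label
    of a plane's band ordering sits on the edge toward which the 90 deg
    counter-clockwise rotation of the neck axis points.
    """

    head_centre: Tuple[float, float]
    head_radius: float
    neck_axis_direction: Tuple[float, float]
    screw_centre_at_head: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.head_radius <= 0:
            raise InvalidMeasurementError(
                f"head_radius must be positive, got {self.head_radius}"
            )
        ux, uy = self.neck_axis_direction
        norm = math.hypot(ux, uy)
        if norm == 0:
            raise InvalidMeasurementError("neck_axis_direction must be nonzero")
        object.__setattr__(self, "neck_axis_direction", (ux / norm, uy / norm))


@dataclass(frozen=True)
class AlignmentMeasures:
    """Neck-shaft angles of both hips and lateral fragment angulation.

    Angles in degrees.  ``lateral_angulation`` is stored as a magnitude:
    the scoring threshold does not distinguish flexion from extension.
    """

    cda_fractured: float
    cda_intact: float
    lateral_angulation: float

    def __post_init__(self) -> None:
        for name in ("cda_fractured", "cda_intact"):
            value = getattr(self, name)
            if not 90.0 <= value <= 180.0:
                raise InvalidMeasurementError(
                    f"{name} must lie in [90, 180] degrees, got {value}"
                )
        if self.lateral_angulation < 0:
            raise InvalidMeasurementError(
                f"lateral_angulation must be non-negative, "
                f"got {self.lateral_angulation}"
            )


@dataclass(frozen=True)
class CorticalSupport:
    """Medial (AP film) and anterior (lateral film) cortical support."""

    mcs: str
    acs: str

    def __post_init__(self) -> None:
        for name in ("mcs", "acs"):
            value = getattr(self, name)
            if value not in CORTICAL_CATEGORIES:
                raise DomainError(
                    f"{name} must be one of {CORTICAL_CATEGORIES}, got {value!r}"
                )


def tip_apex_distance(m: TadMeasurement) -> float:
    """Magnification-corrected tip-apex distance in millimetres.

    Each film's apparent tip-to-apex length is rescaled by the ratio of
    the true to the apparent screw diameter on that film, and the two
    corrected lengths are summed:

        TAD = x_ap * (d_true / d_ap) + x_lat * (d_true / d_lat)

    The result is invariant to uniform magnification of either film.
    """
    return m.x_ap * (m.d_true / m.d_ap) + m.x_lat * (m.d_true / m.d_lat)


def _normalised_position(p: HeadProjection, tolerance: float) -> float:
    """Screw-centre position across the head, normalised to [0, 1].

    Projects the screw-centre offset onto the perpendicular of the neck
    axis and maps the head diameter onto [0, 1], 0 at the edge toward
    ccw90(neck_axis_direction).
    """
    ox = p.screw_centre_at_head[0] - p.head_centre[0]
    oy = p.screw_centre_at_head[1] - p.head_centre[1]
    if math.hypot(ox, oy) > p.head_radius * (1.0 + tolerance):
        raise OutOfHeadError(
            "screw centre lies outside the femoral head circle "
            f"(offset {math.hypot(ox, oy):.3g}, radius {p.head_radius:.3g})"
        )
    ux, uy = p.neck_axis_direction
    # ccw90(u) = (-uy, ux); signed distance along it, in radii.
    t = (ox * -uy + oy * ux) / p.head_radius
    s = (1.0 - t) / 2.0
    return min(max(s, 0.0), 1.0)


def assign_band(
    p: HeadProjection,
    plane_labels: Sequence[str],
    tolerance: float = 0.05,
) -> str:
    """Assign the screw centre to one of three equal bands of the head.

    The head diameter perpendicular to the neck axis is split into equal
    thirds.  Boundary positions (s exactly 1/3 or 2/3) go to the middle
    band, so ties favour the clinically modal central category and the
    three bands partition the head exhaustively.

    ``tolerance`` is the allowed relative overshoot of the screw centre
    beyond the head circle before an :class:`OutOfHeadError` is raised
    (measurement jitter on real films routinely places a well-seated
    screw centre marginally outside the fitted circle).
    """
    if len(plane_labels) != 3:
        raise DomainError(f"expected 3 band labels, got {len(plane_labels)}")
    s = _normalised_position(p, tolerance)
    if s < 1.0 / 3.0:
        return plane_labels[0]
    if s <= 2.0 / 3.0:
        return plane_labels[1]
    return plane_labels[2]


def quadrant_from_projections(
    ap: HeadProjection, lat: HeadProjection, tolerance: float = 0.05
) -> Quadrant:
    """Compose the lag-screw quadrant from the AP and lateral projections."""
    return Quadrant(
        ap_band=assign_band(ap, AP_BANDS, tolerance),
        lat_band=assign_band(lat, LAT_BANDS, tolerance),
    )


def cda_difference(a: AlignmentMeasures) -> float:
    """Fractured-minus-intact collo-diaphyseal angle, degrees.

    Negative values indicate varus alignment of the operated hip,
    positive values valgus.
    """
    return a.cda_fractured - a.cda_intact


def classify_cortical_support(offset: float, tolerance: float = 1.0) -> str:
    """Grade cortical support from a signed cortex-to-cortex offset (mm).

    Positive offsets mean the head-neck fragment cortex rests on or
    medial/anterior to the shaft cortex.  Offsets within ``tolerance``
    of zero are graded neutral; the grading literature defines only the
    three categories, so the neutrality band is configurable (1 mm
    default).
    """
    if tolerance < 0:
        raise DomainError(f"tolerance must be non-negative, got {tolerance}")
    if offset > tolerance:
        return "positive"
    if offset < -tolerance:
        return "negative"
    return "neutral"
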