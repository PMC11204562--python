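"""Planar landmark geometry for full-leg AP radiograph angle measurement.

All computations run on digitized 2D landmark coordinates; no pixel data is
touched.  Five angles are produced per annotation:

``hka_deviation``
    Hip-knee-ankle angle expressed as a signed deviation from 180 degrees
    (negative = varus, positive = valgus).
``mldfa``
    Lateral angle between the femoral mechanical axis (directed toward the
    hip) and the distal femoral joint line (directed medial-to-lateral).
``mmpta``
    Medial angle between the tibial mechanical axis (directed toward the
    ankle) and the tibial plateau line (directed lateral-to-medial).
``tga``
    Angle at the trochlear groove apex subtended by the tangents to the
    medial and lateral facets.
``ba``
    Medial angle between the proximally-directed trochlear groove bisector
    and the distal femoral joint line.

Coordinate conventions
----------------------
The x/y axes are abstract image axes: every angle is invariant under
translation, rotation and uniform positive scaling of all landmarks, and
under mirroring combined with a side flip.  Anatomical direction (medial /
lateral) is resolved from landmark *names*, never from coordinate signs.
The single place where chirality matters is the sign of ``hka_deviation``:
coordinates are assumed to be a rigid motion + scaling of a standard
anteroposterior view with mathematical (counter-clockwise positive) axis
orientation, so that for a *right* limb the lateral direction is the
counter-clockwise rotation of the proximal direction.  Left-limb
annotations are handled by the mirrored convention, which makes
mirror+side-flip an exact symmetry.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

from .errors import (
    DegenerateGeometryError,
    EmptyContourError,
    MissingLandmarkError,
    NoTangentError,
    UndefinedBisectorError,
)

__all__ = [
    "Point",
    "Side",
    "LandmarkAnnotation",
    "AngleSet",
    "LANDMARK_VOCABULARY",
    "CONTOUR_VOCABULARY",
    "ANGLE_NAMES",
    "angle_at_vertex",
    "bisector_direction",
    "tangent_from_point",
    "trochlear_angles",
    "bisector_angle",
    "hka_deviation",
    "mldfa",
    "mmpta",
    "measure_all",
    "mirror_annotation",
]

#: Closed vocabulary of point landmarks.  ``plateau_medial`` /
#: ``plateau_lateral`` carry the tibial joint line used by ``mmpta``.
LANDMARK_VOCABULARY = frozenset(
    {
        "hip_center",
        "femoral_notch_center",
        "trochlear_apex",
        "trochlear_tangent_medial",
        "trochlear_tangent_lateral",
        "condyle_medial",
        "condyle_lateral",
        "tibial_spines_center",
        "ankle_center",
        "plateau_medial",
        "plateau_lateral",
    }
)

#: Ordered contour landmark families (facet outlines, one per branch).
CONTOUR_VOCABULARY = frozenset({"trochlear_contour_medial", "trochlear_contour_lateral"})

#: Canonical angle order used throughout tables and CSV files.
ANGLE_NAMES = ("hka_deviation", "mldfa", "mmpta", "tga", "ba")

#: Point landmarks required by each angle.  ``tga``/``ba`` additionally need
#: either both tangent points or both contours.
REQUIRED_LANDMARKS = {
    "hka_deviation": ("hip_center", "femoral_notch_center", "tibial_spines_center", "ankle_center"),
    "mldfa": ("hip_center", "femoral_notch_center", "condyle_medial", "condyle_lateral"),
    "mmpta": ("tibial_spines_center", "ankle_center", "plateau_medial", "plateau_lateral"),
    "tga": ("trochlear_apex",),
    "ba": ("trochlear_apex", "condyle_medial", "condyle_lateral"),
}

_EPS = 1e-12


@dataclass(frozen=True)
class Point:
    """A 2D landmark coordinate in arbitrary (but consistent) length units."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DegenerateGeometryError(f"non-finite coordinates ({self.x}, {self.y})")


class Side(str, Enum):
    """Limb laterality."""

    LEFT = "left"
    RIGHT = "right"

    @classmethod
    def coerce(cls, value: "Side | str") -> "Side":
        if isinstance(value, cls):
            return value
        return cls(str(value))


@dataclass
class LandmarkAnnotation:
    """One observer's digitized named points for one limb at one occasion."""

    subject_id: str
    side: Side
    observer_id: str
    occasion: int
    points: dict[str, Point] = field(default_factory=dict)
    contours: dict[str, list[Point]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.side = Side.coerce(self.side)
        if int(self.occasion) < 1:
            raise ValueError(f"occasion must be >= 1, got {self.occasion}")
        self.occasion = int(self.occasion)
        for name in self.points:
            if name not in LANDMARK_VOCABULARY:
                raise KeyError(f"unknown landmark name {name!r}")
        for name in self.contours:
            if name not in CONTOUR_VOCABULARY:
                raise KeyError(f"unknown contour name {name!r}")

    def require(self, *names: str) -> tuple[Point, ...]:
        """Return the named points, raising :class:`MissingLandmarkError` otherwise."""
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(
                f"annotation {self.subject_id}/{self.observer_id}/occ{self.occasion}"
                f" is missing landmark(s): {', '.join(missing)}"
            )
        return tuple(self.points[n] for n in names)

    def has(self, *names: str) -> bool:
        return all(n in self.points for n in names)


@dataclass
class AngleSet:
    """The five measured angles for one annotation (``None`` = not measured)."""

    hka_deviation: Optional[float] = None
    mldfa: Optional[float] = None
    mmpta: Optional[float] = None
    tga: Optional[float] = None
    ba: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in ANGLE_NAMES}

    def validate(self) -> None:
        """Check range invariants for the fields that are present."""
        for name in ("mldfa", "mmpta", "ba"):
            v = getattr(self, name)
            if v is not None and not (0.0 < v < 180.0):
                raise ValueError(f"{name}={v} outside (0, 180)")
        if self.tga is not None and not (0.0 <= self.tga < 180.0):
            raise ValueError(f"tga={self.tga} outside [0, 180)")
        if self.hka_deviation is not None and not (-90.0 < self.hka_deviation < 90.0):
            raise ValueError(f"hka_deviation={self.hka_deviation} outside (-90, 90)")


# --- vector helpers ---------------------------------------------------------

def _vec(a: Point, b: Point) -> tuple[float, float]:
    """Vector from a to b."""
    return (b.x - a.x, b.y - a.y)


def _norm(v: tuple[float, float]) -> float:
    return math.hypot(v[0], v[1])


def _unit(v: tuple[float, float]) -> tuple[float, float]:
    n = _norm(v)
    if n < _EPS:
        raise DegenerateGeometryError("zero-length direction vector")
    return (v[0] / n, v[1] / n)


def _dot(u: tuple[float, float], v: tuple[float, float]) -> float:
    return u[0] * v[0] + u[1] * v[1]


def _cross(u: tuple[float, float], v: tuple[float, float]) -> float:
    return u[0] * v[1] - u[1] * v[0]


def _angle_between(u: tuple[float, float], v: tuple[float, float]) -> float:
    """Unsigned angle between two vectors in degrees, in [0, 180]."""
    if _norm(u) < _EPS or _norm(v) < _EPS:
        raise DegenerateGeometryError("zero-length vector in angle computation")
    return math.degrees(math.atan2(abs(_cross(u, v)), _dot(u, v)))


def _signed_angle(u: tuple[float, float], v: tuple[float, float]) -> float:
    """Signed CCW angle from u to v in degrees, in (-180, 180]."""
    return math.degrees(math.atan2(_cross(u, v), _dot(u, v)))


# --- primitive operations ---------------------------------------------------

def angle_at_vertex(apex: Point, p1: Point, p2: Point) -> float:
    """Unsigned angle in [0, 180] degrees between rays apex->p1 and apex->p2.

    Raises
    ------
    DegenerateGeometryError
        If ``p1`` or ``p2`` coincides with ``apex``.
    """
    return _angle_between(_vec(apex, p1), _vec(apex, p2))


def bisector_direction(apex: Point, p1: Point, p2: Point) -> tuple[float, float]:
    """Unit vector from ``apex`` bisecting the internal angle p1-apex-p2.

    Computed as the normalized sum of the two unit ray directions, so the
    result makes equal angles with both rays.

    Raises
    ------
    UndefinedBisectorError
        If the rays are exactly opposite (angle of 180 degrees).
    DegenerateGeometryError
        If either point coincides with the apex.
    """
    u1 = _unit(_vec(apex, p1))
    u2 = _unit(_vec(apex, p2))
    s = (u1[0] + u2[0], u1[1] + u2[1])
    if _norm(s) < 1e-9:
        raise UndefinedBisectorError("rays are opposite; internal bisector undefined")
    return _unit(s)


def tangent_from_point(
    apex: Point,
    contour: Sequence[Point],
    branch: str,
    side: Side | str,
    medial_direction: Optional[tuple[float, float]] = None,
) -> Point:
    """Contour point realizing the supporting line from ``apex``.

    The returned point ``P`` is such that every contour point lies on one
    closed side of the line apex-P; among the two supporting rays the one on
    the named ``branch`` side is chosen (the whole contour lies medially of
    the medial tangent and laterally of the lateral tangent).  Points with
    equal extremal polar angle are tie-broken to the one farthest from the
    apex.

    Parameters
    ----------
    branch:
        ``"medial"`` or ``"lateral"`` — which facet tangent is wanted.
    side:
        Limb side; used only to orient the medial direction when
        ``medial_direction`` is not given (in which case the annotation is
        assumed unrotated, medial = +x for a right limb).
    medial_direction:
        Optional in-plane unit vector pointing medially (e.g. derived from
        the condylar landmarks); supplying it makes the choice of branch
        rotation-invariant.

    Raises
    ------
    EmptyContourError
        If the contour has no points.
    NoTangentError
        If the apex lies inside or on the convex hull of the contour.
    """
    if branch not in ("medial", "lateral"):
        raise ValueError(f"branch must be 'medial' or 'lateral', got {branch!r}")
    pts = list(contour)
    if not pts:
        raise EmptyContourError("contour has no points")
    side = Side.coerce(side)
    vecs = []
    for p in pts:
        v = _vec(apex, p)
        if _norm(v) < _EPS:
            raise NoTangentError("apex coincides with a contour point")
        vecs.append(v)
    if len(pts) == 1:
        return pts[0]

    # Angular offsets about the apex relative to the mean direction.  A
    # strictly external apex sees the contour under an angular spread < 180.
    vec_sum = (sum(v[0] for v in vecs), sum(v[1] for v in vecs))
    if _norm(vec_sum) < _EPS:
        raise NoTangentError("apex lies inside or on the convex hull of the contour")
    ref = _unit(vec_sum)
    offsets = [_signed_angle(ref, v) for v in vecs]
    if max(offsets) - min(offsets) >= 180.0 - 1e-9:
        raise NoTangentError("apex lies inside or on the convex hull of the contour")

    def pick(target: float) -> int:
        cand = [i for i, o in enumerate(offsets) if abs(o - target) <= 1e-9]
        return max(cand, key=lambda i: _norm(vecs[i]))  # farthest from apex

    i_hi, i_lo = pick(max(offsets)), pick(min(offsets))
    if i_hi == i_lo:
        return pts[i_hi]

    if medial_direction is None:
        medial_direction = (1.0, 0.0) if side is Side.RIGHT else (-1.0, 0.0)
    want = medial_direction if branch == "medial" else (-medial_direction[0], -medial_direction[1])

    # The CCW-extreme ray leaves the contour on its clockwise side and vice
    # versa; keep the candidate whose far side is the branch side.
    for idx, contour_sign in ((i_hi, -1.0), (i_lo, 1.0)):
        if _cross(vecs[idx], want) * contour_sign > 0:
            return pts[idx]
    # Branch direction ambiguous (e.g. parallel to both tangents): fall back
    # to the candidate farther from the apex for determinism.
    return pts[max((i_hi, i_lo), key=lambda i: _norm(vecs[i]))]


# --- annotation-level operations -------------------------------------------

def _medial_hint(annotation: LandmarkAnnotation) -> Optional[tuple[float, float]]:
    if annotation.has("condyle_medial", "condyle_lateral"):
        cm, cl = annotation.require("condyle_medial", "condyle_lateral")
        v = _vec(cl, cm)
        if _norm(v) > _EPS:
            return _unit(v)
    return None


def _tangent_points(annotation: LandmarkAnnotation) -> tuple[Point, Point]:
    """Tangent contact points: direct landmarks first, else derived from contours."""
    if annotation.has("trochlear_tangent_medial", "trochlear_tangent_lateral"):
        return annotation.require("trochlear_tangent_medial", "trochlear_tangent_lateral")
    (apex,) = annotation.require("trochlear_apex")
    hint = _medial_hint(annotation)
    out = []
    for branch in ("medial", "lateral"):
        contour = annotation.contours.get(f"trochlear_contour_{branch}")
        if not contour:
            raise MissingLandmarkError(
                f"annotation {annotation.subject_id}/{annotation.observer_id} needs "
                f"trochlear_tangent_{branch} or trochlear_contour_{branch}"
            )
        out.append(tangent_from_point(apex, contour, branch, annotation.side, medial_direction=hint))
    return out[0], out[1]


def trochlear_angles(annotation: LandmarkAnnotation) -> tuple[float, tuple[float, float]]:
    """Trochlear groove angle and the proximally-directed bisector.

    Returns ``(tga, tgb_proximal)`` where ``tgb_proximal`` is the unit
    direction of the groove bisector oriented away from the tangent contact
    points (toward the femoral shaft).
    """
    (apex,) = annotation.require("trochlear_apex")
    t_med, t_lat = _tangent_points(annotation)
    tga = angle_at_vertex(apex, t_med, t_lat)
    b = bisector_direction(apex, t_med, t_lat)
    return tga, (-b[0], -b[1])


def bisector_angle(annotation: LandmarkAnnotation) -> float:
    """Medial angle between the proximal groove bisector and the femoral joint line.

    The joint line is directed lateral-to-medial (``condyle_medial -
    condyle_lateral``); a perpendicular bisector reads exactly 90 and values
    below 90 mean the proximal bisector tip leans medially.
    """
    cm, cl = annotation.require("condyle_medial", "condyle_lateral")
    joint = _vec(cl, cm)
    if _norm(joint) < _EPS:
        raise DegenerateGeometryError("condyle_medial and condyle_lateral coincide")
    _, tgb_proximal = trochlear_angles(annotation)
    return _angle_between(joint, tgb_proximal)


def hka_deviation(annotation: LandmarkAnnotation) -> float:
    """Signed hip-knee-ankle deviation from 180 degrees (varus negative)."""
    hip, notch, spines, ankle = annotation.require(
        "hip_center", "femoral_notch_center", "tibial_spines_center", "ankle_center"
    )
    v_f = _vec(hip, notch)   # distal along femoral mechanical axis
    v_t = _vec(spines, ankle)  # distal along tibial mechanical axis
    dev = _angle_between(v_f, v_t)
    z = _cross(v_f, v_t)
    if annotation.side is Side.LEFT:
        z = -z
    # In the canonical right-limb frame a varus chain turns CCW at the knee.
    return -dev if z > 0 else dev


def mldfa(annotation: LandmarkAnnotation) -> float:
    """Lateral angle between femoral mechanical axis and distal femoral joint line."""
    hip, notch, cm, cl = annotation.require(
        "hip_center", "femoral_notch_center", "condyle_medial", "condyle_lateral"
    )
    axis = _vec(notch, hip)  # proximal
    joint_lat = _vec(cm, cl)  # medial -> lateral
    return _angle_between(axis, joint_lat)


def mmpta(annotation: LandmarkAnnotation) -> float:
    """Medial angle between tibial mechanical axis and tibial plateau line."""
    spines, ankle, pm, pl = annotation.require(
        "tibial_spines_center", "ankle_center", "plateau_medial", "plateau_lateral"
    )
    axis = _vec(spines, ankle)  # distal
    plateau_med = _vec(pl, pm)  # lateral -> medial
    return _angle_between(axis, plateau_med)


_MEASURERS = {
    "hka_deviation": hka_deviation,
    "mldfa": mldfa,
    "mmpta": mmpta,
}


def measure_all(annotation: LandmarkAnnotation, strict: bool = True) -> AngleSet:
    """Compute all five angles for one annotation.

    In strict mode (default) any missing landmark raises
    :class:`MissingLandmarkError` naming it; with ``strict=False`` angles
    whose landmarks are absent are reported as ``None``.
    """
    result = AngleSet()
    for name, fn in _MEASURERS.items():
        try:
            setattr(result, name, fn(annotation))
        except MissingLandmarkError:
            if strict:
                raise
    try:
        tga, _ = trochlear_angles(annotation)
        result.tga = tga
    except MissingLandmarkError:
        if strict:
            raise
    try:
        result.ba = bisector_angle(annotation)
    except MissingLandmarkError:
        if strict:
            raise
    return result


def mirror_annotation(annotation: LandmarkAnnotation) -> LandmarkAnnotation:
    """Mirror all x-coordinates and flip the side (an exact symmetry of all angles)."""
    flip = Side.LEFT if annotation.side is Side.RIGHT else Side.RIGHT
    return LandmarkAnnotation(
        subject_id=annotation.subject_id,
        side=flip,
        observer_id=annotation.observer_id,
        occasion=annotation.occasion,
        points={k: Point(-p.x, p.y) for k, p in annotation.points.items()},
        contours={k: [Point(-p.x, p.y) for p in c] for k, c in annotation.contours.items()},
    )
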