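"""Synthetic cohorts: angle-level measurement tables and landmark-level limbs.

Two simulators are provided because measurement noise enters through manual
landmarking but the agreement statistics operate on angles:

* :func:`simulate_angle_table` draws a crossed subjects x observers x
  occasions table directly from the two-way random-effects model
  ``y_ijk = mu + a_i + b_j + (ab)_ij + e_ijk``;
* :func:`build_subject_geometry` inverts the angle definitions into a
  noise-free stylized limb whose measured angles reproduce the requested
  truth to machine precision, and :func:`simulate_annotations` adds
  observer-specific landmark bias plus per-occasion isotropic jitter on top.

All stochastic entry points require an explicit seed (via the config or an
``rng``); identical seeds give identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .agreement import MeasurementTable
from .errors import ConstructionError
from .geometry import (
    ANGLE_NAMES,
    AngleSet,
    LandmarkAnnotation,
    Point,
    Side,
    mirror_annotation,
)

__all__ = [
    "PopulationConfig",
    "ObserverConfig",
    "AnatomyConfig",
    "simulate_angle_table",
    "build_subject_geometry",
    "simulate_annotations",
    "cohort_summary",
]

# Population angle distributions for healthy adult limbs (degrees).  The BA
# between-subject SD and the groove-angle parameters are package defaults —
# tunable, not literature values.
_DEFAULT_ANGLES = {
    "hka_deviation": (0.0, 2.48),
    "mldfa": (87.6, 1.88),
    "mmpta": (88.0, 2.2),
    "tga": (30.0, 3.0),
    "ba": (89.4, 1.1),
}


@dataclass
class PopulationConfig:
    """Between-subject angle distributions and cohort composition."""

    angle_means: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in _DEFAULT_ANGLES.items()}
    )
    angle_sds: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in _DEFAULT_ANGLES.items()}
    )
    n_subjects: int = 59  # patients
    bilateral_fraction: float = 51.0 / 59.0
    male_fraction: float = 37.0 / 59.0
    age_range: tuple[float, float] = (19.0, 38.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name, sd in self.angle_sds.items():
            if sd < 0:
                raise ValueError(f"negative SD for {name}")
        if not 0.0 <= self.bilateral_fraction <= 1.0:
            raise ValueError("bilateral_fraction must be in [0, 1]")

    @property
    def n_bilateral(self) -> int:
        return int(round(self.bilateral_fraction * self.n_subjects))

    @property
    def n_limbs(self) -> int:
        return self.n_subjects + self.n_bilateral


@dataclass
class ObserverConfig:
    """Crossed measurement-error structure.

    ``sigma_observer`` / ``sigma_interaction`` / ``sigma_residual`` are in
    degrees for the angle-level simulator.  For the landmark-level simulator
    the observer effect is a per-observer, per-landmark coordinate bias with
    SD ``sigma_observer_mm`` and the residual is per-occasion isotropic
    jitter with SD ``landmark_jitter_sd`` (length units).
    """

    m_observers: int = 3
    r_occasions: int = 1
    sigma_observer: float = 0.5
    sigma_interaction: float = 0.0
    sigma_residual: float = 0.5
    landmark_jitter_sd: float = 0.5
    sigma_observer_mm: float = 0.0
    observer_biases: Optional[Sequence[float]] = None
    observer_residual_sds: Optional[Sequence[float]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.m_observers < 1 or self.r_occasions < 1:
            raise ValueError("m_observers and r_occasions must be >= 1")
        for name in ("sigma_observer", "sigma_interaction", "sigma_residual",
                     "landmark_jitter_sd", "sigma_observer_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.observer_biases is not None and len(self.observer_biases) != self.m_observers:
            raise ValueError("observer_biases length must equal m_observers")
        if (
            self.observer_residual_sds is not None
            and len(self.observer_residual_sds) != self.m_observers
        ):
            raise ValueError("observer_residual_sds length must equal m_observers")

    def rng(self, rng: Optional[np.random.Generator] = None) -> np.random.Generator:
        if rng is not None:
            return rng
        if self.seed is None:
            raise ValueError("a seed (or an explicit rng) is required for stochastic calls")
        return np.random.default_rng(self.seed)


@dataclass
class AnatomyConfig:
    """Stylized limb template dimensions (length units, e.g. mm)."""

    femur_length: float = 420.0
    tibia_length: float = 370.0
    condylar_width: float = 80.0
    notch_depth: float = 25.0
    facet_arc_radius: float = 40.0
    contour_points: int = 15

    def __post_init__(self) -> None:
        for name in ("femur_length", "tibia_length", "condylar_width",
                     "notch_depth", "facet_arc_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.contour_points < 3:
            raise ValueError("contour_points must be >= 3 per facet")


def simulate_angle_table(
    pop: PopulationConfig,
    obs: ObserverConfig,
    angle_name: str = "ba",
    rng: Optional[np.random.Generator] = None,
    n_limbs: Optional[int] = None,
    return_effects: bool = False,
):
    """Draw a crossed measurement table from the two-way random-effects model.

    ``y_ijk = mu + a_i + b_j + (ab)_ij + e_ijk`` with independent zero-mean
    normal components; per-observer fixed biases and per-observer residual
    SDs override the random ``b_j`` / common residual SD when configured.

    With ``return_effects=True`` the realized effect draws are returned as a
    second value, enabling parameter-recovery checks against the *realized*
    (rather than population) components.
    """
    if angle_name not in ANGLE_NAMES:
        raise ValueError(f"unknown angle {angle_name!r}; expected one of {ANGLE_NAMES}")
    gen = obs.rng(rng)
    n = n_limbs if n_limbs is not None else pop.n_limbs
    m, r = obs.m_observers, obs.r_occasions
    mu = pop.angle_means[angle_name]
    sd_subj = pop.angle_sds[angle_name]

    a = gen.normal(0.0, sd_subj, size=n)
    if obs.observer_biases is not None:
        # biases are absolute per-observer target means; recenter on mu
        b = np.asarray(obs.observer_biases, dtype=float) - mu
    else:
        b = gen.normal(0.0, obs.sigma_observer, size=m)
    ab = gen.normal(0.0, obs.sigma_interaction, size=(n, m))
    if obs.observer_residual_sds is not None:
        sds = np.asarray(obs.observer_residual_sds, dtype=float)
        e = gen.normal(0.0, 1.0, size=(n, m, r)) * sds[None, :, None]
    else:
        e = gen.normal(0.0, obs.sigma_residual, size=(n, m, r))

    y = mu + a[:, None, None] + b[None, :, None] + ab[:, :, None] + e
    table = MeasurementTable(angle_name, y)
    if return_effects:
        return table, {"mu": mu, "a": a, "b": b, "ab": ab, "e": e}
    return table


# --- landmark-level construction -------------------------------------------

def _rot_ccw(v: tuple[float, float], deg: float) -> tuple[float, float]:
    rad = math.radians(deg)
    c, s = math.cos(rad), math.sin(rad)
    return (v[0] * c - v[1] * s, v[0] * s + v[1] * c)


def build_subject_geometry(
    true_angles: AngleSet,
    anatomy: Optional[AnatomyConfig] = None,
    side: Side | str = Side.RIGHT,
    subject_id: str = "synthetic",
    observer_id: str = "truth",
    occasion: int = 1,
    include_contours: bool = False,
) -> LandmarkAnnotation:
    """Noise-free stylized limb realizing the requested true angles.

    The limb is laid out in a canonical frame (femoral mechanical axis along
    +y, medial toward +x for a right limb) and mirrored for left limbs.
    ``measure_all`` on the result reproduces ``true_angles`` to within
    1e-9 degrees.  With ``include_contours=True`` the trochlear facets are
    sampled as circular arcs whose supporting tangents from the apex pass
    exactly through the tangent landmarks.

    Raises
    ------
    ConstructionError
        If any requested angle is outside its feasible range.
    """
    anatomy = anatomy or AnatomyConfig()
    side = Side.coerce(side)
    t = true_angles
    for name in ANGLE_NAMES:
        if getattr(t, name) is None:
            raise ConstructionError(f"true angle {name} is required")
    if not (0.0 < t.tga < 180.0):
        raise ConstructionError(f"tga={t.tga} outside (0, 180)")
    for name in ("mldfa", "mmpta", "ba"):
        v = getattr(t, name)
        if not (0.0 < v < 180.0):
            raise ConstructionError(f"{name}={v} outside (0, 180)")
    if not (-90.0 < t.hka_deviation < 90.0):
        raise ConstructionError(f"hka_deviation={t.hka_deviation} outside (-90, 90)")

    wf = anatomy.condylar_width
    notch = (0.0, 0.0)
    hip = (0.0, anatomy.femur_length)

    # Distal femoral joint line: unit lateral direction making the requested
    # lateral angle with the proximal mechanical axis (0, 1).
    mldfa_rad = math.radians(t.mldfa)
    d_lat = (-math.sin(mldfa_rad), math.cos(mldfa_rad))
    cond_lat = (notch[0] + 0.5 * wf * d_lat[0], notch[1] + 0.5 * wf * d_lat[1])
    cond_med = (notch[0] - 0.5 * wf * d_lat[0], notch[1] - 0.5 * wf * d_lat[1])

    # Proximal groove bisector: rotate the medial joint-line direction CCW by
    # the bisector angle (ba < 90 leans the proximal tip medially).
    d_med = (-d_lat[0], -d_lat[1])
    b_prox = _rot_ccw(d_med, t.ba)
    apex = (notch[0] + anatomy.notch_depth * b_prox[0], notch[1] + anatomy.notch_depth * b_prox[1])
    b_dist = (-b_prox[0], -b_prox[1])
    t_len = 1.2 * anatomy.notch_depth
    dir_med = _rot_ccw(b_dist, +0.5 * t.tga)
    dir_lat = _rot_ccw(b_dist, -0.5 * t.tga)
    tan_med = (apex[0] + t_len * dir_med[0], apex[1] + t_len * dir_med[1])
    tan_lat = (apex[0] + t_len * dir_lat[0], apex[1] + t_len * dir_lat[1])

    # Tibia: distal axis direction realizing the signed HKA deviation (for a
    # right limb a varus chain turns CCW at the knee).
    spines = (0.0, -0.2 * anatomy.notch_depth)
    v_t = _rot_ccw((0.0, -1.0), -t.hka_deviation)
    ankle = (spines[0] + anatomy.tibia_length * v_t[0], spines[1] + anatomy.tibia_length * v_t[1])

    # Tibial plateau: medial direction making the requested medial angle with
    # the distal tibial axis.
    d_pm = _rot_ccw(v_t, t.mmpta)
    wt = 0.9 * wf
    plat_med = (spines[0] + 0.5 * wt * d_pm[0], spines[1] + 0.5 * wt * d_pm[1])
    plat_lat = (spines[0] - 0.5 * wt * d_pm[0], spines[1] - 0.5 * wt * d_pm[1])

    points = {
        "hip_center": Point(*hip),
        "femoral_notch_center": Point(*notch),
        "trochlear_apex": Point(*apex),
        "trochlear_tangent_medial": Point(*tan_med),
        "trochlear_tangent_lateral": Point(*tan_lat),
        "condyle_medial": Point(*cond_med),
        "condyle_lateral": Point(*cond_lat),
        "tibial_spines_center": Point(*spines),
        "ankle_center": Point(*ankle),
        "plateau_medial": Point(*plat_med),
        "plateau_lateral": Point(*plat_lat),
    }

    contours: dict[str, list[Point]] = {}
    if include_contours:
        contours["trochlear_contour_medial"] = _facet_arc(
            apex, tan_med, dir_med, d_med, anatomy
        )
        contours["trochlear_contour_lateral"] = _facet_arc(
            apex, tan_lat, dir_lat, (-d_med[0], -d_med[1]), anatomy
        )

    ann = LandmarkAnnotation(
        subject_id=subject_id,
        side=Side.RIGHT,
        observer_id=observer_id,
        occasion=occasion,
        points=points,
        contours=contours,
    )
    if side is Side.LEFT:
        ann = mirror_annotation(ann)
    return ann


def _facet_arc(
    apex: tuple[float, float],
    contact: tuple[float, float],
    ray_dir: tuple[float, float],
    outward: tuple[float, float],
    anatomy: AnatomyConfig,
) -> list[Point]:
    """Sample a circular facet arc tangent to the apex ray at ``contact``.

    The circle's center sits on the ``outward`` (branch) side of the tangent
    line, so the whole arc lies on that side and the contact point is the
    supporting point chosen by the tangent search.  The contact point itself
    is the first sample, keeping contour-based measurement exact.
    """
    r = anatomy.facet_arc_radius
    # unit normal of the ray direction pointing outward
    n1 = (-ray_dir[1], ray_dir[0])
    if n1[0] * outward[0] + n1[1] * outward[1] < 0:
        n1 = (-n1[0], -n1[1])
    center = (contact[0] + r * n1[0], contact[1] + r * n1[1])
    phi0 = math.atan2(contact[1] - center[1], contact[0] - center[0])
    # sweep direction moving away from the apex along the wall
    d_plus = (-math.sin(phi0), math.cos(phi0))
    sweep = 1.0 if d_plus[0] * ray_dir[0] + d_plus[1] * ray_dir[1] > 0 else -1.0
    extent = math.radians(50.0)
    pts = []
    for s in np.linspace(0.0, extent, anatomy.contour_points):
        phi = phi0 + sweep * s
        pts.append(Point(center[0] + r * math.cos(phi), center[1] + r * math.sin(phi)))
    return pts


def simulate_annotations(
    pop: PopulationConfig,
    obs: ObserverConfig,
    anatomy: Optional[AnatomyConfig] = None,
    rng: Optional[np.random.Generator] = None,
    include_contours: bool = False,
    return_truth: bool = False,
):
    """Full landmark-level cohort simulation.

    Per limb: draw true angles from the population, build the noise-free
    geometry, then for every observer x occasion apply the observer's fixed
    per-landmark coordinate bias (SD ``sigma_observer_mm``) plus fresh
    isotropic per-landmark jitter (SD ``landmark_jitter_sd``).

    Returns the flat list of annotations ordered by (limb, observer,
    occasion); with ``return_truth=True`` also a list of ``(subject_id, side,
    AngleSet)`` truths.
    """
    anatomy = anatomy or AnatomyConfig()
    gen = obs.rng(rng)
    limbs = _cohort_limbs(pop, gen)

    observers = [f"obs{j + 1}" for j in range(obs.m_observers)]
    landmark_names = None
    # per-observer systematic landmark bias, drawn once
    obs_bias: dict[str, dict[str, tuple[float, float]]] = {}

    annotations: list[LandmarkAnnotation] = []
    truths: list[tuple[str, Side, AngleSet]] = []
    for subject_id, side in limbs:
        angles = AngleSet(
            **{
                name: float(gen.normal(pop.angle_means[name], pop.angle_sds[name]))
                for name in ANGLE_NAMES
            }
        )
        base = build_subject_geometry(
            angles, anatomy, side, subject_id=subject_id, include_contours=include_contours
        )
        truths.append((subject_id, side, angles))
        if landmark_names is None:
            landmark_names = sorted(base.points)
            for o in observers:
                obs_bias[o] = {
                    name: tuple(gen.normal(0.0, obs.sigma_observer_mm, size=2))
                    for name in landmark_names
                }
        for o in observers:
            for k in range(1, obs.r_occasions + 1):
                points = {}
                for name, p in base.points.items():
                    bx, by = obs_bias[o][name]
                    jx, jy = gen.normal(0.0, obs.landmark_jitter_sd, size=2)
                    points[name] = Point(p.x + bx + jx, p.y + by + jy)
                contours = {
                    cname: [
                        Point(
                            q.x + gen.normal(0.0, obs.landmark_jitter_sd),
                            q.y + gen.normal(0.0, obs.landmark_jitter_sd),
                        )
                        for q in cpts
                    ]
                    for cname, cpts in base.contours.items()
                }
                annotations.append(
                    LandmarkAnnotation(
                        subject_id=subject_id,
                        side=side,
                        observer_id=o,
                        occasion=k,
                        points=points,
                        contours=contours,
                    )
                )
    if return_truth:
        return annotations, truths
    return annotations


def _cohort_limbs(pop: PopulationConfig, gen: np.random.Generator) -> list[tuple[str, Side]]:
    """Limb list for the cohort: bilateral patients contribute both sides."""
    limbs: list[tuple[str, Side]] = []
    n_bi = pop.n_bilateral
    for idx in range(pop.n_subjects):
        pid = f"P{idx + 1:03d}"
        if idx < n_bi:
            limbs.append((f"{pid}-R", Side.RIGHT))
            limbs.append((f"{pid}-L", Side.LEFT))
        else:
            side = Side.RIGHT if gen.random() < 0.5 else Side.LEFT
            limbs.append((f"{pid}-{'R' if side is Side.RIGHT else 'L'}", side))
    return limbs


def cohort_summary(pop: PopulationConfig, seed: Optional[int] = None) -> dict:
    """Cohort composition metadata (never enters any computation).

    Sex and age are generated for fixture realism; the male percentage is
    printed to one decimal place.
    """
    n = pop.n_subjects
    n_male = int(round(pop.male_fraction * n))
    gen = np.random.default_rng(0 if seed is None else seed)
    lo, hi = pop.age_range
    ages = gen.uniform(lo, hi, size=n)
    return {
        "n_patients": n,
        "n_limbs": pop.n_limbs,
        "n_unilateral": n - pop.n_bilateral,
        "n_bilateral": pop.n_bilateral,
        "n_male": n_male,
        "n_female": n - n_male,
        "percent_male": round(100.0 * n_male / n, 1),
        "age_min": float(np.min(ages)),
        "age_max": float(np.max(ages)),
        "age_mean": float(np.mean(ages)),
    }
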