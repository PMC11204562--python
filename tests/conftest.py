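import math

import numpy as np
import pytest

from kneemorph.geometry import AngleSet, Point, Side
from kneemorph.simulate import AnatomyConfig, build_subject_geometry


@pytest.fixture
def anatomy():
    return AnatomyConfig()


def random_feasible_angles(rng: np.random.Generator) -> AngleSet:
    """Draw a random truth vector well inside every feasibility range."""
    return AngleSet(
        hka_deviation=float(rng.uniform(-12.0, 12.0)),
        mldfa=float(rng.uniform(80.0, 95.0)),
        mmpta=float(rng.uniform(80.0, 95.0)),
        tga=float(rng.uniform(10.0, 60.0)),
        ba=float(rng.uniform(80.0, 100.0)),
    )


def transform_annotation(ann, angle_deg=0.0, scale=1.0, dx=0.0, dy=0.0):
    """Rigid motion + uniform scaling applied to every landmark."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))

    def tf(p: Point) -> Point:
        x = scale * (c * p.x - s * p.y) + dx
        y = scale * (s * p.x + c * p.y) + dy
        return Point(x, y)

    from kneemorph.geometry import LandmarkAnnotation

    return LandmarkAnnotation(
        subject_id=ann.subject_id,
        side=ann.side,
        observer_id=ann.observer_id,
        occasion=ann.occasion,
        points={k: tf(p) for k, p in ann.points.items()},
        contours={k: [tf(p) for p in c_] for k, c_ in ann.contours.items()},
    )


def random_annotation(rng: np.random.Generator, include_contours=False):
    angles = random_feasible_angles(rng)
    side = Side.RIGHT if rng.random() < 0.5 else Side.LEFT
    ann = build_subject_geometry(angles, side=side, include_contours=include_contours)
    return ann, angles
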