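import sys
from pathlib import Path

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

sys.path.insert(0, str(Path(__file__).parent))

from facesym.landmarks import LandmarkSet, Point3
from facesym.synthetic import TEMPLATE_POINTS, template


@pytest.fixture
def template_set() -> LandmarkSet:
    return template()


@pytest.fixture
def template_points() -> dict:
    """Template as plain tuples, for feeding the pure-math oracles."""
    return dict(TEMPLATE_POINTS)


def make_set(points: dict, subject: str = "", timepoint: str = "") -> LandmarkSet:
    return LandmarkSet(
        points={k: Point3(*v) for k, v in points.items()},
        subject=subject,
        timepoint=timepoint,
    )


def random_rigid(rng: np.random.Generator):
    """A random rotation + translation as a point-mapping callable."""
    rot = Rotation.random(rng=rng)
    t = rng.uniform(-100.0, 100.0, size=3)

    def apply(xyz):
        return tuple((rot.apply(np.asarray(xyz, float)) + t).tolist())

    return apply


def perturb_points(rng: np.random.Generator, scale: float = 5.0) -> dict:
    """Template with every landmark independently jittered (plain tuples)."""
    return {
        key: tuple(np.asarray(xyz, float) + rng.uniform(-scale, scale, size=3))
        for key, xyz in TEMPLATE_POINTS.items()
    }


def transform_points(points: dict, apply) -> dict:
    return {key: apply(xyz) for key, xyz in points.items()}
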