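"""Generator of landmark sets with known, controllable asymmetry.

The starting point is a bilaterally symmetric skull-like template ("unit
skull"): every bilateral pair mirrors exactly across x = 0 and every midline
landmark sits on x = 0, so the asymmetry profile of the unmodified template
is identically zero.  Controlled asymmetry is introduced as per-landmark
displacement vectors; Gaussian landmark-placement noise and an arbitrary
rigid pose (rotation + translation) can be layered on top.  Displacements
are applied first, then noise, then the pose, and everything is
deterministic under a fixed seed.

The positive-x half of each bilateral pair carries the L label — but note
that nothing downstream depends on that choice of axis; left is defined by
the labels alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParseError, ValidationError
from .geometry import plane_from_points, signed_plane_distance
from .landmarks import BILATERAL_NAMES, LandmarkSet, Point3, derive_midz

__all__ = ["TEMPLATE_POINTS", "AsymmetrySpec", "template", "generate", "mirror", "load_spec"]

#: The canonical symmetric landmark configuration in mm.
TEMPLATE_POINTS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("S", "M"): (0.0, 0.0, 0.0),
    ("N", "M"): (0.0, 75.0, 35.0),
    ("Z", "L"): (45.0, 60.0, 25.0),
    ("Z", "R"): (-45.0, 60.0, 25.0),
    ("Po", "L"): (60.0, -10.0, -10.0),
    ("Po", "R"): (-60.0, -10.0, -10.0),
    ("Or", "L"): (35.0, 65.0, 15.0),
    ("Or", "R"): (-35.0, 65.0, 15.0),
    ("Co", "L"): (55.0, -5.0, -15.0),
    ("Co", "R"): (-55.0, -5.0, -15.0),
    ("Go", "L"): (50.0, 5.0, -80.0),
    ("Go", "R"): (-50.0, 5.0, -80.0),
    ("U6", "L"): (25.0, 45.0, -70.0),
    ("U6", "R"): (-25.0, 45.0, -70.0),
    ("L6", "L"): (27.0, 45.0, -75.0),
    ("L6", "R"): (-27.0, 45.0, -75.0),
    ("ANS", "M"): (0.0, 80.0, -45.0),
    ("U1", "M"): (0.0, 82.0, -60.0),
    ("L1", "M"): (0.0, 82.0, -65.0),
    ("B", "M"): (0.0, 78.0, -85.0),
    ("Me", "M"): (0.0, 70.0, -100.0),
}


@dataclass
class AsymmetrySpec:
    """Recipe for a synthetic landmark set.

    ``displacements`` maps ``(name, side)`` to a 3-vector in mm (side ``M``
    for midline landmarks).  ``rotation_deg`` are intrinsic z-y-x Euler
    angles in degrees; ``noise_sd_mm`` is the SD of zero-mean Gaussian noise
    applied independently per coordinate.  Same spec + seed -> identical
    output.
    """

    displacements: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd_mm: float = 0.0
    seed: int = 0
    subject: str = "synthetic"
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be non-negative")
        for key in self.displacements:
            if key not in TEMPLATE_POINTS:
                name, side = key
                raise ValidationError(f"displacement references unknown landmark {name}({side})")


def template(subject: str = "template", timepoint: str = "") -> LandmarkSet:
    """The unmodified symmetric template as a LandmarkSet."""
    points = {key: Point3(*xyz) for key, xyz in TEMPLATE_POINTS.items()}
    return LandmarkSet(points=points, subject=subject, timepoint=timepoint)


def generate(spec: AsymmetrySpec) -> LandmarkSet:
    """Template + displacements, then Gaussian noise, then rigid pose."""
    rng = np.random.default_rng(spec.seed)
    rot = Rotation.from_euler("ZYX", spec.rotation_deg, degrees=True)
    translation = np.asarray(spec.translation_mm, dtype=float)

    # Draw noise in the fixed key order of the template so the stream of
    # random numbers is independent of which displacements were requested.
    points: dict[tuple[str, str], Point3] = {}
    for key, xyz in TEMPLATE_POINTS.items():
        p = np.asarray(xyz, dtype=float)
        if key in spec.displacements:
            p = p + np.asarray(spec.displacements[key], dtype=float)
        if spec.noise_sd_mm > 0:
            p = p + rng.normal(0.0, spec.noise_sd_mm, size=3)
        p = rot.apply(p) + translation
        points[key] = Point3(*p.tolist())
    return LandmarkSet(points=points, subject=spec.subject, timepoint=spec.timepoint)


def mirror(lm_set: LandmarkSet) -> LandmarkSet:
    """Reflect every point across the N-S-MidZ plane and swap L/R labels.

    The template is its own mirror; applied twice this is the identity.
    """
    plane = plane_from_points(
        lm_set.get("N"),
        lm_set.get("S"),
        derive_midz(lm_set),
        left_witness=lm_set.get("Z", "L"),
        fallback_witness=lm_set.get("Po", "L"),
    )
    normal = np.asarray(plane.normal, dtype=float)
    swapped = {"L": "R", "R": "L", "M": "M"}
    points: dict[tuple[str, str], Point3] = {}
    for (name, side), p in lm_set.points.items():
        v = np.array(p.as_tuple(), dtype=float)
        d = signed_plane_distance(plane, p)
        reflected = v - 2.0 * d * normal
        points[(name, swapped[side])] = Point3(*reflected.tolist())
    return LandmarkSet(points=points, subject=lm_set.subject, timepoint=lm_set.timepoint)


def load_spec(source) -> AsymmetrySpec:
    """Parse an AsymmetrySpec from a JSON stream or string.

    Dialect: ``{displacements: [{name, side, dx, dy, dz}], rotation_deg:
    [a,b,c], translation_mm: [tx,ty,tz], noise_sd_mm, seed}``; all keys
    optional.
    """
    if isinstance(source, str):
        doc = json.loads(source)
    else:
        doc = json.load(source)
    if not isinstance(doc, dict):
        raise ParseError("spec must be a JSON object")
    displacements: dict[tuple[str, str], tuple[float, float, float]] = {}
    for i, entry in enumerate(doc.get("displacements", []), start=1):
        try:
            name = str(entry["name"])
            side = str(entry.get("side", "") or "M").upper()
            if side == "":
                side = "M"
            vec = (float(entry.get("dx", 0)), float(entry.get("dy", 0)), float(entry.get("dz", 0)))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"displacement {i}: {exc}") from None
        if name in BILATERAL_NAMES and side == "M":
            raise ParseError(f"displacement {i}: bilateral landmark {name} needs side L or R")
        displacements[(name, side)] = vec

    def _triple(key: str) -> tuple[float, float, float]:
        v = doc.get(key, (0.0, 0.0, 0.0))
        if not isinstance(v, (list, tuple)) or len(v) != 3:
            raise ParseError(f"{key} must be a 3-element list")
        return tuple(float(c) for c in v)

    return AsymmetrySpec(
        displacements=displacements,
        rotation_deg=_triple("rotation_deg"),
        translation_mm=_triple("translation_mm"),
        noise_sd_mm=float(doc.get("noise_sd_mm", 0.0)),
        seed=int(doc.get("seed", 0)),
        subject=str(doc.get("subject", "synthetic")),
        timepoint=str(doc.get("timepoint", "")),
    )
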