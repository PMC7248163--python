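"""Signed facial asymmetry index for bilateral and midline landmarks.

The index for a landmark is the root-sum-of-squares of differences between
distances measured from fixed cranial reference landmarks:

* **bilateral** landmark (e.g. orbitale): for each of the three midline
  references S, N and MidZ, take the distance to the left point minus the
  distance to the right point; the index is the root of the sum of the
  squared differences.  The direction of deviation is the side whose
  unsigned perpendicular distance to the N-S-MidZ plane is longer.

* **midline** landmark (e.g. menton): take the distance differences from the
  Z pair and the Po pair to the landmark; the index is the root of the sum
  of the two squared differences.  The landmark deviates toward whichever
  side's references it sits closer to.

Right deviation is encoded with a negative signed value, left deviation
positive.  Both formulas use only inter-landmark distances, so the index is
invariant to rigid motion of the whole landmark set — no reference
coordinate system is required.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass

from .errors import AnalysisError, ParseError
from .geometry import distance, plane_from_points, signed_plane_distance
from .landmarks import BILATERAL_NAMES, MIDLINE_NAMES, LandmarkSet, derive_midz

__all__ = [
    "AsymmetryResult",
    "AsymmetryProfile",
    "PROFILE_ORDER",
    "BILATERAL_MEASUREMENTS",
    "MIDLINE_MEASUREMENTS",
    "bilateral_index",
    "midsagittal_index",
    "compute_profile",
    "read_profile",
]

#: Bilateral measurement landmarks (analysed as L/R pairs).
BILATERAL_MEASUREMENTS = ("Or", "Co", "Go", "U6", "L6")

#: Midline measurement landmarks (single points).
MIDLINE_MEASUREMENTS = ("ANS", "U1", "L1", "B", "Me")

#: Canonical profile/report order for the ten measurement landmarks.
PROFILE_ORDER = ("Or", "Co", "ANS", "U6", "U1", "L1", "L6", "Go", "B", "Me")

#: Below this (mm) two compared distances are considered tied -> direction
#: "none".  Far below clinical or numerical significance.
DEFAULT_TIE_TOL = 1e-6


@dataclass(frozen=True)
class AsymmetryResult:
    """Signed asymmetry index for one measurement landmark.

    ``magnitude`` is the root-sum-of-squares of the per-reference distance
    differences stored in ``components``; ``direction`` is the transverse
    deviation side; ``signed_value`` is ``+magnitude`` for left (or no)
    deviation and ``-magnitude`` for right deviation.  A nonzero magnitude
    with direction ``"none"`` means pure vertical/anteroposterior asymmetry
    with no transverse deviation.
    """

    landmark: str
    magnitude: float
    direction: str  # "left" | "right" | "none"
    components: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.direction not in ("left", "right", "none"):
            raise ValueError(f"invalid direction: {self.direction!r}")

    @property
    def signed_value(self) -> float:
        return -self.magnitude if self.direction == "right" else self.magnitude

    def to_dict(self) -> dict:
        return {
            "landmark": self.landmark,
            "magnitude": self.magnitude,
            "direction": self.direction,
            "signed_value": self.signed_value,
            "components": list(self.components),
        }


@dataclass
class AsymmetryProfile:
    """Ordered asymmetry results for one subject/timepoint."""

    results: list[AsymmetryResult]
    subject: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        names = [r.landmark for r in self.results]
        if len(set(names)) != len(names):
            raise ValueError("duplicate landmark in profile")
        order = {n: i for i, n in enumerate(PROFILE_ORDER)}
        self.results.sort(key=lambda r: order.get(r.landmark, len(order)))

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def get(self, landmark: str) -> AsymmetryResult:
        for r in self.results:
            if r.landmark == landmark:
                return r
        raise KeyError(landmark)

    def landmarks(self) -> list[str]:
        return [r.landmark for r in self.results]

    def to_json(self) -> str:
        doc = {
            "subject": self.subject,
            "timepoint": self.timepoint,
            "results": [r.to_dict() for r in self.results],
        }
        return json.dumps(doc, indent=2) + "\n"

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["landmark", "magnitude", "direction", "signed_value"])
        for r in self.results:
            writer.writerow([r.landmark, repr(r.magnitude), r.direction, repr(r.signed_value)])
        return buf.getvalue()


def _reference_plane(lm_set: LandmarkSet):
    return plane_from_points(
        lm_set.get("N"),
        lm_set.get("S"),
        derive_midz(lm_set),
        left_witness=lm_set.get("Z", "L"),
        fallback_witness=lm_set.get("Po", "L"),
    )


def bilateral_index(
    lm_set: LandmarkSet, landmark: str, tie_tol: float = DEFAULT_TIE_TOL
) -> AsymmetryResult:
    """Asymmetry index for a bilateral landmark pair.

    Components are ``dist(r, P_L) - dist(r, P_R)`` for the references S, N
    and MidZ, in that order.  Direction is the side with the longer unsigned
    perpendicular distance to the N-S-MidZ reference plane, or ``"none"``
    when the two perpendicular distances differ by less than ``tie_tol``.
    """
    if landmark not in BILATERAL_NAMES:
        raise AnalysisError(f"{landmark} is not a bilateral landmark")
    p_l = lm_set.get(landmark, "L")
    p_r = lm_set.get(landmark, "R")
    midz = derive_midz(lm_set)
    references = (lm_set.get("S"), lm_set.get("N"), midz)
    components = tuple(distance(r, p_l) - distance(r, p_r) for r in references)
    magnitude = math.sqrt(sum(d * d for d in components))

    plane = _reference_plane(lm_set)
    perp_l = abs(signed_plane_distance(plane, p_l))
    perp_r = abs(signed_plane_distance(plane, p_r))
    if perp_l - perp_r > tie_tol:
        direction = "left"
    elif perp_r - perp_l > tie_tol:
        direction = "right"
    else:
        direction = "none"
    return AsymmetryResult(landmark=landmark, magnitude=magnitude, direction=direction, components=components)


def midsagittal_index(
    lm_set: LandmarkSet, landmark: str, tie_tol: float = DEFAULT_TIE_TOL
) -> AsymmetryResult:
    """Asymmetry index for a midline landmark.

    Components are the left-minus-right distance differences from the Z pair
    and the Po pair to the landmark.  The landmark deviates toward the side
    whose references are closer: with ``s`` the sum of right-minus-left
    distance differences, ``s > tie_tol`` means left deviation, ``s <
    -tie_tol`` right, otherwise none.
    """
    if landmark not in MIDLINE_NAMES:
        raise AnalysisError(f"{landmark} is not a midline landmark")
    m = lm_set.get(landmark)
    d_z = distance(lm_set.get("Z", "L"), m) - distance(lm_set.get("Z", "R"), m)
    d_po = distance(lm_set.get("Po", "L"), m) - distance(lm_set.get("Po", "R"), m)
    components = (d_z, d_po)
    magnitude = math.sqrt(d_z * d_z + d_po * d_po)

    s = -(d_z + d_po)  # right-minus-left: positive when closer to left references
    if s > tie_tol:
        direction = "left"
    elif s < -tie_tol:
        direction = "right"
    else:
        direction = "none"
    return AsymmetryResult(landmark=landmark, magnitude=magnitude, direction=direction, components=components)


def compute_profile(lm_set: LandmarkSet, tie_tol: float = DEFAULT_TIE_TOL) -> AsymmetryProfile:
    """Asymmetry profile over every measurement landmark present in the set.

    Bilateral measurement landmarks use :func:`bilateral_index`, midline ones
    :func:`midsagittal_index`; absent landmarks are simply omitted.
    """
    results = []
    for name in PROFILE_ORDER:
        if name in BILATERAL_MEASUREMENTS:
            if lm_set.has(name, "L"):
                results.append(bilateral_index(lm_set, name, tie_tol))
        elif lm_set.has(name):
            results.append(midsagittal_index(lm_set, name, tie_tol))
    return AsymmetryProfile(results=results, subject=lm_set.subject, timepoint=lm_set.timepoint)


def read_profile(source, format: str = "csv") -> AsymmetryProfile:
    """Parse a profile previously written by :meth:`AsymmetryProfile.to_csv`
    or :meth:`~AsymmetryProfile.to_json`.

    CSV rows carry no components, so parsed results store the magnitude as a
    single component (round-trip of magnitude, direction and signed value is
    exact; components are not preserved by the CSV dialect).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    results: list[AsymmetryResult] = []
    if format == "csv":
        reader = csv.reader(source)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty profile CSV") from None
        if [h.strip().lower() for h in header][:3] != ["landmark", "magnitude", "direction"]:
            raise ParseError(f"bad profile CSV header: {','.join(header)!r}")
        for i, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ParseError(f"row {i}: expected at least 3 fields")
            try:
                magnitude = float(row[1])
            except ValueError:
                raise ParseError(f"row {i}: non-numeric magnitude {row[1]!r}") from None
            results.append(
                AsymmetryResult(
                    landmark=row[0].strip(),
                    magnitude=magnitude,
                    direction=row[2].strip(),
                    components=(magnitude,),
                )
            )
        return AsymmetryProfile(results=results)
    if format == "json":
        try:
            doc = json.load(source)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid profile JSON: {exc}") from None
        for entry in doc.get("results", []):
            results.append(
                AsymmetryResult(
                    landmark=entry["landmark"],
                    magnitude=float(entry["magnitude"]),
                    direction=entry["direction"],
                    components=tuple(float(c) for c in entry.get("components", [entry["magnitude"]])),
                )
            )
        return AsymmetryProfile(
            results=results,
            subject=str(doc.get("subject", "")),
            timepoint=str(doc.get("timepoint", "")),
        )
    raise ValueError(f"unknown format: {format!r}")
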