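"""Data model and file I/O for named 3D anatomical landmarks.

Landmark coordinates are plain x/y/z positions in millimetres as exported from
3D-CT simulation software.  The model carries no global orientation
convention: patient left/right is defined purely by the ``L``/``R`` side
labels attached to bilateral landmarks, never by an axis direction.  All
downstream analysis uses inter-landmark distances only, so results are
independent of the scanner coordinate frame.

Two plain-text dialects are supported:

* CSV — UTF-8, header exactly ``name,side,x,y,z``, one landmark per row,
  side one of ``L``, ``R``, ``M`` or empty (midline).
* JSON — object with keys ``subject``, ``timepoint`` and ``landmarks``
  (a list of ``{name, side, x, y, z}`` objects).
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import ParseError, ValidationError

__all__ = [
    "Point3",
    "LandmarkSet",
    "BILATERAL_NAMES",
    "MIDLINE_NAMES",
    "ALL_NAMES",
    "REQUIRED_REFERENCES",
    "canonical_name",
    "read_landmarks",
    "write_landmarks",
    "derive_midz",
]

#: Landmarks occurring as a left/right pair.
BILATERAL_NAMES = frozenset({"Z", "Po", "Or", "Co", "Go", "U6", "L6"})

#: Landmarks nominally on the facial midline (side label ``M``).
MIDLINE_NAMES = frozenset({"S", "N", "ANS", "U1", "L1", "B", "Me"})

ALL_NAMES = BILATERAL_NAMES | MIDLINE_NAMES

#: (name, side) keys that every valid set must contain.  The cranial
#: reference landmarks anchor both index formulas; measurement landmarks
#: are individually optional (partial dentition must not block analysis).
REQUIRED_REFERENCES = (
    ("N", "M"),
    ("S", "M"),
    ("Z", "L"),
    ("Z", "R"),
    ("Po", "L"),
    ("Po", "R"),
)

# Long-form names accepted on input (case-insensitive) and mapped to the
# canonical short form.
_ALIASES = {
    "sella": "S",
    "nasion": "N",
    "z point": "Z",
    "zpoint": "Z",
    "porion": "Po",
    "orbitale": "Or",
    "condylion": "Co",
    "gonion": "Go",
    "anterior nasal spine": "ANS",
    "upper incisor": "U1",
    "lower incisor": "L1",
    "b point": "B",
    "bpoint": "B",
    "menton": "Me",
    "upper first molar": "U6",
    "lower first molar": "L6",
}

_CANONICAL_BY_LOWER = {name.lower(): name for name in ALL_NAMES}


def canonical_name(raw: str) -> str:
    """Map a raw landmark name to its canonical short form.

    Matching is case-insensitive and accepts the long anatomical names
    ("Gonion", "Menton", "B point", ...).  Raises :class:`ValidationError`
    for unknown names; ``MidZ`` is rejected explicitly because it is always
    derived from the two Z points, never supplied.
    """
    key = raw.strip().lower()
    if key == "midz":
        raise ValidationError("MidZ is derived from the Z points, not an input landmark")
    if key in _CANONICAL_BY_LOWER:
        return _CANONICAL_BY_LOWER[key]
    if key in _ALIASES:
        return _ALIASES[key]
    raise ValidationError(f"unknown landmark name: {raw!r}")


@dataclass(frozen=True)
class Point3:
    """A 3D position in millimetres.  All components must be finite."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for axis, v in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValidationError(f"non-finite {axis} coordinate: {v!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (float(self.x), float(self.y), float(self.z))


def _laterality_side(name: str, side: str) -> str:
    """Validate and normalize the side label for a canonical name."""
    side = side.strip().upper()
    if name in BILATERAL_NAMES:
        if side not in ("L", "R"):
            raise ValidationError(
                f"bilateral landmark {name} requires side L or R, got {side!r}"
            )
        return side
    if side in ("", "M"):
        return "M"
    raise ValidationError(f"midline landmark {name} must have side M or empty, got {side!r}")


@dataclass
class LandmarkSet:
    """A validated collection of named, side-labelled landmarks.

    Keys are ``(canonical name, side)`` with side ``L``/``R`` for bilateral
    landmarks and ``M`` for midline landmarks.  Construction enforces the
    structural contract: the six cranial reference landmarks are present,
    bilateral landmarks come as complete L/R pairs, and no duplicates exist.
    """

    points: dict[tuple[str, str], Point3]
    subject: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        for (name, side) in self.points:
            if name not in ALL_NAMES:
                raise ValidationError(f"unknown landmark name: {name!r}")
            expected = _laterality_side(name, side)
            if expected != side:
                raise ValidationError(f"side label {side!r} not canonical for {name}")
        for key in REQUIRED_REFERENCES:
            if key not in self.points:
                name, side = key
                label = name if name in MIDLINE_NAMES else f"{name}({side})"
                raise ValidationError(f"required reference landmark missing: {label}")
        for name in BILATERAL_NAMES:
            has_l = (name, "L") in self.points
            has_r = (name, "R") in self.points
            if has_l != has_r:
                present, absent = ("L", "R") if has_l else ("R", "L")
                raise ValidationError(
                    f"orphan side for bilateral landmark {name}: "
                    f"{name}({present}) present but {name}({absent}) missing"
                )

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.points

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._sorted_keys())

    def _sorted_keys(self) -> list[tuple[str, str]]:
        order = {n: i for i, n in enumerate(sorted(ALL_NAMES))}
        return sorted(self.points, key=lambda k: (order[k[0]], k[1]))

    def get(self, name: str, side: str = "M") -> Point3:
        key = (name, side)
        if key not in self.points:
            label = name if side == "M" else f"{name}({side})"
            raise ValidationError(f"landmark not present: {label}")
        return self.points[key]

    def has(self, name: str, side: str = "M") -> bool:
        return (name, side) in self.points

    def replace_points(self, points: Mapping[tuple[str, str], Point3]) -> "LandmarkSet":
        """Return a new set with the same labels but new coordinates."""
        return LandmarkSet(points=dict(points), subject=self.subject, timepoint=self.timepoint)


def derive_midz(lm_set: LandmarkSet) -> Point3:
    """Midpoint of the line between the two Z points."""
    zl = lm_set.get("Z", "L")
    zr = lm_set.get("Z", "R")
    return Point3((zl.x + zr.x) / 2.0, (zl.y + zr.y) / 2.0, (zl.z + zr.z) / 2.0)


# ---------------------------------------------------------------------------
# I/O

_CSV_HEADER = ["name", "side", "x", "y", "z"]


def _build_set(
    rows: Iterable[tuple[str, str, float, float, float]],
    subject: str,
    timepoint: str,
) -> LandmarkSet:
    points: dict[tuple[str, str], Point3] = {}
    for i, (name_raw, side_raw, x, y, z) in enumerate(rows, start=1):
        try:
            name = canonical_name(name_raw)
            side = _laterality_side(name, side_raw)
            point = Point3(x, y, z)
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        key = (name, side)
        if key in points:
            label = name if side == "M" else f"{name}({side})"
            raise ValidationError(f"row {i}: duplicate landmark {label}")
        points[key] = point
    return LandmarkSet(points=points, subject=subject, timepoint=timepoint)


def _parse_coord(value: str, row: int, axis: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: non-numeric {axis} coordinate: {value!r}") from None


def read_landmarks(source, format: str = "csv", subject: str = "", timepoint: str = "") -> LandmarkSet:
    """Read a landmark file from a text stream or string.

    ``format`` is ``"csv"`` or ``"json"``.  Unknown names, duplicate
    entries, orphan bilateral sides and missing reference landmarks raise
    :class:`ValidationError`; malformed rows raise :class:`ParseError`.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    if format == "csv":
        return _read_csv(source, subject, timepoint)
    if format == "json":
        return _read_json(source, subject, timepoint)
    raise ValueError(f"unknown format: {format!r}")


def _read_csv(stream, subject: str, timepoint: str) -> LandmarkSet:
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty CSV input") from None
    if [h.strip().lower() for h in header] != _CSV_HEADER:
        raise ParseError(
            f"bad CSV header: expected {','.join(_CSV_HEADER)!r}, got {','.join(header)!r}"
        )
    rows = []
    for i, row in enumerate(reader, start=1):
        if not row or all(not cell.strip() for cell in row):
            continue
        if len(row) != 5:
            raise ParseError(f"row {i}: expected 5 fields, got {len(row)}")
        name, side = row[0], row[1]
        x = _parse_coord(row[2], i, "x")
        y = _parse_coord(row[3], i, "y")
        z = _parse_coord(row[4], i, "z")
        rows.append((name, side, x, y, z))
    return _build_set(rows, subject, timepoint)


def _read_json(stream, subject: str, timepoint: str) -> LandmarkSet:
    try:
        doc = json.load(stream)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from None
    if not isinstance(doc, dict) or "landmarks" not in doc:
        raise ParseError("JSON document must be an object with a 'landmarks' list")
    entries = doc["landmarks"]
    if not isinstance(entries, list):
        raise ParseError("'landmarks' must be a list")
    rows = []
    for i, entry in enumerate(entries, start=1):
        if not isinstance(entry, dict):
            raise ParseError(f"row {i}: landmark entry must be an object")
        try:
            name = str(entry["name"])
        except KeyError:
            raise ParseError(f"row {i}: missing 'name'") from None
        side = str(entry.get("side", "") or "")
        coords = []
        for axis in ("x", "y", "z"):
            if axis not in entry:
                raise ParseError(f"row {i}: missing {axis!r} coordinate")
            v = entry[axis]
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ParseError(f"row {i}: non-numeric {axis} coordinate: {v!r}")
            coords.append(float(v))
        rows.append((name, side, *coords))
    return _build_set(
        rows,
        subject or str(doc.get("subject", "")),
        timepoint or str(doc.get("timepoint", "")),
    )


def write_landmarks(lm_set: LandmarkSet, format: str = "csv") -> str:
    """Serialize a LandmarkSet to the canonical CSV or JSON dialect.

    Coordinates are written with enough digits that a read/write round trip
    reproduces them exactly.
    """
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(_CSV_HEADER)
        for name, side in lm_set:
            p = lm_set.points[(name, side)]
            writer.writerow([name, side, repr(float(p.x)), repr(float(p.y)), repr(float(p.z))])
        return buf.getvalue()
    if format == "json":
        entries = []
        for name, side in lm_set:
            p = lm_set.points[(name, side)]
            entries.append(
                {"name": name, "side": side, "x": float(p.x), "y": float(p.y), "z": float(p.z)}
            )
        doc = {"subject": lm_set.subject, "timepoint": lm_set.timepoint, "landmarks": entries}
        return json.dumps(doc, indent=2) + "\n"
    raise ValueError(f"unknown format: {format!r}")
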