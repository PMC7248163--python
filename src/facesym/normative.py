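"""Normal-standard reference ranges, symmetry classification, cohort screen.

The packaged table holds, per measurement landmark, the mean and SD of the
absolute asymmetry index observed in a 25-subject normal standard group.  A
landmark is classified asymmetric when its observed |signed value| exceeds
``mean + z * SD`` (z defaults to 1.96, the two-sided 5% normal quantile; the
multiplier is configurable because other readings — 1 SD, 2 SD — are
plausible conventions).

The cohort inclusion screen is the perpendicular distance from menton to the
N-S-MidZ midsagittal plane: strictly under 4 mm is included.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

from .errors import AnalysisError, ParseError
from .geometry import plane_from_points, signed_plane_distance
from .index import PROFILE_ORDER, AsymmetryProfile
from .landmarks import LandmarkSet, derive_midz

__all__ = [
    "NormativeEntry",
    "NormativeTable",
    "Classification",
    "ScreeningRecord",
    "classify",
    "menton_screen",
    "load_normative",
    "DEFAULT_Z",
]

DEFAULT_Z = 1.96

# Packaged reference values: per-landmark mean and SD of the absolute index
# in the normal standard group (n = 25, mm).
_DEFAULT_ENTRIES = {
    "Or": (2.12, 1.28),
    "Co": (3.38, 1.41),
    "ANS": (1.77, 0.83),
    "U6": (2.81, 1.61),
    "U1": (2.05, 1.07),
    "L1": (1.97, 1.07),
    "L6": (2.35, 1.53),
    "Go": (3.36, 1.29),
    "B": (2.18, 1.05),
    "Me": (2.37, 1.17),
}


@dataclass(frozen=True)
class NormativeEntry:
    """Mean and SD of |index| (mm) for one landmark in the normal group."""

    landmark: str
    mean_abs: float
    sd_abs: float

    def __post_init__(self) -> None:
        if self.mean_abs < 0 or self.sd_abs < 0:
            raise ValueError(f"negative normative value for {self.landmark}")


@dataclass
class NormativeTable:
    """Per-landmark normative entries plus the threshold multiplier."""

    entries: dict[str, NormativeEntry]
    z_multiplier: float = DEFAULT_Z
    provenance: str = "packaged normal-standard reference (n=25, male, absolute values)"

    @classmethod
    def default(cls) -> "NormativeTable":
        entries = {
            name: NormativeEntry(name, mean, sd) for name, (mean, sd) in _DEFAULT_ENTRIES.items()
        }
        return cls(entries=entries)

    def entry(self, landmark: str) -> NormativeEntry:
        if landmark not in self.entries:
            raise AnalysisError(f"no normative entry for landmark {landmark}")
        return self.entries[landmark]

    def threshold(self, landmark: str) -> float:
        e = self.entry(landmark)
        return e.mean_abs + self.z_multiplier * e.sd_abs


@dataclass(frozen=True)
class Classification:
    """Symmetry verdict for one landmark against the normative table."""

    landmark: str
    signed_value: float
    direction: str
    threshold: float
    verdict: str  # "symmetric" | "asymmetric"

    def to_dict(self) -> dict:
        return {
            "landmark": self.landmark,
            "signed_value": self.signed_value,
            "direction": self.direction,
            "threshold": self.threshold,
            "verdict": self.verdict,
        }


def classify(profile: AsymmetryProfile, table: NormativeTable | None = None) -> list[Classification]:
    """One Classification per profile landmark.

    Asymmetric iff |signed value| strictly exceeds ``mean + z * SD``;
    boundary values classify as symmetric (the chart band is inclusive of
    its outline).  Direction never changes the verdict.
    """
    table = table or NormativeTable.default()
    out = []
    for result in profile:
        threshold = table.threshold(result.landmark)
        verdict = "asymmetric" if abs(result.signed_value) > threshold else "symmetric"
        out.append(
            Classification(
                landmark=result.landmark,
                signed_value=result.signed_value,
                direction=result.direction,
                threshold=threshold,
                verdict=verdict,
            )
        )
    return out


@dataclass(frozen=True)
class ScreeningRecord:
    """Menton-deviation inclusion screen for the normal standard group."""

    distance: float
    threshold: float
    included: bool

    def to_dict(self) -> dict:
        return {"distance": self.distance, "threshold": self.threshold, "included": self.included}


def menton_screen(lm_set: LandmarkSet, threshold: float = 4.0) -> ScreeningRecord:
    """Perpendicular menton-to-midsagittal-plane distance; included iff
    strictly under the threshold (default 4 mm)."""
    plane = plane_from_points(
        lm_set.get("N"),
        lm_set.get("S"),
        derive_midz(lm_set),
        left_witness=lm_set.get("Z", "L"),
        fallback_witness=lm_set.get("Po", "L"),
    )
    dist = abs(signed_plane_distance(plane, lm_set.get("Me")))
    return ScreeningRecord(distance=dist, threshold=threshold, included=dist < threshold)


def load_normative(source=None) -> NormativeTable:
    """Load the packaged table, or parse an override CSV.

    Override dialect: rows ``landmark,mean_abs,sd_abs`` (header optional),
    plus an optional comment line ``# z=<float>`` setting the multiplier.
    Overridden landmarks replace the packaged entries; others keep their
    defaults.
    """
    table = NormativeTable.default()
    if source is None:
        return table
    if isinstance(source, str):
        source = io.StringIO(source)
    z = table.z_multiplier
    entries = dict(table.entries)
    reader = csv.reader(source)
    for i, row in enumerate(reader, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        first = row[0].strip()
        if first.startswith("#"):
            directive = first.lstrip("#").strip()
            if directive.lower().startswith("z="):
                try:
                    z = float(directive[2:])
                except ValueError:
                    raise ParseError(f"row {i}: bad z directive {first!r}") from None
            continue
        if first.lower() == "landmark":
            continue
        if len(row) < 3:
            raise ParseError(f"row {i}: expected landmark,mean_abs,sd_abs")
        name = first
        if name not in PROFILE_ORDER:
            raise ParseError(f"row {i}: unknown measurement landmark {name!r}")
        try:
            mean_abs, sd_abs = float(row[1]), float(row[2])
        except ValueError:
            raise ParseError(f"row {i}: non-numeric normative value") from None
        if mean_abs < 0 or sd_abs < 0:
            raise ParseError(f"row {i}: negative normative value for {name}")
        entries[name] = NormativeEntry(name, mean_abs, sd_abs)
    return NormativeTable(entries=entries, z_multiplier=z, provenance="user override")
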