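"""Polygonal (radar) chart rendering and pre/post-operative comparison.

The chart shows signed per-landmark deviation on ten axes in the canonical
profile order.  The normative band is mirrored about zero: the inner outline
at +/- mean and the outer outline at +/- (mean + z*SD) per landmark; values
inside the outer outline read as facial symmetry, outside as asymmetry.
With two profiles the first (pre-operative) polygon is drawn red and the
second (post-operative) blue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import AnalysisError
from .index import PROFILE_ORDER, AsymmetryProfile
from .normative import NormativeTable, classify
from .reliability import ReliabilityResult

__all__ = ["ComparisonRecord", "compare", "render_chart", "render_report"]

# Stable hash salt so SVG output is byte-identical across runs.
matplotlib.rcParams["svg.hashsalt"] = "facesym"


@dataclass(frozen=True)
class ComparisonRecord:
    """Pre/post signed values for one landmark, with derived change metrics.

    ``delta`` is post minus pre; ``improvement`` is |pre| - |post| (negative
    means the landmark moved further from symmetry).
    """

    landmark: str
    pre: float
    post: float
    pre_verdict: str
    post_verdict: str

    @property
    def delta(self) -> float:
        return self.post - self.pre

    @property
    def improvement(self) -> float:
        return abs(self.pre) - abs(self.post)

    def to_dict(self) -> dict:
        return {
            "landmark": self.landmark,
            "pre": self.pre,
            "post": self.post,
            "delta": self.delta,
            "improvement": self.improvement,
            "pre_verdict": self.pre_verdict,
            "post_verdict": self.post_verdict,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ComparisonRecord":
        return cls(
            landmark=doc["landmark"],
            pre=float(doc["pre"]),
            post=float(doc["post"]),
            pre_verdict=doc["pre_verdict"],
            post_verdict=doc["post_verdict"],
        )


def compare(
    pre: AsymmetryProfile,
    post: AsymmetryProfile,
    table: NormativeTable | None = None,
) -> tuple[list[ComparisonRecord], list[str]]:
    """Match pre/post profiles by landmark name.

    Returns the per-landmark records in canonical order plus the list of
    landmarks present in only one profile.  An empty intersection is an
    error.
    """
    table = table or NormativeTable.default()
    pre_cls = {c.landmark: c for c in classify(pre, table)}
    post_cls = {c.landmark: c for c in classify(post, table)}
    shared = [n for n in PROFILE_ORDER if n in pre_cls and n in post_cls]
    if not shared:
        raise AnalysisError("pre and post profiles share no landmarks")
    unmatched = sorted(
        (set(pre_cls) | set(post_cls)) - set(shared),
        key=lambda n: PROFILE_ORDER.index(n) if n in PROFILE_ORDER else len(PROFILE_ORDER),
    )
    records = [
        ComparisonRecord(
            landmark=n,
            pre=pre_cls[n].signed_value,
            post=post_cls[n].signed_value,
            pre_verdict=pre_cls[n].verdict,
            post_verdict=post_cls[n].verdict,
        )
        for n in shared
    ]
    return records, unmatched


def _band_radii(table: NormativeTable, landmarks: list[str]) -> tuple[list[float], list[float]]:
    inner = [table.entry(n).mean_abs for n in landmarks]
    outer = [table.threshold(n) for n in landmarks]
    return inner, outer


def render_chart(
    profiles: AsymmetryProfile | list[AsymmetryProfile],
    table: NormativeTable | None = None,
    output: str | Path = "chart.svg",
) -> Path:
    """Draw the polygonal asymmetry chart to an SVG or PNG file.

    Axes are the ten measurement landmarks in canonical order; each profile
    is drawn as one closed polygon of signed values (first red, second
    blue).  The radial scale auto-fits the largest |value| or outer
    threshold plus 10%, and is shifted so the most negative representable
    deviation maps to the center.
    """
    if isinstance(profiles, AsymmetryProfile):
        profiles = [profiles]
    if not profiles or any(len(p) == 0 for p in profiles):
        raise AnalysisError("cannot render chart from an empty profile")
    table = table or NormativeTable.default()
    output = Path(output)
    if output.suffix.lower() not in (".svg", ".png"):
        raise ValueError(f"unknown chart extension {output.suffix!r} (use .svg or .png)")

    landmarks = list(PROFILE_ORDER)
    inner, outer = _band_radii(table, landmarks)

    values = {}
    for i, profile in enumerate(profiles):
        values[i] = {r.landmark: r.signed_value for r in profile}

    limit = max(
        max(outer),
        max((abs(v) for vs in values.values() for v in vs.values()), default=0.0),
    ) * 1.1

    angles = np.linspace(0, 2 * np.pi, len(landmarks), endpoint=False)

    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"projection": "polar"})
    ax.set_theta_offset(np.pi / 2)
    ax.set_theta_direction(-1)
    # Radial axis spans [-limit, limit]; zero deviation is the mid ring.
    ax.set_ylim(-limit, limit)
    ax.set_xticks(angles)
    ax.set_xticklabels(landmarks)

    def _close(seq):
        return np.concatenate([seq, seq[:1]])

    ang = _close(angles)
    ax.fill(ang, _close(np.array(outer)), color="#c8e6c9", alpha=0.6, zorder=1)
    ax.fill(ang, _close(-np.array(outer)), color="#c8e6c9", alpha=0.6, zorder=1)
    ax.fill(ang, _close(np.array(inner)), color="#66bb6a", alpha=0.5, zorder=2)
    ax.fill(ang, _close(-np.array(inner)), color="#66bb6a", alpha=0.5, zorder=2)
    ax.plot(ang, _close(np.zeros(len(landmarks))), color="#555555", lw=0.8, zorder=3)

    colors = ["#d62728", "#1f77b4"]
    for i, profile in enumerate(profiles):
        radii = np.array([values[i].get(n, 0.0) for n in landmarks])
        color = colors[i % len(colors)]
        label = profile.timepoint or f"profile {i + 1}"
        ax.plot(ang, _close(radii), color=color, lw=1.5, zorder=4, label=label)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    ax.set_title("Facial asymmetry index (mm; left +, right -)")

    fig.savefig(output, metadata=_deterministic_metadata(output.suffix.lower()))
    plt.close(fig)
    return output


def _deterministic_metadata(suffix: str) -> dict:
    if suffix == ".svg":
        return {"Date": None, "Creator": "facesym"}
    return {"Software": "facesym"}


def render_report(
    comparison: list[ComparisonRecord],
    screening=None,
    reliability: ReliabilityResult | None = None,
    change_threshold: float = 0.5,
) -> tuple[dict, str]:
    """Machine-readable + human-readable pre/post report.

    ``change_threshold`` (mm) decides which landmarks the text summary calls
    changed.  Returns (JSON-serializable dict, plain-text summary).
    """
    if not comparison:
        raise AnalysisError("comparison is empty")
    doc: dict = {"comparison": [r.to_dict() for r in comparison]}
    if screening is not None:
        doc["screening"] = screening.to_dict()
    if reliability is not None:
        doc["reliability"] = reliability.to_dict()

    lines = ["Pre/post asymmetry comparison", "=" * 29]
    changed, unchanged = [], []
    for r in comparison:
        tag = ""
        if r.pre_verdict != r.post_verdict:
            tag = f"  [{r.pre_verdict} -> {r.post_verdict}]"
        lines.append(
            f"{r.landmark:>4}: pre {r.pre:+7.2f}  post {r.post:+7.2f}  "
            f"delta {r.delta:+7.2f}  improvement {r.improvement:+7.2f}{tag}"
        )
        (changed if abs(r.delta) > change_threshold else unchanged).append(r.landmark)
    if changed:
        lines.append(f"Changed beyond {change_threshold} mm: {', '.join(changed)}")
    if unchanged:
        lines.append(f"Essentially unchanged: {', '.join(unchanged)}")
    if screening is not None:
        verdict = "included" if screening.included else "excluded"
        lines.append(
            f"Menton screen: {screening.distance:.2f} mm from midsagittal plane -> {verdict}"
        )
    if reliability is not None:
        lines.append(
            f"Reliability: Dahlberg SE {reliability.dahlberg_se:.3f} mm, "
            f"t = {reliability.t_statistic:.3f}, p = {reliability.p_value:.4f} "
            f"(n = {reliability.n})"
        )
    return doc, "\n".join(lines) + "\n"
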