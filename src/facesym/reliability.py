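"""Double-measurement reproducibility statistics.

Implements the two standard checks for repeated cephalometric measurements:
the Dahlberg method error SE = sqrt(sum(d^2) / 2n) over paired double
measurements, and a two-sided paired t test on the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError

__all__ = ["MeasurementPairs", "ReliabilityResult", "dahlberg_error", "paired_t", "assess"]


@dataclass(frozen=True)
class MeasurementPairs:
    """Paired first/second measurements (mm) of the same items."""

    first: tuple[float, ...]
    second: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.first) != len(self.second):
            raise AnalysisError(
                f"unpaired measurements: {len(self.first)} vs {len(self.second)}"
            )
        if len(self.first) == 0:
            raise AnalysisError("at least one measurement pair is required")
        for v in (*self.first, *self.second):
            if not math.isfinite(v):
                raise AnalysisError(f"non-finite measurement: {v!r}")

    @property
    def n(self) -> int:
        return len(self.first)

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.first, dtype=float) - np.asarray(self.second, dtype=float)


@dataclass(frozen=True)
class ReliabilityResult:
    dahlberg_se: float
    t_statistic: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "dahlberg_se": self.dahlberg_se,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n": self.n,
        }


def dahlberg_error(pairs: MeasurementPairs) -> float:
    """Dahlberg method error sqrt(sum(d^2) / 2n) in mm."""
    d = pairs.differences
    return float(np.sqrt(np.sum(d * d) / (2.0 * pairs.n)))


def paired_t(pairs: MeasurementPairs) -> tuple[float, float]:
    """Two-sided paired t test on the differences.

    Requires n >= 2 and nonzero variance of the differences; degenerate
    inputs raise :class:`AnalysisError` rather than returning infinities.
    """
    if pairs.n < 2:
        raise AnalysisError("paired t test requires at least 2 pairs")
    d = pairs.differences
    if float(np.std(d, ddof=1)) == 0.0:
        raise AnalysisError(
            "paired t test undefined: differences have zero variance"
            + (" (all differences are exactly zero)" if np.all(d == 0) else "")
        )
    t, p = stats.ttest_rel(np.asarray(pairs.first, float), np.asarray(pairs.second, float))
    return float(t), float(p)


def assess(pairs: MeasurementPairs) -> ReliabilityResult:
    """Dahlberg SE plus the paired t test in one record."""
    t, p = paired_t(pairs)
    return ReliabilityResult(
        dahlberg_se=dahlberg_error(pairs), t_statistic=t, p_value=p, n=pairs.n
    )
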