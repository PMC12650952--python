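"""Digital quantification: positive fractions to concentrations and times.

In a digital assay the sample is partitioned over many femtoliter
chambers; with mean occupancy lambda = c * V * N_A per chamber, the
fraction of occupied (hence potentially positive) chambers is
1 - exp(-lambda).  The estimator used here by default is the linear one,

    cE = lambda_exp / (V * N_A),

with lambda_exp the observed positive fraction — it ignores multiple
occupancy, a bias below 5% for fractions around 0.1.  The standard
Poisson-corrected estimator, -ln(1 - f) / (V * N_A), inverts the loading
law exactly and is available behind an explicit flag.

Time-lapse series of positive counts yield two figures of merit: the
*detection time* (first time the per-image positive count, initially <= 2,
exceeds a trigger of 10 — about 0.1% of a 10,000-chamber image) and the
*quantification time* (first time after detection that the relative change
in positive count between consecutive frames falls below 20%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23  # mol^-1
UM3_TO_L = 1e-15


class SaturationError(ValueError):
    """All chambers positive: the Poisson-corrected estimate diverges; dilute the sample."""


class InitialStateWarning(UserWarning):
    """First-frame positive count already above the expected initial level."""


def chamber_volume(diameter_um: float, depth_um: float) -> float:
    """Cylindrical chamber volume V = pi * (d/2)^2 * h, in liters."""
    if diameter_um <= 0 or depth_um <= 0:
        raise ValueError("diameter and depth must be positive")
    r = diameter_um / 2.0
    return math.pi * r * r * depth_um * UM3_TO_L


def estimate_concentration(positive_fraction: float, chamber_volume_L: float) -> float:
    """Linear digital estimator cE = f / (V * N_A), in mol/L."""
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    if chamber_volume_L <= 0:
        raise ValueError("chamber_volume_L must be positive")
    return positive_fraction / (chamber_volume_L * AVOGADRO)


def estimate_concentration_poisson(positive_fraction: float,
                                   chamber_volume_L: float) -> float:
    """Poisson-corrected estimator -ln(1 - f) / (V * N_A), in mol/L.

    Inverts the loading law exactly, accounting for multiply occupied
    chambers; always >= the linear estimate, with equality only at f = 0.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    if chamber_volume_L <= 0:
        raise ValueError("chamber_volume_L must be positive")
    if positive_fraction == 1.0:
        raise SaturationError(
            "every chamber is positive; the occupancy estimate diverges — dilute the sample")
    return -math.log1p(-positive_fraction) / (chamber_volume_L * AVOGADRO)


# ---------------------------------------------------------------------------
# time-lapse metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeCourse:
    """Positive-chamber counts over time for one imaged field."""

    times_min: np.ndarray
    positive_counts: np.ndarray
    n_total: int
    frame_interval_min: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_min", np.asarray(self.times_min, dtype=float))
        object.__setattr__(self, "positive_counts",
                           np.asarray(self.positive_counts, dtype=int))
        if self.times_min.size != self.positive_counts.size:
            raise ValueError("times and counts must have equal length")
        if self.times_min.size == 0:
            raise ValueError("time course must be nonempty")
        if self.times_min.size > 1 and not np.all(np.diff(self.times_min) > 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.times_min,
                      "n_positive": self.positive_counts,
                      "n_total": self.n_total}).to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> "TimeCourse":
        frame = pd.read_csv(path)
        return TimeCourse(times_min=frame["time_min"].to_numpy(),
                          positive_counts=frame["n_positive"].to_numpy(),
                          n_total=int(frame["n_total"].iloc[0]))


def detection_time(tc: TimeCourse, initial_max: int = 2,
                   trigger: int = 10) -> float | None:
    """Earliest time whose positive count strictly exceeds ``trigger``.

    The count is expected to start at or below ``initial_max``; if the
    first frame is already above it an :class:`InitialStateWarning` is
    issued and the result is still computed.  Returns None if the trigger
    is never exceeded.
    """
    counts = tc.positive_counts
    if counts[0] > initial_max:
        warnings.warn(f"first-frame positive count {counts[0]} exceeds "
                      f"initial_max={initial_max}", InitialStateWarning,
                      stacklevel=2)
    above = np.nonzero(counts > trigger)[0]
    if above.size == 0:
        return None
    return float(tc.times_min[above[0]])


def quantification_time(tc: TimeCourse, detection_t: float,
                        rel_change: float = 0.2) -> float | None:
    """First time after detection when the count change between consecutive
    frames drops below ``rel_change`` of the previous frame.

    Pairs whose previous count is zero are skipped (relative change
    undefined).  Returns None if the change never settles.
    """
    times = tc.times_min
    if not np.any(np.isclose(times, detection_t)):
        raise ValueError("detection_t must be one of the time points in the series")
    counts = tc.positive_counts
    for i in range(1, times.size):
        if times[i] <= detection_t:
            continue
        prev = counts[i - 1]
        if prev == 0:
            continue
        if abs(int(counts[i]) - int(prev)) / prev < rel_change:
            return float(times[i])
    return None


def replicate_cv(values) -> float:
    """Coefficient of variation in percent: 100 * sample SD (n-1) / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two replicate values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CV undefined for nonpositive mean")
    return float(100.0 * values.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# summary container
# ---------------------------------------------------------------------------

@dataclass
class QuantResult:
    """Endpoint quantification of one analyzed chip image.

    ``positive_fraction`` uses the post-exclusion denominator
    (n_total - n_excluded).  ``concentration_estimate_M`` is the linear
    estimator; ``concentration_poisson_M`` is the Poisson-corrected one
    (None at saturation).
    """

    n_total: int
    n_positive: int
    n_excluded: int
    positive_fraction: float
    chamber_volume_L: float
    concentration_estimate_M: float
    concentration_poisson_M: float | None
    detection_time_min: float | None = None
    quantification_time_min: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_positive": self.n_positive,
            "n_excluded": self.n_excluded,
            "positive_fraction": self.positive_fraction,
            "chamber_volume_L": self.chamber_volume_L,
            "concentration_estimate_M": self.concentration_estimate_M,
            "concentration_poisson_M": self.concentration_poisson_M,
            "detection_time_min": self.detection_time_min,
            "quantification_time_min": self.quantification_time_min,
            "warnings": list(self.warnings),
        }


def summarize_counts(n_total: int, n_positive: int, n_excluded: int,
                     chamber_volume_L: float) -> QuantResult:
    """Build a :class:`QuantResult` from chamber counts and chamber volume."""
    if n_excluded > n_total:
        raise ValueError("cannot exclude more chambers than exist")
    denom = n_total - n_excluded
    fraction = n_positive / denom if denom > 0 else 0.0
    linear = estimate_concentration(fraction, chamber_volume_L)
    try:
        corrected = estimate_concentration_poisson(fraction, chamber_volume_L)
    except SaturationError:
        corrected = None
    return QuantResult(n_total=n_total, n_positive=n_positive, n_excluded=n_excluded,
                       positive_fraction=fraction, chamber_volume_L=chamber_volume_L,
                       concentration_estimate_M=linear,
                       concentration_poisson_M=corrected)
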