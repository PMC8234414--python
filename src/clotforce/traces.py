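"""Displacement-to-force conversion and contraction-curve summaries.

A one-hour assay records platform deflection versus time while the clot
contracts; multiplying by the chip spring constant turns the deflection trace
into a force trace (F = k*x, pointwise). From the force trace we extract the
quantities reported per sample: maximum contraction force (optionally after
moving-average smoothing), plateau force, and simple kinetic landmarks (lag
time, time to half-maximum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataQualityError, InsufficientDataError
from .mems import SensorChip

__all__ = [
    "DisplacementTrace",
    "ForceTrace",
    "ContractionSummary",
    "to_force_trace",
    "max_contraction_force",
    "contraction_kinetics",
]

#: Default assay duration, seconds (the assay length is one hour).
DEFAULT_ASSAY_DURATION_S = 3600.0


def _validate_series(times: np.ndarray, values: np.ndarray, max_duration: Optional[float]) -> None:
    if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
        raise DataQualityError("times and values must be 1-D and equal length")
    if times.size == 0:
        raise InsufficientDataError("empty trace")
    if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
        raise DataQualityError("trace contains non-finite values")
    if times[0] < 0:
        raise DataQualityError("times must start at >= 0")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise DataQualityError("times must be strictly increasing")
    if max_duration is not None and times[-1] > max_duration:
        raise DataQualityError(
            f"trace spans {times[-1]:.0f} s, beyond the {max_duration:.0f} s assay window"
        )


@dataclass
class DisplacementTrace:
    """Platform deflection (um) versus time (s) for one blood sample."""

    times: np.ndarray
    deflections: np.ndarray
    sample_id: str = ""
    condition: str = ""
    max_duration: Optional[float] = DEFAULT_ASSAY_DURATION_S

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.deflections = np.asarray(self.deflections, dtype=float)
        _validate_series(self.times, self.deflections, self.max_duration)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class ForceTrace:
    """Transduced contraction force (uN) versus time (s)."""

    times: np.ndarray
    forces: np.ndarray
    chip_k: float
    sample_id: str = ""
    condition: str = ""
    max_duration: Optional[float] = DEFAULT_ASSAY_DURATION_S

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        _validate_series(self.times, self.forces, self.max_duration)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ContractionSummary:
    """Per-sample contraction descriptors extracted from a force trace.

    ``complete`` is False when the trace never develops force (flat/zero), in
    which case the kinetic landmarks are None.
    """

    max_force: float
    time_to_half_max: Optional[float]
    plateau_force: float
    lag_time: Optional[float]
    complete: bool = True


def to_force_trace(
    trace: DisplacementTrace,
    chip: SensorChip,
    negative_tolerance: float = -1.0,
) -> ForceTrace:
    """Pointwise Hooke's-law transduction of a displacement trace.

    Small negative deflections (thermal drift) are tolerated down to
    ``negative_tolerance`` micrometers; anything below that is a data-quality
    error rather than a physical contraction signal.
    """
    if float(np.min(trace.deflections)) < negative_tolerance:
        raise DataQualityError(
            f"deflection {np.min(trace.deflections):.2f} um below tolerance "
            f"{negative_tolerance} um"
        )
    return ForceTrace(
        times=trace.times.copy(),
        forces=chip.spring_constant_k * trace.deflections,
        chip_k=chip.spring_constant_k,
        sample_id=trace.sample_id,
        condition=trace.condition,
        max_duration=trace.max_duration,
    )


def _smooth(forces: np.ndarray, times: np.ndarray, window_s: float) -> np.ndarray:
    """Centered moving average with an edge-shrinking window."""
    if window_s <= 0 or forces.size < 3:
        return forces
    dt = float(np.median(np.diff(times)))
    n = max(1, int(round(window_s / dt)))
    if n <= 1:
        return forces
    return (
        pd.Series(forces).rolling(window=n, center=True, min_periods=1).mean().to_numpy()
    )


def max_contraction_force(ftrace: ForceTrace, smooth_window: float = 30.0) -> float:
    """Maximum of the (optionally smoothed) force trace, microNewtons.

    ``smooth_window`` is the centered moving-average window in seconds;
    0 disables smoothing and returns the raw maximum. Invariant under any
    monotone reparameterization of time that preserves the sample spacing
    used to size the window.
    """
    if len(ftrace) < 2:
        raise InsufficientDataError("need >= 2 samples for a maximum-force estimate")
    if smooth_window < 0:
        raise ValueError("smooth_window must be >= 0")
    return float(np.max(_smooth(ftrace.forces, ftrace.times, smooth_window)))


def contraction_kinetics(
    ftrace: ForceTrace,
    lag_fraction: float = 0.05,
    plateau_fraction: float = 0.10,
) -> ContractionSummary:
    """Kinetic landmarks of a contraction curve.

    lag time = first crossing of ``lag_fraction`` of the maximum; time to
    half-max = first crossing of 50%; plateau = mean of the final
    ``plateau_fraction`` of samples. A trace that never develops positive
    force is returned flagged (``complete=False``) with kinetics absent.
    """
    if len(ftrace) < 2:
        raise InsufficientDataError("need >= 2 samples for kinetics")
    f, t = ftrace.forces, ftrace.times
    fmax = float(np.max(f))
    n_tail = max(1, int(math.ceil(plateau_fraction * f.size)))
    plateau = float(np.mean(f[-n_tail:]))
    if fmax <= 0.0:
        return ContractionSummary(
            max_force=fmax,
            time_to_half_max=None,
            plateau_force=plateau,
            lag_time=None,
            complete=False,
        )
    lag_idx = int(np.argmax(f >= lag_fraction * fmax))
    half_idx = int(np.argmax(f >= 0.5 * fmax))
    return ContractionSummary(
        max_force=fmax,
        time_to_half_max=float(t[half_idx]),
        plateau_force=plateau,
        lag_time=float(t[lag_idx]),
        complete=True,
    )
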