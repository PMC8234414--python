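"""Group summaries, the study's percent-change convention, and the
force-versus-phosphorylation regression.

The percent-change convention used for all reported effects is asymmetric and
deliberately non-standard: an increase is expressed relative to the *treated*
mean, a decrease relative to the *control* mean,

    treated >= control:  +100 * (treated - control) / treated
    treated <  control:  -100 * (control - treated) / control

This is the only reading that reproduces both reported contraction-force
effects simultaneously (7337 vs 2958 uN -> +60%; 922 vs 2958 uN -> -69%), so
it is adopted package-wide and inverted exactly by the synthetic generator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import DegenerateInputError, DomainError, InsufficientDataError, SingleValueWarning

__all__ = [
    "ConditionGroup",
    "RegressionResult",
    "group_summary",
    "percent_change",
    "fit_force_phospho",
    "condition_table",
]


@dataclass(frozen=True)
class ConditionGroup:
    """Values for one condition with their recomputable summary statistics.

    ``sd`` uses the sample (n-1) denominator; ``iqr`` uses linear-interpolation
    quartiles. For a single observation the SD is reported as 0.0 with
    ``sd_defined=False``.
    """

    condition: str
    values: np.ndarray
    n: int
    mean: float
    sd: float
    median: float
    iqr: float
    sd_defined: bool = True


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary-least-squares line with its coefficient of determination."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def group_summary(values: Sequence[float], condition: str = "") -> ConditionGroup:
    """Mean, sample SD, median and IQR of one condition's values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("cannot summarize an empty group")
    if not np.all(np.isfinite(v)):
        raise DomainError("group values must be finite")
    if v.size == 1:
        warnings.warn("single observation: SD undefined, reported as 0", SingleValueWarning,
                      stacklevel=2)
        sd, sd_defined = 0.0, False
    else:
        sd, sd_defined = float(np.std(v, ddof=1)), True
    q1, q3 = np.percentile(v, [25.0, 75.0])
    return ConditionGroup(
        condition=condition,
        values=v,
        n=int(v.size),
        mean=float(np.mean(v)),
        sd=sd,
        median=float(np.median(v)),
        iqr=float(q3 - q1),
        sd_defined=sd_defined,
    )


def percent_change(treated_mean: float, control_mean: float) -> float:
    """Signed percent change under the asymmetric study convention.

    See the module docstring: increases are relative to the treated mean,
    decreases relative to control. Both means must be strictly positive.
    """
    if not (math.isfinite(treated_mean) and treated_mean > 0):
        raise DomainError(f"treated_mean must be > 0, got {treated_mean!r}")
    if not (math.isfinite(control_mean) and control_mean > 0):
        raise DomainError(f"control_mean must be > 0, got {control_mean!r}")
    if treated_mean >= control_mean:
        return 100.0 * (treated_mean - control_mean) / treated_mean
    return -100.0 * (control_mean - treated_mean) / control_mean


def mean_from_percent_change(pct: float, control_mean: float) -> float:
    """Invert :func:`percent_change`: the treated mean producing ``pct``.

    Used by the synthetic generator to back-compute absolute condition means
    from reported percent changes.
    """
    if not (math.isfinite(control_mean) and control_mean > 0):
        raise DomainError(f"control_mean must be > 0, got {control_mean!r}")
    if pct >= 100.0 or pct <= -100.0:
        raise DomainError(f"percent change must lie in (-100, 100), got {pct}")
    if pct >= 0:
        return control_mean / (1.0 - pct / 100.0)
    return control_mean * (1.0 + pct / 100.0)


def fit_force_phospho(
    forces: Sequence[float], pmlc: Sequence[float]
) -> RegressionResult:
    """OLS regression of normalized pMLC level on mean contraction force.

    Each point is one condition (force mean on x, pMLC level on y). R^2 equals
    the squared Pearson correlation of the paired vectors; collinear input
    yields R^2 = 1.
    """
    x = np.asarray(forces, dtype=float)
    y = np.asarray(pmlc, dtype=float)
    if x.size != y.size:
        raise DomainError("forces and pmlc must be paired (equal length)")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 conditions, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("zero variance in force (x) values")
    if np.ptp(y) == 0.0:
        return RegressionResult(slope=0.0, intercept=float(np.mean(y)), r_squared=0.0,
                                n_points=int(x.size))
    fit = _sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=int(x.size),
    )


def condition_table(
    values_by_condition: Mapping[str, Sequence[float]], control: str = "control"
) -> pd.DataFrame:
    """Per-condition summary table with percent change versus control.

    Columns: condition, n, mean, sd, median, iqr, pct_change_vs_control.
    """
    if control not in values_by_condition:
        raise DomainError(f"control condition {control!r} missing from dataset")
    control_mean = float(np.mean(np.asarray(values_by_condition[control], dtype=float)))
    rows = []
    for cond, vals in values_by_condition.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SingleValueWarning)
            g = group_summary(vals, condition=cond)
        rows.append(
            {
                "condition": cond,
                "n": g.n,
                "mean": g.mean,
                "sd": g.sd,
                "median": g.median,
                "iqr": g.iqr,
                "pct_change_vs_control": percent_change(g.mean, control_mean),
            }
        )
    return pd.DataFrame(rows)
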