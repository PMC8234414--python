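"""Synthetic-data generator for every input the analysis pipeline consumes.

No clot-contraction dataset is publicly deposited, so all stages are exercised
on generated data carrying the reported statistical structure:

* **Contraction traces** — logistic-with-lag deflection curves over the
  3600 s assay; per-subject plateau forces drawn from a truncated normal with
  the condition's mean/SD. The control condition is 2958 +/- 373 uN; U46619
  7337 +/- 1408; Cpd7a 922 +/- 504. Conditions whose absolute means are only
  reported as percent changes are back-computed through the study's
  percent-change convention (increases relative to treated, decreases relative
  to control), with SDs set to the control coefficient of variation.
* **Calibration series** — linear nanoindenter force-deflection data with
  Gaussian force noise defaulting to 4% of full scale, which places the
  linearity score (100 x R^2) in the reported 96-99% band.
* **ELISA plates** — well ODs whose blank-subtracted pMLC/total-MLC ratios
  reproduce each condition's pMLC percent change exactly at zero noise, with
  multiplicative lognormal well noise.
* **Blot lanes** — band intensities matching the configured pMLC ratios.
* **Correlation datasets** — condition-level (force, pMLC) pairs constructed
  to hit a target sample R^2 exactly via residual orthogonalization.

All generators are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import DomainError
from .mems import CalibrationSeries, SensorChip
from .phospho import ANALYTE_BLANK, ANALYTE_PMLC, ANALYTE_TOTAL_MLC, BlotLane, ElisaPlate
from .stats import mean_from_percent_change
from .traces import DisplacementTrace

__all__ = [
    "ConditionConfig",
    "TraceModel",
    "default_condition_configs",
    "pmlc_ratio",
    "expected_plateau_mean",
    "expected_plateau_sd",
    "generate_contraction_trace",
    "generate_condition_dataset",
    "generate_calibration_series",
    "generate_elisa_plate",
    "generate_blot_lanes",
    "generate_correlation_dataset",
    "final_concentration",
    "CONTROL_MEAN_FORCE_UN",
    "CONTROL_SD_FORCE_UN",
    "DEFAULT_CALIBRATION_NOISE_FRACTION",
]

CONTROL_MEAN_FORCE_UN = 2958.0
CONTROL_SD_FORCE_UN = 373.0

#: Gaussian force-noise SD of the simulated nanoindenter, as a fraction of the
#: chip's full-scale force (k x max_stroke). 4% puts 100 x R^2 of a 50-point
#: 0-100 um sweep at ~98, inside the reported 96-99% linearity band for every
#: spring constant.
DEFAULT_CALIBRATION_NOISE_FRACTION = 0.04


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ConditionConfig:
    """Per-condition simulation parameters.

    ``mean_max_force``/``sd_max_force`` parameterize the truncated-normal
    plateau-force distribution across subjects (uN); ``pmlc_effect`` is the
    signed pMLC percent change versus control under the study convention;
    ``direction`` is the expected direction of both force and pMLC change.
    """

    condition: str
    mean_max_force: float
    sd_max_force: float
    pmlc_effect: float
    direction: Literal["up", "down", "none"]

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean_max_force) or self.mean_max_force <= 0:
            raise DomainError(f"mean_max_force must be > 0, got {self.mean_max_force!r}")
        if not math.isfinite(self.sd_max_force) or self.sd_max_force < 0:
            raise DomainError(f"sd_max_force must be >= 0, got {self.sd_max_force!r}")


def _control_cv() -> float:
    return CONTROL_SD_FORCE_UN / CONTROL_MEAN_FORCE_UN


# condition -> (printed mean, printed sd, force % change, pMLC % change, direction)
# Means marked None are back-computed from the force percent change.
_CONDITION_TABLE: dict[str, tuple[Optional[float], Optional[float], float, float, str]] = {
    "control": (CONTROL_MEAN_FORCE_UN, CONTROL_SD_FORCE_UN, 0.0, 0.0, "none"),
    "U46619": (7337.0, 1408.0, 59.7, 41.3, "up"),
    "Cpd7a": (922.0, 504.0, -68.8, -38.5, "down"),
    "sildenafil": (None, None, 34.6, 40.9, "up"),
    "PMA": (None, None, 41.6, 30.5, "up"),
    "okadaic_acid": (None, None, 46.8, 30.7, "up"),
    "ML-7": (None, None, -53.5, -42.8, "down"),
    "K252d": (None, None, -63.0, -39.8, "down"),
    "Y27632": (None, None, -65.0, -46.0, "down"),
}


def default_condition_configs() -> dict[str, ConditionConfig]:
    """The nine default conditions (control + 8 reagents).

    Conditions with no reported absolute mean get one back-computed from the
    reported force percent change, with SD scaled to the control CV.
    """
    configs: dict[str, ConditionConfig] = {}
    for cond, (mean, sd, force_pct, pmlc_pct, direction) in _CONDITION_TABLE.items():
        if mean is None:
            mean = mean_from_percent_change(force_pct, CONTROL_MEAN_FORCE_UN)
            sd = mean * _control_cv()
        configs[cond] = ConditionConfig(
            condition=cond,
            mean_max_force=mean,
            sd_max_force=sd,
            pmlc_effect=pmlc_pct,
            direction=direction,  # type: ignore[arg-type]
        )
    return configs


def pmlc_ratio(config: ConditionConfig) -> float:
    """Normalized pMLC ratio (control = 1.0) realizing the configured effect.

    Inverts the percent-change convention: a +p% effect needs a ratio
    1/(1 - p/100); a -p% effect a ratio 1 - p/100.
    """
    if config.pmlc_effect == 0.0:
        return 1.0
    return mean_from_percent_change(config.pmlc_effect, 1.0)


def expected_plateau_mean(config: ConditionConfig) -> float:
    """Population mean of the truncated-normal plateau distribution, uN.

    Truncation at zero shifts the mean upward for high-CV conditions (e.g.
    Cpd7a, 922 +/- 504); this is the correct recovery target for round-trip
    checks.
    """
    if config.sd_max_force == 0.0:
        return config.mean_max_force
    a = -config.mean_max_force / config.sd_max_force
    return float(
        _sps.truncnorm.mean(a, np.inf, loc=config.mean_max_force, scale=config.sd_max_force)
    )


def expected_plateau_sd(config: ConditionConfig) -> float:
    """Population SD of the truncated-normal plateau distribution, uN."""
    if config.sd_max_force == 0.0:
        return 0.0
    a = -config.mean_max_force / config.sd_max_force
    return float(
        _sps.truncnorm.std(a, np.inf, loc=config.mean_max_force, scale=config.sd_max_force)
    )


@dataclass(frozen=True)
class TraceModel:
    """Logistic-with-lag contraction-curve parameters.

    The deflection curve is a logistic rebased to start at zero:

        x(t) = (F_inf / k) * [s((t - t_half)/tau) - s0] / (1 - s0),

    with ``s`` the logistic function and ``s0 = s(-t_half/tau)``, plus
    Gaussian deflection noise. Defaults: midpoint 900 s, rise time 300 s,
    noise 0.2 um, one-hour assay sampled every 5 s.
    """

    plateau_force: float
    midpoint_t: float = 900.0
    rise_tau: float = 300.0
    noise_sd: float = 0.2
    duration: float = 3600.0
    sampling_dt: float = 5.0

    def __post_init__(self) -> None:
        if self.plateau_force < 0:
            raise DomainError(f"plateau_force must be >= 0, got {self.plateau_force!r}")
        for name in ("midpoint_t", "rise_tau", "duration", "sampling_dt"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.duration / self.sampling_dt < 100:
            raise DomainError("duration/sampling_dt must yield >= 100 points")


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate_contraction_trace(
    model: TraceModel,
    chip: SensorChip,
    seed,
    sample_id: str = "",
    condition: str = "",
) -> DisplacementTrace:
    """One noisy displacement trace following the logistic contraction curve."""
    rng = _rng(seed)
    t = np.arange(0.0, model.duration + model.sampling_dt / 2.0, model.sampling_dt)
    s0 = float(_logistic(np.array([-model.midpoint_t / model.rise_tau]))[0])
    shape = (_logistic((t - model.midpoint_t) / model.rise_tau) - s0) / (1.0 - s0)
    x = (model.plateau_force / chip.spring_constant_k) * shape
    if model.noise_sd > 0:
        x = x + rng.normal(0.0, model.noise_sd, size=t.size)
    return DisplacementTrace(
        times=t,
        deflections=x,
        sample_id=sample_id,
        condition=condition,
        max_duration=model.duration,
    )


def generate_condition_dataset(
    configs: Optional[Mapping[str, ConditionConfig]] = None,
    n_subjects: int = 5,
    chip: SensorChip = SensorChip(),
    seed=0,
    trace_model: Optional[TraceModel] = None,
) -> dict[str, list[DisplacementTrace]]:
    """Per-condition displacement traces for ``n_subjects`` subjects each.

    Each subject's plateau force is drawn from Normal(mean, sd) truncated at
    zero; only the plateau varies across subjects (shared kinetics). The
    default n of 5 matches the study's group size.
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    rng = _rng(seed)
    if configs is None:
        configs = default_condition_configs()
    template = trace_model if trace_model is not None else TraceModel(plateau_force=1.0)
    dataset: dict[str, list[DisplacementTrace]] = {}
    for cond, cfg in configs.items():
        if cfg.sd_max_force == 0.0:
            plateaus = np.full(n_subjects, cfg.mean_max_force)
        else:
            a = -cfg.mean_max_force / cfg.sd_max_force
            plateaus = _sps.truncnorm.rvs(
                a,
                np.inf,
                loc=cfg.mean_max_force,
                scale=cfg.sd_max_force,
                size=n_subjects,
                random_state=rng,
            )
        dataset[cond] = [
            generate_contraction_trace(
                replace(template, plateau_force=float(p)),
                chip,
                rng,
                sample_id=f"{cond}_{i:04d}",
                condition=cond,
            )
            for i, p in enumerate(plateaus)
        ]
    return dataset


def generate_calibration_series(
    chip: SensorChip = SensorChip(),
    n_points: int = 50,
    noise_sd_force: Optional[float] = None,
    seed=0,
) -> CalibrationSeries:
    """Simulated nanoindenter sweep: 0 to max_stroke, force = k*x + noise."""
    if n_points < 3:
        raise DomainError("n_points must be >= 3")
    rng = _rng(seed)
    if noise_sd_force is None:
        noise_sd_force = (
            DEFAULT_CALIBRATION_NOISE_FRACTION * chip.spring_constant_k * chip.max_stroke
        )
    x = np.linspace(0.0, chip.max_stroke, n_points)
    f = chip.spring_constant_k * x
    if noise_sd_force > 0:
        f = f + rng.normal(0.0, noise_sd_force, size=n_points)
    return CalibrationSeries(deflections=x, forces=f)


def generate_elisa_plate(
    configs: Optional[Mapping[str, ConditionConfig]] = None,
    wells_per_condition: int = 8,
    noise_cv: float = 0.05,
    seed=0,
    blank_od: float = 0.08,
    signal_od: float = 1.0,
    n_blank_wells: int = 4,
) -> ElisaPlate:
    """Synthetic in-cell ELISA plate realizing the configured pMLC effects.

    Control's normalized ratio is fixed at 1.0; each condition's pMLC signal
    is scaled so the zero-noise percent change equals its configured
    ``pmlc_effect`` exactly. Well noise is multiplicative lognormal with the
    given CV and unit mean.
    """
    if wells_per_condition < 1:
        raise DomainError("wells_per_condition must be >= 1")
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    rng = _rng(seed)
    if configs is None:
        configs = default_condition_configs()
    sigma = math.sqrt(math.log1p(noise_cv**2))

    def _noise(n: int) -> np.ndarray:
        if sigma == 0.0:
            return np.ones(n)
        return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=n)

    records = []
    counter = 0
    for cond, cfg in configs.items():
        ratio = pmlc_ratio(cfg)
        for analyte, signal in (
            (ANALYTE_PMLC, ratio * signal_od),
            (ANALYTE_TOTAL_MLC, signal_od),
        ):
            ods = (blank_od + signal) * _noise(wells_per_condition)
            for od in ods:
                counter += 1
                records.append(
                    {
                        "well": f"W{counter:03d}",
                        "analyte": analyte,
                        "condition": cond,
                        "od450": float(od),
                    }
                )
    for od in blank_od * _noise(n_blank_wells):
        counter += 1
        records.append(
            {"well": f"W{counter:03d}", "analyte": ANALYTE_BLANK, "condition": "blank",
             "od450": float(od)}
        )
    return ElisaPlate.from_wells(records)


def generate_blot_lanes(
    configs: Optional[Mapping[str, ConditionConfig]] = None,
    seed=0,
    noise_cv: float = 0.05,
    base_intensity: float = 1000.0,
) -> list[BlotLane]:
    """Synthetic blot lanes whose pMLC band scales with the configured ratios."""
    rng = _rng(seed)
    if configs is None:
        configs = default_condition_configs()
    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def _n() -> float:
        return float(rng.lognormal(-sigma**2 / 2.0, sigma)) if sigma > 0 else 1.0

    return [
        BlotLane(
            condition=cond,
            pmlc_intensity=pmlc_ratio(cfg) * base_intensity * _n(),
            total_mlc_intensity=base_intensity * _n(),
            loading_intensity=base_intensity * _n(),
        )
        for cond, cfg in configs.items()
    ]


def generate_correlation_dataset(
    configs: Optional[Mapping[str, ConditionConfig]] = None,
    r_squared: float = 0.91,
    seed=0,
) -> pd.DataFrame:
    """Condition-level (force, pMLC) pairs with an exact target sample R^2.

    The pMLC values are a line through the configured (force mean, pMLC ratio)
    points plus residuals orthogonalized against the regressors and scaled so
    OLS of pMLC on force yields exactly ``r_squared``. Columns: condition,
    force, pmlc.
    """
    if not (0.0 < r_squared <= 1.0):
        raise DomainError(f"r_squared must be in (0, 1], got {r_squared!r}")
    rng = _rng(seed)
    if configs is None:
        configs = default_condition_configs()
    conds = list(configs)
    if len(conds) < 3:
        raise DomainError("need >= 3 conditions")
    x = np.array([configs[c].mean_max_force for c in conds])
    y0 = np.array([pmlc_ratio(configs[c]) for c in conds])
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y0, rcond=None)
    line = design @ coef
    ssr = float(np.sum((line - line.mean()) ** 2))
    if r_squared == 1.0:
        y = line
    else:
        e = rng.standard_normal(x.size)
        e_perp = e - design @ np.linalg.lstsq(design, e, rcond=None)[0]
        norm = float(np.linalg.norm(e_perp))
        while norm < 1e-12:  # pragma: no cover - essentially impossible draw
            e = rng.standard_normal(x.size)
            e_perp = e - design @ np.linalg.lstsq(design, e, rcond=None)[0]
            norm = float(np.linalg.norm(e_perp))
        sse = ssr * (1.0 - r_squared) / r_squared
        y = line + e_perp * (math.sqrt(sse) / norm)
    return pd.DataFrame({"condition": conds, "force": x, "pmlc": y})


def final_concentration(stock_concentration: float, vol_added: float, vol_total: float) -> float:
    """Dilution arithmetic: concentration after adding ``vol_added`` of stock
    to a final volume ``vol_total`` (e.g. 6 uL of 100 mM CaCl2 into 100 uL of
    recalcified blood gives 6 mM)."""
    if vol_added <= 0 or vol_total <= 0:
        raise DomainError("volumes must be > 0")
    if vol_added > vol_total:
        raise DomainError(f"vol_added {vol_added} exceeds vol_total {vol_total}")
    return stock_concentration * vol_added / vol_total
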