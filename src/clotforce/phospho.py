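"""Phospho-MLC assay normalization: in-cell ELISA plates and blot lanes.

The in-cell ELISA reads OD450 for phosphorylated MLC (pMLC) and total MLC on
fixed platelets per condition. Normalization is blank subtraction followed by
the ratio of well means,

    ratio = (mean OD_pMLC - mean OD_blank) / (mean OD_totalMLC - mean OD_blank)

which is invariant under a uniform gain applied to the whole plate. Percent
changes versus control are then computed on these ratios with the study's
percent-change convention. Western-blot lanes are quantified as simple band
ratios against the beta-actin loading control (total-MLC normalization
available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BelowBackgroundError, DomainError, InvalidLaneError
from .stats import percent_change

__all__ = [
    "ANALYTE_PMLC",
    "ANALYTE_TOTAL_MLC",
    "ANALYTE_BLANK",
    "ElisaPlate",
    "BlotLane",
    "normalize_pmlc",
    "phospho_percent_change",
    "blot_ratio",
]

ANALYTE_PMLC = "pMLC"
ANALYTE_TOTAL_MLC = "totalMLC"
ANALYTE_BLANK = "blank"
_ANALYTES = {ANALYTE_PMLC, ANALYTE_TOTAL_MLC, ANALYTE_BLANK}


@dataclass(frozen=True)
class ElisaPlate:
    """Well-level OD450 readings: columns well, analyte, condition, od450."""

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.wells
        required = {"well", "analyte", "condition", "od450"}
        if not required.issubset(df.columns):
            raise DomainError(f"plate table needs columns {sorted(required)}")
        bad = set(df["analyte"].unique()) - _ANALYTES
        if bad:
            raise DomainError(f"unknown analytes {sorted(bad)}; expected {sorted(_ANALYTES)}")
        od = df["od450"].to_numpy(dtype=float)
        if not np.all(np.isfinite(od)) or np.any(od < 0):
            raise DomainError("od450 values must be finite and >= 0")
        for cond, sub in df[df["analyte"] != ANALYTE_BLANK].groupby("condition"):
            analytes = set(sub["analyte"])
            if not {ANALYTE_PMLC, ANALYTE_TOTAL_MLC}.issubset(analytes):
                raise DomainError(
                    f"condition {cond!r} needs >= 1 well of both {ANALYTE_PMLC} "
                    f"and {ANALYTE_TOTAL_MLC}"
                )

    @classmethod
    def from_wells(cls, records: Iterable[Mapping]) -> "ElisaPlate":
        return cls(pd.DataFrame(list(records)))

    def conditions(self) -> list[str]:
        sub = self.wells[self.wells["analyte"] != ANALYTE_BLANK]
        return sorted(sub["condition"].unique())

    def blank_mean(self) -> float:
        blanks = self.wells.loc[self.wells["analyte"] == ANALYTE_BLANK, "od450"]
        return float(blanks.mean()) if len(blanks) else 0.0


@dataclass(frozen=True)
class BlotLane:
    """One Western-blot lane: band intensities for pMLC, total MLC, beta-actin."""

    condition: str
    pmlc_intensity: float
    total_mlc_intensity: float
    loading_intensity: float

    def __post_init__(self) -> None:
        for name in ("pmlc_intensity", "total_mlc_intensity", "loading_intensity"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0:
                raise InvalidLaneError(f"{name} must be finite and > 0, got {v!r}")


def normalize_pmlc(plate: ElisaPlate, condition: str) -> float:
    """Blank-subtracted pMLC / total-MLC ratio of well means for a condition."""
    df = plate.wells
    sub = df[df["condition"] == condition]
    p_wells = sub.loc[sub["analyte"] == ANALYTE_PMLC, "od450"]
    t_wells = sub.loc[sub["analyte"] == ANALYTE_TOTAL_MLC, "od450"]
    if len(p_wells) == 0 or len(t_wells) == 0:
        raise DomainError(f"condition {condition!r} lacks pMLC or totalMLC wells")
    blank = plate.blank_mean()
    numer = float(p_wells.mean()) - blank
    denom = float(t_wells.mean()) - blank
    if denom <= 0 or numer <= 0:
        raise BelowBackgroundError(
            f"condition {condition!r}: signal does not exceed blank "
            f"(pMLC-blank={numer:.4f}, totalMLC-blank={denom:.4f})"
        )
    return numer / denom


def phospho_percent_change(plate: ElisaPlate, condition: str, control: str = "control") -> float:
    """Signed percent change of normalized pMLC for ``condition`` vs control."""
    return percent_change(normalize_pmlc(plate, condition), normalize_pmlc(plate, control))


def blot_ratio(lane: BlotLane, normalize_by: str = "actin") -> float:
    """Relative pMLC band intensity of a lane.

    ``normalize_by='actin'`` divides by the beta-actin loading control
    (default); ``'total_mlc'`` divides by the total-MLC band instead.
    """
    if normalize_by == "actin":
        return lane.pmlc_intensity / lane.loading_intensity
    if normalize_by == "total_mlc":
        return lane.pmlc_intensity / lane.total_mlc_intensity
    raise ValueError(f"normalize_by must be 'actin' or 'total_mlc', got {normalize_by!r}")
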