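"""CSV/YAML file dialects and run manifests.

All on-disk formats are plain text. Traces travel as long-format CSV
(``time_s, displacement_um[, sample_id, condition]``), calibration series as
``deflection_um, force_uN``, ELISA plates as ``well, analyte, condition,
od450``, blot lanes as ``condition, pmlc, total_mlc, actin``, and networks as
``source, target, sign`` edge lists. Configuration and manifests are YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError
from .mems import CalibrationSeries
from .network import SignedNetwork
from .phospho import BlotLane, ElisaPlate
from .traces import DisplacementTrace, ForceTrace

PathLike = Union[str, Path]

__all__ = [
    "read_trace_csv",
    "write_traces_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_plate_csv",
    "write_plate_csv",
    "read_lanes_csv",
    "write_lanes_csv",
    "read_network_csv",
    "write_network_csv",
    "load_config",
    "dump_config",
    "write_manifest",
]


def write_traces_csv(traces: Iterable[DisplacementTrace], path: PathLike) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.times,
                    "displacement_um": tr.deflections,
                    "sample_id": tr.sample_id,
                    "condition": tr.condition,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(path: PathLike, max_duration: float | None = 3600.0) -> list[DisplacementTrace]:
    """Read one or many displacement traces from a long-format CSV."""
    df = pd.read_csv(path)
    if not {"time_s", "displacement_um"}.issubset(df.columns):
        raise DomainError("trace CSV needs columns time_s, displacement_um")
    if "sample_id" not in df.columns:
        df["sample_id"] = ""
    if "condition" not in df.columns:
        df["condition"] = ""
    traces = []
    for (sample_id, condition), sub in df.groupby(["sample_id", "condition"], sort=False):
        traces.append(
            DisplacementTrace(
                times=sub["time_s"].to_numpy(dtype=float),
                deflections=sub["displacement_um"].to_numpy(dtype=float),
                sample_id=str(sample_id),
                condition=str(condition),
                max_duration=max_duration,
            )
        )
    return traces


def write_force_traces_csv(traces: Iterable[ForceTrace], path: PathLike) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.times,
                    "force_uN": tr.forces,
                    "sample_id": tr.sample_id,
                    "condition": tr.condition,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_calibration_csv(cal: CalibrationSeries, path: PathLike) -> None:
    pd.DataFrame({"deflection_um": cal.deflections, "force_uN": cal.forces}).to_csv(
        path, index=False
    )


def read_calibration_csv(path: PathLike) -> CalibrationSeries:
    df = pd.read_csv(path)
    if not {"deflection_um", "force_uN"}.issubset(df.columns):
        raise DomainError("calibration CSV needs columns deflection_um, force_uN")
    return CalibrationSeries(
        deflections=df["deflection_um"].to_numpy(dtype=float),
        forces=df["force_uN"].to_numpy(dtype=float),
    )


def write_plate_csv(plate: ElisaPlate, path: PathLike) -> None:
    plate.wells.to_csv(path, index=False)


def read_plate_csv(path: PathLike) -> ElisaPlate:
    return ElisaPlate(pd.read_csv(path))


def write_lanes_csv(lanes: Sequence[BlotLane], path: PathLike) -> None:
    pd.DataFrame(
        {
            "condition": [ln.condition for ln in lanes],
            "pmlc": [ln.pmlc_intensity for ln in lanes],
            "total_mlc": [ln.total_mlc_intensity for ln in lanes],
            "actin": [ln.loading_intensity for ln in lanes],
        }
    ).to_csv(path, index=False)


def read_lanes_csv(path: PathLike) -> list[BlotLane]:
    df = pd.read_csv(path)
    if not {"condition", "pmlc", "total_mlc", "actin"}.issubset(df.columns):
        raise DomainError("lane CSV needs columns condition, pmlc, total_mlc, actin")
    return [
        BlotLane(
            condition=str(r.condition),
            pmlc_intensity=float(r.pmlc),
            total_mlc_intensity=float(r.total_mlc),
            loading_intensity=float(r.actin),
        )
        for r in df.itertuples()
    ]


def write_network_csv(net: SignedNetwork, path: PathLike) -> None:
    net.to_frame().to_csv(path, index=False)


def read_network_csv(path: PathLike) -> SignedNetwork:
    df = pd.read_csv(path)
    if not {"source", "target", "sign"}.issubset(df.columns):
        raise DomainError("network CSV needs columns source, target, sign")
    net = SignedNetwork()
    for r in df.itertuples():
        net.add_edge(str(r.source), str(r.target), int(r.sign))
    return net


def load_config(path: PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: Mapping, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_plain(config), fh, sort_keys=False)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config: Mapping) -> str:
    """SHA-256 of the canonical JSON form of a configuration mapping."""
    return hashlib.sha256(
        json.dumps(_plain(config), sort_keys=True).encode("utf-8")
    ).hexdigest()


def write_manifest(
    path: PathLike,
    command: str,
    config: Mapping,
    seed: int | None = None,
    inputs: Sequence[str] = (),
    outputs: Sequence[str] = (),
) -> None:
    """Reproducibility manifest for a CLI run: inputs, config + hash, seed."""
    from . import __version__

    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "inputs": list(map(str, inputs)),
        "outputs": list(map(str, outputs)),
        "config": _plain(config),
        "config_sha256": config_hash(config),
    }
    dump_config(manifest, path)
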