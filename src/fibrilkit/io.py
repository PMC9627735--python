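"""File formats and configuration for the analysis pipeline.

Plate-reader data travel as long-format CSV (columns ``time_s``, ``well``,
``signal``) with a companion condition map (YAML or JSON) assigning each
well an assay kind, substrate concentration, inhibitor, molar ratio and
replicate id.  SPR data use CSV columns ``time_s``, ``response_RU``,
``concentration_M``, ``phase`` (``assoc``/``dissoc``); titrations use
``pH``, ``signal``.  Times are seconds, concentrations mol/L, ratios
percent throughout — stated here once so files and code cannot drift.

Vendor exports (BMG plate readers, Biacore) vary in layout and are not
parsed directly; convert them to these CSV dialects first.  A converter
needs to supply: the time stamps per read, one signal column per well, and
the well->condition assignment from the plate layout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import KineticParameters
from .spr import Sensorgram
from .tht import AggregationTrace, TraceCondition

__all__ = [
    "RunConfig",
    "read_condition_map",
    "write_condition_map",
    "read_plate_csv",
    "write_plate_csv",
    "read_sensorgram_csv",
    "write_sensorgram_csv",
    "read_titration_csv",
    "write_titration_csv",
    "kinetic_params_to_dict",
    "kinetic_params_from_dict",
]

_PLATE_COLUMNS = ("time_s", "well", "signal")
_SENSORGRAM_COLUMNS = ("time_s", "response_RU", "concentration_M", "phase")
_CONDITION_KEYS = {"assay", "substrate_M", "inhibitor", "ratio_percent", "replicate"}

_RUNCONFIG_KEYS = {
    "inputs",
    "condition_map",
    "assay",
    "free_parameter",
    "seed",
    "output_dir",
    "window_s",
    "exclude_ratios",
}


@dataclass
class RunConfig:
    """Validated configuration of one analysis run."""

    inputs: list[str] = field(default_factory=list)
    condition_map: str | None = None
    assay: str = "tht"
    free_parameter: str = "k_2"
    seed: int = 0
    output_dir: str = "results"
    window_s: float = 1200.0
    exclude_ratios: list[float] = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_condition_map(path: str | Path) -> dict[str, TraceCondition]:
    """Load a well -> condition mapping from YAML or JSON."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    out: dict[str, TraceCondition] = {}
    for well, entry in raw.items():
        unknown = set(entry) - _CONDITION_KEYS
        if unknown:
            raise ValueError(f"condition map {path}, well {well}: unknown keys {sorted(unknown)}")
        out[str(well)] = TraceCondition(**entry)
    return out


def write_condition_map(conditions: dict[str, TraceCondition], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({w: asdict(c) for w, c in conditions.items()}, fh, sort_keys=True)


def read_plate_csv(
    path: str | Path, condition_map: dict[str, TraceCondition]
) -> list[AggregationTrace]:
    """Read a long-format plate CSV into traces using the condition map.

    Raises on schema violations with the offending line numbers (header is
    line 1).
    """
    df = pd.read_csv(path)
    missing = set(_PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} (header line 1)")
    bad = df.index[~np.isfinite(df["signal"])].tolist()
    if bad:
        raise ValueError(f"{path}: non-finite signal at lines {[i + 2 for i in bad[:5]]}")
    traces = []
    for well, grp in df.groupby("well", sort=True):
        if str(well) not in condition_map:
            first = int(grp.index[0]) + 2
            raise ValueError(f"{path}: well {well!r} (line {first}) not in condition map")
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            i = int(np.nonzero(np.diff(t) <= 0)[0][0])
            line = int(grp.index[i + 1]) + 2
            raise ValueError(f"{path}: time not strictly increasing for well {well!r} at line {line}")
        traces.append(
            AggregationTrace(
                t=t, y=grp["signal"].to_numpy(dtype=float),
                condition=condition_map[str(well)],
            )
        )
    return traces


def write_plate_csv(
    traces: list[AggregationTrace], path: str | Path
) -> dict[str, TraceCondition]:
    """Write traces as a plate CSV; returns the generated condition map."""
    rows = []
    conditions: dict[str, TraceCondition] = {}
    for i, tr in enumerate(traces):
        well = f"W{i + 1:03d}"
        conditions[well] = tr.condition
        rows.append(pd.DataFrame({"time_s": tr.t, "well": well, "signal": tr.y}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return conditions


def read_sensorgram_csv(path: str | Path) -> list[Sensorgram]:
    """Read an SPR CSV (one block per concentration) into sensorgrams."""
    df = pd.read_csv(path)
    missing = set(_SENSORGRAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} (header line 1)")
    bad_phase = ~df["phase"].isin(["assoc", "dissoc"])
    if bad_phase.any():
        line = int(df.index[bad_phase][0]) + 2
        raise ValueError(f"{path}: phase must be 'assoc' or 'dissoc' (line {line})")
    out = []
    for c, grp in df.groupby("concentration_M", sort=True):
        t = grp["time_s"].to_numpy(dtype=float)
        assoc = grp["phase"].to_numpy() == "assoc"
        if not assoc.any():
            raise ValueError(f"{path}: concentration {c:g} M has no association phase")
        t_inject_end = float(t[assoc].max())
        out.append(
            Sensorgram(
                t=t, R=grp["response_RU"].to_numpy(dtype=float),
                c=float(c), t_inject_end=t_inject_end,
            )
        )
    return out


def write_sensorgram_csv(sensorgrams: list[Sensorgram], path: str | Path) -> None:
    rows = []
    for sg in sensorgrams:
        phase = np.where(sg.t <= sg.t_inject_end, "assoc", "dissoc")
        rows.append(
            pd.DataFrame(
                {
                    "time_s": sg.t,
                    "response_RU": sg.R,
                    "concentration_M": sg.c,
                    "phase": phase,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_titration_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a titration CSV (columns pH, signal) into arrays."""
    df = pd.read_csv(path)
    missing = {"pH", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} (header line 1)")
    return df["pH"].to_numpy(dtype=float), df["signal"].to_numpy(dtype=float)


def write_titration_csv(pH: np.ndarray, signal: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"pH": pH, "signal": signal}).to_csv(path, index=False)


def kinetic_params_to_dict(params: KineticParameters) -> dict:
    return asdict(params)


def kinetic_params_from_dict(d: dict) -> KineticParameters:
    return KineticParameters(**d)
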