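"""Tabular and JSON interchange shared by all modules.

Events travel as BIDS-style TSV (onset, duration, direction_deg, session,
trial_type); per-direction vectors and paths as TSV; results as JSON.  All
serialized angles are degrees with an explicit ``_deg`` suffix.  Every
stochastic run can write a RunManifest carrying the seeds needed for
bit-identical replay.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .bold import EVENT_COLUMNS, EventDesign

__all__ = [
    "RunManifest",
    "read_events",
    "write_events",
    "read_direction_values",
    "write_direction_values",
    "read_matrix",
    "write_matrix",
    "write_json",
    "read_json",
]


@dataclass
class RunManifest:
    """Provenance record written beside every command's outputs."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path) -> None:
        write_json(path, asdict(self))


def read_events(path) -> EventDesign:
    """Read and validate an events TSV into an EventDesign."""
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"events file missing column(s): {', '.join(missing)}")
    lure_dirs = tab.loc[tab["trial_type"] == "lure", "direction_deg"]
    if lure_dirs.notna().any():
        warnings.warn("lure trial(s) carry a direction value; ignoring it", stacklevel=2)
        tab.loc[tab["trial_type"] == "lure", "direction_deg"] = np.nan
    return EventDesign(tab)


def write_events(path, design: EventDesign) -> None:
    design.table.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_direction_values(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (direction_deg, value) TSV; returns (directions, values)."""
    tab = pd.read_csv(path, sep="\t")
    for col in ("direction_deg", "value"):
        if col not in tab.columns:
            raise ValueError(f"direction-value file missing column: {col}")
    return tab["direction_deg"].to_numpy(float), tab["value"].to_numpy(float)


def write_direction_values(path, directions_deg, values) -> None:
    pd.DataFrame({"direction_deg": directions_deg, "value": values}).to_csv(
        path, sep="\t", index=False
    )


def read_matrix(path) -> np.ndarray:
    """Read a delimited numeric matrix (rows = voxels or sessions)."""
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_matrix(path, matrix) -> None:
    np.savetxt(path, np.asarray(matrix, float), delimiter="\t", fmt="%.10g")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, set):
            return sorted(obj)
        return super().default(obj)


def write_json(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
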