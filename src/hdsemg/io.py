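"""Reading and writing grid recordings in a plain-text interchange format.

A recording is a pair of files:

* a TSV signal matrix, samples x channels, with a header row of electrode
  ids of the form ``r<row>c<col>``;
* a JSON sidecar declaring sampling rate, units, grid geometry, the channel
  map, recording mode and labels, plus an optional companion torque file.

The on-disk unit may be V, mV or uV; signals are always held in mV in
memory.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .grid import GridGeometry, GridRecording

__all__ = ["load_recording", "save_recording", "UNIT_TO_MV"]

PathLike = Union[str, os.PathLike]

#: Multiplicative factors converting a declared unit to mV.
UNIT_TO_MV = {
    "V": 1e3,
    "mV": 1.0,
    "uV": 1e-3,
    "µV": 1e-3,
    "μV": 1e-3,
}


def _electrode_id(row: int, col: int) -> str:
    return f"r{row}c{col}"


def save_recording(
    rec: GridRecording,
    signal_path: PathLike,
    sidecar_path: PathLike,
    torque_path: Optional[PathLike] = None,
) -> None:
    """Write a recording as signal TSV + JSON sidecar (+ optional torque TSV).

    The stored unit is always mV.  ``load_recording`` of the written pair
    reproduces the signals to better than 1e-9 mV and all metadata exactly.
    """
    signal_path, sidecar_path = Path(signal_path), Path(sidecar_path)
    header = "\t".join(_electrode_id(r, c) for r, c in rec.channel_positions)
    np.savetxt(
        signal_path,
        rec.signals.T,
        fmt="%.12e",
        delimiter="\t",
        header=header,
        comments="",
    )
    sidecar = {
        "fs_hz": rec.fs_hz,
        "unit": "mV",
        "n_rows": rec.geometry.n_rows,
        "n_cols": rec.geometry.n_cols,
        "missing": [list(p) for p in rec.geometry.missing],
        "ied_mm": rec.geometry.ied_mm,
        "mode": rec.mode,
        "channel_map": [list(p) for p in rec.channel_positions],
        "speed_label": rec.speed_label,
        "side": rec.side,
    }
    if rec.torque is not None:
        if torque_path is None:
            torque_path = signal_path.with_name(signal_path.stem + "_torque.tsv")
        torque_path = Path(torque_path)
        np.savetxt(torque_path, rec.torque, fmt="%.12e", header="torque_nm", comments="")
        sidecar["torque_file"] = torque_path.name
        sidecar["torque_fs_hz"] = rec.torque_fs_hz
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
        fh.write("\n")


def load_recording(signal_path: PathLike, sidecar_path: PathLike) -> GridRecording:
    """Load and validate a recording from signal TSV + JSON sidecar.

    Values are converted to mV from the sidecar's declared unit.  Errors are
    raised for a channel-count mismatch between the matrix and the channel
    map, an unknown unit string, and non-finite samples.
    """
    signal_path, sidecar_path = Path(signal_path), Path(sidecar_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)

    unit = meta.get("unit", "mV")
    if unit not in UNIT_TO_MV:
        raise ValueError(
            f"unknown unit {unit!r} in {sidecar_path.name}; "
            f"expected one of {sorted(set(UNIT_TO_MV))}"
        )
    geometry = GridGeometry(
        n_rows=int(meta["n_rows"]),
        n_cols=int(meta["n_cols"]),
        missing=tuple(tuple(p) for p in meta.get("missing", [])),
        ied_mm=float(meta.get("ied_mm", 8.0)),
    )
    channel_map = [tuple(p) for p in meta["channel_map"]]

    frame = pd.read_csv(signal_path, sep="\t")
    if frame.shape[1] != len(channel_map):
        raise ValueError(
            f"signal matrix has {frame.shape[1]} columns but the channel map "
            f"declares {len(channel_map)} channels"
        )
    signals = frame.to_numpy(dtype=float).T * UNIT_TO_MV[unit]
    if not np.all(np.isfinite(signals)):
        bad = np.unique(np.nonzero(~np.isfinite(signals))[0]).tolist()
        names = [frame.columns[k] for k in bad]
        raise ValueError(f"non-finite samples in channels {names}")

    torque = None
    torque_fs = float(meta.get("torque_fs_hz", 100.0))
    if meta.get("torque_file"):
        tpath = sidecar_path.parent / meta["torque_file"]
        torque = np.loadtxt(tpath, skiprows=1, ndmin=1)

    return GridRecording(
        signals=signals,
        fs_hz=float(meta["fs_hz"]),
        geometry=geometry,
        channel_positions=channel_map,
        mode=meta.get("mode", "monopolar"),
        torque=torque,
        torque_fs_hz=torque_fs,
        speed_label=meta.get("speed_label"),
        side=meta.get("side"),
    )
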