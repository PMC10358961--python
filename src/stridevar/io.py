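"""Delimited-text serialisation of recordings, events and features.

Recordings are stored as one CSV per sensor (columns: time, a_x, a_y,
a_z, w_x, w_y, w_z) with a JSON sidecar carrying placement, sampling
rate and free-form provenance (runner, condition, seed); gait events
as a CSV of (foot, event_type, time_s); feature matrices as a CSV with
one row per channel and the 23 named feature columns.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .features import CHANNEL_NAMES, FEATURE_NAMES, FeatureMatrix
from .types import GaitEventSeries, IMURecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_feature_matrix",
    "read_feature_matrix",
]

PathLike = Union[str, Path]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording(
    rec: IMURecording, path: PathLike, metadata: Optional[Dict] = None
) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        np.column_stack([rec.times, rec.channels().T]),
        columns=["time", *CHANNEL_NAMES],
    )
    frame.to_csv(path, index=False, float_format="%.8g")
    meta = {
        "placement": rec.placement,
        "sampling_rate": rec.sampling_rate,
        "start_time": rec.start_time,
        **(metadata or {}),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_recording(path: PathLike) -> IMURecording:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    frame = pd.read_csv(path)
    return IMURecording(
        placement=meta["placement"],
        sampling_rate=float(meta["sampling_rate"]),
        acc=frame[["a_x", "a_y", "a_z"]].to_numpy().T,
        gyro=frame[["w_x", "w_y", "w_z"]].to_numpy().T,
        start_time=float(meta.get("start_time", 0.0)),
    )


def write_events(events_by_foot: List[GaitEventSeries], path: PathLike) -> None:
    rows = []
    for ev in events_by_foot:
        rows += [
            {"foot": ev.foot, "event_type": "foot_strike", "time_s": t}
            for t in ev.foot_strikes
        ]
        rows += [
            {"foot": ev.foot, "event_type": "toe_off", "time_s": t} for t in ev.toe_offs
        ]
    pd.DataFrame(rows).sort_values(["foot", "time_s"]).to_csv(
        path, index=False, float_format="%.8g"
    )


def read_events(path: PathLike) -> List[GaitEventSeries]:
    frame = pd.read_csv(path)
    out = []
    for foot, grp in frame.groupby("foot"):
        out.append(
            GaitEventSeries(
                foot=foot,
                foot_strikes=np.sort(
                    grp[grp["event_type"] == "foot_strike"]["time_s"].to_numpy()
                ),
                toe_offs=np.sort(grp[grp["event_type"] == "toe_off"]["time_s"].to_numpy()),
            )
        )
    return out


def write_feature_matrix(fm: FeatureMatrix, path: PathLike) -> None:
    frame = pd.DataFrame(fm.values, index=list(CHANNEL_NAMES), columns=FEATURE_NAMES)
    frame.index.name = "channel"
    frame.to_csv(path, float_format="%.10g")


def read_feature_matrix(path: PathLike) -> FeatureMatrix:
    frame = pd.read_csv(path, index_col="channel")
    if list(frame.columns) != FEATURE_NAMES:
        raise ValueError("feature columns do not match the registry")
    return FeatureMatrix(values=frame.loc[list(CHANNEL_NAMES)].to_numpy())
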