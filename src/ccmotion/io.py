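"""Tidy CSV time-series I/O shared by the stimulus and simulator modules.

One trace per file, columns ``time_s, position_cm, velocity_cm_s,
acceleration_cm_s2, trial, section``; section annotations travel in a JSON
sidecar next to the CSV (same stem, ``.sections.json``).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import SectionAnnotation
from .types import Trajectory

__all__ = ["write_trajectory", "read_trajectory"]

_COLUMNS = ["time_s", "position_cm", "velocity_cm_s", "acceleration_cm_s2",
            "trial", "section"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".sections.json")


def write_trajectory(path, traj: Trajectory, trial: int | None = None,
                     sections: list[SectionAnnotation] | None = None) -> Path:
    path = Path(path)
    section_col = np.full(len(traj), -1, dtype=int)
    if sections:
        for ann in sections:
            i0, i1 = traj.index_range(ann.t_start, ann.t_end)
            section_col[i0:i1] = ann.index
    df = pd.DataFrame({
        "time_s": traj.time,
        "position_cm": traj.position,
        "velocity_cm_s": traj.velocity,
        "acceleration_cm_s2": traj.acceleration,
        "trial": trial if trial is not None else -1,
        "section": section_col,
    })
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")
    if sections:
        meta = {"sample_rate": traj.sample_rate, "trial": trial,
                "sections": [asdict(a) for a in sections]}
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trajectory(path) -> tuple[Trajectory, list[SectionAnnotation] | None]:
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / np.median(np.diff(t))
    traj = Trajectory(sample_rate=float(round(rate, 6)),
                      position=df["position_cm"].to_numpy(),
                      velocity=df["velocity_cm_s"].to_numpy(),
                      acceleration=df["acceleration_cm_s2"].to_numpy(),
                      t0=float(t[0]))
    sidecar = _sidecar(path)
    sections = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sections = [SectionAnnotation(**a) for a in meta["sections"]]
    return traj, sections
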