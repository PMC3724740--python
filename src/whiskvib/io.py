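"""File formats: TIFF volume stacks, recording CSVs, study-table CSVs.

Volumes travel as multi-page TIFF plus a JSON sidecar
(``{"voxel_size_um": ..., "axis_order": "zyx"}``); recordings as two-column
CSV (``time_s, velocity_m_per_s``) plus a sidecar with the sample rate;
study tables as flat CSV with the canonical header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .spectra import VibrationRecording

__all__ = [
    "write_volume",
    "read_volume",
    "write_recording",
    "read_recording",
    "write_study_table",
    "read_study_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: str | Path, volume: np.ndarray, voxel_size_um: float) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume))
    _sidecar(path).write_text(
        json.dumps({"voxel_size_um": voxel_size_um, "axis_order": "zyx"})
    )


def read_volume(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return tifffile.imread(path), float(meta["voxel_size_um"])


def write_recording(path: str | Path, recording: VibrationRecording) -> None:
    path = Path(path)
    pd.DataFrame(
        {"time_s": recording.times, "velocity_m_per_s": recording.samples}
    ).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"sample_rate": recording.sample_rate}))


def read_recording(path: str | Path) -> VibrationRecording:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path)
    return VibrationRecording(
        samples=df["velocity_m_per_s"].to_numpy(float),
        sample_rate=float(meta["sample_rate"]),
    )


def write_study_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_study_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
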