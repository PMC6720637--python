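"""CSV / JSON readers and writers for the toolkit's data dialects.

Dialects (comma-separated, UTF-8, decimal point):

- gaze:        ``t,x,y,pupil_radius,valid`` (empty pupil field = missing)
- rr:          ``rr_ms`` (one interval per row)
- respiration: ``t,volume_ml``
- paired:      ``t,reference,measured``
- cluster:     ``target_x,target_y,x,y``

Malformed rows are reported with their line numbers; a header mismatch
names the expected and found columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .characterise import FixationCluster, PairedSeries
from .gaze import GazeStream, ROI, ROILayout
from .hrv import RRSeries
from .respiration import RespirationSignal

__all__ = [
    "read_timeseries",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_rr_csv",
    "write_rr_csv",
    "read_respiration_csv",
    "write_respiration_csv",
    "read_paired_csv",
    "write_paired_csv",
    "read_cluster_csv",
    "read_roi_json",
    "write_roi_json",
]

SCHEMAS = {
    "gaze": ["t", "x", "y", "pupil_radius", "valid"],
    "rr": ["rr_ms"],
    "respiration": ["t", "volume_ml"],
    "paired": ["t", "reference", "measured"],
    "cluster": ["target_x", "target_y", "x", "y"],
}


def _load(path: str | Path, schema: str) -> pd.DataFrame:
    expected = SCHEMAS[schema]
    df = pd.read_csv(path)
    found = list(df.columns)
    if found != expected:
        missing = [c for c in expected if c not in found]
        raise ValueError(
            f"{path}: header mismatch for schema {schema!r}: expected {expected}, "
            f"found {found}" + (f" (missing {missing})" if missing else "")
        )
    required = [c for c in expected if c != "pupil_radius"]
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce") if col != "valid" else df[col]
        if col != "valid":
            bad = df.index[coerced.isna() & df[col].notna()] + 2  # 1-based + header
            if len(bad):
                raise ValueError(f"{path}: malformed values in {col!r} at lines {list(bad)}")
            nan = df.index[df[col].isna()] + 2
            if len(nan):
                raise ValueError(f"{path}: missing values in {col!r} at lines {list(nan)}")
            df[col] = coerced
    return df


def read_timeseries(path: str | Path, schema: str):
    """Typed series from a CSV file; ``schema`` picks the dialect."""
    readers = {
        "gaze": read_gaze_csv,
        "rr": read_rr_csv,
        "respiration": read_respiration_csv,
        "paired": read_paired_csv,
        "cluster": read_cluster_csv,
    }
    if schema not in readers:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(readers)}")
    return readers[schema](path)


def read_gaze_csv(path: str | Path, sampling_rate: float | None = None) -> GazeStream:
    df = _load(path, "gaze")
    t = df["t"].to_numpy(dtype=float)
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    pupil = pd.to_numeric(df["pupil_radius"], errors="coerce").to_numpy(dtype=float)
    valid = df["valid"]
    if valid.dtype == object:  # "True"/"False" strings
        valid = valid.map({"True": True, "False": False, "1": True, "0": False})
        if valid.isna().any():
            raise ValueError(f"{path}: malformed boolean values in 'valid'")
    return GazeStream(
        t=t,
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        valid=valid.astype(bool).to_numpy(),
        sampling_rate=sampling_rate,
        pupil_radius=pupil,
    )


def write_gaze_csv(stream: GazeStream, path: str | Path) -> None:
    pupil = (
        stream.pupil_radius
        if stream.pupil_radius is not None
        else np.full(len(stream), np.nan)
    )
    pd.DataFrame(
        {
            "t": stream.t,
            "x": stream.x,
            "y": stream.y,
            "pupil_radius": pupil,
            "valid": stream.valid,
        }
    ).to_csv(path, index=False)


def read_rr_csv(path: str | Path) -> RRSeries:
    return RRSeries(_load(path, "rr")["rr_ms"].to_numpy(dtype=float))


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    pd.DataFrame({"rr_ms": rr.rr}).to_csv(path, index=False)


def read_respiration_csv(path: str | Path) -> RespirationSignal:
    df = _load(path, "respiration")
    return RespirationSignal(
        t=df["t"].to_numpy(dtype=float), volume=df["volume_ml"].to_numpy(dtype=float)
    )


def write_respiration_csv(resp: RespirationSignal, path: str | Path) -> None:
    pd.DataFrame({"t": resp.t, "volume_ml": resp.volume}).to_csv(path, index=False)


def read_paired_csv(path: str | Path) -> PairedSeries:
    df = _load(path, "paired")
    return PairedSeries(
        reference=df["reference"].to_numpy(dtype=float),
        measured=df["measured"].to_numpy(dtype=float),
        t=df["t"].to_numpy(dtype=float),
    )


def write_paired_csv(pair: PairedSeries, path: str | Path) -> None:
    t = pair.t if pair.t is not None else np.arange(len(pair.reference), dtype=float)
    pd.DataFrame(
        {"t": t, "reference": pair.reference, "measured": pair.measured}
    ).to_csv(path, index=False)


def read_cluster_csv(path: str | Path) -> list[FixationCluster]:
    """One cluster per distinct target location."""
    df = _load(path, "cluster")
    out = []
    for (tx, ty), grp in df.groupby(["target_x", "target_y"], sort=True):
        out.append(
            FixationCluster(samples=grp[["x", "y"]].to_numpy(dtype=float), target=(tx, ty))
        )
    return out


def read_roi_json(path: str | Path) -> ROILayout:
    import json

    items = json.loads(Path(path).read_text())
    return ROILayout([ROI(**item) for item in items])


def write_roi_json(layout: ROILayout, path: str | Path) -> None:
    import json

    Path(path).write_text(
        json.dumps([r.__dict__ for r in layout.rois], indent=2)
    )
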