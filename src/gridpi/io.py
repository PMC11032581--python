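"""File formats: trajectory logs, BIDS-style event TSVs, NIfTI, cohort CSV.

Trajectory logs are one CSV per trial with ``#``-prefixed JSON header lines
carrying the cone coordinates, condition, arena geometry and trial
metadata, followed by ``time_s,x_m,y_m,event`` rows. Raw coordinates are
serialized at full precision so scoring is unchanged by a write/read
round-trip; derived result tables use 9 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .arena import ArenaSpec
from .events import EventTable
from .grid import RoiTimeSeries
from .trajectory import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_events",
    "read_events",
    "write_bold_nifti",
    "read_bold",
    "read_mask",
    "load_roi_timeseries",
    "write_orientation_map",
    "FLOAT_FMT",
]

FLOAT_FMT = "%.9g"  # derived outputs; raw trajectories stay full precision


def write_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    header = {
        "cones": traj.cones.tolist(),
        "condition": traj.condition,
        "arena": asdict(traj.arena),
        "meta": traj.meta,
    }
    event_col = [""] * len(traj.times)
    for idx, label in traj.events:
        event_col[idx] = f"{event_col[idx]};{label}" if event_col[idx] else label
    with path.open("w", newline="\n") as fh:
        fh.write(f"# gridpi-trajectory {json.dumps(header)}\n")
        fh.write("time_s,x_m,y_m,event\n")
        for t, (x, y), ev in zip(traj.times, traj.xy, event_col):
            fh.write(
                f"{float(t)!r},{float(x)!r},{float(y)!r},{ev or 'none'}\n"
            )


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# gridpi-trajectory "):
            raise ValueError(f"{path}: not a trajectory log (bad header)")
        header = json.loads(first[len("# gridpi-trajectory ") :])
        colnames = fh.readline().strip().split(",")
        if colnames != ["time_s", "x_m", "y_m", "event"]:
            raise ValueError(f"{path}: unexpected columns {colnames}")
        times, xy, events = [], [], []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                times.append(float(parts[0]))
                xy.append((float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if parts[3] != "none":
                for label in parts[3].split(";"):
                    events.append((len(times) - 1, label))
    arena_kw = dict(header["arena"])
    arena_kw["origin"] = tuple(arena_kw["origin"])
    return Trajectory(
        times=np.asarray(times),
        xy=np.asarray(xy),
        cones=np.asarray(header["cones"]),
        condition=header["condition"],
        events=events,
        arena=ArenaSpec(**arena_kw),
        meta=header.get("meta", {}),
    )


def write_events(events: EventTable, path) -> None:
    """BIDS-style TSV with onset, duration, heading_deg columns."""
    events.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_events(path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable.from_frame(df)


def write_bold_nifti(data: np.ndarray, path, tr_s: float) -> None:
    """Write a (voxels, timepoints) matrix or 4D array as NIfTI-1."""
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, None, None, :]
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(tr_s)))
    nib.save(img, str(path))


def write_mask_nifti(mask: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.eye(4)), str(path))


def read_bold(path) -> nib.Nifti1Image:
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D time series, got {img.ndim}D")
    return img


def read_mask(path, image: nib.Nifti1Image | None = None) -> np.ndarray:
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    if image is not None:
        if mask.shape != image.shape[:3]:
            raise ValueError(
                f"mask grid {mask.shape} does not match image grid "
                f"{image.shape[:3]}"
            )
        if not np.allclose(img.affine, image.affine, atol=1e-4):
            raise ValueError("mask and image affines differ")
    if not mask.any():
        raise ValueError(f"{path}: mask selects no voxels")
    return mask


def load_roi_timeseries(
    bold_path, mask_path, nuisance_path=None
) -> RoiTimeSeries:
    """Extract the within-mask voxel time-series matrix from NIfTI files."""
    img = read_bold(bold_path)
    mask = read_mask(mask_path, image=img)
    data = np.asarray(img.dataobj, dtype=float)[mask]  # (n_voxels, n_tp)
    tr = float(img.header.get_zooms()[3]) or 1.0
    nuisance = None
    if nuisance_path is not None:
        nuisance = pd.read_csv(nuisance_path, sep="\t").to_numpy(float)
    return RoiTimeSeries(data, tr_s=tr, nuisance=nuisance)


def write_orientation_map(
    theta_v: np.ndarray, mask: np.ndarray, path
) -> None:
    """Per-voxel orientation map (degrees) within the mask, as NIfTI."""
    vol = np.full(np.asarray(mask).shape, np.nan, dtype=np.float32)
    vol[np.asarray(mask) > 0] = theta_v
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
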