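"""Readers and writers for the package's on-disk formats.

Trajectories travel as CSV with header ``track_id,frame,t_sec,x_um,y_um``;
images as single- or two-page unsigned 16-bit grayscale TIFF; tables as
UTF-8 CSV; summaries and ground truth as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import InvalidArgumentError
from .image_quant import IntensityImage
from .motility import PopulationSummary, Trajectory

TRACK_COLUMNS = ["track_id", "frame", "t_sec", "x_um", "y_um"]


def write_tracks(path, tracks) -> None:
    """Write trajectories as ``track_id,frame,t_sec,x_um,y_um`` CSV."""
    rows = []
    for t in tracks:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append((t.track_id, int(f), float(f) * t.dt, x, y))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(path) -> list:
    """Read trajectories from CSV; the frame interval is inferred from
    ``t_sec`` (all tracks in one file share it)."""
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidArgumentError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    tracks = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=np.int64)
        t_sec = g["t_sec"].to_numpy(dtype=np.float64)
        df_frames = np.diff(frames)
        if frames.size < 2:
            raise InvalidArgumentError(f"{path}: track {tid!r} has < 2 points")
        if np.any(df_frames != 1):
            raise InvalidArgumentError(
                f"{path}: track {tid!r} has frame gaps; gaps are rejected"
            )
        dts = np.diff(t_sec)
        dt = float(dts[0])
        if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
            raise InvalidArgumentError(
                f"{path}: track {tid!r} has uneven frame intervals"
            )
        tracks.append(
            Trajectory(
                track_id=tid,
                dt=dt,
                frames=frames,
                xy=g[["x_um", "y_um"]].to_numpy(dtype=np.float64),
            )
        )
    return tracks


def write_image(path, img: IntensityImage) -> None:
    """Write an image as unsigned 16-bit grayscale TIFF (values rounded and
    clipped to the uint16 range)."""
    data = np.clip(np.round(img.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_image(path, pixel_size: float = 1.0, channel: str = "", page: int = 0) -> IntensityImage:
    """Read one page of a grayscale TIFF as an :class:`IntensityImage`."""
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[page]
    return IntensityImage(np.asarray(data, dtype=np.float64), pixel_size=pixel_size, channel=channel)


def read_mask(path) -> np.ndarray:
    """Read a binary TIFF mask (nonzero = inside)."""
    return np.asarray(tifffile.imread(path)) > 0


def write_track_summaries(path, summary: PopulationSummary) -> None:
    """Per-track CSV: ``track_id,n_frames,alpha,r_squared,class,n_runs,max_run_um``."""
    rows = []
    for s in summary.tracks:
        rows.append(
            {
                "track_id": s.track_id,
                "n_frames": s.n_frames,
                "alpha": s.alpha,
                "r_squared": s.r_squared,
                "class": s.motility_class.value,
                "n_runs": len(s.run_lengths_um),
                "max_run_um": max(s.run_lengths_um) if s.run_lengths_um else 0.0,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "n_frames",
            "alpha",
            "r_squared",
            "class",
            "n_runs",
            "max_run_um",
        ],
    ).to_csv(path, index=False)


def write_run_lengths(path, summary: PopulationSummary) -> None:
    pd.DataFrame({"run_length_um": summary.run_lengths_um}).to_csv(path, index=False)


def population_to_dict(summary: PopulationSummary) -> dict:
    return {
        "n_tracks_input": summary.n_tracks_input,
        "n_tracks_retained": summary.n_tracks_retained,
        "fractions": summary.fractions,
        "fractions_defined": summary.fractions is not None,
        "run_length_histogram": {
            "bin_edges_um": summary.hist_edges_um.tolist(),
            "counts": summary.hist_counts.tolist(),
        },
    }


def write_population_json(path, summary: PopulationSummary) -> None:
    Path(path).write_text(json.dumps(population_to_dict(summary), indent=2))


def write_particle_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_profile_csv(path, profile) -> None:
    """Profile CSV: ``ring_index,r_inner_um,r_outer_um,intensity_fraction``."""
    rows = [
        {
            "ring_index": i,
            "r_inner_um": profile.edges_um[i],
            "r_outer_um": profile.edges_um[i + 1],
            "intensity_fraction": profile.fractions[i],
        }
        for i in range(profile.n_rings)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calibration(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"ph", "ratio_340_380"} <= set(df.columns):
        raise InvalidArgumentError(
            f"{path}: expected columns ph,ratio_340_380"
        )
    return df


def read_timecourse(path):
    from .assays import TimeCourse

    df = pd.read_csv(path)
    if not {"t_min", "mean_intensity"} <= set(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns t_min,mean_intensity")
    return TimeCourse(
        times_min=df["t_min"].to_numpy(dtype=np.float64),
        intensities=df["mean_intensity"].to_numpy(dtype=np.float64),
    )
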