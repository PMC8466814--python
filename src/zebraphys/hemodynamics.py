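"""Dorsal-aorta blood-flow velocity from blood-cell track tables.

Per-step speeds of all tracked cells are pooled within a subject.  The mean
velocity is the mean over all steps; the maximal velocity is the peak of the
smoothed per-frame mean time-course (a raw per-spot maximum would be
dominated by localization jitter).  Speeds are unsigned magnitudes — no
vessel-axis projection is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .datatypes import CellTrackTable
from .errors import InsufficientDataError


@dataclass
class TrackSpeeds:
    """Pooled per-step speeds (µm/s) with the frame stamp of each step."""

    speeds: np.ndarray
    frames: np.ndarray  # first frame of each step


@dataclass
class FlowEndpoints:
    """Flow summary for one recording."""

    mean_velocity: float       # µm/s, mean over all step speeds
    max_velocity: float        # µm/s, peak of the smoothed time-course
    velocity_timecourse: pd.DataFrame  # columns: frame, mean_speed, smoothed


def track_speeds(tracks: CellTrackTable, config: AcquisitionConfig) -> TrackSpeeds:
    """Per-step speed of every eligible track, gap-corrected.

    speed = Euclidean displacement × frame_rate / frame gap, in µm/s.
    Tracks with fewer than two rows contribute nothing (warned once).
    """
    speeds, frames = [], []
    n_short = 0
    for tr in tracks:
        if not tr.velocity_eligible:
            n_short += 1
            continue
        d = np.hypot(np.diff(tr.x), np.diff(tr.y))
        gaps = np.diff(tr.frames)
        speeds.append(d * config.frame_rate / gaps)
        frames.append(tr.frames[:-1])
    if n_short:
        warnings.warn(f"{n_short} track(s) with < 2 rows contribute no speeds")
    if not speeds:
        return TrackSpeeds(np.empty(0), np.empty(0, dtype=int))
    return TrackSpeeds(np.concatenate(speeds), np.concatenate(frames))


def flow_endpoints(speeds: TrackSpeeds, smoothing_window: int = 5) -> FlowEndpoints:
    """Mean and maximal flow velocity plus the per-frame time-course.

    The time-course is the per-frame mean of step speeds, smoothed by a
    centred moving average of ``smoothing_window`` frames; the maximal
    velocity is its peak.
    """
    if speeds.speeds.size == 0:
        raise InsufficientDataError("no valid steps: cannot compute flow endpoints")
    tc = (
        pd.DataFrame({"frame": speeds.frames, "speed": speeds.speeds})
        .groupby("frame", sort=True)["speed"]
        .mean()
        .rename("mean_speed")
        .reset_index()
    )
    tc["smoothed"] = (
        tc["mean_speed"].rolling(smoothing_window, center=True, min_periods=1).mean()
    )
    return FlowEndpoints(
        mean_velocity=float(speeds.speeds.mean()),
        max_velocity=float(tc["smoothed"].max()),
        velocity_timecourse=tc,
    )
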