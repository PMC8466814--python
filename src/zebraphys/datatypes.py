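"""Typed containers for the tabular inputs and outputs of the pipeline.

Each container validates its structural invariants at construction so that
downstream endpoint code can assume clean data: strictly increasing frame or
time indices, finite coordinates, physically possible chamber axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CHAMBERS = ("atrium", "ventricle")

ENDPOINT_COLUMNS = ["subject_id", "group_label", "endpoint_name", "value", "units"]


def _as_int_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr)) or not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError(f"{name} must be integer frame indices")
    return arr.astype(np.int64)


def _check_increasing(frames: np.ndarray, owner: str) -> None:
    if frames.size > 1 and not np.all(np.diff(frames) > 0):
        bad = int(frames[1:][np.diff(frames) <= 0][0])
        raise ValidationError(f"frames not strictly increasing for {owner!r} (at frame {bad})")


@dataclass
class Trajectory:
    """Per-frame larval centroid path in millimetres."""

    subject_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frames = _as_int_array(self.frames, "frames")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValidationError(f"length mismatch in trajectory {self.subject_id!r}")
        _check_increasing(self.frames, self.subject_id)
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError(f"non-finite coordinates in trajectory {self.subject_id!r}")

    def __len__(self) -> int:
        return len(self.frames)

    def points(self) -> np.ndarray:
        """(n, 2) array of positions in mm."""
        return np.column_stack([self.x, self.y])


@dataclass
class ChamberTrace:
    """Per-frame long/short axis lengths (µm) of one heart chamber."""

    subject_id: str
    chamber: str
    frames: np.ndarray
    long_axis: np.ndarray
    short_axis: np.ndarray

    def __post_init__(self) -> None:
        if self.chamber not in CHAMBERS:
            raise ValidationError(f"chamber must be one of {CHAMBERS}, got {self.chamber!r}")
        self.frames = _as_int_array(self.frames, "frames")
        self.long_axis = np.asarray(self.long_axis, dtype=float)
        self.short_axis = np.asarray(self.short_axis, dtype=float)
        if not (len(self.frames) == len(self.long_axis) == len(self.short_axis)):
            raise ValidationError(f"length mismatch in chamber trace {self.subject_id!r}")
        _check_increasing(self.frames, self.subject_id)
        if not np.all(np.isfinite(self.long_axis)) or not np.all(np.isfinite(self.short_axis)):
            raise ValidationError(f"non-finite axis length in {self.subject_id!r}")
        bad = ~(self.long_axis >= self.short_axis)
        bad |= ~(self.short_axis > 0)
        if np.any(bad):
            frame = int(self.frames[bad][0])
            raise ValidationError(
                f"axis invariant long >= short > 0 violated for {self.subject_id!r} "
                f"({self.chamber}) at frame {frame}"
            )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class O2Trace:
    """Dissolved-oxygen time series (ppm = mg/L) for one well."""

    well_id: str
    is_blank: bool
    times: np.ndarray
    o2: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if len(self.times) != len(self.o2):
            raise ValidationError(f"length mismatch in O2 trace {self.well_id!r}")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(f"times not strictly increasing for well {self.well_id!r}")
        if not np.all(np.isfinite(self.o2)) or np.any(self.o2 < 0):
            raise ValidationError(f"O2 values must be finite and >= 0 in well {self.well_id!r}")


@dataclass
class CellTrack:
    """One linked blood-cell track: positions in µm per frame."""

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frames = _as_int_array(self.frames, "frames")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValidationError(f"length mismatch in track {self.track_id!r}")
        _check_increasing(self.frames, f"track {self.track_id}")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError(f"non-finite position in track {self.track_id!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def velocity_eligible(self) -> bool:
        """Tracks need at least two rows to contribute step speeds."""
        return len(self.frames) >= 2


@dataclass
class CellTrackTable:
    """Collection of blood-cell tracks from one recording."""

    tracks: list[CellTrack] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def n_velocity_eligible(self) -> int:
        return sum(t.velocity_eligible for t in self.tracks)


def make_endpoint_table(rows) -> pd.DataFrame:
    """Assemble and validate a long-format endpoint table.

    Rows are (subject_id, group_label, endpoint_name, value, units) tuples or
    dicts.  (subject_id, endpoint_name) must be unique and units nonempty.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows), columns=ENDPOINT_COLUMNS)
    missing = [c for c in ENDPOINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"endpoint table missing columns: {missing}")
    df = df[ENDPOINT_COLUMNS].reset_index(drop=True)
    if len(df):
        dup = df.duplicated(subset=["subject_id", "endpoint_name"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["subject_id", "endpoint_name"]].tolist()
            raise ValidationError(f"duplicate (subject_id, endpoint_name) row: {pair}")
        if (df["units"].astype(str).str.len() == 0).any():
            raise ValidationError("endpoint units must be nonempty")
    return df
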