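"""Readers and writers for the pipeline's CSV dialects.

Four input schemas are supported:

* ``trajectory`` — columns ``subject_id, frame, x, y`` (positions in mm, or in
  pixels with ``units="px"`` and a configured ``mm_per_pixel``).
* ``chamber`` — ``subject_id, chamber, frame, long_axis_um, short_axis_um``.
* ``o2`` — ``well_id, is_blank, time_s, o2_ppm``.
* ``tracks`` — either the generic ``track_id, frame, x, y`` layout or a
  TrackMate spot-table export (``TRACK_ID, FRAME, POSITION_X, POSITION_Y``),
  auto-detected by header.  TrackMate CSVs may carry non-numeric sub-header
  rows; those are dropped and counted.

Rows are never silently discarded: every load logs row counts and the number
of dropped rows, and malformed values raise instead of being imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .datatypes import CellTrack, CellTrackTable, ChamberTrace, O2Trace, Trajectory
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

_SCHEMAS = {
    "trajectory": ["subject_id", "frame", "x", "y"],
    "chamber": ["subject_id", "chamber", "frame", "long_axis_um", "short_axis_um"],
    "o2": ["well_id", "is_blank", "time_s", "o2_ppm"],
    "tracks": ["track_id", "frame", "x", "y"],
}
_TRACKMATE_COLS = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")


def _pixel_scale(config: AcquisitionConfig, attr: str, path) -> float:
    scale = getattr(config, attr)
    if scale is None:
        raise SchemaError(f"{path}: positions are in pixels but config.{attr} is not set")
    return scale


def load_table(path, schema: str, config: AcquisitionConfig, units: str | None = None):
    """Load and validate one input file.

    Parameters
    ----------
    path
        CSV file to read.
    schema
        One of ``trajectory``, ``chamber``, ``o2``, ``tracks``.
    config
        Acquisition metadata; supplies the pixel scale when ``units="px"``.
    units
        ``"px"`` if positions are in pixels and must be converted to the
        physical unit of the schema (mm for trajectories, µm for tracks);
        ``None`` (default) means positions are already physical.

    Returns
    -------
    list of Trajectory / list of ChamberTrace / list of O2Trace /
    CellTrackTable, depending on ``schema``.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    loader = {
        "trajectory": _load_trajectories,
        "chamber": _load_chambers,
        "o2": _load_o2,
        "tracks": _load_tracks,
    }[schema]
    return loader(path, config, units)


def _load_trajectories(path, config, units):
    df = pd.read_csv(path)
    _require_columns(df, _SCHEMAS["trajectory"], path)
    if df[["frame", "x", "y"]].isna().any().any():
        raise ValidationError(f"{path}: NaN values in trajectory columns")
    if units == "px":
        scale = _pixel_scale(config, "mm_per_pixel", path)
        df = df.assign(x=df["x"] * scale, y=df["y"] * scale)
    out = [
        Trajectory(str(sid), g["frame"].to_numpy(), g["x"].to_numpy(), g["y"].to_numpy())
        for sid, g in df.groupby("subject_id", sort=True)
    ]
    logger.info("loaded %d trajectory rows (%d subjects, 0 dropped) from %s", len(df), len(out), path)
    return out


def _load_chambers(path, config, units):
    df = pd.read_csv(path)
    _require_columns(df, _SCHEMAS["chamber"], path)
    if df[["frame", "long_axis_um", "short_axis_um"]].isna().any().any():
        raise ValidationError(f"{path}: NaN values in chamber columns")
    long_axis, short_axis = df["long_axis_um"], df["short_axis_um"]
    if units == "px":
        scale = _pixel_scale(config, "um_per_pixel", path)
        long_axis, short_axis = long_axis * scale, short_axis * scale
    df = df.assign(long_axis_um=long_axis, short_axis_um=short_axis)
    out = [
        ChamberTrace(
            str(sid), str(chamber), g["frame"].to_numpy(),
            g["long_axis_um"].to_numpy(), g["short_axis_um"].to_numpy(),
        )
        for (sid, chamber), g in df.groupby(["subject_id", "chamber"], sort=True)
    ]
    logger.info("loaded %d chamber rows (%d traces, 0 dropped) from %s", len(df), len(out), path)
    return out


def _parse_blank(v) -> bool:
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"cannot parse is_blank value {v!r}")


def _load_o2(path, config, units):
    df = pd.read_csv(path)
    _require_columns(df, _SCHEMAS["o2"], path)
    if df[["time_s", "o2_ppm"]].isna().any().any():
        raise ValidationError(f"{path}: NaN values in O2 columns")
    out = []
    for wid, g in df.groupby("well_id", sort=True):
        blanks = {_parse_blank(v) for v in g["is_blank"]}
        if len(blanks) != 1:
            raise ValidationError(f"{path}: inconsistent is_blank flags for well {wid!r}")
        out.append(O2Trace(str(wid), blanks.pop(), g["time_s"].to_numpy(), g["o2_ppm"].to_numpy()))
    logger.info("loaded %d O2 rows (%d wells, 0 dropped) from %s", len(df), len(out), path)
    return out


def _load_tracks(path, config, units):
    df = pd.read_csv(path)
    dropped = 0
    if all(c in df.columns for c in _TRACKMATE_COLS):
        # TrackMate exports prepend up to three non-numeric sub-header rows.
        frame_num = pd.to_numeric(df["FRAME"], errors="coerce")
        keep = frame_num.notna()
        dropped = int((~keep).sum())
        df = df.loc[keep]
        df = pd.DataFrame(
            {
                "track_id": df["TRACK_ID"].astype(str),
                "frame": pd.to_numeric(df["FRAME"]),
                "x": pd.to_numeric(df["POSITION_X"]),
                "y": pd.to_numeric(df["POSITION_Y"]),
            }
        )
    else:
        _require_columns(df, _SCHEMAS["tracks"], path)
    if df[["frame", "x", "y"]].isna().any().any():
        raise ValidationError(f"{path}: NaN values in track columns")
    if units == "px":
        scale = _pixel_scale(config, "um_per_pixel", path)
        df = df.assign(x=df["x"] * scale, y=df["y"] * scale)
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(CellTrack(str(tid), g["frame"].to_numpy(), g["x"].to_numpy(), g["y"].to_numpy()))
    table = CellTrackTable(tracks)
    n_short = len(table) - table.n_velocity_eligible
    if n_short:
        logger.warning("%d of %d tracks have < 2 rows and are velocity-ineligible", n_short, len(table))
    logger.info("loaded %d track rows (%d tracks, %d dropped) from %s", len(df), len(table), dropped, path)
    return table


def write_endpoints(table: pd.DataFrame, path) -> None:
    """Write a validated endpoint table to CSV (lossless round-trip)."""
    from .datatypes import make_endpoint_table

    df = make_endpoint_table(table)
    df.to_csv(path, index=False)
    logger.info("wrote %d endpoint rows to %s", len(df), path)


def read_endpoints(path) -> pd.DataFrame:
    """Read back an endpoint CSV written by :func:`write_endpoints`."""
    from .datatypes import make_endpoint_table

    return make_endpoint_table(pd.read_csv(path))
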