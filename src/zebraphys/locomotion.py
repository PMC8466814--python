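"""Photomotor-response endpoints from larval centroid trajectories.

Three endpoint families are computed per subject and light/dark phase:

* distance travelled, split into velocity bands — inactivity (< 0.5 mm/s),
  cruising (0.5–20 mm/s, boundaries inclusive) and burst (> 20 mm/s);
* burst events per minute, an event being a maximal run of steps at or above
  a pixel-based speed threshold (20 px/s by default, converted with the
  configured pixel scale);
* completed clockwise / counter-clockwise rotations: arcs accumulating 360°
  of consistent signed turning whose spatial extent exceeds 2 mm, with a 60°
  "back angle" reversal tolerance that aborts an in-progress rotation.

Counter-clockwise is the mathematically positive turning direction in the
(x, y) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import UNSCHEDULED, AcquisitionConfig, assign_phases, phase_index
from .datatypes import Trajectory, make_endpoint_table
from .errors import ConfigurationError, InsufficientDataError

BANDS = ("inactivity", "cruising", "burst")


@dataclass
class VelocityBands:
    """Speed cut-offs (mm/s) separating inactivity, cruising and burst."""

    inactivity_max: float = 0.5
    cruise_max: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.inactivity_max < self.cruise_max:
            raise ConfigurationError(
                f"need 0 < inactivity_max < cruise_max, got "
                f"{self.inactivity_max}, {self.cruise_max}"
            )


@dataclass
class RotationParams:
    """Rotation-scoring parameters.

    min_diameter : mm — arcs whose maximum pairwise vertex distance does not
        exceed this are abandoned (default 2 mm).
    back_angle : degrees — an opposing turn larger than this aborts an
        in-progress rotation (default 60°).
    min_step : mm — steps shorter than this are merged forward before heading
        computation, since headings of sub-pixel steps are noise (default
        0.05 mm).
    """

    min_diameter: float = 2.0
    back_angle: float = 60.0
    min_step: float = 0.05

    def __post_init__(self) -> None:
        if not self.min_diameter > 0:
            raise ConfigurationError("min_diameter must be > 0")
        if not 0 < self.back_angle < 180:
            raise ConfigurationError("back_angle must be in (0, 180) degrees")


@dataclass
class StepSeries:
    """Per-step kinematics of one trajectory."""

    speeds: np.ndarray      # mm/s
    lengths: np.ndarray     # mm
    start_frames: np.ndarray
    gaps: np.ndarray        # frame gap of each step (>= 1)
    phases: np.ndarray | None = None  # label of each step's first frame


def step_speeds(traj: Trajectory, config: AcquisitionConfig) -> StepSeries:
    """Speed of each consecutive frame pair, gap-corrected.

    ``speed_i = ||p_{i+1} - p_i|| * frame_rate / gap_i``; a step is assigned
    the phase of its first frame when a schedule is configured.
    """
    if len(traj) < 2:
        raise InsufficientDataError(
            f"trajectory {traj.subject_id!r} has {len(traj)} frames; need >= 2"
        )
    d = np.hypot(np.diff(traj.x), np.diff(traj.y))
    gaps = np.diff(traj.frames)
    speeds = d * config.frame_rate / gaps
    start = traj.frames[:-1]
    phases = assign_phases(start, config) if config.phase_schedule else None
    return StepSeries(speeds=speeds, lengths=d, start_frames=start, gaps=gaps, phases=phases)


def band_of(speeds: np.ndarray, bands: VelocityBands) -> np.ndarray:
    """Velocity band of each step.  Boundary speeds (exactly 0.5 or 20 mm/s)
    fall in the cruising band; only strict exceedance of the upper cut-off is
    burst."""
    out = np.full(len(speeds), "cruising", dtype=object)
    out[speeds < bands.inactivity_max] = "inactivity"
    out[speeds > bands.cruise_max] = "burst"
    return out


def banded_distance(steps: StepSeries, bands: VelocityBands) -> pd.DataFrame:
    """Distance (mm) accrued in each velocity band, per phase label.

    Each step's length accrues to exactly one band, so band distances sum to
    the total path length by construction.
    """
    labels = steps.phases if steps.phases is not None else np.full(len(steps.speeds), "all", dtype=object)
    df = pd.DataFrame(
        {"phase": labels, "band": band_of(steps.speeds, bands), "distance_mm": steps.lengths}
    )
    out = df.groupby(["phase", "band"], sort=True)["distance_mm"].sum().reset_index()
    return out


def _burst_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of True, as (start, stop) index pairs."""
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts, stops))


def count_bursts(
    traj: Trajectory,
    config: AcquisitionConfig,
    threshold_px_per_s: float = 20.0,
) -> pd.DataFrame:
    """Burst events per minute, per phase occurrence.

    A burst event is a maximal contiguous run of steps whose speed is at or
    above ``threshold_px_per_s * mm_per_pixel`` mm/s.  An event straddling a
    phase boundary counts in the phase where it starts.

    Returns a frame with one row per scheduled phase occurrence: columns
    ``phase_idx, phase, duration_min, events, rate_per_min``.
    """
    if config.mm_per_pixel is None:
        raise ConfigurationError("mm_per_pixel must be set to convert the pixel burst threshold")
    threshold_mm = threshold_px_per_s * config.mm_per_pixel
    steps = step_speeds(traj, config)
    above = steps.speeds >= threshold_mm
    runs = _burst_runs(above)
    start_idx = phase_index(steps.start_frames, config)
    events_per_phase = np.zeros(len(config.phase_schedule), dtype=int)
    for start, _stop in runs:
        p = start_idx[start]
        if p >= 0:
            events_per_phase[p] += 1
    rows = []
    for i, (label, dur) in enumerate(config.phase_schedule):
        dur_min = dur / 60.0
        rows.append(
            {
                "phase_idx": i,
                "phase": label,
                "duration_min": dur_min,
                "events": int(events_per_phase[i]),
                "rate_per_min": events_per_phase[i] / dur_min,
            }
        )
    return pd.DataFrame(rows)


def _gate_jitter(points: np.ndarray, frames: np.ndarray, min_step: float):
    """Merge steps shorter than ``min_step`` forward: keep a vertex only once
    it has moved at least ``min_step`` from the last kept vertex."""
    keep = [0]
    last = points[0]
    for i in range(1, len(points)):
        if np.hypot(*(points[i] - last)) >= min_step:
            keep.append(i)
            last = points[i]
    idx = np.array(keep)
    return points[idx], frames[idx]


def _turn_angles(points: np.ndarray) -> np.ndarray:
    """Signed turn (degrees, CCW positive) at each interior vertex."""
    v = np.diff(points, axis=0)
    a, b = v[:-1], v[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.einsum("ij,ij->i", a, b)
    return np.degrees(np.arctan2(cross, dot))


def rotation_events(traj: Trajectory, params: RotationParams | None = None) -> list[tuple[int, str]]:
    """Completed rotations as (completion_frame, direction) with direction in
    {"cw", "ccw"}.

    Signed turn angles from consecutive displacement headings (after jitter
    gating) are accumulated; a rotation is scored when the accumulated turn
    reaches 360° with consistent sign and the maximum pairwise distance among
    the arc's vertices exceeds ``min_diameter``.  An opposing turn larger
    than ``back_angle`` resets the accumulator and starts a new arc.
    """
    params = params or RotationParams()
    pts, frames = _gate_jitter(traj.points(), traj.frames, params.min_step)
    if len(pts) < 3:
        return []
    turns = _turn_angles(pts)
    events: list[tuple[int, str]] = []
    cum = 0.0
    arc_start = 0  # index into pts of the current arc's first vertex
    for k, t in enumerate(turns):
        vertex = k + 1  # the turn at pts[vertex]
        if cum != 0.0 and np.sign(t) == -np.sign(cum) and abs(t) > params.back_angle:
            cum = t
            arc_start = vertex
        else:
            cum += t
        # tiny tolerance so a full turn assembled from float headings
        # (e.g. 36 x 10 deg summing to 360 - 1e-13) still completes
        if abs(cum) >= 360.0 - 1e-6:
            arc = pts[arc_start : vertex + 2]
            if _max_pairwise_distance(arc) > params.min_diameter:
                events.append((int(frames[vertex + 1]), "ccw" if cum > 0 else "cw"))
            cum = float(cum - 360.0 * np.sign(cum))
            if abs(cum) < 1e-6:
                cum = 0.0
            arc_start = vertex + 1
    return events


def _max_pairwise_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    # Hull would be faster asymptotically; arcs are bounded (~1 loop) so the
    # quadratic form is fine and has no degenerate cases.
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def count_rotations(
    traj: Trajectory,
    params: RotationParams | None = None,
    config: AcquisitionConfig | None = None,
):
    """Clockwise / counter-clockwise rotation counts.

    Without a config, returns the total ``(cw, ccw)`` tuple.  With a config
    carrying a phase schedule, returns a frame with one row per phase
    occurrence (columns ``phase_idx, phase, cw, ccw``); a rotation belongs to
    the phase of its completion frame.
    """
    events = rotation_events(traj, params)
    if config is None or not config.phase_schedule:
        cw = sum(1 for _, d in events if d == "cw")
        ccw = sum(1 for _, d in events if d == "ccw")
        return cw, ccw
    n = len(config.phase_schedule)
    cw = np.zeros(n, dtype=int)
    ccw = np.zeros(n, dtype=int)
    if events:
        frames = np.array([f for f, _ in events])
        idx = phase_index(frames, config)
        for i, (_, d) in zip(idx, events):
            if i >= 0:
                (ccw if d == "ccw" else cw)[i] += 1
    rows = [
        {"phase_idx": i, "phase": label, "cw": int(cw[i]), "ccw": int(ccw[i])}
        for i, (label, _) in enumerate(config.phase_schedule)
    ]
    return pd.DataFrame(rows)


@dataclass
class LocomotionEndpoints:
    """Per-subject, per-phase-type locomotion endpoints.

    Distances are in cm, burst rates in events/min, rotations in counts; all
    are arithmetic means over the occurrences of each phase type.
    """

    subject_id: str
    phase: str
    total_distance_cm: float
    distance_by_band_cm: dict = field(default_factory=dict)
    burst_rate_per_min: float = 0.0
    rotations_cw: float = 0.0
    rotations_ccw: float = 0.0


def locomotion_report(
    trajectories: list[Trajectory],
    config: AcquisitionConfig,
    bands: VelocityBands | None = None,
    params: RotationParams | None = None,
    groups: dict[str, str] | None = None,
    burst_threshold_px_per_s: float = 20.0,
) -> pd.DataFrame:
    """Endpoint table for a cohort: one row per subject x phase type x endpoint.

    Per phase-type values are means over that phase type's occurrences (the
    photomotor protocol repeats each phase four times).  Endpoint names are
    suffixed with the phase type, e.g. ``distance_total_dark``.
    """
    bands = bands or VelocityBands()
    params = params or RotationParams()
    groups = groups or {}
    if not config.phase_schedule:
        raise ConfigurationError("locomotion_report requires a phase schedule")
    phase_types = sorted({label for label, _ in config.phase_schedule})
    occ = pd.DataFrame(
        {
            "phase_idx": range(len(config.phase_schedule)),
            "phase": [label for label, _ in config.phase_schedule],
            "duration_min": [d / 60.0 for _, d in config.phase_schedule],
        }
    )
    rows = []
    for traj in trajectories:
        steps = step_speeds(traj, config)
        if steps.phases is None or np.all(steps.phases == UNSCHEDULED):
            import warnings

            warnings.warn(f"subject {traj.subject_id!r} has no scheduled frames; excluded")
            continue
        group = groups.get(traj.subject_id, "")
        # distance per phase occurrence and band
        occ_idx = phase_index(steps.start_frames, config)
        dist = pd.DataFrame(
            {
                "phase_idx": occ_idx,
                "band": band_of(steps.speeds, bands),
                "distance_mm": steps.lengths,
            }
        )
        dist = dist[dist["phase_idx"] >= 0]
        per_occ_band = (
            dist.groupby(["phase_idx", "band"])["distance_mm"].sum().unstack(fill_value=0.0)
        )
        per_occ_band = per_occ_band.reindex(columns=BANDS, fill_value=0.0).reindex(
            index=occ["phase_idx"], fill_value=0.0
        )
        bursts = count_bursts(traj, config, burst_threshold_px_per_s)
        rots = count_rotations(traj, params, config)
        merged = occ.join(per_occ_band, on="phase_idx")
        merged["burst_rate"] = bursts["rate_per_min"].to_numpy()
        merged["cw"] = rots["cw"].to_numpy()
        merged["ccw"] = rots["ccw"].to_numpy()
        for ptype in phase_types:
            sel = merged[merged["phase"] == ptype]
            if sel.empty:
                continue
            band_cm = {b: sel[b].mean() / 10.0 for b in BANDS}  # mm -> cm
            total_cm = sum(band_cm.values())
            endpoint_values = {
                f"distance_total_{ptype}": (total_cm, "cm"),
                f"distance_inactivity_{ptype}": (band_cm["inactivity"], "cm"),
                f"distance_cruising_{ptype}": (band_cm["cruising"], "cm"),
                f"distance_burst_{ptype}": (band_cm["burst"], "cm"),
                f"burst_rate_{ptype}": (sel["burst_rate"].mean(), "events/min"),
                f"rotations_cw_{ptype}": (sel["cw"].mean(), "count"),
                f"rotations_ccw_{ptype}": (sel["ccw"].mean(), "count"),
            }
            for name, (value, units) in endpoint_values.items():
                rows.append((traj.subject_id, group, name, float(value), units))
    return make_endpoint_table(rows)
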