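"""Synthetic raw-data generators with known ground truth.

Each generator emulates one of the pipeline's raw inputs — photomotor
trajectories, two-chamber heart axis traces, closed-well O₂ time series,
blood-cell track tables — and returns the realized ground-truth parameters
alongside the data, so every pipeline stage can be exercised as a
parameter-recovery problem.  All generators are deterministic given their
arguments and a seed; a top-level seed streams independent per-subject
sub-seeds.

Design notes
------------
* Trajectories are correlated random walks: per-phase log-normal step speeds
  and wrapped-normal heading increments.  Burst runs and rotation loops are
  injected as deterministic bouts so their counts are exact ground truth;
  rotation loops are entered and exited tangentially (k full loops turn
  exactly k·360°, leaving the heading unchanged), and baseline speeds are
  clipped just below the burst threshold when bursts are requested.
* Inter-beat intervals follow an AR(1) process with configurable lag-1
  autocorrelation ρ, so the Poincaré SD2 > SD1 asymmetry is reachable.
  Chamber axes relax at the diastolic geometry and contract toward the
  systolic geometry in a raised-cosine bump centred on each beat, which puts
  the short-axis minimum exactly at the programmed beat time.
* O₂ wells decline linearly with a plate-wide drift shared by the blank.
* Blood cells are advected along one axis by a rectified-sinusoid velocity
  waveform with i.i.d. localization jitter; tracks enter and leave the field
  so lengths vary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .datatypes import CellTrack, CellTrackTable, ChamberTrace, O2Trace, Trajectory
from .errors import SimSpecError


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and sd."""
    if mean <= 0:
        raise SimSpecError("speed mean must be > 0")
    if sd <= 0:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class RotationBout:
    """A programmed run of full loops: ``n_loops`` circuits of ``diameter``
    mm, ``direction`` in {"cw", "ccw"}, ``vertices_per_loop`` polygon sides
    (None = auto: 36, refined upward so loop steps stay below the burst
    threshold when bursts are also simulated)."""

    n_loops: int = 1
    diameter: float = 4.0
    direction: str = "ccw"
    vertices_per_loop: int | None = None


def sim_trajectories(
    config: AcquisitionConfig,
    n_subjects: int = 1,
    speed_mean: dict[str, float] | None = None,
    speed_sd: dict[str, float] | None = None,
    heading_sd_deg: float = 20.0,
    burst_rate_per_min: dict[str, float] | None = None,
    burst_speed_mm_s: float | None = None,
    burst_duration_s: float = 0.4,
    burst_threshold_mm_s: float = 5.0,
    rotation_bouts: dict[str, list[RotationBout]] | None = None,
    position_jitter_mm: float = 0.0,
    well_diameter_mm: float | None = None,
    seed: int = 0,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate photomotor trajectories with per-phase ground truth.

    Parameters are keyed by phase label where phase-dependent: ``speed_mean``
    / ``speed_sd`` (mm/s; defaults emulate the dark > light photomotor
    pattern at 1.5 / 3.0 mm/s), ``burst_rate_per_min`` (expected burst bouts
    per minute) and ``rotation_bouts`` (inserted once per phase occurrence).

    Returns the trajectories and a ground-truth frame with one row per
    subject × phase occurrence: realized ``distance_mm`` (pre-jitter),
    ``burst_events``, ``rot_cw``, ``rot_ccw``.
    """
    if not config.phase_schedule:
        raise SimSpecError("sim_trajectories needs a phase schedule")
    speed_mean = speed_mean or {"light": 1.5, "dark": 3.0}
    speed_sd = speed_sd or {k: 0.5 * v for k, v in speed_mean.items()}
    burst_rate_per_min = burst_rate_per_min or {}
    rotation_bouts = rotation_bouts or {}
    for bouts in rotation_bouts.values():
        for b in bouts:
            if well_diameter_mm is not None and b.diameter > well_diameter_mm:
                raise SimSpecError(
                    f"rotation diameter {b.diameter} mm exceeds well diameter {well_diameter_mm} mm"
                )
    if burst_speed_mm_s is None:
        burst_speed_mm_s = 5.0 * burst_threshold_mm_s
    if burst_rate_per_min and burst_speed_mm_s < burst_threshold_mm_s:
        raise SimSpecError("burst_speed_mm_s must be >= burst_threshold_mm_s")
    fps = config.frame_rate
    any_bursts = any(r > 0 for r in burst_rate_per_min.values())
    trajectories, gt_rows = [], []
    for subj, rng in enumerate(_rngs(seed, n_subjects)):
        sid = f"sim{subj:03d}"
        lengths_all, headings_all = [], []
        for occ, (label, dur) in enumerate(config.phase_schedule):
            n_steps = int(round(dur * fps))
            mu, sigma = _lognormal_params(speed_mean[label], speed_sd[label])
            speeds = rng.lognormal(mu, sigma, n_steps)
            if any_bursts:
                # keep the baseline strictly below the burst threshold so that
                # programmed burst runs are exact ground truth
                speeds = np.minimum(speeds, 0.9 * burst_threshold_mm_s)
            turns = np.radians(rng.normal(0.0, heading_sd_deg, n_steps))
            # rotation loops replace walk steps (frame count per phase stays
            # fixed so phase boundaries remain aligned)
            rot_cw = rot_ccw = 0
            reserved = np.zeros(n_steps, dtype=bool)
            loop_edits = []
            for bout in rotation_bouts.get(label, []):
                m = bout.vertices_per_loop
                if m is None:
                    m = 36
                    if any_bursts:
                        # loop steps must stay sub-threshold or each loop
                        # would register as a spurious burst run
                        m = max(m, int(np.ceil(
                            np.pi * bout.diameter * fps / (0.9 * burst_threshold_mm_s)
                        )))
                seg_len, seg_head, k = _loop_segment(bout, m)
                span = len(seg_len)
                if span > n_steps - 2:
                    raise SimSpecError(
                        f"rotation bout of {span} steps does not fit a {n_steps}-step phase"
                    )
                for _ in range(200):
                    start = int(rng.integers(1, n_steps - span))
                    if not reserved[max(0, start - 1) : start + span + 1].any():
                        break
                else:  # pragma: no cover - pathological packing
                    raise SimSpecError("could not place non-overlapping rotation bouts")
                reserved[start : start + span] = True
                loop_edits.append((start, seg_len, seg_head))
                if bout.direction == "cw":
                    rot_cw += k
                else:
                    rot_ccw += k
            # burst bouts: non-adjacent supra-threshold runs, clear of loops
            # and of the phase edges (so events never merge across phases)
            is_burst = np.zeros(n_steps, dtype=bool)
            n_events = 0
            rate = burst_rate_per_min.get(label, 0.0)
            if rate > 0:
                n_events = int(rng.poisson(rate * dur / 60.0))
                run_len = max(1, int(round(burst_duration_s * fps)))
                n_events = _place_runs(rng, is_burst, n_events, run_len, blocked=reserved)
                speeds[is_burst] = burst_speed_mm_s
                turns[is_burst] = 0.0
            headings = np.cumsum(turns)
            lengths = speeds / fps
            for start, seg_len, seg_head in loop_edits:
                base = headings[start - 1]
                span = len(seg_len)
                lengths[start : start + span] = seg_len
                headings[start : start + span] = base + seg_head
            lengths_all.append(lengths)
            headings_all.append(headings)
            gt_rows.append(
                {
                    "subject_id": sid,
                    "phase_idx": occ,
                    "phase": label,
                    "distance_mm": float(lengths.sum()),
                    "burst_events": int(n_events),
                    "rot_cw": int(rot_cw),
                    "rot_ccw": int(rot_ccw),
                }
            )
        lengths = np.concatenate(lengths_all)
        headings = np.concatenate(headings_all)
        dx = lengths * np.cos(headings)
        dy = lengths * np.sin(headings)
        x = np.concatenate([[0.0], np.cumsum(dx)])
        y = np.concatenate([[0.0], np.cumsum(dy)])
        if position_jitter_mm > 0:
            x = x + rng.normal(0.0, position_jitter_mm, len(x))
            y = y + rng.normal(0.0, position_jitter_mm, len(y))
        frames = np.arange(len(x))
        trajectories.append(Trajectory(sid, frames, x, y))
    return trajectories, pd.DataFrame(gt_rows)


def _place_runs(
    rng, mask: np.ndarray, n_events: int, run_len: int, blocked: np.ndarray | None = None
) -> int:
    """Mark up to n_events non-adjacent runs of run_len in mask (avoiding
    blocked regions and the first/last step); returns the number placed."""
    n = len(mask)
    placed = 0
    attempts = 0
    while placed < n_events and attempts < 100 * max(1, n_events):
        attempts += 1
        if n - run_len - 1 <= 1:
            break
        start = int(rng.integers(1, n - run_len - 1))
        lo, hi = start - 1, start + run_len + 1
        if mask[lo:hi].any() or (blocked is not None and blocked[lo:hi].any()):
            continue
        mask[start : start + run_len] = True
        placed += 1
    return placed


def _loop_segment(bout: RotationBout, m: int | None = None):
    """Step lengths and headings (relative to entry heading 0) of k tangential
    loops of an m-gon inscribed in a circle of the given diameter."""
    if m is None:
        m = bout.vertices_per_loop or 36
    if m < 4:
        raise SimSpecError("vertices_per_loop must be >= 4")
    k = int(bout.n_loops)
    sgn = {"ccw": 1.0, "cw": -1.0}.get(bout.direction)
    if sgn is None:
        raise SimSpecError(f"direction must be cw or ccw, got {bout.direction!r}")
    side = bout.diameter * np.sin(np.pi / m)
    n_steps = k * m + 1
    headings = sgn * 2.0 * np.pi / m * np.arange(n_steps)
    lengths = np.full(n_steps, side)
    return lengths, headings, k


# ---------------------------------------------------------------------------
# heart
# ---------------------------------------------------------------------------

def sim_heart(
    hr_mean_bpm: float = 150.0,
    ibi_sd_ms: float = 10.0,
    ibi_rho: float = 0.0,
    av_delay_ms: float = 80.0,
    ventricle_diastole_um: tuple[float, float] = (100.0, 50.0),
    ventricle_systole_um: tuple[float, float] = (90.0, 40.0),
    atrium_diastole_um: tuple[float, float] = (90.0, 45.0),
    atrium_systole_um: tuple[float, float] = (80.0, 38.0),
    fps: float = 200.0,
    duration_s: float = 10.0,
    noise_sd_um: float = 0.0,
    subject_id: str = "sim_heart",
    seed: int = 0,
) -> tuple[ChamberTrace, ChamberTrace, dict]:
    """Simulate one larva's two-chamber axis traces with ground truth.

    Atrial beat intervals follow a stationary AR(1) process (mean 60/HR s,
    marginal sd ``ibi_sd_ms``, lag-1 autocorrelation ``ibi_rho``); each
    ventricular beat lags its atrial beat by ``av_delay_ms``.  Chamber axes
    stay at the diastolic geometry and dip to the systolic geometry in a
    raised-cosine bump centred on each beat, so short-axis minima fall
    exactly on the programmed beat times.

    The ground-truth dict records the realized beat times, HR, SD1/SD2 of the
    realized intervals, and the volumetric endpoints implied by the
    programmed geometry.
    """
    from .cardiac import ellipsoid_volume  # local import avoids a cycle

    if not 0 <= abs(ibi_rho) < 1:
        raise SimSpecError("ibi_rho must satisfy |rho| < 1")
    mean_ibi = 60.0 / hr_mean_bpm
    if av_delay_ms / 1000.0 >= mean_ibi:
        raise SimSpecError("AV delay must be shorter than the mean beat interval")
    for dia, sys_ in ((ventricle_diastole_um, ventricle_systole_um),
                      (atrium_diastole_um, atrium_systole_um)):
        for L, W in (dia, sys_):
            if not L >= W > 0:
                raise SimSpecError("chamber geometry needs L >= W > 0")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    sd_s = ibi_sd_ms / 1000.0
    innov_sd = sd_s * np.sqrt(1.0 - ibi_rho**2)
    n_max = int(np.ceil(duration_s / mean_ibi * 2)) + 10
    ibis = np.empty(n_max)
    dev = rng.normal(0.0, sd_s)  # stationary start
    for i in range(n_max):
        ibis[i] = mean_ibi + dev
        dev = ibi_rho * dev + rng.normal(0.0, innov_sd)
    ibis = np.clip(ibis, 0.3 * mean_ibi, None)
    t0 = 0.6 * mean_ibi
    atrial = t0 + np.concatenate([[0.0], np.cumsum(ibis)])
    atrial = atrial[atrial < duration_s - 0.05]
    vent = atrial + av_delay_ms / 1000.0
    vent = vent[vent < duration_s - 0.05]
    frames = np.arange(int(round(duration_s * fps)))
    t = frames / fps
    width = min(0.3 * mean_ibi, 0.45 * float(np.min(np.diff(atrial))) if len(atrial) > 1 else 0.3 * mean_ibi)

    def chamber_trace(events, dia, sys_, chamber):
        bump = np.zeros_like(t)
        for e in events:
            sel = np.abs(t - e) < width
            bump[sel] = np.maximum(bump[sel], np.cos(np.pi * (t[sel] - e) / (2 * width)) ** 2)
        L = dia[0] - (dia[0] - sys_[0]) * bump
        W = dia[1] - (dia[1] - sys_[1]) * bump
        if noise_sd_um > 0:
            L = L + rng.normal(0.0, noise_sd_um, len(L))
            W = W + rng.normal(0.0, noise_sd_um, len(W))
            W = np.minimum(W, L - 1e-9)
            W = np.maximum(W, 1e-6)
        return ChamberTrace(subject_id, chamber, frames, L, W)

    atrium = chamber_trace(atrial, atrium_diastole_um, atrium_systole_um, "atrium")
    ventricle = chamber_trace(vent, ventricle_diastole_um, ventricle_systole_um, "ventricle")
    a_ibis = np.diff(atrial) * 1000.0
    edv = ellipsoid_volume(*ventricle_diastole_um)
    esv = ellipsoid_volume(*ventricle_systole_um)
    sv = edv - esv
    hr_true = (len(vent) - 1) / (vent[-1] - vent[0]) * 60.0 if len(vent) > 1 else np.nan
    sd1 = sd2 = np.nan
    if len(a_ibis) >= 3:
        x, y = a_ibis[:-1], a_ibis[1:]
        sd1 = float(np.sqrt(np.var(y - x) / 2.0))
        sd2 = float(np.sqrt(np.var(y + x) / 2.0))
    truth = {
        "atrial_beat_times": atrial,
        "ventricular_beat_times": vent,
        "hr_bpm": float(hr_true),
        "sd1_ms": sd1,
        "sd2_ms": sd2,
        "av_delay_ms": float(av_delay_ms),
        "edv_pl": edv,
        "esv_pl": esv,
        "sv_pl": sv,
        "ef_pct": 100.0 * sv / edv,
        "sf_pct": 100.0 * (ventricle_diastole_um[1] - ventricle_systole_um[1]) / ventricle_diastole_um[1],
    }
    return atrium, ventricle, truth


# ---------------------------------------------------------------------------
# oxygen plate
# ---------------------------------------------------------------------------

def sim_o2_plate(
    n_wells: int = 24,
    slope_mean_ppm_min: float = 0.03,
    slope_sd_ppm_min: float = 0.005,
    blank_drift_ppm_min: float = 0.01,
    o2_start_ppm: float = 8.0,
    noise_sd_ppm: float = 0.0,
    duration_min: float = 80.0,
    sample_interval_s: float = 60.0,
    seed: int = 0,
) -> tuple[list[O2Trace], pd.DataFrame]:
    """Simulate a sensor-dish plate: one blank, ``n_wells − 1`` fish wells.

    Each fish well declines at its own slope (Gaussian across wells,
    truncated at 0) plus the plate-wide drift; the blank carries drift only.
    Ground truth records each well's true consumption slope (ppm/min).
    """
    if n_wells < 2:
        raise SimSpecError("need at least a blank and one fish well")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    times = np.arange(0.0, duration_min * 60.0 + 1e-9, sample_interval_s)
    t_min = times / 60.0
    traces, rows = [], []
    for i in range(n_wells):
        is_blank = i == 0
        slope = 0.0 if is_blank else max(0.0, rng.normal(slope_mean_ppm_min, slope_sd_ppm_min))
        o2 = o2_start_ppm - (slope + blank_drift_ppm_min) * t_min
        if noise_sd_ppm > 0:
            o2 = o2 + rng.normal(0.0, noise_sd_ppm, len(o2))
        o2 = np.maximum(o2, 0.0)
        wid = "blank" if is_blank else f"well{i:02d}"
        traces.append(O2Trace(wid, is_blank, times, o2))
        rows.append({"well_id": wid, "is_blank": is_blank, "slope_ppm_min": slope})
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# blood tracks
# ---------------------------------------------------------------------------

def sim_blood_tracks(
    n_tracks: int = 10,
    baseline_um_s: float = 500.0,
    amplitude_um_s: float = 400.0,
    frequency_hz: float = 2.5,
    fps: float = 200.0,
    duration_s: float = 10.0,
    jitter_um: float = 0.1,
    min_track_s: float = 0.5,
    max_track_s: float = 2.0,
    seed: int = 0,
) -> tuple[CellTrackTable, dict]:
    """Simulate blood-cell tracks advected by a pulsatile waveform.

    The shared axial velocity is ``v(t) = baseline + amplitude·max(0,
    sin(2π·f·t))`` µm/s; each track covers a random sub-interval of the
    recording (cells enter and leave the field) with i.i.d. Gaussian
    localization jitter on both coordinates.  Ground truth is the waveform's
    time-average and peak over the recording.
    """
    if baseline_um_s < 0 or amplitude_um_s < 0:
        raise SimSpecError("waveform must be non-negative")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps
    v = baseline_um_s + amplitude_um_s * np.maximum(0.0, np.sin(2 * np.pi * frequency_hz * t))
    # position of a virtual particle advected from t=0; each cell is an offset
    x_ref = np.concatenate([[0.0], np.cumsum(v / fps)])[:-1]
    tracks = []
    for i in range(n_tracks):
        max_len = int(max_track_s * fps)
        min_len = max(2, int(min_track_s * fps))
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, max(1, n_frames - length)))
        frames = np.arange(start, start + length)
        x = x_ref[frames] + rng.uniform(0.0, 50.0)
        y = np.full(length, rng.uniform(-10.0, 10.0))
        if jitter_um > 0:
            x = x + rng.normal(0.0, jitter_um, length)
            y = y + rng.normal(0.0, jitter_um, length)
        tracks.append(CellTrack(f"track{i:02d}", frames, x, y))
    truth = {"mean_um_s": float(v.mean()), "peak_um_s": float(v.max())}
    return CellTrackTable(tracks), truth


# ---------------------------------------------------------------------------
# CSV writers (so simulated data round-trips through the io readers)
# ---------------------------------------------------------------------------

def trajectories_to_csv(trajectories: list[Trajectory], path) -> None:
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame({"subject_id": tr.subject_id, "frame": tr.frames, "x": tr.x, "y": tr.y})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def chambers_to_csv(traces: list[ChamberTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "chamber": tr.chamber,
                    "frame": tr.frames,
                    "long_axis_um": tr.long_axis,
                    "short_axis_um": tr.short_axis,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def o2_to_csv(traces: list[O2Trace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": tr.well_id,
                    "is_blank": tr.is_blank,
                    "time_s": tr.times,
                    "o2_ppm": tr.o2,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def tracks_to_csv(table: CellTrackTable, path) -> None:
    frames = []
    for tr in table:
        frames.append(
            pd.DataFrame({"track_id": tr.track_id, "frame": tr.frames, "x": tr.x, "y": tr.y})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
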