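"""Cardiac performance and rhythm endpoints from chamber axis traces.

Beats are detected as local minima of the (lightly smoothed) short-axis
signal — peak contraction, the sharpest landmark in these traces — with
sub-frame timing by parabolic interpolation.  Chamber volumes use a prolate
spheroid model, V = (π/6)·L·W² with both minor axes equal to the short-axis
diameter W, reported in picolitres (1 pL = 1000 µm³).

Performance endpoints: heart rate, end-diastolic and end-systolic volume,
stroke volume SV = EDV − ESV, cardiac output CO = SV × HR, ejection fraction
EF = 100·SV/EDV, and shortening fraction SF = 100·(D_d − D_s)/D_d of the
ventricular short-axis diameter.

Rhythm endpoints: Poincaré SD1/SD2 of the inter-beat-interval sequence
(population variance, so SD1² + SD2² = Var(xᵢ) + Var(xᵢ₊₁) exactly) and the
atrium→ventricle / ventricle→atrium beat delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .config import AcquisitionConfig
from .datatypes import ChamberTrace
from .errors import DataQualityError, InsufficientDataError, PairingError, ValidationError

PL_PER_UM3 = 1e-3  # 1 pL = 1000 µm³


@dataclass
class BeatSeries:
    """Detected beat times (s, peak contraction) and inter-beat intervals (ms)."""

    chamber: str
    beat_times: np.ndarray
    ibis: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValidationError("beat times must be strictly increasing")
        self.ibis = np.diff(self.beat_times) * 1000.0

    def __len__(self) -> int:
        return len(self.beat_times)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(x)]
    return out


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample offset of the extremum at index i from a 3-point parabola."""
    if i == 0 or i == len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -0.5, 0.5))


def detect_beats(
    trace: ChamberTrace,
    config: AcquisitionConfig,
    min_rate: float = 60.0,
    max_rate: float = 360.0,
    smooth_window: int = 5,
) -> BeatSeries:
    """Detect contraction events on a chamber trace.

    Local minima of the smoothed short-axis signal with minimum separation
    ``60 / max_rate`` seconds and prominence at least 20% of the signal's
    peak-to-trough amplitude.  Beat times are refined to sub-frame precision
    by parabolic interpolation around each extremum.
    """
    fs = config.frame_rate
    duration = (trace.frames[-1] - trace.frames[0]) / fs if len(trace) else 0.0
    if duration < 2 * 60.0 / min_rate:
        raise InsufficientDataError(
            f"trace {trace.subject_id!r} spans {duration:.2f} s; need at least two "
            f"expected beats at {min_rate} bpm"
        )
    smoothed = _moving_average(trace.short_axis, smooth_window)
    amplitude = float(smoothed.max() - smoothed.min())
    if amplitude <= 0:
        raise InsufficientDataError(f"flat short-axis trace for {trace.subject_id!r}")
    inverted = -smoothed
    distance = max(1, int(round(60.0 / max_rate * fs)))
    peaks, _ = find_peaks(inverted, distance=distance, prominence=0.2 * amplitude)
    if len(peaks) < 2:
        raise InsufficientDataError(
            f"only {len(peaks)} beat(s) detected for {trace.subject_id!r}; need >= 2"
        )
    offsets = np.array([_parabolic_refine(inverted, i) for i in peaks])
    times = (trace.frames[peaks] + offsets) / fs
    return BeatSeries(chamber=trace.chamber, beat_times=times)


def heart_rate(beats: BeatSeries) -> float:
    """Beats per minute: (n − 1) intervals over the first-to-last beat span."""
    if len(beats) < 2:
        raise InsufficientDataError("heart rate needs >= 2 beats")
    span = beats.beat_times[-1] - beats.beat_times[0]
    return (len(beats) - 1) / span * 60.0


def ellipsoid_volume(long_axis, short_axis):
    """Chamber volume in pL under the prolate-spheroid model.

    V = (π/6)·L·W² µm³ with both short semi-axes W/2; 1 pL = 1000 µm³.
    Accepts scalars or arrays.
    """
    L = np.asarray(long_axis, dtype=float)
    W = np.asarray(short_axis, dtype=float)
    if np.any(L <= 0) or np.any(W <= 0):
        raise ValidationError("axis lengths must be positive")
    if np.any(L < W):
        raise ValidationError("long axis must be >= short axis")
    v = np.pi / 6.0 * L * W**2 * PL_PER_UM3
    return float(v) if v.ndim == 0 else v


@dataclass
class CardiacEndpoints:
    """Volumetric performance of one ventricle recording."""

    hr: float            # beats/min (ventricular)
    edv: float           # pL
    esv: float           # pL
    sv: float            # pL/beat
    co: float            # pL/min
    ef: float            # %
    sf: float            # %


def volumetric_endpoints(
    trace: ChamberTrace, beats: BeatSeries, config: AcquisitionConfig
) -> CardiacEndpoints:
    """EDV/ESV/SV/CO/EF/SF from a ventricular trace and its beat series.

    Per cycle, end-diastole is the frame of maximal short axis between
    successive contraction events, and end-systole the frame of minimal short
    axis between successive diastoles; volumes at those frames are averaged
    over cycles (robust to slow drift).
    """
    if len(beats) < 3:
        raise InsufficientDataError("volumetric endpoints need >= 2 complete cycles (3 beats)")
    frame_t = trace.frames.astype(float)
    beat_f = beats.beat_times * config.frame_rate
    dia_frames = []
    for a, b in zip(beat_f[:-1], beat_f[1:]):
        sel = (frame_t > a) & (frame_t < b)
        if not sel.any():
            continue
        idx = np.flatnonzero(sel)
        dia_frames.append(idx[np.argmax(trace.short_axis[idx])])
    if len(dia_frames) < 2:
        raise InsufficientDataError("could not locate >= 2 end-diastolic frames")
    sys_frames = []
    for a, b in zip(dia_frames[:-1], dia_frames[1:]):
        idx = np.arange(a + 1, b)
        if idx.size == 0:
            continue
        sys_frames.append(idx[np.argmin(trace.short_axis[idx])])
    if not sys_frames:
        raise InsufficientDataError("could not locate end-systolic frames")
    dia_frames = np.array(dia_frames)
    sys_frames = np.array(sys_frames)
    edv = float(np.mean(ellipsoid_volume(trace.long_axis[dia_frames], trace.short_axis[dia_frames])))
    esv = float(np.mean(ellipsoid_volume(trace.long_axis[sys_frames], trace.short_axis[sys_frames])))
    if esv > edv:
        raise DataQualityError(
            f"ESV ({esv:.2f} pL) > EDV ({edv:.2f} pL); beats were likely mis-detected"
        )
    hr = heart_rate(beats)
    sv = edv - esv
    dd = float(np.mean(trace.short_axis[dia_frames]))
    ds = float(np.mean(trace.short_axis[sys_frames]))
    return CardiacEndpoints(
        hr=hr,
        edv=edv,
        esv=esv,
        sv=sv,
        co=sv * hr,
        ef=100.0 * sv / edv,
        sf=100.0 * (dd - ds) / dd,
    )


def poincare_sd(ibis) -> tuple[float, float]:
    """Poincaré SD1/SD2 (ms) of an inter-beat-interval sequence.

    Over lag-1 pairs (xᵢ, xᵢ₊₁): SD1 = sqrt(Var(xᵢ₊₁ − xᵢ)/2) measures
    short-term variability perpendicular to the identity line, SD2 =
    sqrt(Var(xᵢ₊₁ + xᵢ)/2) long-term variability along it.  Population
    variance, making SD1² + SD2² = Var(xᵢ) + Var(xᵢ₊₁) exact.
    """
    x = np.asarray(ibis, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("Poincaré SDs need >= 3 intervals")
    a, b = x[:-1], x[1:]
    sd1 = float(np.sqrt(np.var(b - a) / 2.0))
    sd2 = float(np.sqrt(np.var(b + a) / 2.0))
    return sd1, sd2


@dataclass
class RhythmEndpoints:
    """Rhythm summary for one subject."""

    sd1_atrium: float
    sd2_atrium: float
    sd1_ventricle: float
    sd2_ventricle: float
    av_interval: float  # ms
    va_interval: float  # ms


def av_intervals(atrium: BeatSeries, ventricle: BeatSeries) -> tuple[float, float]:
    """Mean atrium→ventricle and ventricle→atrium beat delays (ms).

    Each atrial beat aⱼ pairs with the first ventricular beat v in
    (aⱼ, aⱼ₊₁); A–V = mean(v − aⱼ), V–A = mean(aⱼ₊₁ − v).  Atrial cycles
    with no ventricular beat are skipped; unpaired beats at the ends drop.
    """
    if len(atrium) < 2 or len(ventricle) < 2:
        raise InsufficientDataError("A–V intervals need >= 2 beats in each chamber")
    av, va = [], []
    vt = ventricle.beat_times
    for a0, a1 in zip(atrium.beat_times[:-1], atrium.beat_times[1:]):
        inside = vt[(vt > a0) & (vt < a1)]
        if inside.size == 0:
            continue
        v = inside[0]
        av.append(v - a0)
        va.append(a1 - v)
    if not av:
        raise PairingError(
            "no atrial cycle contains a ventricular beat; chambers are desynchronized "
            "or beats were mis-detected"
        )
    return float(np.mean(av) * 1000.0), float(np.mean(va) * 1000.0)


def cardiac_report(
    traces: list[ChamberTrace],
    config: AcquisitionConfig,
    groups: dict[str, str] | None = None,
) -> "pd.DataFrame":
    """Endpoint table of cardiac performance, one subject per ventricle trace."""
    import pandas as pd  # noqa: F401  (type only)

    from .datatypes import make_endpoint_table

    groups = groups or {}
    rows = []
    for trace in traces:
        if trace.chamber != "ventricle":
            continue
        beats = detect_beats(trace, config)
        ep = volumetric_endpoints(trace, beats, config)
        g = groups.get(trace.subject_id, "")
        for name, value, units in (
            ("hr_ventricle", ep.hr, "bpm"),
            ("edv", ep.edv, "pL"),
            ("esv", ep.esv, "pL"),
            ("sv", ep.sv, "pL/beat"),
            ("co", ep.co, "pL/min"),
            ("ef", ep.ef, "%"),
            ("sf", ep.sf, "%"),
        ):
            rows.append((trace.subject_id, g, name, float(value), units))
    return make_endpoint_table(rows)


def rhythm_report(
    traces: list[ChamberTrace],
    config: AcquisitionConfig,
    groups: dict[str, str] | None = None,
) -> "pd.DataFrame":
    """Endpoint table of rhythm endpoints for subjects with both chambers."""
    from .datatypes import make_endpoint_table

    groups = groups or {}
    by_subject: dict[str, dict[str, ChamberTrace]] = {}
    for trace in traces:
        by_subject.setdefault(trace.subject_id, {})[trace.chamber] = trace
    rows = []
    for sid, chambers in sorted(by_subject.items()):
        if "atrium" not in chambers or "ventricle" not in chambers:
            continue
        a = detect_beats(chambers["atrium"], config)
        v = detect_beats(chambers["ventricle"], config)
        ep = rhythm_endpoints(a, v)
        g = groups.get(sid, "")
        for name, value in (
            ("hr_atrium", heart_rate(a)),
            ("sd1_atrium", ep.sd1_atrium),
            ("sd2_atrium", ep.sd2_atrium),
            ("sd1_ventricle", ep.sd1_ventricle),
            ("sd2_ventricle", ep.sd2_ventricle),
            ("av_interval", ep.av_interval),
            ("va_interval", ep.va_interval),
        ):
            units = "bpm" if name == "hr_atrium" else "ms"
            rows.append((sid, g, name, float(value), units))
    return make_endpoint_table(rows)


def rhythm_endpoints(atrium: BeatSeries, ventricle: BeatSeries) -> RhythmEndpoints:
    """SD1/SD2 per chamber plus A–V and V–A intervals."""
    sd1a, sd2a = poincare_sd(atrium.ibis)
    sd1v, sd2v = poincare_sd(ventricle.ibis)
    av, va = av_intervals(atrium, ventricle)
    return RhythmEndpoints(
        sd1_atrium=sd1a,
        sd2_atrium=sd2a,
        sd1_ventricle=sd1v,
        sd2_ventricle=sd2v,
        av_interval=av,
        va_interval=va,
    )
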