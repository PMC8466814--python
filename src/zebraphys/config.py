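"""Acquisition configuration and light/dark phase scheduling.

Time convention: frame ``i`` occurs at ``t = i / frame_rate`` with frame 0 at
``t = 0``.  Phase intervals are half-open ``[start, end)`` so a frame falling
exactly on a boundary belongs to the later phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

PHASE_LABELS = ("light", "dark")
UNSCHEDULED = "unscheduled"


def alternating_schedule(
    n_phases: int, phase_duration_s: float, first: str = "light"
) -> list[tuple[str, float]]:
    """Build an alternating light/dark schedule, e.g. the 80-min photomotor
    protocol of eight 10-min phases.

    Parameters
    ----------
    n_phases
        Number of phases.
    phase_duration_s
        Duration of each phase in seconds.
    first
        Label of the first phase, ``"light"`` or ``"dark"``.
    """
    if first not in PHASE_LABELS:
        raise ConfigurationError(f"first phase must be one of {PHASE_LABELS}, got {first!r}")
    if n_phases < 1 or phase_duration_s <= 0:
        raise ConfigurationError("schedule needs n_phases >= 1 and a positive duration")
    other = "dark" if first == "light" else "light"
    return [(first if i % 2 == 0 else other, float(phase_duration_s)) for i in range(n_phases)]


@dataclass
class AcquisitionConfig:
    """Recording metadata shared by all pipeline stages.

    Attributes
    ----------
    frame_rate : float
        Frames per second of the recording (> 0).
    mm_per_pixel : float or None
        Pixel scale for trajectory data, mm per pixel.  Required to convert
        pixel-space positions and the pixel-based burst threshold.
    um_per_pixel : float or None
        Pixel scale for cardiac/flow imaging, micrometres per pixel.
    phase_schedule : list of (label, duration_s)
        Ordered light/dark phases.  May be empty for assays without phases.
    recording_duration : float or None
        Total recording span in seconds, if known.
    """

    frame_rate: float
    mm_per_pixel: float | None = None
    um_per_pixel: float | None = None
    phase_schedule: list[tuple[str, float]] = field(default_factory=list)
    recording_duration: float | None = None

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ConfigurationError(f"frame_rate must be > 0, got {self.frame_rate}")
        for name in ("mm_per_pixel", "um_per_pixel"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ConfigurationError(f"{name} must be > 0, got {v}")
        for label, dur in self.phase_schedule:
            if label not in PHASE_LABELS:
                raise ConfigurationError(f"phase label must be one of {PHASE_LABELS}, got {label!r}")
            if not dur > 0:
                raise ConfigurationError(f"phase duration must be > 0, got {dur}")
        if self.recording_duration is not None:
            total = sum(d for _, d in self.phase_schedule)
            if total > self.recording_duration + 1.0 / self.frame_rate:
                raise ConfigurationError(
                    f"phase schedule ({total} s) exceeds recording_duration "
                    f"({self.recording_duration} s) by more than one frame"
                )

    # -- time helpers ------------------------------------------------------
    def frame_times(self, frames) -> np.ndarray:
        """Time in seconds of each frame index."""
        return np.asarray(frames, dtype=float) / self.frame_rate

    def phase_boundaries(self) -> np.ndarray:
        """Cumulative phase edges in seconds, length ``n_phases + 1``."""
        durs = [d for _, d in self.phase_schedule]
        return np.concatenate([[0.0], np.cumsum(durs)])

    @classmethod
    def from_file(cls, path) -> "AcquisitionConfig":
        """Read a plain-text ``key = value`` configuration file.

        Recognised keys: ``frame_rate``, ``mm_per_pixel``, ``um_per_pixel``,
        ``recording_duration``, and either ``phases`` (comma-separated
        ``label:seconds`` entries) or the triple ``n_phases`` /
        ``phase_duration`` / ``first_phase`` for an alternating schedule.
        Lines starting with ``#`` are comments.
        """
        keys: dict[str, str] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"cannot parse config line: {raw.rstrip()!r}")
                k, v = line.split("=", 1)
                keys[k.strip()] = v.strip()
        if "frame_rate" not in keys:
            raise ConfigurationError("config file must set frame_rate")
        schedule: list[tuple[str, float]] = []
        if "phases" in keys:
            for item in keys["phases"].split(","):
                label, _, dur = item.strip().partition(":")
                if not dur:
                    raise ConfigurationError(f"bad phase entry {item!r}; expected label:seconds")
                schedule.append((label.strip(), float(dur)))
        elif "n_phases" in keys:
            schedule = alternating_schedule(
                int(keys["n_phases"]),
                float(keys.get("phase_duration", 600.0)),
                keys.get("first_phase", "light"),
            )
        return cls(
            frame_rate=float(keys["frame_rate"]),
            mm_per_pixel=float(keys["mm_per_pixel"]) if "mm_per_pixel" in keys else None,
            um_per_pixel=float(keys["um_per_pixel"]) if "um_per_pixel" in keys else None,
            phase_schedule=schedule,
            recording_duration=(
                float(keys["recording_duration"]) if "recording_duration" in keys else None
            ),
        )


def phase_index(frames, config: AcquisitionConfig) -> np.ndarray:
    """Index of the scheduled phase containing each frame, -1 if unscheduled.

    Phases are half-open ``[start, end)`` in time; frame times follow the
    ``t = frame / frame_rate`` convention.
    """
    if not config.phase_schedule:
        raise ConfigurationError("phase schedule is empty")
    t = config.frame_times(frames)
    edges = config.phase_boundaries()
    idx = np.searchsorted(edges, t, side="right") - 1
    idx[(t < 0) | (t >= edges[-1])] = -1
    return idx


def assign_phases(frames, config: AcquisitionConfig) -> np.ndarray:
    """Phase label per frame; frames beyond the schedule get ``"unscheduled"``."""
    idx = phase_index(frames, config)
    labels = np.array([lab for lab, _ in config.phase_schedule] + [UNSCHEDULED], dtype=object)
    return labels[idx]
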