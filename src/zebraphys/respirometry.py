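"""Blank-corrected oxygen-consumption endpoints from sensor-dish O₂ traces.

One well per plate holds water only (the blank); its drift — sensor
temperature response, surface gas exchange — is common to all wells and is
subtracted before quantifying consumption.  Two readouts are reported per
fish well: the O₂ drop over the analysis window (delta, ppm) and the
least-squares decline rate (slope, ppm/min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import O2Trace, make_endpoint_table
from .errors import AlignmentError, ConfigurationError, InsufficientDataError, ValidationError


@dataclass
class RespirationEndpoints:
    """O₂ consumption of one well over one analysis window."""

    delta_o2: float   # ppm consumed over the window
    slope: float      # ppm/min, least-squares decline rate
    window: tuple[float, float]


def o2_consumption(
    trace: O2Trace, blank: O2Trace, window: tuple[float, float] | None = None
) -> RespirationEndpoints:
    """Blank-corrected consumption of one fish well.

    The blank's excursion from its initial value is subtracted from the fish
    trace after aligning both onto the union of their sample times within the
    window (linear interpolation, no extrapolation):

        corrected(t) = o2_fish(t) − (o2_blank(t) − o2_blank(t₀))

    delta_o2 = corrected(t₀) − corrected(t_end); slope is the negated
    least-squares slope of the corrected series, in ppm/min, so both are
    positive for a consuming animal.
    """
    if not blank.is_blank:
        raise ValidationError(f"well {blank.well_id!r} is not flagged as a blank")
    lo = max(trace.times[0], blank.times[0])
    hi = min(trace.times[-1], blank.times[-1])
    if hi <= lo:
        raise AlignmentError(
            f"wells {trace.well_id!r} and {blank.well_id!r} have non-overlapping time ranges"
        )
    if window is None:
        window = (lo, hi)
    w0, w1 = max(window[0], lo), min(window[1], hi)
    if w1 <= w0:
        raise AlignmentError(f"window {window} does not overlap the common range ({lo}, {hi})")
    grid = np.union1d(trace.times, blank.times)
    grid = grid[(grid >= w0) & (grid <= w1)]
    if grid.size < 5:
        raise InsufficientDataError(f"only {grid.size} samples in window; need >= 5")
    fish = np.interp(grid, trace.times, trace.o2)
    bl = np.interp(grid, blank.times, blank.o2)
    corrected = fish - (bl - bl[0])
    delta = float(corrected[0] - corrected[-1])
    slope_per_s = np.polyfit(grid, corrected, 1)[0]
    return RespirationEndpoints(
        delta_o2=delta, slope=float(-slope_per_s * 60.0), window=(float(w0), float(w1))
    )


def plate_report(
    traces: list[O2Trace],
    window: tuple[float, float] | None = None,
    groups: dict[str, str] | None = None,
):
    """Endpoint table for a plate: one row pair (delta, slope) per fish well.

    Exactly one trace must be flagged as the blank; it is used for correction
    and excluded from the output.
    """
    groups = groups or {}
    blanks = [t for t in traces if t.is_blank]
    if len(blanks) != 1:
        raise ConfigurationError(f"expected exactly one blank well, found {len(blanks)}")
    blank = blanks[0]
    rows = []
    for t in traces:
        if t.is_blank:
            continue
        res = o2_consumption(t, blank, window)
        group = groups.get(t.well_id, "")
        rows.append((t.well_id, group, "o2_delta", res.delta_o2, "ppm"))
        rows.append((t.well_id, group, "o2_slope", res.slope, "ppm/min"))
    return make_endpoint_table(rows)
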