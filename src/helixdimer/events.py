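"""Pivot and handedness-flip detection on crossing-angle time series.

A pivoting motion is a large transient swing of the crossing angle Omega —
the dimer tilts open and (usually) returns — during which one helix is free
to rotate about its own axis. A handedness interconversion is a sign change
of Omega, i.e. the packing switching between a left-handed and a
right-handed overlay.

Detection runs on a lightly smoothed copy of the series (centered moving
average); reported angles are taken from the raw series. Pivots are found
by turning-point (zigzag) analysis: reversals smaller than a hysteresis
band (25% of the threshold) are ignored, and any remaining swing between
successive turning points whose magnitude reaches the threshold marks an
event. Overlapping or nearly adjacent events are merged, so a down-and-back
excursion such as -6.4 -> -51 -> +4.6 degrees is reported as a single
pivot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rotation import RotationSeries

DEFAULT_PIVOT_THRESHOLD_DEG = 45.0
#: Alternative preset for the pivot threshold (lower bound quoted for
#: meaningful helix rotation).
ALT_PIVOT_THRESHOLD_DEG = 40.0
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_DEAD_BAND_DEG = 5.0
#: Rotation change (degrees) above which a helix counts as rotating during
#: an event.
ROTATION_ATTRIBUTION_DEG = 50.0


@dataclass
class EventRecord:
    """One detected pivot or handedness flip.

    Times index the trajectory's own time base; omega values are raw
    (unsmoothed). ``excursion`` is the maximum |Omega - Omega(start)| over
    the event window. Rotation attribution fields are filled in by
    :func:`associate_rotations`.
    """

    kind: str  # "pivot" | "handedness_flip"
    start_time: float
    peak_time: float
    end_time: float
    omega_start: float
    omega_peak: float
    omega_end: float
    excursion: float
    dtheta_A: float | None = None
    dtheta_B: float | None = None
    label: str | None = None
    extra: dict = field(default_factory=dict)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinking (window forced odd)."""
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    if window % 2 == 0:
        window += 1
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def _turning_points(x: np.ndarray, min_swing: float) -> list[int]:
    """Indices of zigzag turning points, ignoring reversals < min_swing.

    Always includes the first and last index. Between consecutive returned
    indices the series moves monotonically up or down by at least
    ``min_swing`` (except possibly the final leg).
    """
    n = len(x)
    if n < 2:
        return list(range(n))
    pts = [0]
    ext_idx = 0  # index of the running extremum of the current leg
    direction = 0  # +1 rising, -1 falling, 0 undecided
    for i in range(1, n):
        if direction >= 0 and x[i] > x[ext_idx]:
            ext_idx = i
            if direction == 0 and x[ext_idx] - x[pts[-1]] >= min_swing:
                direction = +1
        elif direction <= 0 and x[i] < x[ext_idx]:
            ext_idx = i
            if direction == 0 and x[pts[-1]] - x[ext_idx] >= min_swing:
                direction = -1
        if direction > 0 and x[ext_idx] - x[i] >= min_swing:
            pts.append(ext_idx)
            direction = -1
            ext_idx = i
        elif direction < 0 and x[i] - x[ext_idx] >= min_swing:
            pts.append(ext_idx)
            direction = +1
            ext_idx = i
    if pts[-1] != n - 1:
        if ext_idx not in pts and ext_idx > pts[-1]:
            pts.append(ext_idx)
        if pts[-1] != n - 1:
            pts.append(n - 1)
    return pts


def detect_pivots(
    times,
    omega,
    *,
    threshold: float = DEFAULT_PIVOT_THRESHOLD_DEG,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[EventRecord]:
    """Detect pivoting excursions of the crossing angle.

    An event is any contiguous run of turning-point swings whose magnitude
    reaches ``threshold`` degrees; consecutive qualifying swings (and those
    separated by at most two smoothing windows) merge into one event, whose
    peak is the sample farthest from the starting value.
    """
    if threshold <= 0:
        raise ValueError("pivot threshold must be positive")
    t = np.asarray(times, dtype=float)
    w_raw = np.asarray(omega, dtype=float)
    if len(t) != len(w_raw):
        raise ValueError("times and omega must have equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 samples for pivot detection")
    w = _smooth(w_raw, smooth_window)
    hyst = 0.25 * threshold
    pts = _turning_points(w, hyst)

    # legs between successive turning points; an excursion is a
    # (departure, return) pair of opposite-direction legs around a swing
    # that reaches the threshold
    swings = [w[pts[k + 1]] - w[pts[k]] for k in range(len(pts) - 1)]
    used = [False] * len(swings)
    merged: list[list[int]] = []
    for k, s in enumerate(swings):
        if abs(s) < threshold or used[k]:
            continue
        legs = [k]
        if k > 0 and not used[k - 1] and swings[k - 1] * s < 0:
            legs.insert(0, k - 1)  # approach leg of the same excursion
        elif k + 1 < len(swings) and not used[k + 1] and swings[k + 1] * s < 0:
            legs.append(k + 1)  # return leg of the same excursion
        for j in legs:
            used[j] = True
        merged.append([pts[legs[0]], pts[legs[-1] + 1]])

    events = []
    for lo, hi in merged:
        seg = w_raw[lo : hi + 1]
        peak_off = int(np.argmax(np.abs(seg - w_raw[lo])))
        events.append(
            EventRecord(
                kind="pivot",
                start_time=float(t[lo]),
                peak_time=float(t[lo + peak_off]),
                end_time=float(t[hi]),
                omega_start=float(w_raw[lo]),
                omega_peak=float(w_raw[lo + peak_off]),
                omega_end=float(w_raw[hi]),
                excursion=float(np.max(np.abs(seg - w_raw[lo]))),
            )
        )
    return events


def detect_handedness_flips(
    times,
    omega,
    *,
    dead_band: float = DEFAULT_DEAD_BAND_DEG,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[EventRecord]:
    """Detect sign changes of the crossing angle (packing handedness flips).

    Only sign changes that leave the +/- dead band on both sides count; the
    event time is the linearly interpolated zero crossing of the smoothed
    series. The dead band suppresses chatter around Omega = 0 where the
    handedness is geometrically ill-defined.
    """
    t = np.asarray(times, dtype=float)
    w_raw = np.asarray(omega, dtype=float)
    w = _smooth(w_raw, smooth_window)

    # confirmed-handedness states: +1 / -1 when outside the dead band
    states = np.where(w >= dead_band, 1, np.where(w <= -dead_band, -1, 0))
    events = []
    prev_sign = 0
    prev_idx = 0
    for i, s in enumerate(states):
        if s == 0:
            continue
        if prev_sign != 0 and s != prev_sign:
            # locate the zero crossing of the smoothed series in between
            seg = w[prev_idx : i + 1]
            cross = np.nonzero(np.diff(np.sign(seg)) != 0)[0]
            j = prev_idx + (int(cross[0]) if len(cross) else 0)
            frac = 0.0
            if w[j + 1] != w[j]:
                frac = -w[j] / (w[j + 1] - w[j])
            tc = float(t[j] + frac * (t[j + 1] - t[j]))
            events.append(
                EventRecord(
                    kind="handedness_flip",
                    start_time=float(t[prev_idx]),
                    peak_time=tc,
                    end_time=float(t[i]),
                    omega_start=float(w_raw[prev_idx]),
                    omega_peak=0.0,
                    omega_end=float(w_raw[i]),
                    excursion=float(abs(w_raw[i] - w_raw[prev_idx])),
                    extra={"from_sign": int(prev_sign), "to_sign": int(s)},
                )
            )
        prev_sign = s
        prev_idx = i
    return events


def associate_rotations(
    events: list[EventRecord],
    series: RotationSeries,
    *,
    pad: float = 0.0,
    attribution_threshold: float = ROTATION_ATTRIBUTION_DEG,
) -> list[EventRecord]:
    """Attach per-event helix rotation changes and a rotating-helix label.

    For each event the rotation change is the unwrapped series value at
    (end_time + pad) minus the value at (start_time - pad), with the padded
    window clamped to the series time base. Events whose own span lies
    outside the series are dropped with a warning. Labels: "A-rotating",
    "B-rotating", "both" or "neither", using a 50-degree attribution
    threshold by default.
    """
    import warnings

    t = series.times
    out = []
    for ev in events:
        t_lo = max(ev.start_time - pad, t[0])
        t_hi = min(ev.end_time + pad, t[-1])
        if ev.start_time < t[0] - 1e-9 or ev.end_time > t[-1] + 1e-9:
            warnings.warn(
                f"event window [{t_lo}, {t_hi}] outside rotation series; dropped",
                stacklevel=2,
            )
            continue
        dA = float(np.interp(t_hi, t, series.dtheta_A) - np.interp(t_lo, t, series.dtheta_A))
        dB = float(np.interp(t_hi, t, series.dtheta_B) - np.interp(t_lo, t, series.dtheta_B))
        a_rot = abs(dA) >= attribution_threshold
        b_rot = abs(dB) >= attribution_threshold
        label = (
            "both" if (a_rot and b_rot)
            else "A-rotating" if a_rot
            else "B-rotating" if b_rot
            else "neither"
        )
        ev.dtheta_A, ev.dtheta_B, ev.label = dA, dB, label
        out.append(ev)
    return out
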