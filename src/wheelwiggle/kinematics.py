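"""Wheel-kinematics: direction-change detection and per-trial wiggle metrics.

A *wiggle* is a wheel movement containing one or more directional changes
(velocity sign changes) between visual stimulus onset and feedback.  The
count k is computed from wheel position interpolated on a uniform 1000 Hz
grid, low-pass filtered at 20 Hz (zero-phase Butterworth), differentiated,
and scanned for sign transitions.  Per-trial metrics follow:

* wiggle speed  — total angular distance between successive extrema divided
  by the movement span ``t_k - t_0``; for k = 0 trials, net displacement
  over the movement span.
* wiggle amplitude — mean absolute inter-extremum displacement.
* wiggle duration  — time between the first and last extremum.
* motion energy    — time-averaged squared speed across inter-extremum
  segments; ``speed**2`` for k = 0.

Here ``theta_0, t_0`` refer to motion onset, ``theta_1..theta_k, t_1..t_k``
to the detected directional changes, and ``theta_f, t_f`` to feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "WheelTrace",
    "DirectionalChangeSet",
    "WiggleMetrics",
    "UndefinedMetricError",
    "resample_position",
    "lowpass_velocity",
    "count_direction_changes",
    "classify_wiggle",
    "wiggle_speed",
    "wiggle_amplitude",
    "wiggle_duration",
    "motion_energy",
    "compute_metrics",
]

#: Motion-onset detection: first time after stimulus onset where the filtered
#: speed stays above the stillness threshold for at least ONSET_HOLD_S.
ONSET_SPEED_DEG_S = 2.0
ONSET_HOLD_S = 0.020
#: Zero-phase Butterworth filtering rings at ~1-2% of peak speed around sharp
#: movement onsets; speeds below this fraction of the in-window peak carry no
#: direction information and are treated as stillness.
RINGING_FRACTION = 0.03


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested for a trial where it is undefined
    (e.g. wiggle amplitude of a k = 0 trial)."""


@dataclass
class WheelTrace:
    """Timestamped wheel position for one trial.

    t is in seconds (strictly increasing), pos in wheel degrees; stim_on and
    feedback delimit the analysis window.
    """

    t: np.ndarray
    pos: np.ndarray
    stim_on: float
    feedback: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.t.size < 2:
            raise ValueError("wheel trace needs at least 2 samples")
        if self.t.shape != self.pos.shape:
            raise ValueError("t and pos must have identical shapes")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.stim_on < self.feedback:
            raise ValueError("stim_on must precede feedback")


@dataclass
class DirectionalChangeSet:
    """Times/positions of velocity sign changes plus onset and end anchors."""

    times: np.ndarray
    positions: np.ndarray
    onset: tuple[float, float]  # (t_0, theta_0) at motion onset
    end: tuple[float, float]    # (t_f, theta_f) at feedback

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.size != self.positions.size:
            raise ValueError("times and positions must match in length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("change times must be strictly increasing")

    @property
    def k(self) -> int:
        return int(self.times.size)


@dataclass
class WiggleMetrics:
    k: int
    is_wiggle: bool
    speed: float            # wheel deg/s
    amplitude: float        # wheel deg (NaN for k = 0)
    duration: float         # s (0 for k <= 1)
    motion_energy: float    # wheel deg^2/s^2


def resample_position(trace: WheelTrace, rate: float = 1000.0) -> WheelTrace:
    """Linearly interpolate a trace onto a uniform grid at ``rate`` Hz.

    The grid starts exactly at the first input timestamp; the last grid point
    is the largest multiple of the sample period not exceeding the final
    timestamp (exactly the final timestamp whenever the span is a multiple of
    the period).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t0, t_end = trace.t[0], trace.t[-1]
    n = int(np.floor((t_end - t0) * rate + 1e-9))
    grid = t0 + np.arange(n + 1) / rate
    pos = np.interp(grid, trace.t, trace.pos)
    return WheelTrace(grid, pos, trace.stim_on, trace.feedback)


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace must be uniformly sampled; use resample_position first")
    return float(dt[0])


def lowpass_velocity(
    trace: WheelTrace,
    cutoff: float = 20.0,
    order: int = 3,
    return_position: bool = False,
):
    """Zero-phase Butterworth low-pass of position followed by a central-
    difference derivative; returns velocity in deg/s (same length as input).

    Sampling must be uniform and at least twice the cutoff (Nyquist).
    """
    dt = _check_uniform(trace.t)
    fs = 1.0 / dt
    if fs < 2.0 * cutoff:
        raise ValueError(f"sampling rate {fs:.1f} Hz below Nyquist for {cutoff} Hz cutoff")
    b, a = signal.butter(order, cutoff, fs=fs)
    pos_f = signal.filtfilt(b, a, trace.pos)
    vel = np.gradient(pos_f, dt)
    if return_position:
        return vel, pos_f
    return vel


def _carry_signs(v: np.ndarray, still_speed: float | None = None) -> np.ndarray:
    """Sign of v with zero-valued runs carrying the preceding sign; a leading
    zero run takes the sign of the first nonzero sample.

    "Zero-valued" means |v| <= still_speed (deg/s): filtered velocities are
    never exactly zero in floating point, and the zero-phase filter rings at
    a small fraction of peak speed around movement onset, so speeds below the
    stillness threshold carry no direction information.  By default the
    threshold is max(ONSET_SPEED_DEG_S, RINGING_FRACTION * peak |v|).
    """
    if still_speed is None:
        still_speed = max(ONSET_SPEED_DEG_S, RINGING_FRACTION * np.max(np.abs(v)))
    s = np.where(np.abs(v) > still_speed, np.sign(v), 0.0).astype(int)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return s  # identically zero: no transitions possible
    s[: nz[0]] = s[nz[0]]
    # forward-fill zeros with previous sign
    idx = np.where(s != 0, np.arange(s.size), 0)
    np.maximum.accumulate(idx, out=idx)
    return s[idx]


def _motion_onset(
    t: np.ndarray, vel: np.ndarray, stim_on: float, dt: float,
    still_speed: float = ONSET_SPEED_DEG_S,
) -> int:
    """Index of motion onset: first sample >= stim_on where |v| stays above
    the stillness threshold for ONSET_HOLD_S; falls back to the first sample
    >= stim_on if the wheel never clearly moves."""
    start = int(np.searchsorted(t, stim_on, side="left"))
    hold = max(1, int(round(ONSET_HOLD_S / dt)))
    above = np.abs(vel[start:]) > still_speed
    if above.size >= hold:
        # running AND over a window of length `hold`
        csum = np.concatenate(([0], np.cumsum(above)))
        runs = csum[hold:] - csum[:-hold]
        hits = np.flatnonzero(runs == hold)
        if hits.size:
            return start + int(hits[0])
    return start


def count_direction_changes(
    trace: WheelTrace,
    velocity: np.ndarray,
    position_filtered: np.ndarray | None = None,
    still_speed: float | None = None,
) -> tuple[int, DirectionalChangeSet]:
    """Count strict velocity sign transitions within [stim_on, feedback].

    Zero-valued velocity runs carry the preceding sign, so plateaus are not
    double-counted.  Each change time is the first sample of the new sign;
    the change position is read from the filtered position at that sample.
    """
    t = trace.t
    pos = trace.pos if position_filtered is None else position_filtered
    mask = (t >= trace.stim_on) & (t <= trace.feedback)
    if not mask.any():
        raise ValueError("empty analysis window")
    dt = _check_uniform(t)
    idx = np.flatnonzero(mask)
    if still_speed is None:
        still_speed = max(ONSET_SPEED_DEG_S,
                          RINGING_FRACTION * np.max(np.abs(velocity[idx])))
    s = _carry_signs(velocity[idx], still_speed)
    trans = np.flatnonzero(s[1:] != s[:-1]) + 1  # first sample of the new sign
    change_idx = idx[trans]

    onset_i = _motion_onset(t, velocity, trace.stim_on, dt, still_speed)
    end_i = idx[-1]
    changes = DirectionalChangeSet(
        times=t[change_idx],
        positions=pos[change_idx],
        onset=(float(t[onset_i]), float(pos[onset_i])),
        end=(float(t[end_i]), float(pos[end_i])),
    )
    return changes.k, changes


def classify_wiggle(k: int) -> bool:
    """A trial is a wiggle iff it has at least one directional change."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return k != 0


def _anchored(changes: DirectionalChangeSet) -> tuple[np.ndarray, np.ndarray]:
    """Positions/times of onset followed by the directional changes.

    Changes at or before the onset time (possible on false starts, where
    movement is under way when the analysis window opens) are dropped so
    every inter-extremum segment has positive duration.
    """
    keep = changes.times > changes.onset[0] + 1e-12
    th = np.concatenate(([changes.onset[1]], changes.positions[keep]))
    tt = np.concatenate(([changes.onset[0]], changes.times[keep]))
    return th, tt


def wiggle_speed(changes: DirectionalChangeSet) -> float:
    """Total angular distance across inter-extremum segments over the span
    ``t_k - t_0``; net displacement rate for k = 0 trials."""
    t0, th0 = changes.onset
    tf, thf = changes.end
    th, tt = _anchored(changes)
    if changes.k == 0 or tt.size < 2:
        span = tf - t0
        if span <= 0:
            raise ValueError("zero time span")
        return abs(thf - th0) / span
    span = tt[-1] - tt[0]
    if span <= 0:
        raise ValueError("zero time span")
    return float(np.sum(np.abs(np.diff(th))) / span)


def wiggle_amplitude(changes: DirectionalChangeSet) -> float:
    """Mean absolute displacement between successive extrema (k >= 1)."""
    if changes.k < 1:
        raise UndefinedMetricError("amplitude undefined for k = 0 trials")
    th, _ = _anchored(changes)
    if th.size < 2:
        raise UndefinedMetricError("no directional changes after motion onset")
    return float(np.mean(np.abs(np.diff(th))))


def wiggle_duration(changes: DirectionalChangeSet) -> float:
    """Time between the first and last extremum; 0 for a single extremum."""
    if changes.k < 1:
        raise UndefinedMetricError("duration undefined for k = 0 trials")
    if changes.k == 1:
        return 0.0
    return float(changes.times[-1] - changes.times[0])


def motion_energy(changes: DirectionalChangeSet) -> float:
    """Time-averaged squared speed across inter-extremum segments; for k = 0,
    the squared net speed."""
    t0, th0 = changes.onset
    tf, thf = changes.end
    th, tt = _anchored(changes)
    if changes.k == 0 or tt.size < 2:
        span = tf - t0
        if span <= 0:
            raise ValueError("zero time span")
        return ((thf - th0) / span) ** 2
    dth = np.abs(np.diff(th))
    dtt = np.diff(tt)
    if np.any(dtt <= 0):
        raise ValueError("coincident directional-change times")
    span = tt[-1] - tt[0]
    return float(np.sum(dth**2 / dtt) / span)


def compute_metrics(
    trace: WheelTrace,
    rate: float = 1000.0,
    cutoff: float = 20.0,
    order: int = 3,
) -> WiggleMetrics:
    """Full per-trial pipeline: resample -> filter/velocity -> count -> metrics.

    For k = 0 trials the amplitude is NaN (undefined) and the duration 0.
    """
    uniform = resample_position(trace, rate=rate)
    vel, pos_f = lowpass_velocity(uniform, cutoff=cutoff, order=order, return_position=True)
    k, changes = count_direction_changes(uniform, vel, pos_f)
    speed = wiggle_speed(changes)
    energy = motion_energy(changes)
    if k == 0:
        amp, dur = float("nan"), 0.0
    else:
        try:
            amp = wiggle_amplitude(changes)
        except UndefinedMetricError:  # all changes precede motion onset
            amp = float("nan")
        dur = wiggle_duration(changes)
    return WiggleMetrics(
        k=k,
        is_wiggle=classify_wiggle(k),
        speed=speed,
        amplitude=amp,
        duration=dur,
        motion_energy=energy,
    )
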