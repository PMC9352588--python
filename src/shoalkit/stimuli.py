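"""Parametric virtual-conspecific visual stimuli and their kinematics.

Virtual conspecifics are small black dots projected beneath a fish.  The
behaviourally critical manipulation is *how* the dot advances along its
path: either continuously (one small step per display frame) or in
discrete, fish-like swim "bouts" (one large jump every 1/f seconds at
bout frequency f).  Both modes share the same time-averaged speed, so
the only difference is the local acceleration structure of the motion.

This module generates those trajectories (circular, trefoil and
naturalistic-smoothed paths, Gaussian-profile bouts, looming discs) and
provides the linear <-> angular unit conversions used to describe them:
angular size uses the exact subtended-angle formula, while angular
speed/acceleration use the arc-length (small-angle) conversion at the
path radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "PositionSeries",
    "angular_size",
    "angular_speed",
    "angular_acceleration",
    "bout_update_interval_ms",
    "bout_jump_acceleration",
    "make_circular_dot_series",
    "revolution_time_s",
    "gaussian_bout_profile",
    "make_trefoil_series",
    "smooth_trajectory",
    "make_looming_series",
]

_KINDS = ("circular_dot", "trefoil_dot", "naturalistic_dot", "looming", "grating", "wholefield")
_PROFILES = ("instant_jump", "gaussian", "continuous")

# int_{-3}^{3} (e^{-u^2/2} - e^{-9/2}) du: mass of the pedestal-subtracted,
# 3-sigma-truncated Gaussian pulse shape
_PULSE_MASS = math.sqrt(2 * math.pi) * math.erf(3 / math.sqrt(2)) - 6 * math.exp(-4.5)


@dataclass
class StimulusSpec:
    """Parametric description of one virtual-conspecific or control stimulus.

    ``bout_freq_hz`` equal to ``frame_rate_hz`` (conventionally 60) encodes
    continuous motion, i.e. a position update on every display frame.
    """

    kind: str = "circular_dot"
    dot_diameter_mm: float = 4.0
    avg_speed_mm_s: float = 5.0
    bout_freq_hz: float = 1.5
    profile: str = "instant_jump"
    peak_accel_m_s2: float = 0.0
    radius_mm: float = 18.0
    frame_rate_hz: float = 60.0
    duration_s: float = 22.6
    direction: str = "cw"
    start_phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}; expected one of {_KINDS}")
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; expected one of {_PROFILES}")
        if self.avg_speed_mm_s < 0:
            raise ValueError("avg_speed_mm_s must be >= 0")
        if self.bout_freq_hz <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("bout_freq_hz and frame_rate_hz must be > 0")
        if self.bout_freq_hz > self.frame_rate_hz:
            raise ValueError("bout_freq_hz cannot exceed frame_rate_hz")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.direction not in ("cw", "ccw"):
            raise ValueError("direction must be 'cw' or 'ccw'")

    def to_json_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PositionSeries:
    """Uniformly sampled 2-D stimulus (or animal) trajectory in mm and s."""

    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    heading_rad: Optional[np.ndarray] = None
    arc_mm: Optional[np.ndarray] = field(default=None, repr=False)  # cumulative arc traversed

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if not (len(self.t_s) == len(self.x_mm) == len(self.y_mm)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_s) > 1:
            dt = np.diff(self.t_s)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time grid must be strictly increasing and uniform")
        if not (np.isfinite(self.x_mm).all() and np.isfinite(self.y_mm).all()):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0]) if len(self.t_s) > 1 else math.nan

    def to_dataframe(self) -> pd.DataFrame:
        d = {"t_s": self.t_s, "x_mm": self.x_mm, "y_mm": self.y_mm}
        if self.heading_rad is not None:
            d["heading_rad"] = self.heading_rad
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PositionSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("t_s", "x_mm", "y_mm"):
            if col not in df.columns:
                raise ValueError(f"track file missing required column {col!r}")
        heading = df["heading_rad"].to_numpy() if "heading_rad" in df.columns else None
        return cls(df["t_s"].to_numpy(), df["x_mm"].to_numpy(), df["y_mm"].to_numpy(), heading)


# ---------------------------------------------------------------------------
# unit conversions


def angular_size(diameter_mm: float, viewing_distance_mm: float) -> float:
    """Full visual angle (degrees) subtended by a dot of given diameter.

    Uses the exact formula 2*atan((d/2)/r); e.g. a 4 mm dot viewed at the
    18 mm path radius subtends 12.7 deg.
    """
    if viewing_distance_mm <= 0:
        raise ValueError("viewing distance must be > 0")
    if diameter_mm < 0:
        raise ValueError("diameter must be >= 0")
    return math.degrees(2.0 * math.atan((diameter_mm / 2.0) / viewing_distance_mm))


def angular_speed(linear_speed_mm_s: float, radius_mm: float) -> float:
    """Angular speed (deg/s) of a dot at ``linear_speed_mm_s`` on a circle of ``radius_mm``."""
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    return math.degrees(linear_speed_mm_s / radius_mm)


def angular_acceleration(linear_accel_m_s2: float, radius_mm: float) -> float:
    """Angular acceleration (deg/s^2) equivalent of a linear acceleration in m/s^2."""
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    return math.degrees(linear_accel_m_s2 * 1000.0 / radius_mm)


def bout_update_interval_ms(bout_freq_hz: float) -> int:
    """Display update interval in whole milliseconds for a bout frequency.

    Floor to integer ms, matching a 666 ms interval at 1.5 Hz.
    """
    if bout_freq_hz <= 0:
        raise ValueError("bout frequency must be > 0")
    return int(math.floor(1000.0 / bout_freq_hz))


def bout_jump_acceleration(avg_speed_mm_s: float, bout_freq_hz: float,
                           frame_rate_hz: float = 60.0) -> float:
    """Acceleration (m/s^2) of an instantaneous bout jump.

    Each bout displaces the dot by d = v_avg / f, executed within a single
    display frame of duration 1/frame_rate; the implied acceleration is
    d / dt^2.  At 5 mm/s, 1.5 Hz and 60 fps this gives 12 m/s^2.
    """
    if avg_speed_mm_s <= 0 or bout_freq_hz <= 0:
        raise ValueError("speed and bout frequency must be > 0")
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be > 0")
    d_mm = avg_speed_mm_s / bout_freq_hz
    dt = 1.0 / frame_rate_hz
    return (d_mm / dt**2) / 1000.0


# ---------------------------------------------------------------------------
# trajectory generators


def _arc_progress(spec: StimulusSpec) -> tuple[np.ndarray, np.ndarray]:
    """Time grid and cumulative arc length traversed under the spec's profile."""
    n = int(round(spec.duration_s * spec.frame_rate_hz))
    t = np.arange(n) / spec.frame_rate_hz
    if spec.profile == "continuous" or spec.bout_freq_hz >= spec.frame_rate_hz:
        arc = spec.avg_speed_mm_s * t
    else:
        if spec.duration_s < 1.0 / spec.bout_freq_hz:
            raise ValueError("duration shorter than one bout update interval: empty series")
        # jump k happens at the first frame with t >= k / f
        jumps_done = np.floor(t * spec.bout_freq_hz)
        arc = (spec.avg_speed_mm_s / spec.bout_freq_hz) * jumps_done
    return t, arc


def make_circular_dot_series(spec: StimulusSpec) -> PositionSeries:
    """Dot positions on a circular path (radius ``spec.radius_mm``, fish at centre)."""
    if spec.kind != "circular_dot":
        raise ValueError("spec.kind must be 'circular_dot'")
    t, arc = _arc_progress(spec)
    sign = -1.0 if spec.direction == "cw" else 1.0
    theta = spec.start_phase_rad + sign * arc / spec.radius_mm
    return PositionSeries(
        t_s=t,
        x_mm=spec.radius_mm * np.cos(theta),
        y_mm=spec.radius_mm * np.sin(theta),
        arc_mm=arc,
    )


def revolution_time_s(avg_speed_mm_s: float, radius_mm: float = 18.0) -> float:
    """Time for one full revolution of the circular path: 2*pi*r / v (22.6 s at 5 mm/s, r=18)."""
    if avg_speed_mm_s <= 0:
        raise ValueError("speed must be > 0")
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    return 2.0 * math.pi * radius_mm / avg_speed_mm_s


def gaussian_bout_profile(peak_accel_m_s2: float, avg_speed_mm_s: float = 5.0,
                          bout_freq_hz: float = 1.5, frame_rate_hz: float = 60.0,
                          n_periods: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Speed series (t_s, speed_mm_s) of Gaussian speed pulses, one per bout period.

    The pulse width is set so the maximum slope of the speed profile equals
    ``peak_accel_m_s2``; its amplitude is renormalized so the mean speed over
    each period equals ``avg_speed_mm_s``.  ``peak_accel_m_s2 = 0`` degenerates
    to constant-speed (continuous) motion.  The pulse is truncated at +-3 sigma
    with its pedestal subtracted, keeping the series continuous at the edges.
    """
    if peak_accel_m_s2 < 0:
        raise ValueError("peak acceleration must be >= 0")
    if avg_speed_mm_s <= 0 or bout_freq_hz <= 0 or frame_rate_hz <= 0:
        raise ValueError("speed, bout frequency and frame rate must be > 0")
    period = 1.0 / bout_freq_hz
    dt = 1.0 / frame_rate_hz
    n = int(round(period * frame_rate_hz))
    if n < 1:
        raise ValueError("frame rate too low to sample one bout period")
    t = np.arange(n) * dt
    if peak_accel_m_s2 == 0:
        speed = np.full(n, avg_speed_mm_s)
        t_all = np.arange(n * n_periods) * dt
        return t_all, np.tile(speed, n_periods)

    a_peak = peak_accel_m_s2 * 1000.0  # mm/s^2
    # Zero-floor pulse: max |ds/dt| of an amplitude-A pulse is A*e^{-1/2}/sigma
    # and the mean over the period is A*sigma*k/T, giving the closed form
    # below.  A pulse whose speed returns to zero between bouts cannot have a
    # peak acceleration below the value reached when 3 sigma fills the half
    # period; shallower accelerations are realized as a Gaussian speed ripple
    # around the mean (sigma fixed at T/6, amplitude set by the target
    # slope) -- the two regimes coincide at the threshold.
    a_floor = avg_speed_mm_s * period * math.exp(-0.5) / (_PULSE_MASS * (period / 6.0) ** 2)
    if a_peak >= a_floor:
        sigma = math.sqrt(avg_speed_mm_s * period * math.exp(-0.5) / (_PULSE_MASS * a_peak))
        if sigma < dt:
            warnings.warn(
                "requested peak acceleration is not representable at this frame rate; "
                "pulse width clipped to one frame interval (realized acceleration is lower)",
                RuntimeWarning,
            )
            sigma = dt
        u = (t - period / 2.0) / sigma
        speed = np.where(np.abs(u) <= 3.0, np.exp(-0.5 * u**2) - math.exp(-4.5), 0.0)
        speed = np.clip(speed, 0.0, None)
        speed *= avg_speed_mm_s / speed.mean()  # exact discrete normalization
    else:
        sigma = period / 6.0
        u = (t - period / 2.0) / sigma
        g = np.clip(np.exp(-0.5 * u**2) - math.exp(-4.5), 0.0, None)
        amp = a_peak * sigma * math.exp(0.5)
        speed = avg_speed_mm_s + amp * (g - g.mean())
    t_all = np.arange(n * n_periods) * dt
    return t_all, np.tile(speed, n_periods)


def _trefoil_xy(u: np.ndarray, scale_mm: float) -> tuple[np.ndarray, np.ndarray]:
    # closed three-lobed rose-like curve, max radius == scale_mm
    x = scale_mm * (np.sin(u) + 2.0 * np.sin(2.0 * u)) / 3.0
    y = scale_mm * (np.cos(u) - 2.0 * np.cos(2.0 * u)) / 3.0
    return x, y


def make_trefoil_series(avg_speed_mm_s: float = 5.0, bout_freq_hz: float = 1.5,
                        scale_mm: float = 18.0, duration_s: float = 60.0,
                        frame_rate_hz: float = 30.0,
                        profile: str = "instant_jump") -> PositionSeries:
    """Arc-length-uniform traversal of a closed three-lobed (trefoil) path.

    The path is reparameterized to uniform arc length on a dense grid, then
    sampled per the motion profile; mean speed equals ``avg_speed_mm_s`` by
    construction (exact in arc length).
    """
    if avg_speed_mm_s <= 0 or scale_mm <= 0 or duration_s <= 0:
        raise ValueError("speed, scale and duration must be > 0")
    spec = StimulusSpec(
        kind="trefoil_dot", avg_speed_mm_s=avg_speed_mm_s, bout_freq_hz=bout_freq_hz,
        profile=profile, radius_mm=scale_mm, frame_rate_hz=frame_rate_hz,
        duration_s=duration_s,
    )
    t, arc = _arc_progress(spec)
    dense_u = np.linspace(0.0, 2.0 * math.pi, 20001)
    dx, dy = _trefoil_xy(dense_u, scale_mm)
    seg = np.hypot(np.diff(dx), np.diff(dy))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    u_of_arc = np.interp(np.mod(arc, total), cum, dense_u)
    x, y = _trefoil_xy(u_of_arc, scale_mm)
    return PositionSeries(t_s=t, x_mm=x, y_mm=y, arc_mm=arc)


def smooth_trajectory(track, window_len: int = 20):
    """Smooth a trajectory with a unit-sum Hamming window (valid mode).

    Removes tracking jitter before heading computation for naturalistic
    replay stimuli.  Output length is n - window_len + 1.  Accepts and
    returns a :class:`PositionSeries` (or any object with t_s/x_mm/y_mm).
    """
    n = len(track.t_s)
    if n <= window_len:
        raise ValueError(f"track length {n} must exceed window length {window_len}")
    win = np.hamming(window_len)
    win /= win.sum()
    x = np.convolve(track.x_mm, win, mode="valid")
    y = np.convolve(track.y_mm, win, mode="valid")
    # centred time stamps for the valid region
    lo = (window_len - 1) // 2
    t = np.asarray(track.t_s)[lo:lo + len(x)]
    return PositionSeries(t_s=t, x_mm=x, y_mm=y)


def make_looming_series(start_deg: float = 0.6, end_deg: float = 110.0,
                        expand_ms: float = 83.0, offset_mm: float = 0.0,
                        frame_rate_hz: float = 60.0,
                        hold_ms: float = 0.0) -> pd.DataFrame:
    """Angular-size time series of an expanding (looming) disc.

    Monotone linear ramp from ``start_deg`` to ``end_deg`` over ``expand_ms``
    (83 ms for the imaging variant; 500 ms for the behavioural variant),
    optionally held at the final size for ``hold_ms``.  ``offset_mm`` records
    the lateral position of the disc centre (e.g. +-5 mm from the animal).
    """
    if end_deg < start_deg:
        raise ValueError("end size must be >= start size")
    if expand_ms < 0 or hold_ms < 0:
        raise ValueError("durations must be >= 0")
    total_s = (expand_ms + hold_ms) / 1000.0
    n = max(int(round(total_s * frame_rate_hz)), 1) + 1
    t = np.linspace(0.0, total_s, n)
    if expand_ms == 0 or end_deg == start_deg:
        size = np.full(n, end_deg if expand_ms == 0 else start_deg)
        if end_deg == start_deg:
            size = np.full(n, start_deg)
    else:
        frac = np.clip(t / (expand_ms / 1000.0), 0.0, 1.0)
        size = start_deg + (end_deg - start_deg) * frac
    return pd.DataFrame({"t_s": t, "size_deg": size, "offset_mm": offset_mm})
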