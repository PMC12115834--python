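"""Smoothed 3D attack kinematics from digitized predation videos.

Input is a per-frame table of 3D coordinates (mm) for three labelled
points — predator head, predator tail and prey centroid — digitized from
high-speed video (1000 fps by default).  Each coordinate axis is smoothed
with a zero-phase Butterworth filter followed by a Savitzky–Golay filter,
then differentiated to speed and acceleration.  Angles are computed in a
prey-centered frame: elevation in [-90, 90] degrees and azimuth folded to
[0, 180] degrees by left–right symmetry (the lateral coordinate enters as
an absolute value).  The retinal angular size of the predator head at the
end of the event is theta = 2*atan(r/d), with 2r the head width and d the
Euclidean head-to-prey distance.

Frame ``end_frame`` marks contact (capture) or take-off (escape) and
defines t = 0; times are reported in ms, negative before the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, savgol_filter, sosfiltfilt

__all__ = [
    "LABELS",
    "TrackedTrajectory",
    "SmoothingParams",
    "AttackKinematics",
    "read_digitized_points",
    "smooth_positions",
    "compute_speed_acceleration",
    "detect_attack_window",
    "elevation_azimuth",
    "peak_metrics",
    "angular_size_at_end",
    "align_and_average",
    "analyze_attack",
]

LABELS = ("damselfly_head", "damselfly_tail", "fly_centroid")

#: Gaps longer than this many frames split the event rather than being
#: interpolated.
MAX_INTERP_GAP = 5


@dataclass
class TrackedTrajectory:
    """Time-indexed labelled 3D points for one predation event.

    ``points`` maps each label to an (n, 3) array in mm; missing frames are
    NaN rows, flagged per label in ``gaps`` (never silently zeroed).
    ``end_frame`` is the frame of contact or escape and defines t = 0.
    """

    frame_rate: float
    points: Mapping[str, np.ndarray]
    outcome: str = "capture"
    end_frame: int | None = None
    times: np.ndarray | None = None
    gaps: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        lengths = {k: len(v) for k, v in self.points.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"labelled series have unequal lengths: {lengths}")
        n = next(iter(lengths.values()))
        if n < 5:
            raise ValueError(f"trajectory too short ({n} frames, need >= 5)")
        if self.outcome not in ("capture", "escape"):
            raise ValueError(f"outcome must be 'capture' or 'escape', got {self.outcome!r}")
        if self.end_frame is None:
            self.end_frame = n - 1
        if not 0 <= self.end_frame < n:
            raise ValueError(f"end_frame {self.end_frame} outside [0, {n})")
        if self.times is None:
            self.times = np.arange(n) / self.frame_rate
        if not self.gaps:
            self.gaps = {
                k: np.isnan(np.asarray(v, float)).any(axis=1) for k, v in self.points.items()
            }

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.points.values())))

    def t_ms(self) -> np.ndarray:
        """Per-frame time in ms relative to t = 0 at ``end_frame`` (negative before)."""
        return (np.arange(self.n_frames) - self.end_frame) / self.frame_rate * 1000.0


@dataclass(frozen=True)
class SmoothingParams:
    """Position-smoothing settings: Butterworth then Savitzky–Golay, per axis."""

    butterworth_order: int = 2
    butterworth_cutoff: float = 50.0  # Hz
    savgol_window: int = 11  # frames, odd
    savgol_polyorder: int = 3

    def validate(self, frame_rate: float) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_polyorder:
            raise ValueError(
                "savgol_window must be odd and > savgol_polyorder, got "
                f"window={self.savgol_window}, polyorder={self.savgol_polyorder}"
            )
        if not 0 < self.butterworth_cutoff < frame_rate / 2:
            raise ValueError(
                f"butterworth_cutoff {self.butterworth_cutoff} Hz must lie below "
                f"the Nyquist frequency {frame_rate / 2} Hz"
            )
        if self.butterworth_order < 1:
            raise ValueError("butterworth_order must be >= 1")


@dataclass
class AttackKinematics:
    """Smoothed per-frame attack kinematics plus peak and endpoint summaries.

    Series are aligned to the trajectory frames; ``t_ms`` is relative to
    t = 0 at the contact-or-escape frame.  Speeds are m/s, accelerations
    m/s^2, distances mm, angles degrees.
    """

    t_ms: np.ndarray
    filtered_positions: Mapping[str, np.ndarray]
    speed: np.ndarray
    acceleration: np.ndarray
    distance: np.ndarray
    elevation: np.ndarray
    azimuth: np.ndarray
    window: tuple[int, int]
    window_fallback: bool
    peak_speed: float
    peak_acceleration: float
    time_of_peak_speed: float
    angular_size_at_end: float
    mean_elevation: float
    mean_azimuth: float
    outcome: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t_ms,
                "speed_m_per_s": self.speed,
                "accel_m_per_s2": self.acceleration,
                "distance_mm": self.distance,
                "elevation_deg": self.elevation,
                "azimuth_deg": self.azimuth,
            }
        )

    def summary(self) -> dict:
        return {
            "outcome": self.outcome,
            "peak_speed_m_per_s": self.peak_speed,
            "peak_acceleration_m_per_s2": self.peak_acceleration,
            "time_of_peak_speed_ms": self.time_of_peak_speed,
            "angular_size_at_end_deg": self.angular_size_at_end,
            "mean_elevation_deg": self.mean_elevation,
            "mean_azimuth_deg": self.mean_azimuth,
            "attack_window_frames": list(self.window),
            "attack_window_fallback": self.window_fallback,
        }


# ---------------------------------------------------------------------------
# input


def read_digitized_points(
    path,
    frame_rate: float = 1000.0,
    label_map: Mapping[str, str] | None = None,
    outcome: str = "capture",
    end_frame: int | None = None,
) -> TrackedTrajectory:
    """Read a digitized-points CSV into a validated trajectory.

    The native dialect has a ``frame`` column plus ``<label>_x/_y/_z`` for
    each of ``damselfly_head``, ``damselfly_tail``, ``fly_centroid`` (mm).
    ``label_map`` renames foreign headers (e.g. DLTdv generic ``pt1_X``)
    onto the native ones before validation: ``{"pt1_X": "damselfly_head_x", ...}``.
    Blank cells become NaN rows flagged as gaps.
    """
    df = pd.read_csv(path)
    if label_map:
        df = df.rename(columns=dict(label_map))
    missing = [
        f"{label}_{ax}"
        for label in LABELS
        for ax in "xyz"
        if f"{label}_{ax}" not in df.columns
    ]
    if missing:
        raise ValueError(f"{path}: unresolvable coordinate columns: {missing}")
    if "frame" in df.columns:
        frames = df["frame"].to_numpy()
        if not np.all(np.diff(frames) > 0):
            raise ValueError(f"{path}: frame indices are not strictly increasing")
    points = {
        label: df[[f"{label}_{ax}" for ax in "xyz"]].to_numpy(dtype=float)
        for label in LABELS
    }
    return TrackedTrajectory(
        frame_rate=frame_rate, points=points, outcome=outcome, end_frame=end_frame
    )


# ---------------------------------------------------------------------------
# smoothing and differentiation


def _interpolate_gaps(series: np.ndarray, max_gap: int = MAX_INTERP_GAP) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap; longer runs raise."""
    out = np.array(series, dtype=float)
    isnan = np.isnan(out)
    if not isnan.any():
        return out
    if isnan[0] or isnan[-1]:
        raise ValueError("gap at trajectory boundary cannot be interpolated")
    # locate runs of NaNs
    edges = np.flatnonzero(np.diff(isnan.astype(int)))
    starts = edges[::2] + 1
    ends = edges[1::2] + 1
    for s, e in zip(starts, ends):
        if e - s > max_gap:
            raise ValueError(
                f"gap of {e - s} frames exceeds the {max_gap}-frame interpolation "
                "limit; split the event at the gap"
            )
    idx = np.arange(len(out))
    out[isnan] = np.interp(idx[isnan], idx[~isnan], out[~isnan])
    return out


def smooth_positions(
    positions: np.ndarray,
    frame_rate: float,
    params: SmoothingParams | None = None,
    max_gap: int = MAX_INTERP_GAP,
) -> np.ndarray:
    """Zero-phase smooth an (n, 3) position series, per component axis.

    Short gaps (NaN runs of at most ``max_gap`` frames) are linearly
    interpolated first.  Each axis then passes through a forward-backward
    Butterworth filter (no phase lag) followed by a Savitzky–Golay filter.
    """
    params = params or SmoothingParams()
    params.validate(frame_rate)
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < params.savgol_window:
        raise ValueError(
            f"series of {positions.shape[0]} frames shorter than "
            f"savgol_window={params.savgol_window}"
        )
    sos = butter(
        params.butterworth_order,
        params.butterworth_cutoff,
        btype="low",
        fs=frame_rate,
        output="sos",
    )
    out = np.empty_like(positions)
    for ax in range(positions.shape[1]):
        col = _interpolate_gaps(positions[:, ax], max_gap=max_gap)
        col = sosfiltfilt(sos, col)
        out[:, ax] = savgol_filter(col, params.savgol_window, params.savgol_polyorder)
    return out


def compute_speed_acceleration(
    filtered_positions: np.ndarray, frame_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Differentiate filtered positions (mm) into speed (m/s) and acceleration (m/s^2).

    Speed is the norm of the central-difference velocity; acceleration is
    the central difference of scalar speed (matching the scalar panels of
    attack-kinematics plots, not the vector-acceleration magnitude).
    One-sided differences are used at the boundaries.
    """
    pos = np.asarray(filtered_positions, dtype=float)
    if pos.shape[0] < 3:
        raise ValueError("need at least 3 frames to differentiate")
    dt = 1.0 / frame_rate
    vel = np.gradient(pos * 1e-3, dt, axis=0)  # mm -> m
    speed = np.linalg.norm(vel, axis=1)
    accel = np.gradient(speed, dt)
    return speed, accel


# ---------------------------------------------------------------------------
# attack window


def detect_attack_window(
    speed: np.ndarray,
    frame_rate: float,
    end_frame: int,
    hover_speed_threshold: float = 0.02,
    hover_min_duration: float = 50.0,
) -> tuple[int, int, bool]:
    """Locate the attack (post-hover dart) window in a speed series.

    The predator hovers nearly stationary before darting; the attack starts
    at the first frame after the last run of at least ``hover_min_duration``
    ms with speed below ``hover_speed_threshold`` m/s, and ends at
    ``end_frame``.  Returns ``(start, end, fallback)``; with no detectable
    hover the full series up to ``end_frame`` is used and ``fallback`` is
    True.
    """
    speed = np.asarray(speed, dtype=float)
    min_frames = max(1, int(round(hover_min_duration * frame_rate / 1000.0)))
    below = speed[: end_frame + 1] < hover_speed_threshold
    start = None
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= min_frames:
            start = i + 1  # frame after this hover run (extends while run grows)
    if start is None or start > end_frame:
        return 0, end_frame, True
    return start, end_frame, False


# ---------------------------------------------------------------------------
# angles


def elevation_azimuth(
    head_positions: np.ndarray,
    fly_positions: np.ndarray,
    window: tuple[int, int] | None = None,
    reference: str = "window_start",
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Prey-centered elevation and azimuth of the predator head, per frame.

    The vector runs from the prey to the predator head.  Elevation is
    atan2(dz, ||dxy||) in [-90, 90] degrees.  Azimuth is the angle of
    (dx, |dy|) from the +X axis (the mesh-wall normal), folded into
    [0, 180] degrees by left-right symmetry: only the lateral Y coordinate
    is folded, so front (0) and back (180) remain distinct.  Frames where
    prey and predator coincide get NaN angles (undefined direction).

    ``reference="window_start"`` anchors the prey position at the first
    window frame (the prey may move during the attack);
    ``reference="per_frame"`` uses the prey's instantaneous position.
    Means are arithmetic means over the window, ignoring undefined frames.
    """
    head = np.asarray(head_positions, dtype=float)
    fly = np.asarray(fly_positions, dtype=float)
    if window is None:
        window = (0, head.shape[0] - 1)
    if reference == "window_start":
        origin = fly[window[0]][None, :]
    elif reference == "per_frame":
        origin = fly
    else:
        raise ValueError(f"unknown reference {reference!r}")
    d = head - origin
    horiz = np.hypot(d[:, 0], d[:, 1])
    norm = np.linalg.norm(d, axis=1)
    with np.errstate(invalid="ignore"):
        elevation = np.degrees(np.arctan2(d[:, 2], horiz))
        azimuth = np.degrees(np.arctan2(np.abs(d[:, 1]), d[:, 0]))
    undefined = norm < 1e-12
    elevation[undefined] = np.nan
    azimuth[undefined | (horiz < 1e-12)] = np.nan  # straight above: azimuth undefined
    sl = slice(window[0], window[1] + 1)
    mean_elev = float(np.nanmean(elevation[sl])) if np.any(~np.isnan(elevation[sl])) else math.nan
    mean_azim = float(np.nanmean(azimuth[sl])) if np.any(~np.isnan(azimuth[sl])) else math.nan
    return elevation, azimuth, mean_elev, mean_azim


# ---------------------------------------------------------------------------
# summaries


def peak_metrics(
    speed: np.ndarray,
    acceleration: np.ndarray,
    t_ms: np.ndarray,
    window: tuple[int, int],
) -> tuple[float, float, float]:
    """Peak speed, peak acceleration and time of peak speed over a window.

    ``time_of_peak_speed`` is in ms relative to t = 0 at the end frame
    (negative before contact/escape); ties go to the latest frame.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError(f"empty attack window {window}")
    sl = slice(lo, hi + 1)
    spd = np.asarray(speed, float)[sl]
    peak_speed = float(np.max(spd))
    # latest frame attaining the maximum
    i_peak = lo + int(np.flatnonzero(spd == peak_speed)[-1])
    peak_accel = float(np.max(np.asarray(acceleration, float)[sl]))
    return peak_speed, peak_accel, float(np.asarray(t_ms, float)[i_peak])


def angular_size_at_end(distance_at_end_mm: float, head_width_mm: float) -> float:
    """Retinal angular size (deg) of the predator head at contact or escape.

    theta = 2*atan(r/d) with 2r the head width and d the Euclidean
    predator-prey distance at the end frame.
    """
    if head_width_mm <= 0:
        raise ValueError(f"head_width must be positive, got {head_width_mm}")
    if distance_at_end_mm <= 0:
        raise ValueError(
            f"distance at end must be positive (contact reached), got {distance_at_end_mm}"
        )
    return math.degrees(2.0 * math.atan((head_width_mm / 2.0) / distance_at_end_mm))


def align_and_average(
    kins: Sequence[AttackKinematics], quantity: str
) -> pd.DataFrame:
    """Per-timepoint mean/sd/n of a kinematic quantity across events.

    Series are aligned at t = 0 (the contact-or-escape frame) and averaged
    over whichever events cover each timepoint, so ``n`` steps down where
    shorter trajectories start.  ``quantity`` is an attribute name such as
    ``"speed"`` or ``"distance"``.
    """
    if not kins:
        raise ValueError("no kinematics to average")
    series = []
    for k in kins:
        t = np.round(np.asarray(k.t_ms), 6)
        series.append(pd.Series(getattr(k, quantity), index=t))
    wide = pd.concat(series, axis=1).sort_index()
    return pd.DataFrame(
        {
            "t_ms": wide.index.to_numpy(),
            "mean": wide.mean(axis=1, skipna=True).to_numpy(),
            "sd": wide.std(axis=1, ddof=1, skipna=True).to_numpy(),
            "n": wide.notna().sum(axis=1).to_numpy(),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline


def analyze_attack(
    traj: TrackedTrajectory,
    smoothing: SmoothingParams | None = None,
    head_width_mm: float = 2.2,
    hover_speed_threshold: float = 0.02,
    hover_min_duration: float = 50.0,
    angle_reference: str = "window_start",
) -> AttackKinematics:
    """Full per-event pipeline: smooth, differentiate, window, angles, summaries."""
    head = smooth_positions(traj.points["damselfly_head"], traj.frame_rate, smoothing)
    fly = smooth_positions(traj.points["fly_centroid"], traj.frame_rate, smoothing)
    speed, accel = compute_speed_acceleration(head, traj.frame_rate)
    start, end, fallback = detect_attack_window(
        speed, traj.frame_rate, traj.end_frame, hover_speed_threshold, hover_min_duration
    )
    window = (start, end)
    distance = np.linalg.norm(head - fly, axis=1)
    elev, azim, mean_elev, mean_azim = elevation_azimuth(
        head, fly, window=window, reference=angle_reference
    )
    t_ms = traj.t_ms()
    pk_speed, pk_accel, t_peak = peak_metrics(speed, accel, t_ms, window)
    theta_end = angular_size_at_end(float(distance[traj.end_frame]), head_width_mm)
    return AttackKinematics(
        t_ms=t_ms,
        filtered_positions={"damselfly_head": head, "fly_centroid": fly},
        speed=speed,
        acceleration=accel,
        distance=distance,
        elevation=elev,
        azimuth=azim,
        window=window,
        window_fallback=fallback,
        peak_speed=pk_speed,
        peak_acceleration=pk_accel,
        time_of_peak_speed=t_peak,
        angular_size_at_end=theta_end,
        mean_elevation=mean_elev,
        mean_azimuth=mean_azim,
        outcome=traj.outcome,
    )
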