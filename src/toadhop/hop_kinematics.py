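"""Angle series, hop-event detection, and per-hop alignment metrics.

Conventions (documented once, used everywhere):

* Analysis is planar.  The direction of travel is the dominant horizontal
  displacement of the snout over the recording; velocities are projected
  onto the sagittal (travel, vertical) plane.
* Angles are degrees from horizontal, positive above.  The forelimb angle
  ``alpha`` is the angle of the mid-humerus -> wrist segment; the
  velocity-vector angle ``gamma`` is the angle of the snout's instantaneous
  velocity (positive ascending, negative descending); ``delta = gamma -
  alpha`` at every frame, exactly.
* ``T0`` (hop initiation) is the first frame with 3-D snout speed above
  5 cm/s; a hop is included only if the vertical velocity at ``T0`` is
  strictly upward.  Touchdown proxies first manus touch with the wrist
  marker, the closest digitized point to the manus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trajectories import HopRecording, smooth_and_differentiate

G = 9.81


class EventDetectionError(ValueError):
    """Raised when a required hop event cannot be found."""


class DegenerateSegmentError(ValueError):
    """Raised when the two forelimb markers coincide at some frame."""


def wrap_angle(deg):
    """Wrap angles (deg) into (-180, 180]."""
    w = (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(w == -180.0, 180.0, w)


@dataclass
class KinematicSeries:
    """Time-aligned angle and velocity series for one hop."""

    times: np.ndarray
    alpha: np.ndarray                    # deg, forelimb vs horizontal
    gamma: np.ndarray                    # deg, snout velocity vs horizontal
    delta: np.ndarray                    # deg, gamma - alpha (exact)
    snout_speed: np.ndarray              # m/s, 3-D
    snout_vertical_velocity: np.ndarray  # m/s
    snout_height: np.ndarray             # m, smoothed snout z
    snout_vertical_acceleration: np.ndarray  # m/s^2, spline 2nd derivative
    wrist_height: np.ndarray             # m, smoothed wrist z
    wrist_vertical_velocity: np.ndarray  # m/s
    frame_rate: float
    smoothing_used: dict                 # marker -> axis -> s actually used

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def index_of(self, time: float) -> int:
        i = int(np.argmin(np.abs(self.times - time)))
        if abs(self.times[i] - time) > 0.51 * self.dt:
            raise ValueError(f"time {time} not on the series time base")
        return i


@dataclass
class HopEvents:
    t0: float
    liftoff: float
    touchdown: float
    included: bool


@dataclass
class AlignmentBand:
    """Interval of delta values counted as 'aligned with the velocity vector'."""

    lower: float
    upper: float
    method: str            # "ci_of_mean" | "fixed_halfwidth"
    n_hops_used: int

    def contains(self, delta):
        d = np.asarray(delta, dtype=float)
        return (d >= self.lower) & (d <= self.upper)


@dataclass
class HopMetrics:
    hop_id: str
    animal_id: str
    treatment: str
    included: bool
    t0: float
    liftoff: float
    touchdown: float
    alpha_td: float
    gamma_td: float
    delta_td: float
    aerial_duration: float
    t_a: float | None            # alignment time; None if delta never in band
    o_t0: float | None           # T_a - T0
    o_lo: float | None           # T_a - liftoff
    d_a: float | None            # touchdown - T_a
    excursion: float | None      # |gamma(T_a) - gamma(touchdown)|, deg
    continually_aligned: bool | None


def forelimb_angle(wrist_sag: np.ndarray, wrist_z: np.ndarray,
                   humerus_sag: np.ndarray, humerus_z: np.ndarray) -> np.ndarray:
    """Signed angle (deg) of the mid-humerus -> wrist segment vs horizontal.

    Positive when the wrist lies above the mid-humerus point's horizontal,
    negative below; forelimbs held parallel to the ground give 0 deg.
    """
    dx = np.asarray(wrist_sag) - np.asarray(humerus_sag)
    dz = np.asarray(wrist_z) - np.asarray(humerus_z)
    if np.any(np.hypot(dx, dz) < 1e-9):
        raise DegenerateSegmentError(
            "degenerate limb segment: wrist and mid-humerus coincide")
    return np.degrees(np.arctan2(dz, dx))


def velocity_vector_angle(v_sag: np.ndarray, v_z: np.ndarray,
                          min_speed: float = 1e-6) -> np.ndarray:
    """Angle (deg) of the sagittal velocity vector; NaN where speed ~ 0.

    Frames with planar speed below ``min_speed`` have no defined tangent
    direction; they propagate as NaN rather than being interpolated.
    """
    v_sag = np.asarray(v_sag, dtype=float)
    v_z = np.asarray(v_z, dtype=float)
    gamma = np.degrees(np.arctan2(v_z, v_sag))
    gamma[np.hypot(v_sag, v_z) < min_speed] = np.nan
    return gamma


def travel_direction(recording: HopRecording) -> np.ndarray:
    """Unit horizontal travel direction from net snout displacement."""
    pos = recording.markers["snout"].positions
    d = pos[-1, :2] - pos[0, :2]
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise EventDetectionError("no hop detected: snout does not translate")
    return d / norm


def compute_kinematics(recording: HopRecording,
                       smoothing: float | str = "auto") -> KinematicSeries:
    """Smooth each marker and derive the angle/velocity series for one hop."""
    u = travel_direction(recording)
    smoothed = {name: smooth_and_differentiate(traj, smoothing)
                for name, traj in recording.markers.items()}

    def sag(marker: str, attr: str) -> np.ndarray:
        s = smoothed[marker]
        return u[0] * getattr(s["x"], attr) + u[1] * getattr(s["y"], attr)

    snout = smoothed["snout"]
    v_sag = sag("snout", "first_derivative")
    v_lat = (-u[1] * snout["x"].first_derivative
             + u[0] * snout["y"].first_derivative)
    v_z = snout["z"].first_derivative
    alpha = forelimb_angle(
        sag("wrist", "value"), smoothed["wrist"]["z"].value,
        sag("mid_humerus", "value"), smoothed["mid_humerus"]["z"].value)
    gamma = velocity_vector_angle(v_sag, v_z)
    return KinematicSeries(
        times=recording.times,
        alpha=alpha,
        gamma=gamma,
        delta=wrap_angle(gamma - alpha),
        snout_speed=np.sqrt(v_sag ** 2 + v_lat ** 2 + v_z ** 2),
        snout_vertical_velocity=v_z,
        snout_height=snout["z"].value,
        snout_vertical_acceleration=snout["z"].second_derivative,
        wrist_height=smoothed["wrist"]["z"].value,
        wrist_vertical_velocity=smoothed["wrist"]["z"].first_derivative,
        frame_rate=recording.frame_rate,
        smoothing_used={m: {ax: s.smoothing for ax, s in d.items()}
                        for m, d in smoothed.items()},
    )


def detect_hop_initiation(series: KinematicSeries,
                          threshold: float = 0.05) -> float:
    """First time the 3-D snout speed exceeds ``threshold`` (default 5 cm/s).

    The crossing is located by walking back from the frame of peak speed
    (mid-hop, where the signal is unambiguous) to the last preceding frame
    at or below the threshold; T0 is the frame after it.  On a recording
    whose speed rises monotonically through the threshold this is exactly
    the first-crossing frame, but unlike a forward scan it is immune to
    spurious crossings from smoothing-spline end effects during the
    pre-hop rest phase.
    """
    speed = series.snout_speed
    if np.nanmax(speed) <= threshold:
        raise EventDetectionError("no hop detected: speed never exceeds "
                                  f"{threshold} m/s")
    ipk = int(np.nanargmax(speed))
    quiet = np.nonzero(speed[:ipk + 1] <= threshold)[0]
    i0 = int(quiet[-1]) + 1 if quiet.size else 0
    return float(series.times[i0])


def apply_inclusion_filter(series: KinematicSeries, t0: float) -> bool:
    """True iff the vertical velocity at hop initiation is strictly upward."""
    return bool(series.snout_vertical_velocity[series.index_of(t0)] > 0.0)


def detect_liftoff(series: KinematicSeries, t0: float,
                   accel_band: float = 0.15,
                   min_duration: float = 0.010) -> float:
    """Onset of the ballistic phase after ``t0``.

    Lift-off is the first frame after ``t0`` from which the snout's vertical
    acceleration (spline second derivative) stays within ``accel_band``
    (default 15%) of -g over the following ``min_duration`` (default
    10 ms).  Membership is judged on the median acceleration over that
    window, which tolerates isolated noisy frames without moving the
    detected onset on clean data.
    """
    az = series.snout_vertical_acceleration
    i0 = series.index_of(t0)
    need = max(1, int(round(min_duration * series.frame_rate)))
    for i in range(i0, az.size - need + 1):
        med = float(np.median(az[i:i + need]))
        if abs(med + G) <= accel_band * G:
            return float(series.times[i])
    raise EventDetectionError("no liftoff: no sustained ballistic segment")


def detect_touchdown(series: KinematicSeries,
                     contact_tolerance: float = 0.003) -> float:
    """First frame after the aerial apex with the wrist at ground level.

    The wrist marker must fall below ``contact_tolerance`` (default 3 mm)
    above the landing surface (z = 0) with downward wrist velocity.
    """
    apex = int(np.argmax(series.snout_height))
    n = series.times.size
    idx = np.arange(n)
    cand = np.nonzero((idx > apex)
                      & (series.wrist_height < contact_tolerance)
                      & (series.wrist_vertical_velocity < 0))[0]
    if cand.size == 0:
        raise EventDetectionError("no touchdown: wrist never reaches ground")
    return float(series.times[cand[0]])


def detect_events(series: KinematicSeries,
                  speed_threshold: float = 0.05,
                  contact_tolerance: float = 0.003,
                  accel_band: float = 0.15,
                  liftoff_min_duration: float = 0.010) -> HopEvents:
    """Run all event detectors and the inclusion filter for one hop."""
    t0 = detect_hop_initiation(series, speed_threshold)
    included = apply_inclusion_filter(series, t0)
    touchdown = detect_touchdown(series, contact_tolerance)
    liftoff = detect_liftoff(series, t0, accel_band, liftoff_min_duration)
    return HopEvents(t0=t0, liftoff=liftoff, touchdown=touchdown,
                     included=included)


def build_alignment_band(delta_td_values, method: str = "fixed_halfwidth",
                         fixed_halfwidth: float = 15.0) -> AlignmentBand:
    """Band of delta values counted as aligned, centred on mean delta_TD.

    ``ci_of_mean`` uses the 95% t-interval for the mean,
    mean +/- t(0.975, n-1) * SD / sqrt(n); ``fixed_halfwidth`` uses
    mean +/- ``fixed_halfwidth`` degrees (default 15).
    """
    vals = np.asarray(list(delta_td_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    n = vals.size
    if method == "ci_of_mean":
        if n < 2:
            raise ValueError("insufficient data for band: need >= 2 values")
        mean = float(np.mean(vals))
        half = float(sps.t.ppf(0.975, n - 1) * np.std(vals, ddof=1)
                     / math.sqrt(n))
    elif method == "fixed_halfwidth":
        if n < 1:
            raise ValueError("insufficient data for band: need >= 1 value")
        mean = float(np.mean(vals))
        half = float(fixed_halfwidth)
    else:
        raise ValueError(f"unknown band method {method!r}")
    return AlignmentBand(lower=mean - half, upper=mean + half,
                         method=method, n_hops_used=n)


def alignment_time(series: KinematicSeries, band: AlignmentBand,
                   events: HopEvents,
                   dropout_tolerance_frames: int = 0,
                   min_duration: float = 0.020
                   ) -> tuple[float | None, bool | None]:
    """First time delta enters the band within [T0, touchdown].

    The entry must be sustained: delta stays in the band for
    ``min_duration`` (default 20 ms) after the entry frame (or to
    touchdown, if sooner).  Early in a hop the snout moves barely faster
    than the initiation threshold, so the velocity-vector direction — and
    with it delta — is dominated by measurement noise and can brush the
    band for a frame or two; the persistence rule rejects those encounters
    while leaving a genuine entry frame unchanged (a converged arm stays in
    the band).

    Returns ``(T_a, continually_aligned)``; ``(None, None)`` if delta never
    enters the band.  ``continually_aligned`` is True when at most
    ``dropout_tolerance_frames`` frames between T_a and touchdown (default
    0) fall outside the band.
    """
    i0 = series.index_of(events.t0)
    i_td = series.index_of(events.touchdown)
    inside = band.contains(series.delta) & np.isfinite(series.delta)
    need = max(1, int(round(min_duration * series.frame_rate)))
    ia = None
    for i in range(i0, i_td + 1):
        stop = min(i + need, i_td + 1)
        if inside[i:stop].all():
            ia = i
            break
    if ia is None:
        return None, None
    out_frames = int(np.sum(~inside[ia:i_td + 1]))
    return float(series.times[ia]), bool(
        out_frames <= dropout_tolerance_frames)


def hop_metrics(recording: HopRecording, series: KinematicSeries,
                events: HopEvents, band: AlignmentBand,
                dropout_tolerance_frames: int = 0,
                alignment_min_duration: float = 0.020) -> HopMetrics:
    """All per-hop scalars; alignment fields are None when T_a is undefined."""
    i_td = series.index_of(events.touchdown)
    alpha_td = float(series.alpha[i_td])
    gamma_td = float(series.gamma[i_td])
    t_a, continually = alignment_time(series, band, events,
                                      dropout_tolerance_frames,
                                      alignment_min_duration)
    if t_a is not None:
        ia = series.index_of(t_a)
        o_t0 = t_a - events.t0
        o_lo = t_a - events.liftoff
        d_a = events.touchdown - t_a
        excursion = abs(float(series.gamma[ia]) - gamma_td)
    else:
        o_t0 = o_lo = d_a = excursion = None
    return HopMetrics(
        hop_id=recording.hop_id,
        animal_id=recording.animal_id,
        treatment=recording.treatment,
        included=events.included,
        t0=events.t0,
        liftoff=events.liftoff,
        touchdown=events.touchdown,
        alpha_td=alpha_td,
        gamma_td=gamma_td,
        delta_td=gamma_td - alpha_td,
        aerial_duration=events.touchdown - events.liftoff,
        t_a=t_a,
        o_t0=o_t0,
        o_lo=o_lo,
        d_a=d_a,
        excursion=excursion,
        continually_aligned=continually,
    )


def metrics_to_frame(metrics: list[HopMetrics]) -> pd.DataFrame:
    cols = ["hop_id", "animal_id", "treatment", "included", "t0", "liftoff",
            "touchdown", "alpha_td", "gamma_td", "delta_td",
            "aerial_duration", "t_a", "o_t0", "o_lo", "d_a", "excursion",
            "continually_aligned"]
    return pd.DataFrame({c: [getattr(m, c) for m in metrics] for c in cols})
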