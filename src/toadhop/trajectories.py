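"""Marker-trajectory data model, CSV I/O, and quintic-spline smoothing.

The pipeline works on three anatomical markers digitized per hop — the
wrist, a point midway along the humerus, and the snout tip — sampled on a
uniform time base (500 frames/s in the study design this emulates).
Coordinates are metres with ``x`` horizontal along the direction of travel,
``y`` horizontal lateral, and ``z`` vertical (``z = 0`` at the landing
surface).  Velocities are always the analytic first derivative of a
degree-5 smoothing spline fitted per axis, never finite differences of
smoothed positions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

MARKER_NAMES = ("wrist", "mid_humerus", "snout")

#: treatment label -> platform height above the landing surface (m)
TREATMENT_HEIGHTS = {"flat": 0.0, "low": 0.05, "high": 0.09}

_CSV_COLUMNS = ["hop_id", "animal_id", "treatment", "time_s", "marker",
                "x_m", "y_m", "z_m"]


class RecordingError(ValueError):
    """Raised for malformed or incomplete hop recordings."""


@dataclass
class MarkerTrajectory:
    """One marker's raw 3-D trajectory on a uniform time base."""

    marker_name: str
    times: np.ndarray          # (n,) seconds, strictly increasing, uniform
    positions: np.ndarray      # (n, 3) metres: x (travel), y (lateral), z (up)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.marker_name not in MARKER_NAMES:
            raise RecordingError(
                f"schema error: unknown marker name {self.marker_name!r}")
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 3):
            raise RecordingError("schema error: times/positions shape mismatch")
        if self.times.size < 7:
            raise RecordingError("too short to smooth: need >= 7 samples")
        if not (np.isfinite(self.times).all()
                and np.isfinite(self.positions).all()):
            raise RecordingError("schema error: non-finite coordinates")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise RecordingError("irregular sampling: times not increasing")
        if np.ptp(dt) > 1e-9:
            raise RecordingError("irregular sampling: non-uniform time base")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class HopRecording:
    """A single hop: the three marker trajectories plus metadata."""

    hop_id: str
    animal_id: str
    treatment: str
    platform_height: float     # m above the landing surface
    frame_rate: float          # Hz
    markers: dict[str, MarkerTrajectory] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in MARKER_NAMES if m not in self.markers]
        if missing:
            raise RecordingError(
                f"incomplete recording: missing marker(s) {missing}")
        if self.treatment not in TREATMENT_HEIGHTS:
            raise RecordingError(
                f"schema error: unknown treatment {self.treatment!r}")
        if abs(self.platform_height - TREATMENT_HEIGHTS[self.treatment]) > 1e-9:
            raise RecordingError(
                "schema error: platform_height inconsistent with treatment "
                f"({self.platform_height} m vs {self.treatment!r})")
        base = self.markers[MARKER_NAMES[0]].times
        for name in MARKER_NAMES[1:]:
            if not np.array_equal(self.markers[name].times, base):
                raise RecordingError(
                    "incomplete recording: markers on different time bases")

    @property
    def times(self) -> np.ndarray:
        return self.markers["snout"].times

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class SmoothedSeries:
    """A smoothing-spline fit of one coordinate: values and derivatives."""

    times: np.ndarray
    value: np.ndarray
    first_derivative: np.ndarray
    second_derivative: np.ndarray
    smoothing: float           # FITPACK residual target s actually used


def estimate_noise_sd(x: np.ndarray) -> float:
    """Second-difference estimate of i.i.d. measurement-noise SD.

    For a signal smooth at the frame scale, the second difference of the
    samples is dominated by noise with variance ``6 * sigma^2``.
    """
    x = np.asarray(x, dtype=float)
    d2 = x[:-2] - 2.0 * x[1:-1] + x[2:]
    return float(np.sqrt(np.mean(d2 ** 2) / 6.0))


def smooth_and_differentiate(
    traj: MarkerTrajectory,
    smoothing: float | str = "auto",
) -> dict[str, SmoothedSeries]:
    """Fit a quintic smoothing spline per axis; return values + derivatives.

    Parameters
    ----------
    traj:
        The marker trajectory (>= 7 samples, uniform time base).
    smoothing:
        FITPACK residual target ``s`` (sum of squared residuals allowed).
        ``0`` gives the interpolating quintic spline, which reproduces
        sampled polynomials of degree <= 5 exactly.  ``"auto"`` (default)
        sets ``s = n * sigma_hat^2`` per axis, with ``sigma_hat`` from
        :func:`estimate_noise_sd` — the classic residual-matching rule.

    Returns
    -------
    dict mapping axis name (``"x"``, ``"y"``, ``"z"``) to
    :class:`SmoothedSeries` evaluated at the original sample times.  The
    derivatives are the spline's analytic derivatives.
    """
    if traj.times.size < 7:
        raise RecordingError("too short to smooth: need >= 7 samples")
    if not isinstance(smoothing, str) and smoothing < 0:
        raise ValueError("smoothing must be >= 0 or 'auto'")
    out: dict[str, SmoothedSeries] = {}
    n = traj.times.size
    for j, axis in enumerate(("x", "y", "z")):
        coord = traj.positions[:, j]
        if isinstance(smoothing, str):
            if smoothing != "auto":
                raise ValueError(f"unknown smoothing mode {smoothing!r}")
            s = n * estimate_noise_sd(coord) ** 2
        else:
            s = float(smoothing)
        spline = UnivariateSpline(traj.times, coord, k=5, s=s)
        out[axis] = SmoothedSeries(
            times=traj.times,
            value=spline(traj.times),
            first_derivative=spline.derivative(1)(traj.times),
            second_derivative=spline.derivative(2)(traj.times),
            smoothing=s,
        )
    return out


# ---------------------------------------------------------------------------
# CSV I/O.  One long-format file may hold one or many hops.


def _recording_to_frame(rec: HopRecording) -> pd.DataFrame:
    rows = []
    for name in MARKER_NAMES:          # deterministic marker-major order
        t = rec.markers[name]
        rows.append(pd.DataFrame({
            "hop_id": rec.hop_id,
            "animal_id": rec.animal_id,
            "treatment": rec.treatment,
            "time_s": t.times,
            "marker": name,
            "x_m": t.positions[:, 0],
            "y_m": t.positions[:, 1],
            "z_m": t.positions[:, 2],
        }))
    return pd.concat(rows, ignore_index=True)


def write_recordings(recordings: list[HopRecording], path) -> None:
    """Write hop recordings to a long-format CSV (9 significant digits)."""
    if not recordings:
        raise RecordingError("incomplete recording: nothing to write")
    frame = pd.concat([_recording_to_frame(r) for r in recordings],
                      ignore_index=True)
    frame.to_csv(path, index=False, float_format="%.9g")


def write_recording(recording: HopRecording, path) -> None:
    """Write a single hop recording to CSV (see :func:`write_recordings`)."""
    write_recordings([recording], path)


def _frame_to_recording(group: pd.DataFrame, hop_id: str) -> HopRecording:
    animal = group["animal_id"].iloc[0]
    treatment = group["treatment"].iloc[0]
    unknown = set(group["marker"]) - set(MARKER_NAMES)
    if unknown:
        raise RecordingError(f"schema error: unknown marker name(s) {unknown}")
    markers = {}
    for name, sub in group.groupby("marker", sort=False):
        sub = sub.sort_values("time_s")
        markers[str(name)] = MarkerTrajectory(
            marker_name=str(name),
            times=sub["time_s"].to_numpy(),
            positions=sub[["x_m", "y_m", "z_m"]].to_numpy(),
        )
    times = next(iter(markers.values())).times
    frame_rate = 1.0 / float(np.mean(np.diff(times)))
    return HopRecording(
        hop_id=str(hop_id),
        animal_id=str(animal),
        treatment=str(treatment),
        platform_height=TREATMENT_HEIGHTS[str(treatment)],
        frame_rate=frame_rate,
        markers=markers,
    )


def read_recordings(path) -> list[HopRecording]:
    """Read all hop recordings from a trajectory CSV."""
    frame = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise RecordingError(f"schema error: missing column(s) {missing}")
    recs = [
        _frame_to_recording(group, hop_id)
        for hop_id, group in frame.groupby("hop_id", sort=True)
    ]
    return recs


def read_recording(path, hop_id: str | None = None) -> HopRecording:
    """Read one hop from a trajectory CSV.

    ``hop_id`` selects a hop when the file holds several; with a single-hop
    file it may be omitted.
    """
    recs = read_recordings(path)
    if hop_id is None:
        if len(recs) != 1:
            raise RecordingError(
                "schema error: file holds multiple hops; pass hop_id")
        return recs[0]
    for rec in recs:
        if rec.hop_id == hop_id:
            return rec
    raise RecordingError(f"incomplete recording: hop {hop_id!r} not in file")


def recordings_to_csv_bytes(recordings: list[HopRecording]) -> bytes:
    """Serialize recordings to the CSV schema in memory (for checksums)."""
    buf = io.StringIO()
    write_recordings(recordings, buf)
    return buf.getvalue().encode()
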