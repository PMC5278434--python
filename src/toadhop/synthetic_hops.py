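"""Synthetic hop cohorts with ground truth for pipeline validation.

The generator emulates the study design the analysis assumes: six toads,
three platform heights (flat 0 cm, low 5 cm, high 9 cm), 6-12 hops per
animal per condition, marker trajectories at 500 frames/s.  Each hop has

* an initiation phase (default 0.20 s) in which the snout accelerates from
  rest along the eventual takeoff direction, crossing the 5 cm/s
  hop-initiation threshold with an upward vertical velocity component;
* a ballistic aerial phase, x(t) = v0 cos(theta) t,
  z(t) = z_liftoff + v0 sin(theta) t - g t^2 / 2 with g = 9.81 m/s^2;
* wrist touchdown: the hop ends when the wrist marker reaches the landing
  surface (z = 0) on descent.

The forelimb control policy is a model of the observed behaviour, not a
measured mechanism: the arm angle alpha starts at gamma(T0) minus a large
initial offset (default 75 deg), converges to the target
gamma(t) - delta_star(animal) with an exponentially decaying error, and
then tracks the velocity-vector angle with AR(1) jitter.  delta_star has a
population mean and per-animal random intercepts, giving the grouped
structure the mixed-model analysis expects.  Gaussian marker noise is
added last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .trajectories import HopRecording, MarkerTrajectory, TREATMENT_HEIGHTS

G = 9.81  # m/s^2

#: exponent of the initiation speed ramp v(t) = v0 (t/Ti)^p; high p keeps the
#: pre-liftoff displacement short so the snout stays above the platform
_RAMP_POWER = 6


@dataclass
class HopSimConfig:
    """Simulator parameters; defaults emulate the study conditions."""

    n_animals: int = 6
    hops_per_treatment: tuple[int, int] = (6, 12)   # inclusive uniform range
    treatments: dict[str, float] = field(
        default_factory=lambda: dict(TREATMENT_HEIGHTS))  # name -> height (m)
    frame_rate: float = 500.0                       # Hz
    takeoff_speed: tuple[float, float] = (1.2, 2.2)  # m/s, per-hop uniform
    takeoff_angle: tuple[float, float] = (30.0, 55.0)  # deg, per-hop uniform
    initiation_duration: float = 0.20               # s, ends at lift-off
    speed_threshold: float = 0.05                   # m/s, hop-initiation rule
    delta_star_mean: float = -4.1    # deg; population mean touchdown offset
    delta_star_animal_sd: float = 3.0   # deg; SD of per-animal intercepts
    tracking_noise_sd: float = 3.0      # deg; stationary SD of AR(1) jitter
    tracking_noise_time_constant: float = 0.12  # s; AR(1) correlation time
    tracking_time_constant: float = 0.04  # s; decay of the initial arm error
    initial_arm_offset: float = 75.0    # deg; gamma - alpha at hop onset
    marker_noise_sd: float = 0.0005     # m
    arm_length: float = 0.045           # m, mid-humerus -> wrist
    snout_to_humerus_offset: tuple[float, float] = (-0.035, -0.025)  # m (x, z)
    snout_liftoff_height: float = 0.055  # m, snout above platform at lift-off
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        lo, hi = self.hops_per_treatment
        if not (1 <= lo <= hi):
            raise ValueError("hops_per_treatment must be an increasing range")
        if not self.treatments:
            raise ValueError("treatments must be non-empty")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for name in ("delta_star_animal_sd", "tracking_noise_sd",
                     "marker_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.arm_length <= 0:
            raise ValueError("arm_length must be positive")
        if self.initiation_duration <= 0:
            raise ValueError("initiation_duration must be positive")


@dataclass
class HopGroundTruth:
    """Exact per-hop quantities the detectors and metrics are tested against."""

    hop_id: str
    animal_id: str
    treatment: str
    takeoff_speed: float        # m/s
    takeoff_angle: float        # deg
    t0: float                   # s; first frame with true speed > threshold
    liftoff: float              # s; start of the ballistic phase
    touchdown: float            # s; first frame with wrist at/below ground,
    #                             descending, after the aerial apex
    gamma_td: float             # deg; true gamma at the touchdown frame
    alpha_td: float             # deg; true alpha (pre marker noise) there
    delta_td: float             # deg; gamma_td - alpha_td, exact
    animal_intercept: float     # deg; this animal's delta_star deviation
    times: np.ndarray = field(repr=False, default=None)
    gamma: np.ndarray = field(repr=False, default=None)   # deg, true series
    alpha: np.ndarray = field(repr=False, default=None)   # deg, true series


@dataclass
class CohortGroundTruth:
    hops: list[HopGroundTruth]
    animal_intercepts: dict[str, float]
    config: HopSimConfig
    seed: int

    def to_frame(self) -> pd.DataFrame:
        cols = ["hop_id", "animal_id", "treatment", "takeoff_speed",
                "takeoff_angle", "t0", "liftoff", "touchdown", "gamma_td",
                "alpha_td", "delta_td", "animal_intercept"]
        data = {c: [getattr(h, c) for h in self.hops] for c in cols}
        return pd.DataFrame(data)


def _ramp_fraction(u: np.ndarray) -> np.ndarray:
    """Speed fraction v/v0 during initiation as a function of u = t/Ti."""
    return u ** _RAMP_POWER


def _ramp_distance_fraction(u: np.ndarray) -> np.ndarray:
    """Integral of the speed ramp: distance/(v0*Ti) at u = t/Ti."""
    return u ** (_RAMP_POWER + 1) / (_RAMP_POWER + 1)


def simulate_hop(
    config: HopSimConfig,
    animal_effect: float,
    rng: np.random.Generator,
    *,
    treatment: str = "flat",
    takeoff_speed: float | None = None,
    takeoff_angle: float | None = None,
    hop_id: str = "hop",
    animal_id: str = "animal",
) -> tuple[HopRecording, HopGroundTruth]:
    """Simulate one hop and return the recording plus its ground truth.

    ``animal_effect`` is the animal's random deviation (deg) from the
    population-mean touchdown offset ``delta_star_mean``.  ``takeoff_speed``
    and ``takeoff_angle`` override the per-hop draws (a negative angle gives
    a downward launch, useful for exercising the inclusion filter).
    """
    config.validate()
    if treatment not in config.treatments:
        raise ValueError(f"unknown treatment {treatment!r}")
    h = config.treatments[treatment]
    v0 = (float(takeoff_speed) if takeoff_speed is not None
          else rng.uniform(*config.takeoff_speed))
    theta = (float(takeoff_angle) if takeoff_angle is not None
             else rng.uniform(*config.takeoff_angle))
    th = math.radians(theta)
    dt = 1.0 / config.frame_rate
    ti = config.initiation_duration
    z_lift = h + config.snout_liftoff_height
    delta_star = config.delta_star_mean + animal_effect

    # generous horizon: initiation + full ballistic fall to below ground
    vz0 = v0 * math.sin(th)
    fall = (vz0 + math.sqrt(max(vz0, 0.0) ** 2 + 2 * G * (z_lift + 0.3))) / G
    n = int(math.ceil((ti + fall + 0.05) / dt)) + 1
    t = np.arange(n) * dt

    init = t < ti
    u = np.clip(t / ti, 0.0, 1.0)
    speed_init = v0 * _ramp_fraction(u)
    dist_init = v0 * ti * _ramp_distance_fraction(u)
    d_total = v0 * ti * _ramp_distance_fraction(np.array(1.0))
    ta = t - ti                                   # aerial time, valid t >= ti

    # snout path: straight line along the takeoff direction, then projectile
    direction = np.array([math.cos(th), math.sin(th)])
    start = np.array([0.0, z_lift]) - d_total * direction
    sx = np.where(init, start[0] + dist_init * math.cos(th),
                  v0 * math.cos(th) * ta)
    sz = np.where(init, start[1] + dist_init * math.sin(th),
                  z_lift + vz0 * ta - 0.5 * G * ta ** 2)
    vx = np.where(init, speed_init * math.cos(th), v0 * math.cos(th))
    vz = np.where(init, speed_init * math.sin(th), vz0 - G * ta)

    gamma = np.degrees(np.arctan2(vz, vx))
    gamma[0] = theta                     # speed 0 at t=0: direction of travel
    speed = np.hypot(vx, vz)

    # hop initiation: first frame with true speed above threshold
    above = np.nonzero(speed > config.speed_threshold)[0]
    if above.size == 0 or t[above[0]] >= ti:
        raise ValueError("degenerate geometry: threshold not crossed "
                         "before lift-off")
    i0 = int(above[0])

    # arm angle: target tracking with exponentially decaying initial error
    # and AR(1) jitter (stationary SD tracking_noise_sd)
    # alpha(t) = gamma(t) - delta_star - err(t), so delta(t) = gamma - alpha
    # = delta_star + err(t) + noise; err(T0) makes delta(T0) the configured
    # initial offset and decays to zero (lag-free tracking once converged)
    err0 = config.initial_arm_offset - delta_star
    decay = np.exp(-np.maximum(t - t[i0], 0.0) / config.tracking_time_constant)
    err = err0 * decay
    if config.tracking_noise_sd > 0:
        phi = math.exp(-dt / config.tracking_noise_time_constant)
        innov = rng.standard_normal(n) * config.tracking_noise_sd
        noise = np.empty(n)
        noise[0] = innov[0]
        c = math.sqrt(1.0 - phi * phi)
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + c * innov[i]
    else:
        noise = np.zeros(n)
    alpha = gamma - delta_star - err + noise
    alpha_rad = np.radians(alpha)

    # marker geometry (sagittal plane; y = 0 before noise)
    hx = sx + config.snout_to_humerus_offset[0]
    hz = sz + config.snout_to_humerus_offset[1]
    wx = hx + config.arm_length * np.cos(alpha_rad)
    wz = hz + config.arm_length * np.sin(alpha_rad)

    # true touchdown: first frame after the aerial apex with the wrist at or
    # below ground level and descending
    aerial = ~init
    if not np.any(aerial & (vz < 0)):
        raise ValueError("degenerate geometry: no descent phase")
    apex = int(np.argmax(np.where(aerial, sz, -np.inf)))
    wvz = np.gradient(wz, dt)
    cand = np.nonzero((np.arange(n) > apex) & (wz <= 0.0) & (wvz < 0))[0]
    if cand.size == 0:
        raise ValueError("degenerate geometry: wrist never reaches ground")
    i_td = int(cand[0])
    if t[i_td] <= ti:
        raise ValueError("degenerate geometry: touchdown precedes lift-off")

    end = min(n, i_td + 6)               # keep a few frames past touchdown
    sl = slice(0, end)

    def _marker(name, xs, zs):
        pos = np.column_stack([xs[sl], np.zeros(end), zs[sl]])
        if config.marker_noise_sd > 0:
            pos = pos + rng.normal(0.0, config.marker_noise_sd, pos.shape)
        return MarkerTrajectory(name, t[sl].copy(), pos)

    recording = HopRecording(
        hop_id=hop_id,
        animal_id=animal_id,
        treatment=treatment,
        platform_height=h,
        frame_rate=config.frame_rate,
        markers={
            "wrist": _marker("wrist", wx, wz),
            "mid_humerus": _marker("mid_humerus", hx, hz),
            "snout": _marker("snout", sx, sz),
        },
    )
    truth = HopGroundTruth(
        hop_id=hop_id, animal_id=animal_id, treatment=treatment,
        takeoff_speed=v0, takeoff_angle=theta,
        t0=float(t[i0]), liftoff=ti, touchdown=float(t[i_td]),
        gamma_td=float(gamma[i_td]), alpha_td=float(alpha[i_td]),
        delta_td=float(gamma[i_td] - alpha[i_td]),
        animal_intercept=animal_effect,
        times=t[sl].copy(), gamma=gamma[sl].copy(), alpha=alpha[sl].copy(),
    )
    return recording, truth


def simulate_cohort(
    config: HopSimConfig | None = None,
    seed: int | None = None,
) -> tuple[list[HopRecording], CohortGroundTruth]:
    """Simulate a full cohort: animals x treatments x hops, reproducibly.

    Per-animal random intercepts are drawn once; each hop gets its own
    deterministic substream derived from ``(seed, animal, treatment, hop)``,
    so the cohort is reproducible from the single seed and insensitive to
    generation order.
    """
    config = config or HopSimConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    master = np.random.default_rng(root.spawn(1)[0])

    animal_ids = [f"toad{i + 1:02d}" for i in range(config.n_animals)]
    intercepts = {
        a: (master.normal(0.0, config.delta_star_animal_sd)
            if config.delta_star_animal_sd > 0 else 0.0)
        for a in animal_ids
    }
    lo, hi = config.hops_per_treatment
    recordings: list[HopRecording] = []
    truths: list[HopGroundTruth] = []
    for ai, animal in enumerate(animal_ids):
        for tj, treatment in enumerate(config.treatments):
            n_hops = int(master.integers(lo, hi + 1))
            for k in range(n_hops):
                sub = np.random.default_rng(
                    np.random.SeedSequence((seed, ai, tj, k)))
                hop_id = f"{animal}_{treatment}_{k:02d}"
                rec, truth = simulate_hop(
                    config, intercepts[animal], sub,
                    treatment=treatment, hop_id=hop_id, animal_id=animal)
                recordings.append(rec)
                truths.append(truth)
    return recordings, CohortGroundTruth(
        hops=truths, animal_intercepts=intercepts, config=config, seed=seed)


def config_to_dict(config: HopSimConfig) -> dict:
    """Plain-dict echo of a config (for manifests and ground-truth files)."""
    return asdict(config)
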