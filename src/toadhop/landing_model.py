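"""Planar rigid-body torque model of a forelimb-first landing.

The body is reduced to a point mass (COM) with the forelimb as a rigid
segment making single-point ground contact.  At the instant of impact the
ground reaction force (GRF) is taken parallel to the impact velocity and
opposing it, so its direction is fixed by the impact angle gamma alone.
The net torque about the COM is then F x d, with d the perpendicular
distance from the COM to the GRF's line of action through the contact
point.  Torque is a static snapshot at impact: no impulse dynamics, no
angular velocity, no muscle action.

Sign conventions: x is the direction of travel, z up; gamma is negative
for a descending impact.  Positive torque pitches the body forward over
the contact point (nose-over in the direction of travel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


class NotALandingError(ValueError):
    """Raised when the impact angle does not describe a descending impact."""


@dataclass
class PlanarLander:
    """Geometry and loading of the simplified lander at impact."""

    com: tuple[float, float]        # (x, z) m, sagittal plane
    contact: tuple[float, float]    # (x, z) m; single manus contact, z = 0
    limb_length: float              # m
    grf_magnitude: float            # N
    impact_angle: float             # deg; gamma, descending negative
    arm_angle: float                # deg; alpha

    def __post_init__(self) -> None:
        if self.limb_length <= 0:
            raise ValueError("limb_length must be positive")
        if self.grf_magnitude < 0:
            raise ValueError("grf_magnitude must be >= 0")
        if abs(self.contact[1]) > 1e-9:
            raise ValueError("contact point must lie at ground level (z = 0)")


@dataclass
class TorqueResult:
    torque: float       # N m; positive = forward topple
    moment_arm: float   # m; perpendicular COM-to-GRF-line distance


def grf_direction(impact_angle: float) -> np.ndarray:
    """Unit GRF direction for a descending impact at ``impact_angle`` (deg).

    The GRF is parallel to the impact velocity and opposes it:
    -(cos(gamma), sin(gamma)).  Requires -180 < gamma < 0.
    """
    if not (-180.0 < impact_angle < 0.0):
        raise NotALandingError(
            f"not a landing: impact angle {impact_angle} deg is not "
            "descending")
    g = math.radians(impact_angle)
    return np.array([-math.cos(g), -math.sin(g)])


def net_torque(lander: PlanarLander) -> TorqueResult:
    """Net torque about the COM from the GRF at the contact point.

    torque = cross2(com - contact, F) with cross2(a, b) = a_x b_z - a_z b_x;
    the moment arm is |torque| / |F|.
    """
    u = grf_direction(lander.impact_angle)
    f = lander.grf_magnitude * u
    r = np.asarray(lander.com, dtype=float) - np.asarray(lander.contact,
                                                         dtype=float)
    torque = float(r[0] * f[1] - r[1] * f[0])
    # perpendicular distance from COM to the GRF line of action
    moment_arm = float(abs(r[0] * u[1] - r[1] * u[0]))
    return TorqueResult(torque=torque, moment_arm=moment_arm)


def _torque_at_alpha(alpha: float, com: np.ndarray, impact_angle: float,
                     limb_length: float, grf_magnitude: float) -> float:
    a = math.radians(alpha)
    contact = limb_length * np.array([math.cos(a), math.sin(a)])
    u = grf_direction(impact_angle)
    r = com - contact
    return grf_magnitude * float(r[0] * u[1] - r[1] * u[0])


def torque_minimizing_arm_angle(
    com_offset: tuple[float, float],
    impact_angle: float,
    limb_length: float,
    grf_magnitude: float = 1.0,
    bounds: tuple[float, float] = (-179.99, -0.01),
    tol: float = 1e-4,
) -> tuple[float, float]:
    """Arm angle minimizing |net torque| for a shoulder-anchored forelimb.

    The shoulder sits at the origin; the contact point is
    ``limb_length * (cos(alpha), sin(alpha))`` and the COM at
    ``com_offset`` from the shoulder.  Returns ``(alpha_deg,
    residual_torque)``: the |torque|-minimizing angle in ``bounds``
    (searched on a coarse grid, then refined to ``tol`` degrees) and the
    torque magnitude there.  When several angles achieve the minimum (the
    torque typically has two zero crossings), the one nearest the impact
    angle is returned.
    """
    com = np.asarray(com_offset, dtype=float)

    def f(alpha: float) -> float:
        return abs(_torque_at_alpha(alpha, com, impact_angle, limb_length,
                                    grf_magnitude))

    n_grid = int(round((bounds[1] - bounds[0]) / 0.1)) + 1
    grid = np.linspace(bounds[0], bounds[1], max(n_grid, 5))
    vals = np.array([f(a) for a in grid])
    # refine every local minimum of |torque| on the grid (plus endpoints)
    cand_idx = {0, len(grid) - 1}
    for i in range(1, len(grid) - 1):
        if vals[i] <= vals[i - 1] and vals[i] <= vals[i + 1]:
            cand_idx.add(i)
    candidates: list[tuple[float, float]] = []
    for i in sorted(cand_idx):
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi - lo < 1e-12:
            candidates.append((float(grid[i]), f(float(grid[i]))))
            continue
        res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                              options={"xatol": tol * 1e-2})
        candidates.append((float(res.x), float(res.fun)))
    best_val = min(v for _, v in candidates)
    scale = abs(grf_magnitude) * limb_length
    near_best = [(a, v) for a, v in candidates
                 if v <= best_val + 1e-9 * max(scale, 1.0)]
    # tie-break: nearest to the impact angle
    alpha_star, residual = min(near_best,
                               key=lambda av: abs(av[0] - impact_angle))
    return alpha_star, residual


def torque_map(alpha_grid, gamma_grid, com_offset, limb_length: float,
               grf_magnitude: float = 1.0) -> np.ndarray:
    """Torque over an (alpha, gamma) grid for strategy maps.

    Returns an array of shape ``(len(alpha_grid), len(gamma_grid))``.
    """
    com = np.asarray(com_offset, dtype=float)
    out = np.empty((len(alpha_grid), len(gamma_grid)))
    for i, a in enumerate(alpha_grid):
        for j, g in enumerate(gamma_grid):
            out[i, j] = _torque_at_alpha(float(a), com, float(g),
                                         limb_length, grf_magnitude)
    return out
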