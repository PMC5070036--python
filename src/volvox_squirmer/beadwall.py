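"""Orbiting-bead-near-wall model of a single beating flagellum.

A beating flagellum anchored on the (locally planar, no-slip) colony surface
is reduced to its crudest hydrodynamic caricature: a small sphere driven
around a circular orbit in a plane perpendicular to the wall.  Although the
bead's motion is periodic with zero mean displacement, the flow it creates
near a no-slip boundary does *not* average to zero over a beat, so passive
tracers trace closed-looking loops that drift steadily from beat to beat --
the mechanism by which a flagellum beating near the colony surface can pump
fluid on average.

The bead is a point force (Stokeslet) of strength ``6 pi mu a_b v(t)``
(its quasi-static Stokes drag), and the no-slip wall at ``z = 0`` is
enforced exactly with the classical image system for a Stokeslet near a
plane boundary: an image Stokeslet, a Stokes doublet and a source doublet
below the wall.  Passive tracers are advected through the resulting
time-dependent field with an adaptive high-order integrator, re-synchronised
to the orbit phase each beat.

Units: lengths um, time s, viscosity Pa s (viscosity cancels between drag
and propagator, but is kept for dimensional clarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BeadModelConfig",
    "TracerTrajectory",
    "wall_green_function",
    "bead_position",
    "bead_flow",
    "advect_tracers",
]


@dataclass(frozen=True)
class BeadModelConfig:
    """Parameters of the orbiting-bead model.

    The orbit lies in the ``x``-``z`` plane (perpendicular to the wall
    ``z = 0``), centred at height ``orbit_height`` above the wall.
    ``orbit_sense = +1`` drives the bead counter-clockwise when viewed from
    ``y > 0`` (moving in ``+x`` at the top of the orbit); ``-1`` reverses it.
    """

    bead_radius: float = 5.0  # um
    orbit_radius: float = 10.0  # um
    orbit_height: float = 20.0  # um, orbit-centre height above the wall
    sigma: float = 203.0  # rad/s beat frequency
    mu: float = 1.0e-3  # Pa s
    orbit_sense: int = 1
    orbit_center_x: float = 0.0
    orbit_phase: float = 0.0  # rad, starting phase of the orbit

    def __post_init__(self):
        if min(self.bead_radius, self.orbit_radius, self.orbit_height) <= 0:
            raise ValueError("bead radius, orbit radius and height must be positive")
        if self.orbit_height <= self.orbit_radius + self.bead_radius:
            raise ValueError(
                "orbit-centre height must exceed orbit radius + bead radius "
                "(no wall contact)"
            )
        if self.orbit_sense not in (-1, 1):
            raise ValueError("orbit_sense must be +1 or -1")

    @property
    def period(self) -> float:
        return 2 * np.pi / self.sigma


@dataclass(frozen=True)
class TracerTrajectory:
    """Per-beat samples of one advected tracer."""

    initial_position: np.ndarray
    positions: np.ndarray  # (n_beats + 1, 3): position at each beat boundary
    net_drift_per_beat: np.ndarray  # (3,): mean displacement per beat
    meta: dict = field(default_factory=dict)


def wall_green_function(x, y, F, mu: float = 1.0e-3):
    """Velocity at points ``x`` due to a point force ``F`` at ``y`` above a
    no-slip plane wall at ``z = 0``.

    Free-space Stokeslet plus the plane-wall image system (image Stokeslet,
    Stokes doublet, source doublet), so the velocity vanishes identically on
    the wall.  ``x`` may be ``(3,)`` or ``(m, 3)``; both ``x`` and ``y``
    must have ``z > 0``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    F = np.asarray(F, dtype=float)
    h = y[2]
    if h <= 0:
        raise ValueError("source must lie strictly above the wall (z > 0)")
    if np.any(x[:, 2] < -1e-12):
        raise ValueError("evaluation points must lie in the half-space z >= 0")
    ystar = np.array([y[0], y[1], -h])

    r = x - y
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn < 1e-12):
        raise ZeroDivisionError("evaluation at the Stokeslet singularity")
    R = x - ystar
    Rn = np.linalg.norm(R, axis=1)

    def stokeslet(d, dn):
        return (
            F[None, :] / dn[:, None]
            + d * (d @ F)[:, None] / dn[:, None] ** 3
        )

    u = stokeslet(r, rn) - stokeslet(R, Rn)

    # image corrections: 2 h M_jl d/dR_l [ h R_i/R^3 - (delta_i3/R + R_i R_3/R^3) ]
    # with M = diag(1, 1, -1) acting on the force index
    MF = F * np.array([1.0, 1.0, -1.0])
    R3 = R[:, 2]
    Rn3 = Rn**3
    Rn5 = Rn**5
    RdotMF = R @ MF
    # D_il MF_l assembled term by term (i indexes the output component)
    term = h * (MF[None, :] / Rn3[:, None] - 3.0 * R * RdotMF[:, None] / Rn5[:, None])
    e3 = np.zeros_like(R)
    e3[:, 2] = 1.0
    term += e3 * RdotMF[:, None] / Rn3[:, None]
    term -= MF[None, :] * R3[:, None] / Rn3[:, None]
    term -= R * MF[2] / Rn3[:, None]
    term += 3.0 * R * (R3 * RdotMF)[:, None] / Rn5[:, None]
    u = u + 2.0 * h * term
    return u / (8.0 * np.pi * mu)


def bead_position(config: BeadModelConfig, t):
    """Bead-centre position and velocity at time ``t``."""
    phi = config.orbit_sense * (
        config.sigma * np.asarray(t, dtype=float) + config.orbit_phase
    )
    c, s = np.cos(phi), np.sin(phi)
    pos = np.stack(
        [
            config.orbit_center_x + config.orbit_radius * s,
            np.zeros_like(phi),
            config.orbit_height + config.orbit_radius * c,
        ],
        axis=-1,
    )
    vel = config.orbit_sense * config.sigma * config.orbit_radius
    vel = vel * np.stack([c, np.zeros_like(phi), -s], axis=-1)
    return pos, vel


def bead_flow(config: BeadModelConfig, t: float, points, strict: bool = True):
    """Instantaneous velocity at ``points`` of the flow driven by the
    orbiting bead (point-force approximation with wall images).

    With ``strict=True``, points inside the nominal bead radius are
    rejected; tracer advection relaxes this (the point force is defined
    everywhere away from its singularity, and the model is only qualitative
    near the bead anyway).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    y, v = bead_position(config, t)
    if strict:
        d = np.linalg.norm(points - y[None, :], axis=1)
        if np.any(d < config.bead_radius):
            raise ValueError("evaluation point inside the bead")
    Fdrive = 6.0 * np.pi * config.mu * config.bead_radius * v
    return wall_green_function(points, y, Fdrive, mu=config.mu)


def advect_tracers(
    config: BeadModelConfig,
    initial_positions,
    n_beats: int = 100,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    samples_per_beat: int = 1,
):
    """Advect passive tracers through the bead's time-dependent flow.

    Integrates beat by beat (re-synchronising to the orbit phase), recording
    positions at each beat boundary (and optionally within the beat).
    Returns a list of :class:`TracerTrajectory`.  A tracer reaching the wall
    raises a diagnostic error.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    X0 = np.atleast_2d(np.asarray(initial_positions, dtype=float))
    if np.any(X0[:, 2] <= 0):
        raise ValueError("tracers must start above the wall (z > 0)")
    period = config.period
    out = []
    for x0 in X0:
        pos = np.empty((n_beats + 1, 3))
        pos[0] = x0
        cur = x0.copy()

        def rhs(t, xx):
            # intermediate integrator stages may dip infinitesimally below the
            # wall, where the true velocity vanishes; clamp for evaluation
            pt = xx.copy()
            pt[2] = max(pt[2], 1e-9)
            return bead_flow(config, t, pt[None, :], strict=False)[0]

        for b in range(n_beats):
            t_eval = (
                None
                if samples_per_beat <= 1
                else b * period + np.linspace(0, period, samples_per_beat + 1)
            )
            sol = solve_ivp(
                rhs,
                (b * period, (b + 1) * period),
                cur,
                method="DOP853",
                rtol=rtol,
                atol=atol,
                t_eval=t_eval,
                dense_output=False,
            )
            if not sol.success:
                raise RuntimeError(f"tracer integration failed in beat {b}: {sol.message}")
            cur = sol.y[:, -1].copy()
            if cur[2] <= 0:
                raise RuntimeError(
                    f"tracer crossed the wall during beat {b} at {cur}; "
                    "reduce tolerances or move the seed away from the wall"
                )
            pos[b + 1] = cur
        drift = (pos[-1] - pos[0]) / n_beats
        out.append(
            TracerTrajectory(
                initial_position=x0,
                positions=pos,
                net_drift_per_beat=drift,
                meta={"n_beats": n_beats, "rtol": rtol, "atol": atol},
            )
        )
    return out
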