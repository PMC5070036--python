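"""Finite-amplitude boundary-collocation solver (independent cross-check).

The closed-form second-order means in :mod:`volvox_squirmer.meanflow` rest
on a perturbation expansion in the beat amplitude.  This module solves the
same free-swimming problem *without* that expansion: at each instant the
force-free exterior eigenfunction series is fitted, by least squares at
collocation points, to the material velocity of the *displaced* envelope

    ``r = R(theta0, t) = a (1 + alpha)``,   ``theta = theta0 + B``,

so the instantaneous swimming speed ``U(t)`` and rotation rate ``Omega(t)``
contain all orders in the amplitude.  Averaging them numerically over one
beat period gives an independent estimate of ``Ubar_2`` and ``Omegabar_2``
whose relative deviation from the closed forms must vanish as the amplitude
does.  It shares no code path with the closed-form routes beyond the basis
functions themselves.

The azimuthal problem is solved in the same way: the swirl series (with the
rotlet excluded, i.e. torque-free) plus the unknown rigid rotation ``Omega``
is fitted to ``R sin(Theta) dPhi/dt`` at the displaced points.
"""

from __future__ import annotations

import numpy as np

from . import spectral
from .envelope import ColonyGeometry, EnvelopeModeSeries

__all__ = ["instantaneous_swim_state", "period_averaged_means"]


def _displacement_fields(env: EnvelopeModeSeries, theta0, t):
    """alpha (radial, units of a), B (angular), dalpha/dt, dB/dt, dC/dt."""
    ph = np.exp(-1j * env.sigma * t)
    P = np.array(
        [np.asarray(spectral.legendre_P(n, np.cos(theta0))) for n in range(env.N + 1)]
    )
    V = np.zeros_like(P)
    for n in range(1, env.N + 1):
        V[n] = np.asarray(spectral.tangential_V(n, theta0))
    alpha = np.real(np.tensordot(env.a_hat * ph, P, axes=(0, 0)))
    B = np.real(np.tensordot(env.b_hat * ph, V, axes=(0, 0)))
    dt = -1j * env.sigma
    alphadot = np.real(np.tensordot(dt * env.a_hat * ph, P, axes=(0, 0)))
    Bdot = np.real(np.tensordot(dt * env.b_hat * ph, V, axes=(0, 0)))
    Cdot = np.real(np.tensordot(dt * env.c_hat * ph, V, axes=(0, 0)))
    return alpha, B, alphadot, Bdot, Cdot


def instantaneous_swim_state(
    env: EnvelopeModeSeries,
    g: ColonyGeometry,
    t: float,
    N_solve: int | None = None,
    n_colloc: int | None = None,
    include_A0: bool = True,
):
    """Fit the exterior series to the displaced-envelope material velocity
    at time ``t``; return ``(U, Omega)`` in (um/s, rad/s)."""
    a = g.a
    if N_solve is None:
        N_solve = env.N + 10
    if n_colloc is None:
        n_colloc = 2 * N_solve + 20
    x, _ = np.polynomial.legendre.leggauss(n_colloc)
    theta0 = np.arccos(x)

    alpha, B, alphadot, Bdot, Cdot = _displacement_fields(env, theta0, t)
    R = a * (1.0 + alpha)
    Theta = theta0 + B
    s = a / R
    xTh = np.cos(Theta)
    sinTh = np.sin(Theta)

    P = np.array([np.asarray(spectral.legendre_P(n, xTh)) for n in range(N_solve + 1)])
    V = np.zeros_like(P)
    for n in range(1, N_solve + 1):
        V[n] = np.asarray(spectral.tangential_V(n, Theta))

    # --- polar problem: unknowns [S0, X1, U, (X_n, Y_n) n = 2..N_solve]
    ncols = 3 + 2 * (N_solve - 1)
    M = np.zeros((2 * n_colloc, ncols))
    if include_A0:
        M[:n_colloc, 0] = s**2  # source
    M[:n_colloc, 1] = s**3 * P[1]
    M[n_colloc:, 1] = 0.5 * s**3 * V[1]
    M[:n_colloc, 2] = -P[1]  # -U cos(theta)
    M[n_colloc:, 2] = V[1]
    col = 3
    for n in range(2, N_solve + 1):
        M[:n_colloc, col] = s ** (n + 2) * P[n]
        M[n_colloc:, col] = (n / 2.0) * s ** (n + 2) * V[n]
        M[:n_colloc, col + 1] = s**n * P[n]
        M[n_colloc:, col + 1] = ((n - 2) / 2.0) * s**n * V[n]
        col += 2
    rhs = np.concatenate([a * alphadot, R * Bdot])
    sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    U = sol[2]

    # --- azimuthal problem: unknowns [Omega, D_n n = 2..N_solve]
    Mphi = np.zeros((n_colloc, N_solve))
    Mphi[:, 0] = -R * sinTh  # -Omega R sin(Theta) moved to the left side
    for n in range(2, N_solve + 1):
        Mphi[:, n - 1] = s ** (n + 1) * V[n]
    # material azimuthal velocity relative to the body: R sin(Theta) Cdot/sin(theta0)
    rhs_phi = R * sinTh * Cdot / np.sin(theta0)
    solp, *_ = np.linalg.lstsq(Mphi, rhs_phi, rcond=None)
    Omega = solp[0]
    return U, Omega


def period_averaged_means(
    env: EnvelopeModeSeries,
    g: ColonyGeometry,
    n_times: int = 32,
    include_A0: bool = True,
    **kwargs,
):
    """Beat-averaged ``(Ubar, Omegabar)`` from the finite-amplitude solver,
    by uniform (spectrally accurate, periodic) time quadrature."""
    period = 2 * np.pi / env.sigma
    times = np.arange(n_times) * period / n_times
    U = np.empty(n_times)
    W = np.empty(n_times)
    for i, t in enumerate(times):
        U[i], W[i] = instantaneous_swim_state(
            env, g, t, include_A0=include_A0, **kwargs
        )
    return U.mean(), W.mean()
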