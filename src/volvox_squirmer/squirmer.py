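"""First-order Stokes-flow solution for the squirmer with swirl.

The exterior flow around the envelope sphere ``r = a`` is written as the
axisymmetric eigenfunction series (body frame, flow ``-> -U e_z`` far away)::

    u_r     = -U P_1 + A_0 (a/r)^2 + (2/3)(A_1+B_1)(a/r)^3 P_1
              + sum_{n>=2} [ X_n (a/r)^{n+2} + Y_n (a/r)^n ] P_n
    u_theta =  U V_1 + (1/3)(A_1+B_1)(a/r)^3 V_1
              + sum_{n>=2} [ n/2 X_n (a/r)^{n+2} + (n-2)/2 Y_n (a/r)^n ] V_n
    u_phi   =  sum_{n>=2} C_n (a/r)^{n+1} V_n

with ``X_n = B_n - (n/2-1) A_n`` and ``Y_n = n/2 A_n - B_n``, so that on the
sphere ``u_r = sum A_n P_n``, ``u_theta = sum B_n V_n`` and the azimuthal
slip (relative to the rotating body) is ``sum C_n V_n``.  The ``Y_1`` branch
is the Stokeslet and the ``n = 1`` swirl branch is the rotlet; setting both
to zero (force- and torque-free swimming) fixes

    ``U = (2 B_1 - A_1) / 3``      and      ``Omega = -C_1 / a``.

At first order in the beat amplitude every coefficient is time-harmonic,
``A_n(t) = Re[A_n_hat e^{-i sigma t}]``, and both ``U(t)`` and ``Omega(t)``
have zero mean; the non-zero means appear at second order (see
:mod:`volvox_squirmer.meanflow`).

The instantaneous rate of working of the envelope on the fluid is the
quadratic form (derived from the surface tractions of the series above)::

    P / (pi mu a) = 16 A_0^2 + (16/3)(A_1 + B_1)^2
        + sum_{n>=2} [ 4(2n^2+3n+4)/((n+1)(2n+1)) A_n^2
                       + 48/((n+1)(2n+1)) A_n B_n + 16/(n(n+1)) B_n^2 ]
        + sum_{n>=2} 16 (n+2) / (n (n+1)(2n+1)) C_n^2

whose swirl part is non-negative mode by mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import spectral
from .envelope import ColonyGeometry, EnvelopeModeSeries, WaveParameters

__all__ = [
    "ModeCoefficientSet",
    "FlowFieldGrid",
    "first_order_coefficients",
    "instantaneous_field",
    "kymograph",
    "mean_power",
    "instantaneous_power",
    "rigid_rotation_projection",
    "reciprocal_theorem_rotation",
]

#: unit conversion: (um/s)^2 * um * Pa s  ->  W
_UM3_TO_M3 = 1e-18


@dataclass(frozen=True)
class ModeCoefficientSet:
    """Time-harmonic mode amplitudes of the first-order solution.

    Arrays indexed by mode number ``n = 0..N`` (``B_hat[0] = C_hat[0] = 0``);
    units um/s.  ``C_hat`` holds the azimuthal *slip* amplitudes (envelope
    motion relative to the rotating body).
    """

    N: int
    sigma: float
    a: float
    A_hat: np.ndarray
    B_hat: np.ndarray
    C_hat: np.ndarray
    include_A0: bool = True
    order: str = "first-order"

    @property
    def U_hat(self) -> complex:
        """Harmonic amplitude of the instantaneous swimming speed [um/s]."""
        return (2.0 * self.B_hat[1] - self.A_hat[1]) / 3.0

    @property
    def Omega_hat(self) -> complex:
        """Harmonic amplitude of the instantaneous rotation rate [rad/s]."""
        return -self.C_hat[1] / self.a

    def U(self, t):
        return np.real(self.U_hat * np.exp(-1j * self.sigma * np.asarray(t)))

    def Omega(self, t):
        return np.real(self.Omega_hat * np.exp(-1j * self.sigma * np.asarray(t)))


def first_order_coefficients(
    env: EnvelopeModeSeries,
    g: ColonyGeometry,
    w: WaveParameters | None = None,
    include_A0: bool = True,
) -> ModeCoefficientSet:
    """Leading-order matching: surface-velocity amplitudes are the time
    derivatives of the displacement amplitudes, ``A_n = a da_n/dt`` etc.

    With ``a_n(t) = Re[a_hat e^{-i sigma t}]`` this is multiplication by
    ``-i sigma``; ``include_A0=False`` drops the volume-change mode ``A_0``
    (the choice of Blake rather than Lighthill).
    """
    if env.N < 2:
        raise ValueError("envelope truncation N must be >= 2")
    factor = -1j * env.sigma * g.a
    A_hat = factor * env.a_hat.astype(complex)
    B_hat = factor * env.b_hat.astype(complex)
    C_hat = factor * env.c_hat.astype(complex)
    if not include_A0:
        A_hat = A_hat.copy()
        A_hat[0] = 0.0
    return ModeCoefficientSet(
        N=env.N,
        sigma=env.sigma,
        a=g.a,
        A_hat=A_hat,
        B_hat=B_hat,
        C_hat=C_hat,
        include_A0=include_A0,
    )


@dataclass(frozen=True)
class FlowFieldGrid:
    """Velocity components on an ``(r, theta, t)`` grid, units um/s."""

    r: np.ndarray
    theta: np.ndarray
    t: np.ndarray
    u_r: np.ndarray
    u_theta: np.ndarray
    u_phi: np.ndarray
    frame: str = "lab"
    meta: dict = field(default_factory=dict)

    def to_dataframe(self):
        """Long-format table with columns r, theta, t, u_r, u_theta, u_phi."""
        import pandas as pd

        R, TH, T = np.meshgrid(self.r, self.theta, self.t, indexing="ij")
        return pd.DataFrame(
            {
                "r": R.ravel(),
                "theta": TH.ravel(),
                "t": T.ravel(),
                "u_r": self.u_r.ravel(),
                "u_theta": self.u_theta.ravel(),
                "u_phi": self.u_phi.ravel(),
            }
        )


def field_amplitudes(coeffs: ModeCoefficientSet, r, theta, frame: str = "lab"):
    """Complex harmonic amplitudes ``(u_r_hat, u_theta_hat, u_phi_hat)`` of
    the first-order field at points ``(r, theta)`` (broadcastable arrays).

    ``frame='lab'``: fluid at rest at infinity (the decaying series alone).
    ``frame='body'``: frame translating with the colony; adds the uniform
    stream ``-U e_z``.
    """
    a = coeffs.a
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(r < a * (1 - 1e-12)):
        raise ValueError("field evaluation requires r >= a")
    r, theta = np.broadcast_arrays(r, theta)
    x = np.cos(theta)
    s = a / r
    A, B, C = coeffs.A_hat, coeffs.B_hat, coeffs.C_hat
    ur = A[0] * s**2 * np.ones_like(x)
    ut = np.zeros_like(x, dtype=complex)
    up = np.zeros_like(x, dtype=complex)
    x1 = (2.0 / 3.0) * (A[1] + B[1])
    ur = ur + x1 * s**3 * x
    ut = ut + 0.5 * x1 * s**3 * np.sin(theta)
    for n in range(2, coeffs.N + 1):
        Xn = B[n] - (n / 2.0 - 1.0) * A[n]
        Yn = n / 2.0 * A[n] - B[n]
        Pn = np.asarray(spectral.legendre_P(n, x))
        Vn = np.asarray(spectral.tangential_V(n, theta))
        ur = ur + (Xn * s ** (n + 2) + Yn * s**n) * Pn
        ut = ut + (n / 2.0 * Xn * s ** (n + 2) + (n - 2) / 2.0 * Yn * s**n) * Vn
        up = up + C[n] * s ** (n + 1) * Vn
    if frame == "body":
        U = coeffs.U_hat
        ur = ur - U * x
        ut = ut + U * np.sin(theta)
    elif frame != "lab":
        raise ValueError("frame must be 'lab' or 'body'")
    return ur, ut, up


def instantaneous_field(
    coeffs: ModeCoefficientSet,
    r,
    theta,
    t,
    frame: str = "lab",
) -> FlowFieldGrid:
    """Evaluate the first-order unsteady field on the tensor grid
    ``r x theta x t`` (``r >= a``)."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ur_h, ut_h, up_h = field_amplitudes(
        coeffs, r[:, None], theta[None, :], frame=frame
    )
    phase = np.exp(-1j * coeffs.sigma * t)[None, None, :]
    return FlowFieldGrid(
        r=r,
        theta=theta,
        t=t,
        u_r=np.real(ur_h[..., None] * phase),
        u_theta=np.real(ut_h[..., None] * phase),
        u_phi=np.real(up_h[..., None] * phase),
        frame=frame,
        meta={"N": coeffs.N, "sigma": coeffs.sigma, "a": coeffs.a},
    )


def kymograph(
    coeffs: ModeCoefficientSet,
    r_eval: float,
    theta=None,
    t=None,
    frame: str = "lab",
):
    """Space-time maps of ``u_r`` and ``u_theta`` at fixed radius ``r_eval``
    over one beat period.  Returns ``(theta, t, u_r, u_theta)`` with arrays
    shaped ``(len(theta), len(t))``."""
    if r_eval <= coeffs.a:
        raise ValueError("kymograph radius must exceed the envelope radius a")
    period = 2 * np.pi / coeffs.sigma
    if theta is None:
        theta = np.linspace(0.0, np.pi, 181)
    if t is None:
        t = np.linspace(0.0, period, 101)
    grid = instantaneous_field(coeffs, np.atleast_1d(r_eval), theta, t, frame=frame)
    return np.asarray(theta), np.asarray(t), grid.u_r[0], grid.u_theta[0]


# ----------------------------------------------------------------------------
# rate of working
# ----------------------------------------------------------------------------

def _power_coeff_arrays(N):
    n = np.arange(2, N + 1)
    c_AA = 4.0 * (2 * n**2 + 3 * n + 4) / ((n + 1) * (2 * n + 1))
    c_AB = 48.0 / ((n + 1) * (2 * n + 1))
    c_BB = 16.0 / (n * (n + 1))
    c_CC = 16.0 * (n + 2) / (n * (n + 1) * (2 * n + 1))
    return n, c_AA, c_AB, c_BB, c_CC


def instantaneous_power(coeffs: ModeCoefficientSet, g: ColonyGeometry, t) -> float:
    """Instantaneous rate of working of the envelope on the fluid [W]."""
    ph = np.exp(-1j * coeffs.sigma * t)
    A = np.real(coeffs.A_hat * ph)
    B = np.real(coeffs.B_hat * ph)
    C = np.real(coeffs.C_hat * ph)
    _, c_AA, c_AB, c_BB, c_CC = _power_coeff_arrays(coeffs.N)
    An, Bn, Cn = A[2:], B[2:], C[2:]
    total = 16.0 * A[0] ** 2 + (16.0 / 3.0) * (A[1] + B[1]) ** 2
    total += np.sum(c_AA * An**2 + c_AB * An * Bn + c_BB * Bn**2 + c_CC * Cn**2)
    return np.pi * g.mu * g.a * total * _UM3_TO_M3


def mean_power(coeffs: ModeCoefficientSet, g: ColonyGeometry):
    """Beat-averaged rate of working, total and swirl part, in watts.

    Time averages of harmonic products use ``<Re[X e^{-i s t}] Re[Y e^{-i s
    t}]> = Re[X conj(Y)]/2``.  Returns ``(P_mean, P_swirl_mean)``;
    the swirl part is non-negative.
    """
    A, B, C = coeffs.A_hat, coeffs.B_hat, coeffs.C_hat
    _, c_AA, c_AB, c_BB, c_CC = _power_coeff_arrays(coeffs.N)
    An, Bn, Cn = A[2:], B[2:], C[2:]
    polar = 16.0 * 0.5 * abs(A[0]) ** 2 + (16.0 / 3.0) * 0.5 * abs(A[1] + B[1]) ** 2
    polar += np.sum(
        c_AA * 0.5 * np.abs(An) ** 2
        + c_AB * 0.5 * np.real(An * np.conj(Bn))
        + c_BB * 0.5 * np.abs(Bn) ** 2
    )
    swirl = np.sum(c_CC * 0.5 * np.abs(Cn) ** 2)
    scale = np.pi * g.mu * g.a * _UM3_TO_M3
    return scale * (polar + swirl), scale * swirl


# ----------------------------------------------------------------------------
# reciprocal theorem
# ----------------------------------------------------------------------------

def rigid_rotation_projection(u_phi_of_theta, a: float, n_nodes: int = 200) -> float:
    """Project a surface azimuthal velocity onto rigid rotation about the
    symmetry axis:

        ``omega = (3 / (8 pi a^3)) * surface_integral(u_phi sin(theta))``
              ``= (3 / (4 a)) * int_0^pi u_phi(theta) sin^2(theta) d theta``.

    For the surface velocity of a rigidly rotating sphere this returns
    exactly its rotation rate; for a purely meridional velocity it is zero.
    """
    x, wts = np.polynomial.legendre.leggauss(n_nodes)
    theta = np.arccos(x)
    vals = np.asarray(u_phi_of_theta(theta), dtype=float)
    return 3.0 / (4.0 * a) * np.sum(wts * vals * np.sin(theta))


def reciprocal_theorem_rotation(slip_u_phi, a: float, n_nodes: int = 200) -> float:
    """Instantaneous rotation rate of a torque-free sphere from the surface
    integral of its azimuthal slip (the Stone--Samuel shortcut):

        ``Omega = -(3 / (8 pi a^3)) * surface_integral(n x u_slip)_z``

    ``slip_u_phi`` is a callable ``theta -> u_phi`` giving the envelope's
    azimuthal velocity relative to the rotating body, on ``r = a``.
    Equals the series result ``Omega = -C_1 / a`` to quadrature accuracy.
    """
    return -rigid_rotation_projection(slip_u_phi, a, n_nodes=n_nodes)
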