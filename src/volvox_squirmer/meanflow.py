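"""Second-order mean swimming speed, rotation rate, power and efficiency.

At first order the envelope's oscillation produces zero-mean translation and
rotation.  The non-zero means arise at second order in the beat amplitude
``eps``, from two quadratic couplings:

* products of first-order *material* motions (e.g. the tangential velocity
  ``R dTheta/dt`` picks up ``a alpha dB/dt`` where ``alpha`` is the radial
  and ``B`` the angular displacement field), and
* the transfer of the boundary condition from the displaced envelope to the
  mean sphere ``r = a`` (Taylor terms ``-(R-a) du/dr - (Theta-theta0)
  du/dtheta`` of the first-order field).

Averaging over a beat leaves a steady effective slip on the mean sphere.
Force-free and torque-free swimming then give the means by projecting that
slip onto the ``n = 1`` modes:

    ``Ubar_2     = (2 Bbar_1 - Abar_1) / 3``
    ``Omegabar_2 = -(3 / 4a) <M_phi, V_1>``

where ``Abar_1, Bbar_1`` are the ``P_1``/``V_1`` projections of the mean
radial/tangential effective slip and ``M_phi`` is the mean azimuthal one.

Two independent evaluation routes are provided and cross-checked:

``method='modal'``
    Explicit bilinear sums over mode pairs, with the projection integrals
    taken from the closed-form Legendre product-integral table
    (:func:`volvox_squirmer.spectral.product_integral`).
``method='quadrature'``
    Pointwise assembly of the time-averaged effective-slip functions on a
    Gauss--Legendre grid and direct numerical projection.

Both routes are validated against a third, fully independent oracle: the
finite-amplitude boundary-collocation solver of
:mod:`volvox_squirmer.collocation`, numerically time-averaged over a beat.

Efficiency follows Lighthill: ``E = 6 pi mu a Ubar_2^2 / Pbar``, the power a
rigid sphere would need to be dragged at the mean speed over the actual mean
rate of working.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import spectral, squirmer
from .envelope import ColonyGeometry, EnvelopeModeSeries, WaveParameters, envelope_modes
from .exceptions import ConvergenceError

__all__ = [
    "SwimSummary",
    "second_order_means",
    "mean_swimming_speed",
    "mean_angular_velocity",
    "power_and_efficiency",
    "swim_summary",
]

_SI_LENGTH = 1e-6  # um -> m


@dataclass(frozen=True)
class SwimSummary:
    """Second-order mean swimming quantities for one colony."""

    Ubar2: float  # mean swimming speed, um/s (positive: toward theta = 0)
    Omegabar2: float  # mean angular velocity, rad/s (sign follows beta)
    Pbar: float  # mean rate of working, W
    Pbar_swirl: float  # swirl contribution to Pbar, W (>= 0)
    efficiency: float  # Lighthill mechanical efficiency, dimensionless
    N: int
    include_A0: bool = True
    method: str = "modal"
    convergence: dict = field(default_factory=dict)


# ----------------------------------------------------------------------------
# first-order surface series needed by both routes
# ----------------------------------------------------------------------------

class _FirstOrderSurface:
    """Complex harmonic coefficient arrays of the first-order fields and
    their radial/tangential surface gradients, indexed by mode number.

    Attributes ending in ``_P`` multiply ``P_n``, ``_V`` multiply ``V_n`` and
    ``_dV`` multiply ``dV_n/dtheta``.  Units: displacements in um (alpha is
    dimensionless, B in rad), velocities um/s, gradients 1/s.
    """

    def __init__(self, env: EnvelopeModeSeries, g: ColonyGeometry, include_A0: bool):
        N, a, sigma = env.N, g.a, env.sigma
        self.N, self.a = N, a
        dt = -1j * sigma
        a_hat = env.a_hat.copy()
        if not include_A0:
            a_hat[0] = 0.0
        # displacement fields (dimensionless / rad) and their rates (1/s)
        self.alpha_P = a_hat
        self.B_V = env.b_hat
        self.Bdot_V = dt * env.b_hat
        self.Cdot_V = dt * env.c_hat
        # first-order velocity coefficients (um/s)
        A = dt * a * a_hat
        B = dt * a * env.b_hat
        C = dt * a * env.c_hat
        self.A, self.B, self.C = A, B, C
        self.U = (2.0 * B[1] - A[1]) / 3.0
        self.Omega1 = -C[1] / a  # rad/s
        n = np.arange(N + 1)
        # surface gradients of the field (see squirmer module for the series)
        self.dur_dr_P = -(2.0 / a) * (A + B)
        self.dur_dth_V = -(n * (n + 1) / 2.0) * A
        dut = np.zeros(N + 1, dtype=complex)
        dut[1] = -(A[1] + B[1]) / a
        nn = n[2:]
        dut[2:] = -(nn / (2.0 * a)) * (4.0 * B[2:] - (nn - 2) * A[2:])
        self.dut_dr_V = dut
        self.dut_dth_dV = B.copy()
        dup = np.zeros(N + 1, dtype=complex)
        dup[2:] = -((nn + 1) / a) * C[2:]
        self.dup_dr_V = dup
        dup_th = C.copy()
        dup_th[1] = 0.0  # torque-free: the field has no n = 1 swirl mode
        self.dup_dth_dV = dup_th
        self.up_V = dup_th  # surface u_phi in the lab frame


def _mean_bilinear_modal(p, q, kind):
    """``<mean[ (sum p_n F_n)(sum q_m G_m) ], projector>`` via the
    closed-form product-integral table ``kind``."""
    total = 0.0
    N = len(p) - 1
    for n in range(N + 1):
        if p[n] == 0:
            continue
        for m in range(N + 1):
            if q[m] == 0:
                continue
            K = spectral.product_integral(kind, n, m) if _valid(kind, n, m) else 0.0
            if K:
                total += K * 0.5 * np.real(p[n] * np.conj(q[m]))
    return total


def _valid(kind, n, m):
    if kind in ("PP", "PP_cos"):
        return True
    if kind == "PV":
        return m >= 1
    return n >= 1 and m >= 1


# ----------------------------------------------------------------------------
# modal route
# ----------------------------------------------------------------------------

def _means_modal(s: _FirstOrderSurface):
    a = s.a
    # --- azimuthal: <M_phi, V_1>, kernels against the V_1 projector
    m_phi = 0.0
    # material: a alpha Cdot  +  a B Cdot cos/sin  + a sin alpha Omega1 + a B cos Omega1
    m_phi += a * _mean_bilinear_modal(s.alpha_P, s.Cdot_V, "PV")
    m_phi += a * _mean_bilinear_modal(s.B_V, s.Cdot_V, "VV_cos")
    om = np.zeros_like(s.alpha_P)
    om[1] = s.Omega1
    m_phi += a * _mean_bilinear_modal(s.alpha_P, om, "PV")  # sin theta = V_1
    m_phi += a * _mean_bilinear_modal(s.B_V, om, "VV_cos")
    # transfer: -(a alpha du_phi/dr + B du_phi/dtheta)
    m_phi -= a * _mean_bilinear_modal(s.alpha_P, s.dup_dr_V, "PV")
    m_phi -= _mean_bilinear_modal(s.B_V, s.dup_dth_dV, "VdV")
    Omegabar2 = -(3.0 / (4.0 * a)) * m_phi

    # --- radial: <M_r, P_1>
    m_r = 0.0
    m_r -= a * _mean_bilinear_modal(s.alpha_P, s.dur_dr_P, "PP_cos")
    m_r -= _mean_bilinear_modal(s.B_V, s.dur_dth_V, "VV_cos")
    Abar1 = 1.5 * m_r

    # --- tangential: <M_theta, V_1>
    m_t = a * _mean_bilinear_modal(s.alpha_P, s.Bdot_V, "PV")
    m_t -= a * _mean_bilinear_modal(s.alpha_P, s.dut_dr_V, "PV")
    m_t -= _mean_bilinear_modal(s.B_V, s.dut_dth_dV, "VdV")
    Bbar1 = 0.75 * m_t

    Ubar2 = (2.0 * Bbar1 - Abar1) / 3.0
    return Ubar2, Omegabar2


# ----------------------------------------------------------------------------
# quadrature route
# ----------------------------------------------------------------------------

def _series_eval(coeffs, basis, theta):
    out = np.zeros_like(theta, dtype=complex)
    for n in range(len(coeffs)):
        if coeffs[n] == 0:
            continue
        if basis == "P":
            out += coeffs[n] * np.asarray(spectral.legendre_P(n, np.cos(theta)))
        elif basis == "V":
            out += coeffs[n] * np.asarray(spectral.tangential_V(n, theta))
        else:  # dV
            out += coeffs[n] * np.asarray(spectral.tangential_V_theta_deriv(n, theta))
    return out


def _means_quadrature(s: _FirstOrderSurface, n_nodes: int | None = None):
    a = s.a
    if n_nodes is None:
        n_nodes = max(4 * s.N + 16, 64)
    x, wts = np.polynomial.legendre.leggauss(n_nodes)
    th = np.arccos(x)
    sin, cos = np.sin(th), x

    alpha = _series_eval(s.alpha_P, "P", th)
    B = _series_eval(s.B_V, "V", th)
    Bdot = _series_eval(s.Bdot_V, "V", th)
    Cdot = _series_eval(s.Cdot_V, "V", th)
    dur_dr = _series_eval(s.dur_dr_P, "P", th)
    dur_dth = _series_eval(s.dur_dth_V, "V", th)
    dut_dr = _series_eval(s.dut_dr_V, "V", th)
    dut_dth = _series_eval(s.dut_dth_dV, "dV", th)
    dup_dr = _series_eval(s.dup_dr_V, "V", th)
    dup_dth = _series_eval(s.dup_dth_dV, "dV", th)

    def mean(Xh, Yh):
        return 0.5 * np.real(Xh * np.conj(Yh))

    M_phi = (
        a * mean(alpha, Cdot)
        + a * mean(B, Cdot) * cos / sin
        + a * sin * mean(alpha, np.full_like(alpha, s.Omega1))
        + a * cos * mean(B, np.full_like(B, s.Omega1))
        - a * mean(alpha, dup_dr)
        - mean(B, dup_dth)
    )
    M_r = -a * mean(alpha, dur_dr) - mean(B, dur_dth)
    M_t = a * mean(alpha, Bdot) - a * mean(alpha, dut_dr) - mean(B, dut_dth)

    # integrals over theta with measure sin dtheta = Gauss-Legendre in x
    Omegabar2 = -(3.0 / (4.0 * a)) * np.sum(wts * M_phi * sin)
    Abar1 = 1.5 * np.sum(wts * M_r * cos)
    Bbar1 = 0.75 * np.sum(wts * M_t * sin)
    Ubar2 = (2.0 * Bbar1 - Abar1) / 3.0
    return Ubar2, Omegabar2


# ----------------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------------

def second_order_means(
    env: EnvelopeModeSeries,
    g: ColonyGeometry,
    include_A0: bool = True,
    method: str = "modal",
):
    """Mean swimming speed [um/s] and angular velocity [rad/s] at second
    order in the beat amplitude.  ``method`` selects the evaluation route
    ('modal' bilinear sums or direct 'quadrature' projection)."""
    s = _FirstOrderSurface(env, g, include_A0)
    if method == "modal":
        return _means_modal(s)
    if method == "quadrature":
        return _means_quadrature(s)
    raise ValueError("method must be 'modal' or 'quadrature'")


def mean_swimming_speed(
    env: EnvelopeModeSeries,
    g: ColonyGeometry,
    include_A0: bool = True,
    method: str = "modal",
) -> float:
    """Time-averaged second-order swimming speed ``Ubar_2`` [um/s]."""
    return second_order_means(env, g, include_A0, method)[0]


def mean_angular_velocity(
    env: EnvelopeModeSeries,
    g: ColonyGeometry,
    include_A0: bool = True,
    method: str = "modal",
) -> float:
    """Time-averaged second-order rotation rate ``Omegabar_2`` [rad/s]."""
    return second_order_means(env, g, include_A0, method)[1]


def power_and_efficiency(
    env: EnvelopeModeSeries,
    g: ColonyGeometry,
    include_A0: bool = True,
    Ubar2: float | None = None,
):
    """Mean rate of working ``Pbar`` [W], its swirl part, and the Lighthill
    efficiency ``E = 6 pi mu a Ubar_2^2 / Pbar``."""
    coeffs = squirmer.first_order_coefficients(env, g, include_A0=include_A0)
    Pbar, Pswirl = squirmer.mean_power(coeffs, g)
    if Pbar <= 0 and env.epsilon > 0:
        raise RuntimeError("mean rate of working must be positive for eps > 0")
    if Ubar2 is None:
        Ubar2 = mean_swimming_speed(env, g, include_A0)
    drag_power = 6.0 * np.pi * g.mu * (g.a * _SI_LENGTH) * (Ubar2 * _SI_LENGTH) ** 2
    eff = drag_power / Pbar if Pbar > 0 else np.nan
    return Pbar, Pswirl, eff


def swim_summary(
    w: WaveParameters,
    g: ColonyGeometry,
    N: int = 25,
    include_A0: bool = True,
    method: str = "modal",
    conv_tol: float | None = None,
    conv_step: int = 5,
) -> SwimSummary:
    """Full second-order summary for one colony.

    Builds the envelope series at truncations ``N`` and ``N + conv_step``
    and records the relative change of ``Ubar_2`` and ``Omegabar_2`` as a
    convergence diagnostic.  If ``conv_tol`` is given and the change
    exceeds it, :class:`ConvergenceError` is raised with the trace.
    """
    env = envelope_modes(w, g, N)
    U2, W2 = second_order_means(env, g, include_A0, method)
    env_hi = envelope_modes(w, g, N + conv_step)
    U2h, W2h = second_order_means(env_hi, g, include_A0, method)
    rel = {
        "Ubar2": abs(U2h - U2) / max(abs(U2h), 1e-300),
        "Omegabar2": abs(W2h - W2) / max(abs(W2h), 1e-300),
    }
    conv = {
        "N": N,
        "N_check": N + conv_step,
        "rel_change": rel,
        "tol": conv_tol,
        "converged": None if conv_tol is None else max(rel.values()) < conv_tol,
    }
    if conv_tol is not None and max(rel.values()) >= conv_tol:
        raise ConvergenceError(
            f"second-order means changed by {max(rel.values()):.2e} between "
            f"N={N} and N={N + conv_step}, exceeding conv_tol={conv_tol:.1e}",
            trace=[(N, (U2, W2)), (N + conv_step, (U2h, W2h))],
        )
    Pbar, Pswirl, eff = power_and_efficiency(env, g, include_A0, Ubar2=U2)
    return SwimSummary(
        Ubar2=U2,
        Omegabar2=W2,
        Pbar=Pbar,
        Pbar_swirl=Pswirl,
        efficiency=eff,
        N=N,
        include_A0=include_A0,
        method=method,
        convergence=conv,
    )
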