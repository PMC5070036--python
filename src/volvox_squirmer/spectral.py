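"""Legendre spectral machinery for the axisymmetric squirmer.

Basis functions
---------------
``P_n(x)``
    Legendre polynomial of degree ``n``, evaluated by the stable three-term
    recurrence ``(n+1) P_{n+1} = (2n+1) x P_n - n P_{n-1}``.
``V_n(theta) = (2 / (n (n+1))) sin(theta) P_n'(cos theta)``
    The tangential basis used for surface-velocity expansions; ``V_1 =
    sin(theta)`` and every ``V_n`` vanishes at both poles.

Product integrals
-----------------
:func:`product_integral` returns closed-form values of the integrals of
products of ``P_n``, ``V_n`` and ``sin/cos`` factors over ``theta in [0, pi]``
that arise in the second-order (quadratic-coupling) mean-flow sums.  All
angular integrals in this package use the measure ``sin(theta) d(theta)``.

Travelling-wave projections
---------------------------
:func:`project_wave` expands ``sin(k theta)`` and ``cos(k theta)`` (functions
of the polar angle itself, not of ``cos theta``) in either basis, in closed
form.  The coefficients follow from the finite cosine representation

    ``P_n(cos theta) = 4^{-n} sum_j C(2j, j) C(2n-2j, n-j) cos((n-2j) theta)``

together with elementary integrals of products of sines and cosines of
non-commensurate frequencies.  Those elementary integrals carry denominators
``k^2 - q^2`` with integer ``q``; the expansion is therefore singular as the
wavenumber approaches an integer, and integer ``k`` (within a guard band
``|k - round(k)| < 1e-6``) is rejected.  The divergent normalization is
exposed as :func:`eta`.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .exceptions import InvalidModeError, SingularWavenumberError

__all__ = [
    "legendre_P",
    "legendre_P_deriv",
    "tangential_V",
    "tangential_V_theta_deriv",
    "product_integral",
    "project_wave",
    "wave_coefficients",
    "eta",
    "check_wavenumber",
    "INTEGER_K_GUARD",
]

#: guard band: wavenumbers closer than this to an integer are rejected
INTEGER_K_GUARD = 1e-6


# ----------------------------------------------------------------------------
# basis functions
# ----------------------------------------------------------------------------

def legendre_P(n: int, x):
    """Legendre polynomial ``P_n(x)`` by three-term recurrence.

    Parameters
    ----------
    n : int
        Degree, ``n >= 0``.
    x : float or array_like
        Argument with ``|x| <= 1``.
    """
    n = _check_degree(n, minimum=0)
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("legendre_P requires |x| <= 1")
    x = np.clip(x, -1.0, 1.0)
    pm1 = np.ones_like(x)
    if n == 0:
        return pm1 if pm1.ndim else float(pm1)
    p = x.copy()
    for m in range(1, n):
        pm1, p = p, ((2 * m + 1) * x * p - m * pm1) / (m + 1)
    return p if p.ndim else float(p)


def legendre_P_deriv(n: int, x):
    """Derivative ``P_n'(x)``, with the pole limit ``P_n'(+-1) =
    (+-1)^{n+1} n(n+1)/2`` applied at the endpoints."""
    n = _check_degree(n, minimum=0)
    x = np.asarray(x, dtype=float)
    if n == 0:
        out = np.zeros_like(x)
        return out if out.ndim else 0.0
    # (1 - x^2) P_n' = n (P_{n-1} - x P_n)
    pn = np.asarray(legendre_P(n, x))
    pnm1 = np.asarray(legendre_P(n - 1, x))
    denom = 1.0 - x * x
    interior = np.abs(denom) > 1e-14
    out = np.empty_like(x)
    out[interior] = n * (pnm1[interior] - x[interior] * pn[interior]) / denom[interior]
    endpoint = ~interior
    if np.any(endpoint):
        s = np.sign(x[endpoint])
        out[endpoint] = s ** (n + 1) * n * (n + 1) / 2.0
    return out if out.ndim else float(out)


def tangential_V(n: int, theta):
    """Tangential basis function ``V_n = (2/(n(n+1))) sin(theta) P_n'(cos
    theta)`` for ``n >= 1``; vanishes identically at both poles."""
    n = _check_degree(n, minimum=1)
    theta = np.asarray(theta, dtype=float)
    x = np.cos(theta)
    out = (2.0 / (n * (n + 1))) * np.sin(theta) * np.asarray(legendre_P_deriv(n, x))
    return out if out.ndim else float(out)


def tangential_V_theta_deriv(n: int, theta):
    """``dV_n/d(theta)``, via the Legendre ODE reduction

    ``dV_n/dtheta = 2 P_n(cos theta) - (2 cos theta / (n(n+1))) P_n'(cos theta)``.
    """
    n = _check_degree(n, minimum=1)
    theta = np.asarray(theta, dtype=float)
    x = np.cos(theta)
    out = 2.0 * np.asarray(legendre_P(n, x)) - (
        2.0 * x / (n * (n + 1))
    ) * np.asarray(legendre_P_deriv(n, x))
    return out if out.ndim else float(out)


def _check_degree(n, minimum):
    if int(n) != n or n < minimum:
        raise InvalidModeError(f"mode index must be an integer >= {minimum}, got {n!r}")
    return int(n)


# ----------------------------------------------------------------------------
# closed-form product integrals
# ----------------------------------------------------------------------------

def product_integral(kind: str, n: int, m: int) -> float:
    """Closed-form product integrals over ``theta in [0, pi]``.

    ======== ==================================================== ==========
    kind     integrand (times ``d theta``)                        validity
    ======== ==================================================== ==========
    PP       ``P_n P_m sin``                                      n, m >= 0
    PP_cos   ``P_n P_m cos sin``                                  n, m >= 0
    VV       ``V_n V_m sin``                                      n, m >= 1
    VV_cos   ``V_n V_m cos sin``                                  n, m >= 1
    PV       ``P_n V_m sin^2``                                    n >= 0, m >= 1
    VdV      ``V_n (dV_m/dtheta) sin^2``                          n, m >= 1
    ======== ==================================================== ==========

    ``P_*`` and ``V_*`` take the argument ``cos theta``; ``sin``/``cos``
    factors are of ``theta``.  Values are exact rationals evaluated in floats.
    """
    if kind == "PP":
        n, m = _check_degree(n, 0), _check_degree(m, 0)
        return 2.0 / (2 * n + 1) if n == m else 0.0
    if kind == "PP_cos":
        n, m = _check_degree(n, 0), _check_degree(m, 0)
        if m == n + 1:
            return 2.0 * (n + 1) / ((2 * n + 1) * (2 * n + 3))
        if m == n - 1:
            return 2.0 * n / ((2 * n + 1) * (2 * n - 1))
        return 0.0
    if kind == "VV":
        n, m = _check_degree(n, 1), _check_degree(m, 1)
        return 8.0 / (n * (n + 1) * (2 * n + 1)) if n == m else 0.0
    if kind == "VV_cos":
        n, m = _check_degree(n, 1), _check_degree(m, 1)
        lo = min(n, m)
        if abs(n - m) == 1:
            return 8.0 / ((lo + 1) * (2 * lo + 1) * (2 * lo + 3))
        return 0.0
    if kind == "PV":
        n, m = _check_degree(n, 0), _check_degree(m, 1)
        if n == m - 1:
            return 4.0 / ((2 * m + 1) * (2 * n + 1))
        if n == m + 1:
            return -4.0 / ((2 * m + 1) * (2 * n + 1))
        return 0.0
    if kind == "VdV":
        n, m = _check_degree(n, 1), _check_degree(m, 1)
        val = 0.0
        if m == n - 1 or m == n + 1:
            sgn = 1.0 if m == n - 1 else -1.0
            val += sgn * 4.0 * m / ((m + 1) * (2 * m + 1))
        if m == n + 1:
            val -= 4.0 / (m * (m + 1))
        return (2.0 / (2 * n + 1)) * val
    raise ValueError(f"unsupported product-integral kind {kind!r}")


# ----------------------------------------------------------------------------
# travelling-wave projections
# ----------------------------------------------------------------------------

def check_wavenumber(k: float) -> float:
    """Validate a metachronal wavenumber: positive and non-integer."""
    k = float(k)
    if not np.isfinite(k) or k <= 0:
        raise SingularWavenumberError(f"wavenumber must be positive, got {k!r}")
    if abs(k - round(k)) < INTEGER_K_GUARD:
        raise SingularWavenumberError(
            f"wavenumber k={k} is within {INTEGER_K_GUARD} of an integer; the "
            "travelling-wave projection is singular there"
        )
    return k


def eta(k: float) -> float:
    """Resonance factor ``eta(k) = pi k / sin(pi k)`` of the travelling-wave
    expansion: finite for non-integer ``k``, divergent at integer ``k``."""
    k = check_wavenumber(k)
    return np.pi * k / np.sin(np.pi * k)


def _cos_rep_coeffs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients ``beta_j`` and integer frequencies ``q_j = n - 2j`` of the
    cosine representation of ``P_n(cos theta)``."""
    j = np.arange(n + 1)

    def logbinom(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    logbeta = logbinom(2 * j, j) + logbinom(2 * (n - j), n - j) - n * np.log(4.0)
    return np.exp(logbeta), n - 2 * j


def _sin_sin(k, q):
    # int_0^pi sin(k t) sin(q t) dt, q integer, k non-integer
    return (-1.0) ** (q % 2) * np.sin(np.pi * k) * q / (k * k - q * q)


def _cos_sin(k, q):
    # int_0^pi cos(k t) sin(q t) dt
    return q * (1.0 - (-1.0) ** (q % 2) * np.cos(np.pi * k)) / (q * q - k * k)


def _sin_cos(k, q):
    # int_0^pi sin(k t) cos(q t) dt
    return k * (1.0 - (-1.0) ** (q % 2) * np.cos(np.pi * k)) / (k * k - q * q)


def _cos_cos(k, q):
    # int_0^pi cos(k t) cos(q t) dt
    return (-1.0) ** (q % 2) * np.sin(np.pi * k) * k / (k * k - q * q)


def _wave_P_inner(form: str, k: float, n: int) -> float:
    """``int_0^pi trig(k theta) P_n(cos theta) sin(theta) d theta``."""
    beta, q = _cos_rep_coeffs(n)
    trig = _sin_sin if form == "sin_ktheta" else _cos_sin
    # sin(theta) cos(q theta) = (sin((q+1) theta) - sin((q-1) theta)) / 2
    total = 0.0
    for b, qq in zip(beta, q):
        total += b * 0.5 * (trig(k, qq + 1) - trig(k, qq - 1))
    return total


def _wave_flat_inner(form: str, k: float, n: int) -> float:
    """``int_0^pi trig(k theta) P_n(cos theta) d theta`` (no sin factor)."""
    beta, q = _cos_rep_coeffs(n)
    trig = _sin_cos if form == "sin_ktheta" else _cos_cos
    return float(sum(b * trig(k, qq) for b, qq in zip(beta, q)))


_FORM_ALIASES = {
    "sin_ktheta": "sin_ktheta",
    "cos_ktheta": "cos_ktheta",
    "sin": "sin_ktheta",
    "cos": "cos_ktheta",
}


def project_wave(form: str, basis: str, k: float, n: int) -> float:
    """Coefficient of ``P_n`` (or ``V_n``) in the expansion of ``sin(k
    theta)`` or ``cos(k theta)`` over ``theta in [0, pi]``.

    The expansions are ``f(theta) = sum_n p_n P_n(cos theta)`` with

        ``p_n = (2n+1)/2 * int f P_n sin dtheta``

    and ``f = sum_n v_n V_n`` with

        ``v_n = n(n+1)(2n+1)/8 * int f V_n sin dtheta``.

    Integer ``k`` raises :class:`SingularWavenumberError`.
    """
    if form not in _FORM_ALIASES:
        raise ValueError(f"unknown wave form {form!r}")
    form = _FORM_ALIASES[form]
    k = check_wavenumber(k)
    if basis == "P":
        n = _check_degree(n, 0)
        return (2 * n + 1) / 2.0 * _wave_P_inner(form, k, n)
    if basis == "V":
        n = _check_degree(n, 1)
        # sin(theta) V_n = (2/(2n+1)) (P_{n-1} - P_{n+1})  (functions of cos theta)
        inner = (2.0 / (2 * n + 1)) * (
            _wave_flat_inner(form, k, n - 1) - _wave_flat_inner(form, k, n + 1)
        )
        return n * (n + 1) * (2 * n + 1) / 8.0 * inner
    raise ValueError(f"unknown basis {basis!r}")


def wave_coefficients(basis: str, k: float, N: int) -> np.ndarray:
    """Complex coefficient array for the wave ``e^{i k theta}``.

    Returns ``c[0..N]`` with ``e^{i k theta} ~ sum_n c[n] B_n`` in the chosen
    basis (``B = P`` or ``V``); for the V basis ``c[0] = 0``.  Row ``n`` is
    ``project_wave(cos) + 1j * project_wave(sin)``.
    """
    k = check_wavenumber(k)
    c = np.zeros(N + 1, dtype=complex)
    n0 = 0 if basis == "P" else 1
    for n in range(n0, N + 1):
        c[n] = project_wave("cos_ktheta", basis, k, n) + 1j * project_wave(
            "sin_ktheta", basis, k, n
        )
    return c
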