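"""Lagrangian kinematics of the flagellar-tip envelope.

The beating flagella of a *Volvox* colony are modelled by a continuous
envelope through their tips: a sphere of mean radius ``a`` whose material
points, labelled by their mean polar angle ``theta0``, execute small
elliptical orbits phase-locked into a symplectic metachronal wave.

Displacement waves (lengths, relative to the mean sphere; the azimuthal one
is measured in the frame co-rotating with the colony body)::

    radial     :  eps * a * sin(k*theta0 - sigma*t)
    tangential :  delta * eps * a * sin(k*theta0 - sigma*t + chi)
    azimuthal  :  beta * (tangential waveform)

``k`` is the dimensionless wavenumber (non-integer), ``sigma`` the beat
frequency in rad/s, ``eps`` the dimensionless amplitude, ``delta`` the
tangential/radial axis ratio of the tip orbit, ``chi`` the phase between the
two (quadrature, ``chi = +pi/2`` by default, gives an axis-aligned ellipse
traversed in the power-stroke sense),
and ``beta`` the tangent of the azimuthal offset angle of the beat plane that
drives the colony's rotation.  An optional orbit tilt ``psi`` (angle of the
ellipse's major axis to the local surface) mixes the radial and tangential
waveforms by a rotation.

:func:`envelope_modes` projects the three waves onto the Legendre bases
(``P_n`` for radial, ``V_n`` for tangential/azimuthal), returning the
complex harmonic amplitudes ``a_n, b_n, c_n`` such that e.g.
``a_n(t) = Re[a_n_hat * exp(-i sigma t)]`` and

    ``R(theta0, t) = a * (1 + sum_n a_n(t) P_n(cos theta0))``.

The amplitudes carry the ``eps`` scaling, so every one is linear in ``eps``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import spectral
from .exceptions import SingularWavenumberError

__all__ = [
    "WaveParameters",
    "ColonyGeometry",
    "EnvelopeModeSeries",
    "radial_displacement",
    "tangential_displacement",
    "azimuthal_displacement",
    "envelope_modes",
    "tilted_envelope_modes",
    "read_colony_table",
    "COLONY_COLUMNS",
]

#: default flagellum length [um] when a colony table does not provide one
DEFAULT_FLAGELLUM_LENGTH_UM = 20.0
#: default azimuthal beat-plane offset: tan(15 degrees)
DEFAULT_BETA = math.tan(math.radians(15.0))
#: default radial/tangential phase: quadrature (axis-aligned tip ellipse),
#: with the sign for which the extended tip sweeps with the wave (power stroke)
DEFAULT_CHI = math.pi / 2
#: default tangential-to-radial amplitude ratio of the tip orbit
DEFAULT_DELTA = 1.68


@dataclass(frozen=True)
class WaveParameters:
    """Kinematic parameters of the metachronal wave and tip orbit.

    Parameters
    ----------
    k : float
        Dimensionless wavenumber (positive, non-integer).
    sigma : float
        Beat angular frequency [rad/s].
    epsilon : float or None
        Dimensionless radial amplitude; if ``None`` it is resolved from the
        colony geometry as ``L / (3 a)`` (tip-orbit scale).
    delta : float
        Tangential-to-radial amplitude ratio (>0).
    chi : float
        Phase of the tangential wave relative to the radial one [rad].
    beta : float
        Tangent of the azimuthal beat-plane offset angle.
    psi : float
        Tilt of the tip-orbit major axis to the local surface [rad],
        ``|psi| < pi/2``.
    """

    k: float
    sigma: float
    epsilon: float | None = None
    delta: float = DEFAULT_DELTA
    chi: float = DEFAULT_CHI
    beta: float = DEFAULT_BETA
    psi: float = 0.0

    def __post_init__(self):
        spectral.check_wavenumber(self.k)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.epsilon is not None and not (0 <= self.epsilon <= 0.1):
            raise ValueError("epsilon must lie in [0, 0.1] for the amplitude expansion")
        if not abs(self.psi) < math.pi / 2:
            raise ValueError("|psi| must be < pi/2")

    def resolve_epsilon(self, geometry: "ColonyGeometry") -> float:
        """Amplitude actually used: the explicit value, else ``L / (3 a)``."""
        if self.epsilon is not None:
            return self.epsilon
        return geometry.L / (3.0 * geometry.a)

    @classmethod
    def volvox_mean(cls, **overrides) -> "WaveParameters":
        """Population-mean wave: ``k = 4.7``, ``sigma = 203`` rad/s,
        ``delta = 1.68``, ``epsilon = 0.035``."""
        params = dict(k=4.7, sigma=203.0, epsilon=0.035)
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class ColonyGeometry:
    """Colony radii and fluid viscosity.

    ``a0`` is the radius of the extracellular-matrix surface [um]; the
    flagellar-tip envelope has mean radius ``a = a0 + (2/3) L`` by default,
    with ``L`` the flagellum length [um].  ``mu`` is the dynamic viscosity
    [Pa s].
    """

    a0: float
    L: float = DEFAULT_FLAGELLUM_LENGTH_UM
    a: float | None = None
    mu: float = 1.0e-3

    def __post_init__(self):
        if self.a0 <= 0 or self.L <= 0 or self.mu <= 0:
            raise ValueError("a0, L and mu must be positive")
        if self.a is None:
            object.__setattr__(self, "a", self.a0 + 2.0 * self.L / 3.0)
        if self.a <= self.a0:
            raise ValueError("envelope radius a must exceed matrix radius a0")


@dataclass(frozen=True)
class EnvelopeModeSeries:
    """Harmonic Legendre-mode amplitudes of the envelope displacements.

    Arrays are indexed by mode number ``n`` (``b_hat[0] = c_hat[0] = 0``;
    the tangential basis starts at ``n = 1``).  ``a_n(t) = Re[a_hat[n] *
    exp(-i sigma t)]`` etc.  All amplitudes include the factor ``epsilon``.
    """

    N: int
    sigma: float
    epsilon: float
    a_hat: np.ndarray
    b_hat: np.ndarray
    c_hat: np.ndarray
    defaults_used: dict = field(default_factory=dict)

    def scaled(self, factor: float) -> "EnvelopeModeSeries":
        """Series with every amplitude (and epsilon) multiplied by factor."""
        return replace(
            self,
            epsilon=self.epsilon * factor,
            a_hat=self.a_hat * factor,
            b_hat=self.b_hat * factor,
            c_hat=self.c_hat * factor,
        )

    def evaluate(self, theta0, t, which: str = "radial"):
        """Reconstruct a displacement field (in units of the envelope radius
        ``a``) from the truncated mode series at angles ``theta0``, time ``t``."""
        theta0 = np.asarray(theta0, dtype=float)
        phase = np.exp(-1j * self.sigma * t)
        if which == "radial":
            coeffs, basis = self.a_hat, spectral.legendre_P
            vals = sum(
                coeffs[n] * np.asarray(basis(n, np.cos(theta0)))
                for n in range(self.N + 1)
            )
        else:
            coeffs = self.b_hat if which == "tangential" else self.c_hat
            vals = sum(
                coeffs[n] * np.asarray(spectral.tangential_V(n, theta0))
                for n in range(1, self.N + 1)
            )
        return np.real(vals * phase)


def _phase(theta0, t, w: WaveParameters, extra: float = 0.0):
    return w.k * np.asarray(theta0, dtype=float) - w.sigma * t + extra


def radial_displacement(theta0, t, w: WaveParameters, g: ColonyGeometry):
    """Radial tip displacement ``eps a sin(k theta0 - sigma t)`` [um]."""
    eps = w.resolve_epsilon(g)
    return eps * g.a * np.sin(_phase(theta0, t, w))


def tangential_displacement(theta0, t, w: WaveParameters, g: ColonyGeometry):
    """Tangential tip displacement ``delta eps a sin(k theta0 - sigma t +
    chi)`` [um]."""
    eps = w.resolve_epsilon(g)
    return w.delta * eps * g.a * np.sin(_phase(theta0, t, w, w.chi))


def azimuthal_displacement(theta0, t, w: WaveParameters, g: ColonyGeometry):
    """Azimuthal tip displacement in the co-rotating frame: ``beta`` times
    the tangential waveform [um]."""
    return w.beta * tangential_displacement(theta0, t, w, g)


def envelope_modes(
    w: WaveParameters, g: ColonyGeometry, N: int = 25
) -> EnvelopeModeSeries:
    """Project the displacement waves onto the Legendre bases.

    Uses ``sin(k theta - sigma t) = Re[-i e^{i k theta} e^{-i sigma t}]``:
    the complex spatial profile ``-i e^{i k theta}`` is expanded once per
    basis and scaled by the orbit parameters.
    """
    return tilted_envelope_modes(w, g, N)


def tilted_envelope_modes(
    w: WaveParameters, g: ColonyGeometry, N: int = 25
) -> EnvelopeModeSeries:
    """Mode series for a tip orbit tilted by ``psi`` to the local surface.

    The (radial, tangential) displacement pair is the ``psi = 0`` pair
    rotated by ``psi`` in the local (surface-normal, surface-tangent) plane;
    ``psi = 0`` reduces exactly to the untilted series.  The azimuthal
    displacement is ``beta`` times the (tilted) tangential component.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    eps = w.resolve_epsilon(g)
    # complex spatial amplitudes of the psi = 0 waves, units of a:
    #   radial profile     : eps * (-i) e^{i k theta}
    #   tangential profile : eps * delta * e^{i chi} * (-i) e^{i k theta}
    zr = -1j * eps
    zt = -1j * eps * w.delta * np.exp(1j * w.chi)
    c, s = math.cos(w.psi), math.sin(w.psi)
    # rotate the orbit by psi in the (radial, tangential) plane
    zr_t, zt_t = c * zr - s * zt, s * zr + c * zt
    wave_P = spectral.wave_coefficients("P", w.k, N)
    wave_V = spectral.wave_coefficients("V", w.k, N)
    a_hat = zr_t * wave_P
    b_hat = zt_t * wave_V
    c_hat = w.beta * b_hat
    defaults = {}
    if w.epsilon is None:
        defaults["epsilon"] = f"L/(3a) = {eps:.4f} (package default, not a measured value)"
    return EnvelopeModeSeries(
        N=N,
        sigma=w.sigma,
        epsilon=eps,
        a_hat=a_hat,
        b_hat=b_hat,
        c_hat=c_hat,
        defaults_used=defaults,
    )


# ----------------------------------------------------------------------------
# colony tables
# ----------------------------------------------------------------------------

#: required and optional columns of a colony CSV
COLONY_COLUMNS = {
    "required": ["colony_id", "a0_um", "k", "sigma_rad_s"],
    "optional": ["epsilon", "delta", "beta", "chi", "psi", "L_um"],
}


def read_colony_table(path) -> pd.DataFrame:
    """Read a per-colony parameter CSV.

    Required columns: ``colony_id, a0_um, k, sigma_rad_s``.  Optional:
    ``epsilon, delta, beta, chi, psi, L_um`` (missing values are filled from
    package defaults; a ``defaults_used`` column records which).
    """
    df = pd.read_csv(path)
    missing = [c for c in COLONY_COLUMNS["required"] if c not in df.columns]
    if missing:
        raise ValueError(f"colony table missing required columns: {missing}")
    fill = {
        "delta": DEFAULT_DELTA,
        "beta": DEFAULT_BETA,
        "chi": DEFAULT_CHI,
        "psi": 0.0,
        "L_um": DEFAULT_FLAGELLUM_LENGTH_UM,
        "epsilon": np.nan,  # resolved later from L/(3a)
    }
    notes = []
    for _, row in df.iterrows():
        used = [
            c
            for c in COLONY_COLUMNS["optional"]
            if c not in df.columns or pd.isna(row.get(c, np.nan))
        ]
        notes.append(",".join(used))
    for col, val in fill.items():
        if col not in df.columns:
            df[col] = val
        else:
            df[col] = df[col].fillna(val)
    df["defaults_used"] = notes
    return df
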