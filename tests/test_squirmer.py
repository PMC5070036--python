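"""First-order flow solution: boundary conditions, conservation laws,
far-field decay, kymographs, rate of working, reciprocal theorem."""

import numpy as np
import pytest

from volvox_squirmer import (
    ColonyGeometry,
    WaveParameters,
    envelope_modes,
    first_order_coefficients,
    instantaneous_field,
    instantaneous_power,
    kymograph,
    mean_power,
    reciprocal_theorem_rotation,
    rigid_rotation_projection,
)
from volvox_squirmer import spectral
from volvox_squirmer.squirmer import ModeCoefficientSet, field_amplitudes


@pytest.fixture(scope="module")
def coeffs(env25, geometry):
    return first_order_coefficients(env25, geometry)


class TestFirstOrderCoefficients:
    def test_zero_amplitude_gives_zero_coefficients(self, geometry):
        w = WaveParameters(k=4.7, sigma=203.0, epsilon=0.0)
        c = first_order_coefficients(envelope_modes(w, geometry, 10), geometry)
        assert np.all(c.A_hat == 0) and np.all(c.B_hat == 0) and np.all(c.C_hat == 0)

    def test_U_and_Omega_have_zero_time_mean(self, coeffs):
        period = 2 * np.pi / coeffs.sigma
        t = np.linspace(0, period, 256, endpoint=False)
        assert np.mean(coeffs.U(t)) == pytest.approx(0.0, abs=1e-9)
        assert np.mean(coeffs.Omega(t)) == pytest.approx(0.0, abs=1e-12)

    def test_swirl_coefficients_proportional_to_beta(self, geometry, mean_wave):
        c1 = first_order_coefficients(envelope_modes(mean_wave, geometry, 12), geometry)
        w2 = WaveParameters.volvox_mean(beta=2 * mean_wave.beta)
        c2 = first_order_coefficients(envelope_modes(w2, geometry, 12), geometry)
        assert np.allclose(c2.C_hat, 2 * c1.C_hat, rtol=1e-14)
        assert np.allclose(c2.B_hat, c1.B_hat, rtol=1e-14)

    def test_force_and_torque_free_relations(self, coeffs):
        assert coeffs.U_hat == (2 * coeffs.B_hat[1] - coeffs.A_hat[1]) / 3.0
        assert coeffs.Omega_hat == -coeffs.C_hat[1] / coeffs.a


class TestFieldProperties:
    def test_surface_velocities_match_prescribed_series(self, coeffs, geometry):
        theta = np.linspace(0.02, np.pi - 0.02, 90)
        ur, ut, up = field_amplitudes(coeffs, geometry.a, theta, frame="body")
        A, B, C = coeffs.A_hat, coeffs.B_hat, coeffs.C_hat
        x = np.cos(theta)
        ur_bc = sum(A[n] * np.asarray(spectral.legendre_P(n, x)) for n in range(coeffs.N + 1))
        ut_bc = sum(
            B[n] * np.asarray(spectral.tangential_V(n, theta))
            for n in range(1, coeffs.N + 1)
        )
        assert np.max(np.abs(ur - ur_bc)) < 1e-8 * np.max(np.abs(ur_bc))
        assert np.max(np.abs(ut - ut_bc)) < 1e-8 * np.max(np.abs(ut_bc))

    def test_divergence_free_on_grid(self, coeffs, geometry):
        # oracle: small-step central differences of the axisymmetric divergence
        a = geometry.a
        r = np.linspace(1.2 * a, 3.0 * a, 50)
        th = np.linspace(0.1, np.pi - 0.1, 50)
        R, TH = np.meshgrid(r, th, indexing="ij")
        hr, ht = 1e-5 * a, 1e-5
        urp, _, _ = field_amplitudes(coeffs, R + hr, TH)
        urm, _, _ = field_amplitudes(coeffs, R - hr, TH)
        _, utp, _ = field_amplitudes(coeffs, R, TH + ht)
        _, utm, _ = field_amplitudes(coeffs, R, TH - ht)
        ur0, _, _ = field_amplitudes(coeffs, R, TH)
        div = ((R + hr) ** 2 * urp - (R - hr) ** 2 * urm) / (2 * hr) / R**2
        div += (np.sin(TH + ht) * utp - np.sin(TH - ht) * utm) / (2 * ht) / (R * np.sin(TH))
        grad_scale = coeffs.N * np.max(np.abs(ur0)) / a
        assert np.max(np.abs(div)) < 1e-6 * grad_scale

    def test_far_field_excludes_stokeslet_and_rotlet(self, coeffs, geometry):
        # mode-1 projections of u_r and u_phi at several radii; fit the
        # forbidden slow components and compare with the field amplitude
        a = geometry.a
        x, wts = np.polynomial.legendre.leggauss(64)
        tt = np.arccos(x)

        def proj(rr):
            ur, _, up = field_amplitudes(coeffs, rr, tt)
            return 1.5 * np.sum(wts * ur * x), 0.75 * np.sum(wts * up * np.sin(tt))

        rads = np.array([2.0, 4.0, 8.0]) * a
        p1 = np.array([proj(r_)[0] for r_ in rads])
        v1 = np.array([proj(r_)[1] for r_ in rads])
        # u_r mode 1 ~ cS/r (Stokeslet) + cD/r^3 (doublet): solve and test cS
        M = np.array([[1 / rads[0], 1 / rads[0] ** 3], [1 / rads[1], 1 / rads[1] ** 3]])
        cS, cD = np.linalg.solve(M, p1[:2])
        u_scale = np.max(np.abs(field_amplitudes(coeffs, 2 * a, tt)[0]))
        assert abs(cS / (2 * a)) < 1e-6 * u_scale
        # u_phi mode 1 ~ cR/r^2 (rotlet): compare to the surface swirl amplitude
        up_scale = np.max(np.abs(field_amplitudes(coeffs, 2 * a, tt)[2]))
        M2 = np.array(
            [[1 / rads[0] ** 2, 1 / rads[0] ** 3], [1 / rads[1] ** 2, 1 / rads[1] ** 3]]
        )
        cR, _ = np.linalg.solve(M2, v1[:2])
        assert abs(cR / (2 * a) ** 2) < 1e-6 * up_scale

    def test_all_components_decay_far_away(self, coeffs, geometry):
        ur, ut, up = field_amplitudes(coeffs, 200 * geometry.a, np.array([1.0]))
        near = field_amplitudes(coeffs, 1.5 * geometry.a, np.array([1.0]))
        for far_c, near_c in zip((ur, ut, up), near):
            assert np.abs(far_c) < 1e-4 * np.abs(near_c)

    def test_evaluation_inside_sphere_rejected(self, coeffs, geometry):
        with pytest.raises(ValueError):
            instantaneous_field(coeffs, 0.5 * geometry.a, 1.0, 0.0)

    def test_tangential_decays_faster_than_radial(self, coeffs, geometry):
        theta = np.linspace(0.1, np.pi - 0.1, 60)
        near = field_amplitudes(coeffs, 1.1 * geometry.a, theta)
        far = field_amplitudes(coeffs, 2.0 * geometry.a, theta)
        ratio_r = np.max(np.abs(far[0])) / np.max(np.abs(near[0]))
        ratio_t = np.max(np.abs(far[1])) / np.max(np.abs(near[1]))
        assert ratio_t < ratio_r


class TestKymograph:
    def test_crest_advances_with_time(self, coeffs, geometry):
        theta, t, u_r, _ = kymograph(coeffs, 1.3 * geometry.a)
        mid = (theta > 0.8) & (theta < 2.3)
        c0 = theta[mid][np.argmax(u_r[mid, 0])]
        c1 = theta[mid][np.argmax(u_r[mid, 8])]
        assert c1 > c0

    def test_amplitude_scales_as_eps_a_sigma(self, geometry):
        # doubling epsilon, a and sigma each doubles the oscillation amplitude
        def amp(eps_fac, a_fac, sig_fac):
            g = ColonyGeometry(a0=200.0 * a_fac, L=20.0 * a_fac)
            w = WaveParameters(k=4.7, sigma=203.0 * sig_fac, epsilon=0.02 * eps_fac)
            c = first_order_coefficients(envelope_modes(w, g, 20), g)
            _, _, u_r, _ = kymograph(c, 1.3 * g.a)
            return np.max(np.abs(u_r))

        base = amp(1, 1, 1)
        assert amp(2, 1, 1) == pytest.approx(2 * base, rel=1e-12)
        assert amp(1, 1, 2) == pytest.approx(2 * base, rel=1e-12)
        assert amp(1, 2, 1) == pytest.approx(2 * base, rel=1e-9)

    def test_time_mean_is_zero_at_first_order(self, coeffs, geometry):
        theta, t, u_r, _ = kymograph(
            coeffs, 1.3 * geometry.a, t=np.linspace(0, 2 * np.pi / coeffs.sigma, 64, endpoint=False)
        )
        assert np.max(np.abs(u_r.mean(axis=1))) < 1e-10 * np.max(np.abs(u_r))

    def test_radius_below_surface_rejected(self, coeffs, geometry):
        with pytest.raises(ValueError):
            kymograph(coeffs, 0.9 * geometry.a)


class TestRateOfWorking:
    def test_mean_power_positive_and_swirl_nonneg(self, coeffs, geometry):
        P, Ps = mean_power(coeffs, geometry)
        assert P > 0 and 0 <= Ps < P

    def test_no_swirl_power_without_azimuthal_offset(self, geometry):
        w = WaveParameters.volvox_mean(beta=0.0)
        c = first_order_coefficients(envelope_modes(w, geometry, 20), geometry)
        _, Ps = mean_power(c, geometry)
        assert Ps == 0.0

    def test_swirl_power_nonnegative_across_sweep(self, geometry, rng):
        for _ in range(8):
            w = WaveParameters(
                k=float(rng.uniform(3.1, 6.4)),
                sigma=float(rng.uniform(150, 260)),
                epsilon=float(rng.uniform(0.01, 0.05)),
                delta=float(rng.uniform(1.4, 1.9)),
                beta=float(rng.uniform(-0.5, 0.5)),
            )
            if abs(w.k - round(w.k)) < 1e-3:
                continue
            c = first_order_coefficients(envelope_modes(w, geometry, 20), geometry)
            _, Ps = mean_power(c, geometry)
            assert Ps >= 0

    def test_mean_equals_time_average_of_instantaneous(self, coeffs, geometry):
        period = 2 * np.pi / coeffs.sigma
        t = np.linspace(0, period, 64, endpoint=False)
        Pt = np.array([instantaneous_power(coeffs, geometry, ti) for ti in t])
        P, _ = mean_power(coeffs, geometry)
        assert np.mean(Pt) == pytest.approx(P, rel=1e-10)
        assert np.all(Pt >= 0)

    def test_power_quadratic_form_against_dissipation_integral(self, geometry):
        # independent oracle: volume dissipation 2 mu int e:e dV over the
        # exterior equals the surface rate of working, checked one snapshot
        # at a time for a single low mode so quadrature is cheap and sharp
        a, mu = geometry.a, geometry.mu
        N = 6
        A = np.zeros(N + 1, dtype=complex)
        B = np.zeros(N + 1, dtype=complex)
        C = np.zeros(N + 1, dtype=complex)
        A[3], B[3], C[4] = 40.0, -25.0, 30.0  # um/s, real snapshot at t = 0
        coeffs1 = ModeCoefficientSet(
            N=N, sigma=203.0, a=a, A_hat=A, B_hat=B, C_hat=C
        )
        P_form = instantaneous_power(coeffs1, geometry, 0.0)

        xs, ws = np.polynomial.legendre.leggauss(60)  # radial: s = a/r in (0,1)
        s = 0.5 * (xs + 1)
        ws_s = 0.5 * ws
        xc, wc = np.polynomial.legendre.leggauss(80)
        th = np.arccos(xc)
        R, TH = np.meshgrid(a / s, th, indexing="ij")

        h = 1e-6 * a

        def vel(rr, tt):
            return field_amplitudes(coeffs1, rr, tt)

        ur, ut, up = [np.real(v) for v in vel(R, TH)]
        urp, utp, upp = [np.real(v) for v in vel(R + h, TH)]
        urm, utm, upm = [np.real(v) for v in vel(R - h, TH)]
        urtp, uttp, uptp = [np.real(v) for v in vel(R, TH + h / a)]
        urtm, uttm, uptm = [np.real(v) for v in vel(R, TH - h / a)]
        dr = lambda p, m: (p - m) / (2 * h)
        dth = lambda p, m: (p - m) / (2 * h / a)
        e_rr = dr(urp, urm)
        e_tt = (dth(uttp, uttm) + ur) / R
        e_pp = (ur + ut / np.tan(TH)) / R
        e_rt = 0.5 * (dr(utp, utm) - ut / R + dth(urtp, urtm) / R)
        e_rp = 0.5 * (dr(upp, upm) - up / R)
        e_tp = 0.5 * (dth(uptp, uptm) - up / np.tan(TH)) / R
        diss = 2 * mu * (
            e_rr**2 + e_tt**2 + e_pp**2 + 2 * e_rt**2 + 2 * e_rp**2 + 2 * e_tp**2
        )
        # dV = 2 pi r^2 sin dth dr; with r = a/s, dr = a/s^2 ds
        integrand = diss * 2 * np.pi * R**2 * (a / s[:, None] ** 2)
        P_vol = np.sum(ws_s[:, None] * wc[None, :] * integrand) * 1e-18
        assert P_vol == pytest.approx(P_form, rel=1e-4)


class TestReciprocalTheorem:
    def test_rigid_rotation_recovered_exactly(self, geometry):
        omega = 0.7
        out = rigid_rotation_projection(
            lambda th: omega * geometry.a * np.sin(th), geometry.a
        )
        assert out == pytest.approx(omega, rel=1e-12)

    def test_translation_only_surface_velocity_gives_zero(self, geometry):
        assert rigid_rotation_projection(lambda th: 0.0 * th, geometry.a) == 0.0

    def test_series_rotation_matches_surface_integral_at_phases(self, coeffs, geometry):
        period = 2 * np.pi / coeffs.sigma
        C = coeffs.C_hat
        for frac in np.arange(8) / 8.0:
            t = frac * period

            def slip(th, t=t):
                ph = np.exp(-1j * coeffs.sigma * t)
                return np.real(
                    ph
                    * sum(
                        C[n] * np.asarray(spectral.tangential_V(n, th))
                        for n in range(1, coeffs.N + 1)
                    )
                )

            Om = reciprocal_theorem_rotation(slip, geometry.a)
            ref = coeffs.Omega(t)
            assert Om == pytest.approx(ref, rel=1e-8, abs=1e-12)
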