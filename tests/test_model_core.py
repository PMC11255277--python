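"""Eigenvalue problem and truncated-series solution of the hollow sphere."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cherrydiff import model_core as mc
from cherrydiff.model_core import DomainError

from conftest import STUDY_A, STUDY_H


class TestNondimensionalize:
    def test_zero_time_gives_zero_theta(self, geom):
        p = mc.TransportParams.from_geometry(1e-10, 1e-11, geom)
        assert mc.nondimensionalize(0.0, geom.r_flesh / 2 + geom.r_inner, p, geom).Theta == 0.0

    def test_study_scale_fourier_number(self, geom):
        # D t / r0^2 for the erythrosine flesh diffusivity over one hour
        p = mc.TransportParams.from_geometry(1.18e-10, 2.01e-11, geom)
        st_ = mc.nondimensionalize(3600.0, geom.r_flesh, p, geom)
        assert st_.Theta == pytest.approx(1.18e-10 * 3600 / 0.0131**2, rel=1e-12)
        assert st_.Theta == pytest.approx(2.475e-3, rel=2e-4)

    def test_inner_radius_maps_to_A(self, geom):
        p = mc.TransportParams.from_geometry(1e-10, 1e-11, geom)
        assert mc.nondimensionalize(10.0, geom.r_inner, p, geom).R == pytest.approx(
            geom.A, abs=0
        )

    def test_round_trip(self, geom):
        p = mc.TransportParams.from_geometry(3.3e-10, 5e-11, geom)
        state = mc.nondimensionalize(1234.5, 0.007, p, geom)
        t, r = mc.redimensionalize(state, p, geom)
        assert t == pytest.approx(1234.5, rel=1e-12)
        assert r == pytest.approx(0.007, rel=1e-12)

    def test_outside_flesh_domain_raises(self, geom):
        p = mc.TransportParams.from_geometry(1e-10, 1e-11, geom)
        with pytest.raises(DomainError, match="flesh domain"):
            mc.nondimensionalize(1.0, geom.r_skin, p, geom)


class TestSkinFactor:
    def test_study_value(self):
        # red gardenia 357 ppm / 60 C magnitudes with the cherry geometry
        g = mc.Geometry(r_inner=1.1e-3, r_flesh=0.0131, r_skin=0.0131 + 4e-4)
        assert mc.skin_factor(6.61e-9, 3.89e-8, g) == pytest.approx(5.565, abs=1e-3)

    def test_identity_when_ratios_cancel(self):
        g = mc.Geometry(r_inner=0.0, r_flesh=4e-4, r_skin=8e-4)
        assert mc.skin_factor(2e-10, 2e-10, g) == pytest.approx(1.0, rel=1e-14)

    def test_impermeable_skin_limit(self, geom):
        assert mc.skin_factor(1e-20, 1e-10, geom) < 1e-6

    def test_nonpositive_inputs_raise(self, geom):
        with pytest.raises(DomainError):
            mc.skin_factor(0.0, 1e-10, geom)

    def test_transport_params_consistency_guard(self, geom):
        p = mc.TransportParams(D_flesh=1e-10, D_skin=1e-11, H=1.23)
        with pytest.raises(DomainError, match="inconsistent"):
            p.check_consistency(geom)
        mc.TransportParams.from_geometry(1e-10, 1e-11, geom).check_consistency(geom)


class TestEigenvalues:
    def test_dirichlet_limit(self):
        # H -> inf turns the Robin condition into a Dirichlet one, with
        # eigenvalues n*pi/(1-A)
        eig = mc.solve_eigenvalues(0.2, 1e8, 20)
        expected = np.arange(1, 21) * math.pi / 0.8
        assert np.max(np.abs(eig.eigenvalues - expected) / expected) <= 1e-6

    def test_closed_form_H_equal_one(self):
        # at H = 1 the transcendental equation degenerates to cos(0.8 lam)=0
        eig = mc.solve_eigenvalues(0.2, 1.0, 3)
        assert eig.eigenvalues[0] == pytest.approx(math.pi / 1.6, rel=1e-12)

    @pytest.mark.parametrize("A,H", [(0.084, 5.565), (0.0, 2.0), (0.5, 0.3)])
    def test_residuals_ordering_and_spacing(self, A, H):
        eig = mc.solve_eigenvalues(A, H, 220)
        lam = eig.eigenvalues
        assert np.all(np.diff(lam) > 0)
        res = np.abs(mc._char_eq(lam, A, H))
        assert np.max(res / np.maximum(1.0, lam)) <= 1e-10
        assert np.max(res[:50]) <= 1e-10
        assert np.all(np.diff(lam) < 2 * math.pi / (1 - A))

    def test_norms_and_coefficients_match_quadrature(self, study_eig):
        A = study_eig.A
        for n in (0, 3, 50):
            lam = study_eig.eigenvalues[n]
            b, _ = quad(
                lambda R: np.sin(lam * (R - A)) ** 2, A, 1, epsabs=1e-13, limit=200
            )
            c, _ = quad(
                lambda R: R * np.sin(lam * (R - A)), A, 1, epsabs=1e-13, limit=200
            )
            assert study_eig.norms[n] == pytest.approx(b, abs=1e-12)
            assert study_eig.coefficients[n] == pytest.approx(c, abs=1e-12)

    def test_orthogonality_by_quadrature(self, study_eig):
        A = study_eig.A
        lam = study_eig.eigenvalues
        for m, n in [(0, 1), (0, 5), (2, 7)]:
            val, _ = quad(
                lambda R: np.sin(lam[m] * (R - A)) * np.sin(lam[n] * (R - A)),
                A,
                1,
                epsabs=1e-12,
                limit=200,
            )
            assert abs(val) <= 1e-8

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            mc.solve_eigenvalues(1.0, 1.0, 5)
        with pytest.raises(DomainError):
            mc.solve_eigenvalues(0.1, -1.0, 5)
        with pytest.raises(DomainError):
            mc.solve_eigenvalues(0.1, 1.0, 0)

    def test_json_round_trip(self, study_eig):
        back = mc.EigenSystem.from_json(study_eig.to_json())
        np.testing.assert_array_equal(back.eigenvalues, study_eig.eigenvalues)
        np.testing.assert_array_equal(back.coefficients, study_eig.coefficients)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        A=st.floats(0.0, 0.8),
        H=st.floats(0.05, 50.0),
    )
    def test_first_eigenvalue_below_dirichlet_bound(self, A, H):
        # the Robin spectrum interlaces below the Dirichlet one:
        # lambda_1 < pi/(1-A) for any finite H
        eig = mc.solve_eigenvalues(A, H, 1)
        assert 0 < eig.eigenvalues[0] < math.pi / (1 - A) + 1e-9


class TestSeries:
    def test_initial_volume_average_completeness(self, study_eig):
        # truncation-limited reconstruction of the unit initial condition
        assert abs(mc.series_volume_average(0.0, study_eig) - 1.0) <= 2e-3

    def test_long_time_decay(self, study_eig):
        prof = mc.series_profile(5.0, np.linspace(STUDY_A, 1, 7), study_eig)
        assert np.all(np.abs(prof) < 1e-6)
        assert abs(mc.series_volume_average(50.0, study_eig)) < 1e-12

    def test_profile_vanishes_at_cavity_wall(self, study_eig):
        for theta in (1e-3, 0.05, 1.0):
            assert abs(mc.series_profile(theta, [STUDY_A], study_eig)[0]) <= 1e-10

    def test_negative_theta_raises(self, study_eig):
        with pytest.raises(DomainError):
            mc.series_profile(-0.1, [0.5], study_eig)
        with pytest.raises(DomainError):
            mc.series_volume_average(-0.1, study_eig)

    def test_volume_average_consistent_with_profile_quadrature(self, study_eig):
        A = study_eig.A
        for theta in (1e-3, 0.05, 0.3):
            direct = mc.series_volume_average(theta, study_eig)
            integral, _ = quad(
                lambda R: R**2 * mc.series_profile(theta, [R], study_eig)[0],
                A,
                1.0,
                epsabs=1e-10,
                limit=300,
            )
            assert abs(direct - 3 / (1 - A**3) * integral) <= 1e-6

    def test_volume_average_monotone_decay(self, study_eig):
        thetas = np.linspace(1e-4, 1.0, 60)
        vals = mc.series_volume_average(thetas, study_eig)
        assert np.all(np.diff(vals) < 0)

    def test_profile_bounded_after_initial_transient(self, study_eig):
        R = np.linspace(STUDY_A, 1.0, 41)
        for theta in (1e-4, 1e-3, 0.01, 0.1):
            prof = mc.series_profile(theta, R, study_eig)
            assert np.all(prof >= -5e-3) and np.all(prof <= 1 + 5e-3)

    def test_term_count_convergence(self):
        e220 = mc.solve_eigenvalues(STUDY_A, STUDY_H, 220)
        e440 = mc.solve_eigenvalues(STUDY_A, STUDY_H, 440)
        thetas = np.geomspace(1e-3, 1.0, 25)
        diff = np.abs(
            np.asarray(mc.series_volume_average(thetas, e220))
            - np.asarray(mc.series_volume_average(thetas, e440))
        )
        assert np.max(diff) <= 1e-4

    def test_forcing_zero_reduces_to_eigen_decay(self, study_eig):
        base = mc.series_volume_average(0.07, study_eig)
        forced = mc.series_volume_average(
            0.07, study_eig, mc.ForcingParams(W=0.0, A0=5.0, A1=3.0)
        )
        assert forced == base

    def test_forcing_singularity_guard(self, study_eig):
        lam1_sq = study_eig.eigenvalues[0] ** 2
        bad = mc.ForcingParams(W=1.0, A0=1.0, A1=lam1_sq + 1e-12)
        with pytest.raises(mc.SingularityError):
            mc.series_volume_average(0.1, study_eig, bad)

    def test_forcing_profile_volume_average_consistency(self, study_eig):
        # the forced profile must volume-average to the forced a*_V
        A = study_eig.A
        forcing = mc.ForcingParams(W=0.4, A0=1.3, A1=2.0)
        theta = 0.08
        direct = mc.series_volume_average(theta, study_eig, forcing)
        integral, _ = quad(
            lambda R: R**2 * mc.series_profile(theta, [R], study_eig, forcing)[0],
            A,
            1.0,
            epsabs=1e-10,
            limit=300,
        )
        assert abs(direct - 3 / (1 - A**3) * integral) <= 1e-6


class TestGeometry:
    def test_defaults(self, geom):
        assert geom.skin_thickness == pytest.approx(4.0e-4, rel=1e-12)
        assert geom.A == pytest.approx(1.1 / 13.1, rel=1e-12)

    def test_invalid_ordering(self):
        with pytest.raises(DomainError):
            mc.Geometry(r_inner=0.014, r_flesh=0.0131, r_skin=0.0135)
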