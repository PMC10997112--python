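"""Orbit analysis: periodic orbits, transition matrix, stability region."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstab import (
    MidstanceState,
    SingularOrbitError,
    WalkerParams,
    half_step_constants,
    hof_gains,
    is_stable,
    midstance_map,
    periodic_orbit,
    recurrence_period,
    region_area,
    region_grid,
    region_vertices,
    region_vs_cadence,
    spectral_norm,
    transition_matrix,
    xcom,
)

OMEGA, T_STEP = 3.13, 0.5
C, S = half_step_constants(OMEGA, T_STEP)


def example_params(b_p=2.5, b_d=0.6, b_o=0.02, mode="alternating", omega=OMEGA, t_step=T_STEP):
    return WalkerParams(omega=omega, b_o=b_o, b_p=b_p, b_d=b_d, t_step=t_step, mode=mode)


class TestPeriodicOrbit:
    def test_no_offset_gives_rest_orbit(self):
        for mode in ("progressive", "alternating"):
            ref = periodic_orbit(example_params(b_o=0.0, mode=mode))
            assert ref.q == 0.0 and ref.v == 0.0

    def test_progressive_closed_form(self):
        ref = periodic_orbit(example_params(b_o=-0.05, mode="progressive"))
        assert ref.q == 0.0
        assert ref.v == pytest.approx(1.054, abs=2e-3)

    def test_alternating_closed_form(self):
        ref = periodic_orbit(example_params(b_o=0.02))
        assert ref.v == 0.0
        assert ref.q == pytest.approx(0.1387, abs=1e-4)

    def test_singular_denominators_raise(self):
        with pytest.raises(SingularOrbitError):
            periodic_orbit(
                example_params(b_d=2 * S / OMEGA, mode="progressive")
            )
        with pytest.raises(SingularOrbitError):
            periodic_orbit(example_params(b_p=2 * C, mode="alternating"))

    def test_recurrence_periods(self):
        assert recurrence_period(
            example_params(b_o=0.02, mode="alternating")
        ) == pytest.approx(2 * T_STEP, abs=1e-9)
        assert recurrence_period(
            example_params(b_o=-0.05, mode="progressive")
        ) == pytest.approx(T_STEP, abs=1e-9)


class TestTransitionMatrix:
    def test_closed_form_entries(self):
        A = transition_matrix(example_params())
        expected = np.array(
            [
                [C * C + S * S - C * 2.5, (2 * S / OMEGA - 0.6) * C],
                [(2 * C - 2.5) * S * OMEGA, C * C + S * S - S * OMEGA * 0.6],
            ]
        )
        np.testing.assert_allclose(A, expected, rtol=1e-15)

    def test_independent_of_mode_and_offset(self):
        A1 = transition_matrix(example_params(b_o=0.02, mode="alternating"))
        A2 = transition_matrix(example_params(b_o=-3.0, mode="progressive"))
        np.testing.assert_array_equal(A1, A2)

    def test_eigenvalue_minus_one_on_bp_boundary(self):
        A = transition_matrix(example_params(b_p=2 * C, b_d=0.8))
        lam = np.sort(np.linalg.eigvals(A).real)
        assert lam[0] == pytest.approx(-1.0, abs=1e-9)

    def test_eigenvalue_plus_one_on_bd_boundary(self):
        A = transition_matrix(example_params(b_p=1.8, b_d=2 * S / OMEGA))
        lam = np.sort(np.linalg.eigvals(A).real)
        assert lam[-1] == pytest.approx(1.0, abs=1e-9)

    def test_xcom_controller_spectral_norm(self):
        """Constant-XCoM-offset placement is strongly stable: rho ~ 0.21."""
        bp, bd = hof_gains(OMEGA, T_STEP)
        rho = spectral_norm(transition_matrix(example_params(b_p=bp, b_d=bd)))
        assert round(rho, 2) == 0.21

    @given(
        bp=st.floats(0.5, 3.5),
        bd=st.floats(0.1, 1.5),
        omega=st.floats(2.0, 5.0),
        t_step=st.floats(0.3, 0.9),
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_finite_difference_jacobian(self, bp, bd, omega, t_step):
        params = example_params(b_p=bp, b_d=bd, omega=omega, t_step=t_step)
        A = transition_matrix(params)
        h = 1e-6
        J = np.empty((2, 2))
        base = MidstanceState(0.01, -0.02, 0)
        for j, (dq, dv) in enumerate([(h, 0), (0, h)]):
            plus = midstance_map(params, MidstanceState(base.q + dq, base.v + dv, 0))
            minus = midstance_map(params, MidstanceState(base.q - dq, base.v - dv, 0))
            J[0, j] = (plus.q - minus.q) / (2 * h)
            J[1, j] = (plus.v - minus.v) / (2 * h)
        np.testing.assert_allclose(J, A, atol=1e-5)


class TestSpectralNorm:
    def test_identity(self):
        assert spectral_norm(np.eye(2)) == 1.0

    @pytest.mark.parametrize(
        "b_d, expected",
        [(0.3, 1.735), (0.6, 0.857), (1.1, 0.820), (1.5, 1.325)],
    )
    def test_derivative_gain_quartet(self, b_d, expected):
        """The four-system example: stable only for the middle gains."""
        rho = spectral_norm(transition_matrix(example_params(b_d=b_d)))
        assert rho == pytest.approx(expected, abs=5e-4)

    def test_complex_pair_modulus(self):
        A = transition_matrix(example_params(b_d=1.1))
        lam = np.linalg.eigvals(A)
        assert abs(lam[0].imag) > 0  # genuinely complex
        assert spectral_norm(A) == pytest.approx(np.max(np.abs(lam)), abs=1e-12)

    def test_agrees_with_numpy_eig(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            A = rng.normal(size=(2, 2))
            assert spectral_norm(A) == pytest.approx(
                np.max(np.abs(np.linalg.eigvals(A))), abs=1e-10
            )


class TestIsStable:
    @pytest.mark.parametrize(
        "b_d, stable", [(0.3, False), (0.6, True), (1.1, True), (1.5, False)]
    )
    def test_quartet_verdicts(self, b_d, stable):
        report = is_stable(example_params(b_d=b_d))
        assert report.stable is stable
        assert report.inequalities_hold is stable

    def test_boundary_is_marginal(self):
        report = is_stable(example_params(b_p=2 * C, b_d=0.8))
        assert not report.stable
        assert report.marginal

    def test_report_eigen_consistency(self):
        report = is_stable(example_params())
        lam1, lam2 = report.eigenvalues
        # eigenvalues solve the characteristic polynomial
        for lam in (complex(lam1), complex(lam2)):
            val = lam * lam - report.trace * lam + report.det
            assert abs(val) < 1e-10
        assert report.rho == pytest.approx(
            max(abs(complex(lam1)), abs(complex(lam2))), abs=1e-12
        )

    def test_inequalities_match_eigenvalues_randomized(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(2000):
            bp, bd = rng.uniform(0, 4), rng.uniform(0, 2)
            report = is_stable(example_params(b_p=bp, b_d=bd))
            if abs(report.rho - 1) < 1e-6:
                continue  # boundary excluded
            assert report.inequalities_hold == report.stable
            n_checked += 1
        assert n_checked > 1900


class TestRegionGeometry:
    def test_vertices_closed_form(self):
        v = region_vertices(OMEGA, T_STEP)
        np.testing.assert_allclose(
            v,
            [[1.13145, 0.55261], [2.64419, 0.55261], [2.64419, 1.29145]],
            atol=5e-5,
        )

    def test_vertices_have_unit_spectral_norm(self):
        for bp, bd in region_vertices(OMEGA, T_STEP):
            rho = spectral_norm(transition_matrix(example_params(b_p=bp, b_d=bd)))
            assert rho == pytest.approx(1.0, abs=1e-9)

    def test_short_step_limit_degenerates(self):
        v = region_vertices(OMEGA, 1e-4)
        # c -> 1, s -> 0: triangle collapses onto the b_p in {0, 2}, b_d = 0 edge
        assert v[0, 0] == pytest.approx(0.0, abs=1e-3)
        assert v[1, 0] == pytest.approx(2.0, abs=1e-3)
        assert np.all(v[:2, 1] < 1e-3)

    def test_grid_consistent_with_triangle(self):
        region = region_grid(OMEGA, T_STEP, (0.0, 3.5), (0.0, 1.6), (101, 81))
        BP, BD = np.meshgrid(region.bp, region.bd)
        c, s, w = C, S, OMEGA
        margin = 1e-3
        inside = (
            (BP < 2 * c - margin)
            & (BD > 2 * s / w + margin)
            & (BD < BP * c / (w * s) - margin)
        )
        outside = (
            (BP > 2 * c + margin)
            | (BD < 2 * s / w - margin)
            | (BD > BP * c / (w * s) + margin)
        )
        assert np.all(region.rho[inside] < 1.0)
        assert np.all(region.rho[outside] >= 1.0)

    def test_grid_minimum_not_above_xcom_controller(self):
        region = region_grid(OMEGA, T_STEP, (0.5, 3.0), (0.2, 1.4), (201, 201))
        assert np.nanmin(region.rho) <= 0.21

    def test_single_cell_grid_at_example_gains(self):
        region = region_grid(OMEGA, T_STEP, (2.5, 2.51), (0.6, 0.61), (2, 2))
        assert region.rho[0, 0] < 1.0

    def test_area_grows_with_leg_length(self):
        areas = [
            region_area(np.sqrt(9.81 / leg), T_STEP) for leg in (0.7, 0.9, 1.1)
        ]
        assert areas[0] < areas[1] < areas[2]


class TestCadenceSweep:
    def test_three_endpoints_decrease_with_cadence(self):
        """bp_min = 2s^2/c, bp_max = 2c and bd_min = 2s/omega are strictly
        decreasing in cadence everywhere: slower walking needs higher
        gains."""
        df = region_vs_cadence(OMEGA, (60.0, 140.0), 41)
        for col in ("bp_min", "bp_max", "bd_min"):
            assert np.all(np.diff(df[col]) < 0), col

    def test_bd_upper_endpoint_turns_at_asinh_one(self):
        """bd_max = 2c^2/(omega*s) is not monotone: it has a single
        minimum where omega*t_step/2 = asinh(1), i.e. near 106.5
        steps/min for omega = 3.13 s^-1, decreasing before and
        increasing after (in cadence)."""
        turn = 30.0 * OMEGA / np.arcsinh(1.0)
        assert turn == pytest.approx(106.54, abs=0.01)
        below = region_vs_cadence(OMEGA, (60.0, turn - 1.0), 21)
        above = region_vs_cadence(OMEGA, (turn + 1.0, 140.0), 21)
        assert np.all(np.diff(below["bd_max"]) < 0)
        assert np.all(np.diff(above["bd_max"]) > 0)

    def test_cadence_120_bd_interval(self):
        df = region_vs_cadence(OMEGA, 120.0)
        assert len(df) == 1
        assert df.loc[0, "bd_min"] == pytest.approx(0.55261, abs=5e-5)
        assert df.loc[0, "bd_max"] == pytest.approx(1.29145, abs=5e-5)

    def test_single_cadence_consistent_with_vertices(self):
        df = region_vs_cadence(OMEGA, 100.0)
        v = region_vertices(OMEGA, 0.6)
        assert df.loc[0, "bp_min"] == pytest.approx(v[0, 0])
        assert df.loc[0, "bp_max"] == pytest.approx(v[1, 0])
        assert df.loc[0, "bd_min"] == pytest.approx(v[0, 1])
        assert df.loc[0, "bd_max"] == pytest.approx(v[2, 1])


class TestHofGains:
    def test_values(self):
        bp, bd = hof_gains(OMEGA, T_STEP)
        assert bp == pytest.approx(2.1869, abs=5e-5)
        assert bd == pytest.approx(0.6987, abs=5e-5)

    def test_inside_region_across_step_times(self):
        for t_step in np.linspace(0.3, 1.0, 15):
            bp, bd = hof_gains(OMEGA, t_step)
            report = is_stable(
                example_params(b_p=bp, b_d=bd, t_step=t_step)
            )
            assert report.inequalities_hold and report.stable

    def test_near_deadbeat_determinant(self):
        bp, bd = hof_gains(OMEGA, T_STEP)
        A = transition_matrix(example_params(b_p=bp, b_d=bd))
        assert np.linalg.det(A) == pytest.approx(0.0, abs=1e-12)


class TestXCoM:
    def test_reduces_to_position_at_zero_velocity(self):
        assert xcom(0.3, 0.0, OMEGA) == 0.3

    def test_unit_velocity_scaling(self):
        assert xcom(0.0, OMEGA, OMEGA) == pytest.approx(1.0)

    def test_constant_on_contracting_invariant_arc(self):
        """On the stable manifold v = -omega*q the XCoM stays at zero."""
        from gaitstab import PendulumState, propagate

        q0 = 0.2
        state = PendulumState(0.0, q0, -OMEGA * q0, 0.0)
        for dt in (0.1, 0.3, 0.7):
            out = propagate(state, dt, OMEGA)
            assert xcom(out.q, out.v, OMEGA) == pytest.approx(0.0, abs=1e-12)


class TestConvergenceRate:
    def test_deviation_ratio_approaches_spectral_norm(self):
        """||delta_n||/||delta_{n-1}|| -> rho(A) for a generic perturbation."""
        params = example_params()  # rho ~ 0.857, real dominant eigenvalue
        rho = spectral_norm(transition_matrix(params))
        ref = periodic_orbit(params)
        ms = MidstanceState(ref.q + 0.01, ref.v + 0.003, 0)
        from gaitstab import orbit_reference

        devs = []
        for n in range(120):
            r = orbit_reference(params, ms.n)
            devs.append(np.hypot(ms.q - r.q, ms.v - r.v))
            ms = midstance_map(params, ms)
        ratios = np.array(devs[1:]) / np.array(devs[:-1])
        # subdominant eigenvalue (|lambda_2/lambda_1| ~ 0.93) dies off slowly
        assert ratios[-1] == pytest.approx(rho, rel=1e-3)
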