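import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson

from initmut.core_model import (
    RateParams,
    PiecewiseRates,
    cumulative_intensity,
    first_mutation_time,
    integrate_continuous_ode,
    integrate_piecewise_ode,
    intensity_inverse,
    mutation_fraction,
    mutation_rate,
)


class TestRateLaw:
    @pytest.mark.parametrize(
        "t,mu0,b,expected",
        [
            (0.0, 0.02, 5e-4, 0.02),        # e^0 = 1
            (123.0, 0.02, 0.0, 0.02),       # b=0: constant rate
            (1000.0, 0.01, 0.001, 0.01 * np.e),
        ],
    )
    def test_closed_form(self, t, mu0, b, expected):
        assert mutation_rate(t, RateParams(mu0, b)) == pytest.approx(expected, rel=1e-12)

    def test_monotone_with_sign_of_b(self):
        t = np.linspace(0, 500, 50)
        assert np.all(np.diff(mutation_rate(t, RateParams(0.02, 1e-4))) > 0)
        assert np.all(np.diff(mutation_rate(t, RateParams(0.02, -1e-4))) < 0)
        assert np.ptp(mutation_rate(t, RateParams(0.02, 0.0))) == 0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate(-1.0, RateParams(0.02))
        with pytest.raises(ValueError):
            cumulative_intensity(-0.5, RateParams(0.02))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RateParams(0.0)
        with pytest.raises(ValueError):
            RateParams(-0.01)
        with pytest.raises(ValueError):
            RateParams(0.02, float("nan"))


class TestCumulativeIntensity:
    @pytest.mark.parametrize(
        "t,mu0,b,expected",
        [
            (0.0, 0.02, 1e-4, 0.0),
            (50.0, 0.02, 0.0, 1.0),
            (100.0, 0.02, 2e-5, 0.02 / 2e-5 * np.expm1(2e-5 * 100)),  # 2.00200...
        ],
    )
    def test_closed_form(self, t, mu0, b, expected):
        assert cumulative_intensity(t, RateParams(mu0, b)) == pytest.approx(
            expected, abs=1e-12, rel=1e-12
        )

    def test_reference_value(self):
        # high-precision expm1 evaluation of (mu0/b)(e^{bt}-1)
        assert cumulative_intensity(100.0, RateParams(0.02, 2e-5)) == pytest.approx(
            2.002001334000267, rel=1e-12
        )

    @given(
        mu0=st.floats(1e-4, 1.0),
        b=st.floats(-1e-9, 1e-9),
        t=st.floats(1e-3, 500.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_continuity_in_b_at_zero(self, mu0, b, t):
        """For |b t| < 1e-6 the intensity matches the linear limit mu0*t."""
        if abs(b * t) < 1e-6:
            lam = cumulative_intensity(t, RateParams(mu0, b))
            assert lam == pytest.approx(mu0 * t, rel=1e-9 + abs(b * t))


class TestMutationFraction:
    def test_zero_class_is_survival_of_intensity(self):
        p = RateParams(0.02, 3e-5)
        for t in (0.0, 40.0, 300.0):
            lam = cumulative_intensity(t, p)
            assert mutation_fraction(0, t, p) == pytest.approx(np.exp(-lam))

    def test_pmf_value(self):
        # lambda = 1 exactly when mu0*t = 1 at b=0; p_2 = e^{-1}/2
        p = RateParams(0.02, 0.0)
        assert mutation_fraction(2, 50.0, p) == pytest.approx(np.exp(-1) / 2, rel=1e-12)

    def test_normalisation_and_truncated_tail(self):
        p = RateParams(0.05, 1e-4)
        t, k = 150.0, 6
        probs = [mutation_fraction(j, t, p, k=k) for j in range(k + 1)]
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)
        lam = cumulative_intensity(t, p)
        assert probs[k] == pytest.approx(poisson.sf(k - 1, lam))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            mutation_fraction(-1, 10.0, RateParams(0.02))


class TestContinuousODE:
    def test_matches_poisson_closed_form(self):
        """The truncated continuous-rate system has the Poisson solution,
        with the absorbing class collecting the upper tail."""
        p = RateParams(0.05, 1e-4)
        k = 8
        times = np.linspace(0.0, 380.0, 60)  # lambda up to ~20
        assert cumulative_intensity(times[-1], p) <= 20.5
        traj = integrate_continuous_ode(k, p, times)
        lam = cumulative_intensity(times, p)
        closed = np.column_stack(
            [poisson.pmf(j, lam) for j in range(k)] + [poisson.sf(k - 1, lam)]
        )
        assert np.abs(traj.fractions - closed).max() < 1e-6

    def test_conservation_and_absorbing_monotonicity(self):
        p = RateParams(0.02, 3e-5)
        traj = integrate_continuous_ode(5, p, np.linspace(0, 600, 80))
        assert traj.conservation_error() < 1e-8
        assert np.all(np.diff(traj.fractions[:, -1]) >= -1e-10)

    def test_negligible_rate_keeps_initial_condition(self):
        traj = integrate_continuous_ode(
            3, RateParams(1e-12, 0.0), np.linspace(0, 100, 10)
        )
        assert np.abs(traj.fractions[:, 0] - 1.0).max() < 1e-9

    def test_tidy_export(self, tmp_path):
        traj = integrate_continuous_ode(2, RateParams(0.02), np.linspace(0, 10, 5))
        df = traj.to_frame()
        assert list(df.columns) == ["time_days", "j", "fraction"]
        assert len(df) == 5 * 3
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        assert out.read_text().startswith("time_days,j,fraction")


class TestPiecewiseODE:
    def test_equal_rates_match_constant_continuous_system(self):
        times = np.linspace(0, 400, 50)
        c = 0.01
        a = integrate_piecewise_ode(PiecewiseRates((c,) * 4), times)
        b = integrate_continuous_ode(4, RateParams(c, 0.0), times)
        assert np.abs(a.fractions - b.fractions).max() < 1e-8

    def test_two_stage_closed_form(self):
        # k=2, mu_0 = mu_1 = 0.01: p_0(100) = e^{-1}
        traj = integrate_piecewise_ode(
            PiecewiseRates((0.01, 0.01)), np.linspace(0, 100, 11)
        )
        assert traj.fractions[-1, 0] == pytest.approx(np.exp(-1), abs=1e-8)

    def test_conservation(self):
        traj = integrate_piecewise_ode(
            PiecewiseRates((0.02, 0.03, 0.05)), np.linspace(0, 300, 40)
        )
        assert traj.conservation_error() < 1e-8

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            PiecewiseRates((0.01, -0.02))
        with pytest.raises(ValueError):
            PiecewiseRates(())


class TestFirstMutationTime:
    def test_b_zero_limit(self):
        assert first_mutation_time(1, RateParams(0.02, 0.0)) == pytest.approx(50.0)

    def test_closed_form(self):
        p = RateParams(0.02, 2e-5)
        expected = np.log(2e-5 * 28 / 0.02 + 1) / 2e-5
        assert first_mutation_time(28, p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("j", [1, 3, 10, 49])
    def test_inverse_of_cumulative_intensity(self, j):
        p = RateParams(0.0192, 1e-5)
        t = first_mutation_time(j, p)
        assert cumulative_intensity(t, p) == pytest.approx(j, abs=1e-10)

    def test_inverse_rejects_unreachable(self):
        # with b < 0 the intensity saturates at mu0/|b|
        with pytest.raises(ValueError):
            intensity_inverse(100.0, RateParams(0.01, -1e-3))
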