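"""Luz-Meiboom model evaluation, joint fitting, classification and MC errors."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecpmg import (
    FitConfig,
    classify_curve,
    exchange_bracket,
    fit_dispersion,
    model_r2eff,
    monte_carlo_errors,
)
from ecpmg.extraction import DispersionCurve
from ecpmg.fitting import ppm2_to_rad2, subsample_curve

NU_GRID = np.geomspace(200.0, 30000.0, 25)


def synthetic_curve(
    residue="A", field=600.0, r2_0=8.0, phi=0.01, tau=55e-6,
    sigma=0.0, seed=None, nu=NU_GRID,
):
    clean = model_r2eff(nu, r2_0, phi, tau, field)
    if seed is not None and sigma > 0:
        clean = clean + np.random.default_rng(seed).standard_normal(nu.size) * sigma
    return DispersionCurve(residue, field, nu, clean, np.full(nu.size, sigma))


class TestExchangeBracket:
    def test_unit_argument(self):
        assert exchange_bracket(1.0) == pytest.approx(1.0 - np.tanh(1.0), rel=1e-12)

    def test_zero_limit(self):
        assert exchange_bracket(0.0) == 1.0

    def test_series_branch_agrees_with_direct_formula(self):
        """Just above the switch the series matches the exact expression."""
        for x in (20.5, 40.0, 80.0):
            direct = 1.0 - x * np.tanh(1.0 / x)  # still ~1e-13 accurate here
            assert exchange_bracket(x) == pytest.approx(direct, rel=1e-6)

    def test_large_argument_asymptotics(self):
        x = 1e8
        assert exchange_bracket(x) == pytest.approx(1.0 / (3 * x * x), rel=1e-6)

    @given(st.floats(1e-3, 1e6))
    def test_monotone_decreasing(self, x):
        assert exchange_bracket(x * 1.01) < exchange_bracket(x)


class TestModelR2eff:
    def test_no_exchange_returns_baseline(self):
        nu = np.array([300.0, 3000.0, 30000.0])
        np.testing.assert_allclose(model_r2eff(nu, 12.0, 0.0, 5e-5, 600.0), 12.0)

    def test_zero_frequency_limit(self):
        """As nu -> 0 the exchange term saturates at phi_ex * tau_ex."""
        phi_ppm2, tau, field = 0.01, 55e-6, 600.0
        expected = 5.0 + ppm2_to_rad2(phi_ppm2, field) * tau
        assert model_r2eff(1e-3, 5.0, phi_ppm2, tau, field) == pytest.approx(
            expected, rel=1e-6
        )

    def test_quarter_period_matching(self):
        """At 4*nu*tau = 1 with phi*tau = 10 (rad units): 5 + 10*(1 - tanh 1)."""
        tau, nu, field = 50e-6, 5000.0, 600.0
        phi_rad2 = 10.0 / tau
        phi_ppm2 = phi_rad2 / (2 * np.pi * field) ** 2
        assert model_r2eff(nu, 5.0, phi_ppm2, tau, field) == pytest.approx(
            7.3840, abs=1e-4
        )

    def test_infinite_frequency_returns_baseline(self):
        assert model_r2eff(1e9, 9.0, 0.01, 5e-5, 600.0) == pytest.approx(9.0, abs=1e-3)

    @given(
        tau_us=st.floats(1.0, 500.0),
        phi=st.floats(1e-4, 0.05),
        nu=st.floats(100.0, 2.9e4),
    )
    def test_monotonically_non_increasing_in_frequency(self, tau_us, phi, nu):
        lo = model_r2eff(nu, 5.0, phi, tau_us * 1e-6, 600.0)
        hi = model_r2eff(nu * 1.1, 5.0, phi, tau_us * 1e-6, 600.0)
        assert hi <= lo + 1e-12


class TestFitDispersion:
    def test_noise_free_single_field_recovery(self):
        curve = synthetic_curve()
        result = fit_dispersion([curve], FitConfig())
        assert result.converged and result.classification == "exchange"
        assert result.tau_ex == pytest.approx(55e-6, rel=1e-3)
        ff = result.field_fits[600.0]
        assert ff.phi_ex_ppm2 == pytest.approx(0.01, rel=1e-3)
        assert ff.r2_0 == pytest.approx(8.0, rel=1e-3)

    def test_two_field_joint_fit_shares_tau(self):
        c600 = synthetic_curve(field=600.0)
        c800 = synthetic_curve(field=800.0, r2_0=9.5)
        result = fit_dispersion([c600, c800], FitConfig())
        assert result.tau_ex == pytest.approx(55e-6, rel=1e-3)
        assert result.field_fits[600.0].phi_ex_ppm2 == pytest.approx(
            result.field_fits[800.0].phi_ex_ppm2, rel=1e-3
        )

    def test_flat_noise_free_curve_classified_flat(self):
        curve = synthetic_curve(phi=0.0, r2_0=14.0)
        result = fit_dispersion([curve], FitConfig())
        assert result.classification == "flat"
        assert "tau_unidentifiable" in result.flags
        summary = result.flat_summary[600.0]
        assert summary["mean_r2eff"] == pytest.approx(14.0)
        assert summary["rmsd"] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_flagged(self):
        curve = synthetic_curve(nu=np.array([500.0, 5000.0]))
        result = fit_dispersion([curve], FitConfig())
        assert not result.converged and "too_few_points" in result.flags

    def test_deterministic(self):
        curve = synthetic_curve(sigma=0.2, seed=5)
        r1 = fit_dispersion([curve], FitConfig())
        r2 = fit_dispersion([curve], FitConfig())
        assert r1.tau_ex == r2.tau_ex and r1.chi2 == r2.chi2


class TestClassifyCurve:
    def test_threshold_is_strict(self):
        """An amplitude exactly at the threshold is classified flat, not exchange."""
        curve = synthetic_curve(phi=0.0039, tau=55e-6)
        first = classify_curve(curve, FitConfig())
        ff = first.field_fits[600.0]
        amplitude = model_r2eff(
            curve.nu_cpmg[0], ff.r2_0, ff.phi_ex_ppm2, first.tau_ex, 600.0
        ) - model_r2eff(
            curve.nu_cpmg[-1], ff.r2_0, ff.phi_ex_ppm2, first.tau_ex, 600.0
        )
        at_threshold = classify_curve(
            curve, FitConfig(inclusion_threshold=float(amplitude))
        )
        assert at_threshold.classification == "flat"

    def test_amplitude_above_threshold_is_exchange(self):
        # amplitude ~3 1/s at 600 MHz
        curve = synthetic_curve(phi=0.0039, tau=55e-6)
        result = classify_curve(curve, FitConfig())
        assert result.classification == "exchange"

    def test_insufficient_sampling_withheld(self):
        short = synthetic_curve(nu=np.geomspace(200, 1000, 4))
        result = classify_curve(short, FitConfig())
        assert result.classification is None
        assert "insufficient_sampling" in result.flags

    def test_narrow_span_withheld(self):
        narrow = synthetic_curve(nu=np.linspace(1000, 5000, 8))
        assert classify_curve(narrow, FitConfig()).classification is None


class TestMonteCarloErrors:
    def test_zero_sigma_gives_zero_errors(self):
        curve = synthetic_curve(sigma=0.0)
        cfg = FitConfig(mc_runs=20, seed=1)
        result = monte_carlo_errors(fit_dispersion([curve], cfg), [curve], cfg)
        assert result.tau_ex_err == pytest.approx(0.0, abs=1e-12)
        assert result.field_fits[600.0].phi_ex_err_ppm2 == pytest.approx(0.0, abs=1e-15)

    def test_default_runs_500(self):
        curve = synthetic_curve(sigma=0.2, seed=3)
        cfg = FitConfig(seed=1)
        assert cfg.mc_runs == 500
        result = monte_carlo_errors(fit_dispersion([curve], cfg), [curve], cfg)
        assert result.mc_runs_done == 500
        assert result.tau_ex_err > 0

    def test_reproducible_for_fixed_seed(self):
        curve = synthetic_curve(sigma=0.2, seed=3)
        cfg = FitConfig(mc_runs=50, seed=9)
        r1 = monte_carlo_errors(fit_dispersion([curve], cfg), [curve], cfg)
        r2 = monte_carlo_errors(fit_dispersion([curve], cfg), [curve], cfg)
        assert r1.tau_ex_err == r2.tau_ex_err

    def test_errors_scale_linearly_with_noise(self):
        """Doubling the per-point sigma roughly doubles the parameter errors."""
        errs = {}
        for sigma in (0.2, 0.4):
            curve = synthetic_curve(sigma=sigma, seed=11)
            cfg = FitConfig(mc_runs=200, seed=2)
            result = monte_carlo_errors(fit_dispersion([curve], cfg), [curve], cfg)
            errs[sigma] = result.tau_ex_err
        ratio = errs[0.4] / errs[0.2]
        assert 1.6 <= ratio <= 2.4


def test_subsample_curve_is_seeded():
    curve = synthetic_curve()
    s1 = subsample_curve(curve, 10, seed=4)
    s2 = subsample_curve(curve, 10, seed=4)
    assert len(s1) == 10
    np.testing.assert_array_equal(s1.nu_cpmg, s2.nu_cpmg)
    assert "subsampled" in s1.flags
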