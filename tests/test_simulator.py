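"""Phase cycling, relaxation mixing, and spin propagation through the echo train."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

from ecpmg import (
    ExchangeParams,
    PhaseCycle,
    PulseCalibration,
    build_schedule,
    compute_entry,
    linear_decay_slope,
    make_phase_cycle,
    model_r2eff,
    run_cpmg_plane,
    simulate_experiment,
    transverse_fraction,
)
from ecpmg.simulator import (
    BASE_PHASES_FIRST,
    BASE_PHASES_SECOND,
    bloch_mcconnell_generator,
)

NO_EXCHANGE = ExchangeParams(p_a=0.95, k_ex=0.0, delta_omega_ppm=0.0, r1=1.0, r2=20.0)


def r2eff(entry, schedule, params, **kwargs):
    return -np.log(run_cpmg_plane(entry, schedule, params, **kwargs)) / schedule.t_cpmg


class TestPhaseCycle:
    def test_first_half_base(self):
        assert make_phase_cycle(4, "first") == ["y", "y", "-x", "x"]

    def test_second_half_base(self):
        assert make_phase_cycle(4, "second") == ["-y", "y", "-x", "-x"]

    def test_supercycle_is_cyclic_permutation_of_base(self):
        phases = make_phase_cycle(16, "first")
        base = list(BASE_PHASES_FIRST)
        for shift in range(4):
            block = phases[4 * shift : 4 * shift + 4]
            assert block == base[shift:] + base[:shift]

    def test_long_trains_repeat_the_supercycle(self):
        assert make_phase_cycle(48) == make_phase_cycle(16) * 3

    def test_indivisible_train_rejected(self):
        with pytest.raises(ValueError, match="divisible by 4"):
            make_phase_cycle(6)

    def test_phase_cycle_object(self):
        pc = PhaseCycle(half="second")
        assert pc.base_phases == BASE_PHASES_SECOND
        assert len(pc.supercycle) == 16


class TestTransverseFraction:
    def test_base_cycle_mixes_three_quarters(self):
        assert transverse_fraction(BASE_PHASES_FIRST, "y") == pytest.approx(0.75)

    def test_spin_lock_limit(self):
        assert transverse_fraction(["y"] * 8, "y") == 1.0

    def test_pure_inversion_limit(self):
        assert transverse_fraction(["x"] * 8, "y") == 0.5

    def test_second_half_base_also_three_quarters(self):
        assert transverse_fraction(BASE_PHASES_SECOND, "y") == pytest.approx(0.75)


class TestGeometricModel:
    def test_compensated_no_exchange_is_flat(self, sched600):
        rates = [
            r2eff(e, sched600, NO_EXCHANGE, model="geometric", pulse_model="finite")
            for e in sched600.cpmg_entries
        ]
        assert max(rates) - min(rates) < 1e-9
        assert rates[0] == pytest.approx(20.0, abs=1e-9)

    def test_equal_rates_kill_the_artifact(self, cal600):
        sched = build_schedule([2000.0, 10000.0], 0.040, cal600, divisor=4)
        params = ExchangeParams(p_a=0.95, k_ex=0.0, delta_omega_ppm=0.0, r1=5.0, r2=5.0)
        rates = [
            r2eff(e, sched, params, pulse_model="finite", compensated=False)
            for e in sched.cpmg_entries
        ]
        assert rates[0] == pytest.approx(rates[1], abs=1e-9)
        assert rates[0] == pytest.approx(5.0, abs=1e-9)

    def test_uncompensated_rate_at_10_khz(self, cal600):
        """R2 - (R2-R1)*nu*tau180/2 = 18.404 1/s for R2=20, R1=1 at 10 kHz."""
        sched = build_schedule([10000.0], 0.040, cal600, divisor=4)
        rate = r2eff(
            sched.cpmg_entries[0], sched, NO_EXCHANGE,
            pulse_model="finite", compensated=False,
        )
        assert rate == pytest.approx(18.404, abs=1e-9)

    def test_offset_rejected(self, sched600):
        params = ExchangeParams(
            p_a=0.95, k_ex=0.0, delta_omega_ppm=0.0, r1=1.0, r2=20.0, offset_ppm=1.0
        )
        with pytest.raises(ValueError, match="on-resonance"):
            run_cpmg_plane(sched600.cpmg_entries[0], sched600, params)


class TestLinearDecaySlope:
    def test_analytic_value(self, cal600):
        assert linear_decay_slope(NO_EXCHANGE, cal600) == pytest.approx(
            -1.596e-4, rel=1e-6
        )

    def test_vanishes_for_equal_rates(self, cal600):
        params = ExchangeParams(p_a=0.9, k_ex=0.0, delta_omega_ppm=0.0, r1=7.0, r2=7.0)
        assert linear_decay_slope(params, cal600) == 0.0

    def test_offset_at_2_khz_is_significant(self, cal600):
        """The artifact reaches ~0.32 1/s at 2 kHz, growing linearly beyond."""
        assert linear_decay_slope(NO_EXCHANGE, cal600) * 2000.0 == pytest.approx(
            -0.3192, abs=1e-4
        )

    @pytest.mark.parametrize("r2", [6.0, 15.0, 31.0])
    def test_simulated_uncompensated_slope_matches(self, cal800, r2):
        """Regression on Bloch-McConnell uncompensated curves recovers the slope."""
        params = ExchangeParams(p_a=0.95, k_ex=0.0, delta_omega_ppm=0.0, r1=1.0, r2=r2)
        ns = [80, 320, 640, 960, 1200]
        sched = build_schedule([n / 0.040 for n in ns], 0.040, cal800, divisor=16)
        nus, rates = [], []
        for e in sched.cpmg_entries:
            nus.append(e.nu_cpmg)
            rates.append(
                r2eff(e, sched, params, model="bloch_mcconnell",
                      pulse_model="finite", compensated=False)
            )
        slope = np.polyfit(nus, rates, 1)[0]
        assert slope == pytest.approx(linear_decay_slope(params, cal800), rel=0.02)


class TestBlochMcConnell:
    def test_finite_pulse_compensated_flatness(self, sched600):
        rates = [
            r2eff(e, sched600, NO_EXCHANGE, model="bloch_mcconnell", pulse_model="finite")
            for e in sched600.cpmg_entries
        ]
        assert all(abs(r - 20.0) < 0.1 for r in rates)

    def test_delta_pulse_matches_luz_meiboom_in_fast_exchange(self, cal600):
        """Numeric two-site propagation against the closed form, k_ex = 18*dw."""
        params = ExchangeParams(
            p_a=0.95, k_ex=2.0e4, delta_omega_ppm=0.3, r1=1.0, r2=10.0
        )
        amp = params.phi_ex_rad2(600.0) * params.tau_ex
        sched = build_schedule(np.geomspace(200, 30000, 15), 0.040, cal600, divisor=4)
        for e in sched.cpmg_entries:
            bm = r2eff(e, sched, params, model="bloch_mcconnell", pulse_model="delta")
            lm = model_r2eff(e.nu_cpmg, 10.0, params.phi_ex_ppm2(), params.tau_ex, 600.0)
            assert abs(bm - lm) <= 0.02 * amp

    def test_phase_inversion_symmetry(self, sched600):
        params = ExchangeParams(
            p_a=0.95, k_ex=2.0e4, delta_omega_ppm=0.3, r1=1.0, r2=10.0
        )
        e = sched600.cpmg_entries[4]
        direct = run_cpmg_plane(e, sched600, params, model="bloch_mcconnell")
        flipped = run_cpmg_plane(
            e, sched600, params, model="bloch_mcconnell", invert_phases=True
        )
        assert direct == pytest.approx(flipped, abs=1e-12)

    @given(
        offset=st.floats(-2.0, 2.0),
        dw=st.floats(0.0, 1.0),
        phase=st.sampled_from(["x", "-x", "y", "-y"]),
        duration_us=st.floats(1.0, 100.0),
    )
    def test_propagators_are_orthogonal_without_relaxation(self, offset, dw, phase, duration_us):
        """With all rates zero the 6x6 generator is skew, so norms are conserved."""
        params = ExchangeParams(
            p_a=0.7, k_ex=0.0, delta_omega_ppm=dw, r1=0.0, r2=0.0, offset_ppm=offset
        )
        L = bloch_mcconnell_generator(params, 600.0, w1=np.pi / 16.8e-6, phase=phase)
        P = expm(L * duration_us * 1e-6)
        assert np.allclose(P.T @ P, np.eye(6), atol=1e-12)


class TestSimulateExperiment:
    def test_noiseless_equals_plane_model(self, sched600):
        table = simulate_experiment(sched600, [("A", NO_EXCHANGE)], noise_sigma=0.0)
        for _, row in table.data[table.data.nu_cpmg_hz.notna()].iterrows():
            entry = next(
                e for e in sched600.entries
                if not e.is_reference and e.nu_cpmg == row.nu_cpmg_hz
            )
            expected = run_cpmg_plane(entry, sched600, NO_EXCHANGE, pulse_model="delta")
            assert row.intensity == pytest.approx(expected, rel=1e-12)

    def test_same_seed_reproduces_table(self, sched600):
        import pandas.testing as pdt

        t1 = simulate_experiment(sched600, [("A", NO_EXCHANGE)], noise_sigma=0.01, seed=7)
        t2 = simulate_experiment(sched600, [("A", NO_EXCHANGE)], noise_sigma=0.01, seed=7)
        pdt.assert_frame_equal(t1.data, t2.data)

    def test_different_seed_differs(self, sched600):
        t1 = simulate_experiment(sched600, [("A", NO_EXCHANGE)], noise_sigma=0.01, seed=7)
        t2 = simulate_experiment(sched600, [("A", NO_EXCHANGE)], noise_sigma=0.01, seed=8)
        assert not np.allclose(t1.data.intensity, t2.data.intensity)

    def test_ppm2_parameterization_is_field_invariant(self, cal600, cal800):
        """Exchange amplitudes at two fields agree once expressed in ppm^2."""
        params = ExchangeParams(
            p_a=0.95, k_ex=1.0 / 55e-6, delta_omega_ppm=0.3, r1=1.0, r2=10.0
        )
        for cal in (cal600, cal800):
            sched = build_schedule([500.0], 0.040, cal, divisor=4)
            rate = r2eff(sched.cpmg_entries[0], sched, params, pulse_model="delta")
            expected = model_r2eff(
                500.0, 10.0, params.phi_ex_ppm2(), 55e-6, cal.larmor_mhz
            )
            assert rate == pytest.approx(expected, rel=1e-9)


def test_exchange_params_validation():
    with pytest.raises(ValueError):
        ExchangeParams(p_a=1.2, k_ex=1.0, delta_omega_ppm=0.1, r1=1.0, r2=5.0)
    with pytest.raises(ValueError):
        ExchangeParams(p_a=0.9, k_ex=1.0, delta_omega_ppm=0.1, r1=5.0, r2=1.0)
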