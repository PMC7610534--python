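"""Calorimetry reductions: integration, dilution control, normalisation."""

import numpy as np
import pytest

from nanowrap.itc import (
    HeatSeries,
    InjectionSchedule,
    Thermogram,
    gibbs_identity,
    integrate_thermogram,
    normalize_enthalpy,
    subtract_dilution,
)
from nanowrap.synthetic_data import gen_thermogram


@pytest.fixture(scope="module")
def schedule():
    return InjectionSchedule()


class TestIntegrateThermogram:
    def test_zero_power_gives_zero_heats(self, schedule):
        trace, _ = gen_thermogram(schedule, [0.0] * 13, noise_sd=0.0)
        heats = integrate_thermogram(trace, schedule)
        assert np.allclose(heats.heats, 0.0, atol=1e-9)
        assert len(heats.heats) == schedule.count + 1
        assert heats.first_discardable

    def test_constant_offset_absorbed_by_baseline(self, schedule):
        trace, _ = gen_thermogram(
            schedule, [0.0] * 13, noise_sd=0.0, baseline_power=5.0
        )
        heats = integrate_thermogram(trace, schedule)
        assert np.allclose(heats.heats, 0.0, atol=1e-9)

    def test_recovers_known_heats_without_noise(self, schedule):
        """Noiseless recovery is exact up to the onset half-bin of the
        centred-bin sampling, ~dt/(4*tau) ~ 0.3% at the defaults."""
        truth_heats = list(np.linspace(-10.0, -4.0, 12))
        trace, truth = gen_thermogram(
            schedule, truth_heats, peak_tau=8.0, noise_sd=0.0, drift=0.01
        )
        heats = integrate_thermogram(trace, schedule)
        rel = np.abs(
            (heats.heats[1:] - truth["heats_uJ"][1:]) / truth["heats_uJ"][1:]
        )
        assert np.max(rel) < 5e-3

    def test_recovers_known_heats_from_noisy_trace(self, schedule):
        """At 0.02 uW white noise the per-injection heat uncertainty is
        ~0.15 uJ (window + baseline-fit noise); every recovered heat stays
        within 0.5 uJ of truth."""
        truth_heats = list(np.linspace(-10.0, -4.0, 12))
        trace, truth = gen_thermogram(
            schedule, truth_heats, peak_tau=8.0, noise_sd=0.02, seed=1
        )
        heats = integrate_thermogram(trace, schedule)
        assert np.max(np.abs(heats.heats[1:] - truth["heats_uJ"][1:])) < 0.5

    def test_affine_drift_invariance(self, schedule):
        """Adding any affine function of time changes recovered heats by <0.5%."""
        truth_heats = list(np.linspace(-10, -4, 12))
        trace, _ = gen_thermogram(schedule, truth_heats, noise_sd=0.02, seed=3)
        heats_plain = integrate_thermogram(trace, schedule)
        tilted = Thermogram(trace.time, trace.power + 7.0 + 0.004 * trace.time)
        heats_tilted = integrate_thermogram(tilted, schedule)
        rel_change = np.abs(
            (heats_tilted.heats[1:] - heats_plain.heats[1:]) / heats_plain.heats[1:]
        )
        assert np.max(rel_change) < 0.005

    def test_truncated_trace_names_missing_injections(self, schedule):
        trace, _ = gen_thermogram(schedule, [0.0] * 13, noise_sd=0.0)
        short = Thermogram(trace.time[:5000], trace.power[:5000])
        with pytest.raises(ValueError, match="windows"):
            integrate_thermogram(short, schedule)


class TestSubtractDilution:
    def test_control_equal_to_sample_gives_zeros(self):
        sample = HeatSeries(np.array([-10.0, -8.0]))
        assert np.allclose(subtract_dilution(sample, sample).heats, 0.0)

    def test_zero_control_is_identity(self):
        sample = HeatSeries(np.array([-10.0, -8.0]))
        control = HeatSeries(np.zeros(2))
        assert np.allclose(subtract_dilution(sample, control).heats, sample.heats)

    def test_elementwise_difference(self):
        sample = HeatSeries(np.array([-10.0, -8.0]))
        control = HeatSeries(np.array([-1.0, -1.0]))
        assert np.allclose(subtract_dilution(sample, control).heats, [-9.0, -7.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            subtract_dilution(HeatSeries(np.zeros(3)), HeatSeries(np.zeros(2)))


class TestNormalizeEnthalpy:
    def test_five_nm_stock_in_cell(self):
        # dQ = -0.7664 uJ over SA_Au = 7.664e-4 m^2 -> -1.00 mJ/m^2
        heats = HeatSeries(np.array([-0.1, -0.7664]), first_discardable=True)
        result = normalize_enthalpy(heats, sa_au_m2=7.664e-4)
        assert result.delta_H == pytest.approx(-1.00, rel=1e-3)

    def test_zero_heat_zero_enthalpy(self):
        heats = HeatSeries(np.array([0.0, 0.0]))
        assert normalize_enthalpy(heats, 1e-3).delta_H == 0.0

    def test_chained_form_matches_direct_quotient(self):
        heats = HeatSeries(np.array([-0.1, -0.7664]))
        rng = np.random.default_rng(11)
        for sa_l in 10 ** rng.uniform(-5, 0, size=20):
            result = normalize_enthalpy(heats, 7.664e-4, sa_l_m2=float(sa_l))
            assert result.delta_H == pytest.approx(-1.00, rel=1e-3)

    def test_linear_in_heat_inverse_in_area(self):
        h1 = HeatSeries(np.array([0.0, -2.0]))
        h2 = HeatSeries(np.array([0.0, -4.0]))
        assert normalize_enthalpy(h2, 1e-3).delta_H == pytest.approx(
            2 * normalize_enthalpy(h1, 1e-3).delta_H
        )
        assert normalize_enthalpy(h1, 2e-3).delta_H == pytest.approx(
            normalize_enthalpy(h1, 1e-3).delta_H / 2
        )

    def test_sign_preserved_and_mean_reported(self):
        heats = HeatSeries(np.array([-0.1, -2.0, -4.0, -6.0]))
        result = normalize_enthalpy(heats, 1e-3)
        assert result.delta_H < 0
        assert result.delta_H_mean == pytest.approx(
            np.mean([-2.0, -4.0, -6.0]) * 1e-6 / 1e-3 * 1e3
        )

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            normalize_enthalpy(HeatSeries(np.array([0.0, -1.0])), 0.0)


class TestGibbsIdentity:
    def test_zero_entropy_makes_enthalpy_the_free_energy(self):
        assert gibbs_identity(298.15, delta_H=-1.0, delta_S=0.0) == -1.0

    def test_equal_g_and_h_imply_zero_entropy(self):
        assert gibbs_identity(298.15, delta_H=-3.0, delta_G=-3.0) == 0.0

    def test_solve_for_entropy(self):
        assert gibbs_identity(250.0, delta_H=-2.0, delta_G=-5.0) == pytest.approx(
            0.012
        )

    def test_solve_for_enthalpy(self):
        assert gibbs_identity(300.0, delta_G=-5.0, delta_S=0.01) == pytest.approx(
            -2.0
        )

    def test_underdetermined_call_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            gibbs_identity(298.15, delta_H=-1.0)
        with pytest.raises(ValueError, match="exactly one"):
            gibbs_identity(298.15, delta_H=-1.0, delta_S=0.0, delta_G=-1.0)
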