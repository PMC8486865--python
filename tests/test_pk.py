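"""Plasma pharmacokinetics: binding, clearance, release, exchange."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oncotherm.geometry import ProtocolConfig
from oncotherm.pk import (PKRates, PKVolumes, binding_step, simulate_plasma_pk,
                          thermodox_release_rate, vessel_feedback_check)
from oncotherm.protocols import default_protocol_config


class TestBinding:
    def test_no_association_keeps_bound_zero(self):
        rates = PKRates(k_a=0.0)
        F, B = 1.0, 0.0
        for _ in range(100):
            F, B = binding_step(F, B, rates, 1.0)
        assert B == 0.0

    def test_step_conserves_total(self):
        rates = PKRates()
        F, B = 0.7, 0.3
        F2, B2 = binding_step(F, B, rates, 5.0)
        assert F2 + B2 == pytest.approx(1.0, abs=1e-15)

    def test_equilibrium_free_fraction_is_quarter(self):
        """Integrating the pure binding pair from an all-free bolus settles at
        F/(F+B) = k_d/(k_a+k_d) = 25%."""
        rates = PKRates()
        F, B = 1.0, 0.0
        for _ in range(20000):
            F, B = binding_step(F, B, rates, 1.0)
        assert F / (F + B) == pytest.approx(0.25, abs=1e-9)
        assert B == pytest.approx(3.0 * F, rel=1e-6)

    def test_bound_roughly_three_times_free_in_full_run(self):
        series = simulate_plasma_pk(default_protocol_config("classical_chemo"),
                                    duration=7200, dt=1.0)
        i = len(series.times) // 2
        ratio = series.systemic["B"][i] / series.systemic["F"][i]
        assert ratio == pytest.approx(3.0, rel=0.05)


class TestRelease:
    def test_leak_rate_at_body_temperature(self):
        rates = PKRates()
        assert thermodox_release_rate(37.0, rates) == rates.k_leak

    def test_95_percent_release_within_a_minute_at_41C(self):
        rates = PKRates()
        k = thermodox_release_rate(41.0, rates)
        assert 1.0 - np.exp(-k * 60.0) >= 0.95

    @settings(derandomize=True, max_examples=50)
    @given(t1=st.floats(30.0, 50.0), t2=st.floats(30.0, 50.0))
    def test_monotone_temperature_trigger(self, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        assert thermodox_release_rate(lo) <= thermodox_release_rate(hi)


class TestPlasmaPK:
    def test_mass_conserved_without_sinks(self):
        rates = PKRates(k_el_F=0.0, k_el_B=0.0, k_el_T=0.0, k_endo=0.0,
                        k_leak=0.0, Q_perf=0.0)
        series = simulate_plasma_pk(default_protocol_config("classical_chemo"),
                                    rates, duration=3600, dt=1.0)
        m0 = series.total_plasma_mass(0)
        assert series.total_plasma_mass(-1) == pytest.approx(m0, rel=1e-8)

    def test_free_drug_half_life_below_30_minutes(self):
        series = simulate_plasma_pk(default_protocol_config("classical_chemo"),
                                    duration=7200, dt=1.0, store_every=10)
        F = series.systemic["F"]
        idx = np.argmax(F < 0.5 * F[0])
        assert 0 < series.times[idx] < 30 * 60

    def test_dose_linearity_of_trajectories(self):
        s1 = simulate_plasma_pk(default_protocol_config("thermodox", 50.0),
                                duration=3600, dt=1.0)
        s2 = simulate_plasma_pk(default_protocol_config("thermodox", 100.0),
                                duration=3600, dt=1.0)
        for key in ("T", "F", "B"):
            assert np.allclose(s2.systemic[key], 2.0 * s1.systemic[key],
                               rtol=1e-10, atol=1e-20)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(data=st.data())
    def test_trajectories_stay_nonnegative(self, data):
        rate = st.floats(0.0, 5e-3)
        rates = PKRates(k_a=data.draw(rate), k_d=data.draw(rate),
                        k_el_F=data.draw(rate), k_el_B=data.draw(rate),
                        k_el_T=data.draw(rate), k_endo=data.draw(rate),
                        Q_perf=data.draw(st.floats(0.0, 0.1)),
                        k_leak=data.draw(st.floats(0.0, 1e-4)))
        series = simulate_plasma_pk(default_protocol_config("thermodox", 50.0),
                                    rates, duration=1200, dt=1.0)
        for side in (series.systemic, series.vessel):
            for arr in side.values():
                assert np.all(arr >= 0.0)


class TestVesselFeedback:
    def test_default_ratio_perturbs_systemic_below_one_percent(self):
        cfg = default_protocol_config("thermodox", 50.0)
        assert vessel_feedback_check(cfg, duration=3600.0) < 0.01

    def test_zero_ratio_gives_zero_feedback(self):
        cfg = default_protocol_config("classical_chemo", 50.0)
        vol = PKVolumes(vtp_over_vsp=0.0)
        assert vessel_feedback_check(cfg, volumes=vol, duration=1800.0) == 0.0

    def test_feedback_grows_with_volume_ratio(self):
        cfg = default_protocol_config("thermodox", 50.0)
        small = vessel_feedback_check(cfg, volumes=PKVolumes(vtp_over_vsp=1e-3),
                                      duration=1800.0)
        large = vessel_feedback_check(cfg, volumes=PKVolumes(vtp_over_vsp=5e-2),
                                      duration=1800.0)
        assert large > small


def test_thermodox_vessel_concentration_collapses_under_heating(thermodox_50):
    """Intravascular burst release empties the tumor-vessel carrier pool by
    >= 90% relative to the unheated (systemic) level during the heating hour."""
    d = thermodox_50.delivery
    i = np.searchsorted(d.times, 3500.0)
    decline = 1.0 - d.vessel["T"][i] / d.systemic["T"][i]
    assert decline >= 0.90
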