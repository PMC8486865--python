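"""Focused-ultrasound field (O'Neil oracle), CEM43 dose, and lesion zoning."""

import numpy as np
import pytest

from oncotherm.hifu import (AcousticMedium, AxisymGrid, TransducerSpec,
                            ZONE_ALPHA, ZONE_BETA, ZONE_GAMMA, ZONE_NONE,
                            build_perfusion_damage, classify_ablation_zones,
                            compute_acoustic_field, compute_thermal_dose,
                            oneil_axial_pressure, solve_focal_bioheat)


class TestAcousticField:
    def test_onaxis_matches_oneil_closed_form(self):
        """Numerical Rayleigh integral vs the O'Neil solution on axis,
        away from pressure nulls, to < 3%."""
        spec = TransducerSpec()
        medium = AcousticMedium()
        z = np.arange(0.030, 0.070, 1.5e-4)
        exact = oneil_axial_pressure(spec, medium, z, lossless=True)
        grid = AxisymGrid(r=np.array([0.0, 1.5e-4]), z=z)
        field = compute_acoustic_field(spec, medium, grid, lossless=True)
        num = field.pressure_amplitude[:, 0]
        mask = exact > 0.05 * exact.max()
        assert np.max(np.abs(num[mask] - exact[mask]) / exact[mask]) < 0.03

    def test_zero_power_gives_zero_field(self):
        spec = TransducerSpec(acoustic_power=0.0)
        grid = AxisymGrid.around_focus(spec, half_width=2e-3)
        field = compute_acoustic_field(spec, AcousticMedium(), grid,
                                       n_rings=32, n_azimuth=32)
        assert np.all(field.pressure_amplitude == 0.0)
        assert np.all(field.heat_source == 0.0)

    def test_pressure_peaks_near_geometric_focus(self, hifu_run):
        spec, medium, grid, field, _, _ = hifu_run
        jz, jr = np.unravel_index(np.argmax(field.pressure_amplitude),
                                  field.pressure_amplitude.shape)
        lam = medium.wavelength(spec.frequency)
        assert abs(grid.z[jz] - spec.focal_length) < lam
        assert grid.r[jr] < lam

    def test_coarse_grid_refused_with_spacing_message(self):
        spec = TransducerSpec()
        grid = AxisymGrid(r=np.arange(0, 2e-3, 5e-4),
                          z=np.arange(0.046, 0.050, 5e-4))
        with pytest.raises(ValueError, match="need <="):
            compute_acoustic_field(spec, AcousticMedium(), grid)

    def test_heat_source_consistent_with_intensity(self, hifu_run):
        spec, medium, _, field, _, _ = hifu_run
        expected = 2.0 * medium.absorption(spec.frequency) * field.intensity
        assert np.allclose(field.heat_source, expected)


class TestThermalDose:
    def test_constant_43_definition(self):
        times = np.linspace(0, 600, 601)
        T = np.full((601, 1), 43.0)
        assert compute_thermal_dose(times, T)[0] == pytest.approx(10.0, rel=1e-9)

    def test_constant_47_sixteen_equivalent_minutes(self):
        times = np.linspace(0, 60, 121)
        T = np.full((121, 1), 47.0)
        assert compute_thermal_dose(times, T)[0] == pytest.approx(16.0, rel=1e-9)

    def test_body_temperature_hour_matches_brute_force(self):
        # brute-force left-rectangle sum at 1 s resolution
        times = np.arange(0, 3601.0)
        T = np.full((times.size, 1), 37.0)
        brute = sum(0.25 ** (43.0 - 37.0) * (1.0 / 60.0)
                    for _ in range(times.size - 1))
        assert compute_thermal_dose(times, T)[0] == pytest.approx(brute, rel=1e-9)
        assert brute == pytest.approx(60 * 0.25**6, rel=1e-12)

    def test_dose_monotone_in_duration(self, hifu_run):
        *_, heating, _ = hifu_run
        # recompute the dose from truncations of the focal history
        t, T = heating.focal_times, heating.focal_T[:, None]
        d_short = compute_thermal_dose(t[:1500], T[:1500])
        d_long = compute_thermal_dose(t, T)
        assert d_long[0] >= d_short[0]


class TestLesionZoning:
    def test_uniform_44C_minute_is_gamma_only(self):
        dose = np.full((4, 4), 4.0)  # 44 degC for 1 min -> 4 equivalent min
        peak = np.full((4, 4), 44.0)
        zones = classify_ablation_zones(dose, peak)
        assert np.all(zones.zone == ZONE_GAMMA)

    def test_huge_dose_is_alpha(self):
        zones = classify_ablation_zones(np.array([[1e4]]), np.array([[80.0]]))
        assert zones.zone[0, 0] == ZONE_ALPHA

    def test_default_run_zones_nest_around_focus(self, hifu_run):
        spec, _, grid, _, heating, lesion = hifu_run
        R2, Z2 = np.meshgrid(grid.r, grid.z)
        dist = np.sqrt(R2**2 + (Z2 - spec.focal_length) ** 2)
        ext = {}
        for code in (ZONE_ALPHA, ZONE_BETA, ZONE_GAMMA):
            m = lesion.zone == code
            assert m.any()
            ext[code] = dist[m].max()
        assert ext[ZONE_ALPHA] < ext[ZONE_BETA] < ext[ZONE_GAMMA]

    def test_gamma_peak_temperature_below_45(self, hifu_run):
        *_, heating, lesion = hifu_run
        gamma = lesion.zone == ZONE_GAMMA
        assert np.all(heating.peak_T[gamma] < 45.0)
        assert np.all(heating.peak_T[gamma] >= 43.0)

    def test_focal_temperature_exceeds_65C(self, hifu_run):
        *_, heating, _ = hifu_run
        assert heating.peak_focal_temperature > 65.0

    def test_zone_extent_shrinks_with_power(self, hifu_run):
        spec, medium, grid, _, heating, _ = hifu_run
        weak_spec = TransducerSpec(acoustic_power=15.0)
        field = compute_acoustic_field(weak_spec, medium, grid, n_rings=64,
                                       n_azimuth=64)
        weak = solve_focal_bioheat(field)
        lesion_hi = classify_ablation_zones(heating.cem43, heating.peak_T, grid)
        lesion_lo = classify_ablation_zones(weak.cem43, weak.peak_T, grid)
        for code in (ZONE_ALPHA, ZONE_BETA):
            assert np.sum(lesion_lo.zone == code) < np.sum(lesion_hi.zone == code)


class TestPerfusionDamage:
    def test_damage_factors_by_zone(self):
        zone = np.array([[ZONE_ALPHA, ZONE_BETA, ZONE_GAMMA, ZONE_NONE]])
        lesion = classify_ablation_zones(np.zeros((1, 4)), np.zeros((1, 4)))
        lesion.zone = zone
        dmg = build_perfusion_damage(lesion)
        assert dmg[0, 0] == 0.0          # no perfusion in the necrotic core
        assert dmg[0, 1] == pytest.approx(0.2)   # under the 25% bound
        assert dmg[0, 1] < 0.25
        assert dmg[0, 2] == 0.5          # half perfusion in gamma
        assert dmg[0, 3] == 1.0
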