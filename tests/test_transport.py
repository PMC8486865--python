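"""Interstitial transport: Patlak flux vs a pore-diffusion oracle, cellular
exchange, and the coupled delivery invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_bvp

from oncotherm.geometry import Zone, build_domain
from oncotherm.pd import PDParams
from oncotherm.transport import (TransportParams, cellular_exchange,
                                 transvascular_flux, _diffusion_bands)
from scipy.linalg import solve_banded


def pore_flux_oracle(C_v, C_i, v_f, P, L=1.0e-6):
    """Numerically integrate steady advection-diffusion across a membrane of
    thickness L and permeability P = D/L; returns the area flux J such that
    J = v C - D dC/dx with C(0) = C_v, C(L) = C_i."""
    D = P * L

    def rhs(x, y):
        C, J = y
        return np.vstack([(v_f * C - J) / D, np.zeros_like(J)])

    def bc(ya, yb):
        return np.array([ya[0] - C_v, yb[0] - C_i])

    x = np.linspace(0.0, L, 200)
    y0 = np.vstack([np.linspace(C_v, C_i, x.size),
                    np.full(x.size, P * (C_v - C_i))])
    sol = solve_bvp(rhs, bc, x, y0, tol=1e-10, max_nodes=200000)
    assert sol.success
    return sol.y[1][0]


class TestPatlakFlux:
    def test_diffusive_limit_without_filtration(self):
        J = transvascular_flux(1.0, 0.25, 0.0, 1e-7, 0.1, 2e4)
        assert J == pytest.approx(1e-7 * 2e4 * 0.75, rel=1e-12)

    def test_zero_gradient_zero_filtration_gives_zero(self):
        assert transvascular_flux(0.5, 0.5, 0.0, 1e-7, 0.1, 2e4) == 0.0

    def test_pure_convective_limit_when_impermeable(self):
        phi_v = 2e-4
        J = transvascular_flux(1.0, 0.9, phi_v, 0.0, 0.95, 7e3)
        assert J == pytest.approx(phi_v * 0.05 * 1.0, rel=1e-12)

    def test_matches_pore_transport_oracle_on_random_draws(self):
        """The Patlak formula equals the numerically integrated 1-D pore
        transport solution to better than 1e-6 relative."""
        rng = np.random.default_rng(42)
        SV = 2.0e4
        for _ in range(12):
            P = 10 ** rng.uniform(-8.5, -6.5)
            sigma = rng.uniform(0.0, 0.95)
            phi_v = 10 ** rng.uniform(-6, -3.5)
            C_v, C_i = rng.uniform(0.0, 1.0, 2)
            v_f = phi_v * (1 - sigma) / SV
            if v_f / P > 20:  # keep the oracle's boundary layer resolvable
                continue
            J = transvascular_flux(C_v, C_i, phi_v, P, sigma, SV)
            J_oracle = SV * pore_flux_oracle(C_v, C_i, v_f, P)
            assert J == pytest.approx(J_oracle, rel=1e-6, abs=1e-12)

    def test_permeability_multiplier_scales_diffusive_part(self):
        J1 = transvascular_flux(1.0, 0.0, 0.0, 1e-7, 0.1, 2e4, perm_mult=1.0)
        J2 = transvascular_flux(1.0, 0.0, 0.0, 1e-7, 0.1, 2e4, perm_mult=2.0)
        assert J2 == pytest.approx(2.0 * J1, rel=1e-12)


class TestCellularExchange:
    def test_balance_point_has_no_net_flux(self):
        tp = TransportParams()
        C_F = 1.0
        C_int = tp.xi / tp.eps * C_F
        F2, I2 = cellular_exchange(C_F, C_int, tp.xi, tp.eps, 37.0, 10.0)
        assert F2 == pytest.approx(C_F, abs=1e-15)
        assert I2 == pytest.approx(C_int, abs=1e-15)

    def test_step_conserves_total(self):
        F2, I2 = cellular_exchange(0.8, 0.1, 5e-4, 1e-3, 40.0, 30.0)
        assert F2 + I2 == pytest.approx(0.9, abs=1e-15)

    def test_hyperthermia_multiplies_initial_uptake_slope_by_2_4(self):
        tp = TransportParams()
        dt = 1.0
        _, I_cold = cellular_exchange(1.0, 0.0, tp.xi, tp.eps, 37.0, dt)
        _, I_hot = cellular_exchange(1.0, 0.0, tp.xi, tp.eps, 42.6, dt)
        assert I_hot / I_cold == pytest.approx(2.4, rel=1e-9)


class TestConservation:
    def test_uniform_field_invariant_under_diffusion(self):
        dom, _ = build_domain()
        ab = _diffusion_bands(dom, 5e-11, 60.0)
        C = np.full(dom.n_nodes, 0.3)
        C2 = solve_banded((1, 1), ab, C)
        assert np.allclose(C2, 0.3, rtol=1e-12)

    def test_diffusion_conserves_total_mass(self):
        dom, _ = build_domain()
        rng = np.random.default_rng(7)
        C = rng.random(dom.n_nodes)
        ab = _diffusion_bands(dom, 5e-11, 60.0)
        C2 = solve_banded((1, 1), ab, C)
        assert np.sum(C2 * dom.node_volumes) == pytest.approx(
            np.sum(C * dom.node_volumes), rel=1e-12)

    def test_whole_system_mass_audit_below_half_percent(self, classical_50,
                                                        thermodox_50):
        assert classical_50.delivery.mass_audit_max < 0.005
        assert thermodox_50.delivery.mass_audit_max < 0.005


class TestDeliveryInvariants:
    def test_free_drug_accumulates_in_proliferative_zone(self, classical_50,
                                                         domain_zones):
        dom, zn = domain_zones
        F = classical_50.delivery.fields["F"]
        peak_per_node = np.where(dom.tumor_mask, F.max(axis=0), 0.0)
        assert zn.zone_of_node[np.argmax(peak_per_node)] == Zone.PROLIFERATIVE

    def test_carrier_accumulates_at_tumor_periphery(self, thermodox_50,
                                                    domain_zones):
        dom, _ = domain_zones
        d = thermodox_50.delivery
        CT = d.fields["T"]
        avg = d.tumor_avg["T"]
        rim = np.argmin(np.abs(dom.node_positions - 4.9e-3))
        center = np.argmin(np.abs(dom.node_positions - 0.5e-3))
        active = avg > 0.2 * avg.max()
        active[0] = False  # both zero before any extravasation
        assert np.all(CT[active, rim] > CT[active, center])

    def test_net_backflux_after_heating(self, thermodox_50, domain_zones):
        """After the hyperthermia window, the locally released drug returns
        to the microvessels somewhere (negative transvascular flux)."""
        dom, zn = domain_zones
        d = thermodox_50.delivery
        tp = TransportParams()
        i = np.searchsorted(d.times, 5400.0)
        P_F = np.where(dom.tumor_mask, tp.P_F_tumor, tp.P_F_normal)
        C_near = np.where(dom.tumor_mask, d.vessel["F"][i], d.systemic["F"][i])
        J = transvascular_flux(C_near, d.fields["F"][i],
                               thermodox_50.flow.phi_v, P_F, tp.sigma_f_F,
                               zn.surface_area_density)
        assert J.min() < 0.0

    def test_thermochemo_delivers_more_free_drug_than_classical(
            self, thermochemo_50, classical_50):
        ia = np.trapezoid(thermochemo_50.delivery.tumor_avg["F"],
                          thermochemo_50.delivery.times)
        ib = np.trapezoid(classical_50.delivery.tumor_avg["F"],
                          classical_50.delivery.times)
        assert ia > ib

    def test_intracellular_washout_after_plasma_clearance(self, classical_50):
        """Intracellular drug is essentially gone a few hours after the
        plasma has cleared: ~2% of peak at 5 h, under 1% by 6.5 h."""
        d = classical_50.delivery
        ci = d.tumor_avg["int"]
        peak = ci.max()
        i5 = np.searchsorted(d.times, 5 * 3600.0)
        i65 = np.searchsorted(d.times, 6.5 * 3600.0)
        assert ci[i5] < 0.02 * peak
        assert ci[i65] < 0.01 * peak

    def test_intracellular_peak_lags_extracellular_by_20_minutes(
            self, classical_50):
        d = classical_50.delivery
        lag = (d.times[np.argmax(d.tumor_avg["int"])]
               - d.times[np.argmax(d.tumor_avg["F"])]) / 60.0
        assert lag == pytest.approx(20.0, abs=5.0)
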