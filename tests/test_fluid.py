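"""Interstitial flow solver against the spherical analytic solution and its
conservation/monotonicity properties."""

import numpy as np
import pytest

from oncotherm.fluid import FluidParams, solve_interstitial_flow, \
    apply_perfusion_damage_to_flow
from oncotherm.geometry import build_domain


def analytic_uniform_tumor_ifp(r, R, p_e, alpha):
    """Closed-form IFP for a uniform spherical tumor with p(R) = 0:
    p(r) = p_e [1 - (R/r) sinh(alpha r / R) / sinh(alpha)]."""
    out = np.empty_like(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = p_e * (1.0 - (R / r) * np.sinh(alpha * r / R) / np.sinh(alpha))
    out[r == 0] = p_e * (1.0 - alpha / np.sinh(alpha))
    return out


@pytest.fixture(scope="module")
def uniform_tumor():
    # single-zone tumor without a normal shell; fine grid for the oracle
    dom, zn = build_domain(tumor_radius=5e-3, normal_shell_thickness=0.0,
                           grid_spacing=2.5e-5, zone_boundaries=(0.0, 0.0))
    return dom, zn


def test_matches_spherical_analytic_solution(uniform_tumor):
    dom, zn = uniform_tumor
    params = FluidParams()
    field = solve_interstitial_flow(dom, zn, params)
    p_e = params.effective_pressure(normal=False)
    SV = zn.surface_area_density[0]
    alpha = np.sqrt(params.Lp_tumor * SV * dom.tumor_radius**2 / params.K_tumor)
    exact = analytic_uniform_tumor_ifp(dom.node_positions, dom.tumor_radius,
                                       p_e, alpha)
    assert np.max(np.abs(field.ifp - exact)) / p_e < 0.01


def test_center_pressure_approaches_effective_pressure(uniform_tumor):
    dom, zn = uniform_tumor
    params = FluidParams()
    field = solve_interstitial_flow(dom, zn, params)
    p_e = params.effective_pressure(normal=False)
    assert field.ifp[0] == pytest.approx(p_e, rel=0.02)


def test_velocity_peaks_at_rim_and_vanishes_at_center(domain_zones):
    dom, zn = domain_zones
    field = solve_interstitial_flow(dom, zn)
    speed = np.abs(field.ifv)
    rim = np.argmin(np.abs(dom.node_positions - dom.tumor_radius))
    assert abs(np.argmax(speed) - rim) <= 2
    assert speed[0] == 0.0
    assert speed[5] < 0.05 * speed.max()


def test_global_mass_balance(domain_zones):
    dom, zn = domain_zones
    field = solve_interstitial_flow(dom, zn)
    assert field.mass_balance_error < 1e-10
    assert field.residual_norm < 1e-10


def test_ifp_plateau_over_inner_half_radius(domain_zones):
    dom, zn = domain_zones
    field = solve_interstitial_flow(dom, zn)
    inner = dom.node_positions <= dom.tumor_radius / 2
    plateau = field.ifp[inner]
    assert (plateau.max() - plateau.min()) / plateau.max() < 0.05


def test_plateau_rises_toward_pe_with_Lp(domain_zones):
    dom, zn = domain_zones
    p_e = FluidParams().effective_pressure(normal=False)
    centers = []
    for scale in (0.5, 1.0, 4.0):
        params = FluidParams(Lp_tumor=2.1e-11 * scale)
        centers.append(solve_interstitial_flow(dom, zn, params).ifp[0])
    assert centers[0] < centers[1] < centers[2] < p_e


def test_darcy_consistency(domain_zones):
    dom, zn = domain_zones
    params = FluidParams()
    field = solve_interstitial_flow(dom, zn, params)
    # interior tumor nodes: v = -K dp/dr (central difference)
    dr = dom.grid_spacing
    i = slice(1, 40)
    grad = (field.ifp[2:41] - field.ifp[0:39]) / (2 * dr)
    assert np.allclose(field.ifv[i], -params.K_tumor * grad, rtol=1e-12)


class TestPerfusionDamage:
    def test_identity_damage_is_identity(self, domain_zones):
        dom, zn = domain_zones
        base = solve_interstitial_flow(dom, zn)
        same = apply_perfusion_damage_to_flow(dom, zn, FluidParams(),
                                              np.ones(dom.n_nodes))
        assert np.allclose(base.ifp, same.ifp)

    def test_zero_damage_kills_source(self, domain_zones):
        dom, zn = domain_zones
        damage = np.ones(dom.n_nodes)
        damage[:20] = 0.0
        field = apply_perfusion_damage_to_flow(dom, zn, FluidParams(), damage)
        assert np.all(field.phi_v[:20] == 0.0)

    def test_half_damage_halves_flux_at_fixed_pressure(self, domain_zones):
        dom, zn = domain_zones
        params = FluidParams()
        base = solve_interstitial_flow(dom, zn, params)
        damage = np.ones(dom.n_nodes)
        damage[20:30] = 0.5
        field = apply_perfusion_damage_to_flow(dom, zn, params, damage)
        # phi_v = damage * Lp * S/V * (p_e - p): at equal pressure the source
        # coefficient exactly halves
        p_e = params.effective_pressure(normal=False)
        coeff_base = base.phi_v[25] / (p_e - base.ifp[25])
        coeff_half = field.phi_v[25] / (p_e - field.ifp[25])
        assert coeff_half == pytest.approx(0.5 * coeff_base, rel=1e-12)

    def test_damage_out_of_range_rejected(self, domain_zones):
        dom, zn = domain_zones
        with pytest.raises(ValueError):
            apply_perfusion_damage_to_flow(dom, zn, FluidParams(),
                                           np.full(dom.n_nodes, 1.5))
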