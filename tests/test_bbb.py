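from decimal import Decimal, getcontext

import numpy as np
import pytest

import brainunit as bu
from brainunit.bbb import assemble_exchange_terms, bbb_flux, compose_permeability, exchange_rates
from brainunit.ecf import ECFGrid
from brainunit.plasma import build_capillary_graph


@pytest.fixture(scope="module")
def passive_only():
    return bu.BBBParams(P=1e-8)


@pytest.fixture(scope="module")
def full_params(defaults):
    return defaults.bbb


class TestFluxLaw:
    def test_passive_equilibrium_is_zero(self, passive_only):
        assert bbb_flux(123.0, 123.0, passive_only).total_flux == 0.0

    def test_half_saturation_gives_half_maximal_rate(self):
        p = bu.BBBParams(P=0.0, T_m_in=2e-13, T_m_out=0.0, K_m_in=1e2,
                         SA_BBB=1e-8)
        mu_internal = p.K_m_in_internal            # μ = K_m_in
        res = bbb_flux(mu_internal, 0.0, p)
        assert res.total_flux == pytest.approx(p.T_m_in / (2 * p.SA_BBB), rel=1e-12)

    def test_reference_values_against_decimal_arithmetic(self, full_params):
        """Term-by-term re-evaluation in 50-digit decimal arithmetic."""
        getcontext().prec = 50
        p = full_params
        mu, rho = 1.0e3, 0.0                        # 1 and 0 μmol/L internal
        res = bbb_flux(mu, rho, p)
        P, Tin, Tout = Decimal(p.P), Decimal(p.T_m_in), Decimal(p.T_m_out)
        sa = Decimal(p.SA_BBB)
        km_in = Decimal(p.K_m_in) * 1000
        md, rd = Decimal(mu), Decimal(rho)
        expected = P * (md - rd) + Tin / (sa * (km_in + md)) * md
        assert res.total_flux == pytest.approx(float(expected), rel=1e-12)
        assert res.total_flux == pytest.approx(
            res.passive_part + res.active_in_part - res.active_out_part, rel=1e-12)

    def test_monotone_in_mu_and_antitone_in_rho(self, full_params):
        grid = np.linspace(0.0, 5e5, 40)
        for rho in (0.0, 1e3, 4e5):
            f = bbb_flux(grid, np.full_like(grid, rho), full_params).total_flux
            assert np.all(np.diff(f) > 0)
        for mu in (0.0, 1e3, 4e5):
            f = bbb_flux(np.full_like(grid, mu), grid, full_params).total_flux
            assert np.all(np.diff(f) < 0)

    def test_active_influx_saturates(self, full_params):
        p = full_params
        mu = 1e6 * p.K_m_in_internal
        res = bbb_flux(mu, 0.0, p)
        assert res.active_in_part == pytest.approx(p.T_m_in / p.SA_BBB, rel=1e-4)

    def test_passive_antisymmetry(self, passive_only):
        f1 = bbb_flux(7.0, 2.0, passive_only).total_flux
        f2 = bbb_flux(2.0, 7.0, passive_only).total_flux
        assert f1 == -f2

    def test_negative_concentration_rejected(self, passive_only):
        with pytest.raises(ValueError):
            bbb_flux(-1.0, 0.0, passive_only)

    def test_active_rate_without_area_rejected(self):
        with pytest.raises(Exception):
            bu.BBBParams(P=1e-8, T_m_in=1e-13, SA_BBB=0.0)


class TestComposePermeability:
    def test_zero_fractions(self):
        assert compose_permeability(1e-6, 0.0, 1e-10, 1e-8, 0.0) == 0.0

    def test_purely_transcellular(self):
        assert compose_permeability(3e-7, 1.0, 1e-10, 1e-8, 0.0) == 3e-7

    def test_paracellular_route(self):
        assert compose_permeability(0.0, 0.0, 1e-10, 1e-8, 0.001) \
            == pytest.approx(1e-5, rel=1e-12)

    def test_overlapping_fractions_warn(self):
        with pytest.warns(UserWarning):
            compose_permeability(1e-7, 0.9, 1e-10, 1e-8, 0.5)

    def test_composition_used_when_P_absent(self):
        p = bu.BBBParams(p_trans=1e-8, f_trans=1.0, f_para=0.0)
        assert p.permeability == 1e-8


@pytest.fixture(scope="module")
def setup(defaults):
    graph = build_capillary_graph(defaults.geometry, 9)
    grid = ECFGrid.from_geometry(defaults.geometry, 8, 8, 8)
    plan = assemble_exchange_terms(graph, grid.face_centers_yz(),
                                   grid.h_y * grid.h_z)
    return graph, grid, plan


class TestExchangeAssembly:

    def test_every_boundary_cell_paired(self, setup, defaults):
        graph, grid, plan = setup
        L = graph.unit_length
        for plane, x_plane in ((0, 0.0), (1, L)):
            nodes = plan.plane_nodes[plane]
            assert nodes.shape == (grid.n_y * grid.n_z,)
            np.testing.assert_allclose(graph.coords[nodes][:, 0], x_plane, atol=1e-18)
            assert graph.inlet not in nodes and graph.outlet not in nodes

    def test_zero_flux_gives_zero_rates(self, setup, defaults):
        graph, grid, plan = setup
        mu = np.zeros(graph.n_nodes)
        zero = np.zeros(grid.n_y * grid.n_z)
        for coupling in ("plane_mean", "per_node"):
            w, e, sink, transfer = exchange_rates(plan, defaults.bbb, mu, zero, zero,
                                                  grid.cell_volume, coupling=coupling)
            assert not np.any(w) and not np.any(e) and not np.any(sink)
            assert transfer == 0.0

    @pytest.mark.parametrize("coupling", ["plane_mean", "per_node"])
    def test_pairwise_conservation(self, setup, defaults, coupling, rng):
        graph, grid, plan = setup
        mu = rng.random(graph.n_nodes) * 1e3
        rho_w = rng.random(grid.n_y * grid.n_z) * 1e2
        rho_e = rng.random(grid.n_y * grid.n_z) * 1e2
        w, e, sink, transfer = exchange_rates(plan, defaults.bbb, mu, rho_w, rho_e,
                                              grid.cell_volume, coupling=coupling)
        ecf_gain = (np.sum(w) + np.sum(e)) * grid.cell_volume
        plasma_loss = -np.sum(sink * plan.plasma_volumes)
        assert ecf_gain == pytest.approx(transfer, rel=1e-12)
        assert plasma_loss == pytest.approx(transfer, rel=1e-12)

    def test_uniform_passive_gradient_all_cells_gain(self, setup):
        graph, grid, plan = setup
        p = bu.BBBParams(P=1e-8)
        mu = np.full(graph.n_nodes, 1e3)
        zero = np.zeros(grid.n_y * grid.n_z)
        w, e, sink, transfer = exchange_rates(plan, p, mu, zero, zero,
                                              grid.cell_volume, coupling="per_node")
        assert np.all(w > 0) and np.all(e > 0)
        lost = {n for plane in (0, 1) for n in plan.plane_nodes[plane]}
        assert np.all(sink[list(lost)] < 0)
        # per-pair equality: each cell's gain matches its node's share of loss
        node_loss = -sink * plan.plasma_volumes
        gain_by_node = np.zeros_like(node_loss)
        for plane, src in ((0, w), (1, e)):
            np.add.at(gain_by_node, plan.plane_nodes[plane], src * grid.cell_volume)
        np.testing.assert_allclose(node_loss, gain_by_node, rtol=1e-12, atol=1e-30)

    def test_coupled_step_conserves_total_drug(self, defaults, small_grid_overrides):
        params = bu.default_parameters(**small_grid_overrides)
        res = bu.run_simulation(params)
        report = bu.mass_audit(res, tolerance=1e-10)
        assert report.passed, report
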