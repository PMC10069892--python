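"""Closed-form respiration models: growth/maintenance decomposition, the
general unit-cost sum, the nitrogen-carbon growth ODE, and FvCB algebra."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respitraits import (FvCBFluxes, GrowthMaintenanceParams, NCGrowthParams,
                         UnitCostSpec, cue_from_fvcb, fvcb_assimilation,
                         rd_from_assimilation, respiration_eq1,
                         respiration_general, simulate_nc_growth)

finite = st.floats(min_value=0.0, max_value=1e3,
                   allow_nan=False, allow_infinity=False)


class TestGrowthMaintenance:
    def test_components_add_up(self):
        params = GrowthMaintenanceParams(gR=0.25, mR=0.01)
        total, growth, maint = respiration_eq1(params, dWdt=4.0, W=100.0)
        assert growth == pytest.approx(1.0)
        assert maint == pytest.approx(1.0)
        assert total == pytest.approx(2.0)

    def test_zero_coefficients_give_zero_respiration(self):
        params = GrowthMaintenanceParams(gR=0.0, mR=0.0)
        assert respiration_eq1(params, 123.0, 456.0)[0] == 0.0

    def test_no_growth_leaves_pure_maintenance(self):
        params = GrowthMaintenanceParams(gR=0.3, mR=0.02)
        total, growth, maint = respiration_eq1(params, 0.0, 50.0)
        assert growth == 0.0
        assert total == maint == pytest.approx(1.0)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            GrowthMaintenanceParams(gR=-0.1, mR=0.0)

    @given(g=finite, m=finite, d1=finite, d2=finite, w1=finite, w2=finite,
           scale=st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_growth_and_biomass(self, g, m, d1, d2, w1, w2, scale):
        params = GrowthMaintenanceParams(gR=g, mR=m)
        r_sum = respiration_eq1(params, d1 + d2, w1 + w2)[0]
        r_parts = respiration_eq1(params, d1, w1)[0] + \
            respiration_eq1(params, d2, w2)[0]
        assert r_sum == pytest.approx(r_parts, rel=1e-9, abs=1e-9)
        assert respiration_eq1(params, scale * d1, scale * w1)[0] == \
            pytest.approx(scale * respiration_eq1(params, d1, w1)[0],
                          rel=1e-9, abs=1e-9)


class TestGeneralParadigm:
    def test_weighted_sum_of_process_rates(self):
        spec = UnitCostSpec(costs={"p1": 0.2, "p2": 0.05},
                            rates={"p1": 10.0, "p2": 40.0})
        assert respiration_general(spec) == pytest.approx(4.0)

    def test_empty_rates_give_zero(self):
        assert respiration_general(UnitCostSpec(costs={"p": 1.0}, rates={})) == 0.0

    def test_reduces_to_growth_maintenance_decomposition(self):
        params = GrowthMaintenanceParams(gR=0.25, mR=0.01)
        dwdt, w = 4.0, 100.0
        spec = UnitCostSpec(costs={"growth": params.gR, "maintenance": params.mR},
                            rates={"growth": dwdt, "maintenance": w})
        assert respiration_general(spec) == \
            pytest.approx(respiration_eq1(params, dwdt, w)[0])

    def test_rates_without_costs_rejected(self):
        with pytest.raises(ValueError):
            UnitCostSpec(costs={}, rates={"p": 1.0})

    def test_negative_cost_warns_but_is_allowed(self, caplog):
        with caplog.at_level("WARNING"):
            spec = UnitCostSpec(costs={"carboxylation": -1.0}, rates={"carboxylation": 2.0})
        assert respiration_general(spec) == pytest.approx(-2.0)
        assert any("negative CO2 cost" in r.message for r in caplog.records)


PARAM_GRID = [
    # (gR, mR, phiCN, Np, gamma, k, W0) spanning growth, decay, equilibrium
    (0.25, 0.015, 2.0, 5.0, 0.01, 0.5, 1.0),
    (0.25, 0.015, 2.0, 5.0, 0.01, 0.5, 50.0),
    (0.1, 0.0, 1.5, 2.0, 0.02, 1.0, 10.0),
    (0.0, 0.05, 1.0, 1.0, 0.0, 1.0, 3.0),
    (0.5, 0.1, 3.0, 0.0, 0.05, 0.7, 20.0),   # Np = 0: pure decay
    (0.3, 0.02, 2.5, 8.0, 0.015, 0.4, 0.0),  # start from zero biomass
    (0.2, 0.01, 0.0, 5.0, 0.01, 0.5, 7.0),   # no N conversion
    (0.15, 0.03, 1.2, 3.0, 0.0, 0.9, 5.0),
    (0.4, 0.0, 2.0, 4.0, 0.03, 0.6, 2.0),
    (0.05, 0.2, 4.0, 10.0, 0.1, 0.3, 100.0),
    (0.25, 0.015, 0.5, 0.5, 0.005, 2.0, 1.0),
    (0.6, 0.08, 1.0, 6.0, 0.02, 1.5, 30.0),
    (0.0, 0.0, 2.0, 5.0, 0.0, 0.5, 4.0),     # b = 0: linear growth
    (0.33, 0.07, 2.2, 7.0, 0.04, 0.8, 15.0),
    (0.12, 0.01, 3.5, 1.0, 0.06, 0.25, 0.5),
    (0.45, 0.12, 1.8, 9.0, 0.02, 1.2, 60.0),
    (0.28, 0.04, 2.7, 3.5, 0.03, 0.55, 8.0),
    (0.09, 0.25, 0.8, 2.5, 0.07, 0.35, 12.0),
    (0.52, 0.02, 1.4, 4.5, 0.01, 0.65, 25.0),
    (0.2, 0.06, 2.9, 6.5, 0.05, 0.45, 40.0),
]


class TestNCGrowthODE:
    @pytest.mark.parametrize("gR,mR,phiCN,Np,gamma,k,W0", PARAM_GRID)
    def test_integrator_matches_closed_form(self, gR, mR, phiCN, Np, gamma, k, W0):
        gm = GrowthMaintenanceParams(gR=gR, mR=mR)
        nc = NCGrowthParams(phiCN=phiCN, Np=Np, gamma=gamma, k=k, W0=W0)
        traj = simulate_nc_growth(gm, nc, np.linspace(0.0, 50.0, 26))
        ref = traj.closed_form()
        scale = np.maximum(np.abs(ref), 1e-300)
        assert np.max(np.abs(traj.W - ref) / scale) <= 1e-8

    def test_equilibrium_start_stays_constant(self):
        gm = GrowthMaintenanceParams(gR=0.25, mR=0.02)
        nc = NCGrowthParams(phiCN=2.0, Np=5.0, gamma=0.01, k=0.5, W0=1.0)
        a = nc.phiCN * nc.Np / (nc.k * (1 + gm.gR))
        b = (nc.phiCN * nc.gamma + gm.mR) / (1 + gm.gR)
        nc_eq = NCGrowthParams(phiCN=2.0, Np=5.0, gamma=0.01, k=0.5, W0=a / b)
        traj = simulate_nc_growth(gm, nc_eq, np.linspace(0.0, 30.0, 16))
        assert np.allclose(traj.W, a / b, rtol=1e-8)
        assert np.allclose(traj.dWdt, 0.0, atol=1e-8)

    def test_no_nitrogen_pool_decays_exponentially(self):
        gm = GrowthMaintenanceParams(gR=0.5, mR=0.1)
        nc = NCGrowthParams(phiCN=3.0, Np=0.0, gamma=0.05, k=0.7, W0=20.0)
        traj = simulate_nc_growth(gm, nc, np.linspace(0.0, 20.0, 11))
        b = (nc.phiCN * nc.gamma + gm.mR) / (1 + gm.gR)
        assert np.allclose(traj.W, 20.0 * np.exp(-b * traj.t), rtol=1e-8)

    def test_approach_to_steady_state_is_monotone(self):
        gm = GrowthMaintenanceParams(gR=0.25, mR=0.015)
        nc = NCGrowthParams(phiCN=2.0, Np=5.0, gamma=0.01, k=0.5, W0=1.0)
        traj = simulate_nc_growth(gm, nc, np.linspace(0.0, 200.0, 101))
        diffs = np.diff(traj.W)
        assert np.all(diffs >= -1e-10)  # rising toward a/b, never overshooting
        assert traj.W[-1] <= traj.a / traj.b + 1e-8

    def test_respiration_balances_photosynthate_at_steady_state(self):
        """At equilibrium dW/dt = 0, so all assimilated carbon is respired:
        R equals the maintenance term exactly."""
        gm = GrowthMaintenanceParams(gR=0.25, mR=0.02)
        nc = NCGrowthParams(phiCN=2.0, Np=5.0, gamma=0.01, k=0.5, W0=1.0)
        traj = simulate_nc_growth(gm, nc, np.linspace(0.0, 2000.0, 21))
        assert traj.dWdt[-1] == pytest.approx(0.0, abs=1e-6)
        assert traj.R[-1] == pytest.approx(gm.mR * traj.W[-1], rel=1e-6)

    def test_bad_time_grid_rejected(self):
        gm = GrowthMaintenanceParams(gR=0.1, mR=0.01)
        nc = NCGrowthParams(phiCN=1.0, Np=1.0, gamma=0.01, k=1.0, W0=1.0)
        with pytest.raises(ValueError):
            simulate_nc_growth(gm, nc, [1.0, 2.0])       # t0 != 0
        with pytest.raises(ValueError):
            simulate_nc_growth(gm, nc, [0.0, 2.0, 1.0])  # not increasing


class TestFvCB:
    def test_assimilation_balance(self):
        f = FvCBFluxes(Vc=100.0, Vo=20.0, Rd=5.0)
        assert fvcb_assimilation(f) == pytest.approx(85.0)

    def test_compensation_point(self):
        # Vo = 2 (Vc - Rd) zeroes net assimilation
        f = FvCBFluxes(Vc=50.0, Vo=2 * (50.0 - 4.0), Rd=4.0)
        assert fvcb_assimilation(f) == pytest.approx(0.0)

    @given(vc=st.floats(0.1, 500.0), vo=st.floats(0.0, 500.0),
           rd=st.floats(0.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_rd_inversion_round_trips(self, vc, vo, rd):
        f = FvCBFluxes(Vc=vc, Vo=vo, Rd=rd)
        assert rd_from_assimilation(fvcb_assimilation(f), vc, vo) == \
            pytest.approx(rd, rel=1e-9, abs=1e-9)

    def test_cue_equals_assimilation_per_carboxylation(self):
        f = FvCBFluxes(Vc=100.0, Vo=20.0, Rd=5.0)
        assert cue_from_fvcb(f) == pytest.approx(0.85)
        assert cue_from_fvcb(f) == pytest.approx(fvcb_assimilation(f) / f.Vc)

    def test_cue_zero_at_full_respiratory_loss(self):
        f = FvCBFluxes(Vc=60.0, Vo=40.0, Rd=60.0 - 20.0)
        assert cue_from_fvcb(f) == pytest.approx(0.0)

    def test_cue_upper_bound_reached_only_without_losses(self):
        assert cue_from_fvcb(FvCBFluxes(Vc=10.0, Vo=0.0, Rd=0.0)) == 1.0

    @given(vc=st.floats(0.1, 500.0), vo=st.floats(0.0, 500.0),
           rd=st.floats(0.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_cue_never_exceeds_one(self, vc, vo, rd):
        cue = cue_from_fvcb(FvCBFluxes(Vc=vc, Vo=vo, Rd=rd))
        assert cue <= 1.0
        if (0.5 * vo + rd) / vc > 1e-12:  # losses large enough to represent
            assert cue < 1.0

    def test_zero_carboxylation_is_undefined(self):
        with pytest.raises(ValueError):
            cue_from_fvcb(FvCBFluxes(Vc=0.0, Vo=0.0, Rd=0.0))

    def test_negative_fluxes_rejected(self):
        with pytest.raises(ValueError):
            FvCBFluxes(Vc=-1.0, Vo=0.0, Rd=0.0)
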