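"""Respiration trait panel: RuBisCO ratio constraint, A_net, CUE, Rg,
contributor ranking and the day/night comparison."""

from __future__ import annotations

import numpy as np
import pytest

from respitraits import (FluxDistribution, RubiscoConstraint, ToyModelSpec,
                         TraitOptions, build_inventory, compare_conditions,
                         compute_traits, constrain_rubisco, fba,
                         generate_toyplant, net_assimilation, pfba,
                         rank_contributors)
from respitraits.lp import apply_knockout
from respitraits.traits import MissingPhotorespirationError

PHOTON_BOUND = 100.0


class TestRubiscoConstraint:
    def test_ratio_window_is_enforced(self, toyplant, rubisco):
        model, _ = toyplant
        cons = constrain_rubisco(model, rubisco)
        sol = pfba(model, cons)
        ratio = sol.flux["R_RBC_o"] / sol.flux["R_RBC_c"]
        assert 0.31 - 1e-7 <= ratio <= 0.55 + 1e-7
        # oxygenation is pure waste, so the optimum sits at the lower edge
        assert ratio == pytest.approx(0.31, abs=1e-6)

    def test_equal_bounds_pin_the_ratio(self, toyplant):
        model, _ = toyplant
        rc = RubiscoConstraint("R_RBC_c", "R_RBC_o", 0.5, 0.5)
        sol = pfba(model, constrain_rubisco(model, rc))
        assert sol.flux["R_RBC_o"] == pytest.approx(0.5 * sol.flux["R_RBC_c"],
                                                    rel=1e-6)

    def test_zero_carboxylation_forces_zero_oxygenation(self, day_night, rubisco):
        _, night, _ = day_night
        sol = pfba(night, constrain_rubisco(night, rubisco))
        assert sol.flux["R_RBC_c"] == pytest.approx(0.0, abs=1e-8)
        assert sol.flux["R_RBC_o"] == pytest.approx(0.0, abs=1e-8)

    def test_missing_oxygenation_reaction_is_reported(self, heterotroph):
        rc = RubiscoConstraint("R_GLYC", "R_RBC_o")
        with pytest.raises(MissingPhotorespirationError, match="photorespiration"):
            constrain_rubisco(heterotroph, rc)

    def test_invalid_ratio_window_rejected(self):
        with pytest.raises(ValueError):
            RubiscoConstraint("vc", "vo", 0.5, 0.3)


class TestNetAssimilation:
    def test_all_zero_flux_gives_zero(self, toyplant, toy_inventory):
        model, _ = toyplant
        zero = FluxDistribution(model_id=model.id,
                               flux={r.id: 0.0 for r in model.reactions},
                               objective_value=0.0, status="optimal")
        assert net_assimilation(zero, toy_inventory) == 0.0

    def test_sub_threshold_magnitudes_reported_as_zero(self, toyplant,
                                                       toy_inventory):
        model, _ = toyplant
        tiny = FluxDistribution(model_id=model.id,
                                flux={r.id: 0.0 for r in model.reactions},
                                objective_value=0.0, status="optimal")
        tiny.flux["R_GDC"] = 3e-10  # below the 1e-9 reporting threshold
        assert net_assimilation(tiny, toy_inventory) == 0.0

    def test_model_mismatch_rejected(self, toyplant, heterotroph):
        model, _ = toyplant
        inv_het = build_inventory(heterotroph)
        sol = pfba(model)
        with pytest.raises(ValueError, match="inventory"):
            net_assimilation(sol, inv_het)

    def test_day_a_net_equals_biomass_carbon_flux(self, toyplant, toy_inventory,
                                                  rubisco):
        """Elemental bookkeeping oracle: with CO2 the only non-biomass carbon
        exchange, net assimilation must equal biomass carbon x growth."""
        model, truth = toyplant
        sol = pfba(model, constrain_rubisco(model, rubisco), lexicographic=True)
        a_net = net_assimilation(sol, toy_inventory)
        assert a_net > 0
        assert a_net == pytest.approx(truth.biomass_carbon * sol.flux["R_BIO"],
                                      rel=1e-6)


class TestComputeTraits:
    def test_cue_equals_anet_over_vc(self, toyplant, toy_inventory, rubisco):
        model, _ = toyplant
        traits = compute_traits(model, toy_inventory, rubisco)
        assert traits.CUE == pytest.approx(traits.A_net / traits.Vc, abs=1e-9)
        # and the defining identity Rd = Vc - 0.5 Vo - A_net holds
        assert traits.Rd == pytest.approx(
            traits.Vc - 0.5 * traits.Vo - traits.A_net, abs=1e-9)

    def test_day_rd_is_nonphotorespiratory_release(self, toyplant, toy_inventory,
                                                   rubisco):
        """Rd isolates the decarboxylations that are not photorespiratory:
        in the day toy these are glycine synthesis (1 CO2) and the oxPPP
        (2 CO2) per unit biomass."""
        model, _ = toyplant
        traits = compute_traits(model, toy_inventory, rubisco)
        assert traits.Rd == pytest.approx(3.0 * traits.mu, rel=1e-6)

    def test_photorespiration_knockout_leaves_only_dark_decarboxylations(
            self, toyplant, toy_inventory):
        """With oxygenation knocked out and the ratio window opened, day
        respiration reduces to the non-RuBisCO decarboxylations (glycine
        synthesis + oxPPP here, the TCA being idle in the light)."""
        model, _ = toyplant
        ko = apply_knockout(model, ["R_RBC_o"])
        inv = build_inventory(ko)
        relaxed = RubiscoConstraint("R_RBC_c", "R_RBC_o", 0.0, 1000.0)
        traits = compute_traits(ko, inv, relaxed)
        assert traits.Vo == pytest.approx(0.0, abs=1e-9)
        sol = pfba(ko, lexicographic=True)
        producers = sum(max(0.0, inv.production_coefficient(r) * v)
                        for r, v in sol.flux.items())
        assert traits.Rd == pytest.approx(producers, rel=1e-6)
        assert traits.Rd == pytest.approx(3.0 * traits.mu, rel=1e-6)
        assert traits.Rg == pytest.approx(producers, rel=1e-6)

    def test_heterotroph_has_undefined_cue_but_positive_rg(self, heterotroph):
        inv = build_inventory(heterotroph)
        traits = compute_traits(heterotroph, inv, rc=None)
        assert traits.CUE is None
        assert "cue-undefined" in traits.flags
        assert traits.Rg > 0

    def test_non_growing_model_is_flagged(self, toyplant, toy_inventory):
        model, _ = toyplant
        dark = model.copy()
        dark.rxn["E_photon"].lower_bound = 0.0  # no light, no carbon source
        traits = compute_traits(dark, toy_inventory)
        assert traits.mu == pytest.approx(0.0, abs=1e-9)
        assert traits.Rg_scaled is None
        assert "non-growing" in traits.flags

    def test_anetmax_dominates_pfba_anet(self, toyplant, toy_inventory, rubisco):
        model, _ = toyplant
        traits = compute_traits(model, toy_inventory, rubisco)
        assert traits.Anetmax >= traits.A_net - 1e-6

    def test_day_exchange_extremes_pinned_by_carbon_balance(
            self, toyplant, toy_inventory, rubisco):
        """Day toy: photons are exactly exhausted at optimal growth and CO2 is
        the only non-biomass carbon exchange, so CO2 exchange is pinned and
        Rnetmax = -Anetmax = -(biomass carbon) x mu."""
        model, truth = toyplant
        traits = compute_traits(model, toy_inventory, rubisco)
        pinned = truth.biomass_carbon * traits.mu
        assert traits.Anetmax == pytest.approx(pinned, rel=1e-6)
        assert traits.Rnetmax == pytest.approx(-pinned, rel=1e-6)

    def test_night_rnetmax_dominates_rg(self, day_night, rubisco):
        """Night model under a growth cap has starch slack: burning it makes
        maximum CO2 release exceed the parsimonious growth respiration."""
        day, night, _ = day_night
        inv_n = build_inventory(night)
        inv_d = build_inventory(day)
        t_day, t_night = compare_conditions(day, night, inv_d, inv_n, rubisco)
        assert t_night.Rnetmax >= t_night.Rg - 1e-6
        assert t_night.Rnetmax > 10 * t_night.Rg  # ample slack, not a tie

    def test_tightening_ratio_max_never_raises_rd(self, toyplant, toy_inventory):
        model, _ = toyplant
        for bound in (40.0, 70.0, 100.0):
            clipped = model.copy()
            clipped.rxn["E_photon"].lower_bound = -bound
            loose = compute_traits(clipped, toy_inventory,
                                   RubiscoConstraint("R_RBC_c", "R_RBC_o", 0.31, 0.55))
            tight = compute_traits(clipped, toy_inventory,
                                   RubiscoConstraint("R_RBC_c", "R_RBC_o", 0.31, 0.31))
            assert tight.Rd <= loose.Rd + 1e-6

    def test_rg_scaled_invariant_under_uniform_bound_rescaling(
            self, toy_inventory, rubisco):
        base, _ = generate_toyplant(ToyModelSpec(photon_bound=PHOTON_BOUND))
        ref = compute_traits(base, toy_inventory, rubisco).Rg_scaled
        scaled, _ = generate_toyplant(ToyModelSpec(photon_bound=PHOTON_BOUND * 2.5))
        for rxn in scaled.reactions:
            if rxn.id != "E_photon":
                rxn.lower_bound *= 2.5
                rxn.upper_bound *= 2.5
        inv = build_inventory(scaled)
        assert compute_traits(scaled, inv, rubisco).Rg_scaled == \
            pytest.approx(ref, rel=1e-6)


class TestRankContributors:
    def test_day_ranking_is_led_by_glycine_decarboxylase(
            self, toyplant, toy_inventory, rubisco):
        model, _ = toyplant
        sol = pfba(model, constrain_rubisco(model, rubisco), lexicographic=True)
        ranking = rank_contributors(sol, toy_inventory, model)
        assert ranking.entries[0].reaction_id == "R_GDC"
        assert "1.4.4.2" in ranking.entries[0].ec_numbers
        shares = sum(e.share for e in ranking.entries)
        assert shares == pytest.approx(1.0, abs=1e-6)
        fluxes = [e.co2_flux for e in ranking.entries]
        assert fluxes == sorted(fluxes, reverse=True)

    def test_night_ranking_is_led_by_oxppp(self, day_night, rubisco):
        day, night, _ = day_night
        capped = night.copy()
        capped.rxn["R_BIO"].upper_bound = 0.25  # below the starch-limited max
        inv = build_inventory(capped)
        sol = pfba(capped, constrain_rubisco(capped, rubisco), lexicographic=True)
        ranking = rank_contributors(sol, inv, capped)
        assert ranking.entries[0].reaction_id == "R_PGD"
        assert "1.1.1.44" in ranking.entries[0].ec_numbers

    def test_single_producer_takes_share_one(self, heterotroph):
        inv = build_inventory(heterotroph)
        sol = pfba(heterotroph, lexicographic=True)
        ranking = rank_contributors(sol, inv, heterotroph)
        assert len(ranking.entries) >= 1
        assert ranking.entries[0].share <= 1.0 + 1e-9

    def test_zero_release_gives_empty_ranking_with_note(self, toyplant,
                                                        toy_inventory):
        model, _ = toyplant
        zero = FluxDistribution(model_id=model.id,
                                flux={r.id: 0.0 for r in model.reactions},
                                objective_value=0.0, status="optimal")
        ranking = rank_contributors(zero, toy_inventory, model)
        assert ranking.entries == []
        assert "no CO2 release" in ranking.note


class TestCompareConditions:
    def test_identical_models_give_identical_traits(self, toyplant,
                                                    toy_inventory, rubisco):
        model, _ = toyplant
        day, night = compare_conditions(model, model.copy(), toy_inventory,
                                        toy_inventory, rubisco)
        for attr in ("A_net", "Vc", "Vo", "Rd", "CUE", "Rg", "mu", "Rg_scaled"):
            assert getattr(day, attr) == pytest.approx(getattr(night, attr),
                                                       rel=1e-6)

    def test_scaled_day_respiration_exceeds_night(self, day_night, rubisco):
        day, night, _ = day_night
        t_day, t_night = compare_conditions(
            day, night, build_inventory(day), build_inventory(night), rubisco)
        assert t_day.mu == pytest.approx(t_night.mu, rel=1e-6)  # night capped
        assert t_day.Rg_scaled > t_night.Rg_scaled

    def test_night_without_carbon_source_flagged_non_growing(self, rubisco):
        day, _ = generate_toyplant(ToyModelSpec(photon_bound=PHOTON_BOUND))
        starved, _ = generate_toyplant(ToyModelSpec(night=True, starch_bound=0.0))
        t_day, t_night = compare_conditions(
            day, starved, build_inventory(day), build_inventory(starved), rubisco)
        assert t_night.mu == pytest.approx(0.0, abs=1e-9)
        assert "non-growing" in t_night.flags
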