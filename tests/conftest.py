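"""Shared fixtures: toy photoautotroph variants and hand-sized LP fixtures."""

from __future__ import annotations

import pytest

from respitraits import (MetabolicModel, Metabolite, Reaction, RubiscoConstraint,
                         ToyModelSpec, build_inventory, generate_day_night_pair,
                         generate_toyplant)

PHOTON_BOUND = 100.0
STARCH_BOUND = 10.0


@pytest.fixture(scope="session")
def toyplant():
    model, truth = generate_toyplant(ToyModelSpec(photon_bound=PHOTON_BOUND))
    return model, truth


@pytest.fixture(scope="session")
def toyplant_loop():
    model, truth = generate_toyplant(
        ToyModelSpec(photon_bound=PHOTON_BOUND, include_futile_loop=True))
    return model, truth


@pytest.fixture(scope="session")
def day_night():
    return generate_day_night_pair(PHOTON_BOUND, STARCH_BOUND)


@pytest.fixture(scope="session")
def rubisco():
    return RubiscoConstraint("R_RBC_c", "R_RBC_o")


@pytest.fixture(scope="session")
def toy_inventory(toyplant):
    model, _ = toyplant
    return build_inventory(model)


def make_two_route_model() -> MetabolicModel:
    """Two routes from substrate to biomass precursor: a high-yield route
    releasing 5 CO2 per substrate and a low-yield route releasing 2.

    FBA picks the high-yield route; the minimum of CO2 release per biomass
    carbon is achieved on the low-yield one (hand ratio 2/4 = 0.5)."""
    mets = [
        Metabolite("s_c", "substrate", "c", "C6H12O6"),
        Metabolite("b_c", "precursor", "c", "C4H8O4"),
        Metabolite("co2_c", "carbon dioxide", "c", "CO2"),
        Metabolite("bio_c", "biomass", "c"),
    ]
    rxns = [
        Reaction("E_S", "substrate uptake", {"s_c": -1.0}, -10.0, 0.0),
        Reaction("E_CO2", "CO2 exchange", {"co2_c": -1.0}, -1000.0, 1000.0),
        Reaction("E_BIO", "biomass sink", {"bio_c": -1.0}, 0.0, 1000.0),
        Reaction("R_HIGH", "high-yield, CO2-expensive route",
                 {"s_c": -1.0, "b_c": 1.2, "co2_c": 5.0}, 0.0, 1000.0),
        Reaction("R_LOW", "low-yield, CO2-cheap route",
                 {"s_c": -1.0, "b_c": 1.0, "co2_c": 2.0}, 0.0, 1000.0),
        Reaction("R_BIO", "biomass synthesis", {"b_c": -1.0, "bio_c": 1.0},
                 0.0, 1000.0),
    ]
    model = MetabolicModel(id="tworoute", metabolites=mets, reactions=rxns,
                           objective={"R_BIO": 1.0})
    model.validate()
    model.detect_exchanges_and_transports()
    return model


@pytest.fixture()
def two_route():
    return make_two_route_model()


def make_heterotroph_model() -> MetabolicModel:
    """Glucose-fed heterotroph with no RuBisCO: CUE undefined, Rg > 0."""
    mets = [
        Metabolite("glc_c", "glucose", "c", "C6H12O6"),
        Metabolite("pyr_c", "pyruvate", "c", "C3H4O3"),
        Metabolite("co2_c", "carbon dioxide", "c", "CO2"),
        Metabolite("bio_c", "biomass", "c"),
    ]
    rxns = [
        Reaction("E_GLC", "glucose uptake", {"glc_c": -1.0}, -5.0, 0.0),
        Reaction("E_CO2", "CO2 exchange", {"co2_c": -1.0}, -1000.0, 1000.0),
        Reaction("E_BIO", "biomass sink", {"bio_c": -1.0}, 0.0, 1000.0),
        Reaction("R_GLYC", "glycolysis", {"glc_c": -1.0, "pyr_c": 2.0}, 0.0, 1000.0),
        Reaction("R_PDC", "pyruvate decarboxylation burn",
                 {"pyr_c": -1.0, "co2_c": 3.0}, 0.0, 1000.0),
        Reaction("R_BIO", "biomass synthesis",
                 {"pyr_c": -2.0, "bio_c": 1.0, "co2_c": 1.0}, 0.0, 1000.0),
    ]
    model = MetabolicModel(id="heterotroph", metabolites=mets, reactions=rxns,
                           objective={"R_BIO": 1.0})
    model.validate()
    model.detect_exchanges_and_transports()
    return model


@pytest.fixture()
def heterotroph():
    return make_heterotroph_model()


def make_chain_model() -> MetabolicModel:
    """Linear chain with one decarboxylating step and no redundancy:
    every internal step is essential and the flux space is a single ray."""
    mets = [
        Metabolite("s0_c", "substrate", "c", "C3H6O3"),
        Metabolite("s1_c", "intermediate 1", "c", "C3H6O3"),
        Metabolite("s2_c", "intermediate 2", "c", "C2H4O2"),
        Metabolite("s3_c", "precursor", "c", "C2H4O2"),
        Metabolite("co2_c", "carbon dioxide", "c", "CO2"),
        Metabolite("bio_c", "biomass", "c"),
    ]
    rxns = [
        Reaction("E_IN", "uptake", {"s0_c": -1.0}, -1.0, 0.0),
        Reaction("R_0", "isomerization", {"s0_c": -1.0, "s1_c": 1.0}, 0.0, 1000.0),
        Reaction("R_1", "decarboxylation",
                 {"s1_c": -1.0, "s2_c": 1.0, "co2_c": 1.0}, 0.0, 1000.0),
        Reaction("R_2", "activation", {"s2_c": -1.0, "s3_c": 1.0}, 0.0, 1000.0),
        Reaction("R_BIO", "biomass synthesis", {"s3_c": -1.0, "bio_c": 1.0},
                 0.0, 1000.0),
        Reaction("E_CO2", "CO2 exchange", {"co2_c": -1.0}, -1000.0, 1000.0),
        Reaction("E_BIO", "biomass sink", {"bio_c": -1.0}, 0.0, 1000.0),
    ]
    model = MetabolicModel(id="chain", metabolites=mets, reactions=rxns,
                           objective={"R_BIO": 1.0})
    model.validate()
    model.detect_exchanges_and_transports()
    return model


@pytest.fixture()
def chain_model():
    return make_chain_model()
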