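"""Synthetic compartmentalized photoautotroph model with closed-form optima.

``generate_toyplant`` builds "toyplant-v1": a miniature C3-plant central
metabolism with four compartments (cytosol ``c``, chloroplast ``h``,
mitochondrion ``m``, peroxisome ``p``) containing RuBisCO carboxylation and
oxygenation, a lumped Calvin-Benson-Bassham cycle, linear and cyclic light
reactions, the photorespiratory glycolate salvage loop closed by glycine
decarboxylase (EC 1.4.4.2), lumped glycolysis, a TCA cycle with NADP-IDH
(EC 1.1.1.42) and 2-oxoglutarate dehydrogenase (EC 1.2.4.2), the oxidative
pentose-phosphate decarboxylation (EC 1.1.1.44), NADP-malic enzyme
(EC 1.1.1.40), a biomass reaction with full elemental formulas, and
CO2/O2/photon/ammonia exchanges.  All carbon-bearing internal reactions are
elementally balanced for C and N; energy carriers (ATP, NADPH, NADH) are
carbon-free pseudo-species shared across compartments with water and protons
implicit.

Closed-form optima (derivation)
-------------------------------
Photons are the only limiting resource in the day model.  Per unit biomass
flux the network needs 4 units of triose (3 into biomass + 1 consumed making
glycine) plus 4 more for the hexose feeding the oxidative pentose phosphate
route that supplies the 2 ribose-5P units in biomass, i.e. 8 triose total,
which forces 2*Vc - Vo = 48 via the Calvin-cycle balance.  With the
oxygenation:carboxylation ratio pinned at its lower bound rho = 0.31 (any
extra oxygenation wastes photons) this gives Vc = 4800/169 per unit growth.
The NADPH demand N = 2*Vc + 1.5*Vo (Calvin reduction + biomass, less the
oxPPP contribution) and ATP demand D = 3*Vc + 2.5*Vo + 8 are covered by
linear electron flow (8 photons -> 2 ATP + 2 NADPH) with surplus NADPH
shuttled through the transhydrogenase/oxphos route (1 NADPH -> 2 ATP), the
cheapest ATP source at 4/3 photons per ATP; cyclic electron flow (2 photons
per ATP) is retained in the network as a strictly dominated alternative and
carries no flux at the optimum.  Solving the two currency balances gives a
total photon cost of (28*Vc + 18*Vo + 32)/3 = 166592/507 per unit biomass:

    mu*_day(photon_bound) = 507 * photon_bound / 166592.

Without the oxygenation constraint (Vo = 0) the same balance gives Vc = 24
and a photon cost of 704/3, so mu*_unconstrained = 3 * photon_bound / 704.
At night the photon bound is zero and a starch (hexose) source of s units
sustains growth; per unit biomass the network consumes 2 hexose through the
oxPPP (for ribose-5P and NADPH) plus 30/13 hexose mobilized to triose for
biomass carbon, glycine synthesis and the TCA flux of 8/13 that covers the
ATP demand (13 ATP per triose oxidized), totalling 56/13 hexose, so

    mu*_night(starch_bound) = 13 * starch_bound / 56.

These constants are recorded in :class:`GroundTruth` and asserted against
the LP solutions in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

import numpy as np

from .core import MetabolicModel, Metabolite, Reaction

DAY_PHOTON_BOUND = 100.0
NIGHT_STARCH_BOUND = 10.0

#: photon cost per unit biomass flux in the day model with Vo/Vc = 0.31
DAY_PHOTON_COST = Fraction(166592, 507)
#: photon cost per unit biomass flux without the oxygenation constraint
DAY_PHOTON_COST_UNCONSTRAINED = Fraction(704, 3)
#: hexose (starch) cost per unit biomass flux in the night model
NIGHT_STARCH_COST = Fraction(56, 13)
#: mol carbon per unit biomass flux (3 triose + 1 glycine + 2 ribose-5P)
BIOMASS_CARBON = 21.0


@dataclass
class ToyModelSpec:
    photon_bound: float = DAY_PHOTON_BOUND
    starch_bound: float = NIGHT_STARCH_BOUND
    include_futile_loop: bool = False
    night: bool = False  # night variant: photons off, starch source open
    seed: int | None = None  # randomized bound jitter for variant generation

    def __post_init__(self) -> None:
        if self.photon_bound < 0 or self.starch_bound < 0:
            raise ValueError("bounds must be nonnegative")


@dataclass
class GroundTruth:
    optimal_growth: Callable[[float], float]       # constrained (Vo/Vc = 0.31)
    optimal_growth_unconstrained: Callable[[float], float]
    producer_labels: dict[str, str]  # reaction-id -> producer|consumer|excluded
    biomass_carbon: float
    dominant_day_producer: str
    dominant_night_producer: str
    biomass_reaction: str = "R_BIO"
    carboxylation_reaction: str = "R_RBC_c"
    oxygenation_reaction: str = "R_RBC_o"


def _metabolites() -> list[Metabolite]:
    def met(mid, name, comp, formula=None, **kw):
        return Metabolite(id=mid, name=name, compartment=comp, formula=formula, **kw)

    return [
        met("photon_h", "photon", "h"),
        met("co2_c", "carbon dioxide", "c", "CO2",
            annotations={"chebi": ["CHEBI:16526"]}),
        met("co2_h", "carbon dioxide", "h", "CO2",
            annotations={"chebi": ["CHEBI:16526"]}),
        met("co2_m", "carbon dioxide", "m", "CO2",
            annotations={"chebi": ["CHEBI:16526"]}),
        met("o2_h", "oxygen", "h", "O2"),
        met("nh3_c", "ammonia", "c", "H3N"),
        met("nh3_p", "ammonia", "p", "H3N"),
        met("nh3_m", "ammonia", "m", "H3N"),
        met("rubp_h", "ribulose-1,5-bisphosphate", "h", "C5H12O11P2"),
        met("pga_h", "3-phosphoglycerate", "h", "C3H7O7P"),
        met("pga_m", "3-phosphoglycerate", "m", "C3H7O7P"),
        met("pg_h", "2-phosphoglycolate", "h", "C2H5O6P"),
        met("gca_h", "glycolate", "h", "C2H4O3"),
        met("gca_p", "glycolate", "p", "C2H4O3"),
        met("gly_p", "glycine", "p", "C2H5NO2"),
        met("gly_m", "glycine", "m", "C2H5NO2"),
        met("gly_c", "glycine", "c", "C2H5NO2"),
        met("ser_m", "serine", "m", "C3H7NO3"),
        met("tp_h", "triose phosphate", "h", "C3H6O3"),
        met("tp_c", "triose phosphate", "c", "C3H6O3"),
        met("hex_h", "hexose (starch unit)", "h", "C6H12O6"),
        met("rp5_h", "ribose-5-phosphate", "h", "C5H10O5"),
        met("rp5_c", "ribose-5-phosphate", "c", "C5H10O5"),
        met("pyr_c", "pyruvate", "c", "C3H4O3"),
        met("pyr_m", "pyruvate", "m", "C3H4O3"),
        met("ace_m", "acetyl unit", "m", "C2H4O2"),
        met("cit_m", "citrate", "m", "C6H8O7"),
        met("akg_m", "2-oxoglutarate", "m", "C5H6O5"),
        met("suc_m", "succinate", "m", "C4H6O4"),
        met("mal_m", "malate", "m", "C4H6O5"),
        met("oaa_m", "oxaloacetate", "m", "C4H4O5"),
        met("atp_c", "ATP (shared energy pool)", "c"),
        met("nadph_c", "NADPH (shared redox pool)", "c"),
        met("nadh_c", "NADH (shared redox pool)", "c"),
        met("biomass_c", "biomass", "c", "C21H43NO21"),
    ]


def _reactions(spec: ToyModelSpec) -> list[Reaction]:
    def rxn(rid, name, stoich, lb=0.0, ub=1000.0, ec=()):
        return Reaction(id=rid, name=name, stoichiometry=stoich,
                        lower_bound=lb, upper_bound=ub, ec_numbers=set(ec))

    photon_lb = 0.0 if spec.night else -spec.photon_bound
    starch_lb = -spec.starch_bound if spec.night else 0.0

    reactions = [
        # exchanges (signed single-metabolite convention: import < 0 < export)
        rxn("E_photon", "photon uptake", {"photon_h": -1.0}, lb=photon_lb, ub=0.0),
        rxn("E_co2", "CO2 exchange", {"co2_c": -1.0}, lb=-1000.0, ub=1000.0),
        rxn("E_o2", "O2 exchange", {"o2_h": -1.0}, lb=-1000.0, ub=1000.0),
        rxn("E_nh3", "ammonia uptake", {"nh3_c": -1.0}, lb=-1000.0, ub=0.0),
        rxn("E_biomass", "biomass sink", {"biomass_c": -1.0}, lb=0.0, ub=1000.0),
        rxn("E_starch", "starch mobilization source", {"hex_h": -1.0},
            lb=starch_lb, ub=0.0),
        # chloroplast light reactions
        rxn("R_LIGHT", "linear electron flow",
            {"photon_h": -8.0, "atp_c": 2.0, "nadph_c": 2.0, "o2_h": 1.0}),
        rxn("R_CEF", "cyclic electron flow", {"photon_h": -2.0, "atp_c": 1.0}),
        # RuBisCO
        rxn("R_RBC_c", "RuBisCO carboxylase",
            {"rubp_h": -1.0, "co2_h": -1.0, "pga_h": 2.0}, ec=["4.1.1.39"]),
        rxn("R_RBC_o", "RuBisCO oxygenase",
            {"rubp_h": -1.0, "o2_h": -1.0, "pga_h": 1.0, "pg_h": 1.0},
            ec=["4.1.1.39"]),
        # Calvin-Benson-Bassham cycle (lumped)
        rxn("R_CBB_red", "CBB reduction phase",
            {"pga_h": -1.0, "atp_c": -1.0, "nadph_c": -1.0, "tp_h": 1.0}),
        rxn("R_CBB_reg", "CBB regeneration phase",
            {"tp_h": -5.0, "atp_c": -3.0, "rubp_h": 3.0}),
        rxn("R_HEX", "hexose (starch) synthesis", {"tp_h": -2.0, "hex_h": 1.0}),
        rxn("R_HXM", "hexose mobilization to triose",
            {"hex_h": -1.0, "tp_h": 2.0}),
        rxn("R_PGD", "oxidative pentose phosphate decarboxylation",
            {"hex_h": -1.0, "rp5_h": 1.0, "co2_h": 1.0, "nadph_c": 2.0},
            ec=["1.1.1.44"]),
        rxn("R_PRK", "phosphoribulokinase",
            {"rp5_h": -1.0, "atp_c": -1.0, "rubp_h": 1.0}, ec=["2.7.1.19"]),
        # photorespiratory salvage
        rxn("R_PGP", "phosphoglycolate phosphatase",
            {"pg_h": -1.0, "gca_h": 1.0}, ec=["3.1.3.18"]),
        rxn("R_GCAt_hp", "glycolate transport h->p",
            {"gca_h": -1.0, "gca_p": 1.0}),
        rxn("R_GGT", "glycine synthesis from glycolate",
            {"gca_p": -1.0, "nh3_p": -1.0, "gly_p": 1.0}, ec=["2.6.1.4"]),
        rxn("R_GLYt_pm", "glycine transport p->m",
            {"gly_p": -1.0, "gly_m": 1.0}),
        rxn("R_GDC", "glycine decarboxylase complex",
            {"gly_m": -2.0, "ser_m": 1.0, "co2_m": 1.0, "nh3_m": 1.0,
             "nadh_c": 1.0}, ec=["1.4.4.2"]),
        rxn("R_SGA", "serine to glycerate (lumped)",
            {"ser_m": -1.0, "pga_m": 1.0, "nh3_m": 1.0}),
        rxn("R_PGAt_mh", "glycerate return m->h", {"pga_m": -1.0, "pga_h": 1.0}),
        # transporters
        rxn("R_CO2t_ch", "CO2 transport c<->h", {"co2_c": -1.0, "co2_h": 1.0},
            lb=-1000.0),
        rxn("R_CO2t_cm", "CO2 transport c<->m", {"co2_c": -1.0, "co2_m": 1.0},
            lb=-1000.0),
        rxn("R_NH3t_mc", "ammonia transport m->c", {"nh3_m": -1.0, "nh3_c": 1.0}),
        rxn("R_NH3t_cp", "ammonia transport c->p", {"nh3_c": -1.0, "nh3_p": 1.0}),
        rxn("R_TPt_hc", "triose phosphate export h->c",
            {"tp_h": -1.0, "tp_c": 1.0}),
        rxn("R_RP5t_hc", "ribose-5-phosphate export h->c",
            {"rp5_h": -1.0, "rp5_c": 1.0}),
        rxn("R_PYRt_cm", "pyruvate transport c->m", {"pyr_c": -1.0, "pyr_m": 1.0}),
        # cytosol
        rxn("R_GLYC", "glycolysis (lumped)",
            {"tp_c": -1.0, "pyr_c": 1.0, "atp_c": 1.0, "nadh_c": 1.0}),
        rxn("R_GLYS", "glycine synthesis from triose",
            {"tp_c": -1.0, "nh3_c": -1.0, "gly_c": 1.0, "co2_c": 1.0}),
        rxn("R_BIO", "biomass synthesis",
            {"tp_c": -3.0, "gly_c": -1.0, "rp5_c": -2.0, "atp_c": -8.0,
             "nadph_c": -4.0, "biomass_c": 1.0}),
        rxn("R_ATPM", "ATP maintenance / dissipation", {"atp_c": -1.0}),
        # mitochondrion
        rxn("R_PDH", "pyruvate dehydrogenase complex",
            {"pyr_m": -1.0, "ace_m": 1.0, "co2_m": 1.0, "nadh_c": 1.0},
            ec=["1.2.4.1"]),
        rxn("R_CS", "citrate synthase",
            {"ace_m": -1.0, "oaa_m": -1.0, "cit_m": 1.0}, ec=["2.3.3.1"]),
        rxn("R_IDH", "NADP-isocitrate dehydrogenase",
            {"cit_m": -1.0, "akg_m": 1.0, "co2_m": 1.0, "nadph_c": 1.0},
            ec=["1.1.1.42"]),
        rxn("R_OGDH", "2-oxoglutarate dehydrogenase complex",
            {"akg_m": -1.0, "suc_m": 1.0, "co2_m": 1.0, "nadh_c": 1.0},
            ec=["1.2.4.2"]),
        rxn("R_SOM", "succinate to malate (lumped SDH+fumarase)",
            {"suc_m": -1.0, "mal_m": 1.0, "nadh_c": 1.0}),
        rxn("R_MDH", "malate dehydrogenase",
            {"mal_m": -1.0, "oaa_m": 1.0, "nadh_c": 1.0}, ec=["1.1.1.37"]),
        rxn("R_ME", "NADP-malic enzyme",
            {"mal_m": -1.0, "pyr_m": 1.0, "co2_m": 1.0, "nadph_c": 1.0},
            ec=["1.1.1.40"]),
        rxn("R_PYC", "pyruvate carboxylase (anaplerosis)",
            {"pyr_m": -1.0, "co2_m": -1.0, "atp_c": -1.0, "oaa_m": 1.0},
            ec=["6.4.1.1"]),
        rxn("R_OXPHOS", "oxidative phosphorylation (lumped)",
            {"nadh_c": -1.0, "atp_c": 2.0}),
        rxn("R_TRANSH", "transhydrogenase (NADPH->NADH)",
            {"nadph_c": -1.0, "nadh_c": 1.0}),
    ]
    if spec.include_futile_loop:
        reactions += [
            Reaction(id="R_LOOP_A", name="futile loop A->B",
                     stoichiometry={"fla_c": -1.0, "flb_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id="R_LOOP_B", name="futile loop B->A",
                     stoichiometry={"flb_c": -1.0, "fla_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
        ]
    return reactions


PRODUCER_LABELS = {
    "R_PGD": "producer", "R_GDC": "producer", "R_GLYS": "producer",
    "R_PDH": "producer", "R_IDH": "producer", "R_OGDH": "producer",
    "R_ME": "producer",
    "R_RBC_c": "consumer", "R_PYC": "consumer",
    "R_CO2t_ch": "excluded", "R_CO2t_cm": "excluded", "E_co2": "excluded",
}


def generate_toyplant(spec: ToyModelSpec | None = None,
                      ) -> tuple[MetabolicModel, GroundTruth]:
    """Build toyplant-v1 (or its night variant) plus its ground truth."""
    spec = spec or ToyModelSpec()
    metabolites = _metabolites()
    if spec.include_futile_loop:
        metabolites += [
            Metabolite(id="fla_c", name="futile carrier A", compartment="c",
                       formula="C2H4O2"),
            Metabolite(id="flb_c", name="futile carrier B", compartment="c",
                       formula="C2H4O2"),
        ]
    model = MetabolicModel(
        id="toyplant_v1_night" if spec.night else "toyplant_v1",
        metabolites=metabolites,
        reactions=_reactions(spec),
        objective={"R_BIO": 1.0},
    )
    model.validate()
    model.detect_exchanges_and_transports()
    if spec.seed is not None:
        # jitter the wide (non-binding) default bounds only
        rng = np.random.default_rng(spec.seed)
        for rxn in model.reactions:
            if rxn.upper_bound == 1000.0 and not rxn.is_exchange:
                rxn.upper_bound = float(1000.0 + np.round(rng.uniform(0, 100), 6))

    truth = GroundTruth(
        optimal_growth=lambda pb: float(Fraction(pb) / DAY_PHOTON_COST)
        if not spec.night else float(Fraction(spec.starch_bound) / NIGHT_STARCH_COST),
        optimal_growth_unconstrained=lambda pb: float(
            Fraction(pb) / DAY_PHOTON_COST_UNCONSTRAINED),
        producer_labels=dict(PRODUCER_LABELS),
        biomass_carbon=BIOMASS_CARBON,
        dominant_day_producer="R_GDC",
        dominant_night_producer="R_PGD",
    )
    return model, truth


def generate_day_night_pair(photon_bound: float = DAY_PHOTON_BOUND,
                            starch_bound: float = NIGHT_STARCH_BOUND,
                            ) -> tuple[MetabolicModel, MetabolicModel, GroundTruth]:
    """Day and night toyplant variants sharing the biomass reaction id."""
    day, truth = generate_toyplant(ToyModelSpec(photon_bound=photon_bound))
    night, _ = generate_toyplant(ToyModelSpec(photon_bound=photon_bound,
                                              starch_bound=starch_bound,
                                              night=True))
    return day, night, truth


# ----------------------------------------------------------------------
# Randomized variants for property tests
# ----------------------------------------------------------------------

_BYPASS_POOL = [
    # carbon-bearing internal metabolites usable as bypass endpoints
    "tp_c", "pyr_c", "gly_c", "rp5_c",
    "tp_h", "hex_h", "rp5_h", "pga_h",
    "pyr_m", "ace_m", "cit_m", "akg_m", "suc_m", "mal_m", "oaa_m",
]


def generate_random_variant(spec: ToyModelSpec | None = None,
                            n_extra_reactions: int = 0,
                            seed: int = 0) -> tuple[MetabolicModel, GroundTruth]:
    """toyplant-v1 plus carbon-balanced random bypass reactions.

    Each added reaction converts one pool metabolite into another, emitting
    or absorbing compartment-matched CO2 to balance carbon exactly; its
    ground-truth producer/consumer label is derived from the sampled
    stoichiometry at generation time.  Added reactions are irreversible with
    small bounds, so the model stays feasible and the closed-form optimum can
    only improve marginally or stay put (they are never energy sources).
    """
    if n_extra_reactions < 0:
        raise ValueError("n_extra_reactions must be nonnegative")
    model, truth = generate_toyplant(spec)
    if n_extra_reactions > 0:
        model.id = f"{model.id}_variant_s{seed}"
    rng = np.random.default_rng(seed)
    co2_for_comp = {"c": "co2_c", "h": "co2_h", "m": "co2_m", "p": "co2_c"}
    for k in range(n_extra_reactions):
        src, dst = (str(x) for x in rng.choice(_BYPASS_POOL, size=2, replace=False))
        src_met, dst_met = model.met[src], model.met[dst]
        c_src = src_met.elements["C"]
        c_dst = dst_met.elements["C"]
        # n_src * c_src = n_dst * c_dst + delta * CO2, all integers >= 1
        n_src = int(rng.integers(1, 3))
        n_dst = max(1, (n_src * c_src) // c_dst) if n_src * c_src >= c_dst else 1
        delta = n_src * c_src - n_dst * c_dst
        stoich = {src: -float(n_src), dst: float(n_dst)}
        label = None
        if delta != 0:
            co2_id = co2_for_comp[src_met.compartment]
            stoich[co2_id] = stoich.get(co2_id, 0.0) + float(delta)
            label = "producer" if delta > 0 else "consumer"
        rid = f"R_BYPASS_{k:03d}"
        model.reactions.append(Reaction(
            id=rid, name=f"random bypass {src}->{dst}", stoichiometry=stoich,
            lower_bound=0.0, upper_bound=float(np.round(rng.uniform(0.0, 5.0), 6)),
        ))
        if label is not None:
            truth.producer_labels[rid] = label
    model.invalidate_index()
    model.validate()
    model.detect_exchanges_and_transports()
    return model, truth
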