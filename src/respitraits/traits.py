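"""CO2-related trait panel for a metabolic model under a RuBisCO-ratio regime.

Computes, from one parsimonious flux distribution per model: net CO2
assimilation (A_net), carboxylation and oxygenation fluxes (Vc, Vo), day
respiration (Rd = Vc - 0.5*Vo - A_net), carbon use efficiency
(CUE = 1 - (0.5*Vo + Rd)/Vc, which reduces algebraically to A_net/Vc),
growth respiration (Rg, the sum of CO2-releasing fluxes), its scaled variant
Rg/(mu * biomass carbon fraction), and the flux-variability-style extremes
Rnetmax (maximum CO2 export at optimal growth) and Anetmax (maximum net CO2
fixation at optimal growth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import MetabolicModel, biomass_carbon_fraction
from .inventory import CO2Inventory
from .lp import (FEASIBILITY_TOL, FluxDistribution, LinearConstraint, fba,
                 maximize_flux, pfba)

logger = logging.getLogger(__name__)

REPORTING_THRESHOLD = 1e-9  # |value| below this is reported as 0 (solver noise)


@dataclass
class RubiscoConstraint:
    """Bounds on the RuBisCO oxygenation:carboxylation flux ratio.

    The default range 0.31-0.55 spans ambient-air estimates of the
    photorespiratory burden in C3 leaves.
    """

    carboxylation_reaction_id: str
    oxygenation_reaction_id: str
    ratio_min: float = 0.31
    ratio_max: float = 0.55

    def __post_init__(self) -> None:
        if not (0.0 <= self.ratio_min <= self.ratio_max):
            raise ValueError("require 0 <= ratio_min <= ratio_max")


class MissingPhotorespirationError(KeyError):
    pass


def constrain_rubisco(model: MetabolicModel,
                      rc: RubiscoConstraint) -> list[LinearConstraint]:
    """Emit vo >= ratio_min*vc and vo <= ratio_max*vc as linear constraints."""
    if rc.carboxylation_reaction_id not in model.rxn:
        raise KeyError(f"model lacks carboxylation reaction {rc.carboxylation_reaction_id!r}")
    if rc.oxygenation_reaction_id not in model.rxn:
        raise MissingPhotorespirationError(
            f"model {model.id} lacks photorespiration "
            f"({rc.oxygenation_reaction_id!r} not found)")
    for rid in (rc.carboxylation_reaction_id, rc.oxygenation_reaction_id):
        if model.rxn[rid].lower_bound < 0:
            raise ValueError(f"{rid} must be irreversible-forward for the ratio constraint")
    vc, vo = rc.carboxylation_reaction_id, rc.oxygenation_reaction_id
    return [
        LinearConstraint({vo: 1.0, vc: -rc.ratio_min}, ">=", 0.0),
        LinearConstraint({vo: 1.0, vc: -rc.ratio_max}, "<=", 0.0),
    ]


def net_assimilation(flux: FluxDistribution, inv: CO2Inventory,
                     threshold: float = REPORTING_THRESHOLD) -> float:
    """Direction-aware net CO2 assimilation of a flux distribution.

    A_net = sum of realized CO2 consumption minus sum of realized CO2
    production over non-excluded reactions; a reversible producer running
    backward counts as consumption.  Magnitudes below *threshold* are
    reported as exactly 0.
    """
    if flux.model_id != inv.model_id:
        raise ValueError(f"flux is for model {flux.model_id!r} but inventory "
                         f"for {inv.model_id!r}")
    consumption = production = 0.0
    for rid, g in inv.net_co2.items():
        if rid in inv.excluded:
            continue
        release = g * flux.flux.get(rid, 0.0)
        if release > 0:
            production += release
        else:
            consumption += -release
    a_net = consumption - production
    return 0.0 if abs(a_net) < threshold else a_net


def growth_respiration(flux: FluxDistribution, inv: CO2Inventory) -> float:
    """Rg: summed realized CO2 release over non-excluded reactions."""
    return sum(max(0.0, g * flux.flux.get(rid, 0.0))
               for rid, g in inv.net_co2.items() if rid not in inv.excluded)


@dataclass
class RespirationTraits:
    model_id: str
    A_net: float
    Vc: float
    Vo: float
    Rd: float
    CUE: float | None  # None when Vc == 0 (e.g. heterotrophs)
    Rg: float
    Rnetmax: float
    Anetmax: float
    mu: float
    Rg_scaled: float | None  # None when mu == 0 or carbon fraction undefined
    carbon_fraction: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class TraitOptions:
    biomass_reaction_id: str | None = None  # default: sole objective reaction
    optimum_fraction: float = 1.0
    lexicographic: bool = True
    threshold: float = REPORTING_THRESHOLD
    extra_constraints: list[LinearConstraint] = field(default_factory=list)


def _biomass_id(model: MetabolicModel, options: TraitOptions) -> str:
    if options.biomass_reaction_id is not None:
        return options.biomass_reaction_id
    if len(model.objective) != 1:
        raise ValueError("biomass reaction ambiguous; set TraitOptions.biomass_reaction_id")
    return next(iter(model.objective))


def _co2_exchange_target(model: MetabolicModel, inv: CO2Inventory) -> dict[str, float]:
    """Linear expression whose positive value is total CO2 export.

    An exchange reaction with stoichiometry {co2: -1} exports CO2 at positive
    flux; the expression weights each CO2 exchange by minus its CO2
    coefficient so that "export" is always positive.
    """
    co2 = set(inv.co2_species)
    target: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.is_exchange:
            coef = sum(c for mid, c in rxn.stoichiometry.items() if mid in co2)
            if coef != 0.0:
                target[rxn.id] = -coef
    if not target:
        raise ValueError(f"model {model.id} has no CO2 exchange reaction")
    return target


def compute_traits(model: MetabolicModel, inv: CO2Inventory,
                   rc: RubiscoConstraint | None = None,
                   options: TraitOptions | None = None) -> RespirationTraits:
    """Compute the full CO2 trait panel from one pFBA distribution.

    A_net, Vc/Vo, Rd, CUE and Rg all come from the same parsimonious
    distribution at optimal growth; Rnetmax and Anetmax are separate
    maximizations of CO2 export and net CO2 uptake with growth held at its
    optimum.
    """
    options = options or TraitOptions()
    flags: list[str] = []
    constraints = list(options.extra_constraints)
    vc_id = vo_id = None
    if rc is not None:
        try:
            constraints += constrain_rubisco(model, rc)
            vc_id, vo_id = rc.carboxylation_reaction_id, rc.oxygenation_reaction_id
        except MissingPhotorespirationError:
            logger.warning("model %s lacks photorespiration; ratio constraint dropped",
                           model.id)
            flags.append("no-photorespiration")

    sol = pfba(model, constraints, options.optimum_fraction,
               lexicographic=options.lexicographic)
    if sol.status != "optimal":
        raise RuntimeError(f"model {model.id} does not grow ({sol.status})")
    biomass_id = _biomass_id(model, options)
    mu = sol.flux[biomass_id]

    vc = sol.flux.get(vc_id, 0.0) if vc_id else 0.0
    vo = sol.flux.get(vo_id, 0.0) if vo_id else 0.0
    a_net = net_assimilation(sol, inv, options.threshold)
    rd = vc - 0.5 * vo - a_net
    cue = None
    if vc > options.threshold:
        cue = 1.0 - (0.5 * vo + rd) / vc
    else:
        flags.append("cue-undefined")
    rg = growth_respiration(sol, inv)

    target = _co2_exchange_target(model, inv)
    rnet = maximize_flux(model, target, options.optimum_fraction, constraints)
    anet = maximize_flux(model, {k: -v for k, v in target.items()},
                         options.optimum_fraction, constraints)
    rnetmax = rnet.objective_value if rnet.status == "optimal" else float("nan")
    anetmax = anet.objective_value if anet.status == "optimal" else float("nan")

    cf = rg_scaled = None
    try:
        cf = biomass_carbon_fraction(model, biomass_id).value
    except Exception:
        flags.append("carbon-fraction-undefined")
    if cf is not None and mu > FEASIBILITY_TOL and cf > 0:
        rg_scaled = rg / (mu * cf)
    elif "carbon-fraction-undefined" not in flags:
        flags.append("non-growing")

    return RespirationTraits(
        model_id=model.id, A_net=a_net, Vc=vc, Vo=vo, Rd=rd, CUE=cue, Rg=rg,
        Rnetmax=rnetmax, Anetmax=anetmax, mu=mu, Rg_scaled=rg_scaled,
        carbon_fraction=cf, flags=flags,
    )


@dataclass
class ContributionEntry:
    reaction_id: str
    ec_numbers: set[str]
    co2_flux: float
    share: float


@dataclass
class ContributionRanking:
    entries: list[ContributionEntry]
    total: float
    note: str = ""


def rank_contributors(flux: FluxDistribution, inv: CO2Inventory,
                      model: MetabolicModel) -> ContributionRanking:
    """Rank CO2-releasing reactions by realized release, descending.

    Ties are broken by reaction id so output is reproducible.
    """
    releases = []
    for rid, g in inv.net_co2.items():
        if rid in inv.excluded:
            continue
        release = max(0.0, g * flux.flux.get(rid, 0.0))
        if release > 0:
            releases.append((rid, release))
    total = sum(r for _, r in releases)
    if total <= 0:
        return ContributionRanking(entries=[], total=0.0,
                                   note="no CO2 release in this flux distribution")
    releases.sort(key=lambda item: (-item[1], item[0]))
    entries = [ContributionEntry(reaction_id=rid,
                                 ec_numbers=set(model.rxn[rid].ec_numbers),
                                 co2_flux=release, share=release / total)
               for rid, release in releases]
    return ContributionRanking(entries=entries, total=total)


def compare_conditions(model_day: MetabolicModel, model_night: MetabolicModel,
                       inv_day: CO2Inventory, inv_night: CO2Inventory,
                       rc: RubiscoConstraint | None = None,
                       options: TraitOptions | None = None,
                       ) -> tuple[RespirationTraits, RespirationTraits]:
    """Day/night trait pair with the night growth capped at the day optimum.

    The day model is solved first; its optimal growth rate becomes an upper
    bound on the night model's biomass flux, so scaled quantities from the two
    conditions share the same reference.  If the night model cannot reach any
    growth under that cap (infeasible), the cap is dropped with a warning.
    """
    options = options or TraitOptions()
    day = compute_traits(model_day, inv_day, rc, options)

    biomass_id = _biomass_id(model_day, options)
    if biomass_id not in model_night.rxn:
        raise ValueError("day and night models must share the biomass reaction id")
    night_model = model_night.copy()
    rxn = night_model.rxn[biomass_id]
    rxn.upper_bound = min(rxn.upper_bound, day.mu)
    night_rc = rc
    try:
        night = compute_traits(night_model, inv_night, night_rc, options)
    except RuntimeError:
        logger.warning("night model infeasible at day-optimal growth cap; "
                       "falling back to night-optimal growth")
        night = compute_traits(model_night, inv_night, night_rc, options)
    return day, night


def traits_to_row(traits: RespirationTraits) -> dict:
    """Flatten a trait set to the TSV column convention."""
    return {
        "model_id": traits.model_id, "A_net": traits.A_net, "Vc": traits.Vc,
        "Vo": traits.Vo, "Rd": traits.Rd,
        "CUE": traits.CUE if traits.CUE is not None else float("nan"),
        "Rg": traits.Rg, "Rnetmax": traits.Rnetmax, "Anetmax": traits.Anetmax,
        "mu": traits.mu,
        "Rg_scaled": traits.Rg_scaled if traits.Rg_scaled is not None else float("nan"),
        "flags": ";".join(traits.flags),
    }
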