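"""Reaction-knockout screening of respiratory CO2 traits and the
respiration-per-carbon ratio minimization.

``run_screen`` enumerates single or double reaction knockouts, re-solving a
parsimonious flux distribution for each and recording growth, growth
respiration, its carbon-scaled variant and fold-changes versus wild type.
``minimize_scaled_respiration`` asks the complementary question: over the
whole flux polytope (no knockouts), what is the smallest achievable ratio of
summed CO2-producing flux to carbon fixed in biomass?
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .core import MetabolicModel, biomass_carbon_fraction
from .inventory import CO2Inventory
from .lp import (FluxDistribution, LinearConstraint, apply_knockout, fba,
                 minimize_linear_fractional, pfba)
from .traits import RubiscoConstraint, constrain_rubisco, growth_respiration

logger = logging.getLogger(__name__)


@dataclass
class KnockoutRecord:
    knockout_ids: tuple[str, ...]  # empty tuple = wild type
    mu: float
    Rg: float | None
    Rg_scaled: float | None
    fold_nominal: float | None
    fold_scaled: float | None
    viable: bool


@dataclass
class ScreenReport:
    model_id: str
    wild_type: KnockoutRecord
    records: list[KnockoutRecord]
    skipped: int  # pruned pairs


@dataclass
class ScreenOptions:
    lexicographic: bool = True
    #: skip pairs where both reactions carry zero wild-type pFBA flux (their
    #: joint removal provably leaves the wild-type optimum feasible)
    prune_zero_pairs: bool = True
    viability_fraction: float = 1e-6  # viable if mu >= fraction * wild-type mu
    zero_flux_tol: float = 1e-9
    #: candidate filter; exchange and biomass reactions are always excluded
    candidate_ids: list[str] | None = None
    extra_constraints: list[LinearConstraint] = field(default_factory=list)


def _solve_record(model: MetabolicModel, inv: CO2Inventory,
                  constraints, biomass_id: str, cf: float,
                  knockout_ids: tuple[str, ...], wild_type: KnockoutRecord | None,
                  options: ScreenOptions) -> KnockoutRecord:
    ko_model = apply_knockout(model, knockout_ids) if knockout_ids else model
    # cheap viability gate: one plain LP before the parsimonious machinery
    quick = fba(ko_model, constraints)
    mu = quick.flux.get(biomass_id, 0.0) if quick.status == "optimal" else 0.0
    wt_mu = wild_type.mu if wild_type is not None else mu
    viable = mu >= options.viability_fraction * wt_mu if wt_mu > 0 else False
    if not viable:
        return KnockoutRecord(knockout_ids=knockout_ids, mu=mu, Rg=None,
                              Rg_scaled=None, fold_nominal=None,
                              fold_scaled=None, viable=False)
    sol = pfba(ko_model, constraints, 1.0, lexicographic=options.lexicographic)
    if sol.status != "optimal":  # should not happen after the gate
        return KnockoutRecord(knockout_ids=knockout_ids, mu=0.0, Rg=None,
                              Rg_scaled=None, fold_nominal=None,
                              fold_scaled=None, viable=False)
    mu = sol.flux[biomass_id]
    rg = growth_respiration(sol, inv)
    rg_scaled = rg / (mu * cf) if mu > 0 and cf > 0 else None
    fold_nominal = fold_scaled = None
    if wild_type is not None:
        if wild_type.Rg and wild_type.Rg > 0:
            fold_nominal = rg / wild_type.Rg
        if wild_type.Rg_scaled and wild_type.Rg_scaled > 0 and rg_scaled is not None:
            fold_scaled = rg_scaled / wild_type.Rg_scaled
    return KnockoutRecord(knockout_ids=knockout_ids, mu=mu, Rg=rg,
                          Rg_scaled=rg_scaled, fold_nominal=fold_nominal,
                          fold_scaled=fold_scaled, viable=True)


def run_screen(model: MetabolicModel, inv: CO2Inventory,
               rc: RubiscoConstraint | None = None, depth: int = 1,
               options: ScreenOptions | None = None) -> ScreenReport:
    """Exhaustive single (depth=1) or double (depth=2) knockout screen.

    Exchange reactions and the biomass reaction are excluded from the
    candidate set.  Records are ordered lexicographically by knockout ids and
    two runs with identical inputs produce identical reports.
    """
    if depth not in (1, 2):
        raise ValueError("only depth 1 or 2 screens are supported")
    options = options or ScreenOptions()
    constraints = list(options.extra_constraints)
    if rc is not None:
        constraints += constrain_rubisco(model, rc)
    if len(model.objective) != 1:
        raise ValueError("screen requires a single-reaction objective (biomass)")
    biomass_id = next(iter(model.objective))
    cf = biomass_carbon_fraction(model, biomass_id).value

    wt = _solve_record(model, inv, constraints, biomass_id, cf, (), None, options)
    if not wt.viable or wt.mu <= 0:
        raise RuntimeError(f"wild-type model {model.id} does not grow")
    wt_sol = pfba(model, constraints, 1.0, lexicographic=options.lexicographic)
    wt_flux = wt_sol.flux

    if options.candidate_ids is not None:
        candidates = list(options.candidate_ids)
    else:
        candidates = [r.id for r in model.reactions
                      if not r.is_exchange and r.id != biomass_id]
    candidates.sort()

    records: list[KnockoutRecord] = []
    skipped = 0
    if depth == 1:
        sets = [(rid,) for rid in candidates]
    else:
        sets = [tuple(sorted(pair)) for pair in itertools.combinations(candidates, 2)]
        sets.sort()
    for knockout_ids in sets:
        if (depth == 2 and options.prune_zero_pairs
                and all(abs(wt_flux.get(rid, 0.0)) <= options.zero_flux_tol
                        for rid in knockout_ids)):
            skipped += 1
            continue
        records.append(_solve_record(model, inv, constraints, biomass_id, cf,
                                     knockout_ids, wt, options))
    return ScreenReport(model_id=model.id, wild_type=wt, records=records,
                        skipped=skipped)


def run_explicit_sets(model: MetabolicModel, inv: CO2Inventory,
                      knockout_sets: list[tuple[str, ...]],
                      rc: RubiscoConstraint | None = None,
                      options: ScreenOptions | None = None) -> ScreenReport:
    """Screen arbitrary explicit knockout sets (any size) against wild type."""
    options = options or ScreenOptions()
    constraints = list(options.extra_constraints)
    if rc is not None:
        constraints += constrain_rubisco(model, rc)
    biomass_id = next(iter(model.objective))
    cf = biomass_carbon_fraction(model, biomass_id).value
    wt = _solve_record(model, inv, constraints, biomass_id, cf, (), None, options)
    records = [_solve_record(model, inv, constraints, biomass_id, cf,
                             tuple(sorted(ks)), wt, options)
               for ks in knockout_sets]
    return ScreenReport(model_id=model.id, wild_type=wt, records=records, skipped=0)


def find_respiration_reducers(report: ScreenReport,
                              tolerance: float = 1e-6) -> list[KnockoutRecord]:
    """Viable knockouts that reduce CO2 release per carbon in biomass.

    Returns records with fold_scaled < 1 - tolerance.  An empty result is a
    legitimate outcome: for plant central metabolism no knockout combination
    is expected to lower respiration per unit of carbon fixed.
    """
    return [rec for rec in report.records
            if rec.viable and rec.fold_scaled is not None
            and rec.fold_scaled < 1.0 - tolerance]


@dataclass
class RatioMinimizationResult:
    ratio_before: float
    ratio_after: float
    solution: FluxDistribution
    #: number of reactions whose activity state (zero vs nonzero) changed
    #: relative to the reference pFBA distribution
    rerouted_reactions: int


def minimize_scaled_respiration(model: MetabolicModel, inv: CO2Inventory,
                                rc: RubiscoConstraint | None = None,
                                lexicographic: bool = True,
                                extra_constraints: list[LinearConstraint] | None = None,
                                zero_flux_tol: float = 1e-6,
                                ) -> RatioMinimizationResult:
    """Minimize (sum of CO2-producing fluxes) / (growth rate x carbon fraction).

    ``ratio_before`` is the scaled growth respiration of the reference pFBA
    solution; ``ratio_after`` solves the linear-fractional program over the
    whole flux polytope via the Charnes-Cooper substitution, with the
    direction-aware CO2-production sum linearized through reversible
    splitting.
    """
    constraints = list(extra_constraints or [])
    if rc is not None:
        constraints += constrain_rubisco(model, rc)
    biomass_id = next(iter(model.objective))
    cf = biomass_carbon_fraction(model, biomass_id).value
    if cf <= 0:
        raise ValueError(f"model {model.id}: biomass carbon fraction is not positive")
    ref = pfba(model, constraints, 1.0, lexicographic=lexicographic)
    if ref.status != "optimal":
        raise RuntimeError(f"model {model.id} does not grow")
    mu_ref = ref.flux[biomass_id]
    if mu_ref <= 0:
        raise RuntimeError(f"model {model.id} does not grow (mu = 0)")
    ratio_before = growth_respiration(ref, inv) / (mu_ref * cf)

    fwd: dict[str, float] = {}
    rev: dict[str, float] = {}
    for rid, g in inv.net_co2.items():
        if rid in inv.excluded:
            continue
        if g > 0:
            fwd[rid] = g          # forward flux of a producer releases CO2
        else:
            rev[rid] = -g         # a consumer running backward releases CO2
    sol = minimize_linear_fractional(model, (fwd, rev), {biomass_id: cf},
                                     constraints)
    ratio_after = sol.objective_value

    rerouted = sum(
        1 for rid in ref.flux
        if (abs(ref.flux[rid]) > zero_flux_tol)
        != (abs(sol.flux.get(rid, 0.0)) > zero_flux_tol)
    )
    return RatioMinimizationResult(ratio_before=ratio_before,
                                   ratio_after=ratio_after,
                                   solution=sol, rerouted_reactions=rerouted)
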