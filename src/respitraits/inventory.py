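"""CO2-reaction inventory and cross-model EC-set comparison.

Classifies every reaction of a model as CO2-producing or CO2-consuming per
unit forward flux, excluding pure CO2 translocation and boundary exchange,
and compares the EC-number complements of CO2-producing reactions across
models with the Jaccard index.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MetabolicModel, Metabolite

logger = logging.getLogger(__name__)

CO2_CHEBI = "CHEBI:16526"
_CO2_ID_RE = re.compile(r"(^|[_\W])co2([_\W]|$)", re.IGNORECASE)
_HCO3_ID_RE = re.compile(r"(^|[_\W])(hco3|bicarbonate)([_\W]|$)", re.IGNORECASE)


@dataclass
class InventoryConfig:
    #: route CO2/HCO3 interconversions to `excluded` instead of counting them
    ignore_bicarbonate: bool = False
    #: reaction ids excluded a priori (e.g. to apply the stricter biochemical
    #: definition that leaves out photosynthesis and photorespiration)
    exclusion_list: set[str] = field(default_factory=set)


@dataclass
class CO2Inventory:
    model_id: str
    co2_species: list[str]
    #: reaction-id -> net mol CO2 made per unit forward flux
    net_co2: dict[str, float]
    producers_forward: set[str]
    consumers_forward: set[str]
    #: reaction-id -> reason ("transport" | "exchange" | "bicarbonate-only" | "user")
    excluded: dict[str, str]

    def production_coefficient(self, reaction_id: str) -> float:
        """Net CO2 per unit forward flux, 0 for excluded or CO2-free reactions."""
        if reaction_id in self.excluded:
            return 0.0
        return self.net_co2.get(reaction_id, 0.0)


def _is_co2(met: Metabolite) -> bool:
    """CO2 recognition precedence: CHEBI CV-term, exact formula, id/name regex."""
    for accessions in met.annotations.values():
        if CO2_CHEBI in accessions:
            return True
    if met.formula is not None and met.formula.strip() == "CO2":
        return True
    if _CO2_ID_RE.search(met.id) or met.name.strip().lower() == "carbon dioxide":
        return True
    return False


def _is_bicarbonate(met: Metabolite) -> bool:
    if met.formula is not None and met.formula.strip().rstrip("+-0123456789") in ("CHO3", "HCO3"):
        return True
    return bool(_HCO3_ID_RE.search(met.id) or met.name.strip().lower() == "bicarbonate")


def build_inventory(model: MetabolicModel,
                    config: InventoryConfig | None = None) -> CO2Inventory:
    """Identify CO2-producing and CO2-consuming reactions of *model*.

    ``net_co2(r)`` sums the stoichiometric coefficients of all recognized CO2
    species in reaction r; positive means CO2 is made per unit forward flux.
    Transport and exchange reactions are routed to ``excluded`` (translocation
    is not production), as are reactions on the user exclusion list and, when
    ``ignore_bicarbonate`` is set, CO2/bicarbonate interconversions.
    """
    config = config or InventoryConfig()
    co2_ids = [m.id for m in model.metabolites if _is_co2(m)]
    if not co2_ids:
        raise ValueError(f"model {model.id} lacks CO2 species")
    co2_set = set(co2_ids)
    hco3_set = {m.id for m in model.metabolites if _is_bicarbonate(m)}

    net_co2: dict[str, float] = {}
    producers: set[str] = set()
    consumers: set[str] = set()
    excluded: dict[str, str] = {}
    for rxn in model.reactions:
        touches_co2 = any(mid in co2_set for mid in rxn.stoichiometry)
        net = sum(coef for mid, coef in rxn.stoichiometry.items() if mid in co2_set)
        if net != 0.0:
            net_co2[rxn.id] = net
        if rxn.id in config.exclusion_list:
            excluded[rxn.id] = "user"
            continue
        if not touches_co2:
            continue
        if rxn.is_transport:
            excluded[rxn.id] = "transport"
        elif rxn.is_exchange:
            excluded[rxn.id] = "exchange"
        elif net == 0.0:
            continue
        elif config.ignore_bicarbonate and any(m in hco3_set for m in rxn.stoichiometry):
            excluded[rxn.id] = "bicarbonate-only"
        elif net > 0:
            producers.add(rxn.id)
        else:
            consumers.add(rxn.id)

    return CO2Inventory(model_id=model.id, co2_species=co2_ids, net_co2=net_co2,
                        producers_forward=producers, consumers_forward=consumers,
                        excluded=excluded)


def co2_ec_set(model: MetabolicModel, inventory: CO2Inventory) -> set[str]:
    """Union of EC numbers over forward CO2-producing reactions.

    Reactions without EC annotations contribute nothing; partial EC numbers
    (trailing ``-``) are retained as opaque strings.
    """
    if inventory.model_id != model.id:
        raise ValueError("inventory was built for a different model")
    ecs: set[str] = set()
    for rid in inventory.producers_forward:
        ecs |= model.rxn[rid].ec_numbers
    return ecs


@dataclass
class ECSetComparison:
    model_ids: list[str]
    jaccard: pd.DataFrame  # symmetric, unit diagonal for nonempty sets
    coverage: dict[str, float] | None  # None when no reference list given


def jaccard_index(a: set, b: set) -> float:
    """|A∩B| / |A∪B|, defined as 1.0 when both sets are empty."""
    if not a and not b:
        return 1.0
    union = a | b
    return len(a & b) / len(union)


def jaccard_compare(ec_sets: dict[str, set[str]],
                    reference: list[str] | None = None) -> ECSetComparison:
    """Pairwise Jaccard matrix of CO2-producing EC sets plus reference coverage."""
    if len(ec_sets) < 2:
        raise ValueError("need at least two models to compare")
    ids = list(ec_sets)
    n = len(ids)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard_index(ec_sets[ids[i]], ec_sets[ids[j]])
    jac = pd.DataFrame(mat, index=ids, columns=ids)

    coverage = None
    if reference is not None:
        ref = set(reference)
        if not ref:
            logger.warning("empty reference EC list; coverage omitted")
        else:
            coverage = {mid: len(ec_sets[mid] & ref) / len(ref) for mid in ids}
    return ECSetComparison(model_ids=ids, jaccard=jac, coverage=coverage)


def read_ec_list(path) -> list[str]:
    """Plain-text EC list: one EC per line, '#' comments allowed."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out
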