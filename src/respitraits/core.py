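"""Core data model for compartmentalized stoichiometric metabolic networks.

A :class:`MetabolicModel` is a plain in-memory representation of a
constraint-based model: metabolites with elemental formulas, reactions with
signed stoichiometry and flux bounds, and a linear objective (typically the
biomass reaction).  The module also provides the tabular (TSV) dialect used
for lossless round-tripping, Hill-notation formula parsing, and the biomass
carbon accounting needed to express respiration per mole of carbon fixed in
biomass.

Conventions
-----------
* Stoichiometric coefficients are signed: negative = substrate, positive =
  product.
* Exchange reactions carry a single metabolite; negative flux imports it,
  positive flux exports it.
* A reaction is a transport reaction when the multiset of metabolite base
  names (id minus the compartment tag) is identical on the substrate and
  product sides, e.g. ``co2_c -> co2_m``.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHARGE_SUFFIX = re.compile(r"[+-]\d*$")
# generic/undefined groups make element counts undefined
_GENERIC_ELEMENTS = {"R", "X", "Z"}


class FormulaError(ValueError):
    """Raised when an elemental formula cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula into element counts.

    A trailing charge suffix (``+``, ``-2`` ...) is stripped.  Formulas
    containing generic group elements (R, X, Z) raise :class:`FormulaError`
    because atom counts are undefined for them.

    >>> parse_formula("C6H12O6")
    {'C': 6, 'H': 12, 'O': 6}
    """
    if not formula:
        raise FormulaError("empty formula")
    stripped = _CHARGE_SUFFIX.sub("", formula.strip())
    pos = 0
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(stripped):
        if match.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, digits = match.groups()
        if element in _GENERIC_ELEMENTS:
            raise FormulaError(f"generic group element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(stripped):
        raise FormulaError(f"cannot parse formula {formula!r}")
    return counts


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a formula (0 if carbon-free)."""
    return parse_formula(formula).get("C", 0)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    is_boundary: bool = False
    #: resource annotations, e.g. {"chebi": ["CHEBI:16526"]}
    annotations: dict[str, list[str]] = field(default_factory=dict)

    @property
    def elements(self) -> dict[str, int] | None:
        """Parsed element counts, or None when the formula is absent/unusable."""
        if self.formula is None:
            return None
        try:
            return parse_formula(self.formula)
        except FormulaError:
            return None

    def base_name(self) -> str:
        """Metabolite id with the compartment tag removed (``co2_c`` -> ``co2``)."""
        if self.compartment:
            for pattern in (f"_{self.compartment}", f"[{self.compartment}]"):
                if self.id.endswith(pattern):
                    return self.id[: -len(pattern)]
            prefix = f"{self.compartment}_"
            if self.id.startswith(prefix):
                return self.id[len(prefix):]
        return self.id


@dataclass
class Reaction:
    id: str
    name: str = ""
    #: metabolite-id -> signed coefficient (negative = substrate)
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    ec_numbers: set[str] = field(default_factory=set)
    is_exchange: bool = False
    is_transport: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class CarbonFraction:
    """Mol carbon incorporated per unit biomass-reaction flux."""

    value: float
    skipped_metabolites: list[str] = field(default_factory=list)


class ModelValidationError(ValueError):
    pass


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    #: reaction-id -> objective weight
    objective: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._met_index: dict[str, Metabolite] | None = None
        self._rxn_index: dict[str, Reaction] | None = None

    # -- lookups ---------------------------------------------------------
    @property
    def met(self) -> dict[str, Metabolite]:
        if self._met_index is None or len(self._met_index) != len(self.metabolites):
            self._met_index = {m.id: m for m in self.metabolites}
        return self._met_index

    @property
    def rxn(self) -> dict[str, Reaction]:
        if self._rxn_index is None or len(self._rxn_index) != len(self.reactions):
            self._rxn_index = {r.id: r for r in self.reactions}
        return self._rxn_index

    def invalidate_index(self) -> None:
        self._met_index = None
        self._rxn_index = None

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on failure."""
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {m.id}")
            seen.add(m.id)
        seen.clear()
        met_ids = self.met.keys()
        for r in self.reactions:
            if r.id in seen:
                raise ModelValidationError(f"duplicate reaction id {r.id}")
            seen.add(r.id)
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id} has empty stoichiometry")
            unknown = set(r.stoichiometry) - met_ids
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id} references unknown metabolites {sorted(unknown)}"
                )
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(f"reaction {r.id} has inverted bounds")
        unknown = set(self.objective) - {r.id for r in self.reactions}
        if unknown:
            raise ModelValidationError(f"objective references unknown reactions {sorted(unknown)}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[
                Metabolite(
                    id=m.id, name=m.name, compartment=m.compartment,
                    formula=m.formula, is_boundary=m.is_boundary,
                    annotations={k: list(v) for k, v in m.annotations.items()},
                )
                for m in self.metabolites
            ],
            reactions=[
                Reaction(
                    id=r.id, name=r.name, stoichiometry=dict(r.stoichiometry),
                    lower_bound=r.lower_bound, upper_bound=r.upper_bound,
                    ec_numbers=set(r.ec_numbers), is_exchange=r.is_exchange,
                    is_transport=r.is_transport, notes=r.notes,
                )
                for r in self.reactions
            ],
            objective=dict(self.objective),
        )

    # -- derived flags ---------------------------------------------------
    def detect_exchanges_and_transports(self) -> None:
        """(Re)compute the is_exchange / is_transport flags structurally."""
        for r in self.reactions:
            internal = [m for m in r.stoichiometry if not self.met[m].is_boundary]
            r.is_exchange = len(internal) == 1 and (
                len(r.stoichiometry) == 1
                or all(self.met[m].is_boundary for m in r.stoichiometry if m != internal[0])
            )
            r.is_transport = False
            if not r.is_exchange:
                subs = Counter()
                prods = Counter()
                for mid, coef in r.stoichiometry.items():
                    base = self.met[mid].base_name()
                    if coef < 0:
                        subs[base] += -coef
                    elif coef > 0:
                        prods[base] += coef
                if subs and subs == prods:
                    r.is_transport = True


def biomass_carbon_fraction(model: MetabolicModel, biomass_reaction_id: str) -> CarbonFraction:
    """Mol carbon incorporated into biomass per unit biomass-reaction flux.

    Sums carbon over biomass substrates (by |coefficient| x carbon atoms) and
    subtracts carbon returned in by-products.  The biomass pseudo-species
    itself (a product whose id or name contains "biomass", or the single
    formula-less product) is not subtracted.  Metabolites without a parseable
    formula are reported in ``skipped_metabolites``.
    """
    try:
        rxn = model.rxn[biomass_reaction_id]
    except KeyError:
        raise KeyError(f"no biomass reaction {biomass_reaction_id!r} in model {model.id}")

    def is_biomass_species(met: Metabolite) -> bool:
        text = f"{met.id} {met.name}".lower()
        return "biomass" in text or re.search(r"\bbio(_|\b)", text) is not None

    value = 0.0
    skipped: list[str] = []
    any_carbon_substrate = False
    for mid, coef in sorted(rxn.stoichiometry.items()):
        met = model.met[mid]
        if coef > 0 and is_biomass_species(met):
            continue  # the biomass pseudo-species itself
        elements = met.elements
        if elements is None:
            skipped.append(mid)
            continue
        carbons = elements.get("C", 0)
        if coef < 0 and carbons > 0:
            any_carbon_substrate = True
        # substrates contribute +|coef|*C, by-products subtract coef*C
        value += -coef * carbons
    if not any_carbon_substrate:
        raise ModelValidationError(
            f"carbon fraction undefined: no biomass substrate of {biomass_reaction_id} "
            "has a carbon-bearing formula"
        )
    return CarbonFraction(value=value, skipped_metabolites=skipped)


def carbon_imbalance(model: MetabolicModel, reaction_id: str) -> float | None:
    """Net carbon change of a reaction, or None if any participant lacks a formula."""
    rxn = model.rxn[reaction_id]
    total = 0.0
    for mid, coef in rxn.stoichiometry.items():
        elements = model.met[mid].elements
        if elements is None:
            return None
        total += coef * elements.get("C", 0)
    return total


# ----------------------------------------------------------------------
# Tabular (TSV) dialect: three UTF-8 files with header rows.
#   metabolites.tsv: id name compartment formula is_boundary annotations
#   reactions.tsv:   id name stoichiometry lower_bound upper_bound ec_numbers notes
#   objective.tsv:   reaction_id weight
# Floats are serialized with repr() so the round trip is bit-exact.
# ----------------------------------------------------------------------

MET_COLUMNS = ["id", "name", "compartment", "formula", "is_boundary", "annotations"]
RXN_COLUMNS = ["id", "name", "stoichiometry", "lower_bound", "upper_bound",
               "ec_numbers", "is_exchange", "is_transport", "notes"]
OBJ_COLUMNS = ["reaction_id", "weight"]


def _esc(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unesc(text: str) -> str:
    out, i = [], 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def write_tabular(model: MetabolicModel, out_dir: str | Path) -> None:
    """Write the TSV trio (metabolites/reactions/objective) for *model*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "metabolites.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(MET_COLUMNS) + "\n")
        for m in model.metabolites:
            fh.write("\t".join([
                m.id, _esc(m.name), m.compartment,
                m.formula if m.formula is not None else "",
                "1" if m.is_boundary else "0",
                json.dumps(m.annotations, sort_keys=True) if m.annotations else "",
            ]) + "\n")
    with open(out / "reactions.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(RXN_COLUMNS) + "\n")
        for r in model.reactions:
            stoich = ";".join(f"{mid}:{coef!r}" for mid, coef in sorted(r.stoichiometry.items()))
            fh.write("\t".join([
                r.id, _esc(r.name), stoich, repr(r.lower_bound), repr(r.upper_bound),
                ";".join(sorted(r.ec_numbers)),
                "1" if r.is_exchange else "0",
                "1" if r.is_transport else "0",
                _esc(r.notes),
            ]) + "\n")
    with open(out / "objective.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(OBJ_COLUMNS) + "\n")
        for rid, weight in sorted(model.objective.items()):
            fh.write(f"{rid}\t{weight!r}\n")
    with open(out / "model.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\n")
        fh.write(model.id + "\n")


def read_tabular(in_dir: str | Path) -> MetabolicModel:
    """Inverse of :func:`write_tabular`."""
    src = Path(in_dir)

    def rows(name: str, columns: list[str]):
        with open(src / name, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != columns:
                raise ValueError(f"{name}: unexpected columns {header}")
            for line in fh:
                yield line.rstrip("\n").split("\t")

    model_id = "model"
    model_file = src / "model.tsv"
    if model_file.exists():
        model_id = model_file.read_text(encoding="utf-8").splitlines()[1]

    metabolites = []
    for mid, name, comp, formula, boundary, annot in rows("metabolites.tsv", MET_COLUMNS):
        metabolites.append(Metabolite(
            id=mid, name=_unesc(name), compartment=comp,
            formula=formula or None, is_boundary=boundary == "1",
            annotations=json.loads(annot) if annot else {},
        ))
    reactions = []
    for rid, name, stoich, lb, ub, ecs, is_ex, is_tr, notes in rows("reactions.tsv", RXN_COLUMNS):
        coeffs = {}
        if stoich:
            for part in stoich.split(";"):
                mid, val = part.rsplit(":", 1)
                coeffs[mid] = float(val)
        reactions.append(Reaction(
            id=rid, name=_unesc(name), stoichiometry=coeffs,
            lower_bound=float(lb), upper_bound=float(ub),
            ec_numbers=set(ecs.split(";")) if ecs else set(),
            is_exchange=is_ex == "1", is_transport=is_tr == "1",
            notes=_unesc(notes),
        ))
    objective = {rid: float(w) for rid, w in rows("objective.tsv", OBJ_COLUMNS)}
    model = MetabolicModel(id=model_id, metabolites=metabolites,
                           reactions=reactions, objective=objective)
    model.validate()
    return model


def models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Field-for-field equality of two models (used by round-trip tests)."""
    if a.id != b.id or len(a.metabolites) != len(b.metabolites) or len(a.reactions) != len(b.reactions):
        return False
    for ma, mb in zip(a.metabolites, b.metabolites):
        if (ma.id, ma.name, ma.compartment, ma.formula, ma.is_boundary, ma.annotations) != \
           (mb.id, mb.name, mb.compartment, mb.formula, mb.is_boundary, mb.annotations):
            return False
    for ra, rb in zip(a.reactions, b.reactions):
        if (ra.id, ra.name, ra.stoichiometry, ra.lower_bound, ra.upper_bound,
                ra.ec_numbers, ra.is_exchange, ra.is_transport, ra.notes) != \
           (rb.id, rb.name, rb.stoichiometry, rb.lower_bound, rb.upper_bound,
                rb.ec_numbers, rb.is_exchange, rb.is_transport, rb.notes):
            return False
    return a.objective == b.objective
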