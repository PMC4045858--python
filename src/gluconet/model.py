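"""Stoichiometric model representation, validation and I/O.

A :class:`MetabolicModel` is the shared in-memory container for every
analysis in this package: an ordered list of metabolites (rows of the
stoichiometric matrix ``S``), an ordered list of reactions (columns of
``S``, each carrying box flux bounds in mmol/gDW/h) and a linear
objective ``c`` given as a map from reaction id to coefficient.

Models can be read from SBML (both FBC-v2 flux bounds and the legacy
kinetic-law ``LOWER_BOUND``/``UPPER_BOUND`` parameter dialect used by
genome-scale models deposited around 2011), round-tripped losslessly
through a small JSON schema, and exported as a TSV reaction table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

#: COBRA-convention default flux bound magnitude (mmol/gDW/h).
DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Metabolite:
    """A compartmented chemical species (BiGG-style id, e.g. ``glcn_c``)."""

    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None

    def species_key(self) -> str:
        """Id with the compartment suffix stripped.

        Used when counting *unique* small metabolites: ``glc_D_c`` and
        ``glc_D_e`` are the same species in two compartments.
        """
        if self.compartment and self.id.endswith("_" + self.compartment):
            return self.id[: -(len(self.compartment) + 1)]
        return self.id


@dataclass
class Reaction:
    """A column of S: signed stoichiometry plus box flux bounds."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        """True for boundary reactions touching exactly one metabolite."""
        return len(self.stoichiometry) == 1

    def equation(self) -> str:
        lhs = []
        rhs = []
        for met, coef in sorted(self.stoichiometry.items()):
            part = met if abs(coef) == 1 else f"{abs(coef):g} {met}"
            (lhs if coef < 0 else rhs).append(part)
        arrow = "<=>" if self.lower_bound < 0 < self.upper_bound else "-->"
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}"


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective: dict[str, float] = field(default_factory=dict)
    id: str = ""

    # -- basic accessors -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def get_metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}")

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def n_unique_metabolites(self) -> int:
        """Number of distinct species after stripping compartment suffixes."""
        return len({m.species_key() for m in self.metabolites})

    # -- numerical view --------------------------------------------------

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with one row per metabolite, one column per reaction."""
        index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[index[met], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        for j, r in enumerate(self.reactions):
            if r.id in self.objective:
                c[j] = self.objective[r.id]
        return c

    # -- mutation helpers ------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[
                Reaction(r.id, dict(r.stoichiometry), r.lower_bound,
                         r.upper_bound, r.name)
                for r in self.reactions
            ],
            objective=dict(self.objective),
            id=self.id,
        )

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        if lower > upper:
            raise ValueError(
                f"lower bound {lower} exceeds upper bound {upper} for {rxn_id}"
            )
        rxn = self.get_reaction(rxn_id)
        rxn.lower_bound = lower
        rxn.upper_bound = upper


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Issue:
    """One validation finding; ``kind`` is a stable machine-readable tag."""

    kind: str
    subject: str
    message: str


def validate(model: MetabolicModel) -> list[Issue]:
    """Report structural problems; an empty list means a consistent model.

    Checks: bound violations (lb > ub), duplicate ids, references to
    undeclared metabolites, orphan metabolites (used by no reaction) and
    dead-end metabolites (internal species that no reaction can produce,
    or none can consume, given bound signs).
    """
    issues: list[Issue] = []
    met_ids = model.metabolite_ids
    seen = set()
    for mid in met_ids:
        if mid in seen:
            issues.append(Issue("duplicate_metabolite", mid,
                                f"metabolite id {mid} declared twice"))
        seen.add(mid)
    seen_r: set[str] = set()
    producible: set[str] = set()
    consumable: set[str] = set()
    used: set[str] = set()
    boundary: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in seen_r:
            issues.append(Issue("duplicate_reaction", rxn.id,
                                f"reaction id {rxn.id} declared twice"))
        seen_r.add(rxn.id)
        if rxn.lower_bound > rxn.upper_bound:
            issues.append(Issue(
                "bound_violation", rxn.id,
                f"lower bound {rxn.lower_bound} > upper bound {rxn.upper_bound}"))
        if not rxn.stoichiometry:
            issues.append(Issue("empty_stoichiometry", rxn.id,
                                "reaction has no metabolites"))
        for met, coef in rxn.stoichiometry.items():
            if met not in seen:
                issues.append(Issue("unknown_metabolite", rxn.id,
                                    f"reaction references undeclared {met}"))
                continue
            used.add(met)
            if rxn.is_exchange:
                # the system boundary both feeds and drains its metabolite
                boundary.add(met)
                continue
            if (coef > 0 and rxn.upper_bound > 0) or (coef < 0 and rxn.lower_bound < 0):
                producible.add(met)
            if (coef < 0 and rxn.upper_bound > 0) or (coef > 0 and rxn.lower_bound < 0):
                consumable.add(met)
    for rid in model.objective:
        if rid not in seen_r:
            issues.append(Issue("unknown_objective_reaction", rid,
                                f"objective references missing reaction {rid}"))
    for mid in met_ids:
        if mid not in used:
            issues.append(Issue("orphan_metabolite", mid,
                                "metabolite not used by any reaction"))
        elif mid not in boundary:
            if mid not in producible:
                issues.append(Issue("dead_end", mid,
                                    "metabolite has no producing reaction"))
            if mid not in consumable:
                issues.append(Issue("dead_end", mid,
                                    "metabolite has no consuming reaction"))
    return issues


# ---------------------------------------------------------------------------
# element balance (used to check the gluconate extension reactions)


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for element, number in _FORMULA_TOKEN.findall(formula):
        if element:
            counts[element] = counts.get(element, 0) + int(number or 1)
    return counts


def element_imbalance(model: MetabolicModel, rxn_id: str,
                      elements: tuple[str, ...] = ("C", "P")) -> dict[str, float]:
    """Net element production of a reaction, per element.

    Only metabolites carrying a formula annotation contribute; returns
    {} for exchange reactions (boundary reactions are never balanced).
    """
    rxn = model.get_reaction(rxn_id)
    if rxn.is_exchange:
        return {}
    net: dict[str, float] = {e: 0.0 for e in elements}
    for met_id, coef in rxn.stoichiometry.items():
        formula = model.get_metabolite(met_id).formula
        if formula is None:
            continue
        counts = parse_formula(formula)
        for e in elements:
            net[e] += coef * counts.get(e, 0)
    return net


# ---------------------------------------------------------------------------
# SBML input


def _strip_sbml_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def read_sbml(path: str) -> MetabolicModel:
    """Load a constraint-based model from SBML level 2 or 3.

    Flux bounds are taken from the FBC-v2 plugin when present; otherwise
    from ``LOWER_BOUND``/``UPPER_BOUND`` kinetic-law parameters (the
    dialect of pre-FBC genome-scale models). Missing bounds default to
    0/±1000 depending on the ``reversible`` flag. Objective coefficients
    come from FBC or from ``OBJECTIVE_COEFFICIENT`` parameters.

    Species flagged ``boundaryCondition`` are dropped (they sit outside
    the mass balance); reactions that then touch a single metabolite are
    exchanges. Leading ``R_``/``M_`` id mangling is stripped.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        fatal = [doc.getError(i) for i in range(doc.getNumErrors())
                 if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        if fatal:
            raise ValueError(
                f"SBML parse error in {path}: {fatal[0].getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"{path} contains no SBML model")

    boundary_species = set()
    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        sid = _strip_sbml_prefix(sp.getId(), "M_")
        if sp.getBoundaryCondition():
            boundary_species.add(sp.getId())
            continue
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = fbc_sp.getChemicalFormula()
        metabolites.append(Metabolite(
            id=sid,
            name=sp.getName() or sid,
            compartment=sp.getCompartment() or "",
            formula=formula,
        ))

    fbc_model = sbml_model.getPlugin("fbc")

    def fbc_bound(rxn, which: str) -> float | None:
        plug = rxn.getPlugin("fbc")
        if plug is None:
            return None
        pid = (plug.getLowerFluxBound() if which == "lower"
               else plug.getUpperFluxBound())
        if not pid:
            return None
        param = sbml_model.getParameter(pid)
        return param.getValue() if param is not None else None

    def kinetic_param(rxn, name: str) -> float | None:
        kl = rxn.getKineticLaw()
        if kl is None:
            return None
        p = kl.getParameter(name) or kl.getLocalParameter(name)
        return p.getValue() if p is not None else None

    objective: dict[str, float] = {}
    reactions = []
    for rxn in sbml_model.getListOfReactions():
        rid = _strip_sbml_prefix(rxn.getId(), "R_")
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            if ref.getSpecies() in boundary_species:
                continue
            met = _strip_sbml_prefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            if ref.getSpecies() in boundary_species:
                continue
            met = _strip_sbml_prefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}

        reversible = rxn.getReversible()
        lb = fbc_bound(rxn, "lower")
        if lb is None:
            lb = kinetic_param(rxn, "LOWER_BOUND")
        if lb is None:
            lb = -DEFAULT_BOUND if reversible else 0.0
        ub = fbc_bound(rxn, "upper")
        if ub is None:
            ub = kinetic_param(rxn, "UPPER_BOUND")
        if ub is None:
            ub = DEFAULT_BOUND
        lb = max(lb, -DEFAULT_BOUND)
        ub = min(ub, DEFAULT_BOUND)

        coef = kinetic_param(rxn, "OBJECTIVE_COEFFICIENT")
        if coef:
            objective[rid] = coef
        reactions.append(Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            name=rxn.getName() or rid))

    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        active = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if active is not None:
            sense = -1.0 if active.getType() == "minimize" else 1.0
            for fo in active.getListOfFluxObjectives():
                rid = _strip_sbml_prefix(fo.getReaction(), "R_")
                objective[rid] = sense * fo.getCoefficient()

    if not reactions:
        raise ValueError(f"{path}: model has no reactions")
    model = MetabolicModel(metabolites=metabolites, reactions=reactions,
                           objective=objective, id=sbml_model.getId() or "")
    return model


# ---------------------------------------------------------------------------
# JSON round trip and TSV export


def write_json(model: MetabolicModel, path: str) -> None:
    payload = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             **({"formula": m.formula} if m.formula else {})}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "name": r.name, "stoichiometry": r.stoichiometry,
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound}
            for r in model.reactions
        ],
        "objective": model.objective,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_json(path: str) -> MetabolicModel:
    with open(path) as fh:
        payload = json.load(fh)
    return MetabolicModel(
        metabolites=[
            Metabolite(id=m["id"], name=m.get("name", ""),
                       compartment=m.get("compartment", ""),
                       formula=m.get("formula"))
            for m in payload["metabolites"]
        ],
        reactions=[
            Reaction(id=r["id"], stoichiometry=dict(r["stoichiometry"]),
                     lower_bound=float(r["lower_bound"]),
                     upper_bound=float(r["upper_bound"]),
                     name=r.get("name", ""))
            for r in payload["reactions"]
        ],
        objective={k: float(v) for k, v in payload.get("objective", {}).items()},
        id=payload.get("id", ""),
    )


def write_reaction_tsv(model: MetabolicModel, path: str) -> None:
    """Reaction table: id, equation, lb, ub (mmol/gDW/h)."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tequation\tlower_bound\tupper_bound\n")
        for r in model.reactions:
            fh.write(f"{r.id}\t{r.equation()}\t{r.lower_bound:g}\t{r.upper_bound:g}\n")
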