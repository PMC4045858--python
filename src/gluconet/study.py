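"""The gluconate study pipeline on an erythrocyte-style network.

Extends a red-cell constraint-based model with gluconate uptake
(exchange, passive transport, and gluconokinase feeding
6-phospho-D-gluconate into the hexose monophosphate shunt), then runs
the study analyses around it:

* baseline vs gluconate FVA and the >=40 % flux-range-change tally;
* robustness: the objective as a function of forced gluconate uptake;
* shadow-price comparison between the closed and open condition;
* an exchange/transport bound-relaxation scan.

The objective throughout is the ATP-dependent Na+/K+ pump, located by
its stoichiometry (ATP hydrolysis coupled to Na+ export and K+ import)
so that no model-specific reaction id needs to be hard-coded.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction
from .lp import DUAL_TOL, InfeasibleModelError, fba, shadow_price_profile
from .fva import fva, classify_changes, change_summary

#: ids of the three reactions the extension adds
GLUCONATE_EXCHANGE = "EX_glcn_e"
GLUCONATE_TRANSPORT = "GLCNt"
GLUCONOKINASE = "GNTK"

#: BiGG formulas for the species the extension touches (used for the
#: carbon/phosphorus balance check of the added gluconokinase reaction)
_FORMULAS = {
    "glcn": "C6H11O7",
    "6pgc": "C6H10O10P",
    "atp": "C10H12N5O13P3",
    "adp": "C10H12N5O10P2",
    "h": "H",
}


class ExtensionError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Constraint setup of the study.

    ``glucose_uptake`` is fixed (both bounds) on the glucose exchange;
    the oxidative-HMS entry (glucose-6-phosphate dehydrogenase) is
    floated between ``g6pd_fraction_bounds`` of the glucose uptake;
    ``sweep_grid`` lists the forced gluconate uptake rates of the
    robustness analysis (all fluxes in mmol/gDW/h).
    """

    glucose_uptake: float = 1.12
    objective_reaction_id: str | None = None
    glucose_exchange_id: str | None = None
    g6pd_reaction_id: str | None = None
    g6pd_fraction_bounds: tuple[float, float] = (0.05, 0.10)
    gluconate_exchange_bounds: tuple[float, float] = (-DEFAULT_BOUND,
                                                      DEFAULT_BOUND)
    sweep_grid: tuple[float, ...] = tuple(np.round(np.arange(0, 20.0001, 0.1), 3))
    refine_breakpoints: bool = True
    refine_tol: float = 1e-3
    decline_tol: float = 1e-6
    dual_tol: float = DUAL_TOL

    def __post_init__(self) -> None:
        if self.glucose_uptake <= 0:
            raise ValueError("glucose_uptake must be positive")
        lo, hi = self.g6pd_fraction_bounds
        if not 0 <= lo <= hi:
            raise ValueError("g6pd_fraction_bounds must be ordered and >= 0")
        grid = np.asarray(self.sweep_grid, dtype=float)
        if len(grid) and (np.any(grid < 0) or np.any(np.diff(grid) < 0)):
            raise ValueError("sweep_grid must be non-negative and sorted")


@dataclass
class RobustnessCurve:
    """Objective flux as a function of forced gluconate uptake."""

    uptake: list[float]
    objective: list[float | None]
    status: list[str]
    #: smallest uptake at which the curve first attains its maximum
    first_max_uptake: float | None = None
    #: largest uptake before the objective falls below the maximum
    decline_uptake: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gluconate_uptake": self.uptake,
                             "objective": self.objective,
                             "status": self.status})


# ---------------------------------------------------------------------------
# model extension


def add_gluconate(model: MetabolicModel) -> MetabolicModel:
    """Extended copy with gluconate exchange, transport and gluconokinase.

    Adds ``glcn_e``/``glcn_c`` plus::

        EX_glcn_e : glcn_e <=> (boundary)
        GLCNt     : glcn_e <=> glcn_c (passive diffusion)
        GNTK      : atp_c + glcn_c -> adp_c + 6pgc_c + h_c

    The gluconokinase proton follows BiGG convention and is included
    when the model carries a cytosolic proton. The exchange is created
    *closed to uptake* (lb 0) so the extended model is the baseline
    condition until the exchange is opened.
    """
    for rid in (GLUCONATE_EXCHANGE, GLUCONATE_TRANSPORT, GLUCONOKINASE):
        if rid in model.reaction_ids:
            raise ExtensionError(f"model already contains {rid}; "
                                 "gluconate extension applied twice?")
    met_ids = set(model.metabolite_ids)
    for required in ("6pgc_c", "atp_c", "adp_c"):
        if required not in met_ids:
            raise ExtensionError(
                f"cannot add gluconokinase: species {required} absent from model")
    new = model.copy()
    new.metabolites = new.metabolites + [
        Metabolite("glcn_e", "D-gluconate", "e", _FORMULAS["glcn"]),
        Metabolite("glcn_c", "D-gluconate", "c", _FORMULAS["glcn"]),
    ]
    gntk_stoich = {"atp_c": -1.0, "glcn_c": -1.0, "adp_c": 1.0, "6pgc_c": 1.0}
    if "h_c" in met_ids:
        gntk_stoich["h_c"] = 1.0
    new.reactions = new.reactions + [
        Reaction(GLUCONATE_EXCHANGE, {"glcn_e": -1.0}, 0.0, DEFAULT_BOUND,
                 "D-gluconate exchange"),
        Reaction(GLUCONATE_TRANSPORT, {"glcn_e": -1.0, "glcn_c": 1.0},
                 -DEFAULT_BOUND, DEFAULT_BOUND, "D-gluconate diffusion"),
        Reaction(GLUCONOKINASE, gntk_stoich, 0.0, DEFAULT_BOUND,
                 "gluconokinase"),
    ]
    return new


def open_gluconate(model: MetabolicModel,
                   bounds: tuple[float, float] = (-DEFAULT_BOUND,
                                                  DEFAULT_BOUND)) -> MetabolicModel:
    """Copy with the gluconate exchange bounds opened (uptake allowed)."""
    new = model.copy()
    new.set_bounds(GLUCONATE_EXCHANGE, *bounds)
    return new


def close_gluconate(model: MetabolicModel) -> MetabolicModel:
    new = model.copy()
    new.set_bounds(GLUCONATE_EXCHANGE, 0.0, DEFAULT_BOUND)
    return new


# ---------------------------------------------------------------------------
# id resolution and constraint setup


def find_sodium_pump(model: MetabolicModel) -> str:
    """Locate the ATP-dependent Na+/K+ pump by stoichiometry.

    Searches for a reaction hydrolysing ATP (atp consumed, adp
    produced) while translocating both sodium and potassium between
    compartments. Falls back to the BiGG id ``NaKt`` if present.
    """
    for rxn in model.reactions:
        s = rxn.stoichiometry
        if s.get("atp_c", 0) < 0 and s.get("adp_c", 0) > 0:
            na = [m for m in s if m.startswith("na1_")]
            k = [m for m in s if m.startswith("k_")]
            if len(na) >= 2 and len(k) >= 2:
                return rxn.id
    if "NaKt" in model.reaction_ids:
        return "NaKt"
    raise KeyError("no Na+/K+ pump stoichiometry found; set "
                   "StudyConfig.objective_reaction_id explicitly")


def _find_exchange_for(model: MetabolicModel, species_prefixes: tuple[str, ...]) -> str:
    for prefix in species_prefixes:
        for rxn in model.exchanges:
            (met,) = rxn.stoichiometry
            if met.startswith(prefix):
                return rxn.id
    raise KeyError(f"no exchange found for species {species_prefixes}")


def find_glucose_exchange(model: MetabolicModel) -> str:
    return _find_exchange_for(model, ("glc_D_", "glc__D_", "glc_"))


def find_g6pd(model: MetabolicModel) -> str:
    """Glucose-6-phosphate dehydrogenase: g6p + nadp -> 6pgl (or 6pgc)."""
    for rxn in model.reactions:
        s = rxn.stoichiometry
        if (s.get("g6p_c", 0) < 0 and s.get("nadp_c", 0) < 0
                and (s.get("6pgl_c", 0) > 0 or s.get("6pgc_c", 0) > 0)):
            return rxn.id
    raise KeyError("no glucose-6-phosphate dehydrogenase found; set "
                   "StudyConfig.g6pd_reaction_id explicitly")


def apply_study_constraints(model: MetabolicModel,
                            config: StudyConfig) -> MetabolicModel:
    """Fix glucose uptake, float the HMS entry, set the pump objective.

    Glucose uptake "fixed" means both exchange bounds at
    ``-glucose_uptake``; the G6PD flux is floated between the
    configured fractions of that uptake.
    """
    new = model.copy()
    glc_ex = config.glucose_exchange_id or find_glucose_exchange(new)
    new.set_bounds(glc_ex, -config.glucose_uptake, -config.glucose_uptake)
    g6pd = config.g6pd_reaction_id or find_g6pd(new)
    lo, hi = config.g6pd_fraction_bounds
    new.set_bounds(g6pd, lo * config.glucose_uptake, hi * config.glucose_uptake)
    pump = config.objective_reaction_id or find_sodium_pump(new)
    new.objective = {pump: 1.0}
    return new


# ---------------------------------------------------------------------------
# robustness analysis


def _objective_at_uptake(model: MetabolicModel, uptake: float):
    probed = model.copy()
    probed.set_bounds(GLUCONATE_EXCHANGE, -uptake, -uptake)
    sol = fba(probed)
    return sol


def robustness(model: MetabolicModel, config: StudyConfig) -> RobustnessCurve:
    """Objective vs forced gluconate uptake over ``config.sweep_grid``.

    Each grid point fixes the gluconate exchange at that uptake (both
    bounds) and re-solves the FBA problem. The summary locates the
    uptake at which the objective first reaches its maximum and the
    last uptake before it declines by more than ``decline_tol``; both
    are sharpened by bisection to ``refine_tol`` when enabled.
    """
    grid = [float(u) for u in config.sweep_grid]
    if not grid:
        raise ValueError("sweep_grid is empty")
    objectives: list[float | None] = []
    statuses: list[str] = []
    for u in grid:
        sol = _objective_at_uptake(model, u)
        statuses.append(sol.status)
        objectives.append(sol.objective_value if sol.optimal else None)
    feasible = [(u, z) for u, z in zip(grid, objectives) if z is not None]
    if not feasible:
        raise InfeasibleModelError("robustness sweep: no feasible grid point")

    zmax = max(z for _, z in feasible)
    tol = config.decline_tol

    def refine(lo: float, hi: float, predicate) -> float:
        # smallest uptake in (lo, hi] satisfying predicate
        while hi - lo > config.refine_tol:
            mid = 0.5 * (lo + hi)
            sol = _objective_at_uptake(model, mid)
            if sol.optimal and predicate(sol.objective_value):
                hi = mid
            else:
                lo = mid
        return hi

    first_max = None
    for i, (u, z) in enumerate(feasible):
        if z >= zmax - tol:
            first_max = u
            if config.refine_breakpoints and i > 0:
                first_max = refine(feasible[i - 1][0], u,
                                   lambda z_: z_ >= zmax - tol)
            break

    decline = None
    at_max = [u for u, z in feasible if z >= zmax - tol]
    if at_max:
        last_at_max = max(at_max)
        later = [u for u, z in feasible if u > last_at_max] + \
                [u for u, s in zip(grid, statuses) if s != "optimal" and u > last_at_max]
        if later:
            decline = last_at_max
            if config.refine_breakpoints:
                # push the plateau edge right up to where the drop starts
                lo, hi = last_at_max, min(later)
                while hi - lo > config.refine_tol:
                    mid = 0.5 * (lo + hi)
                    sol = _objective_at_uptake(model, mid)
                    if sol.optimal and sol.objective_value >= zmax - tol:
                        lo = mid
                    else:
                        hi = mid
                decline = lo
    return RobustnessCurve(uptake=grid, objective=objectives, status=statuses,
                           first_max_uptake=first_max, decline_uptake=decline)


# ---------------------------------------------------------------------------
# relaxation scan and shadow comparison


def _is_transport(rxn: Reaction, model: MetabolicModel) -> bool:
    comps = set()
    for met in rxn.stoichiometry:
        try:
            comps.add(model.get_metabolite(met).compartment)
        except KeyError:
            pass
    return len(comps) > 1


def relaxation_scan(model: MetabolicModel,
                    reactions: list[str] | None = None,
                    effect_tol: float = 1e-6) -> pd.DataFrame:
    """Relax each exchange/transport bound and re-solve FBA.

    Exchange bounds open fully to +-1000 (medium availability is a
    modelling choice); internal transports keep their directionality
    and only have their magnitudes widened, since reversing an
    irreversible active transporter would manufacture thermodynamically
    impossible energy loops.

    Returns a DataFrame indexed by reaction id with the baseline and
    relaxed objective, their difference and an ``affects`` flag
    (|delta| > ``effect_tol``). Unbounded relaxed problems are flagged
    as affecting with an infinite delta.
    """
    base = fba(model)
    if not base.optimal:
        raise InfeasibleModelError(f"baseline model is {base.status}")
    if reactions is None:
        reactions = [r.id for r in model.reactions
                     if r.is_exchange or _is_transport(r, model)]
    rows = []
    for rid in reactions:
        relaxed = model.copy()
        rxn = relaxed.get_reaction(rid)
        if rxn.is_exchange:
            relaxed.set_bounds(rid, -DEFAULT_BOUND, DEFAULT_BOUND)
        else:
            relaxed.set_bounds(rid,
                               -DEFAULT_BOUND if rxn.lower_bound < 0 else 0.0,
                               DEFAULT_BOUND if rxn.upper_bound > 0 else 0.0)
        sol = fba(relaxed)
        if sol.optimal:
            delta = sol.objective_value - base.objective_value
            relaxed_obj = sol.objective_value
        elif sol.status == "unbounded":
            delta = np.inf
            relaxed_obj = np.inf
        else:
            delta = np.nan
            relaxed_obj = np.nan
        rows.append((rid, base.objective_value, relaxed_obj, delta,
                     bool(np.isfinite(delta) and abs(delta) > effect_tol
                          or np.isinf(delta))))
    return pd.DataFrame(
        rows,
        columns=["reaction_id", "baseline_objective", "relaxed_objective",
                 "delta_objective", "affects"],
    ).set_index("reaction_id")


def shadow_comparison(closed: MetabolicModel, open_: MetabolicModel,
                      dual_tol: float = DUAL_TOL) -> pd.DataFrame:
    """Per-metabolite shadow prices without vs with gluconate uptake.

    Raises naming the offending condition when either model has no
    optimum. The ``affects_*`` flags use ``dual_tol``; note that dual
    values of degenerate optima are solver-dependent, so the *counts*
    of affecting metabolites carry that caveat.
    """
    try:
        sp_closed = shadow_price_profile(closed)
    except InfeasibleModelError as err:
        raise InfeasibleModelError(f"closed-gluconate condition: {err}") from err
    try:
        sp_open = shadow_price_profile(open_)
    except InfeasibleModelError as err:
        raise InfeasibleModelError(f"open-gluconate condition: {err}") from err
    mets = sorted(set(sp_closed) | set(sp_open))
    table = pd.DataFrame(
        {
            "sp_without": [sp_closed.get(m, np.nan) for m in mets],
            "sp_with": [sp_open.get(m, np.nan) for m in mets],
        },
        index=pd.Index(mets, name="metabolite_id"),
    )
    table["affects_without"] = table["sp_without"].abs() > dual_tol
    table["affects_with"] = table["sp_with"].abs() > dual_tol
    return table


def unique_species_affect_counts(table: pd.DataFrame,
                                 model: MetabolicModel) -> dict[str, int]:
    """Affecting-metabolite counts collapsed to unique species.

    A species counts as affecting in a condition when any of its
    compartmented forms does (the convention behind per-species
    tallies over a compartmented model).
    """
    keys = {}
    for m in model.metabolites:
        keys.setdefault(m.id, m.species_key())
    by_species = table.copy()
    by_species["species"] = [keys.get(m, m) for m in table.index]
    grouped = by_species.groupby("species")[["affects_without", "affects_with"]].any()
    return {
        "affecting_without": int(grouped["affects_without"].sum()),
        "affecting_with": int(grouped["affects_with"].sum()),
    }


# ---------------------------------------------------------------------------
# orchestration


def run_study(model: MetabolicModel, config: StudyConfig,
              outdir: str | None = None,
              reaction_subset: list[str] | None = None) -> dict:
    """Run the whole pipeline and return (and optionally write) a report.

    Stages: extend with gluconate (if not already extended), apply the
    study constraints, FVA closed vs open, range-change classification,
    robustness sweep, shadow comparison, relaxation scan. When
    ``outdir`` is given, writes ``fva_before.tsv``, ``fva_after.tsv``,
    ``changes.tsv``, ``robustness.tsv``, ``shadow.tsv``,
    ``relaxation.tsv`` and ``summary.json``.

    ``reaction_subset`` optionally names a curated reaction list over
    which a second change tally is reported (full-set counts are always
    included).
    """
    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"study stage '{name}' failed: {err}") from err

    if GLUCONOKINASE not in model.reaction_ids:
        model = stage("add_gluconate", add_gluconate, model)
    constrained = stage("constraints", apply_study_constraints, model, config)
    closed = close_gluconate(constrained)
    opened = open_gluconate(constrained, config.gluconate_exchange_bounds)

    sol_closed = stage("fba_closed", fba, closed)
    sol_open = stage("fba_open", fba, opened)
    if not (sol_closed.optimal and sol_open.optimal):
        raise RuntimeError("study stage 'fba' failed: closed/open condition "
                           f"status {sol_closed.status}/{sol_open.status}")

    fva_before = stage("fva_closed", fva, closed, 1.0)
    fva_after = stage("fva_open", fva, opened, 1.0)
    changes = stage("classify", classify_changes, fva_before, fva_after)
    summary_counts = change_summary(changes)
    subset_counts = (change_summary(changes, subset=reaction_subset)
                     if reaction_subset else None)

    curve = stage("robustness", robustness, constrained, config)
    shadows = stage("shadow_comparison", shadow_comparison, closed, opened,
                    config.dual_tol)
    species_counts = unique_species_affect_counts(shadows, opened)
    relax_closed = stage("relaxation_closed", relaxation_scan, closed)
    relax_open = stage("relaxation_open", relaxation_scan, opened)

    gntk = fva_after.loc[GLUCONOKINASE]
    summary = {
        "objective_closed": sol_closed.objective_value,
        "objective_open": sol_open.objective_value,
        "objective_gain": sol_open.objective_value - sol_closed.objective_value,
        "gntk_flux_min": float(gntk["minimum"]),
        "gntk_flux_max": float(gntk["maximum"]),
        "robustness_first_max_uptake": curve.first_max_uptake,
        "robustness_decline_uptake": curve.decline_uptake,
        "change_counts": summary_counts,
        "change_counts_subset": subset_counts,
        "affecting_metabolites": species_counts,
        "relaxation_affecting_closed": int(relax_closed["affects"].sum()),
        "relaxation_affecting_open": int(relax_open["affects"].sum()),
        "relaxation_affecting_open_ids":
            sorted(relax_open.index[relax_open["affects"]]),
    }
    report = {
        "summary": summary,
        "fva_before": fva_before,
        "fva_after": fva_after,
        "changes": changes,
        "robustness": curve,
        "shadow": shadows,
        "relaxation_closed": relax_closed,
        "relaxation_open": relax_open,
    }
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        fva_before.to_csv(os.path.join(outdir, "fva_before.tsv"), sep="\t")
        fva_after.to_csv(os.path.join(outdir, "fva_after.tsv"), sep="\t")
        changes.to_csv(os.path.join(outdir, "changes.tsv"), sep="\t")
        curve.as_frame().to_csv(os.path.join(outdir, "robustness.tsv"),
                                sep="\t", index=False)
        shadows.to_csv(os.path.join(outdir, "shadow.tsv"), sep="\t")
        pd.concat({"closed": relax_closed, "open": relax_open},
                  names=["condition"]).to_csv(
            os.path.join(outdir, "relaxation.tsv"), sep="\t")
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
            fh.write("\n")
    return report
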