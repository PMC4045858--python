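"""Flux balance analysis: the linear-programming core with duals.

Solves max/min c·v subject to S·v = 0 and lb <= v <= ub with the HiGHS
simplex through :func:`scipy.optimize.linprog`, and reports the duals of
the mass-balance rows as shadow prices.

Sign convention: the shadow price of metabolite ``i`` is dZ*/db_i for
the *sensed* objective when the balance is written S·v = b (b = 0),
with b_i > 0 meaning the network is forced to net-produce (accumulate)
metabolite i. Under maximization a *negative* shadow price therefore
marks an objective-limiting metabolite: supplying it from outside
(b_i < 0) would raise the optimum. Duals of
degenerate LPs are not unique; the package reports the solver's basic
solution and treats shadow-price *counts* as solver-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

#: solver feasibility/optimality tolerance
SOLVER_TOL = 1e-9
#: fluxes below this magnitude are reported as zero
FLUX_ZERO_TOL = 1e-6
#: |dual| above this flags a metabolite as affecting the objective
DUAL_TOL = 1e-9

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


class InfeasibleModelError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    """Optimal flux vector with mass-balance duals.

    ``shadow_prices`` maps metabolite id to dZ*/db_i (see module
    docstring); ``reduced_costs`` maps reaction id to the combined dual
    of its box bounds.
    """

    status: str
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    shadow_prices: dict[str, float] = field(default_factory=dict)
    reduced_costs: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _linprog_solve(c_min: np.ndarray, S: np.ndarray, lb: np.ndarray,
                   ub: np.ndarray, A_ub=None, b_ub=None):
    return linprog(
        c_min,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs-ds",
        options={
            "primal_feasibility_tolerance": SOLVER_TOL,
            "dual_feasibility_tolerance": SOLVER_TOL,
        },
    )


def fba(model: MetabolicModel, sense: str = "max") -> FluxSolution:
    """Flux balance analysis of ``model``'s declared objective.

    Parameters
    ----------
    model:
        Model with a non-empty linear objective.
    sense:
        ``"max"`` (default) or ``"min"``.

    Returns a :class:`FluxSolution`; infeasible or unbounded problems
    come back with the corresponding status and no fluxes rather than
    raising.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    c = model.objective_vector()
    if not np.any(c):
        raise ValueError("model objective is empty")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    sign = -1.0 if sense == "max" else 1.0
    res = _linprog_solve(sign * c, S, lb, ub)
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=None)

    v = np.asarray(res.x)
    v[np.abs(v) < FLUX_ZERO_TOL] = 0.0
    # scipy reports marginals of the minimization problem: dZmin/db.
    # Converting to the sensed objective flips the sign under max.
    duals = sign * np.asarray(res.eqlin.marginals)
    rc = sign * (np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals))
    duals[np.abs(duals) < DUAL_TOL] = 0.0
    return FluxSolution(
        status="optimal",
        objective_value=float(c @ res.x),
        fluxes=dict(zip(model.reaction_ids, v.tolist())),
        shadow_prices=dict(zip(model.metabolite_ids, duals.tolist())),
        reduced_costs=dict(zip(model.reaction_ids, rc.tolist())),
    )


def shadow_price_profile(model: MetabolicModel, sense: str = "max",
                         dual_tol: float = DUAL_TOL) -> dict[str, float]:
    """Mass-balance duals at the optimum.

    Metabolites with ``|dual| > dual_tol`` are the ones whose balance
    constrains the objective ("affecting" metabolites). Raises
    :class:`InfeasibleModelError` when the model has no optimum.
    """
    sol = fba(model, sense=sense)
    if not sol.optimal:
        raise InfeasibleModelError(
            f"model {model.id!r} is {sol.status}; no shadow prices")
    return sol.shadow_prices


def affecting_metabolites(shadow_prices: dict[str, float],
                          dual_tol: float = DUAL_TOL) -> list[str]:
    return sorted(m for m, sp in shadow_prices.items() if abs(sp) > dual_tol)


def shadow_price_finite_difference(model: MetabolicModel, metabolite_id: str,
                                   eps: float = 1e-4,
                                   sense: str = "max") -> float:
    """Finite-difference estimate (Z(b_i=eps) - Z(0)) / eps.

    Uses the same sign convention as :func:`fba` shadow prices
    (b_i > 0 forces net accumulation of the metabolite). Independent of
    the solver duals; only meaningful when the optimum is differentiable
    in b_i (non-degenerate duals).
    """
    c = model.objective_vector()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    sign = -1.0 if sense == "max" else 1.0
    i = model.metabolite_ids.index(metabolite_id)

    def solve(b):
        res = linprog(sign * c, A_eq=S, b_eq=b, bounds=list(zip(lb, ub)),
                      method="highs-ds")
        if res.status != 0:
            raise InfeasibleModelError(
                f"perturbed model infeasible at {metabolite_id}")
        return float(c @ res.x)

    b = np.zeros(S.shape[0])
    z0 = solve(b)
    b[i] = eps
    return (solve(b) - z0) / eps
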