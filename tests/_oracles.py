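"""Independent oracles used only by the test suite.

Kept deliberately separate from the package: brute-force enumeration of
basic feasible solutions for tiny LPs, the closed-form (Lambert-W)
Michaelis-Menten progress curve, and a converter to cobrapy models so
an unrelated solver stack can confirm FBA/FVA results.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.special import lambertw


def enumerate_vertices(S: np.ndarray, b: np.ndarray, lb: np.ndarray,
                       ub: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """All basic feasible solutions of {S v = b, lb <= v <= ub}.

    Every bound must be finite. Exhaustive over basic column sets and
    lower/upper assignments of the nonbasic variables, so only suitable
    for networks of ~10 reactions.
    """
    S = np.asarray(S, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = S.shape
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("vertex enumeration needs finite bounds")
    r = np.linalg.matrix_rank(S)
    vertices = []
    for basic in combinations(range(n), r):
        SB = S[:, basic]
        if np.linalg.matrix_rank(SB) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for choice in product((0, 1), repeat=len(nonbasic)):
            v = np.empty(n)
            for j, side in zip(nonbasic, choice):
                v[j] = lb[j] if side == 0 else ub[j]
            rhs = b - S[:, nonbasic] @ v[nonbasic]
            sol, *_ = np.linalg.lstsq(SB, rhs, rcond=None)
            v[list(basic)] = sol
            if (np.max(np.abs(S @ v - b)) < 1e-7
                    and np.all(v >= lb - tol) and np.all(v <= ub + tol)):
                vertices.append(np.clip(v, lb, ub))
    if not vertices:
        return np.empty((0, n))
    return np.unique(np.round(np.array(vertices), 9), axis=0)


def lp_max_by_enumeration(model, extra_ineq=None) -> float:
    """Max of the model objective over enumerated vertices.

    ``extra_ineq = (a, rhs)`` appends a constraint a.v >= rhs via a
    bounded slack variable so that FVA-style pinned problems can be
    enumerated too.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = model.objective_vector()
    verts = feasible_vertices(model, extra_ineq)
    if verts.size == 0:
        raise ValueError("no feasible vertex")
    return float(np.max(verts @ c))


def feasible_vertices(model, extra_ineq=None) -> np.ndarray:
    """Vertices of the model's flux polytope (original variables only)."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    b = np.zeros(S.shape[0])
    if extra_ineq is not None:
        a, rhs = extra_ineq
        # a.v - s = rhs with s in [0, big] turns the inequality into a row
        big = float(np.sum(np.abs(a) * np.maximum(np.abs(lb), np.abs(ub)))) + abs(rhs)
        S = np.vstack([np.hstack([S, np.zeros((S.shape[0], 1))]),
                       np.hstack([a, [-1.0]])])
        b = np.concatenate([b, [rhs]])
        lb = np.concatenate([lb, [0.0]])
        ub = np.concatenate([ub, [big]])
        verts = enumerate_vertices(S, b, lb, ub)
        return verts[:, :-1] if verts.size else verts
    return enumerate_vertices(S, b, lb, ub)


# ---------------------------------------------------------------------------
# closed-form Michaelis-Menten substrate depletion


def mm_substrate_closed_form(s0: float, km: float, vmax: float,
                             t: np.ndarray) -> np.ndarray:
    """S(t) for dS/dt = -vmax S/(km+S), via the Lambert W function."""
    arg = (s0 / km) * np.exp((s0 - vmax * np.asarray(t, dtype=float)) / km)
    return km * np.real(lambertw(arg))


# ---------------------------------------------------------------------------
# cobrapy bridge


def to_cobra(model):
    """Convert a gluconet model to a cobrapy model (for cross-checks)."""
    import cobra

    cm = cobra.Model(model.id or "model")
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, name=m.name,
                                compartment=m.compartment or "c")
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name or r.id,
                            lower_bound=r.lower_bound,
                            upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coef for mid, coef in r.stoichiometry.items()})
    cm.objective = {cm.reactions.get_by_id(rid): coef
                    for rid, coef in model.objective.items()}
    return cm
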