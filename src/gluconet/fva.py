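"""Flux variability analysis and flux-range-change classification.

FVA computes, for every reaction, the minimum and maximum flux it can
carry while the network stays at steady state within its bounds,
optionally with the objective pinned at (a fraction of) its optimum.
The *flux range* of a reaction is |v_max - v_min|.

Comparing two conditions, a reaction is

* ``activated``   -- carried no flux before, carries flux after;
* ``deactivated`` -- the converse;
* ``changed``     -- its flux range moved by at least ``threshold``
  (default 40 %) of the range in the *before* condition;
* ``unchanged``   -- otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import MetabolicModel
from .lp import (FLUX_ZERO_TOL, InfeasibleModelError, _linprog_solve)

#: ranges below this are treated as "carries no flux"
ZERO_TOL = 1e-6
#: inclusive relative-change threshold for the "changed" class
CHANGE_THRESHOLD = 0.4


def fva(model: MetabolicModel,
        fix_objective_fraction: float = 1.0) -> pd.DataFrame:
    """Per-reaction flux extrema (2n LP solves).

    Parameters
    ----------
    model:
        A feasible model; its objective is only consulted when
        ``fix_objective_fraction`` > 0.
    fix_objective_fraction:
        Pin c.v >= fraction * Z_opt during the per-reaction solves.
        The default 1.0 explores only the optimal face, the convention
        under which a secondary substrate the optimum depends on is
        forced to carry flux.

    Returns a DataFrame indexed by reaction id with columns
    ``minimum``, ``maximum`` and ``flux_range`` (mmol/gDW/h), plus a
    boolean ``solved`` flag (reactions whose sub-problem failed keep
    NaN extrema rather than being dropped silently).
    """
    if not 0.0 <= fix_objective_fraction <= 1.0:
        raise ValueError("fix_objective_fraction must lie in [0, 1]")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)

    A_ub = b_ub = None
    if fix_objective_fraction > 0:
        c = model.objective_vector()
        if not np.any(c):
            raise ValueError("objective is empty but a fraction was requested")
        res = _linprog_solve(-c, S, lb, ub)
        if res.status != 0:
            raise InfeasibleModelError(
                f"base model is not optimal (status {res.status}); FVA aborted")
        z_opt = float(c @ res.x)
        # c.v >= fraction * z_opt  (z_opt may be negative; the inequality
        # is kept one-sided as written, matching optPercentage semantics
        # for the usual positive-optimum case)
        A_ub = -c.reshape(1, -1)
        b_ub = np.array([-fix_objective_fraction * z_opt])

    minima = np.full(n, np.nan)
    maxima = np.full(n, np.nan)
    solved = np.zeros(n, dtype=bool)
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        lo = _linprog_solve(e, S, lb, ub, A_ub=A_ub, b_ub=b_ub)
        hi = _linprog_solve(-e, S, lb, ub, A_ub=A_ub, b_ub=b_ub)
        if lo.status == 0 and hi.status == 0:
            vmin, vmax = float(lo.x[j]), float(hi.x[j])
            if abs(vmin) < FLUX_ZERO_TOL:
                vmin = 0.0
            if abs(vmax) < FLUX_ZERO_TOL:
                vmax = 0.0
            # numerical jitter can invert near-degenerate extrema
            if vmin > vmax:
                vmin = vmax = 0.5 * (vmin + vmax)
            minima[j], maxima[j] = vmin, vmax
            solved[j] = True
    return pd.DataFrame(
        {
            "minimum": minima,
            "maximum": maxima,
            "flux_range": np.abs(maxima - minima),
            "solved": solved,
        },
        index=pd.Index(model.reaction_ids, name="reaction_id"),
    )


def classify_changes(before: pd.DataFrame, after: pd.DataFrame,
                     threshold: float = CHANGE_THRESHOLD,
                     zero_tol: float = ZERO_TOL) -> pd.DataFrame:
    """Classify per-reaction flux-range changes between two conditions.

    ``before`` and ``after`` are :func:`fva` outputs over the same
    reaction set. The comparison is inclusive: a relative change equal
    to ``threshold`` counts as changed.

    Returns a DataFrame with columns ``range_before``, ``range_after``,
    ``relative_change`` (NaN where the before-range is zero) and
    ``change_class``.
    """
    missing = before.index.symmetric_difference(after.index)
    if len(missing):
        raise ValueError(
            "before/after FVA cover different reactions: "
            + ", ".join(map(str, missing[:10])))
    after = after.loc[before.index]
    rb = before["flux_range"].to_numpy(dtype=float)
    ra = after["flux_range"].to_numpy(dtype=float)

    blocked_before = rb < zero_tol
    blocked_after = ra < zero_tol
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(blocked_before, np.nan, np.abs(ra - rb) / rb)

    cls = np.full(rb.shape, "unchanged", dtype=object)
    cls[blocked_before & ~blocked_after] = "activated"
    cls[~blocked_before & blocked_after] = "deactivated"
    # inclusive comparison; the epsilon keeps "exactly 40%" cases from
    # falling on the wrong side through float roundoff
    changed = ~blocked_before & ~blocked_after & \
        (rel >= threshold * (1.0 - 1e-9))
    cls[changed] = "changed"
    return pd.DataFrame(
        {
            "range_before": rb,
            "range_after": ra,
            "relative_change": rel,
            "change_class": cls,
        },
        index=before.index,
    )


def change_summary(changes: pd.DataFrame,
                   subset: list[str] | None = None) -> dict[str, int]:
    """Counts per class (optionally over a user-supplied reaction subset).

    Includes ``total`` and the headline ``changed_or_activated`` tally.
    """
    if subset is not None:
        missing = [r for r in subset if r not in changes.index]
        if missing:
            raise KeyError(f"subset reactions absent from results: {missing[:10]}")
        changes = changes.loc[subset]
    counts = changes["change_class"].value_counts().to_dict()
    summary = {cls: int(counts.get(cls, 0))
               for cls in ("unchanged", "changed", "activated", "deactivated")}
    summary["total"] = int(len(changes))
    summary["changed_or_activated"] = summary["changed"] + summary["activated"]
    return summary
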