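"""Substrate-specificity plate analysis: z-scores and hit calling.

Each well pairs a candidate substrate with ATP and the kinase; after
incubation the remaining ATP is read out as luminescence, with a
matched no-enzyme control well per compound. Phosphorylation activity
depletes ATP, so true substrates show *lower* luminescence than their
controls: the background-corrected signal ``delta = sample - control``
is strongly negative for hits, and z-scores are computed over the
deltas of all compounds on the plate. The one-tailed lower-tail normal
p-value quantifies how surprising each depletion is under the
no-activity null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm


def score_plate(plate: pd.DataFrame, sd_ddof: int = 1,
                robust: bool = False) -> pd.DataFrame:
    """Score a plate of luminescence readings against matched controls.

    Parameters
    ----------
    plate:
        DataFrame with columns ``compound``, ``luminescence`` (RLU) and
        ``control_luminescence`` (no-enzyme RLU); an optional
        ``taxonomy_class`` column is carried through.
    sd_ddof:
        1 (default) for the sample standard deviation, 0 for the
        population convention.
    robust:
        Use median/MAD location and scale instead of mean/SD (off by
        default; the plate mean over *all* compounds, hits included, is
        the standard convention).

    Returns the plate with ``delta``, ``z_score`` and ``p_value``
    columns added. Requires >= 3 compounds and non-zero spread.
    """
    required = {"compound", "luminescence", "control_luminescence"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table lacks columns {sorted(missing)}")
    if len(plate) < 3:
        raise ValueError("need at least 3 compounds to score a plate")
    if plate["control_luminescence"].isna().any():
        bad = plate.loc[plate["control_luminescence"].isna(), "compound"]
        raise ValueError(f"missing control wells for: {', '.join(map(str, bad))}")

    scored = plate.copy()
    delta = (scored["luminescence"] - scored["control_luminescence"]).astype(float)
    if robust:
        center = float(delta.median())
        scale = 1.4826 * float((delta - center).abs().median())
    else:
        center = float(delta.mean())
        scale = float(delta.std(ddof=sd_ddof))
    if scale == 0 or not np.isfinite(scale):
        raise ValueError("zero spread across compounds; z-scores undefined")
    scored["delta"] = delta
    scored["z_score"] = (delta - center) / scale
    scored["p_value"] = norm.cdf(scored["z_score"])
    return scored


def call_hits(screen: pd.DataFrame, z_cut: float = -3.0) -> list[str]:
    """Compounds with z <= z_cut (ATP-depleting), sorted by z ascending."""
    if "z_score" not in screen.columns:
        raise ValueError("screen is not scored; run score_plate first")
    hits = screen.loc[screen["z_score"] <= z_cut]
    return hits.sort_values("z_score")["compound"].tolist()
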