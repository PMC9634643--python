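"""Supply–demand deviation between accessibility level and observed visitation.

For each residential cell i the deviation index compares the cell's
share of total accessibility level (the supply side) with its share of
observed green-space visitors (the demand side):

    Z_i = (level_i / Σ_all levels) / (P_i / P)

where P_i is the number of distinct residents of cell i who visited a
green space in the analysis window and P = Σ P_i.  The denominator of
the supply share sums the levels of *all* cells; cells without any
visitor (P_i = 0) are excluded from the surface (a blank area), not
assigned Z = 0.

Bands: Z < 0.8 → low supply–high demand; 0.8 ≤ Z ≤ 1.2 → balanced;
Z > 1.2 → high supply–low demand.  The band edges are closed into the
balanced class on both sides.

The supply level is the 1–5 accessibility grade by default, with raw
comprehensive accessibility C_i supported as an alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["deviation_index", "classify_deviation", "CATEGORIES"]

LOW_SUPPLY = "low-supply-high-demand"
BALANCED = "balanced"
HIGH_SUPPLY = "high-supply-low-demand"
EXCLUDED = "excluded"
CATEGORIES = (LOW_SUPPLY, BALANCED, HIGH_SUPPLY, EXCLUDED)


def deviation_index(levels: pd.Series, visitors: pd.Series) -> pd.Series:
    """Per-cell deviation Z_i; NaN marks excluded (visitor-free) cells.

    ``levels`` and ``visitors`` are aligned on cell id; cells present in
    ``levels`` but absent from ``visitors`` count zero visitors and are
    excluded, while their level still enters the supply denominator.
    """
    levels = pd.Series(levels, dtype=float)
    total_level = levels.sum()
    if total_level <= 0:
        raise ValueError("total accessibility level must be positive")
    vis = pd.Series(visitors, dtype=float).reindex(levels.index, fill_value=0.0)
    total_vis = vis.sum()
    if total_vis <= 0:
        raise ValueError("no visitors anywhere: deviation undefined")
    level_share = levels / total_level
    vis_share = vis / total_vis
    z = level_share / vis_share.where(vis_share > 0)
    z.name = "Z"
    return z


def classify_deviation(z: pd.Series, low: float = 0.8, high: float = 1.2) -> pd.Series:
    """Three-band classification of the deviation index.

    NaN (excluded) entries map to the ``excluded`` category.
    """
    z = pd.Series(z, dtype=float)
    cat = pd.Series(EXCLUDED, index=z.index, dtype=object, name="category")
    cat[z < low] = LOW_SUPPLY
    cat[(z >= low) & (z <= high)] = BALANCED
    cat[z > high] = HIGH_SUPPLY
    return cat
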