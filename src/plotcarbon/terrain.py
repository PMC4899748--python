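"""Quadrat altitude and terrain convexity from the corner-elevation lattice."""

from __future__ import annotations

import numpy as np
import pandas as pd

from plotcarbon.core_data import ElevationGrid

#: labels for which convexity rule applied to each quadrat
RULE_INTERIOR = "interior"       # focal altitude - mean of 8 neighbours
RULE_CENTER = "center"           # center-point altitude - mean of 4 corners
RULE_FALLBACK = "fallback"       # focal altitude - mean of existing neighbours


def quadrat_altitude(elev: ElevationGrid) -> np.ndarray:
    """Per-quadrat altitude = mean of the quadrat's four corner altitudes.

    Returns a (n_qy, n_qx) array indexed [row, col].
    """
    c = elev.corners
    return 0.25 * (c[:-1, :-1] + c[:-1, 1:] + c[1:, :-1] + c[1:, 1:])


def convexity(elev: ElevationGrid) -> pd.DataFrame:
    """Terrain convexity per quadrat.

    Interior quadrats: focal altitude minus the mean altitude of the eight
    surrounding quadrats. Edge and corner quadrats: center-point altitude
    minus the quadrat's own (mean-of-four-corners) altitude, using the
    supplied center altitudes. If no centers are available the fallback is
    focal altitude minus the mean over the existing 3-5 neighbours, and the
    quadrat is flagged ``fallback``.

    Returns a DataFrame indexed by linear quadrat id with columns
    ``altitude``, ``convexity``, ``edge_rule_used``.
    """
    alt = quadrat_altitude(elev)
    n_qy, n_qx = alt.shape
    conv = np.empty_like(alt)
    rule = np.empty(alt.shape, dtype=object)

    # neighbour sums via a padded cumulative trick: sum over 3x3 window
    padded = np.pad(alt, 1, constant_values=np.nan)
    stacks = [
        padded[dr : dr + n_qy, dc : dc + n_qx]
        for dr in range(3)
        for dc in range(3)
        if not (dr == 1 and dc == 1)
    ]
    neigh = np.stack(stacks)
    neigh_mean = np.nanmean(neigh, axis=0)
    n_neigh = np.sum(~np.isnan(neigh), axis=0)

    interior = n_neigh == 8
    conv[interior] = alt[interior] - neigh_mean[interior]
    rule[interior] = RULE_INTERIOR

    edge = ~interior
    if elev.centers is not None:
        conv[edge] = elev.centers[edge] - alt[edge]
        rule[edge] = RULE_CENTER
    else:
        conv[edge] = alt[edge] - neigh_mean[edge]
        rule[edge] = RULE_FALLBACK

    qid = np.arange(alt.size)
    return pd.DataFrame(
        {
            "altitude": alt.ravel(),
            "convexity": conv.ravel(),
            "edge_rule_used": rule.ravel(),
        },
        index=pd.Index(qid, name="quadrat_id"),
    )
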