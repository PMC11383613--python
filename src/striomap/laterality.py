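"""Hemisphere-wise network proportions and a laterality index.

For each network and hemisphere, the proportion is the raw count of
locations assigned to the network divided by the total number of
locations in that hemisphere (UNASSIGNED locations count toward the
total but toward no network).  The caudate analysis is restricted to the
undilated caudate mask so only voxels with clear striatal signal enter.

The laterality index (pL - pR) / (pL + pR) summarizes each network's
asymmetry: +1 fully left-lateralized, -1 fully right, 0 symmetric (and 0
by convention when the network is absent from both hemispheres).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import HEMI_NAMES, LEFT, NETWORK_NAMES, RIGHT

__all__ = ["LateralityTable", "count_by_hemisphere", "laterality_index"]


@dataclass
class LateralityTable:
    """Tidy per-(network, hemisphere) counts and proportions."""

    table: pd.DataFrame  # columns: network, network_name, hemisphere, raw_count, total, proportion
    domain: str  # "cortex" | "caudate"

    def proportion(self, network: int, hemisphere: int) -> float:
        sel = (self.table["network"] == network) & (self.table["hemisphere"] == hemisphere)
        return float(self.table.loc[sel, "proportion"].iloc[0])


def count_by_hemisphere(
    assignments: np.ndarray,
    hemispheres: np.ndarray,
    domain: str,
    include: np.ndarray | None = None,
) -> LateralityTable:
    """Exact per-network, per-hemisphere counts over ``include`` locations.

    ``assignments`` holds network ids (0 = unassigned/unlabeled),
    ``hemispheres`` LEFT/RIGHT per location.  ``include`` restricts the
    tally (e.g. to the undilated caudate mask, or to non-medial-wall
    vertices); excluded locations contribute to neither counts nor totals.
    """
    assignments = np.asarray(assignments)
    hemispheres = np.asarray(hemispheres)
    if assignments.shape != hemispheres.shape:
        raise ValueError("assignments and hemispheres must align")
    if include is None:
        include = np.ones(assignments.shape, dtype=bool)
    rows = []
    for h in (LEFT, RIGHT):
        sel = include & (hemispheres == h)
        total = int(sel.sum())
        if total == 0:
            raise ValueError(f"no locations in hemisphere {HEMI_NAMES[h]}")
        counts = np.bincount(assignments[sel], minlength=16)
        for net, name in NETWORK_NAMES.items():
            rows.append(
                {
                    "network": net,
                    "network_name": name,
                    "hemisphere": h,
                    "hemisphere_name": HEMI_NAMES[h],
                    "raw_count": int(counts[net]),
                    "total": total,
                    "proportion": counts[net] / total,
                }
            )
    return LateralityTable(table=pd.DataFrame(rows), domain=domain)


def laterality_index(table: LateralityTable, network: int) -> float:
    """(pL - pR) / (pL + pR); 0 when the network is absent on both sides."""
    if network not in set(table.table["network"]):
        raise ValueError(f"network {network} not present in table")
    p_l = table.proportion(network, LEFT)
    p_r = table.proportion(network, RIGHT)
    if p_l + p_r == 0:
        return 0.0
    return (p_l - p_r) / (p_l + p_r)
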