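"""Winner-takes-all parcellation of the striatum by cortical network.

For every striatal voxel, the k = 400 cortical vertices most correlated
with it (run-averaged Fisher z, both hemispheres pooled) are collected and
the voxel is assigned to the network holding the largest share of those
vertices.  A thresholded variant additionally discards, within the top
400, vertices whose correlation falls below a fixed value; a voxel whose
top 400 are all sub-threshold receives no assignment.  Sweeping that
threshold over unsmoothed and smoothed data is the control for cortical
signal bleeding into the striatum.

Vertices without a network label (medial wall) are excluded from the count
but not replaced by deeper-ranked vertices, preserving "top k" semantics
without inventing an extra category.  Ties between networks are broken by
the larger summed z among the tied networks' contributing vertices, then
by the lower network id; every tie is flagged in the provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .connectivity import ConnMatrix
from .geometry import UNASSIGNED, NetworkLabelMap, VolumeModel

__all__ = [
    "VoteResult",
    "Parcellation",
    "dilate_mask",
    "top_k_vertices",
    "vote_assign",
    "parcellate",
    "blur_sweep",
    "DEFAULT_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: blur-control sweep: r = 0.01 and 0.05 ... 0.40 in steps of 0.05
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)

DEFAULT_K = 400


@dataclass
class VoteResult:
    """Provenance of one voxel's winner-takes-all vote."""

    voxel_index: int
    counts: np.ndarray  # (16,) contributing-vertex count per network id (0 unused)
    n_contributing: int
    winner: int  # network id or UNASSIGNED (0)
    tie_flag: bool = False
    threshold_used: float | None = None


@dataclass
class Parcellation:
    """Per-voxel network assignment with full vote provenance."""

    winners: np.ndarray  # (n_voxels,) int16, UNASSIGNED = 0
    votes: list[VoteResult]
    params: dict = field(default_factory=dict)

    @property
    def n_unassigned(self) -> int:
        return int((self.winners == UNASSIGNED).sum())

    def winner_volume(self, volume: VolumeModel) -> np.ndarray:
        """Scatter winners back into the 3-D grid (0 outside the mask)."""
        out = np.zeros(volume.shape, dtype=np.int16)
        idx = volume.voxel_indices
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = self.winners
        return out


def dilate_mask(mask: np.ndarray, level: int) -> np.ndarray:
    """``level`` repeated binary dilations with a 3x3x3 box element.

    Level 1 outlines the striatal boundary, level 3 defines the analysis
    mask for parcellation, level 5 reaches the adjacent cortical ribbon.
    """
    if level < 0:
        raise ValueError("dilation level must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if level == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), dtype=bool), iterations=level)


def top_k_vertices(
    z_row: np.ndarray, k: int = DEFAULT_K, excluded: np.ndarray | None = None
) -> np.ndarray:
    """Indices of the k largest-z vertices, descending; ties -> lower index.

    ``excluded`` marks vertices (e.g. zero-variance flagged) removed before
    ranking.  If everything is excluded an empty list is returned with a
    warning.
    """
    z_row = np.asarray(z_row, dtype=np.float64)
    if k > len(z_row):
        raise ValueError(f"k={k} exceeds vertex count {len(z_row)}")
    valid = np.ones(len(z_row), dtype=bool) if excluded is None else ~np.asarray(excluded, bool)
    idx = np.flatnonzero(valid)
    if len(idx) == 0:
        logger.warning("top_k_vertices: all vertices flagged; returning empty ranking")
        return np.empty(0, dtype=np.int64)
    k_eff = min(k, len(idx))
    vals = z_row[idx]
    # stable sort on (-z, index): lowest index wins ties
    order = np.lexsort((idx, -vals))[:k_eff]
    return idx[order]


def vote_assign(
    z_row: np.ndarray,
    labels: NetworkLabelMap,
    k: int = DEFAULT_K,
    threshold: float | None = None,
    excluded: np.ndarray | None = None,
    voxel_index: int = 0,
) -> VoteResult:
    """Winner-takes-all vote for a single voxel.

    Takes the top-k vertices (hemispheres pooled), drops unlabeled vertices
    from the count, drops sub-threshold vertices if a threshold is set, and
    assigns the network with the highest count.  With zero contributing
    vertices the voxel is UNASSIGNED.
    """
    if labels.n_vertices != len(z_row):
        raise ValueError("label map does not match vertex count")
    if labels.n_vertices == 0:
        raise ValueError("empty label map")
    top = top_k_vertices(z_row, k=k, excluded=excluded)
    lab = labels.labels[top]
    zz = np.asarray(z_row, dtype=np.float64)[top]
    keep = lab > 0
    if threshold is not None:
        keep &= zz >= threshold
    lab, zz = lab[keep], zz[keep]
    counts = np.bincount(lab, minlength=16).astype(np.int64)
    counts[0] = 0
    n_contributing = int(counts.sum())
    if n_contributing == 0:
        return VoteResult(voxel_index, counts, 0, UNASSIGNED, False, threshold)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    tie = len(tied) > 1
    if tie:
        sums = np.bincount(lab, weights=zz, minlength=16)
        winner = int(tied[np.lexsort((tied, -sums[tied]))[0]])
        logger.debug("voxel %d: tie between networks %s -> %d", voxel_index, tied, winner)
    else:
        winner = int(tied[0])
    return VoteResult(voxel_index, counts, n_contributing, winner, tie, threshold)


def parcellate(
    conn: ConnMatrix,
    labels: NetworkLabelMap,
    k: int = DEFAULT_K,
    threshold: float | None = None,
    keep_votes: bool = True,
) -> Parcellation:
    """Apply :func:`vote_assign` independently to every voxel of ``conn``."""
    if labels.n_vertices != conn.z.shape[1]:
        raise ValueError(
            f"label map has {labels.n_vertices} vertices, matrix {conn.z.shape[1]}"
        )
    excluded = conn.flagged_vertices
    winners = np.zeros(conn.z.shape[0], dtype=np.int16)
    votes: list[VoteResult] = []
    n_ties = 0
    for v in range(conn.z.shape[0]):
        res = vote_assign(
            conn.z[v], labels, k=k, threshold=threshold, excluded=excluded, voxel_index=v
        )
        winners[v] = res.winner
        n_ties += res.tie_flag
        if keep_votes:
            votes.append(res)
    params = {
        "k": k,
        "threshold": threshold,
        "n_runs": conn.n_runs,
        "taxonomy": dict(labels.names),
        "n_ties": n_ties,
    }
    if n_ties:
        logger.info("parcellate: %d tied votes (broken by summed z, then id)", n_ties)
    return Parcellation(winners=winners, votes=votes, params=params)


def blur_sweep(
    conn: ConnMatrix | Mapping[str, ConnMatrix],
    labels: NetworkLabelMap,
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
    k: int = DEFAULT_K,
) -> dict[tuple[str, float], Parcellation]:
    """Threshold sweep per smoothing condition.

    ``conn`` is either a single matrix or a mapping of condition name
    (e.g. ``"raw"``, ``"smoothed"``) to matrix.  Thresholds must ascend;
    the UNASSIGNED count is checked to be non-decreasing along the sweep
    (monotone exclusion).
    """
    thresholds = [float(t) for t in thresholds]
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    if isinstance(conn, ConnMatrix):
        conn = {"raw": conn}
    out: dict[tuple[str, float], Parcellation] = {}
    for name, matrix in conn.items():
        prev = -1
        for thr in thresholds:
            p = parcellate(matrix, labels, k=k, threshold=thr, keep_votes=False)
            if p.n_unassigned < prev:  # pragma: no cover - structurally impossible
                raise AssertionError("UNASSIGNED count decreased along the threshold sweep")
            prev = p.n_unassigned
            out[(name, thr)] = p
    return out


def assignment_accuracy(
    parcellation: Parcellation, truth_coupling: np.ndarray, subset: np.ndarray | None = None
) -> float:
    """Fraction of (optionally subset) coupled voxels assigned their true network."""
    winners = parcellation.winners
    truth = np.asarray(truth_coupling)
    sel = np.arange(len(winners)) if subset is None else np.asarray(subset)
    sel = sel[truth[sel] > 0]
    if len(sel) == 0:
        raise ValueError("no coupled voxels in subset")
    return float(np.mean(winners[sel] == truth[sel]))


def contiguous_zone_count(
    parcellation: Parcellation, volume: VolumeModel, network: int, subset_mask: np.ndarray | None = None
) -> int:
    """Connected components (6-connectivity) of a network's assigned voxels."""
    vol = parcellation.winner_volume(volume) == network
    if subset_mask is not None:
        vol &= subset_mask
    structure = ndimage.generate_binary_structure(3, 1)
    _, n = ndimage.label(vol, structure=structure)
    return int(n)
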