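"""Striatum-to-cortex correlation matrices and connectivity profiles.

Per run, the Pearson correlation between every striatal voxel (3x dilated
mask) and every cortical vertex is computed, Fisher r-to-z transformed,
and averaged across runs into a single voxel x vertex estimate — the
object every downstream stage (parcellation, blur control) consumes.

The same machinery builds the cortical connectivity profiles used as
clustering input elsewhere: per-vertex correlation to a set of uniformly
distributed surface ROIs, binarized by keeping the top 10% per vertex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .geometry import SurfaceModel

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import RunData

__all__ = [
    "ConnMatrix",
    "ConnectivityProfile",
    "run_correlation",
    "fisher_z",
    "average_runs",
    "build_conn_matrix",
    "sample_uniform_rois",
    "build_connectivity_profiles",
]

logger = logging.getLogger(__name__)

R_CLAMP = 1.0 - 1e-7


@dataclass
class ConnMatrix:
    """Run-averaged Fisher-z voxel x vertex matrix.

    ``flagged_voxels`` / ``flagged_vertices`` mark locations with a
    zero-variance series in any contributing run; their entries are 0 and
    must be excluded from ranking.
    """

    z: np.ndarray  # (n_voxels, n_vertices)
    n_runs: int
    flagged_voxels: np.ndarray = field(default=None)
    flagged_vertices: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("ConnMatrix entries must be finite (clamp r before arctanh)")
        if self.flagged_voxels is None:
            self.flagged_voxels = np.zeros(self.z.shape[0], dtype=bool)
        if self.flagged_vertices is None:
            self.flagged_vertices = np.zeros(self.z.shape[1], dtype=bool)


@dataclass
class ConnectivityProfile:
    """Binary vertices x ROI profile matrix (top ``keep_fraction`` per row)."""

    profiles: np.ndarray  # (n_vertices, n_rois) uint8
    roi_centers: np.ndarray
    keep_fraction: float


def _standardize(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean and unit-norm rows; returns (standardized, zero-variance flags)."""
    ts = np.asarray(ts, dtype=np.float64)
    centered = ts - ts.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    flagged = norm == 0
    centered /= np.where(flagged, 1.0, norm)[:, None]
    centered[flagged] = 0.0
    return centered, flagged


def run_correlation(
    striatum_ts: np.ndarray, cortex_ts: np.ndarray, block_voxels: int = 512
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise Pearson r between every voxel and vertex series.

    Returns (r, flagged_voxels, flagged_vertices).  Zero-variance pairs get
    r = 0 and are flagged.  The computation runs in voxel blocks to bound
    peak memory; the result is identical to the whole-matrix product.
    """
    if striatum_ts.shape[1] != cortex_ts.shape[1]:
        raise ValueError(
            f"time mismatch: striatum T={striatum_ts.shape[1]}, cortex T={cortex_ts.shape[1]}"
        )
    if striatum_ts.shape[1] < 3:
        raise ValueError("need at least 3 frames for a correlation")
    a, flagged_vox = _standardize(striatum_ts)
    b, flagged_vert = _standardize(cortex_ts)
    r = np.empty((a.shape[0], b.shape[0]))
    for start in range(0, a.shape[0], block_voxels):
        stop = min(start + block_voxels, a.shape[0])
        r[start:stop] = a[start:stop] @ b.T
    np.clip(r, -1.0, 1.0, out=r)
    if flagged_vox.any() or flagged_vert.any():
        logger.warning(
            "run_correlation: %d voxel / %d vertex zero-variance series flagged",
            int(flagged_vox.sum()),
            int(flagged_vert.sum()),
        )
    return r, flagged_vox, flagged_vert


def fisher_z(r: np.ndarray) -> np.ndarray:
    """arctanh with |r| clamped to 1 - 1e-7 so the output stays finite."""
    r = np.clip(np.asarray(r, dtype=np.float64), -R_CLAMP, R_CLAMP)
    return np.arctanh(r)


def average_runs(z_matrices: Sequence[np.ndarray]) -> ConnMatrix:
    """Element-wise arithmetic mean of per-run z matrices."""
    if len(z_matrices) == 0:
        raise ValueError("need at least one run")
    shape = z_matrices[0].shape
    for m in z_matrices:
        if m.shape != shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {shape}")
    return ConnMatrix(z=np.mean(z_matrices, axis=0), n_runs=len(z_matrices))


def build_conn_matrix(runs: Sequence["RunData"], block_voxels: int = 512) -> ConnMatrix:
    """Per-run correlation -> Fisher z -> streaming mean across runs."""
    if len(runs) == 0:
        raise ValueError("need at least one run")
    acc = None
    flagged_vox = flagged_vert = None
    for run in runs:
        r, fvox, fvert = run_correlation(run.striatum_ts, run.cortex_ts, block_voxels)
        z = fisher_z(r)
        acc = z if acc is None else acc + z
        flagged_vox = fvox if flagged_vox is None else (flagged_vox | fvox)
        flagged_vert = fvert if flagged_vert is None else (flagged_vert | fvert)
    return ConnMatrix(
        z=acc / len(runs),
        n_runs=len(runs),
        flagged_voxels=flagged_vox,
        flagged_vertices=flagged_vert,
    )


def sample_uniform_rois(surface: SurfaceModel, n_rois_per_hemi: int) -> np.ndarray:
    """Deterministic farthest-point sampling of ROI center vertices.

    Per hemisphere, starts from the lowest vertex index and greedily adds
    the vertex maximizing the minimum geodesic distance to the chosen set
    (ties -> lowest index), yielding quasi-uniform coverage of the mesh.
    """
    if n_rois_per_hemi <= 0:
        raise ValueError("n_rois_per_hemi must be positive")
    centers = []
    for h in np.unique(surface.hemi):
        members = np.flatnonzero(surface.hemi == h)
        if n_rois_per_hemi > len(members):
            raise ValueError("more ROIs than vertices in a hemisphere")
        if n_rois_per_hemi == len(members):
            centers.append(members)
            continue
        chosen = [int(members[0])]
        mindist = surface.geodesic_from([chosen[0]])[members]
        while len(chosen) < n_rois_per_hemi:
            nxt = int(members[np.argmax(mindist)])  # argmax -> first (lowest) index on ties
            chosen.append(nxt)
            d = surface.geodesic_from([nxt])[members]
            mindist = np.minimum(mindist, d)
        centers.append(np.sort(chosen))
    return np.concatenate(centers)


def _roi_series(
    cortex_ts: np.ndarray, surface: SurfaceModel, roi_centers: np.ndarray
) -> np.ndarray:
    """ROI series = mean over the 1-ring patch around each center vertex."""
    hops = dijkstra(surface.adjacency, directed=False, indices=roi_centers, limit=1.0)
    out = np.empty((len(roi_centers), cortex_ts.shape[1]))
    for i in range(len(roi_centers)):
        patch = np.flatnonzero(np.isfinite(hops[i]))
        out[i] = cortex_ts[patch].mean(axis=0)
    return out


def binarize_top_fraction(values: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Keep the top fraction per row; full ties resolve to lowest indices."""
    n_keep = int(round(keep_fraction * values.shape[1]))
    out = np.zeros(values.shape, dtype=np.uint8)
    if n_keep == 0:
        return out
    cols = np.arange(values.shape[1])
    n_tie_rows = 0
    for i, row in enumerate(values):
        order = np.lexsort((cols, -row))[:n_keep]
        out[i, order] = 1
        kept_min = row[order].min()
        if (row == kept_min).sum() > (row[order] == kept_min).sum():
            n_tie_rows += 1
    if n_tie_rows:
        logger.warning(
            "binarize_top_fraction: %d rows had ties at the cutoff; lowest-index retention",
            n_tie_rows,
        )
    return out


def build_connectivity_profiles(
    runs: Sequence["RunData"],
    surface: SurfaceModel,
    roi_centers: np.ndarray,
    keep_fraction: float = 0.10,
) -> ConnectivityProfile:
    """Per-vertex correlation to each ROI patch series, run-averaged in z,
    then binarized by keeping the top ``keep_fraction`` per vertex row."""
    if len(runs) == 0:
        raise ValueError("need at least one run")
    acc = None
    flagged = None
    for run in runs:
        roi_ts = _roi_series(run.cortex_ts, surface, roi_centers)
        r, fvert, _ = run_correlation(run.cortex_ts, roi_ts)
        z = fisher_z(r)
        acc = z if acc is None else acc + z
        flagged = fvert if flagged is None else flagged | fvert
    z_mean = acc / len(runs)
    if flagged.any():
        logger.warning("connectivity profiles: %d degenerate vertex rows", int(flagged.sum()))
        z_mean[flagged] = -np.inf  # degenerate rows keep nothing meaningful
        z_mean[flagged, 0] = 0.0
    profiles = binarize_top_fraction(z_mean, keep_fraction)
    return ConnectivityProfile(
        profiles=profiles, roi_centers=np.asarray(roi_centers), keep_fraction=keep_fraction
    )
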