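"""Per-run preprocessing: nuisance regression, band-pass filtering, spatial
smoothing, and temporal signal-to-noise (tSNR) mapping.

The pipeline order is fixed: regress nuisance -> band-pass 0.01-0.10 Hz ->
spatial smoothing (2-mm FWHM on the surface graph, 4-mm FWHM mask-aware in
the volume).  tSNR is always computed from data *before* whole-brain
regression; the resulting map carries a stage flag so downstream code can
assert it was not computed from residuals.

Surface smoothing operates on the mesh graph, not in 3-D Euclidean space,
so signal never mixes across the inter-hemispheric gap (the property that
motivates surface-based processing in the first place).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import SurfaceModel, VolumeModel
    from .phantom import RunData

__all__ = [
    "TsnrMap",
    "compute_tsnr",
    "regress_nuisance",
    "bandpass",
    "bandpass_array",
    "smooth_volume",
    "smooth_surface",
    "volume_smoother",
    "surface_smoothing_iterations",
    "preprocess_run",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class TsnrMap:
    """Per-location tSNR = mean(series) / SD(series), averaged across runs.

    ``flagged`` marks zero-variance locations where the ratio is undefined
    (values there are 0 but must not be interpreted).  ``pre_regression``
    asserts the map was computed before whole-brain/nuisance regression.
    """

    values: np.ndarray
    flagged: np.ndarray
    n_runs_averaged: int
    pre_regression: bool = True


def compute_tsnr(runs: Sequence["RunData"], which: str = "striatum") -> TsnrMap:
    """Mean/SD per location per run (unbiased SD, n-1), then mean over runs.

    ``which`` selects the sampling domain: ``"striatum"`` (voxels) or
    ``"cortex"`` (vertices).
    """
    if len(runs) == 0:
        raise ValueError("compute_tsnr needs at least one run")
    attr = {"striatum": "striatum_ts", "cortex": "cortex_ts"}[which]
    per_run = []
    flagged = None
    for run in runs:
        ts = getattr(run, attr)
        mu = ts.mean(axis=1)
        sd = ts.std(axis=1, ddof=1)
        bad = sd == 0
        tsnr = np.zeros_like(mu)
        np.divide(np.abs(mu), sd, out=tsnr, where=~bad)
        per_run.append(tsnr)
        flagged = bad if flagged is None else (flagged | bad)
    return TsnrMap(
        values=np.mean(per_run, axis=0),
        flagged=flagged,
        n_runs_averaged=len(runs),
        pre_regression=True,
    )


def _design_matrix(run: "RunData") -> np.ndarray:
    T = run.nuisance.shape[1]
    return np.column_stack([np.ones(T), run.nuisance.T])


def regress_nuisance(run: "RunData") -> "RunData":
    """OLS residuals of every series on [intercept + nuisance rows].

    Raises if the design is rank deficient, naming the collinear rows.
    Residuals are orthogonal to every regressor by construction.
    """
    X = _design_matrix(run)
    # detect collinearity via the R diagonal of a pivoted QR
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * diag.max()
    if np.any(diag < tol):
        bad = np.flatnonzero(diag < tol)
        names = ["intercept"] + [f"nuisance[{i}]" for i in range(run.nuisance.shape[0])]
        raise ValueError(
            "rank-deficient nuisance design; collinear columns: "
            + ", ".join(names[i] for i in bad)
        )
    pinv = np.linalg.pinv(X)

    def resid(ts: np.ndarray) -> np.ndarray:
        beta = pinv @ ts.T  # (p, n_series)
        return ts - (X @ beta).T

    return replace(run, cortex_ts=resid(run.cortex_ts), striatum_ts=resid(run.striatum_ts))


def bandpass_array(
    data: np.ndarray, tr_s: float, low_hz: float = 0.01, high_hz: float = 0.10
) -> np.ndarray:
    """Zero-phase FFT-domain band-pass along the last axis.

    Frequency bins with low_hz <= |f| <= high_hz are kept, everything else
    (including the DC term) is zeroed.  The operator is a projection, so it
    is exactly zero-phase and exactly idempotent — re-filtering already
    band-limited data is a no-op, which keeps the preprocessing chain
    approximately idempotent on residuals.
    """
    data = np.asarray(data, dtype=np.float64)
    nyquist = 0.5 / tr_s
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist} Hz)"
        )
    t = data.shape[-1]
    freqs = np.fft.rfftfreq(t, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(data, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=-1)


def bandpass(run: "RunData", low_hz: float = 0.01, high_hz: float = 0.10) -> "RunData":
    return replace(
        run,
        cortex_ts=bandpass_array(run.cortex_ts, run.tr_s, low_hz, high_hz),
        striatum_ts=bandpass_array(run.striatum_ts, run.tr_s, low_hz, high_hz),
    )


def volume_smoother(volume: "VolumeModel", fwhm_mm: float = 4.0) -> sparse.csr_matrix:
    """Mask-aware Gaussian smoothing operator over in-mask voxels.

    Weights are a Gaussian of the world-mm distance between voxel centers,
    truncated at 3 sigma, renormalized over the voxels actually inside the
    mask, so no signal is drawn from (or lost to) the outside.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    n = volume.n_voxels
    if fwhm_mm == 0:
        return sparse.identity(n, format="csr")
    sigma = fwhm_mm * FWHM_TO_SIGMA
    coords = volume.world_coords()
    tree = cKDTree(coords)
    pairs = tree.sparse_distance_matrix(tree, max_distance=3.0 * sigma, output_type="coo_matrix")
    w = np.exp(-0.5 * (pairs.data / sigma) ** 2)
    mat = sparse.csr_matrix((w, (pairs.row, pairs.col)), shape=(n, n))
    mat.setdiag(1.0)  # unit self-weight regardless of how the tree reports it
    norm = np.asarray(mat.sum(axis=1)).ravel()
    return sparse.diags(1.0 / norm) @ mat


def smooth_volume(
    data: np.ndarray,
    volume: "VolumeModel",
    fwhm_mm: float = 4.0,
    smoother: sparse.spmatrix | None = None,
) -> np.ndarray:
    """Smooth per-voxel data (K,) or (K, T) over the volume mask."""
    if smoother is None:
        smoother = volume_smoother(volume, fwhm_mm)
    data = np.asarray(data, dtype=np.float64)
    if data.shape[0] != smoother.shape[1]:
        raise ValueError(
            f"data has {data.shape[0]} rows but the mask holds {smoother.shape[1]} voxels"
        )
    return smoother @ data


def _row_normalized_adjacency(surface: "SurfaceModel") -> sparse.csr_matrix:
    a = surface.adjacency
    deg = np.asarray(a.sum(axis=1)).ravel()
    isolated = deg == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} disconnected vertices left unsmoothed", stacklevel=3
        )
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=~isolated)
    return sparse.diags(inv) @ a


def surface_smoothing_iterations(surface: "SurfaceModel", fwhm_mm: float) -> int:
    """Calibrate diffusion steps so a delta's half-maximum geodesic radius
    reaches ~fwhm/2.

    The kernel per step is x <- (x + mean-over-neighbors(x)) / 2; the number
    of steps is found by smoothing an actual delta on this mesh, so the
    calibration adapts to the mesh's edge lengths.
    """
    if fwhm_mm <= 0:
        return 0
    a = _row_normalized_adjacency(surface)
    # a well-connected source: the max-degree vertex of the left hemisphere
    deg = np.asarray(surface.adjacency.sum(axis=1)).ravel()
    candidates = np.flatnonzero(surface.hemi == surface.hemi[0])
    src = int(candidates[np.argmax(deg[candidates])])
    geo = surface.geodesic_from([src])
    x = np.zeros(surface.n_vertices)
    x[src] = 1.0
    target = fwhm_mm / 2.0
    for it in range(1, 201):
        x = 0.5 * (x + a @ x)
        half = x >= 0.5 * x.max()
        radius = geo[half & np.isfinite(geo)].max()
        if radius >= target:
            return it
    return 200


def smooth_surface(
    data: np.ndarray,
    surface: "SurfaceModel",
    fwhm_mm: float = 2.0,
    n_iter: int | None = None,
) -> np.ndarray:
    """Iterative neighbor-averaging diffusion on the mesh graph.

    ``n_iter`` may be precomputed once per (mesh, fwhm) with
    :func:`surface_smoothing_iterations` and reused across runs.
    """
    if n_iter is None:
        n_iter = surface_smoothing_iterations(surface, fwhm_mm)
    if n_iter == 0:
        return np.asarray(data, dtype=np.float64).copy()
    a = _row_normalized_adjacency(surface)
    out = np.asarray(data, dtype=np.float64)
    for _ in range(n_iter):
        out = 0.5 * (out + a @ out)
    return out


def preprocess_run(
    run: "RunData",
    surface: "SurfaceModel",
    volume: "VolumeModel",
    low_hz: float = 0.01,
    high_hz: float = 0.10,
    fwhm_surface_mm: float = 2.0,
    fwhm_volume_mm: float = 4.0,
    volume_op: sparse.spmatrix | None = None,
    surface_iters: int | None = None,
) -> "RunData":
    """Full per-run chain: regress -> band-pass -> smooth (surface & volume).

    The nuisance regressors are band-limited to the analysis band before
    the regression so that the subsequent temporal filter cannot
    reintroduce nuisance covariance; combined with the projection filter
    this makes regress -> band-pass idempotent on residuals.
    """
    run = replace(run, nuisance=bandpass_array(run.nuisance, run.tr_s, low_hz, high_hz))
    run = regress_nuisance(run)
    run = bandpass(run, low_hz, high_hz)
    cortex = smooth_surface(run.cortex_ts, surface, fwhm_surface_mm, n_iter=surface_iters)
    striatum = smooth_volume(run.striatum_ts, volume, fwhm_volume_mm, smoother=volume_op)
    return replace(run, cortex_ts=cortex, striatum_ts=striatum)
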