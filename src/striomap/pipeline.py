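"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
parcellate (+ blur sweep) -> seed maps (split-half) -> laterality -> report.

The heavy lifting lives in the stage modules; this module wires them
together, computes the recovery metrics against the phantom's ground
truth, and writes the artifact directory with provenance.

Two protocol details deserve emphasis:

* tSNR is computed from the raw (pre-regression) runs even when the rest
  of the pipeline runs end-to-end;
* seed maps follow a split-half protocol: seeds are placed using a
  parcellation built from the first half of the runs, and the maps are
  computed from the second half, so recapitulation is never circular.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as smio
from .config import PipelineConfig
from .connectivity import ConnMatrix, build_conn_matrix
from .geometry import (
    ASSOCIATION_NETWORKS,
    CAUDATE,
    NETWORK_NAMES,
    SurfaceModel,
    VolumeModel,
)
from .laterality import LateralityTable, count_by_hemisphere, laterality_index
from .parcellation import (
    Parcellation,
    assignment_accuracy,
    blur_sweep,
    contiguous_zone_count,
    parcellate,
)
from .phantom import PhantomBundle, PhantomSpec, RunData, simulate_bundle, write_phantom
from .seedmaps import SeedRegion, make_seed, network_selectivity, seed_correlation_map
from .signal_processing import (
    TsnrMap,
    bandpass,
    bandpass_array,
    compute_tsnr,
    regress_nuisance,
    smooth_surface,
    smooth_volume,
    surface_smoothing_iterations,
    volume_smoother,
)

__all__ = [
    "PipelineResult",
    "preprocess_bundle",
    "evaluate_subject",
    "run_blur_study",
    "bleed_change_counts",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.1f s", name, dt)
            else:
                logger.error("stage %s: FAILED after %.1f s: %s", name, dt, exc)
            return False

    return _Timer()


def preprocess_bundle(
    bundle: PhantomBundle,
    band: tuple[float, float] = (0.01, 0.10),
    fwhm_surface_mm: float = 2.0,
    fwhm_volume_mm: float = 4.0,
) -> tuple[list[RunData], list[RunData], TsnrMap]:
    """Returns (smoothed runs, unsmoothed band-passed residual runs, tSNR).

    The tSNR map comes from the raw runs, before any regression.  Nuisance
    regressors are band-limited to the analysis band before regression so
    the temporal filter cannot reintroduce nuisance covariance.
    """
    tsnr = compute_tsnr(bundle.runs, which="striatum")
    surf_iters = surface_smoothing_iterations(bundle.surface, fwhm_surface_mm)
    vol_op = volume_smoother(bundle.volume, fwhm_volume_mm)
    unsmoothed, smoothed = [], []
    for run in bundle.runs:
        run = replace(run, nuisance=bandpass_array(run.nuisance, run.tr_s, *band))
        rb = bandpass(regress_nuisance(run), *band)
        unsmoothed.append(rb)
        smoothed.append(
            replace(
                rb,
                cortex_ts=smooth_surface(rb.cortex_ts, bundle.surface, n_iter=surf_iters),
                striatum_ts=smooth_volume(rb.striatum_ts, bundle.volume, smoother=vol_op),
            )
        )
    return smoothed, unsmoothed, tsnr


def _caudate_voxels(volume: VolumeModel) -> np.ndarray:
    return np.flatnonzero(volume.substructure_of() == CAUDATE)


def _zone_seed_center(volume: VolumeModel, candidates: np.ndarray) -> int:
    """Medoid voxel (min summed world distance) of a candidate set."""
    coords = volume.world_coords()[candidates]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2).sum(axis=1)
    return int(candidates[np.argmin(d)])


def split_half_seed_analysis(
    bundle: PhantomBundle,
    runs: list[RunData],
    k: int = 400,
    seed_radius_mm: float = 4.8,
    surface_hops: int = 2,
) -> dict:
    """Caudate megacluster seeds + somatomotor seeds under split-half data.

    A parcellation from the first half of the runs chooses one caudate
    seed per association network (the medoid of the network's assigned
    caudate voxels); correlation maps come from the second half only.
    Returns the 5x5 selectivity matrix (seed network x scored network) and,
    for each somatomotor cortical seed, whether the peak striatal z falls
    inside the matching ground-truth putamen zone.
    """
    half = len(runs) // 2
    if half == 0:
        raise ValueError("split-half analysis needs at least 2 runs")
    first, second = runs[:half], runs[half:]
    conn_first = build_conn_matrix(first)
    parc_first = parcellate(conn_first, bundle.truth.vertex_labels, k=k, keep_votes=False)
    caudate = _caudate_voxels(bundle.volume)
    labels = bundle.truth.vertex_labels

    selectivity = pd.DataFrame(
        index=[NETWORK_NAMES[n] for n in ASSOCIATION_NETWORKS],
        columns=[NETWORK_NAMES[n] for n in ASSOCIATION_NETWORKS],
        dtype=float,
    )
    for net in ASSOCIATION_NETWORKS:
        assigned = caudate[parc_first.winners[caudate] == net]
        if len(assigned) == 0:
            selectivity.loc[NETWORK_NAMES[net]] = np.nan
            logger.warning("no caudate voxels assigned to %s in half 1", NETWORK_NAMES[net])
            continue
        seed = make_seed(
            "striatum", _zone_seed_center(bundle.volume, assigned), seed_radius_mm,
            volume=bundle.volume,
        )
        smap = seed_correlation_map(second, seed)
        for target in ASSOCIATION_NETWORKS:
            selectivity.loc[NETWORK_NAMES[net], NETWORK_NAMES[target]] = network_selectivity(
                smap, labels, target
            )

    somato = {}
    for name, zone in bundle.truth.somatomotor_zones.items():
        # seed = the body-part patch itself, one hemisphere (a 2-hop disk
        # would spill into surrounding somatomotor cortex and dilute the
        # body-part signal)
        verts = zone["vertices"]
        hemi = bundle.surface.hemi[verts[0]]
        members = verts[bundle.surface.hemi[verts] == hemi]
        seed = SeedRegion(
            domain="cortex", center=int(members[0]), radius=float(surface_hops), members=members
        )
        smap = seed_correlation_map(second, seed)
        peak = int(np.argmax(smap.values))
        somato[name] = {
            "peak_voxel": peak,
            "in_true_zone": bool(np.isin(peak, zone["voxels"])),
        }
    return {"selectivity": selectivity, "somatomotor": somato}


def evaluate_subject(
    spec: PhantomSpec, subject: int = 0, bleed_threshold: float | None = 0.25
) -> dict:
    """Simulate one phantom subject and score end-to-end recovery.

    Returns caudate assignment accuracy, the set of association networks
    recovered in the caudate, their contiguity, caudate/cortex laterality
    indices, the split-half seed selectivity matrix, the somatomotor
    peak-location checks, and (if ``bleed_threshold`` is set) how often
    near-surface versus interior assignments change between the raw and
    high-threshold votes.
    """
    bundle = simulate_bundle(spec, subject=subject)
    smoothed, unsmoothed, _ = preprocess_bundle(bundle)
    conn = build_conn_matrix(smoothed)
    parc = parcellate(conn, bundle.truth.vertex_labels, keep_votes=False)
    caudate = _caudate_voxels(bundle.volume)
    truth = bundle.truth

    accuracy = assignment_accuracy(parc, truth.voxel_coupling, subset=caudate)
    winners_caudate = parc.winners[caudate]
    recovered = sorted(
        set(np.unique(winners_caudate[winners_caudate > 0])) & set(ASSOCIATION_NETWORKS)
    )
    caudate_mask = bundle.volume.substructure == CAUDATE
    components = {
        NETWORK_NAMES[n]: contiguous_zone_count(parc, bundle.volume, n, caudate_mask)
        for n in ASSOCIATION_NETWORKS
    }

    hemis = bundle.volume.voxel_hemi()
    include = np.zeros(bundle.volume.n_voxels, dtype=bool)
    include[caudate] = True
    caud_table = count_by_hemisphere(parc.winners, hemis, "caudate", include=include)
    cortex_table = count_by_hemisphere(
        truth.vertex_labels.labels,
        bundle.surface.hemi,
        "cortex",
        include=~bundle.surface.medial_wall,
    )
    li = {
        "caudate": {
            NETWORK_NAMES[n]: laterality_index(caud_table, n) for n in ASSOCIATION_NETWORKS
        },
        "cortex": {
            NETWORK_NAMES[n]: laterality_index(cortex_table, n) for n in ASSOCIATION_NETWORKS
        },
    }
    # per-voxel network contrast: own-network mean z beats every other network
    labels = truth.vertex_labels.labels
    net_means = np.stack(
        [conn.z[:, labels == n].mean(axis=1) for n in sorted(NETWORK_NAMES)], axis=1
    )
    clean = (
        (truth.voxel_coupling > 0)
        & (truth.bleed_weight < 0.05)
        & ~np.isin(np.arange(bundle.volume.n_voxels), truth.dropout_voxels)
        & (truth.voxel_zone < 0)  # zone voxels carry mixed latents by design
    )
    own = net_means[np.arange(len(clean)), truth.voxel_coupling - 1]
    other = net_means.copy()
    other[np.arange(len(clean)), truth.voxel_coupling - 1] = -np.inf
    contrast_frac = float(np.mean(own[clean] > other[clean].max(axis=1)))

    seeds = split_half_seed_analysis(bundle, smoothed)
    bleed = None
    if bleed_threshold is not None:
        # bleed detection runs on the unsmoothed matrix: volume smoothing
        # pools coherent bleed across neighboring rim voxels and would keep
        # them supra-threshold
        conn_raw = build_conn_matrix(unsmoothed)
        p_raw = parcellate(conn_raw, bundle.truth.vertex_labels, keep_votes=False)
        p_thr = parcellate(
            conn_raw, bundle.truth.vertex_labels, threshold=bleed_threshold, keep_votes=False
        )
        changed = p_raw.winners != p_thr.winners
        dist = truth.surface_distance_mm
        fwhm = max(spec.bleed_fwhm_mm, 1e-6)
        near = dist <= 2 * fwhm  # the bleed kernel's support
        interior = (
            (dist > 2 * fwhm)
            & (truth.voxel_coupling > 0)
            & ~np.isin(np.arange(bundle.volume.n_voxels), truth.dropout_voxels)
        )
        bleed = {
            "near_changed": int(changed[near].sum()),
            "near_total": int(near.sum()),
            "interior_changed": int(changed[interior].sum()),
            "interior_total": int(interior.sum()),
        }
    return {
        "caudate_accuracy": accuracy,
        "bleed_change": bleed,
        "network_contrast_frac": contrast_frac,
        "recovered_association_networks": [NETWORK_NAMES[n] for n in recovered],
        "n_recovered_association_networks": len(recovered),
        "zone_components": components,
        "laterality": li,
        "selectivity": seeds["selectivity"],
        "somatomotor": seeds["somatomotor"],
        "n_caudate_voxels": int(len(caudate)),
    }


def run_blur_study(spec: PhantomSpec, thresholds=None, subject: int = 0) -> dict:
    """Threshold sweep over raw and smoothed data on one deeply sampled
    phantom subject.

    Runs are simulated, preprocessed, correlated, and discarded one at a
    time (only the two z accumulators persist), so a 62-run study fits in
    ordinary memory.  Reports the UNASSIGNED count per (condition,
    threshold) and, on the smoothed condition at threshold 0.10, the
    fraction of dropout voxels unassigned and of clean coupled caudate
    voxels still assigned.
    """
    from .connectivity import fisher_z, run_correlation
    from .parcellation import DEFAULT_THRESHOLDS
    from .phantom import build_phantom_geometry, derive_run_seed, simulate_run
    from .signal_processing import smooth_surface as _ss, smooth_volume as _sv

    thresholds = DEFAULT_THRESHOLDS if thresholds is None else tuple(thresholds)
    surface, volume, truth = build_phantom_geometry(spec)
    surf_iters = surface_smoothing_iterations(surface, 2.0)
    vol_op = volume_smoother(volume, 4.0)
    acc = {"raw": None, "smoothed": None}
    for r in range(spec.n_runs):
        run = simulate_run(truth, spec, derive_run_seed(spec.rng_seed, subject, r), run_id=r)
        run = replace(run, nuisance=bandpass_array(run.nuisance, run.tr_s, 0.01, 0.10))
        rb = bandpass(regress_nuisance(run), 0.01, 0.10)
        del run
        for cond in ("raw", "smoothed"):
            if cond == "smoothed":
                rb = replace(
                    rb,
                    cortex_ts=_ss(rb.cortex_ts, surface, n_iter=surf_iters),
                    striatum_ts=_sv(rb.striatum_ts, volume, smoother=vol_op),
                )
            z = fisher_z(run_correlation(rb.striatum_ts, rb.cortex_ts)[0])
            acc[cond] = z if acc[cond] is None else acc[cond] + z
    conns = {
        cond: ConnMatrix(z=acc[cond] / spec.n_runs, n_runs=spec.n_runs) for cond in acc
    }
    sweep = blur_sweep(conns, truth.vertex_labels, thresholds=thresholds)
    unassigned = {
        cond: {thr: sweep[(cond, thr)].n_unassigned for thr in thresholds}
        for cond in conns
    }
    caudate = _caudate_voxels(volume)
    dropout = truth.dropout_voxels
    clean_caudate = caudate[~np.isin(caudate, dropout)]
    out = {
        "unassigned": unassigned,
        "thresholds": thresholds,
        "truth": truth,
        "volume": volume,
        "sweep": sweep,
    }
    if 0.10 in thresholds:
        ref = sweep[("smoothed", 0.10)]
        out["dropout_unassigned_frac"] = float(np.mean(ref.winners[dropout] == 0))
        out["caudate_assigned_frac"] = float(np.mean(ref.winners[clean_caudate] != 0))
    return out


def bleed_change_counts(spec: PhantomSpec, high_threshold: float = 0.25, subject: int = 0) -> dict:
    """How often assignments flip between the raw vote and the
    high-threshold vote, for near-surface versus interior voxels.

    Near-surface: analysis-mask voxels within one bleed FWHM of the
    cortical sheet.  Interior: coupled, non-dropout voxels at least two
    FWHM away.  With bleed enabled, near-surface voxels are expected to
    change far more often.
    """
    bundle = simulate_bundle(spec, subject=subject)
    _, unsmoothed, _ = preprocess_bundle(bundle)
    conn = build_conn_matrix(unsmoothed)
    labels = bundle.truth.vertex_labels
    p_raw = parcellate(conn, labels, keep_votes=False)
    p_thr = parcellate(conn, labels, threshold=high_threshold, keep_votes=False)
    changed = p_raw.winners != p_thr.winners
    dist = bundle.truth.surface_distance_mm
    fwhm = max(spec.bleed_fwhm_mm, 1e-6)
    near = dist <= 2 * fwhm
    interior = (
        (dist > 2 * fwhm)
        & (bundle.truth.voxel_coupling > 0)
        & ~np.isin(np.arange(bundle.volume.n_voxels), bundle.truth.dropout_voxels)
    )
    return {
        "near_changed": int(changed[near].sum()),
        "near_total": int(near.sum()),
        "interior_changed": int(changed[interior].sum()),
        "interior_total": int(interior.sum()),
    }


# ---------------------------------------------------------------------------
# full pipeline with artifacts


@dataclass
class PipelineResult:
    config: PipelineConfig
    bundle: PhantomBundle
    tsnr: TsnrMap
    conn: ConnMatrix
    parcellation: Parcellation
    sweep_unassigned: pd.DataFrame
    seed_analysis: dict
    laterality_caudate: LateralityTable
    laterality_cortex: LateralityTable
    metrics: dict


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage on one phantom subject and (optionally) write the
    artifact directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    spec = config.phantom.to_spec(seed=config.resolved_seed())
    prep = config.preprocessing

    with _stage("simulate"):
        bundle = simulate_bundle(spec)
    with _stage("preprocess"):
        smoothed, unsmoothed, tsnr = preprocess_bundle(
            bundle,
            band=(prep.band_low_hz, prep.band_high_hz),
            fwhm_surface_mm=prep.fwhm_surface_mm,
            fwhm_volume_mm=prep.fwhm_volume_mm,
        )
    with _stage("connectivity"):
        conn = build_conn_matrix(smoothed)
        conn_raw = build_conn_matrix(unsmoothed)
    with _stage("parcellate"):
        parc = parcellate(
            conn,
            bundle.truth.vertex_labels,
            k=config.parcellation.k,
            threshold=config.parcellation.threshold,
            keep_votes=False,
        )
        sweep = blur_sweep(
            {"raw": conn_raw, "smoothed": conn},
            bundle.truth.vertex_labels,
            thresholds=config.parcellation.sweep_thresholds,
            k=config.parcellation.k,
        )
        sweep_rows = [
            {"condition": cond, "threshold": thr, "n_unassigned": p.n_unassigned}
            for (cond, thr), p in sweep.items()
        ]
        sweep_df = pd.DataFrame(sweep_rows).sort_values(["condition", "threshold"])
    with _stage("seedmaps"):
        seeds = split_half_seed_analysis(
            bundle,
            smoothed,
            k=config.parcellation.k,
            seed_radius_mm=config.seeds.volume_radius_mm,
            surface_hops=config.seeds.surface_hops,
        )
    with _stage("laterality"):
        caudate = _caudate_voxels(bundle.volume)
        include = np.zeros(bundle.volume.n_voxels, dtype=bool)
        include[caudate] = True
        lat_caud = count_by_hemisphere(
            parc.winners, bundle.volume.voxel_hemi(), "caudate", include=include
        )
        lat_cortex = count_by_hemisphere(
            bundle.truth.vertex_labels.labels,
            bundle.surface.hemi,
            "cortex",
            include=~bundle.surface.medial_wall,
        )
    with _stage("report"):
        accuracy = assignment_accuracy(parc, bundle.truth.voxel_coupling, subset=caudate)
        winners_caudate = parc.winners[caudate]
        recovered = sorted(
            set(np.unique(winners_caudate[winners_caudate > 0])) & set(ASSOCIATION_NETWORKS)
        )
        metrics = {
            "caudate_accuracy": accuracy,
            "recovered_association_networks": [NETWORK_NAMES[n] for n in recovered],
            "laterality_index_caudate": {
                NETWORK_NAMES[n]: laterality_index(lat_caud, n) for n in ASSOCIATION_NETWORKS
            },
            "laterality_index_cortex": {
                NETWORK_NAMES[n]: laterality_index(lat_cortex, n) for n in ASSOCIATION_NETWORKS
            },
            "somatomotor_peaks_in_zone": {
                k: v["in_true_zone"] for k, v in seeds["somatomotor"].items()
            },
            "n_ties": parc.params.get("n_ties", 0),
        }
    result = PipelineResult(
        config=config,
        bundle=bundle,
        tsnr=tsnr,
        conn=conn,
        parcellation=parc,
        sweep_unassigned=sweep_df,
        seed_analysis=seeds,
        laterality_caudate=lat_caud,
        laterality_cortex=lat_cortex,
        metrics=metrics,
    )
    if out_dir is not None:
        write_artifacts(result, Path(out_dir))
    return result


def _stamp_tsv(df: pd.DataFrame, config_hash: str) -> pd.DataFrame:
    out = df.copy()
    out["config_hash"] = config_hash
    return out


def write_artifacts(result: PipelineResult, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    h = cfg.config_hash()
    vol = result.bundle.volume

    write_phantom(result.bundle, out_dir / "phantom")

    tsnr_grid = np.zeros(vol.shape)
    idx = vol.voxel_indices
    tsnr_grid[idx[:, 0], idx[:, 1], idx[:, 2]] = result.tsnr.values
    smio.save_nifti(out_dir / "tsnr_striatum.nii.gz", tsnr_grid, vol.affine)
    smio.save_json(
        out_dir / "tsnr_striatum.json",
        {
            "n_runs_averaged": result.tsnr.n_runs_averaged,
            "pre_regression": result.tsnr.pre_regression,
            "n_flagged": int(result.tsnr.flagged.sum()),
            "config_hash": h,
        },
    )

    smio.save_nifti(out_dir / "conn_z.nii.gz", result.conn.z, np.eye(4))
    smio.save_json(
        out_dir / "conn_z.json",
        {
            "n_runs": result.conn.n_runs,
            "n_voxels": int(result.conn.z.shape[0]),
            "n_vertices": int(result.conn.z.shape[1]),
            "voxel_order": "C-order scan of the analysis mask",
            "config_hash": h,
        },
    )

    smio.save_nifti(
        out_dir / "parcellation.nii.gz", result.parcellation.winner_volume(vol), vol.affine, np.int16
    )
    legend = pd.DataFrame(
        [{"network": 0, "name": "UNASSIGNED"}]
        + [{"network": k, "name": v} for k, v in NETWORK_NAMES.items()]
    )
    smio.save_tsv(out_dir / "parcellation_legend.tsv", _stamp_tsv(legend, h))
    smio.save_json(
        out_dir / "parcellation.json",
        {
            "params": {
                k: v for k, v in result.parcellation.params.items() if k != "taxonomy"
            },
            "n_unassigned": result.parcellation.n_unassigned,
            "config_hash": h,
        },
    )

    smio.save_tsv(out_dir / "blur_sweep.tsv", _stamp_tsv(result.sweep_unassigned, h))
    smio.save_tsv(out_dir / "laterality_caudate.tsv", _stamp_tsv(result.laterality_caudate.table, h))
    smio.save_tsv(out_dir / "laterality_cortex.tsv", _stamp_tsv(result.laterality_cortex.table, h))

    sel = result.seed_analysis["selectivity"]
    smio.save_tsv(out_dir / "seed_selectivity.tsv", _stamp_tsv(sel.reset_index(names="seed"), h))
    smio.save_json(
        out_dir / "seed_somatomotor.json",
        {"somatomotor": {k: v for k, v in result.seed_analysis["somatomotor"].items()}, "config_hash": h},
    )

    smio.save_json(out_dir / "provenance.json", {"config": cfg.to_dict(), "config_hash": h})
    (out_dir / "config.yaml").write_text(
        __import__("yaml").safe_dump(cfg.to_dict(), sort_keys=True)
    )
    (out_dir / "report.md").write_text(_render_report(result, h))
    return out_dir


def _render_report(result: PipelineResult, config_hash: str) -> str:
    m = result.metrics
    lines = [
        "# striomap pipeline report",
        "",
        f"config hash: `{config_hash}`",
        f"runs: {result.conn.n_runs}, voxels: {result.conn.z.shape[0]}, "
        f"vertices: {result.conn.z.shape[1]}",
        "",
        "## Caudate recovery",
        f"- assignment accuracy (caudate, vs ground truth): {m['caudate_accuracy']:.3f}",
        f"- association networks recovered in the caudate: "
        f"{', '.join(m['recovered_association_networks'])}",
        f"- tied votes: {m['n_ties']}",
        "",
        "## Seed-map recapitulation (split-half)",
        "```\n" + result.seed_analysis["selectivity"].round(3).to_string() + "\n```",
        "",
        "## Somatomotor topography",
    ]
    for name, hit in m["somatomotor_peaks_in_zone"].items():
        lines.append(f"- {name} seed peak inside its true putamen zone: {hit}")
    lines += ["", "## Laterality indices (caudate / cortex)"]
    for net in m["laterality_index_caudate"]:
        lines.append(
            f"- {net}: caudate {m['laterality_index_caudate'][net]:+.3f}, "
            f"cortex {m['laterality_index_cortex'][net]:+.3f}"
        )
    lines += [
        "",
        "## Blur-control sweep (UNASSIGNED voxels per threshold)",
        "```\n" + result.sweep_unassigned.to_string(index=False) + "\n```",
        "",
    ]
    return "\n".join(lines)
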