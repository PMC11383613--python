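"""Synthetic multi-run BOLD phantom with fully known ground truth.

The phantom emulates the acquisition and anatomical structure of a
within-individual precision fMRI study of striatum-to-cortex coupling:

* two cortical "hemispheres" (triangulated spheres placed lateral to a
  striatal voxel grid), tiled into 15 contiguous network patches, with the
  five association networks (FPN-A, FPN-B, LANG, DN-B, DN-A) arranged in
  side-by-side rows (supra-areal association megacluster motif, two per
  hemisphere);
* a striatal grid holding caudate / putamen / NAc masks; the caudate is
  partitioned into five contiguous zones, one per association network, in
  anatomically motivated relative positions (DN-A dorsomedial head, DN-B
  posterior, LANG lateral, FPN-A/FPN-B ventral); the putamen carries a
  foot / hand / tongue somatomotor gradient from dorsolateral to
  ventromedial; the NAc sits in a signal-dropout zone;
* runs of 422 frames at TR = 1.0 s with the first 12 frames removed,
  mirroring a standard T1-equilibration trim;
* shared band-limited (0.01-0.10 Hz) latent network signals, a nuisance
  set (6 motion + whole-brain + ventricle + white matter + derivatives),
  Gaussian sensor noise, cortex-to-striatum signal bleed for voxels near
  the cortical sheet, and planted hemispheric asymmetries of network
  extents (LANG enlarged on the left, FPN-B on the right).

Every random quantity flows from one master seed through documented
``numpy`` SeedSequence spawning, so a fixed seed reproduces the bundle
bit-for-bit.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, cKDTree

from . import io as smio
from .geometry import (
    ASSOCIATION_NETWORKS,
    CAUDATE,
    LEFT,
    NAC,
    NETWORK_IDS,
    NETWORK_NAMES,
    PUTAMEN,
    RIGHT,
    GeometryError,
    NetworkLabelMap,
    SurfaceModel,
    VolumeModel,
)
from .signal_processing import FWHM_TO_SIGMA, bandpass_array

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "RunData",
    "PhantomBundle",
    "build_phantom_geometry",
    "simulate_run",
    "simulate_bundle",
    "write_phantom",
    "read_phantom",
    "derive_run_seed",
]

# ---------------------------------------------------------------------------
# geometry layout constants (world mm)

SPHERE_CENTER_X = 55.0  # |x| of each hemisphere sphere center
SPHERE_RADIUS = 25.0

# ellipsoids (center |x|, y, z; semi-axes), right hemisphere; left mirrors x
_CAUDATE_CENTER = np.array([13.0, 6.0, 8.0])
_CAUDATE_SEMI = np.array([5.0, 13.0, 7.0])
_PUTAMEN_CENTER = np.array([22.0, -2.0, 2.0])
_PUTAMEN_SEMI = np.array([4.5, 10.0, 6.5])
_NAC_CENTER = np.array([10.0, 14.0, -8.0])
_NAC_RADIUS = 4.0

#: caudate zone anchors (right hemisphere, world mm): relative positions of
#: the five association-network zones within the caudate head/body.
_CAUDATE_ANCHORS = {
    NETWORK_IDS["DN-A"]: np.array([9.5, 16.0, 13.0]),  # dorsomedial head
    NETWORK_IDS["DN-B"]: np.array([13.0, -5.0, 8.0]),  # posterior body
    NETWORK_IDS["LANG"]: np.array([17.5, 8.0, 8.0]),  # lateral
    NETWORK_IDS["FPN-A"]: np.array([12.0, 1.0, 2.0]),  # ventral posterior
    NETWORK_IDS["FPN-B"]: np.array([12.0, 13.0, 2.0]),  # ventral anterior
}

# seed directions on the unit sphere in hemisphere-local coordinates
# (x: toward the midline, y: anterior, z: dorsal); the two SAAM rows place
# the five association networks side by side along an arc.
_SAAM_ORDER = ("FPN-A", "FPN-B", "LANG", "DN-B", "DN-A")
_SAAM_ARCS = (
    (np.array([-0.80, 0.50, 0.20]), np.array([0.0, 0.0, 1.0])),
    (np.array([0.60, 0.20, 0.75]), np.array([0.0, 1.0, 0.0])),
)
_OTHER_SEED_DIRS = {
    "VIS-C": np.array([0.10, -0.80, 0.55]),
    "VIS-P": np.array([0.50, -0.75, -0.20]),
    "SMOT-A": np.array([-0.30, 0.05, 0.95]),
    "SMOT-B": np.array([0.30, 0.55, 0.75]),
    "PM-PPr": np.array([0.80, 0.55, 0.20]),
    "CG-OP": np.array([0.90, 0.00, -0.40]),
    "SAL/PMN": np.array([0.40, 0.90, 0.10]),
    "dATN-A": np.array([0.85, -0.40, 0.30]),
    "dATN-B": np.array([0.50, -0.50, 0.70]),
    "AUD": np.array([0.10, 0.95, -0.30]),
}
_MEDIAL_WALL_DIR = np.array([0.0, -1.0, 0.0])  # posterior cap, kept off the seeds
_MEDIAL_WALL_COS = 0.95

_ZONE_NAMES = ("foot", "hand", "tongue")
_DROPOUT_ATTENUATION = 0.02  # residual coupling amplitude in dropout voxels
_DROPOUT_NOISE_FACTOR = 2.0
_BASELINE_MEAN = 1000.0
_BASELINE_CV = 0.05
_DROPOUT_BASELINE_FACTOR = 0.3
_TISSUE_LOADING_SD = 0.25
_MOTION_LOADING_SD = 0.10


@dataclass
class PhantomSpec:
    """Study-condition knobs of the phantom.

    Defaults mirror the acquisition they emulate: runs of 422 frames at
    TR = 1.0 s with 12 frames dropped, a 15-network cortical taxonomy, a
    2.4-mm striatal grid.  ``snr_cortex``/``snr_striatum`` are clean-signal
    amplitudes relative to unit sensor noise (striatum set to half the
    cortex, reflecting its poorer SNR).  ``laterality_plan`` maps network
    name -> left:right vertex-extent ratio.
    """

    n_vertices_per_hemi: int = 2000
    grid_shape: tuple[int, int, int] = (32, 40, 32)
    voxel_size_mm: float = 2.4
    n_runs: int = 4
    frames_per_run: int = 422
    frames_dropped: int = 12
    tr_s: float = 1.0
    network_count: int = 15
    snr_cortex: float = 1.0
    snr_striatum: float = 0.5
    bleed_fwhm_mm: float = 4.0
    dropout_center: tuple[float, float, float] = (10.0, 14.0, -8.0)
    dropout_radius_mm: float = 6.0
    laterality_plan: dict[str, float] = field(
        default_factory=lambda: {"LANG": 1.5, "FPN-B": 1.0 / 1.5}
    )
    dilation_level: int = 3
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if self.n_vertices_per_hemi <= 0 or self.n_runs <= 0 or self.frames_per_run <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.frames_dropped < self.frames_per_run:
            raise ValueError("frames_dropped must be in [0, frames_per_run)")
        if self.network_count != 15:
            raise ValueError("only the 15-network taxonomy is supported")
        if self.snr_cortex < 0 or self.snr_striatum < 0:
            raise ValueError("snr must be non-negative")
        unknown = set(self.laterality_plan) - set(NETWORK_IDS)
        if unknown:
            raise ValueError(f"laterality_plan names unknown networks: {sorted(unknown)}")

    @property
    def n_frames_kept(self) -> int:
        return self.frames_per_run - self.frames_dropped

    def to_dict(self) -> dict:
        return {
            "n_vertices_per_hemi": self.n_vertices_per_hemi,
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "n_runs": self.n_runs,
            "frames_per_run": self.frames_per_run,
            "frames_dropped": self.frames_dropped,
            "tr_s": self.tr_s,
            "network_count": self.network_count,
            "snr_cortex": self.snr_cortex,
            "snr_striatum": self.snr_striatum,
            "bleed_fwhm_mm": self.bleed_fwhm_mm,
            "dropout_center": list(self.dropout_center),
            "dropout_radius_mm": self.dropout_radius_mm,
            "laterality_plan": dict(self.laterality_plan),
            "dilation_level": self.dilation_level,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "dropout_center" in d:
            d["dropout_center"] = tuple(d["dropout_center"])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Everything the pipeline is supposed to recover.

    Voxel arrays are aligned with ``VolumeModel.voxel_indices`` (the 3x
    dilated analysis mask); ``voxel_coupling`` is 0 for uncoupled (dilation
    rim) voxels.  ``somatomotor_zones`` pairs each putamen zone's voxels
    with its cortical patch.  ``bleed_weight`` / ``bleed_source`` define the
    cortical-bleed mixing applied by :func:`simulate_run`, and
    ``surface_distance_mm`` records each voxel's distance to the cortical
    sheet (used to separate near-surface from interior voxels in blur
    analyses).
    """

    vertex_labels: NetworkLabelMap
    vertex_zone: np.ndarray  # (n_vertices,) int8: -1 none, 0 foot, 1 hand, 2 tongue
    vertex_loadings: np.ndarray  # (n_vertices,)
    voxel_coupling: np.ndarray  # (n_voxels,) int16 network id, 0 uncoupled
    voxel_zone: np.ndarray  # (n_voxels,) int8
    voxel_loadings: np.ndarray  # (n_voxels,)
    dropout_voxels: np.ndarray  # indices into the voxel axis
    somatomotor_zones: dict[str, dict]
    bleed_weight: np.ndarray  # (n_voxels,)
    bleed_source: np.ndarray  # (n_voxels,) vertex index
    surface_distance_mm: np.ndarray  # (n_voxels,)
    vertex_baseline: np.ndarray
    voxel_baseline: np.ndarray


@dataclass
class RunData:
    """One run of paired surface + volume series, already trimmed.

    ``nuisance`` holds 18 zero-mean rows: 6 motion, whole-brain, ventricle,
    deep white matter, and their backward-difference temporal derivatives.
    """

    cortex_ts: np.ndarray  # (n_vertices, T)
    striatum_ts: np.ndarray  # (n_voxels, T)
    nuisance: np.ndarray  # (18, T)
    tr_s: float
    run_id: int = 0

    @property
    def n_frames(self) -> int:
        return self.cortex_ts.shape[1]


@dataclass
class PhantomBundle:
    spec: PhantomSpec
    surface: SurfaceModel
    volume: VolumeModel
    truth: PhantomTruth
    runs: list[RunData]


# ---------------------------------------------------------------------------
# surface construction


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n, dtype=np.float64)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _hemisphere_mesh(n: int, side: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One closed sphere mesh; local +x points toward the midline."""
    unit = _fibonacci_sphere(n)
    faces = ConvexHull(unit).simplices
    sign = -1.0 if side == LEFT else 1.0
    world = unit.copy()
    # local +x (medial) maps to world -x on the right sphere, +x on the left
    world[:, 0] = -unit[:, 0] if side == RIGHT else unit[:, 0]
    world = world * SPHERE_RADIUS
    world[:, 0] += sign * SPHERE_CENTER_X
    return world, faces, unit


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer split of ``total`` proportional to ``weights`` (sums exactly)."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _network_capacities(
    n_left: int, n_right: int, plan: dict[str, float]
) -> dict[int, tuple[int, int]]:
    """Per-network (left, right) vertex counts honoring the laterality plan.

    Network totals are split evenly across the 15 networks; within each
    network the left:right split follows the plan ratio (1 when absent).
    Residual imbalance from rounding is absorbed by ratio-1 networks so the
    planned ratios are preserved to +-1 vertex.
    """
    nets = sorted(NETWORK_NAMES)
    totals = _largest_remainder(n_left + n_right, np.ones(len(nets)))
    ratios = {NETWORK_IDS[k]: float(v) for k, v in plan.items()}
    caps: dict[int, list[int]] = {}
    for net, total in zip(nets, totals):
        rho = ratios.get(net, 1.0)
        left = int(round(total * rho / (1.0 + rho)))
        caps[net] = [left, total - left]
    # rebalance hemisphere sums using networks without a planned asymmetry
    diff = n_left - sum(c[0] for c in caps.values())
    free = [net for net in nets if net not in ratios]
    k = 0
    while diff != 0 and free:
        net = free[k % len(free)]
        step = 1 if diff > 0 else -1
        if 0 <= caps[net][0] + step <= sum(caps[net]):
            caps[net][0] += step
            caps[net][1] -= step
            diff -= step
        k += 1
        if k > 10 * len(free) * (abs(diff) + 1):  # pragma: no cover
            raise GeometryError("could not balance hemisphere capacities")
    return {net: (c[0], c[1]) for net, c in caps.items()}


def _seed_vertices(
    unit: np.ndarray, usable: np.ndarray
) -> dict[int, list[int]]:
    """Seed vertex indices (into one hemisphere's local array) per network."""
    seeds: dict[int, list[int]] = {net: [] for net in NETWORK_NAMES}
    taken = np.zeros(len(unit), dtype=bool)

    def grab(direction: np.ndarray) -> int:
        d = direction / np.linalg.norm(direction)
        score = unit @ d
        score[~usable | taken] = -np.inf
        idx = int(np.argmax(score))
        taken[idx] = True
        return idx

    for center, tangent in _SAAM_ARCS:
        c = center / np.linalg.norm(center)
        t = tangent - (tangent @ c) * c
        t = t / np.linalg.norm(t)
        for pos, name in enumerate(_SAAM_ORDER):
            angle = (pos - 2) * 0.28
            seeds[NETWORK_IDS[name]].append(grab(np.cos(angle) * c + np.sin(angle) * t))
    for name, direction in _OTHER_SEED_DIRS.items():
        seeds[NETWORK_IDS[name]].append(grab(direction))
    return seeds


def _grow_labels(
    surface: SurfaceModel,
    unit_by_hemi: dict[int, np.ndarray],
    caps: dict[int, tuple[int, int]],
) -> np.ndarray:
    """Capacity-constrained region growing of network patches, per hemisphere.

    For each hemisphere, every network's geodesic distance from its seed
    vertices is computed; (distance, network, vertex) triples are then
    consumed in ascending order, assigning each vertex to the nearest
    not-yet-full network.  Capacities sum to the hemisphere's labelable
    vertex count, so every vertex is labeled and counts are exact.
    """
    labels = np.zeros(surface.n_vertices, dtype=np.int16)
    for h in (LEFT, RIGHT):
        hemi_idx = np.flatnonzero(surface.hemi == h)
        usable_local = ~surface.medial_wall[hemi_idx]
        seeds_local = _seed_vertices(unit_by_hemi[h], usable_local)
        nets = sorted(NETWORK_NAMES)
        dists = np.empty((len(nets), len(hemi_idx)))
        for row, net in enumerate(nets):
            src = hemi_idx[seeds_local[net]]
            d = dijkstra(surface.edge_lengths, directed=False, indices=src, min_only=True)
            dists[row] = d[hemi_idx]
        remaining = {net: caps[net][h] for net in nets}
        candidates = np.flatnonzero(usable_local)
        order = []
        for row, net in enumerate(nets):
            for v in candidates:
                order.append((dists[row, v], row, int(v)))
        heapq.heapify(order)
        assigned = np.zeros(len(hemi_idx), dtype=bool)
        n_todo = len(candidates)
        while n_todo and order:
            _, row, v = heapq.heappop(order)
            net = nets[row]
            if assigned[v] or remaining[net] == 0:
                continue
            labels[hemi_idx[v]] = net
            assigned[v] = True
            remaining[net] -= 1
            n_todo -= 1
        if n_todo:  # pragma: no cover - capacities always sum to the total
            raise GeometryError("unlabeled vertices remain after region growing")
    return labels


def _somatomotor_patches(
    surface: SurfaceModel, labels: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Carve foot/hand/tongue patches inside SMOT-A, dorsal to ventral."""
    smot = NETWORK_IDS["SMOT-A"]
    vertex_zone = np.full(surface.n_vertices, -1, dtype=np.int8)
    patches: dict[str, list[np.ndarray]] = {name: [] for name in _ZONE_NAMES}
    for h in (LEFT, RIGHT):
        members = np.flatnonzero((labels == smot) & (surface.hemi == h))
        if len(members) < 9:
            raise GeometryError("SMOT-A patch too small to carve somatomotor zones")
        z = surface.vertices[members, 2]
        order = members[np.argsort(-z, kind="stable")]
        centers = [order[int(q * (len(order) - 1))] for q in (0.1, 0.5, 0.9)]
        hops = dijkstra(surface.adjacency, directed=False, indices=centers)
        hops = hops[:, members]
        near = hops.min(axis=0) <= 2.0
        zone_of = np.argmin(hops, axis=0)
        for zi, name in enumerate(_ZONE_NAMES):
            sel = members[near & (zone_of == zi)]
            vertex_zone[sel] = zi
            patches[name].append(sel)
    return vertex_zone, {k: np.concatenate(v) for k, v in patches.items()}


# ---------------------------------------------------------------------------
# volume construction


def _build_volume(spec: PhantomSpec) -> VolumeModel:
    from .parcellation import dilate_mask  # local: parcellation imports nothing from here

    shape = spec.grid_shape
    vs = spec.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -(np.asarray(shape, dtype=np.float64) - 1.0) / 2.0 * vs
    ijk = np.indices(shape).reshape(3, -1).T
    world = ijk @ affine[:3, :3].T + affine[:3, 3]
    mirrored = np.abs(world) * [1, 0, 0] + world * [0, 1, 1]  # |x|, y, z

    def in_ellipsoid(center, semi):
        return (((mirrored - center) / semi) ** 2).sum(axis=1) <= 1.0

    sub = np.zeros(len(world), dtype=np.int8)
    sub[in_ellipsoid(_NAC_CENTER, np.full(3, _NAC_RADIUS))] = NAC
    sub[in_ellipsoid(_PUTAMEN_CENTER, _PUTAMEN_SEMI)] = PUTAMEN
    sub[in_ellipsoid(_CAUDATE_CENTER, _CAUDATE_SEMI)] = CAUDATE
    substructure = sub.reshape(shape)
    striatum = substructure > 0
    if not striatum.any():
        raise GeometryError("grid does not contain the striatal mask")
    if striatum[0].any() or striatum[-1].any():
        raise GeometryError("striatal mask touches the grid boundary")
    analysis = dilate_mask(striatum, spec.dilation_level)
    return VolumeModel(shape=shape, affine=affine, mask=analysis, substructure=substructure)


def _caudate_zones(
    world: np.ndarray, hemi: np.ndarray, is_caudate: np.ndarray, plan: dict[str, float]
) -> np.ndarray:
    """Weighted-nearest-anchor partition of the caudate into the five
    association-network zones; laterality-plan ratios scale zone reach."""
    coupling = np.zeros(len(world), dtype=np.int16)
    ratios = {NETWORK_IDS[k]: float(v) for k, v in plan.items()}
    nets = sorted(_CAUDATE_ANCHORS)
    for h in (LEFT, RIGHT):
        sel = np.flatnonzero(is_caudate & (hemi == h))
        if len(sel) == 0:
            continue
        pts = world[sel].copy()
        pts[:, 0] = np.abs(pts[:, 0])
        cost = np.empty((len(nets), len(sel)))
        for row, net in enumerate(nets):
            rho = ratios.get(net, 1.0)
            w = np.sqrt(rho) if h == LEFT else 1.0 / np.sqrt(rho)
            cost[row] = np.linalg.norm(pts - _CAUDATE_ANCHORS[net], axis=1) / w
        coupling[sel] = np.asarray(nets, dtype=np.int16)[np.argmin(cost, axis=0)]
    return coupling


def _putamen_zones(world: np.ndarray, hemi: np.ndarray, is_putamen: np.ndarray) -> np.ndarray:
    """Tertiles of a dorsolateral->ventromedial score: foot, hand, tongue."""
    zone = np.full(len(world), -1, dtype=np.int8)
    for h in (LEFT, RIGHT):
        sel = np.flatnonzero(is_putamen & (hemi == h))
        if len(sel) == 0:
            continue
        p = world[sel]
        score = (p[:, 2] - _PUTAMEN_CENTER[2]) / _PUTAMEN_SEMI[2] + (
            np.abs(p[:, 0]) - _PUTAMEN_CENTER[0]
        ) / _PUTAMEN_SEMI[0]
        ranks = np.argsort(np.argsort(-score, kind="stable"), kind="stable")
        zone[sel] = np.minimum(2, (3 * ranks) // len(sel)).astype(np.int8)
    return zone


# ---------------------------------------------------------------------------
# public operations


def build_phantom_geometry(
    spec: PhantomSpec,
) -> tuple[SurfaceModel, VolumeModel, PhantomTruth]:
    """Deterministically construct surface, volume, and ground truth."""
    meshes = {h: _hemisphere_mesh(spec.n_vertices_per_hemi, h) for h in (LEFT, RIGHT)}
    verts = np.vstack([meshes[LEFT][0], meshes[RIGHT][0]])
    faces = np.vstack(
        [meshes[LEFT][1], meshes[RIGHT][1] + spec.n_vertices_per_hemi]
    )
    hemi = np.repeat([LEFT, RIGHT], spec.n_vertices_per_hemi).astype(np.int8)
    unit_by_hemi = {LEFT: meshes[LEFT][2], RIGHT: meshes[RIGHT][2]}
    medial = np.concatenate(
        [unit_by_hemi[h] @ _MEDIAL_WALL_DIR > _MEDIAL_WALL_COS for h in (LEFT, RIGHT)]
    )
    surface = SurfaceModel(vertices=verts, faces=faces, hemi=hemi, medial_wall=medial)

    n_left = int((~medial[: spec.n_vertices_per_hemi]).sum())
    n_right = int((~medial[spec.n_vertices_per_hemi :]).sum())
    caps = _network_capacities(n_left, n_right, spec.laterality_plan)
    labels = _grow_labels(surface, unit_by_hemi, caps)
    vertex_zone, zone_patches = _somatomotor_patches(surface, labels)

    volume = _build_volume(spec)
    vox_ijk = volume.voxel_indices
    world = volume.world_coords()
    hemi_vox = volume.voxel_hemi()
    sub = volume.substructure_of()

    coupling = np.zeros(volume.n_voxels, dtype=np.int16)
    coupling[sub == PUTAMEN] = NETWORK_IDS["SMOT-A"]
    coupling[sub == NAC] = NETWORK_IDS["SAL/PMN"]
    coupling = np.where(
        sub == CAUDATE,
        _caudate_zones(world, hemi_vox, sub == CAUDATE, spec.laterality_plan),
        coupling,
    )
    voxel_zone = _putamen_zones(world, hemi_vox, sub == PUTAMEN)

    # dropout: mirrored sphere around the ventral striatum / NAc
    center = np.asarray(spec.dropout_center, dtype=np.float64)
    mirrored = np.abs(world) * [1, 0, 0] + world * [0, 1, 1]
    dropout_mask = (
        np.linalg.norm(mirrored - np.abs(center) * [1, 0, 0] - center * [0, 1, 1], axis=1)
        <= spec.dropout_radius_mm
    )
    dropout_voxels = np.flatnonzero(dropout_mask & (sub > 0))

    loadings = (coupling > 0).astype(np.float64)
    loadings[dropout_voxels] *= _DROPOUT_ATTENUATION

    # cortical bleed: Gaussian of the distance to the nearest cortical vertex
    tree = cKDTree(surface.vertices)
    dist, nearest = tree.query(world)
    bleed = np.zeros(volume.n_voxels)
    if spec.bleed_fwhm_mm > 0:
        sigma = spec.bleed_fwhm_mm * FWHM_TO_SIGMA
        inside = dist <= 2.0 * spec.bleed_fwhm_mm
        bleed[inside] = np.exp(-0.5 * (dist[inside] / sigma) ** 2)

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), 0]))
    vertex_baseline = _BASELINE_MEAN * (1.0 + _BASELINE_CV * rng.standard_normal(len(verts)))
    voxel_baseline = _BASELINE_MEAN * (
        1.0 + _BASELINE_CV * rng.standard_normal(volume.n_voxels)
    )
    voxel_baseline[dropout_voxels] *= _DROPOUT_BASELINE_FACTOR

    zone_voxels = {
        name: np.flatnonzero(voxel_zone == zi) for zi, name in enumerate(_ZONE_NAMES)
    }
    somatomotor_zones = {
        name: {
            "voxels": zone_voxels[name],
            "vertices": zone_patches[name],
            "network": NETWORK_IDS["SMOT-A"],
        }
        for name in _ZONE_NAMES
    }

    vertex_loadings = (~medial).astype(np.float64)
    truth = PhantomTruth(
        vertex_labels=NetworkLabelMap(labels),
        vertex_zone=vertex_zone,
        vertex_loadings=vertex_loadings,
        voxel_coupling=coupling,
        voxel_zone=voxel_zone,
        voxel_loadings=loadings,
        dropout_voxels=dropout_voxels,
        somatomotor_zones=somatomotor_zones,
        bleed_weight=bleed,
        bleed_source=nearest.astype(np.int64),
        surface_distance_mm=dist,
        vertex_baseline=vertex_baseline,
        voxel_baseline=voxel_baseline,
    )
    caudate_nets = set(np.unique(coupling[sub == CAUDATE])) - {0}
    if not set(ASSOCIATION_NETWORKS) <= caudate_nets:  # pragma: no cover
        raise GeometryError("caudate zone layout lost an association network")
    _ = vox_ijk  # voxel ordering fixed by VolumeModel.voxel_indices
    return surface, volume, truth


def derive_run_seed(master_seed: int, subject: int, run: int) -> int:
    """Documented seed-derivation rule: one stream per (subject, run)."""
    ss = np.random.SeedSequence([int(master_seed), int(subject), int(run)])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def _band_limited(rng: np.random.Generator, n: int, t_full: int, spec: PhantomSpec) -> np.ndarray:
    """White series band-passed to the analysis band, unit SD after trimming."""
    raw = rng.standard_normal((n, t_full))
    filtered = bandpass_array(raw, spec.tr_s, 0.01, 0.10)
    kept = filtered[:, spec.frames_dropped :]
    kept = kept - kept.mean(axis=1, keepdims=True)
    sd = kept.std(axis=1, ddof=0)
    return kept / np.where(sd == 0, 1.0, sd)[:, None]


def simulate_run(
    truth: PhantomTruth, spec: PhantomSpec, run_seed: int, run_id: int = 0
) -> RunData:
    """One run of synthetic BOLD with the planted coupling structure.

    Each location's series is loading x (band-limited latent of its coupled
    network, mixed 50/50 with a somatomotor zone latent where applicable)
    + shared nuisance components + independent Gaussian noise.  Near-surface
    striatal voxels additionally receive a Gaussian-weighted copy of their
    nearest cortical vertex's clean signal (the bleed model); dropout voxels
    have coupling attenuated by 98% and doubled noise.  The first
    ``frames_dropped`` frames are already removed.
    """
    if spec.snr_cortex < 0 or spec.snr_striatum < 0:
        raise ValueError("snr must be non-negative")
    labels = truth.vertex_labels.labels
    if len(labels) != len(truth.vertex_loadings):
        raise ValueError("truth arrays are inconsistent")
    rng = np.random.default_rng(np.random.SeedSequence([int(run_seed)]))
    t_full, t_kept = spec.frames_per_run, spec.n_frames_kept

    latents = _band_limited(rng, 15, t_full, spec)  # row net-1
    zone_latents = _band_limited(rng, 3, t_full, spec)
    tissue = _band_limited(rng, 2, t_full, spec)  # ventricle, white matter
    motion = np.cumsum(0.05 * rng.standard_normal((6, t_full)), axis=1)
    motion = motion[:, spec.frames_dropped :]
    motion = motion - motion.mean(axis=1, keepdims=True)
    sd = motion.std(axis=1, ddof=0)
    motion = motion / np.where(sd == 0, 1.0, sd)[:, None]

    inv_sqrt2 = 1.0 / np.sqrt(2.0)

    def clean_mix(net_ids: np.ndarray, zones: np.ndarray) -> np.ndarray:
        out = np.zeros((len(net_ids), t_kept))
        coupled = net_ids > 0
        out[coupled] = latents[net_ids[coupled] - 1]
        zoned = zones >= 0
        out[zoned] = inv_sqrt2 * (out[zoned] + zone_latents[zones[zoned]])
        return out

    cortex_clean = spec.snr_cortex * truth.vertex_loadings[:, None] * clean_mix(
        labels.astype(np.int64), truth.vertex_zone
    )
    voxel_clean = spec.snr_striatum * truth.voxel_loadings[:, None] * clean_mix(
        truth.voxel_coupling.astype(np.int64), truth.voxel_zone
    )
    # cortical signal bleed into near-surface voxels
    has_bleed = truth.bleed_weight > 0
    if has_bleed.any():
        src = truth.bleed_source[has_bleed]
        voxel_clean[has_bleed] += truth.bleed_weight[has_bleed, None] * cortex_clean[src]

    n_vert, n_vox = len(labels), len(truth.voxel_coupling)
    tissue_load_c = _TISSUE_LOADING_SD * rng.standard_normal((n_vert, 2))
    tissue_load_v = _TISSUE_LOADING_SD * rng.standard_normal((n_vox, 2))
    motion_load_c = _MOTION_LOADING_SD * rng.standard_normal((n_vert, 6))
    motion_load_v = _MOTION_LOADING_SD * rng.standard_normal((n_vox, 6))

    noise_c = rng.standard_normal((n_vert, t_kept))
    noise_v = rng.standard_normal((n_vox, t_kept))
    noise_scale = np.ones(n_vox)
    noise_scale[truth.dropout_voxels] = _DROPOUT_NOISE_FACTOR

    cortex_ts = (
        truth.vertex_baseline[:, None]
        + cortex_clean
        + tissue_load_c @ tissue
        + motion_load_c @ motion
        + noise_c
    )
    striatum_ts = (
        truth.voxel_baseline[:, None]
        + voxel_clean
        + tissue_load_v @ tissue
        + motion_load_v @ motion
        + noise_scale[:, None] * noise_v
    )

    # whole-brain regressor: mean over the union of cortex + striatum series
    whole_brain = np.vstack([cortex_ts, striatum_ts]).mean(axis=0, keepdims=True)
    base = np.vstack([motion, whole_brain, tissue])
    base = base - base.mean(axis=1, keepdims=True)
    deriv = np.diff(base, axis=1, prepend=base[:, :1])  # backward diff, first = 0
    nuisance = np.vstack([base, deriv])
    nuisance = nuisance - nuisance.mean(axis=1, keepdims=True)

    return RunData(
        cortex_ts=cortex_ts,
        striatum_ts=striatum_ts,
        nuisance=nuisance,
        tr_s=spec.tr_s,
        run_id=run_id,
    )


def simulate_bundle(spec: PhantomSpec, subject: int = 0) -> PhantomBundle:
    """Geometry + ``spec.n_runs`` simulated runs, all from the master seed."""
    surface, volume, truth = build_phantom_geometry(spec)
    runs = [
        simulate_run(truth, spec, derive_run_seed(spec.rng_seed, subject, r), run_id=r)
        for r in range(spec.n_runs)
    ]
    return PhantomBundle(spec=spec, surface=surface, volume=volume, truth=truth, runs=runs)


# ---------------------------------------------------------------------------
# disk round trip


def write_phantom(bundle: PhantomBundle, directory, create: bool = True) -> Path:
    """Write the bundle: NIfTI volumes, GIFTI surface data, TSV truth tables."""
    directory = Path(directory)
    if not directory.exists():
        if not create:
            raise FileNotFoundError(f"output directory {directory} does not exist")
        directory.mkdir(parents=True)
    vol = bundle.volume
    smio.save_nifti(directory / "analysis_mask.nii.gz", vol.mask.astype(np.int16), vol.affine)
    smio.save_nifti(directory / "substructure.nii.gz", vol.substructure, vol.affine, np.int16)
    surf = bundle.surface
    n_hemi = bundle.spec.n_vertices_per_hemi
    for h, tag in ((LEFT, "lh"), (RIGHT, "rh")):
        sel = slice(h * n_hemi, (h + 1) * n_hemi)
        faces = surf.faces[surf.hemi[surf.faces[:, 0]] == h] - h * n_hemi
        smio.save_gifti_mesh(directory / f"{tag}.surf.gii", surf.vertices[sel], faces)
        smio.save_gifti_data(
            directory / f"{tag}.labels.gii", bundle.truth.vertex_labels.labels[sel], labels=True
        )
    for run in bundle.runs:
        grid = np.zeros(vol.shape + (run.n_frames,))
        idx = vol.voxel_indices
        grid[idx[:, 0], idx[:, 1], idx[:, 2]] = run.striatum_ts
        smio.save_nifti(directory / f"run-{run.run_id:03d}_striatum.nii.gz", grid, vol.affine)
        for h, tag in ((LEFT, "lh"), (RIGHT, "rh")):
            sel = slice(h * n_hemi, (h + 1) * n_hemi)
            smio.save_gifti_data(
                directory / f"run-{run.run_id:03d}_{tag}.func.gii", run.cortex_ts[sel]
            )
        smio.save_tsv(
            directory / f"run-{run.run_id:03d}_nuisance.tsv",
            pd.DataFrame(run.nuisance.T, columns=[f"nuis_{i}" for i in range(18)]),
        )
    t = bundle.truth
    voxel_table = pd.DataFrame(
        {
            "i": vol.voxel_indices[:, 0],
            "j": vol.voxel_indices[:, 1],
            "k": vol.voxel_indices[:, 2],
            "substructure": vol.substructure_of(),
            "coupling": t.voxel_coupling,
            "zone": t.voxel_zone,
            "loading": t.voxel_loadings,
            "dropout": np.isin(np.arange(vol.n_voxels), t.dropout_voxels).astype(int),
            "bleed_weight": t.bleed_weight,
            "bleed_source": t.bleed_source,
            "surface_distance_mm": t.surface_distance_mm,
            "baseline": t.voxel_baseline,
        }
    )
    smio.save_tsv(directory / "truth_voxels.tsv", voxel_table)
    vertex_table = pd.DataFrame(
        {
            "vertex": np.arange(surf.n_vertices),
            "hemi": surf.hemi,
            "label": t.vertex_labels.labels,
            "zone": t.vertex_zone,
            "loading": t.vertex_loadings,
            "medial_wall": surf.medial_wall.astype(int),
            "baseline": t.vertex_baseline,
        }
    )
    smio.save_tsv(directory / "truth_vertices.tsv", vertex_table)
    (directory / "phantom_spec.yaml").write_text(yaml.safe_dump(bundle.spec.to_dict()))
    return directory


def read_phantom(directory) -> PhantomBundle:
    """Re-read a written bundle; inverse of :func:`write_phantom`."""
    directory = Path(directory)
    spec = PhantomSpec.from_dict(yaml.safe_load((directory / "phantom_spec.yaml").read_text()))
    mask, affine = smio.load_nifti(directory / "analysis_mask.nii.gz")
    substructure, aff2 = smio.load_nifti(directory / "substructure.nii.gz")
    smio.require_same_affine(affine, aff2, "mask/substructure")
    volume = VolumeModel(
        shape=mask.shape, affine=affine, mask=mask > 0, substructure=substructure
    )
    verts, faces, hemi = [], [], []
    offset = 0
    for h, tag in ((LEFT, "lh"), (RIGHT, "rh")):
        v, f = smio.load_gifti_mesh(directory / f"{tag}.surf.gii")
        verts.append(v)
        faces.append(f + offset)
        hemi.append(np.full(len(v), h, dtype=np.int8))
        offset += len(v)
    labels = np.concatenate(
        [smio.load_gifti_data(directory / f"{tag}.labels.gii") for tag in ("lh", "rh")]
    )
    vertex_table = smio.load_tsv(directory / "truth_vertices.tsv")
    voxel_table = smio.load_tsv(directory / "truth_voxels.tsv")
    surface = SurfaceModel(
        vertices=np.vstack(verts),
        faces=np.vstack(faces),
        hemi=np.concatenate(hemi),
        medial_wall=vertex_table["medial_wall"].to_numpy() > 0,
    )
    expected = np.argwhere(volume.mask)
    got = voxel_table[["i", "j", "k"]].to_numpy()
    if not np.array_equal(expected, got):
        raise smio.FormatError("truth_voxels.tsv rows do not match the analysis mask")
    voxel_zone = voxel_table["zone"].to_numpy().astype(np.int8)
    zone_voxels = {n: np.flatnonzero(voxel_zone == zi) for zi, n in enumerate(_ZONE_NAMES)}
    vertex_zone = vertex_table["zone"].to_numpy().astype(np.int8)
    zone_verts = {n: np.flatnonzero(vertex_zone == zi) for zi, n in enumerate(_ZONE_NAMES)}
    truth = PhantomTruth(
        vertex_labels=NetworkLabelMap(labels.astype(np.int16)),
        vertex_zone=vertex_zone,
        vertex_loadings=vertex_table["loading"].to_numpy(),
        voxel_coupling=voxel_table["coupling"].to_numpy().astype(np.int16),
        voxel_zone=voxel_zone,
        voxel_loadings=voxel_table["loading"].to_numpy(),
        dropout_voxels=np.flatnonzero(voxel_table["dropout"].to_numpy() > 0),
        somatomotor_zones={
            n: {"voxels": zone_voxels[n], "vertices": zone_verts[n], "network": NETWORK_IDS["SMOT-A"]}
            for n in _ZONE_NAMES
        },
        bleed_weight=voxel_table["bleed_weight"].to_numpy(),
        bleed_source=voxel_table["bleed_source"].to_numpy().astype(np.int64),
        surface_distance_mm=voxel_table["surface_distance_mm"].to_numpy(),
        vertex_baseline=vertex_table["baseline"].to_numpy(),
        voxel_baseline=voxel_table["baseline"].to_numpy(),
    )
    runs = []
    for r in range(spec.n_runs):
        grid, aff3 = smio.load_nifti(directory / f"run-{r:03d}_striatum.nii.gz")
        smio.require_same_affine(affine, aff3, "mask/series")
        idx = volume.voxel_indices
        striatum_ts = grid[idx[:, 0], idx[:, 1], idx[:, 2]]
        cortex_ts = np.vstack(
            [smio.load_gifti_data(directory / f"run-{r:03d}_{tag}.func.gii") for tag in ("lh", "rh")]
        )
        nuisance = smio.load_tsv(directory / f"run-{r:03d}_nuisance.tsv").to_numpy().T
        runs.append(
            RunData(
                cortex_ts=cortex_ts,
                striatum_ts=striatum_ts,
                nuisance=nuisance,
                tr_s=spec.tr_s,
                run_id=r,
            )
        )
    return PhantomBundle(spec=spec, surface=surface, volume=volume, truth=truth, runs=runs)
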