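"""Model-free seed-based correlation maps and a recapitulation score.

Seeds live either in the striatum (sphere in world mm, clipped to the
mask) or on the cortical surface (graph-hop disk within one hemisphere).
A seed's mean series is correlated per run against every target location,
Fisher-z transformed and run-averaged.  ``network_selectivity`` condenses
the qualitative check "does a caudate seed's cortical map respect the
boundaries of its network" into one number: mean z inside the target
network minus the best mean z of any other network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .connectivity import fisher_z, run_correlation
from .geometry import NetworkLabelMap, SurfaceModel, VolumeModel

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import RunData
    from .signal_processing import TsnrMap

__all__ = ["SeedRegion", "SeedMap", "make_seed", "seed_correlation_map", "network_selectivity"]

logger = logging.getLogger(__name__)


@dataclass
class SeedRegion:
    """A small set of voxels or vertices averaged into one seed series."""

    domain: str  # "striatum" | "cortex"
    center: int  # index into the domain's location axis
    radius: float  # mm (striatum) or graph hops (cortex)
    members: np.ndarray  # indices into the domain's location axis

    def __post_init__(self) -> None:
        if self.domain not in ("striatum", "cortex"):
            raise ValueError("domain must be 'striatum' or 'cortex'")
        if len(self.members) == 0:
            raise ValueError("seed has no members")


@dataclass
class SeedMap:
    """Run-averaged Fisher-z map of a seed against the opposite domain."""

    seed: SeedRegion
    values: np.ndarray
    n_runs: int


def make_seed(
    domain: str,
    center: int,
    radius: float,
    surface: SurfaceModel | None = None,
    volume: VolumeModel | None = None,
    tsnr: "TsnrMap | None" = None,
) -> SeedRegion:
    """Build a seed region around ``center`` (index into the domain's axis).

    Striatal seeds are spheres of ``radius`` mm clipped to the analysis
    mask; cortical seeds are all vertices within ``radius`` graph hops in
    the center's hemisphere.  Radius 0 yields a singleton.  If a tSNR map
    is supplied and the center is flagged or in its lowest decile, the
    seed is still created but a low-tSNR warning is logged.
    """
    if domain == "striatum":
        if volume is None:
            raise ValueError("striatal seeds need a VolumeModel")
        coords = volume.world_coords()
        if not 0 <= center < len(coords):
            raise ValueError("seed center outside the mask")
        members = np.flatnonzero(np.linalg.norm(coords - coords[center], axis=1) <= radius)
    else:
        if surface is None:
            raise ValueError("cortical seeds need a SurfaceModel")
        if not 0 <= center < surface.n_vertices:
            raise ValueError("seed center outside the surface")
        hops = surface.graph_hops_from([center])
        members = np.flatnonzero((hops <= radius) & (surface.hemi == surface.hemi[center]))
    if tsnr is not None:
        low = np.quantile(tsnr.values[~tsnr.flagged], 0.10)
        if tsnr.flagged[center] or tsnr.values[center] <= low:
            logger.warning(
                "seed center %d sits in a low-tSNR region (%.2f <= %.2f)",
                center,
                float(tsnr.values[center]),
                float(low),
            )
    return SeedRegion(domain=domain, center=int(center), radius=float(radius), members=members)


def seed_correlation_map(runs: Sequence["RunData"], seed: SeedRegion) -> SeedMap:
    """Mean-member seed series -> per-run Pearson r to every target location
    in the opposite domain -> Fisher z -> run average."""
    if len(runs) == 0:
        raise ValueError("need at least one run")
    source_attr, target_attr = (
        ("striatum_ts", "cortex_ts") if seed.domain == "striatum" else ("cortex_ts", "striatum_ts")
    )
    zs = []
    for run in runs:
        seed_series = getattr(run, source_attr)[seed.members].mean(axis=0, keepdims=True)
        if seed_series.std() == 0:
            raise ValueError("zero-variance seed series")
        r, _, _ = run_correlation(seed_series, getattr(run, target_attr))
        zs.append(fisher_z(r[0]))
    return SeedMap(seed=seed, values=np.mean(zs, axis=0), n_runs=len(runs))


def network_selectivity(
    seed_map: SeedMap, labels: NetworkLabelMap, target_network: int
) -> float:
    """mean z within the target network minus the best other network's mean z.

    Positive scores mean the map recapitulates the target network; the map
    must be cortical (per-vertex) so the label map applies.
    """
    values = seed_map.values
    if labels.n_vertices != len(values):
        raise ValueError("label map does not cover the seed map domain")
    present = labels.present_networks()
    if target_network not in present:
        raise ValueError(f"target network {target_network} absent from labels")
    target_mean = float(values[labels.labels == target_network].mean())
    others = [float(values[labels.labels == n].mean()) for n in present if n != target_network]
    return target_mean - max(others)
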