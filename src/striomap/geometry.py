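"""Core spatial containers: cortical surface, striatal volume, network labels.

The package works on two sampling domains that mirror a precision fMRI
analysis: a triangulated two-hemisphere cortical surface (vertices in world
millimeters) and a 3-D voxel grid with an affine holding binary striatal
masks (caudate / putamen / nucleus accumbens).  A ``NetworkLabelMap`` carries
the per-vertex assignment of the cortex to a 15-network taxonomy; it is the
voting target of the winner-takes-all striatal parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "NETWORK_NAMES",
    "NETWORK_IDS",
    "ASSOCIATION_NETWORKS",
    "UNASSIGNED",
    "LEFT",
    "RIGHT",
    "SurfaceModel",
    "VolumeModel",
    "NetworkLabelMap",
]

#: 15-network cortical taxonomy. 0 is reserved for "no label" (medial wall on
#: the surface, and the UNASSIGNED state in striatal parcellations).
NETWORK_NAMES: dict[int, str] = {
    1: "VIS-C",
    2: "VIS-P",
    3: "SMOT-A",
    4: "SMOT-B",
    5: "PM-PPr",
    6: "CG-OP",
    7: "SAL/PMN",
    8: "dATN-A",
    9: "dATN-B",
    10: "AUD",
    11: "FPN-A",
    12: "FPN-B",
    13: "LANG",
    14: "DN-B",
    15: "DN-A",
}
NETWORK_IDS: dict[str, int] = {v: k for k, v in NETWORK_NAMES.items()}

#: The five higher-order association networks that form supra-areal
#: association megaclusters (SAAMs) in cortex and side-by-side zones in the
#: caudate.
ASSOCIATION_NETWORKS: tuple[int, ...] = (
    NETWORK_IDS["FPN-A"],
    NETWORK_IDS["FPN-B"],
    NETWORK_IDS["LANG"],
    NETWORK_IDS["DN-B"],
    NETWORK_IDS["DN-A"],
)

UNASSIGNED: int = 0

LEFT, RIGHT = 0, 1
HEMI_NAMES = {LEFT: "L", RIGHT: "R"}

# striatal substructure codes in VolumeModel.substructure
SUBSTRUCTURE_NAMES = {0: "none", 1: "caudate", 2: "putamen", 3: "NAc"}
CAUDATE, PUTAMEN, NAC = 1, 2, 3


class GeometryError(ValueError):
    """Inconsistent surface/volume geometry (mask outside grid, bad affine...)."""


@dataclass
class SurfaceModel:
    """Two-hemisphere triangulated mesh in world millimeters.

    Vertices of both hemispheres are concatenated; ``hemi`` gives 0 (left)
    or 1 (right) per vertex, and ``medial_wall`` marks vertices excluded
    from network labeling.  Hemispheres share no edges: graph operations
    (smoothing, geodesics, region growing) never mix them.
    """

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int, indices into vertices
    hemi: np.ndarray  # (n,) int8, LEFT/RIGHT
    medial_wall: np.ndarray = field(default=None)  # (n,) bool

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.hemi = np.asarray(self.hemi, dtype=np.int8)
        if self.medial_wall is None:
            self.medial_wall = np.zeros(len(self.vertices), dtype=bool)
        self.medial_wall = np.asarray(self.medial_wall, dtype=bool)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if len(self.hemi) != len(self.vertices):
            raise GeometryError("hemi length must match vertex count")
        fh = self.hemi[self.faces]
        if np.any(fh.min(axis=1) != fh.max(axis=1)):
            raise GeometryError("faces must not span hemispheres")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @cached_property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric binary vertex adjacency from the face list."""
        i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
        j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
        n = self.n_vertices
        a = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
        a = ((a + a.T) > 0).astype(np.float64)
        return a.tocsr()

    @cached_property
    def edge_lengths(self) -> sparse.csr_matrix:
        """Adjacency weighted by Euclidean edge length (mm)."""
        a = self.adjacency.tocoo()
        d = np.linalg.norm(self.vertices[a.row] - self.vertices[a.col], axis=1)
        return sparse.csr_matrix((d, (a.row, a.col)), shape=a.shape)

    def geodesic_from(self, sources: np.ndarray | list[int]) -> np.ndarray:
        """Edge-length-weighted shortest-path distance from a source set (mm)."""
        return dijkstra(self.edge_lengths, directed=False, indices=sources, min_only=True)

    def graph_hops_from(self, sources: np.ndarray | list[int]) -> np.ndarray:
        return dijkstra(self.adjacency, directed=False, indices=sources, min_only=True)

    def hemisphere_components(self) -> int:
        """Number of connected mesh components (expected: one per hemisphere)."""
        n, _ = connected_components(self.adjacency, directed=False)
        return n


@dataclass
class VolumeModel:
    """Voxel grid with an affine and striatal masks.

    ``affine`` maps 0-based voxel indices (i, j, k, 1) to world millimeters
    (RAS: +x right).  ``mask`` is the analysis mask (possibly dilated);
    ``substructure`` labels voxels of the undilated anatomy as caudate (1),
    putamen (2) or NAc (3), 0 elsewhere.  Voxel hemisphere follows the sign
    of world x (negative = left).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4)
    mask: np.ndarray  # (X, Y, Z) bool
    substructure: np.ndarray = field(default=None)  # (X, Y, Z) int8

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise GeometryError(
                f"mask shape {self.mask.shape} does not match grid {self.shape}"
            )
        if self.substructure is None:
            self.substructure = np.zeros(self.shape, dtype=np.int8)
        self.substructure = np.asarray(self.substructure, dtype=np.int8)
        if self.substructure.shape != self.shape:
            raise GeometryError("substructure shape does not match grid")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @cached_property
    def voxel_indices(self) -> np.ndarray:
        """(K, 3) integer indices of in-mask voxels in C order.

        This ordering defines the voxel axis of every downstream matrix
        (time series, connectivity, parcellation provenance).
        """
        return np.argwhere(self.mask)

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    def world_coords(self, ijk: np.ndarray | None = None) -> np.ndarray:
        """World-mm coordinates of voxel indices (defaults to in-mask voxels)."""
        if ijk is None:
            ijk = self.voxel_indices
        ijk = np.asarray(ijk, dtype=np.float64)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_hemi(self, ijk: np.ndarray | None = None) -> np.ndarray:
        """LEFT where world x < 0 else RIGHT (MNI convention)."""
        x = self.world_coords(ijk)[:, 0]
        return np.where(x < 0, LEFT, RIGHT).astype(np.int8)

    def substructure_of(self, ijk: np.ndarray | None = None) -> np.ndarray:
        if ijk is None:
            ijk = self.voxel_indices
        return self.substructure[ijk[:, 0], ijk[:, 1], ijk[:, 2]]


@dataclass
class NetworkLabelMap:
    """Per-vertex integer network label; 0 marks unlabeled (medial wall)."""

    labels: np.ndarray  # (n_vertices,) int16
    names: dict[int, str] = field(default_factory=lambda: dict(NETWORK_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        bad = set(np.unique(self.labels)) - set(self.names) - {0}
        if bad:
            raise GeometryError(f"labels outside taxonomy: {sorted(bad)}")

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    def vertices_of(self, network: int) -> np.ndarray:
        return np.flatnonzero(self.labels == network)

    def present_networks(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u != 0]
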