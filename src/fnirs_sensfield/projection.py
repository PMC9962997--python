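"""Voxel-to-surface mapping and on-surface smoothing.

Voxel sensitivities live on the grey-matter ribbon; analyses live on the
pial mesh. The projection assigns every GM voxel to exactly one pial
vertex by a multi-source breadth-first flood over the 26-connected GM
voxel graph seeded at each vertex's nearest GM voxel — a Voronoi
partition under geodesic-within-GM distance, which carries sulcal-wall
sensitivity to the correct bank instead of jumping across the sulcus.
Vertex values are the volume-weighted mean of their cell, so projection
conserves volume-weighted mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .optics import GM
from .phantom import SurfaceMesh, VoxelHeadModel


@dataclass
class CorticalMap:
    values: np.ndarray  # one scalar per pial vertex
    kind: str = "sensitivity_row"  # or "total_sensitivity", "activation"
    wavelength_nm: int | None = None


class VoronoiProjector:
    """Precomputed GM-voxel -> pial-vertex Voronoi assignment.

    ``empty_vertices`` flags pial vertices that own no GM voxel (their
    projected value is 0); ties in the flood go to the lower vertex
    index for reproducibility.
    """

    def __init__(self, head: VoxelHeadModel, pial: SurfaceMesh):
        self.head = head
        self.n_vertices = pial.n_vertices
        gm = head.labels == GM
        self.gm_mask = gm
        gm_idx = np.argwhere(gm)
        if len(gm_idx) == 0:
            raise ValueError("head model has no grey-matter voxels")
        # map each pial vertex to its nearest GM voxel (seed)
        centers = head.voxel_center_mm(gm_idx)
        tree = cKDTree(centers)
        _, seed_of_vertex = tree.query(pial.vertices)
        self.seed_of_vertex = seed_of_vertex
        # owner of each GM voxel, flooded outward from the seeds
        owner = np.full(len(gm_idx), -1, dtype=np.int64)
        # lower vertex index wins a shared seed voxel
        for v in range(self.n_vertices - 1, -1, -1):
            owner[seed_of_vertex[v]] = v
        lin = np.full(head.shape, -1, dtype=np.int64)
        lin[tuple(gm_idx.T)] = np.arange(len(gm_idx))
        shifts = [(dx, dy, dz)
                  for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                  if (dx, dy, dz) != (0, 0, 0)]
        frontier = np.flatnonzero(owner >= 0)
        while frontier.size:
            nxt = []
            coords = gm_idx[frontier]
            for dx, dy, dz in shifts:
                nb = coords + np.array([dx, dy, dz])
                ok = np.all((nb >= 0) & (nb < np.array(head.shape)), axis=1)
                nb_lin = lin[tuple(nb[ok].T)]
                src = frontier[ok]
                valid = nb_lin >= 0
                nb_lin = nb_lin[valid]
                src = src[valid]
                unclaimed = owner[nb_lin] < 0
                nb_lin = nb_lin[unclaimed]
                src = src[unclaimed]
                if nb_lin.size:
                    # lowest owner index wins simultaneous claims
                    order = np.argsort(owner[src], kind="stable")[::-1]
                    owner[nb_lin[order]] = owner[src[order]]
                    nxt.append(nb_lin)
            frontier = np.unique(np.concatenate(nxt)) if nxt else np.empty(0, np.int64)
        self.gm_lin_index = gm_idx
        self.owner = owner
        counts = np.bincount(owner[owner >= 0], minlength=self.n_vertices)
        self.cell_voxel_counts = counts
        self.empty_vertices = counts == 0
        self.voxel_volume = head.voxel_size_mm ** 3

    def project(self, voxel_values: np.ndarray,
                fill_empty: bool = False) -> np.ndarray:
        """Volume-weighted mean of each Voronoi cell; empty cells -> 0.

        With ``fill_empty`` a vertex that owns no cell (possible when
        the mesh is denser than the GM ribbon) borrows the value of its
        nearest GM voxel's owner instead of 0. Cells stay zero-volume,
        so mass conservation is unaffected.
        """
        vals = np.asarray(voxel_values)[tuple(self.gm_lin_index.T)]
        keep = self.owner >= 0
        sums = np.bincount(self.owner[keep], weights=vals[keep],
                           minlength=self.n_vertices)
        out = np.zeros(self.n_vertices)
        nz = self.cell_voxel_counts > 0
        out[nz] = sums[nz] / self.cell_voxel_counts[nz]
        if fill_empty and np.any(self.empty_vertices):
            donor = self.owner[self.seed_of_vertex[self.empty_vertices]]
            out[self.empty_vertices] = out[donor]
        return out

    def cell_volumes(self) -> np.ndarray:
        return self.cell_voxel_counts * self.voxel_volume


def voronoi_project(voxel_values: np.ndarray, head: VoxelHeadModel,
                    pial: SurfaceMesh, kind: str = "sensitivity_row") -> CorticalMap:
    proj = VoronoiProjector(head, pial)
    return CorticalMap(values=proj.project(voxel_values), kind=kind)


class GaussianMeshSmoother:
    """Geodesic Gaussian smoothing on a surface mesh.

    Kernel rows are normalized to sum to one, so uniform fields are
    fixed points; fwhm_mm = 0 is the identity. Geodesic distances are
    shortest paths over mesh edges (Dijkstra), so disconnected
    components are smoothed independently.
    """

    def __init__(self, mesh: SurfaceMesh, fwhm_mm: float, cutoff_sigmas: float = 3.0):
        if fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        self.fwhm_mm = fwhm_mm
        n = mesh.n_vertices
        if fwhm_mm == 0:
            self.kernel = sparse.identity(n, format="csr")
            return
        sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        limit = cutoff_sigmas * sigma
        v, f = mesh.vertices, mesh.faces
        edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        lengths = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
        graph = sparse.csr_matrix((lengths, (edges[:, 0], edges[:, 1])), shape=(n, n))
        graph = graph.maximum(graph.T)
        dist = dijkstra(graph, directed=False, limit=limit)
        with np.errstate(over="ignore"):
            k = np.exp(-0.5 * (dist / sigma) ** 2)
        k[~np.isfinite(dist)] = 0.0
        np.fill_diagonal(k, 1.0)
        k /= k.sum(axis=1, keepdims=True)
        self.kernel = sparse.csr_matrix(k)

    def smooth(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(self.kernel @ np.asarray(values, dtype=float))


def mesh_gaussian_smooth(cmap: CorticalMap, pial: SurfaceMesh,
                         fwhm_mm: float) -> CorticalMap:
    sm = GaussianMeshSmoother(pial, fwhm_mm)
    return CorticalMap(values=sm.smooth(cmap.values), kind=cmap.kind,
                       wavelength_nm=cmap.wavelength_nm)


def total_sensitivity(A) -> CorticalMap:
    """Column sums of the sensitivity matrix: per-vertex total
    sensitivity over all channels."""
    mat = A.A if hasattr(A, "A") and not isinstance(A, np.ndarray) else np.asarray(A)
    wl = getattr(A, "wavelength_nm", None)
    return CorticalMap(values=np.asarray(mat).sum(axis=0),
                       kind="total_sensitivity", wavelength_nm=wl)


def normalized_log10(cmap: CorticalMap, floor_ratio: float = 1e-2) -> np.ndarray:
    """Rendering values: log10 of the map normalized to its maximum,
    floored at ``floor_ratio`` of the maximum (display only)."""
    v = np.asarray(cmap.values, dtype=float)
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("map has no positive values to render")
    return np.log10(np.clip(v / vmax, floor_ratio, None))
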