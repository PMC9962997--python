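"""Parametric sulcogyral head phantoms.

A phantom is a flat "head patch": a stack of scalp, skull and CSF layers
above a grey-matter ribbon that follows a sinusoidal sulcogyral
corrugation, with white matter underneath and air above. The geometry is
a stand-in for MRI-derived subject anatomy that preserves the quantities
the sensitivity analysis measures — scalp-to-cortex depth and its
gyral/sulcal modulation — while keeping Monte Carlo transport desk-scale.

Axes: x, y lateral (mm), z depth (mm, increasing into the head). The
scalp outer surface sits at z = 0; voxel centers at (i + 1/2) * h - air.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .optics import BACKGROUND, CSF, GM, SCALP, SKULL, WM


@dataclass
class Variability:
    """Per-subject anatomical jitter scales for cohort generation.

    All zero means every cohort member is bit-identical to the base
    phantom. ``phase_sd_rad`` jitters the corrugation phase (a value of
    ~pi effectively decorrelates the sulcal pattern across subjects).
    """

    thickness_sd_mm: float = 0.0
    sulcal_depth_sd_mm: float = 0.0
    phase_sd_rad: float = 0.0


@dataclass
class PhantomParams:
    grid_shape: tuple[int, int, int] = (50, 50, 26)
    voxel_size_mm: float = 2.0
    layer_thickness_mm: tuple[float, float, float] = (5.0, 6.0, 2.0)  # scalp, skull, CSF
    gyral_wavelength_mm: float = 20.0
    sulcal_depth_mm: float = 8.0
    gm_thickness_mm: float = 3.0
    corrugation_phase: tuple[float, float] = (0.0, 0.0)
    air_mm: float = 4.0
    variability: Variability = field(default_factory=Variability)
    seed: int = 0

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if any(t <= 0 for t in self.layer_thickness_mm):
            raise ValueError("layer thicknesses must be > 0")
        if self.gyral_wavelength_mm <= 0 or self.gm_thickness_mm <= 0:
            raise ValueError("gyral wavelength and GM thickness must be > 0")
        if self.sulcal_depth_mm < 0:
            raise ValueError("sulcal_depth_mm must be >= 0")
        depth_mm = self.grid_shape[2] * self.voxel_size_mm - self.air_mm
        needed = sum(self.layer_thickness_mm) + self.sulcal_depth_mm + self.gm_thickness_mm
        if needed >= depth_mm:
            raise ValueError(
                f"layers need {needed:.1f} mm but the grid provides only "
                f"{depth_mm:.1f} mm below the scalp surface; enlarge "
                "grid_shape[2] or shrink the layers")

    @property
    def crown_depth_mm(self) -> float:
        """Depth of the shallowest pial point (gyral crown)."""
        return float(sum(self.layer_thickness_mm))


@dataclass
class VoxelHeadModel:
    """Labelled tissue grid: 0 air, 1 scalp, 2 skull, 3 CSF, 4 GM, 5 WM."""

    labels: np.ndarray  # int8, shape grid_shape
    voxel_size_mm: float
    affine: np.ndarray  # 4x4 voxel-index -> mm (voxel centers)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_center_mm(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        return (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    role: str  # "scalp" or "pial"

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def pial_depth_function(params: PhantomParams,
                        phase: tuple[float, float] | None = None):
    """Closed-form pial (GM/CSF interface) depth z_p(x, y) in mm.

    z_p = crown + (a/2) * (1 + sin(2 pi x / L + px) * sin(2 pi y / L + py))
    so the peak-to-trough corrugation amplitude is exactly
    ``sulcal_depth_mm`` and the shallowest point sits at the crown depth.
    """
    if phase is None:
        phase = params.corrugation_phase
    crown = params.crown_depth_mm
    amp = params.sulcal_depth_mm
    k = 2.0 * np.pi / params.gyral_wavelength_mm
    px, py = phase

    def z_p(x, y):
        return crown + 0.5 * amp * (1.0 + np.sin(k * x + px) * np.sin(k * y + py))

    return z_p


def _extract_level_surface(depth_field: np.ndarray, z_centers: np.ndarray,
                           params: PhantomParams, role: str) -> SurfaceMesh:
    """Marching cubes on the signed level set z - z_surface(x, y)."""
    h = params.voxel_size_mm
    nx, ny, nz = params.grid_shape
    level = z_centers[None, None, :] - depth_field[:, :, None]
    verts, faces, normals, _ = marching_cubes(level, level=0.0, spacing=(h, h, h))
    # marching_cubes works in voxel-index space scaled by h; voxel centers
    # sit at (i + 1/2) h laterally and z_centers in depth
    verts = verts + np.array([0.5 * h, 0.5 * h, z_centers[0]])
    # orient faces so normals point outward (toward air, -z)
    if np.mean(normals[:, 2]) > 0:
        faces = faces[:, ::-1]
    return SurfaceMesh(vertices=verts, faces=faces.astype(np.int64), role=role)


def generate_head_phantom(params: PhantomParams
                          ) -> tuple[VoxelHeadModel, SurfaceMesh, SurfaceMesh]:
    """Build the labelled voxel grid and its scalp and pial meshes.

    Deterministic: the same params produce bit-identical grids. The pial
    mesh is extracted on the smooth corrugation level set so its vertices
    lie on the GM/CSF voxel interface to within one voxel.
    """
    nx, ny, nz = params.grid_shape
    h = params.voxel_size_mm
    ts, tk, tc = params.layer_thickness_mm

    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h - params.air_mm  # depth below scalp top

    z_p = pial_depth_function(params)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    pial_depth = z_p(xx, yy)

    zc = z[None, None, :]
    labels = np.full(params.grid_shape, BACKGROUND, dtype=np.int8)
    labels[np.broadcast_to(zc >= 0, labels.shape)] = SCALP
    labels[np.broadcast_to(zc >= ts, labels.shape)] = SKULL
    labels[np.broadcast_to(zc >= ts + tk, labels.shape)] = CSF
    pd = pial_depth[:, :, None]
    labels[np.broadcast_to(zc >= pd, labels.shape)] = GM
    labels[np.broadcast_to(zc >= pd + params.gm_thickness_mm, labels.shape)] = WM

    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = h
    affine[:3, 3] = (0.5 * h, 0.5 * h, 0.5 * h - params.air_mm)
    head = VoxelHeadModel(labels=labels, voxel_size_mm=h, affine=affine)

    scalp_mesh = _extract_level_surface(np.zeros((nx, ny)), z, params, "scalp")
    pial_mesh = _extract_level_surface(pial_depth, z, params, "pial")
    return head, scalp_mesh, pial_mesh


def homogeneous_block(shape: tuple[int, int, int], voxel_size_mm: float,
                      tissue: int = GM) -> VoxelHeadModel:
    """A uniform block of one tissue: the infinite-medium validation
    domain (sources placed well inside, boundary index-matched)."""
    labels = np.full(shape, tissue, dtype=np.int8)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size_mm
    affine[:3, 3] = 0.5 * voxel_size_mm
    return VoxelHeadModel(labels=labels, voxel_size_mm=voxel_size_mm, affine=affine)


def generate_cohort(n: int, params: PhantomParams
                    ) -> list[tuple[VoxelHeadModel, SurfaceMesh, SurfaceMesh]]:
    """Generate ``n`` phantoms with per-subject anatomical jitter.

    Subject seeds derive reproducibly from ``params.seed``; jitter scales
    come from ``params.variability``. Thickness jitter is additive
    Gaussian on each layer (floored at half a voxel), corrugation
    amplitude jitter additive Gaussian (floored at 0), phase jitter
    Gaussian in radians on both corrugation phases.
    """
    return [generate_head_phantom(p) for p in subject_params(n, params)]


def subject_params(n: int, params: PhantomParams) -> list[PhantomParams]:
    """The per-subject parameter sets generate_cohort realizes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    var = params.variability
    out = []
    for s in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, s]))
        ts, tk, tc = params.layer_thickness_mm
        floor = 0.5 * params.voxel_size_mm
        thick = tuple(
            max(floor, t + rng.normal(0.0, var.thickness_sd_mm) if var.thickness_sd_mm else t)
            for t in (ts, tk, tc))
        depth = params.sulcal_depth_mm
        if var.sulcal_depth_sd_mm:
            depth = max(0.0, depth + rng.normal(0.0, var.sulcal_depth_sd_mm))
        phase = params.corrugation_phase
        if var.phase_sd_rad:
            phase = tuple(p + rng.normal(0.0, var.phase_sd_rad) for p in phase)
        out.append(replace(params, layer_thickness_mm=thick, sulcal_depth_mm=depth,
                           corrugation_phase=phase, seed=params.seed))
    return out
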