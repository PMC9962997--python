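"""Sensitivity displacement surfaces (SDS) and depth statistics.

Each channel gets a curvilinear chart around its center: the
longitudinal axis gamma runs along the scalp from source to detector,
the transverse axis tau orthogonal to it, both sampled on a 40 x 40 mm
field with 2 x 2 mm bins. At every bin the local inward scalp normal is
cast to the pial surface, recording the scalp-to-cortex depth d and the
sensitivity of the struck cortical element. Pooling the bins of all
channels of a subject and segmenting by depth quartile (Q1 shallowest =
gyral crowns, Q4 deepest = sulcal floors) yields four SDS surfaces,
their integrals (IUS%, summing to 100), and full-width-at-half-maximum
extents along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .phantom import SurfaceMesh
from .projection import CorticalMap

#: bin centers span [-20, 20] mm on both axes in 2 mm steps
BIN_CENTERS_MM = np.arange(-20.0, 20.0 + 1e-9, 2.0)
FIELD_HALF_MM = 20.0
MAX_DEPTH_MM = 40.0


@dataclass
class ChannelFrame:
    channel_id: int
    gamma_mm: np.ndarray  # bin centers, longitudinal
    tau_mm: np.ndarray  # bin centers, transverse
    depth_mm: np.ndarray  # (n_gamma, n_tau); NaN where the ray missed
    sensitivity: np.ndarray  # (n_gamma, n_tau); NaN where missing
    missing: np.ndarray  # bool mask of missed bins


@dataclass
class SdsProfile:
    sds: np.ndarray  # (4, n_gamma, n_tau), NaN where undefined
    ius_percent: np.ndarray  # (4,), sums to 100
    depth_boundaries_mm: np.ndarray  # (3,) quartile separations
    fwhm_gamma_mm: np.ndarray  # (2,) for Q1, Q2
    fwhm_tau_mm: np.ndarray  # (2,)
    fwhm_censored: np.ndarray  # (2, 2) bool, [quartile, axis(gamma,tau)]
    subject_id: int | None = None
    wavelength_nm: int | None = None


def cast_vertical_rays(origins: np.ndarray, vertices: np.ndarray,
                       faces: np.ndarray, chunk: int = 128) -> np.ndarray:
    """First intersection depth of +z rays with a triangle mesh.

    Returns, per ray, the z coordinate of the nearest intersection with
    z >= origin z, or NaN if the ray misses. Vectorized barycentric test
    in the lateral plane; exact for the height-field surfaces used here.
    """
    tri = vertices[faces]  # (F, 3, 3)
    x1, y1, z1 = tri[:, 0, 0], tri[:, 0, 1], tri[:, 0, 2]
    x2, y2, z2 = tri[:, 1, 0], tri[:, 1, 1], tri[:, 1, 2]
    x3, y3, z3 = tri[:, 2, 0], tri[:, 2, 1], tri[:, 2, 2]
    denom = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
    ok = np.abs(denom) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, denom, 1.0), 0.0)
    out = np.full(len(origins), np.nan)
    eps = 1e-9
    for lo in range(0, len(origins), chunk):
        o = origins[lo:lo + chunk]
        px = o[:, 0][:, None]
        py = o[:, 1][:, None]
        a = ((y2 - y3) * (px - x3) + (x3 - x2) * (py - y3)) * inv
        b = ((y3 - y1) * (px - x3) + (x1 - x3) * (py - y3)) * inv
        c = 1.0 - a - b
        inside = (a >= -eps) & (b >= -eps) & (c >= -eps) & ok
        z = a * z1 + b * z2 + c * z3
        z = np.where(inside & (z >= o[:, 2][:, None] - 1e-9), z, np.inf)
        zmin = z.min(axis=1)
        out[lo:lo + chunk] = np.where(np.isfinite(zmin), zmin, np.nan)
    return out


def build_channel_frame(channel_id: int, montage, scalp: SurfaceMesh,
                        pial: SurfaceMesh, a_row,
                        max_depth_mm: float = MAX_DEPTH_MM) -> ChannelFrame:
    """Sample depth and sensitivity on the (gamma, tau) chart of one channel.

    The gamma axis follows the scalp source->detector direction through
    the channel center; rays are cast along the local inward scalp
    normal and the sensitivity of the nearest pial vertex to the first
    intersection is recorded. Bins whose ray misses cortex within
    ``max_depth_mm`` are flagged missing.
    """
    values = a_row.values if isinstance(a_row, CorticalMap) else np.asarray(a_row)
    s_idx, d_idx = montage.channels[channel_id]
    src = montage.sources[s_idx]
    det = montage.detectors[d_idx]
    cc = montage.channel_centers[channel_id]
    g_dir = det - src
    g_dir[2] = 0.0
    norm = np.linalg.norm(g_dir)
    if norm == 0:
        raise ValueError("source and detector coincide laterally")
    g_dir /= norm
    t_dir = np.array([-g_dir[1], g_dir[0], 0.0])

    scalp_tree = cKDTree(scalp.vertices)
    pial_tree = cKDTree(pial.vertices)

    ng, nt = len(BIN_CENTERS_MM), len(BIN_CENTERS_MM)
    origins = np.empty((ng * nt, 3))
    for a, ga in enumerate(BIN_CENTERS_MM):
        for b, ta in enumerate(BIN_CENTERS_MM):
            p = cc + ga * g_dir + ta * t_dir
            # snap to the scalp surface height (curvilinear chart)
            _, i = scalp_tree.query(p)
            p[2] = scalp.vertices[i, 2]
            origins[a * nt + b] = p

    hit_z = cast_vertical_rays(origins, pial.vertices, pial.faces)
    depth = np.full((ng, nt), np.nan)
    sens = np.full((ng, nt), np.nan)
    for rid in range(ng * nt):
        if not np.isfinite(hit_z[rid]):
            continue
        d = hit_z[rid] - origins[rid, 2]
        if d > max_depth_mm:
            continue
        a, b = divmod(rid, nt)
        depth[a, b] = d
        _, vi = pial_tree.query([origins[rid, 0], origins[rid, 1], hit_z[rid]])
        sens[a, b] = values[vi]
    missing = ~np.isfinite(depth)
    return ChannelFrame(channel_id=channel_id, gamma_mm=BIN_CENTERS_MM.copy(),
                        tau_mm=BIN_CENTERS_MM.copy(), depth_mm=depth,
                        sensitivity=sens, missing=missing)


def pool_depth_quartiles(frames: list[ChannelFrame]) -> np.ndarray:
    """25/50/75th percentiles (linear interpolation) of all sampled
    depths across every channel and bin of one subject."""
    depths = np.concatenate([f.depth_mm[~f.missing].ravel() for f in frames])
    if depths.size == 0:
        raise ValueError("no valid depth samples in any frame")
    return np.percentile(depths, [25.0, 50.0, 75.0])


def assign_quartile(depth, boundaries) -> np.ndarray:
    """Quartile index 1..4; depths equal to a boundary go to the lower
    quartile. Degenerate (equal) boundaries collapse onto Q1."""
    d = np.asarray(depth, dtype=float)
    b1, b2, b3 = boundaries
    q = np.full(d.shape, 4, dtype=np.int64)
    q[d <= b3] = 3
    q[d <= b2] = 2
    q[d <= b1] = 1
    q = np.where(np.isfinite(d), q, 0)  # 0 marks missing
    return q


def compute_sds(frames: list[ChannelFrame], boundaries: np.ndarray) -> np.ndarray:
    """Per-bin mean sensitivity over channels, stratified by quartile.

    Returns (4, n_gamma, n_tau); a (Q, gamma, tau) cell is NaN when no
    channel sampled that bin at that depth quartile.
    """
    ng, nt = frames[0].depth_mm.shape
    sums = np.zeros((4, ng, nt))
    counts = np.zeros((4, ng, nt), dtype=np.int64)
    for f in frames:
        q = assign_quartile(f.depth_mm, boundaries)
        for Q in (1, 2, 3, 4):
            m = q == Q
            sums[Q - 1][m] += f.sensitivity[m]
            counts[Q - 1][m] += 1
    sds = np.full((4, ng, nt), np.nan)
    nz = counts > 0
    sds[nz] = sums[nz] / counts[nz]
    return sds


def compute_ius(sds: np.ndarray, bin_area_mm2: float = 4.0) -> np.ndarray:
    """Integral under each SDS surface as a percentage of their sum."""
    ius = np.array([np.nansum(s) * bin_area_mm2 for s in sds])
    for Q in range(4):
        if not np.any(np.isfinite(sds[Q])):
            raise ValueError(f"quartile {Q + 1} has no defined bins")
    total = ius.sum()
    if total <= 0:
        raise ValueError("all-zero SDS surfaces: IUS undefined")
    return 100.0 * ius / total


def compute_fwhm(surface: np.ndarray, axis: str,
                 bin_centers: np.ndarray = BIN_CENTERS_MM,
                 ) -> tuple[float, bool]:
    """FWHM of the 1-D profile through the surface maximum.

    ``axis="gamma"`` profiles along the first array axis, ``"tau"``
    along the second. Half-maximum crossings are located by linear
    interpolation between bins and the FWHM is the distance between the
    outermost crossings. If the profile never falls below half maximum
    before the field border, the border is used and the result flagged
    censored. Missing bins count as zero sensitivity.
    """
    s = np.array(surface, dtype=float)
    s[~np.isfinite(s)] = 0.0
    if s.max() <= 0:
        raise ValueError("surface has no positive maximum")
    imax = np.unravel_index(np.argmax(s), s.shape)
    prof = s[:, imax[1]] if axis == "gamma" else s[imax[0], :]
    half = prof.max() / 2.0
    x = bin_centers
    censored = False
    above = prof >= half
    # outermost crossings: scan inward from each border
    ileft = int(np.argmax(above))  # first bin at/above half
    if ileft == 0:
        left = x[0]
        censored = True
    else:
        frac = (half - prof[ileft - 1]) / (prof[ileft] - prof[ileft - 1])
        left = x[ileft - 1] + frac * (x[ileft] - x[ileft - 1])
    iright = len(prof) - 1 - int(np.argmax(above[::-1]))  # last bin at/above half
    if iright == len(prof) - 1:
        right = x[-1]
        censored = True
    else:
        frac = (prof[iright] - half) / (prof[iright] - prof[iright + 1])
        right = x[iright] + frac * (x[iright + 1] - x[iright])
    return float(right - left), censored


def sds_profile(frames: list[ChannelFrame], subject_id: int | None = None,
                wavelength_nm: int | None = None) -> SdsProfile:
    """Full per-subject profile: quartiles, SDS, IUS%, FWHMs."""
    boundaries = pool_depth_quartiles(frames)
    sds = compute_sds(frames, boundaries)
    ius = compute_ius(sds)
    fg, ft = np.zeros(2), np.zeros(2)
    cens = np.zeros((2, 2), dtype=bool)
    for Q in (0, 1):
        fg[Q], cens[Q, 0] = compute_fwhm(sds[Q], "gamma")
        ft[Q], cens[Q, 1] = compute_fwhm(sds[Q], "tau")
    return SdsProfile(sds=sds, ius_percent=ius, depth_boundaries_mm=boundaries,
                      fwhm_gamma_mm=fg, fwhm_tau_mm=ft, fwhm_censored=cens,
                      subject_id=subject_id, wavelength_nm=wavelength_nm)
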