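"""Voxel Monte Carlo photon transport and adjoint sensitivity assembly.

Photons are tracked through the labelled voxel grid with exponential
free paths in optical depth, Henyey-Greenstein scattering, albedo
weighting (a fraction mua/mut of the weight is absorbed at each
collision), Russian roulette below a weight threshold, and Fresnel
reflection at refractive-index mismatches against the ambient medium.
Fluence is scored with a track-length estimator, normalized per launched
photon and per voxel volume (units 1/mm^2).

Channel sensitivity follows the adjoint (Rytov) construction: the
product of the source and detector fluences, normalized by the source
fluence at the detector, gives the change in channel optical density per
unit absorption perturbation per unit volume.

Determinism: every photon owns a counter-based RNG stream derived from
(seed, photon index), so results are bit-identical for a given seed and
independent of batching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .optics import GM, OpticalProperties
from .phantom import SurfaceMesh, VoxelHeadModel

log = logging.getLogger(__name__)

#: Russian roulette: played below this weight, survivors keep 1/P_SURVIVE
W_MIN = 1e-4
P_SURVIVE = 0.1
#: photons are terminated after this total path length (mm)
MAX_PATH_MM = 1e3


@dataclass
class FluenceVolume:
    values: np.ndarray  # (nx, ny, nz) track-length fluence per photon, 1/mm^2
    source_position: np.ndarray  # world mm
    n_photons: int
    seed: int
    deposited: float  # total absorbed weight (per launched photon)
    escaped: float  # weight transmitted out of the domain (per photon)
    terminated: float  # roulette + path-limit losses (per photon)
    voxel_size_mm: float
    origin_mm: np.ndarray  # world mm of grid corner
    batch_probe_values: np.ndarray | None = None  # (n_batches, n_probes)

    def value_at(self, pos_mm: np.ndarray) -> float:
        idx = np.floor((np.asarray(pos_mm, float) - self.origin_mm)
                       / self.voxel_size_mm).astype(int)
        idx = np.clip(idx, 0, np.array(self.values.shape) - 1)
        return float(self.values[idx[0], idx[1], idx[2]])


@dataclass
class SensitivityMatrix:
    A: np.ndarray  # (channels, pial vertices), >= 0
    channel_ids: list[int]  # indices into the montage channel list
    wavelength_nm: int

    def __post_init__(self):
        if np.any(self.A < 0):
            raise ValueError("sensitivity coefficients must be >= 0")


# ---------------------------------------------------------------- RNG ----

@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x, z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rng_next(state):
    x = state
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    r = (x * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x, (r >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _photon_state(seed, p):
    s = np.uint64(seed) ^ (np.uint64(p) * np.uint64(0xD1342543DE82EF95))
    s, z1 = _splitmix64(s)
    s, z2 = _splitmix64(s)
    state = z1 ^ (z2 << np.uint64(1))
    if state == np.uint64(0):
        state = np.uint64(0x1234567887654321)
    return state


# ----------------------------------------------------------- transport ----

@njit(cache=True, fastmath={"nnan", "ninf", "nsz", "arcp", "contract", "afn"})
def _run_photons(labels, h, mua, mus, g, n_idx, p0, p1, seed,
                 src, pencil_dir, isotropic, fluence):
    """Trace photons [p0, p1); returns (deposited, escaped, roulette_net).

    The roulette tally is the *net* weight removed by Russian roulette
    and the path-length cutoff (kills positive, survivor boosts
    negative), so launched = deposited + escaped + roulette_net holds
    exactly per photon, not just in expectation.
    """
    nx, ny, nz = labels.shape
    mt_tab = mua + mus
    inv_mt = np.empty(mt_tab.shape)
    alb = np.empty(mt_tab.shape)
    for k in range(mt_tab.shape[0]):
        inv_mt[k] = 1.0 / mt_tab[k] if mt_tab[k] > 0.0 else 1e30
        alb[k] = mua[k] / mt_tab[k] if mt_tab[k] > 0.0 else 0.0
    # Kahan-compensated global tallies of per-photon budgets, so the
    # launched = deposited + escaped + roulette identity closes to
    # ~1e-15 per photon even over 10^6+ photons
    dep_sum = 0.0
    dep_c = 0.0
    esc_sum = 0.0
    esc_c = 0.0
    rou_sum = 0.0
    rou_c = 0.0
    for p in range(p0, p1):
        deposited = 0.0
        escaped = 0.0
        roulette = 0.0
        state = _photon_state(seed, p)
        px, py, pz = src[0], src[1], src[2]
        if isotropic:
            state, u1 = _rng_next(state)
            cz = 2.0 * u1 - 1.0
            sz = np.sqrt(max(0.0, 1.0 - cz * cz))
            # Marsaglia polar sampling of the azimuth (no trig)
            while True:
                state, a = _rng_next(state)
                state, b = _rng_next(state)
                a = 2.0 * a - 1.0
                b = 2.0 * b - 1.0
                r2 = a * a + b * b
                if 0.0 < r2 < 1.0:
                    break
            inv = 1.0 / r2
            ux, uy, uz = sz * (a * a - b * b) * inv, sz * 2.0 * a * b * inv, cz
        else:
            ux, uy, uz = pencil_dir[0], pencil_dir[1], pencil_dir[2]
        ix = int(px / h)
        iy = int(py / h)
        iz = int(pz / h)
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            y_k = 1.0 - esc_c
            t_k = esc_sum + y_k
            esc_c = (t_k - esc_sum) - y_k
            esc_sum = t_k
            continue
        bx0 = ix * h
        by0 = iy * h
        bz0 = iz * h
        lab = labels[ix, iy, iz]
        w = 1.0
        path = 0.0
        alive = True
        while alive:
            if lab == 0:
                escaped += w
                break
            state, u = _rng_next(state)
            if u <= 0.0:
                u = 1e-300
            s = -np.log(u)  # optical depth to next collision
            # fast path: collision inside the current voxel
            ds = s * inv_mt[lab]
            qx = px + ux * ds
            qy = py + uy * ds
            qz = pz + uz * ds
            collided = False
            if (bx0 <= qx < bx0 + h and by0 <= qy < by0 + h
                    and bz0 <= qz < bz0 + h and path + ds < MAX_PATH_MM):
                fluence[ix, iy, iz] += w * ds
                px, py, pz = qx, qy, qz
                path += ds
                collided = True
            else:
                # walk voxel faces until the optical depth is consumed
                while s > 0.0 and alive:
                    mt = mt_tab[lab]
                    db = 1e30
                    baxis = 0
                    bdir = 0
                    if ux > 0.0:
                        t = (bx0 + h - px) / ux
                        if t < db:
                            db = t; baxis = 0; bdir = 1
                    elif ux < 0.0:
                        t = (bx0 - px) / ux
                        if t < db:
                            db = t; baxis = 0; bdir = -1
                    if uy > 0.0:
                        t = (by0 + h - py) / uy
                        if t < db:
                            db = t; baxis = 1; bdir = 1
                    elif uy < 0.0:
                        t = (by0 - py) / uy
                        if t < db:
                            db = t; baxis = 1; bdir = -1
                    if uz > 0.0:
                        t = (bz0 + h - pz) / uz
                        if t < db:
                            db = t; baxis = 2; bdir = 1
                    elif uz < 0.0:
                        t = (bz0 - pz) / uz
                        if t < db:
                            db = t; baxis = 2; bdir = -1
                    if db < 0.0:
                        db = 0.0
                    ds = s * inv_mt[lab]
                    step = ds if ds < db else db
                    if path + step >= MAX_PATH_MM:
                        step = MAX_PATH_MM - path
                        fluence[ix, iy, iz] += w * step
                        roulette += w
                        alive = False
                        break
                    fluence[ix, iy, iz] += w * step
                    px += ux * step
                    py += uy * step
                    pz += uz * step
                    path += step
                    if ds <= db:
                        s = 0.0
                        collided = True
                        break
                    # voxel face: consume optical depth, cross or reflect
                    s -= step * mt
                    if baxis == 0:
                        px = bx0 + h if bdir > 0 else bx0
                        jx, jy, jz = ix + bdir, iy, iz
                    elif baxis == 1:
                        py = by0 + h if bdir > 0 else by0
                        jx, jy, jz = ix, iy + bdir, iz
                    else:
                        pz = bz0 + h if bdir > 0 else bz0
                        jx, jy, jz = ix, iy, iz + bdir
                    if jx < 0 or jy < 0 or jz < 0 or jx >= nx or jy >= ny or jz >= nz:
                        escaped += w
                        alive = False
                        break
                    lab2 = labels[jx, jy, jz]
                    n1 = n_idx[lab]
                    n2 = n_idx[lab2]
                    if n1 != n2:
                        ci = ux if baxis == 0 else (uy if baxis == 1 else uz)
                        if ci < 0.0:
                            ci = -ci
                        ratio = n1 / n2
                        st2 = ratio * ratio * (1.0 - ci * ci)
                        if st2 >= 1.0:
                            refl = 1.0
                        else:
                            ctr = np.sqrt(1.0 - st2)
                            rs = (n1 * ci - n2 * ctr) / (n1 * ci + n2 * ctr)
                            rp = (n1 * ctr - n2 * ci) / (n1 * ctr + n2 * ci)
                            refl = 0.5 * (rs * rs + rp * rp)
                        state, u4 = _rng_next(state)
                        if u4 < refl:
                            # specular reflection off the face, same voxel
                            if baxis == 0:
                                ux = -ux
                            elif baxis == 1:
                                uy = -uy
                            else:
                                uz = -uz
                            continue
                    if lab2 == 0:
                        escaped += w
                        alive = False
                        break
                    ix, iy, iz = jx, jy, jz
                    bx0 = ix * h
                    by0 = iy * h
                    bz0 = iz * h
                    lab = lab2
            if not (alive and collided):
                continue
            # collision: absorb a fraction of the weight, scatter the rest
            dep = w * alb[lab]
            deposited += dep
            w -= dep
            gg = g[lab]
            state, u1 = _rng_next(state)
            if gg > 1e-6:
                tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * u1)
                ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
            else:
                ct = 2.0 * u1 - 1.0
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            st = np.sqrt(1.0 - ct * ct)
            while True:
                state, a = _rng_next(state)
                state, b = _rng_next(state)
                a = 2.0 * a - 1.0
                b = 2.0 * b - 1.0
                r2 = a * a + b * b
                if 0.0 < r2 < 1.0:
                    break
            inv = 1.0 / r2
            cp = (a * a - b * b) * inv
            sp = 2.0 * a * b * inv
            if uz > 0.99999 or uz < -0.99999:
                sign = 1.0 if uz >= 0.0 else -1.0
                ux = st * cp
                uy = st * sp
                uz = sign * ct
            else:
                den = np.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -st * cp * den + uz * ct
                ux, uy, uz = nux, nuy, nuz
            if w < W_MIN:
                state, u3 = _rng_next(state)
                if u3 < P_SURVIVE:
                    boost = w * (1.0 / P_SURVIVE - 1.0)
                    w += boost
                    roulette -= boost
                else:
                    roulette += w
                    alive = False
        # fold this photon's budget into the compensated global sums
        y_k = deposited - dep_c
        t_k = dep_sum + y_k
        dep_c = (t_k - dep_sum) - y_k
        dep_sum = t_k
        y_k = escaped - esc_c
        t_k = esc_sum + y_k
        esc_c = (t_k - esc_sum) - y_k
        esc_sum = t_k
        y_k = roulette - rou_c
        t_k = rou_sum + y_k
        rou_c = (t_k - rou_sum) - y_k
        rou_sum = t_k
    return dep_sum, esc_sum, rou_sum


def run_mc_fluence(head: VoxelHeadModel, optode_pos: np.ndarray,
                   props: OpticalProperties, n_photons: int, seed: int,
                   beam: str = "pencil", n_batches: int = 1,
                   probes: np.ndarray | None = None,
                   ) -> FluenceVolume:
    """Monte Carlo fluence for one optode (or point source).

    ``beam="pencil"`` launches straight into the head (+z) from the
    optode scalp position; ``beam="isotropic"`` launches uniformly over
    the sphere, the right source model for validating against the
    infinite-medium diffusion Green's function.

    ``probes`` is an optional (k, 3) array of world-mm positions; with
    ``n_batches > 1`` the returned volume carries ``batch_probe_values``
    of shape (n_batches, k), the per-batch fluence estimates used for
    Monte Carlo standard errors. Results are independent of n_batches.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if beam not in ("pencil", "isotropic"):
        raise ValueError("beam must be 'pencil' or 'isotropic'")
    h = head.voxel_size_mm
    origin = head.affine[:3, 3] - 0.5 * h  # world mm of grid corner
    src = np.asarray(optode_pos, dtype=float) - origin
    # nudge a launch point sitting exactly on a face into the grid
    eps = 1e-9 * h
    src = np.clip(src, eps, np.array(head.shape) * h - eps)
    if beam == "pencil":
        src[2] = max(src[2], (np.argmax(head.labels[
            int(src[0] / h), int(src[1] / h)] > 0) * h) + eps)
    pencil_dir = np.array([0.0, 0.0, 1.0])

    labels = np.ascontiguousarray(head.labels)
    fluence = np.zeros(head.shape, dtype=np.float64)
    dep = esc = term = 0.0
    probe_vals = None
    if probes is not None:
        probes = np.atleast_2d(np.asarray(probes, dtype=float))
        probe_idx = np.floor((probes - origin) / h).astype(int)
        probe_vals = np.zeros((n_batches, len(probes)))
    prev = np.zeros(0)
    bounds = np.linspace(0, n_photons, n_batches + 1).astype(np.int64)
    for b in range(n_batches):
        d, e, t = _run_photons(labels, h, props.mua, props.mus, props.g,
                               props.n, bounds[b], bounds[b + 1], seed,
                               src, pencil_dir, beam == "isotropic", fluence)
        dep += d
        esc += e
        term += t
        if probe_vals is not None:
            cur = np.array([fluence[i, j, k] for i, j, k in probe_idx])
            nb = bounds[b + 1] - bounds[b]
            probe_vals[b] = (cur - (prev if prev.size else 0.0)) / (nb * h ** 3)
            prev = cur.copy()
    fluence /= n_photons * h ** 3
    vol = FluenceVolume(values=fluence, source_position=np.asarray(optode_pos, float),
                        n_photons=n_photons, seed=seed,
                        deposited=dep / n_photons, escaped=esc / n_photons,
                        terminated=term / n_photons, voxel_size_mm=h,
                        origin_mm=origin)
    if probe_vals is not None:
        vol.batch_probe_values = probe_vals
    return vol


# ------------------------------------------------------------ adjoint ----

def channel_sensitivity(src_fluence: FluenceVolume, det_fluence: FluenceVolume,
                        normalizer: float) -> np.ndarray:
    """Adjoint (Rytov) voxel sensitivity Phi_src * Phi_det / normalizer.

    ``normalizer`` is the source fluence at the detector position; a
    non-positive value means the detector was never reached and the
    channel is invalid.
    """
    if src_fluence.values.shape != det_fluence.values.shape:
        raise ValueError("source and detector fluences must share one grid")
    if normalizer <= 0:
        raise ValueError("invalid channel: source fluence at detector is <= 0")
    return src_fluence.values * det_fluence.values / normalizer


def assemble_sensitivity_matrix(head: VoxelHeadModel, montage, props: OpticalProperties,
                                pial: SurfaceMesh, projector, n_photons: int,
                                seed: int, smoother=None) -> SensitivityMatrix:
    """Sensitivity matrix A (channels x pial vertices) at one wavelength.

    Runs exactly one fluence simulation per optode (sources and
    detectors), forms each channel's Rytov voxel sensitivity masked to
    grey matter, projects it onto the pial mesh with ``projector`` and
    optionally smooths it with ``smoother``. Invalid channels (detector
    unreached) are dropped and logged.
    """
    gm_mask = head.labels == GM
    optodes = montage.optode_positions()
    n_src = len(montage.sources)
    fluences = []
    for k, pos in enumerate(optodes):
        sub = (int(seed) * 1000003 + 101 * k + props.wavelength_nm) % (2 ** 31)
        fluences.append(run_mc_fluence(head, pos, props, n_photons, sub))
    rows, kept = [], []
    for c, (s, d) in enumerate(montage.channels):
        phi_s = fluences[s]
        phi_d = fluences[n_src + d]
        norm = phi_s.value_at(montage.detectors[d])
        if norm <= 0:
            log.warning("channel %d dropped: detector not reached", c)
            continue
        sens = channel_sensitivity(phi_s, phi_d, norm)
        sens = np.where(gm_mask, sens, 0.0)
        cmap = projector.project(sens, fill_empty=True)
        if smoother is not None:
            cmap = smoother.smooth(cmap)
        rows.append(np.asarray(cmap, dtype=float))
        kept.append(c)
    if not rows:
        raise ValueError("no valid channels in montage")
    return SensitivityMatrix(A=np.vstack(rows), channel_ids=kept,
                             wavelength_nm=props.wavelength_nm)
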