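"""Physics validation studies: closed-form oracles and end-to-end runs.

These are the quantitative checks a user should run after changing
transport or projection code: agreement of homogeneous-medium fluence
with the diffusion approximation, first-order (adjoint) consistency of
the sensitivity product against brute-force perturbation, source to
detector reciprocity, and the full corrugated-phantom sensitivity
study. All entry points are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sds as sds_mod
from .mc import assemble_sensitivity_matrix, run_mc_fluence
from .montage import place_optodes
from .optics import GM, OpticalProperties, with_perturbed_voxel
from .phantom import PhantomParams, VoxelHeadModel, generate_head_phantom, homogeneous_block
from .projection import GaussianMeshSmoother, VoronoiProjector


def diffusion_point_source(r_mm: np.ndarray, mua: float, mus: float,
                           g: float) -> np.ndarray:
    """Infinite-medium diffusion Green's function for an isotropic
    point source of unit power: exp(-mu_eff r) / (4 pi D r), with
    D = 1/(3 (mua + mus')) and mu_eff = sqrt(mua / D)."""
    musp = mus * (1.0 - g)
    D = 1.0 / (3.0 * (mua + musp))
    mu_eff = np.sqrt(mua / D)
    r = np.asarray(r_mm, dtype=float)
    return np.exp(-mu_eff * r) / (4.0 * np.pi * D * r)


def homogeneous_diffusion_check(n_photons: int = 1_000_000, seed: int = 1,
                                shape: int = 40, voxel_mm: float = 2.0,
                                r_test_mm=(10.0, 12.5, 15.0, 17.5, 20.0, 22.5, 25.0),
                                shell_mm: float = 1.0) -> dict:
    """Homogeneous grey-matter block vs the diffusion oracle.

    Isotropic point source at the center of an index-matched block;
    fluence is averaged over radial shells and compared with the
    closed form. Returns the per-shell relative errors, their maximum,
    and the photon weight-budget residual per launched photon.
    """
    head = homogeneous_block((shape, shape, shape), voxel_mm)
    props = OpticalProperties.homogeneous(760, tissue=GM)
    center = np.full(3, shape * voxel_mm / 2.0)
    fl = run_mc_fluence(head, center, props, n_photons, seed, beam="isotropic")
    xs = (np.arange(shape) + 0.5) * voxel_mm
    xx, yy, zz = np.meshgrid(xs, xs, xs, indexing="ij")
    r = np.sqrt((xx - center[0]) ** 2 + (yy - center[1]) ** 2
                + (zz - center[2]) ** 2)
    rel_errors = {}
    for r0 in r_test_mm:
        m = (r > r0 - shell_mm) & (r < r0 + shell_mm)
        mc = fl.values[m].mean()
        th = diffusion_point_source(r[m], props.mua[GM], props.mus[GM],
                                    props.g[GM]).mean()
        rel_errors[r0] = abs(mc - th) / th
    resid = abs(1.0 - (fl.deposited + fl.escaped + fl.terminated))
    return {"rel_errors": rel_errors,
            "max_rel_error": max(rel_errors.values()),
            "conservation_residual_per_photon": resid,
            "fluence": fl}


@dataclass
class AdjointReport:
    reciprocity_z: float  # |Phi_s(det) - Phi_d(src)| in pooled SE units
    predicted_dod: float  # first-order A * dmua prediction
    direct_dod: float  # brute-force two-run MC difference
    dod_se: float  # MC standard error of the comparison
    dmua: float
    z: float  # |predicted - direct| / se


def _detector_block_mm(head: VoxelHeadModel, pos_mm: np.ndarray) -> np.ndarray:
    """Voxel centers of a 3x3x3 tissue block under a scalp position —
    the finite detection aperture used by the validation observables."""
    idx = head.mm_to_voxel(pos_mm).astype(int)[0]
    iz = int(np.argmax(head.labels[idx[0], idx[1]] > 0))
    offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (0, 1, 2)]
    cells = np.array([[idx[0] + dx, idx[1] + dy, iz + dz] for dx, dy, dz in offs])
    return head.voxel_center_mm(cells)


def adjoint_perturbation_check(n_photons: int = 1_000_000, seed: int = 2,
                               n_batches: int = 20,
                               dmua: float = 0.04) -> AdjointReport:
    """First-order sensitivity vs brute-force perturbation, plus
    source-detector reciprocity, on a flat layered head patch.

    The detected signal is the mean fluence over a 3x3x3 voxel aperture
    under the detector; the matching adjoint run launches isotropically
    from the aperture center. The perturbation (``dmua``, 1/mm, applied
    to one grey-matter voxel under the channel center) is kept small so
    the voxel-chord optical-depth change stays first-order, and the
    perturbed run reuses the unperturbed RNG streams (common random
    numbers), so the paired difference has a far smaller MC error than
    either run alone.
    """
    params = PhantomParams(sulcal_depth_mm=0.0, seed=seed)
    head, _, _ = generate_head_phantom(params)
    src = np.array([35.0, 50.0, 0.0])
    det = np.array([65.0, 50.0, 0.0])
    h = head.voxel_size_mm
    # perturbation voxel: first grey-matter voxel under the channel center
    icol = head.mm_to_voxel([50.0, 50.0, 0.0]).astype(int)[0]
    iz = int(np.argmax(head.labels[icol[0], icol[1]] == GM))
    vox = (int(icol[0]), int(icol[1]), iz)
    vox_mm = head.voxel_center_mm(np.array(vox))[0]

    det_block = _detector_block_mm(head, det)
    src_block = _detector_block_mm(head, src)
    det_center = det_block.mean(axis=0)
    props = OpticalProperties(760)
    probes_s = np.vstack([det_block, vox_mm])
    fl_s = run_mc_fluence(head, src, props, n_photons, seed,
                          n_batches=n_batches, probes=probes_s)
    # pencil detector launch: the symmetric partner for reciprocity
    fl_d = run_mc_fluence(head, det, props, n_photons, seed + 1,
                          n_batches=n_batches, probes=src_block)
    # isotropic adjoint launch matching the block observable
    fl_adj = run_mc_fluence(head, det_center, props, n_photons, seed + 2,
                            beam="isotropic", n_batches=n_batches,
                            probes=np.atleast_2d(vox_mm))

    def batch_stats(vals):
        return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))

    s_blocks = fl_s.batch_probe_values[:, :-1].mean(axis=1)
    s_at_det, se_s_det = batch_stats(s_blocks)
    d_at_src, se_d_src = batch_stats(fl_d.batch_probe_values.mean(axis=1))
    rec_z = abs(s_at_det - d_at_src) / np.sqrt(se_s_det ** 2 + se_d_src ** 2)

    # first-order prediction: dOD = dmua * V * Phi_s(v) * Phi_adj(v) / I
    prod_b = (fl_s.batch_probe_values[:, -1]
              * fl_adj.batch_probe_values[:, 0]) * h ** 3 * dmua / s_at_det
    predicted, se_prod = batch_stats(prod_b)
    se_pred = np.hypot(se_prod, predicted * se_s_det / s_at_det)

    labels_p, props_p = with_perturbed_voxel(head.labels, props, vox, dmua)
    head_p = VoxelHeadModel(labels=labels_p, voxel_size_mm=h, affine=head.affine)
    fl_p = run_mc_fluence(head_p, src, props_p, n_photons, seed,
                          n_batches=n_batches, probes=probes_s)
    p_blocks = fl_p.batch_probe_values[:, :-1].mean(axis=1)
    direct = -np.log(p_blocks.mean() / s_at_det)
    diff_b = p_blocks - s_blocks  # common-random-number pairing
    se_dir = diff_b.std(ddof=1) / np.sqrt(n_batches) / s_at_det
    se = float(np.hypot(se_pred, se_dir))
    return AdjointReport(reciprocity_z=float(rec_z), predicted_dod=float(predicted),
                         direct_dod=float(direct), dod_se=se, dmua=float(dmua),
                         z=float(abs(predicted - direct) / se))


def corrugated_sensitivity_study(n_photons: int = 1_000_000, seed: int = 3,
                                 wavelength_nm: int = 760,
                                 rows: int = 3, cols: int = 4,
                                 pitch_mm: float = 30.0,
                                 params: PhantomParams | None = None) -> dict:
    """Full forward study on the default corrugated phantom.

    Generates the phantom, places a ``rows x cols`` alternating lattice
    of 30 mm channels, assembles the sensitivity matrix (one fluence
    simulation per optode at ``n_photons``), builds all channel frames
    and returns the per-subject SDS profile alongside every
    intermediate object.
    """
    if params is None:
        params = PhantomParams(seed=seed)
    head, scalp, pial = generate_head_phantom(params)
    montage = place_optodes(scalp, rows, cols, pitch_mm)
    projector = VoronoiProjector(head, pial)
    smoother = GaussianMeshSmoother(pial, 2.0)
    props = OpticalProperties(wavelength_nm)
    A = assemble_sensitivity_matrix(head, montage, props, pial, projector,
                                    n_photons, seed, smoother=smoother)
    frames = [sds_mod.build_channel_frame(c, montage, scalp, pial, A.A[k])
              for k, c in enumerate(A.channel_ids)]
    profile = sds_mod.sds_profile(frames, subject_id=0,
                                  wavelength_nm=wavelength_nm)
    return {"params": params, "head": head, "scalp": scalp, "pial": pial,
            "montage": montage, "projector": projector, "smoother": smoother,
            "A": A, "frames": frames, "profile": profile}

def inverse_recovery_study(study: dict, n_photons_secondary: int = 250_000,
                           seed: int = 5, noise_sd: float = 5e-4,
                           physio_amp: float = 2e-3,
                           activation_amplitude_mm: float = 1.0,
                           secondary_A=None) -> dict:
    """End-to-end reconstruction of a single-parcel activation.

    Uses the forward model from :func:`corrugated_sensitivity_study` at
    760 nm, assembles the 850 nm matrix at a lighter photon budget
    (``n_photons_secondary``; the two wavelengths carry near-identical
    spatial information), simulates a block-design recording whose
    activation is confined to the gyral-crown part of one rectangular
    parcel, runs the full preprocessing chain, estimates the ReML
    hyperparameters, solves the minimum-norm inverse and unmixes
    hemoglobin. Reports whether the peak |dHbO2| vertex falls inside
    the true parcel and the per-parcel area means at the peak sample.
    """
    from .inverse import InverseModel, area_timecourse, reml_hyperparameters, \
        mne_solve, unmix_hemoglobin
    from .montage import make_parcellation
    from .preprocess import (bandpass_filter, block_average, intensity_to_od,
                             reject_by_cv, tddr_correct)
    from .recording import Events, NoiseSpec, simulate_recording

    head, pial, montage = study["head"], study["pial"], study["montage"]
    A760 = study["A"]
    if secondary_A is None:
        A850 = assemble_sensitivity_matrix(
            head, montage, OpticalProperties(850), pial, study["projector"],
            n_photons_secondary, seed, smoother=study["smoother"])
    else:
        A850 = secondary_A
    if A760.channel_ids != A850.channel_ids:
        keep = sorted(set(A760.channel_ids) & set(A850.channel_ids))
        A760 = type(A760)(A=A760.A[[A760.channel_ids.index(c) for c in keep]],
                          channel_ids=keep, wavelength_nm=760)
        A850 = type(A850)(A=A850.A[[A850.channel_ids.index(c) for c in keep]],
                          channel_ids=keep, wavelength_nm=850)

    boxes = [(30.0, 50.0, 30.0, 50.0), (50.0, 70.0, 30.0, 50.0),
             (30.0, 50.0, 50.0, 70.0), (50.0, 70.0, 50.0, 70.0)]
    parc = make_parcellation(pial, boxes=boxes)
    depth_med = float(np.median(pial.vertices[:, 2]))
    crown = pial.vertices[:, 2] <= depth_med
    true_parcel = 0
    activation = np.where((parc.area_labels == true_parcel) & crown, 1.0, 0.0)

    fs_hz = 5.0
    events = Events(onsets_s=np.arange(30.0, 270.0, 40.0),
                    durations_s=np.full(6, 10.0))
    rec = simulate_recording({760: A760, 850: A850}, activation, events,
                             duration_s=300.0, sampling_rate_hz=fs_hz,
                             amplitude_mm=activation_amplitude_mm,
                             noise=NoiseSpec(white_sd=noise_sd,
                                             physio_amp=physio_amp), seed=seed)
    rec, _ = reject_by_cv(rec)
    od = intensity_to_od(rec.intensities)
    od = tddr_correct(od, fs_hz)
    od = bandpass_filter(od, fs_hz)

    window = (5.0, 35.0)
    dmua_hat = {}
    hyper = {}
    for k, wl in enumerate(rec.wavelengths_nm):
        A = {760: A760, 850: A850}[wl]
        h1, h2 = reml_hyperparameters(od[:, k, :], A.A, np.eye(A.A.shape[0]))
        hyper[wl] = (h1, h2)
        ba = block_average(od[:, k, :], events.onsets_s, fs_hz, window)
        model = InverseModel(A=A.A, C1=np.eye(A.A.shape[0]), h1=h1, h2=h2)
        dmua_hat[wl] = mne_solve(ba.mean, model)
    act = unmix_hemoglobin(dmua_hat)
    t_peak = int(np.argmax(np.linalg.norm(act.hbo, axis=0)))
    peak_map = act.hbo[:, t_peak]
    peak_vertex = int(np.argmax(np.abs(peak_map)))
    area_means = {a: area_timecourse(peak_map, parc, a)["peak_value"]
                  for a in parc.area_ids}
    return {"parcellation": parc, "true_parcel": true_parcel,
            "activation": activation, "hbo": act.hbo, "peak_map": peak_map,
            "peak_vertex": peak_vertex,
            "peak_in_parcel": bool(parc.area_labels[peak_vertex] == true_parcel),
            "area_means": area_means, "hyperparameters": hyper,
            "A760": A760, "A850": A850}
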