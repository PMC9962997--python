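# fnirs-sensfield

Monte Carlo forward-sensitivity analysis for functional near-infrared
spectroscopy (fNIRS), built around synthetic sulcogyral head phantoms.

Sparse continuous-wave fNIRS caps sense the cortex through 3-4 cm
source-detector channels whose sensitivity falls off sharply with
cortical depth and lateral displacement, so the coupling between a
scalp channel and a cortical area depends strongly on the underlying
sulcogyral anatomy. This package implements the full quantitative
pipeline for studying that effect when no subject MRI is available:

- **`phantom` / `montage` / `recording`** — parametric layered head
  patches (scalp, skull, CSF, corrugated grey-matter ribbon, white
  matter) with cohort-level anatomical jitter, alternating
  source/detector lattices, synthetic cortical parcellations, and
  HRF-convolved block-design recordings with physiological and white
  noise.
- **`mc`** — voxel Monte Carlo photon transport (Henyey-Greenstein
  scattering, albedo weighting, Fresnel boundaries, Russian roulette,
  track-length fluence estimator; numba-compiled, bit-reproducible per
  seed) and adjoint (Rytov) assembly of the channel x vertex
  sensitivity matrix `A` in the forward model `dOD = A dmua`.
- **`projection`** — Voronoi-style projection of voxel sensitivity onto
  the pial mesh (mass-conserving, geodesic within the grey-matter
  ribbon) and geodesic Gaussian smoothing.
- **`sds`** — per-channel curvilinear (gamma, tau) sensitivity charts,
  depth-quartile pooling, sensitivity displacement surfaces (SDS),
  integral-under-surface percentages (IUS%), and FWHM statistics.
- **`a2ch`** — area-to-channel coupling: reduced matrix
  `B[i,a] = sum_{j in area a} A[i,j]`, normalized `A2Ch%` in [0, 1],
  group median/IQR, 0.2 reporting threshold and 0.2 difference flags
  against reference anatomies.
- **`preprocess`** — CV-based channel rejection, optical-density
  conversion, TDDR motion correction, 0.01-0.08 Hz zero-phase
  Butterworth bandpass, block averaging.
- **`inverse`** — ReML-estimated hyperparameters and the minimum-norm
  estimate `x = C2 A' (A C2 A' + (h2/h1) C1)^-1 y`, hemoglobin
  unmixing, and per-area time courses.
- **`validation`** — the physics oracles: diffusion-approximation
  agreement, brute-force perturbation vs adjoint prediction,
  reciprocity, and the end-to-end corrugated-phantom study.

## Worked example

```python
import numpy as np
import fnirs_sensfield as fs

# corrugated head patch: 8 mm deep sulci on a 20 mm gyral wavelength
params = fs.PhantomParams(sulcal_depth_mm=8.0, gyral_wavelength_mm=20.0, seed=7)
head, scalp, pial = fs.generate_head_phantom(params)

montage = fs.place_optodes(scalp, rows=3, cols=4, pitch_mm=30.0)
projector = fs.VoronoiProjector(head, pial)
smoother = fs.GaussianMeshSmoother(pial, fwhm_mm=2.0)
A = fs.assemble_sensitivity_matrix(head, montage, fs.OpticalProperties(760),
                                   pial, projector, n_photons=200_000,
                                   seed=7, smoother=smoother)

frames = [fs.build_channel_frame(c, montage, scalp, pial, A.A[k])
          for k, c in enumerate(A.channel_ids)]
prof = fs.sds_profile(frames)
print("IUS% by depth quartile:", prof.ius_percent.round(1))
print("depth boundaries (mm):", prof.depth_boundaries_mm.round(1))
print("FWHM gamma Q1/Q2 (mm):", prof.fwhm_gamma_mm.round(1))
print("FWHM tau   Q1/Q2 (mm):", prof.fwhm_tau_mm.round(1))
```

Output (200k photons/optode, seed 7):

```
IUS% by depth quartile: [41.6 30.4 16.1 11.8]
depth boundaries (mm): [15.8 17.  18.2]
FWHM gamma Q1/Q2 (mm): [16.3 22.1]
FWHM tau   Q1/Q2 (mm): [13.  14.1]
```

Reading: the shallowest depth quartile (gyral crowns, above 15.8 mm)
carries ~42% of the total cortical sensitivity and the deepest
(sulcal floors) ~12% — about 70% of the signal comes from the top two
quartiles, i.e. the gyri. The sensitivity field is wider along the
source-detector axis than transversely in both upper quartiles:
channels sense a strip of cortex between their optodes. (At the full
10^6-photon budget used by the validation suite the transverse
confinement is sharper still — roughly 8 vs 20 mm in the first
quartile.)

A CLI writes phantoms to disk for external tools:

```sh
fnirs-sensfield phantom --seed 7 --out out/ --montage-rows 3 --montage-cols 4
```

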