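# Methods

## The problem

Continuous-wave fNIRS measures light attenuation between scalp optode
pairs at two wavelengths (760 and 850 nm here). The measured
optical-density changes relate to cortical absorption changes through a
linear forward model

    dOD_lambda = A_lambda * dmua_lambda,

where the rows of `A` are channels, the columns are cortical-surface
elements (pial-mesh vertices), and `dmua` decomposes into hemoglobin
concentration changes via the molar extinction coefficients,
`dmua = eps_HbO2 dHbO2 + eps_HbR dHbR`. This package estimates `A` by
Monte Carlo photon transport on a layered voxel head model, quantifies
how channel sensitivity is distributed over cortical depth and lateral
displacement, reduces `A` over cortical parcellations into
area-to-channel couplings, and solves the regularized inverse problem.
Because subject MRIs are not available, all anatomies are parametric
sulcogyral phantoms generated by the package itself.

## Synthetic anatomy

A phantom is a flat "head patch": air above a scalp/skull/CSF stack, a
grey-matter ribbon whose upper surface (the pial surface) follows an
egg-carton corrugation

    z_p(x, y) = crown + (a/2) * (1 + sin(2 pi x / L + px) sin(2 pi y / L + py)),

and white matter below. Defaults: 2 mm isotropic voxels on a
100 x 100 x 52 mm grid; scalp 5 mm, skull 6 mm, CSF 2 mm (crown depth
13 mm, in the range of adult scalp-cortex distances); corrugation
wavelength L = 20 mm and peak-to-trough amplitude a = 8 mm, giving
pial depths of 13-21 mm; grey-matter thickness 3 mm. The peak-to-trough
amplitude equals `sulcal_depth_mm` exactly, and the shallowest pial
point sits at the crown — both are verified by ray casting on the
generated label grid. Meshes are extracted by marching cubes on the
smooth height-field level set `z - z_surface(x, y)`, so vertices lie on
the GM/CSF interface to sub-voxel accuracy with a deterministic vertex
order.

Cohorts jitter layer thicknesses (Gaussian, floored at half a voxel),
corrugation amplitude, and corrugation phase per subject, with subject
seeds derived from the master seed. No published values exist for these
jitter scales — inter-subject variability in the source setting is
anatomical truth, not a parametric model — so they are free parameters;
tests verify that realized amplitude spread tracks the requested scale.

What the phantom deliberately omits: head curvature (the patch is
flat, so scalp geodesics are straight lines and the inward normal is
the z axis), distinct sulcal CSF clefts (CSF fills the space between
skull and the corrugated pial sheet), gyral anisotropy, and any
atlas-grade anatomical detail. Passing tests therefore demonstrate the
*mechanisms* — depth-dependent sensitivity loss, transverse confinement,
anatomy-dependent area coupling — not subject-level numbers, which
require real MRI anatomy.

## Monte Carlo transport

Voxel MC with the standard five-tissue optical table (absorption and
scattering in 1/mm, g = 0.89, n = 1.37 for every tissue; magnitudes are
consistent with full, not reduced, scattering coefficients given g).
Photons carry a weight: free paths are sampled in optical depth,
`mua/mut` of the weight is absorbed at each collision,
Henyey-Greenstein sampling sets the new direction, and fluence is
scored with a track-length estimator (chosen over a collision estimator
for its lower variance in low-absorption CSF), normalized per launched
photon and voxel volume (units 1/mm^2). Fresnel reflection applies at
any refractive-index mismatch against the ambient medium (air, n = 1);
internal boundaries share n = 1.37, so no internal refraction occurs.
Russian roulette below weight 1e-4 with survival probability 0.1; a
1000 mm path-length cap. Weight tallies (absorbed, escaped, roulette
net) are Kahan-compensated, so launched = absorbed + escaped + roulette
closes to ~1e-15 per photon at any photon count; roulette is booked as
a *net* (kills minus survivor boosts) so the identity is exact rather
than an expectation.

Every photon owns a counter-based RNG stream (splitmix64-seeded
xorshift64*), keyed by (seed, photon index): results are bit-identical
for a given seed and independent of batching.

Desk-scale default is 1e6 photons per optode (a GPU-scale study would
use ~5e7); at 1e6 the homogeneous grey-matter fluence agrees with the
infinite-medium diffusion Green's function within a few percent over
10-25 mm, comfortably inside the 10% validation band. The validation
uses an isotropic launch and an index-matched boundary, matching the
closed form's assumptions; optode launches are pencil beams.

Channel sensitivity uses the adjoint (Rytov) product
`Phi_src(v) Phi_det(v) / Phi_src(det)`, masked to grey matter. The
validation study checks this against a brute-force perturbation: one
grey-matter voxel's absorption is raised by 0.04/mm (small enough that
the voxel-chord optical-depth change stays first-order) and the induced
dOD is measured directly from two common-random-number runs; prediction
and measurement agree within MC error. The detection observable there
is a 3x3x3-voxel aperture, with a matching isotropic adjoint launch.

## Surface projection and smoothing

Each grey-matter voxel is assigned to exactly one pial vertex by a
multi-source breadth-first flood over the 26-connected GM voxel graph,
seeded at each vertex's nearest GM voxel (ties to the lower vertex
index). This restricts distances to the GM ribbon, so sulcal-wall
sensitivity lands on the correct bank. Vertex values are cell means, so
the volume-weighted mass of a projected field is conserved exactly. On
meshes denser than the GM ribbon some vertices own no cell; these are
flagged and reported as zero by the projector, and the sensitivity
assembly fills them from the nearest cell's value to avoid punched-hole
artifacts (zero-volume cells, so conservation is untouched).

Smoothing uses a geodesic-distance Gaussian on the mesh graph
(Dijkstra edge distances, 2 mm FWHM default), rows normalized to sum to
one: uniform fields are fixed points, FWHM 0 is the identity, and
disconnected components smooth independently. Rendered maps use a
log10 scale floored at 1/100 of the maximum; analyses always use raw
values.

## Depth and displacement statistics

Each channel gets a curvilinear chart: gamma along the source-detector
direction, tau orthogonal, 2 x 2 mm bins with centers spanning
[-20, 20] mm. At each bin the inward normal ray is cast to the pial
mesh (exact barycentric intersection for the height-field meshes),
recording depth and the smoothed sensitivity of the nearest pial vertex
to the hit — one sample per bin per channel. Depth quartile boundaries
are the 25/50/75th percentiles (linear-interpolation convention) of all
pooled samples of a subject; ties on a boundary go to the lower
quartile, so a degenerate constant depth field collapses into Q1. SDS
surfaces average sensitivity per bin within each quartile; IUS is the
bin-area-weighted integral of each surface expressed as a percentage
(summing to 100 by construction). FWHM takes the 1-D profile through
the surface maximum, locates the outermost half-maximum crossings by
linear interpolation (missing bins count as zero), and flags profiles
that never fall below half maximum at the field border as censored,
returning the field width — relevant because transversely broad
atlas-like anatomies approach the 40 mm field limit.

On the default corrugated phantom with 17 channels at 30 mm separation,
the study reproduces the canonical findings as strict inequalities:
IUS decreases over depth quartiles near a 40/30/20/10% split, and the
transverse FWHM is substantially narrower than the longitudinal one in
the two upper quartiles. These are computed fresh by the test suite and
the acceptance script, not stored.

## Area-to-channel coupling

`B[i, a]` sums a channel's sensitivity over an area's vertices;
`A2Ch%[i, a]` divides by the channel's total over all vertices, so
values lie in [0, 1], exhaustive parcellations give unit row sums, and
the measure is invariant to global rescaling of `A`. Group summaries
use median and IQR (Q3 - Q1, same linear-interpolation percentile
convention as the depth quartiles, kept for internal consistency).
Reporting drops channels whose every cell (group median and all
references) is at or below 0.2, and cells are flagged when the group
median differs from any reference by strictly more than 0.2 — both
comparisons strict.

## Preprocessing

Channels are rejected when the raw-intensity coefficient of variation
exceeds 10% at either wavelength (zero-mean channels get their own
reason code). OD conversion is natural-log against the mean intensity,
shared with the generative model so round trips are exact up to a
per-channel constant. TDDR operates on temporal derivatives with
iteratively reweighted Tukey biweight (c = 4.685, sigma = 1.4826 MAD,
tolerance 1e-8, max 50 iterations), re-integrates, and above 1 Hz
sampling applies the repair to the sub-0.5 Hz component with the
high-frequency residual added back. Note a model-level caveat verified
while building the recovery study: on signals whose low-frequency band
is nearly noise-free, the evoked response's own derivatives become the
outliers and TDDR attenuates the response itself; the synthetic
recordings therefore include sinusoidal physiological interference
(default cardiac 1.1 Hz, respiratory 0.25 Hz) as real recordings would.
The bandpass is a zero-phase (forward-backward) order-3 Butterworth at
0.01-0.08 Hz. Block averaging extracts epochs around onsets, corrects
each by its pre-onset baseline mean, and skips epochs that leave the
record.

## Inverse problem

The estimator is the channel-space form of the Tikhonov/minimum-norm
solution,

    x_hat = C2 A' (A C2 A' + (h2/h1) C1)^-1 y,

factorizing only an I x I matrix; it is unit-tested against the
explicit regularized normal-equations form and against the
pseudoinverse in the small-regularization limit. The printed form of
the source estimator is typographically ambiguous, so the standard
weighted-minimum-norm reading is implemented and documented here.
Hyperparameters maximize the likelihood of the zero-mean two-component
model `cov(y) = (1/h1) C1 + (1/h2) A C2 A'` over a log-scale grid
refined by Nelder-Mead; a signal component collapsing to zero is
clipped to a tiny positive value (boundary case). A caveat worth
knowing: how well the variance *ratio* is identified depends on the
design — with smooth, comparably-scaled channel profiles a 200-epoch
sample pins the ratio to a few percent, whereas Monte Carlo sensitivity
matrices whose channel signal power spans more than an order of
magnitude leave it with 15-20% sampling scatter (the estimates stay
unbiased). The variance-recovery validation therefore uses a
well-identified design; the Monte Carlo matrices are exercised through
the end-to-end reconstruction instead. C1 defaults to the
identity in the synthetic studies, whose generative noise is
homoscedastic across channels; with heteroscedastic data a diagonal of
baseline OD variances is the intended substitute. C2 defaults to the
identity (a depth-weighted prior would be a natural extension, not
implemented as a claim).

Chromophore unmixing is a per-vertex 2 x 2 solve with extinction
coefficients from a standard published compilation (760 nm:
0.5864 / 1.5485; 850 nm: 1.0581 / 0.6910, in 1/(mM cm)) — external
constants, configurable, not printed in any source reproduced here.
Concentration outputs are flagged arbitrary-scale: no partial
pathlength or calibration factor is applied, which is why reconstructed
amplitudes sit at hundreds of uM rather than physiological uM levels.

The end-to-end recovery study activates the gyral-crown part of one
20 x 20 mm parcel, simulates a six-block recording (1 mM drive on the
arbitrary scale, white noise 5e-4, physiological interference 2e-3),
runs the full preprocessing chain, estimates (h1, h2) by ReML per
wavelength, reconstructs, and unmixes. With the matched forward model
the peak |dHbO2| vertex falls inside the true parcel and the true
parcel's area mean dominates every other parcel — the mechanism by
which anatomy drives localization. Reconstructing the same surface data
through a different phantom's forward model shifts amplitude between
neighbouring parcels; this mismatch experiment needs a second full MC
forward model and is exercised in the library (same code path with
`secondary_A`/a different study) rather than in the default test run.

## Problem sizes and numerical choices

Default problem sizes: 50 x 50 x 26 voxel phantoms (2 mm), pial meshes
of ~5,000 vertices, 12-optode / 17-channel montages, 1e6 photons per
optode for transport-physics validation and the sensitivity study, and
2.5e5 photons per optode for the secondary-wavelength matrix of the
reconstruction demo (the two wavelengths carry near-identical spatial
information, so the lighter budget only adds benign noise). Tolerances:
diffusion agreement 10%, adjoint and reciprocity 3 MC standard errors,
conservation 1e-12 per photon, percentile oracles exact, FWHM of a
sigma = 3 mm Gaussian within 0.2 mm on the 2 mm grid.

Known limitations: flat-patch geometry (no geodesic curvature effects),
single-corrugation-mode cortex, voxelized 2 mm anatomy (the source
setting's MRI is 0.8 mm), pencil-beam optode model without fiber
numerical aperture, no scalp-coupling or superficial-physiology
regressors in preprocessing, and arbitrary-scale concentrations.
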