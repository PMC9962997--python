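"""Monte Carlo transport: conservation, determinism, physics sanity.

The quantitative physics oracles (diffusion approximation, adjoint
perturbation, reciprocity) run at full photon budgets in the acceptance
suite; here the same machinery is exercised at small budgets together
with the exact structural invariants.
"""

import numpy as np
import pytest

import fnirs_sensfield as fs
from fnirs_sensfield.optics import BACKGROUND, GM, with_perturbed_voxel
from fnirs_sensfield.phantom import homogeneous_block

N_SMALL = 50_000


@pytest.fixture(scope="module")
def gm_block():
    return homogeneous_block((30, 30, 30), 2.0)


@pytest.fixture(scope="module")
def gm_props():
    return fs.OpticalProperties.homogeneous(760)


@pytest.fixture(scope="module")
def block_fluence(gm_block, gm_props):
    center = np.full(3, 30.0)
    return fs.run_mc_fluence(gm_block, center, gm_props, N_SMALL, seed=123,
                             beam="isotropic")


class TestConservation:
    def test_weight_budget_exact(self, block_fluence):
        resid = abs(1.0 - (block_fluence.deposited + block_fluence.escaped
                           + block_fluence.terminated))
        # tallies are per launched photon: the budget must close to
        # 1e-12 per photon
        assert resid <= 1e-12 * block_fluence.n_photons

    def test_fluence_nonnegative(self, block_fluence):
        assert np.all(block_fluence.values >= 0)

    def test_zero_outside_tissue(self, gm_props):
        head, _, _ = fs.generate_head_phantom(
            fs.PhantomParams(grid_shape=(20, 20, 26)))
        fl = fs.run_mc_fluence(head, np.array([20.0, 20.0, 0.0]),
                               fs.OpticalProperties(760), 20_000, seed=5)
        assert np.all(fl.values[head.labels == BACKGROUND] == 0)


class TestDeterminism:
    def test_same_seed_bit_identical(self, gm_block, gm_props):
        center = np.full(3, 30.0)
        f1 = fs.run_mc_fluence(gm_block, center, gm_props, 20_000, seed=77)
        f2 = fs.run_mc_fluence(gm_block, center, gm_props, 20_000, seed=77)
        assert np.array_equal(f1.values, f2.values)

    def test_independent_of_batching(self, gm_block, gm_props):
        center = np.full(3, 30.0)
        f1 = fs.run_mc_fluence(gm_block, center, gm_props, 20_000, seed=77)
        f2 = fs.run_mc_fluence(gm_block, center, gm_props, 20_000, seed=77,
                               n_batches=5, probes=center)
        assert np.array_equal(f1.values, f2.values)
        assert f2.batch_probe_values.shape == (5, 1)

    def test_different_seeds_differ(self, gm_block, gm_props):
        center = np.full(3, 30.0)
        f1 = fs.run_mc_fluence(gm_block, center, gm_props, 10_000, seed=1)
        f2 = fs.run_mc_fluence(gm_block, center, gm_props, 10_000, seed=2)
        assert not np.array_equal(f1.values, f2.values)


class TestPhysicsSanity:
    def test_fluence_decays_with_distance(self, block_fluence, gm_block):
        h = gm_block.voxel_size_mm
        n = gm_block.shape[0]
        xs = (np.arange(n) + 0.5) * h
        xx, yy, zz = np.meshgrid(xs, xs, xs, indexing="ij")
        r = np.sqrt((xx - 30) ** 2 + (yy - 30) ** 2 + (zz - 30) ** 2)
        means = []
        for r0 in (6.0, 12.0, 18.0, 24.0):
            m = (r > r0 - 1) & (r < r0 + 1)
            means.append(block_fluence.values[m].mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_depth_monotone_decay_in_layered_slab(self):
        head, _, _ = fs.generate_head_phantom(
            fs.PhantomParams(grid_shape=(30, 30, 26)))
        fl = fs.run_mc_fluence(head, np.array([30.0, 30.0, 0.0]),
                               fs.OpticalProperties(760), N_SMALL, seed=9)
        column = fl.values[15, 15, 2:]  # below the air margin
        coarse = column.reshape(-1, 4).mean(axis=1)  # bin over 8 mm
        assert all(a > b for a, b in zip(coarse, coarse[1:]))


class TestUnbiasedness:
    def test_fluence_estimate_stable_under_photon_doubling(self, gm_block,
                                                           gm_props):
        """Doubling the photon count changes a probe fluence only
        within its Monte Carlo error (the estimator is unbiased)."""
        center = np.full(3, 30.0)
        probe = np.array([[30.0, 30.0, 42.0]])
        f1 = fs.run_mc_fluence(gm_block, center, gm_props, 40_000, seed=4,
                               beam="isotropic", n_batches=10, probes=probe)
        f2 = fs.run_mc_fluence(gm_block, center, gm_props, 80_000, seed=5,
                               beam="isotropic", n_batches=10, probes=probe)
        m1 = f1.batch_probe_values[:, 0]
        m2 = f2.batch_probe_values[:, 0]
        se = np.hypot(m1.std(ddof=1) / np.sqrt(10), m2.std(ddof=1) / np.sqrt(10))
        assert abs(m1.mean() - m2.mean()) <= 4 * se


class TestChannelSensitivity:
    def test_zero_detector_fluence_gives_zero(self, block_fluence):
        import dataclasses
        zero = dataclasses.replace(block_fluence,
                                   values=np.zeros_like(block_fluence.values))
        sens = fs.channel_sensitivity(block_fluence, zero, normalizer=1.0)
        assert np.all(sens == 0)

    def test_invalid_normalizer_rejected(self, block_fluence):
        with pytest.raises(ValueError, match="invalid channel"):
            fs.channel_sensitivity(block_fluence, block_fluence, 0.0)

    def test_perturbation_helper_extends_labels(self, gm_block, gm_props):
        labels, props = with_perturbed_voxel(gm_block.labels, gm_props,
                                             (15, 15, 15), 0.01)
        assert labels[15, 15, 15] == 6
        assert props.mua[6] == pytest.approx(gm_props.mua[GM] + 0.01)
        assert labels.sum() - gm_block.labels.sum() == 6 - GM


class TestAssembly:
    def test_matrix_shape_and_nonnegativity(self, flat_phantom, flat_montage):
        head, _, pial = flat_phantom
        proj = fs.VoronoiProjector(head, pial)
        A = fs.assemble_sensitivity_matrix(head, flat_montage,
                                           fs.OpticalProperties(760), pial,
                                           proj, 30_000, seed=21)
        assert A.A.shape == (flat_montage.n_channels, pial.n_vertices)
        assert np.all(A.A >= 0)

    def test_total_sensitivity_equals_projected_row_sums(self, flat_phantom,
                                                         flat_montage):
        head, _, pial = flat_phantom
        proj = fs.VoronoiProjector(head, pial)
        A = fs.assemble_sensitivity_matrix(head, flat_montage,
                                           fs.OpticalProperties(760), pial,
                                           proj, 30_000, seed=21)
        ts = fs.total_sensitivity(A)
        manual = np.zeros(pial.n_vertices)
        for row in A.A:
            manual = manual + row
        assert np.allclose(ts.values, manual)
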