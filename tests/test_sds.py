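"""Channel frames, depth quartiles, SDS surfaces, IUS and FWHM."""

import numpy as np
import pytest

import fnirs_sensfield as fs
from fnirs_sensfield.phantom import pial_depth_function
from fnirs_sensfield.sds import (BIN_CENTERS_MM, ChannelFrame, assign_quartile,
                                 compute_fwhm, compute_ius, compute_sds,
                                 pool_depth_quartiles)


def make_frame(depth, sens, channel_id=0):
    depth = np.asarray(depth, dtype=float)
    sens = np.asarray(sens, dtype=float)
    return ChannelFrame(channel_id=channel_id, gamma_mm=BIN_CENTERS_MM.copy(),
                        tau_mm=BIN_CENTERS_MM.copy(), depth_mm=depth,
                        sensitivity=sens, missing=~np.isfinite(depth))


class TestChannelFrame:
    def test_flat_anatomy_gives_constant_depth(self, flat_phantom, flat_params,
                                               flat_montage):
        _, scalp, pial = flat_phantom
        row = np.ones(pial.n_vertices)
        frame = fs.build_channel_frame(0, flat_montage, scalp, pial, row)
        d = frame.depth_mm[~frame.missing]
        assert d.size > 0
        assert np.allclose(d, flat_params.crown_depth_mm,
                           atol=flat_params.voxel_size_mm)

    def test_center_bin_is_channel_midpoint(self, flat_phantom, flat_montage):
        _, scalp, pial = flat_phantom
        m = flat_montage
        frame = fs.build_channel_frame(0, m, scalp, pial,
                                       np.ones(pial.n_vertices))
        ic = len(BIN_CENTERS_MM) // 2
        assert BIN_CENTERS_MM[ic] == 0.0
        assert not frame.missing[ic, ic]
        s, d = m.channels[0]
        mid = (m.sources[s] + m.detectors[d]) / 2
        assert np.allclose(m.channel_centers[0][:2], mid[:2], atol=1e-6)

    def test_corrugated_depths_match_generator_surface(self, small_phantom,
                                                       small_params):
        head, scalp, pial = small_phantom
        mont = fs.place_optodes(scalp, 2, 2, 30.0)
        frame = fs.build_channel_frame(0, mont, scalp, pial,
                                       np.ones(pial.n_vertices))
        z_p = pial_depth_function(small_params)
        s, d = mont.channels[0]
        g_dir = mont.detectors[d] - mont.sources[s]
        g_dir[2] = 0
        g_dir /= np.linalg.norm(g_dir)
        t_dir = np.array([-g_dir[1], g_dir[0], 0.0])
        cc = mont.channel_centers[0]
        for a in range(0, len(BIN_CENTERS_MM), 5):
            for b in range(0, len(BIN_CENTERS_MM), 5):
                if frame.missing[a, b]:
                    continue
                p = cc + BIN_CENTERS_MM[a] * g_dir + BIN_CENTERS_MM[b] * t_dir
                expected = z_p(p[0], p[1])
                assert frame.depth_mm[a, b] == pytest.approx(
                    expected, abs=small_params.voxel_size_mm)


class TestQuartiles:
    def test_eight_depths_median_boundary(self):
        d = np.full((21, 21), np.nan)
        d.ravel()[:8] = np.arange(1.0, 9.0)
        f = make_frame(d, np.ones_like(d))
        b = pool_depth_quartiles([f])
        assert b[1] == pytest.approx(4.5)

    def test_constant_depth_degenerates_to_q1(self):
        d = np.full((21, 21), 12.0)
        f = make_frame(d, np.ones_like(d))
        b = pool_depth_quartiles([f])
        q = assign_quartile(d, b)
        assert np.all(q == 1)

    def test_matches_brute_force_sort_oracle(self, rng):
        depths = rng.uniform(10, 25, size=(21, 21))
        f = make_frame(depths, np.ones_like(depths))
        b = pool_depth_quartiles([f])
        # brute-force linear-interpolation percentile on the sorted pool
        pool = np.sort(depths.ravel())
        n = pool.size
        for k, p in enumerate((0.25, 0.5, 0.75)):
            idx = p * (n - 1)
            lo = int(np.floor(idx))
            frac = idx - lo
            expect = pool[lo] * (1 - frac) + pool[min(lo + 1, n - 1)] * frac
            assert b[k] == pytest.approx(expect, rel=1e-12)

    def test_all_missing_raises(self):
        d = np.full((21, 21), np.nan)
        f = make_frame(d, d)
        with pytest.raises(ValueError):
            pool_depth_quartiles([f])


class TestSds:
    def test_identical_frames_reduce_to_single_frame(self):
        rng = np.random.default_rng(5)
        depth = rng.uniform(10, 20, (21, 21))
        sens = rng.random((21, 21))
        frames = [make_frame(depth, sens, i) for i in range(5)]
        b = pool_depth_quartiles(frames)
        sds = compute_sds(frames, b)
        q = assign_quartile(depth, b)
        for Q in (1, 2, 3, 4):
            m = q == Q
            assert np.allclose(sds[Q - 1][m], sens[m])
            assert np.all(np.isnan(sds[Q - 1][~m]))

    def test_constant_sensitivity_gives_constant_sds(self):
        rng = np.random.default_rng(6)
        frames = [make_frame(rng.uniform(10, 20, (21, 21)),
                             np.full((21, 21), 3.0), i) for i in range(3)]
        b = pool_depth_quartiles(frames)
        sds = compute_sds(frames, b)
        defined = np.isfinite(sds)
        assert np.allclose(sds[defined], 3.0)

    def test_two_channel_hand_enumerated_bins(self):
        # two frames, one bin populated with hand-listed (d, A) samples
        d1 = np.full((21, 21), np.nan)
        d2 = np.full((21, 21), np.nan)
        s1 = np.full((21, 21), np.nan)
        s2 = np.full((21, 21), np.nan)
        # bin (0, 0): depths 10 (Q1) and 40 (Q4); bin (0, 1): both mid
        d1[0, 0], s1[0, 0] = 10.0, 2.0
        d2[0, 0], s2[0, 0] = 40.0, 8.0
        d1[0, 1], s1[0, 1] = 20.0, 4.0
        d2[0, 1], s2[0, 1] = 21.0, 6.0
        frames = [make_frame(d1, s1, 0), make_frame(d2, s2, 1)]
        # pooled depths 10, 20, 21, 40 -> boundaries 17.5, 20.5, 25.75
        b = pool_depth_quartiles(frames)
        assert np.allclose(b, [17.5, 20.5, 25.75])
        sds = compute_sds(frames, b)
        assert sds[0][0, 0] == 2.0  # depth 10 in Q1
        assert sds[3][0, 0] == 8.0  # depth 40 in Q4
        assert sds[1][0, 1] == 4.0  # depth 20 <= 20.5 in Q2
        assert sds[2][0, 1] == 6.0  # depth 21 in Q3
        assert np.isnan(sds[0][0, 1])


class TestIus:
    def test_constant_quartile_surfaces(self):
        sds = np.stack([np.full((21, 21), v) for v in (4.0, 3.0, 2.0, 1.0)])
        ius = compute_ius(sds)
        assert np.allclose(ius, [40.0, 30.0, 20.0, 10.0])

    def test_equal_surfaces_give_25_each(self):
        sds = np.stack([np.full((21, 21), 1.0)] * 4)
        assert np.allclose(compute_ius(sds), 25.0)

    def test_percentages_sum_to_exactly_100(self, rng):
        sds = rng.random((4, 21, 21))
        sds[0, :3, :3] = np.nan
        assert compute_ius(sds).sum() == pytest.approx(100.0, abs=1e-12)

    def test_permutation_equivariance(self, rng):
        sds = rng.random((4, 21, 21))
        perm = [2, 0, 3, 1]
        assert np.allclose(compute_ius(sds)[perm], compute_ius(sds[perm]))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            compute_ius(np.zeros((4, 21, 21)))


class TestFwhm:
    def test_gaussian_sigma3_closed_form(self):
        sigma = 3.0
        gg, tt = np.meshgrid(BIN_CENTERS_MM, BIN_CENTERS_MM, indexing="ij")
        surf = np.exp(-(gg ** 2 + tt ** 2) / (2 * sigma ** 2))
        expect = 2 * np.sqrt(2 * np.log(2)) * sigma  # 7.064
        for axis in ("gamma", "tau"):
            w, cens = compute_fwhm(surf, axis)
            assert not cens
            assert w == pytest.approx(expect, abs=0.2)

    def test_triangular_profile(self):
        gg = np.meshgrid(BIN_CENTERS_MM, BIN_CENTERS_MM, indexing="ij")[0]
        surf = np.clip(1.0 - np.abs(gg) / 10.0, 0.0, None)
        w, cens = compute_fwhm(surf, "gamma")
        assert not cens
        assert w == pytest.approx(10.0, abs=1e-9)

    def test_bimodal_outermost_crossings_match_brute_force(self):
        x = BIN_CENTERS_MM
        prof = (np.exp(-(x + 8) ** 2 / 8.0) + 0.9 * np.exp(-(x - 10) ** 2 / 18.0))
        surf = np.tile(prof, (21, 1))
        w, cens = compute_fwhm(surf, "tau")
        # brute force: all half-max crossings by dense linear interpolation
        half = prof.max() / 2
        xs = np.linspace(x[0], x[-1], 200001)
        dense = np.interp(xs, x, prof)
        above = xs[dense >= half]
        assert not cens
        assert w == pytest.approx(above[-1] - above[0], abs=1e-3)

    def test_border_censoring_flagged(self):
        surf = np.ones((21, 21))
        w, cens = compute_fwhm(surf, "gamma")
        assert cens
        assert w == pytest.approx(BIN_CENTERS_MM[-1] - BIN_CENTERS_MM[0])

    def test_flat_zero_raises(self):
        with pytest.raises(ValueError):
            compute_fwhm(np.zeros((21, 21)), "gamma")
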