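"""BoxFD, lacunarity, and MSTFD estimators against analytic oracles."""

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from fractolung import (
    BinaryMask3D,
    PhantomSpec,
    ProfileSettings,
    box_counting_dimension,
    box_counts,
    compute_profile,
    compute_single_profile,
    generate_phantom,
    generate_point_cloud,
    lacunarity,
    mst_dimension_from_points,
    mst_fractal_dimension,
    mst_total_length,
)
from fractolung.errors import ConfigurationError, UndefinedMetricError
from tests.conftest import brute_force_box_counts, brute_force_lacunarity

MENGER_SLOPE = np.log(20) / np.log(3)


class TestBoxCounts:
    @pytest.mark.parametrize("seed,density", [(0, 0.05), (1, 0.3), (2, 0.8)])
    def test_matches_brute_force(self, seed, density):
        rng = np.random.default_rng(seed)
        occ = rng.random((16, 16, 16)) < density
        scales = [1, 2, 3, 4, 5, 8]
        np.testing.assert_array_equal(
            box_counts(occ, scales), brute_force_box_counts(occ, scales)
        )

    def test_menger_level3_counts_exact(self):
        occ = generate_phantom(PhantomSpec("menger_sponge", 27, level=3)).occupancy
        np.testing.assert_array_equal(
            box_counts(occ, [1, 3, 9]), [20**3, 20**2, 20]
        )

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        pattern = rng.random((10, 10, 10)) < 0.2
        big = np.zeros((32, 32, 32), bool)
        big[5:15, 7:17, 11:21] = pattern
        d_small, _ = box_counting_dimension(pattern, scales=[1, 2, 4])
        d_big, _ = box_counting_dimension(big, scales=[1, 2, 4])
        assert d_small == d_big  # bounding-box crop removes the offset

    def test_bad_scale(self):
        with pytest.raises(ConfigurationError):
            box_counts(np.ones((4, 4, 4), bool), [0])


class TestBoxCountingDimension:
    def test_filled_cube(self):
        d, _ = box_counting_dimension(np.ones((32, 32, 32), bool))
        assert d == pytest.approx(3.0, abs=0.05)

    def test_plane(self):
        occ = np.zeros((64, 64, 64), bool)
        occ[:, :, 30] = True
        d, _ = box_counting_dimension(occ)
        assert d == pytest.approx(2.0, abs=0.05)

    def test_menger_slope(self):
        occ = generate_phantom(PhantomSpec("menger_sponge", 81, level=4)).occupancy
        d, curve = box_counting_dimension(occ, scales=[1, 3, 9, 27])
        assert d == pytest.approx(MENGER_SLOPE, abs=1e-12)
        np.testing.assert_array_equal(curve.values, [20**4, 20**3, 20**2, 20])

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(4)
        occ = rng.random((20, 20, 20)) < 0.15
        d0, _ = box_counting_dimension(occ)
        d1, _ = box_counting_dimension(np.transpose(occ, (2, 0, 1)))
        assert d0 == d1

    def test_empty_mask(self):
        with pytest.raises(UndefinedMetricError):
            box_counting_dimension(np.zeros((8, 8, 8), bool))

    def test_fit_range_needs_three_scales(self):
        with pytest.raises(ConfigurationError):
            box_counting_dimension(np.ones((32, 32, 32), bool),
                                   fit_range=(1.0, 2.0))


class TestLacunarity:
    def test_homogeneous_volume_is_zero(self):
        lam, _ = lacunarity(np.ones((16, 16, 16), bool))
        assert lam == 0.0

    def test_checkerboard_r2_is_zero(self):
        x, y, z = np.indices((16, 16, 16))
        board = (x + y + z) % 2 == 0
        lam, _ = lacunarity(board, box_sizes=[2])
        assert lam == 0.0  # every 2-cube holds exactly 4 occupied voxels

    def test_single_voxel_oracle(self):
        occ = np.zeros((8, 8, 8), bool)
        occ[3, 4, 2] = True
        lam, _ = lacunarity(occ, box_sizes=[2])
        # 343 windows, 8 contain the voxel: Var/Mean^2 = 343/8 - 1
        assert lam == pytest.approx(343 / 8 - 1, abs=1e-12)
        assert lam == pytest.approx(41.875, abs=1e-12)

    @pytest.mark.parametrize("seed,density", [(0, 0.1), (1, 0.5)])
    def test_matches_enumeration_oracle(self, seed, density):
        rng = np.random.default_rng(seed)
        occ = rng.random((10, 10, 10)) < density
        for r in (2, 3, 4):
            lam, _ = lacunarity(occ, box_sizes=[r])
            assert lam == pytest.approx(brute_force_lacunarity(occ, r), abs=1e-10)

    def test_mean_over_scales(self):
        rng = np.random.default_rng(2)
        occ = rng.random((12, 12, 12)) < 0.3
        per_scale = [lacunarity(occ, box_sizes=[r])[0] for r in (2, 4)]
        lam, curve = lacunarity(occ, box_sizes=(2, 4))
        assert lam == pytest.approx(np.mean(per_scale))
        np.testing.assert_allclose(curve.values, per_scale)

    def test_errors(self):
        with pytest.raises(UndefinedMetricError):
            lacunarity(np.zeros((8, 8, 8), bool))
        with pytest.raises(ConfigurationError):
            lacunarity(np.ones((4, 4, 4), bool), box_sizes=[8])
        with pytest.raises(ConfigurationError):
            lacunarity(np.ones((4, 4, 4), bool), box_sizes=[0])


class TestMST:
    def test_collinear_points(self):
        pts = np.array([[0, 0, 0], [3, 0, 0], [1, 0, 0]], float)
        assert mst_total_length(pts) == pytest.approx(3.0)

    def test_matches_scipy_csgraph(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 50, size=(200, 3))
        dense = squareform(pdist(pts))
        expected = minimum_spanning_tree(dense).sum()
        assert mst_total_length(pts) == pytest.approx(expected, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ConfigurationError):
            mst_total_length(np.array([[0.0, 0.0, 0.0]]))

    @pytest.mark.parametrize("kind,target,tol", [
        ("volume", 3.0, 0.15), ("plane", 2.0, 0.15), ("line", 1.0, 0.1),
    ])
    def test_dimension_recovery(self, kind, target, tol):
        pts = generate_point_cloud(kind, 6000, seed=10)
        d, curve = mst_dimension_from_points(
            pts, subsample_sizes=(128, 256, 512, 1024), reps=5, seed=3
        )
        assert d == pytest.approx(target, abs=tol)
        if target > 1:  # a line's L(n) is ~constant, so R^2 is uninformative
            assert curve.r_squared > 0.99

    def test_validation(self):
        pts = generate_point_cloud("volume", 100, seed=0)
        with pytest.raises(ConfigurationError):
            mst_dimension_from_points(pts, subsample_sizes=(8, 16))
        with pytest.raises(ConfigurationError):
            mst_dimension_from_points(pts, subsample_sizes=(16, 32, 512))

    def test_mask_coordinates_respect_spacing(self):
        # the same occupancy on a stretched grid has longer MST edges
        rng = np.random.default_rng(6)
        occ = rng.random((12, 12, 12)) < 0.5
        iso = BinaryMask3D(occ, (1, 1, 1))
        aniso = BinaryMask3D(occ, (1, 1, 2.5))
        sizes, reps = (32, 64, 128, 256), 3
        d_iso, c_iso = mst_fractal_dimension(iso, sizes, reps=reps, seed=0)
        d_aniso, c_aniso = mst_fractal_dimension(aniso, sizes, reps=reps, seed=0)
        assert np.all(c_aniso.values > c_iso.values)


class TestProfiles:
    def _dust(self, seed=0):
        return generate_phantom(
            PhantomSpec("random_dust", 24, occupancy=0.5, seed=seed)
        )

    def _settings(self, seed=0):
        return ProfileSettings(
            mst_subsample_sizes=(64, 128, 256, 512), mst_reps=2, seed=seed
        )

    def test_identical_masks_give_zero_delta(self):
        mask = self._dust()
        pre, post, delta = compute_profile(mask, mask.copy(), self._settings())
        assert delta.d_boxfd == 0.0
        assert delta.d_lacunarity == 0.0
        assert delta.d_mstfd == 0.0

    def test_determinism(self):
        mask = self._dust()
        p1 = compute_single_profile(mask, self._settings(seed=42))
        p2 = compute_single_profile(mask, self._settings(seed=42))
        assert p1.as_row() == p2.as_row()
        assert p1.diagnostics == p2.diagnostics

    def test_diagnostics_recorded(self):
        prof = compute_single_profile(self._dust(), self._settings())
        d = prof.diagnostics
        assert d["settings"]["mst_reps"] == 2
        assert len(d["box_scales"]) == len(d["box_counts"])
        assert d["flags"] == []
        row = prof.as_row("pre_")
        assert set(row) == {"pre_boxfd", "pre_lacunarity", "pre_mstfd"}

    def test_anisotropic_mask_is_resampled(self):
        rng = np.random.default_rng(8)
        occ = rng.random((24, 24, 10)) < 0.5
        mask = BinaryMask3D(occ, (1.0, 1.0, 2.5))
        prof = compute_single_profile(mask, self._settings())
        assert 0 < prof.boxfd <= 3.0
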