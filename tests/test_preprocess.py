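import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import phenohull as ph
from phenohull.preprocess import RigidTransform, StatFilterParams


def _cloud(coords, colors=None):
    coords = np.asarray(coords, dtype=float)
    if colors is None:
        colors = np.zeros((len(coords), 3), dtype=np.uint8)
    return ph.PointCloud(coords=coords, colors=colors)


def _random_rigid(rng):
    return RigidTransform(
        Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix(),
        rng.normal(size=3),
    )


class TestRigidTransform:
    def test_identity_leaves_cloud_unchanged(self, random_cloud):
        out = ph.apply_rigid_transform(random_cloud, RigidTransform.identity())
        np.testing.assert_allclose(out.coords, random_cloud.coords)
        np.testing.assert_array_equal(out.colors, random_cloud.colors)

    def test_quarter_turn_about_vertical(self):
        R = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        out = ph.apply_rigid_transform(
            _cloud([[1, 0, 0]]), RigidTransform(R, np.zeros(3))
        )
        np.testing.assert_allclose(out.coords[0], [0, 0, -1], atol=1e-12)

    def test_composition_matches_matrix_product(self, rng, random_cloud):
        t1, t2 = _random_rigid(rng), _random_rigid(rng)
        via_compose = ph.apply_rigid_transform(
            ph.apply_rigid_transform(random_cloud, t1), t2
        )
        via_product = ph.apply_rigid_transform(random_cloud, t2.compose(t1))
        np.testing.assert_allclose(
            via_compose.coords, via_product.coords, atol=1e-9
        )

    def test_pairwise_distances_preserved(self, rng):
        cloud = _cloud(rng.normal(size=(50, 3)))
        out = ph.apply_rigid_transform(cloud, _random_rigid(rng))
        d0 = np.linalg.norm(
            cloud.coords[:, None] - cloud.coords[None], axis=2
        )
        d1 = np.linalg.norm(out.coords[:, None] - out.coords[None], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 2, np.zeros(3))
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestPrincipalAxisTransform:
    def test_vertical_cloud_maps_to_near_identity_rotation(self, rng):
        coords = rng.normal(size=(500, 3)) * [0.2, 3.0, 0.2]
        t = ph.principal_axis_transform(_cloud(coords))
        # growth axis already vertical: rotation fixes Y up to sign
        assert abs(t.rotation[1, 1]) > 0.99

    def test_recovers_tilted_plant_extent(self, rng):
        cloud, _ = ph.generate_plant_cloud(
            ph.make_profile("cylinder"), rings=20, azimuth_steps=36
        )
        h0 = ph.measure_height_width(cloud).height
        R = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        tilted = ph.apply_rigid_transform(
            cloud, RigidTransform(R, np.array([1.0, -2.0, 0.5]))
        )
        fixed = ph.apply_rigid_transform(
            tilted, ph.principal_axis_transform(tilted)
        )
        assert abs(ph.measure_height_width(fixed).height - h0) < 1e-3

    def test_centers_horizontal_centroid(self, rng):
        coords = rng.normal(size=(200, 3)) * [0.3, 2.0, 0.3] + [5, 0, -7]
        fixed = ph.apply_rigid_transform(
            _cloud(coords), ph.principal_axis_transform(_cloud(coords))
        )
        np.testing.assert_allclose(
            fixed.coords[:, [0, 2]].mean(axis=0), [0, 0], atol=1e-9
        )

    def test_degenerate_clouds_rejected(self):
        with pytest.raises(ValueError):
            ph.principal_axis_transform(_cloud([[0, 0, 0], [1, 1, 1]]))
        line = np.outer(np.arange(10), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            ph.principal_axis_transform(_cloud(line))


class TestStatisticalFilter:
    def test_hand_computed_outlier_band(self):
        # mean 2-NN distances: (1.5, 1, 1, 1.5, 97.5); mu=20.5, sigma~38.5
        coords = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [100, 0, 0]]
        out = ph.statistical_outlier_filter(
            _cloud(coords), StatFilterParams(k=2, std_mult=1.0)
        )
        np.testing.assert_array_equal(out.coords[:, 0], [0, 1, 2, 3])

    def test_huge_band_keeps_everything(self, random_cloud):
        out = ph.statistical_outlier_filter(
            random_cloud, StatFilterParams(k=5, std_mult=1e6)
        )
        assert len(out) == len(random_cloud)

    def test_uniform_grid_zero_variance_keeps_all(self):
        # every grid point (even a corner) has >= 3 axis neighbors at
        # distance 1, so with k=3 all mean distances are equal and the
        # zero-variance band contains the mean
        g = np.arange(5, dtype=float)
        coords = np.array(
            [(x, y, z) for x in g for y in g for z in g]
        )
        out = ph.statistical_outlier_filter(
            _cloud(coords), StatFilterParams(k=3, std_mult=1.0)
        )
        assert len(out) == len(coords)

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.normal(size=(120, 3))
        k, mult = 6, 1.0
        d = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        np.fill_diagonal(d, np.inf)
        mean_knn = np.sort(d, axis=1)[:, :k].mean(axis=1)
        mu, sigma = mean_knn.mean(), mean_knn.std()
        expected = (mean_knn >= mu - sigma * mult) & (
            mean_knn <= mu + sigma * mult
        )
        out = ph.statistical_outlier_filter(
            _cloud(coords), StatFilterParams(k=k, std_mult=mult)
        )
        np.testing.assert_allclose(out.coords, coords[expected])

    def test_repeat_application_never_grows(self, rng):
        coords = np.vstack(
            [rng.normal(size=(100, 3)), rng.uniform(20, 30, (5, 3))]
        )
        params = StatFilterParams(k=8, std_mult=1.0)
        once = ph.statistical_outlier_filter(_cloud(coords), params)
        twice = ph.statistical_outlier_filter(once, params)
        assert len(twice) <= len(once) <= len(coords)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="more than"):
            ph.statistical_outlier_filter(
                _cloud(np.zeros((3, 3))), StatFilterParams(k=3)
            )


class TestColorFilter:
    def test_full_range_is_identity(self, random_cloud):
        out = ph.color_condition_filter(
            random_cloud, (0, 0, 0), (255, 255, 255)
        )
        assert len(out) == len(random_cloud)

    def test_channelwise_band(self):
        cloud = _cloud(
            np.zeros((2, 3)), colors=[[10, 10, 10], [120, 200, 90]]
        )
        out = ph.color_condition_filter(cloud, (41, 41, 41), (255, 255, 255))
        assert len(out) == 1
        np.testing.assert_array_equal(out.colors[0], [120, 200, 90])

    def test_matches_per_point_predicate_oracle(self, rng):
        colors = rng.integers(0, 256, (500, 3))
        cloud = _cloud(rng.normal(size=(500, 3)), colors=colors)
        lo, hi = (30, 60, 10), (200, 220, 190)
        expected = np.array(
            [
                all(lo[c] <= col[c] <= hi[c] for c in range(3))
                for col in colors
            ]
        )
        out = ph.color_condition_filter(cloud, lo, hi)
        np.testing.assert_allclose(out.coords, cloud.coords[expected])

    def test_invalid_band_rejected(self, random_cloud):
        with pytest.raises(ValueError):
            ph.color_condition_filter(random_cloud, (100, 0, 0), (50, 255, 255))


class TestVoxelDownsample:
    def test_single_voxel_centroid(self):
        corners = np.array(
            [(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)],
            dtype=float,
        )
        out = ph.voxel_downsample(_cloud(corners), leaf=2.0)
        assert len(out) == 1
        np.testing.assert_allclose(out.coords[0], [0.5, 0.5, 0.5])

    def test_small_leaf_preserves_points(self, rng):
        coords = rng.uniform(0, 10, (200, 3))
        out = ph.voxel_downsample(_cloud(coords), leaf=1e-4)
        assert len(out) == len(coords)
        assert {tuple(np.round(p, 9)) for p in out.coords} == {
            tuple(np.round(p, 9)) for p in coords
        }

    def test_matches_bucket_mean_oracle(self, rng):
        coords = rng.uniform(-5, 5, (10_000, 3))
        leaf = 0.8
        out = ph.voxel_downsample(_cloud(coords), leaf=leaf)
        origin = coords.min(axis=0)
        buckets: dict[tuple, list] = {}
        for p in coords:
            buckets.setdefault(
                tuple(np.floor((p - origin) / leaf).astype(int)), []
            ).append(p)
        expected = {
            tuple(np.round(np.mean(v, axis=0), 9)) for v in buckets.values()
        }
        got = {tuple(np.round(p, 9)) for p in out.coords}
        assert got == expected
        assert len(out) <= len(coords)

    def test_bad_leaf_rejected(self, random_cloud):
        with pytest.raises(ValueError, match="leaf"):
            ph.voxel_downsample(random_cloud, leaf=0.0)


class TestTraits:
    def test_unit_cube(self):
        corners = np.array(
            [(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)],
            dtype=float,
        )
        traits = ph.measure_height_width(_cloud(corners))
        assert traits.height == pytest.approx(1.0)
        assert traits.width == pytest.approx(np.sqrt(2))

    def test_cylinder_preset_geometry(self):
        cloud, _ = ph.generate_plant_cloud(ph.make_profile("cylinder"))
        traits = ph.measure_height_width(cloud)
        assert traits.height == pytest.approx(4.5, abs=1e-9)
        assert traits.width == pytest.approx(1.60, abs=1e-6)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            ph.measure_height_width(_cloud([[0, 0, 0]]))
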