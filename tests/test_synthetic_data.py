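import numpy as np
import pytest

import lakechl.synthetic_data as synth
from lakechl.calibration import CANONICAL_COEFFICIENTS, chl_from_iops
from lakechl.flags import Flag, valid_pixel_mask
from lakechl.synthetic_data import SceneTruthParams


class TestGenerateLakeGeometry:
    def test_circle_cell_count_point_in_circle_oracle(self, circle_geometry):
        geo = circle_geometry
        grid = geo.grid
        cx = grid.x0 + grid.cols * grid.cell_size / 2
        cy = grid.y0 - grid.rows * grid.cell_size / 2
        count = 0
        for r in range(grid.rows):
            for c in range(grid.cols):
                x, y = grid.index_to_xy(r, c)
                if (x - cx) ** 2 + (y - cy) ** 2 < 900.0 ** 2:
                    count += 1
        assert geo.lake_mask.sum() == count
        assert abs(count - np.pi * 15 ** 2) / (np.pi * 15 ** 2) < 0.03

    def test_deterministic(self):
        a = synth.generate_lake_geometry(30, 30, 60, {"radius_m": 700}, seed=5)
        b = synth.generate_lake_geometry(30, 30, 60, {"radius_m": 700}, seed=5)
        assert np.array_equal(a.lake_mask, b.lake_mask)
        assert np.array_equal(a.bathymetry, b.bathymetry)
        assert a.lake_polygon.equals(b.lake_polygon)

    def test_bathymetry_shape(self, circle_geometry):
        geo = circle_geometry
        assert (geo.bathymetry >= 0).all()
        assert (geo.bathymetry[~geo.lake_mask] == 0).all()
        # deepest near the centroid
        from shapely.geometry import Point

        r, c = np.unravel_index(np.argmax(geo.bathymetry), geo.bathymetry.shape)
        x, y = geo.grid.index_to_xy(r, c)
        assert geo.lake_polygon.centroid.distance(Point(x, y)) < 3 * geo.grid.cell_size

    def test_degenerate_lake_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            synth.generate_lake_geometry(20, 20, 60, {"radius_m": 100})

    def test_tiny_grid_raises(self):
        with pytest.raises(ValueError, match="10x10"):
            synth.generate_lake_geometry(5, 50, 60)

    def test_working_resolution_default(self):
        geo = synth.generate_lake_geometry(20, 20, lake_shape_params={"radius_m": 400})
        assert geo.grid.cell_size == 60.0


class TestGenerateScene:
    def test_no_contamination_no_negative_flags(self, small_world):
        geo, truth, scenes, vwm = small_world
        for scene in scenes:
            neg = scene.flags & ~np.int32(Flag.IDEPIX_WATER | Flag.SHORE_SHALLOW_BUFFER)
            assert (neg == 0).all()
            assert valid_pixel_mask(scene.flags)[vwm].all()

    def test_noiseless_limit_exact(self, small_world):
        geo, truth, scenes, _ = small_world
        m = truth.lake_mask
        expected = truth.base_chl * truth.pattern[m]
        np.testing.assert_array_equal(scenes[0].chl[m], expected)

    def test_iop_forward_roundtrip(self, small_world):
        geo, truth, scenes, _ = small_world
        for scene in scenes:
            chk = chl_from_iops(scene.a_pig, scene.a_det, scene.a_cdom,
                                CANONICAL_COEFFICIENTS)
            m = truth.lake_mask
            rel = np.abs(chk[m] - scene.chl[m]) / scene.chl[m]
            assert rel.max() <= 1e-9

    def test_nan_outside_lake(self, small_world):
        geo, truth, scenes, _ = small_world
        assert np.isnan(scenes[0].chl[~truth.lake_mask]).all()

    def test_cloud_disc_area_and_buffer(self, circle_geometry):
        truth = synth.make_lake_truth(circle_geometry, n_scenes=1, seed=0)
        params = SceneTruthParams("2017-03-01T00:00:00Z", cloud_fraction=0.3)
        scene = synth.generate_scene(truth, params, seed=9)
        cloud = (scene.flags & np.int32(Flag.IDEPIX_CLOUD)) != 0
        n_lake = truth.lake_mask.sum()
        assert 0.15 * n_lake < cloud.sum()  # disc may extend past the lake
        buf = (scene.flags & np.int32(Flag.IDEPIX_CLOUD_BUFFER)) != 0
        assert not (buf & cloud).any()
        assert buf.any()

    def test_flag_noise_rates(self, circle_geometry):
        truth = synth.make_lake_truth(circle_geometry, n_scenes=1, seed=0)
        params = SceneTruthParams("2017-03-01T00:00:00Z",
                                  flag_noise_rates={"RTOSA_OOS": 0.5})
        scene = synth.generate_scene(truth, params, seed=2)
        hit = (scene.flags & np.int32(Flag.RTOSA_OOS)) != 0
        frac = hit[truth.lake_mask].mean()
        assert 0.4 < frac < 0.6
        assert not hit[~truth.lake_mask].any()

    def test_deterministic(self, circle_geometry):
        truth = synth.make_lake_truth(circle_geometry, n_scenes=1,
                                      noise_cv=0.2, seed=0)
        params = SceneTruthParams("2017-03-01T00:00:00Z", cloud_fraction=0.2)
        s1 = synth.generate_scene(truth, params, seed=7)
        s2 = synth.generate_scene(truth, params, seed=7)
        np.testing.assert_array_equal(s1.chl, s2.chl)
        np.testing.assert_array_equal(s1.flags, s2.flags)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            SceneTruthParams("2017-03-01", cloud_fraction=1.5)
        with pytest.raises(ValueError):
            SceneTruthParams("2017-03-01", flag_noise_rates={"IDEPIX_WATER": 0.1})
        with pytest.raises(KeyError):
            SceneTruthParams("2017-03-01", flag_noise_rates={"NOT_A_FLAG": 0.1})

    def test_negative_noise_cv_rejected(self, circle_geometry):
        with pytest.raises(ValueError, match="noise_cv"):
            synth.make_lake_truth(circle_geometry, noise_cv=-0.1)


class TestLakeTruthInvariants:
    def test_pattern_mean_near_one(self, small_world):
        geo, truth, _, _ = small_world
        assert abs(truth.pattern[truth.lake_mask].mean() - 1.0) <= 0.01

    def test_off_mean_pattern_rejected(self, circle_geometry):
        bad = np.full(circle_geometry.grid.shape, 1.3)
        with pytest.raises(ValueError, match="pattern mean"):
            synth.make_lake_truth(circle_geometry, pattern=bad)

    def test_pattern_recoverable_from_many_scenes(self):
        # averaging noisy scenes recovers the planted pattern within
        # 3*noise_cv/sqrt(n_scenes) per pixel (fixed-seed fixture)
        geo = synth.generate_lake_geometry(30, 30, 60, {"radius_m": 700}, seed=0)
        truth = synth.make_lake_truth(geo, base_chl=8.0, n_scenes=200,
                                      temporal_cv=0.0, noise_cv=0.1, seed=5)
        scenes = synth.generate_scene_series(truth, cloud_fraction=0.0, seed=105)
        est = np.nanmean(np.stack([s.chl for s in scenes]), axis=0) / truth.base_chl
        m = truth.lake_mask
        rel = np.abs(est[m] - truth.pattern[m]) / truth.pattern[m]
        assert rel.max() <= 3 * truth.noise_cv / np.sqrt(200)


class TestGenerateInsituSurvey:
    def test_noiseless_colocated(self, small_world):
        geo, truth, scenes, _ = small_world
        r, c = map(int, np.argwhere(truth.lake_mask)[10])
        samples = synth.generate_insitu_survey(truth, scenes, [(r, c)],
                                               time_offsets_h=0.0, seed=0)
        for sample, scene in zip(samples, scenes):
            assert sample.chl == scene.chl[r, c]
            assert sample.timestamp == scene.timestamp

    def test_candidate_counting(self, small_world):
        geo, truth, scenes, _ = small_world
        stations = [tuple(map(int, rc)) for rc in np.argwhere(truth.lake_mask)[:4]]
        samples = synth.generate_insitu_survey(truth, scenes, stations,
                                               time_offsets_h=3.0, seed=0)
        assert len(samples) == 4 * len(scenes)

    def test_30h_offset_rejected_downstream(self, small_world):
        from lakechl.matchup import build_matchups

        geo, truth, scenes, _ = small_world
        r, c = map(int, np.argwhere(truth.lake_mask)[0])
        samples = synth.generate_insitu_survey(truth, scenes[:1], [(r, c)],
                                               time_offsets_h=30.0, seed=0)
        assert build_matchups(samples, scenes[:1]) == []
        samples = synth.generate_insitu_survey(truth, scenes[:1], [(r, c)],
                                               time_offsets_h=-30.0, seed=0)
        assert build_matchups(samples, scenes[:1]) == []

    def test_station_outside_lake_raises(self, small_world):
        geo, truth, scenes, _ = small_world
        with pytest.raises(ValueError, match="outside the lake"):
            synth.generate_insitu_survey(truth, scenes, [(0, 0)], seed=0)

    def test_deterministic(self, small_world):
        geo, truth, scenes, _ = small_world
        r, c = map(int, np.argwhere(truth.lake_mask)[3])
        a = synth.generate_insitu_survey(truth, scenes, [(r, c)],
                                         time_offsets_h=(-12.0, 12.0),
                                         measurement_cv=0.1, seed=6)
        b = synth.generate_insitu_survey(truth, scenes, [(r, c)],
                                         time_offsets_h=(-12.0, 12.0),
                                         measurement_cv=0.1, seed=6)
        assert [(s.chl, s.timestamp) for s in a] == [(s.chl, s.timestamp) for s in b]


class TestGenerateSecchiSamples:
    def test_degenerate_sigma_zero(self):
        depths = synth.generate_secchi_samples(50, median=6.0, sigma=0.0, seed=0)
        assert (depths == 6.0).all()
        assert np.quantile(depths, 0.95) == 6.0

    def test_sample_quantile_near_analytic(self):
        median, sigma = 5.0, 0.4
        depths = synth.generate_secchi_samples(1000, median=median,
                                               sigma=sigma, seed=12)
        analytic = median * np.exp(1.6448536269514722 * sigma)
        assert np.quantile(depths, 0.95) == pytest.approx(analytic, rel=0.05)

    def test_positive(self):
        assert (synth.generate_secchi_samples(500, seed=1) > 0).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="at least 1"):
            synth.generate_secchi_samples(0)

    def test_deterministic(self):
        a = synth.generate_secchi_samples(20, seed=3)
        b = synth.generate_secchi_samples(20, seed=3)
        np.testing.assert_array_equal(a, b)
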