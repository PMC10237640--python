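"""Statistical structure of the synthetic coast, populations, flights, detections."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nearshore_overlap.camera import CameraModel, frame_footprint
from nearshore_overlap.config import GROUPS, CrossShoreLaw, GeneratorConfig
from nearshore_overlap.generator import (generate_coast, generate_environment,
                                         generate_subjects, render_detections,
                                         simulate_flight, survey_day_observations)


def cross2(u, v):
    return u[0] * v[1] - u[1] * v[0]


def segments_intersect(p1, p2, p3, p4):
    """Brute-force proper segment intersection test."""
    d1 = cross2(p4 - p3, p1 - p3)
    d2 = cross2(p4 - p3, p2 - p3)
    d3 = cross2(p2 - p1, p3 - p1)
    d4 = cross2(p2 - p1, p4 - p1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def cov_row_for(config, beach=0, day=0):
    env = generate_environment(config)
    return env[(env["beach"] == beach) & (env["day"] == day)].iloc[0]


class TestCoast:
    def test_constant_offset_break_is_translated_shoreline(self):
        cfg = GeneratorConfig(seed=1, break_offset_amplitude=0.0)
        coast = generate_coast(cfg, 0)
        assert np.allclose(coast.wavebreak[:, 0], coast.shoreline[:, 0])
        assert np.allclose(coast.wavebreak[:, 1], coast.shoreline[:, 1] + 50.0)

    def test_sinusoid_amplitude_bounds_offset(self):
        cfg = GeneratorConfig(seed=2, break_offset_mean=50.0, break_offset_amplitude=10.0)
        coast = generate_coast(cfg, 0)
        off = coast.wavebreak[:, 1] - coast.shoreline[:, 1]
        assert off.min() == pytest.approx(40.0, abs=0.5)
        assert off.max() == pytest.approx(60.0, abs=0.5)

    def test_polylines_never_cross_100_seeds(self):
        for seed in range(100):
            cfg = GeneratorConfig(seed=seed, break_offset_amplitude=30.0,
                                  break_offset_mean=50.0)
            coast = generate_coast(cfg, seed % 5)
            s, b = coast.shoreline, coast.wavebreak
            for i in range(len(s) - 1):
                for j in range(max(0, i - 2), min(len(b) - 1, i + 3)):
                    assert not segments_intersect(s[i], s[i + 1], b[j], b[j + 1])

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            generate_coast(GeneratorConfig(seed=0, beach_length=-1.0), 0)

    def test_crossing_amplitude_rejected(self):
        with pytest.raises(ValueError):
            generate_coast(GeneratorConfig(seed=0, break_offset_amplitude=60.0), 0)


class TestSubjects:
    def test_zero_rate_yields_no_subjects(self, small_config):
        cfg = small_config
        for gp in cfg.group_params.values():
            gp.base_mean = 0.0
        subj = generate_subjects(cfg, 0, 0, cov_row_for(cfg), generate_coast(cfg, 0))
        assert subj.empty

    def test_shark_lognormal_median_recovered(self):
        law = CrossShoreLaw("lognormal", {"median": 101.0, "sigma": 1.1})
        draws = law.sample(100_000, np.random.default_rng(3))
        assert np.median(draws) == pytest.approx(101.0, rel=0.01)

    def test_wader_distances_strictly_shoreward(self, small_config):
        cfg = small_config
        cfg.group_params["wader"].base_mean = 50.0
        subj = generate_subjects(cfg, 0, 0, cov_row_for(cfg), generate_coast(cfg, 0))
        waders = subj[subj["group"] == "wader"]
        assert len(waders) > 0
        assert (waders["signed_distance"] < 0).all()

    def test_unknown_group_rejected(self, small_config):
        from nearshore_overlap.generator import daily_mean
        with pytest.raises(ValueError, match="unknown group"):
            daily_mean(small_config, "kayaker", cov_row_for(small_config), 0)

    def test_positions_inside_beach_domain(self, small_config):
        cfg = small_config
        coast = generate_coast(cfg, 1)
        cov = cov_row_for(cfg, beach=1)
        frames = [generate_subjects(cfg, 1, d, cov, coast) for d in range(5)]
        subj = pd.concat(frames)
        assert subj["x"].between(0, cfg.beach_length).all()
        assert (subj["y"] > 0).all()  # everything seaward of the shoreline

    def test_uniform_alongshore_when_clustering_off(self):
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = GeneratorConfig(seed=seed)
            for gp in cfg.group_params.values():
                gp.alongshore_scale = None
                gp.base_mean = 0.0
            cfg.group_params["surfer"].base_mean = 150.0
            cfg.group_params["surfer"].alongshore_scale = None
            coast = generate_coast(cfg, 0)
            subj = generate_subjects(cfg, 0, 0, cov_row_for(cfg), coast)
            x = subj["x"].to_numpy() / cfg.beach_length
            if len(x) >= 20:
                p = sps.kstest(x, "uniform").pvalue
                rejections += p < 0.01
        assert rejections <= 0.05 * n_seeds


class TestFlight:
    def test_pose_spacing_is_speed_times_interval(self, small_config):
        cfg = small_config
        cfg.survey_speed = 6.0
        coast = generate_coast(cfg, 0)
        frames = simulate_flight(cfg, coast)
        leg0 = frames[frames["leg"] == 0]
        gaps = np.hypot(np.diff(leg0["x"]), np.diff(leg0["y"]))
        assert gaps == pytest.approx(30.0, abs=0.5)

    def test_first_leg_heading_constant_on_straight_shore(self, small_config):
        cfg = small_config
        cfg.break_offset_amplitude = 0.0
        frames = simulate_flight(cfg, generate_coast(cfg, 0))
        assert frames[frames["leg"] == 0]["heading"].nunique() == 1

    def test_later_legs_at_60m(self, small_config):
        frames = simulate_flight(small_config, generate_coast(small_config, 0))
        assert (frames.loc[frames["leg"] > 0, "altitude"] == 60.0).all()
        assert frames["altitude"].between(60, 120).all()

    def test_offshore_extent_beyond_domain_rejected(self, small_config):
        coast = generate_coast(small_config, 0)
        coast.domain_extent = 300.0
        with pytest.raises(ValueError):
            simulate_flight(small_config, coast)

    def test_footprints_cover_default_strip(self, small_config):
        cfg = small_config
        cfg.break_offset_amplitude = 0.0
        coast = generate_coast(cfg, 0)
        frames = simulate_flight(cfg, coast)
        cam = CameraModel()
        gx, gy = np.meshgrid(np.arange(1, 1000, 2.0), np.arange(1, 500, 2.0))
        covered = np.zeros(gx.shape, dtype=bool)
        for f in frames.itertuples():
            fw, fh, _ = frame_footprint(cam, f.altitude)
            theta = np.radians(f.heading)
            ct, st = np.cos(theta), np.sin(theta)
            dx, dy = gx - f.x, gy - f.y
            u = ct * dx + st * dy
            v = -st * dx + ct * dy
            covered |= (np.abs(u) <= fw / 2) & (np.abs(v) <= fh / 2)
        assert covered.mean() >= 0.99


class TestDetections:
    def test_zero_subjects_zero_detections(self, small_config):
        cfg = small_config
        coast = generate_coast(cfg, 0)
        frames = simulate_flight(cfg, coast)
        empty = pd.DataFrame(columns=["subject_id", "group", "beach", "day",
                                      "x", "y", "signed_distance", "marked"])
        det = render_detections(cfg, CameraModel(), frames, empty, "s0")
        assert det.empty

    def test_single_subject_single_footprint(self, small_config):
        cfg = small_config
        frames = pd.DataFrame([{"frame_id": 0, "leg": 0, "timestamp": 0.0,
                                "x": 100.0, "y": 45.0, "altitude": 60.0,
                                "heading": 0.0}])
        subj = pd.DataFrame([{"subject_id": "s1", "group": "surfer", "beach": 0,
                              "day": 0, "x": 110.0, "y": 50.0,
                              "signed_distance": 0.0, "marked": True}])
        det = render_detections(cfg, CameraModel(), frames, subj, "s0")
        assert len(det) == 1
        assert det.iloc[0]["key"] == "app-s1"

    def test_shark_availability_binomial(self, small_config):
        cfg = small_config
        cfg.shark_surface_prob = 0.7
        frames = pd.DataFrame([{"frame_id": 0, "leg": 0, "timestamp": 0.0,
                                "x": 100.0, "y": 45.0, "altitude": 60.0,
                                "heading": 0.0}])
        subj = pd.DataFrame([{"subject_id": "sh1", "group": "shark", "beach": 0,
                              "day": 0, "x": 100.0, "y": 45.0,
                              "signed_distance": 0.0, "marked": False}])
        n = 10_000
        rng = np.random.default_rng(9)
        hits = sum(len(render_detections(cfg, CameraModel(), frames, subj, "s0",
                                         rng=rng)) for _ in range(n))
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(hits / n - 0.7) < 3 * se

    def test_marked_sharks_carry_marks_unmarked_tracks(self, small_config):
        cfg = small_config
        cfg.group_params["shark"].base_mean = 30.0
        cfg.shark_surface_prob = 1.0
        coast = generate_coast(cfg, 0)
        frames = simulate_flight(cfg, coast)
        subj = generate_subjects(cfg, 0, 0, cov_row_for(cfg), coast)
        det = render_detections(cfg, CameraModel(), frames, subj, "s0")
        sharks = det[det["group"] == "shark"]
        assert len(sharks) > 0
        marked = sharks["mark_id"].notna()
        assert sharks.loc[marked, "key"].str.startswith("mark-").all()
        assert sharks.loc[~marked, "key"].str.startswith("trk-").all()

    def test_altitude_mismatch_rejected(self, small_config):
        frames = pd.DataFrame([{"frame_id": 0, "leg": 0, "timestamp": 0.0,
                                "x": 0.0, "y": 0.0, "altitude": 500.0,
                                "heading": 0.0}])
        subj = pd.DataFrame([{"subject_id": "s1", "group": "surfer", "beach": 0,
                              "day": 0, "x": 0.0, "y": 0.0,
                              "signed_distance": 0.0, "marked": True}])
        with pytest.raises(ValueError):
            render_detections(small_config, CameraModel(), frames, subj, "s0")


def test_fast_path_matches_distance_truth(small_config):
    cfg = small_config
    coast = generate_coast(cfg, 0)
    obs = survey_day_observations(cfg, coast, 0, 0, cov_row_for(cfg),
                                  measure_groups=("shark",))
    sharks = obs[obs["group"] == "shark"]
    if len(sharks):
        # measured polyline distance agrees with construction truth to ~1 m
        assert sharks["dist_break_m"].to_numpy() == pytest.approx(
            sharks["signed_distance"].to_numpy(), abs=2.0)


def test_environment_schema_and_ranges(small_config):
    env = generate_environment(small_config)
    assert len(env) == small_config.n_beaches * small_config.n_days
    assert env["wave_height"].ge(0).all()
    assert env["mean_wave_period"].gt(0).all()
    assert env["wave_direction"].between(0, 360).all()
    assert env["month"].between(1, 12).all()
    assert env["lunar_illumination"].between(0, 1).all()
    assert env["wind_speed"].le(8.0).all()  # drone operating limit
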