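"""Detection, linking, velocimetry, kymographs, colocalization, MSD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mukiss.imaging import (
    DriftingCluster,
    ImageSeries,
    LabelingBand,
    NoiseModel,
    PSFModel,
    QUIET,
    SpotModel,
    generate_cluster_timelapse,
    generate_extended_series,
    generate_punctual_series,
)
from mukiss.quant import (
    Kymograph,
    build_kymograph,
    cluster_timecourse,
    detect_spots,
    kymograph_feature_speed,
    link_trajectories,
    manders_coefficients,
    msd_exponent,
    velocity_map,
)
from mukiss.tracers import TrajectorySet


def _spot_frame(centers, amp=200.0, sigma_px=1.5, shape=(64, 64)):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.zeros(shape)
    for cx, cy in centers:
        img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                            / (2 * sigma_px**2))
    return img


class TestDetection:
    def test_single_spot_localized_within_tenth_pixel(self):
        img = _spot_frame([(30.3, 22.7)])
        locs = detect_spots(img, expected_size=3, threshold=5)
        assert len(locs) == 1
        assert locs["x"].iloc[0] == pytest.approx(30.3 + 0.5, abs=0.1)
        assert locs["y"].iloc[0] == pytest.approx(22.7 + 0.5, abs=0.1)

    def test_empty_frame_no_detections(self):
        locs = detect_spots(np.zeros((32, 32)), expected_size=3, threshold=5)
        assert len(locs) == 0

    def test_two_separated_spots_both_found(self):
        img = _spot_frame([(15.0, 15.0), (45.0, 45.0)])
        locs = detect_spots(img, expected_size=3, threshold=5)
        assert len(locs) == 2

    def test_small_expected_size_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((8, 8)), expected_size=1)

    def test_saturated_frame_warns(self):
        img = np.zeros((32, 32))
        img[:10] = 255.0
        with pytest.warns(UserWarning, match="saturated"):
            detect_spots(img, expected_size=3, threshold=1e9)


class TestLinking:
    def _locs(self, tracks):
        rows = []
        for f, pts in enumerate(tracks):
            for x, y in pts:
                rows.append({"frame": f, "x": x, "y": y})
        return pd.DataFrame(rows)

    def test_single_particle_full_track(self):
        locs = self._locs([[(1.0, 1.0)], [(1.2, 1.0)], [(1.4, 1.1)]])
        traj = link_trajectories(locs, max_displacement=0.5)
        assert len(traj.particle_ids) == 1
        assert len(traj.positions(traj.particle_ids[0])) == 3

    def test_two_separated_tracks_stay_distinct(self):
        locs = self._locs([
            [(0.0, 0.0), (10.0, 10.0)],
            [(0.3, 0.0), (9.7, 10.0)],
            [(0.6, 0.1), (9.4, 10.1)],
        ])
        traj = link_trajectories(locs, max_displacement=1.0)
        assert len(traj.particle_ids) == 2
        for pid in traj.particle_ids:
            assert len(traj.positions(pid)) == 3

    def test_zero_gate_every_localization_its_own_track(self):
        locs = self._locs([[(0.0, 0.0)], [(0.2, 0.0)], [(0.4, 0.0)]])
        traj = link_trajectories(locs, max_displacement=0.0)
        assert len(traj.particle_ids) == 3

    def test_memory_bridges_a_missed_frame(self):
        rows = [
            {"frame": 0, "x": 0.0, "y": 0.0},
            {"frame": 2, "x": 0.2, "y": 0.0},
        ]
        traj = link_trajectories(pd.DataFrame(rows), max_displacement=0.5,
                                 memory=1)
        assert len(traj.particle_ids) == 1

    def test_exact_tie_rejects_both(self):
        # two heads exactly equidistant from one localization
        locs = self._locs([[(0.0, 0.0), (2.0, 0.0)], [(1.0, 0.0)]])
        traj = link_trajectories(locs, max_displacement=1.5)
        lengths = sorted(len(traj.positions(p)) for p in traj.particle_ids)
        assert lengths == [1, 1, 1]  # no link formed


class TestVelocityMap:
    def test_uniform_translation_recovered_exactly(self):
        rows = []
        v = (3.0, -1.0)
        for pid, origin in enumerate([(0.0, 0.0), (2.0, 5.0)]):
            for k in range(10):
                rows.append({"particle_id": pid, "t": 0.1 * k,
                             "x": origin[0] + v[0] * 0.1 * k,
                             "y": origin[1] + v[1] * 0.1 * k, "z": 0.0})
        traj = TrajectorySet(pd.DataFrame(rows), frame_interval=0.1)
        vm = velocity_map(traj, np.arange(-1, 7, 1.0), np.arange(-2, 7, 1.0))
        occupied = vm["count"] > 0
        assert np.allclose(vm["vx"][occupied], 3.0)
        assert np.allclose(vm["vy"][occupied], -1.0)

    def test_empty_bins_masked_not_zero(self):
        rows = [{"particle_id": 0, "t": t, "x": 0.5 + t, "y": 0.5, "z": 0.0}
                for t in (0.0, 1.0)]
        traj = TrajectorySet(pd.DataFrame(rows), frame_interval=1.0)
        vm = velocity_map(traj, np.arange(0, 5, 1.0), np.arange(0, 5, 1.0))
        assert np.isnan(vm["vx"][3, 3])
        assert vm["count"][3, 3] == 0


class TestKymograph:
    def _extended(self, speed=0.0075, n_frames=120, noise=QUIET):
        band = LabelingBand(2.0, 0.8, 80.0)
        cl = DriftingCluster((1.5, 2.0), speed, amplitude=120.0, sigma=0.25)
        psf = PSFModel.from_optics(488.0, 1.0)
        return generate_extended_series(band, [cl], psf, noise,
                                        frame_interval=5.0,
                                        n_frames=n_frames, seed=3)

    def test_static_series_columns_identical(self):
        s = self._extended(speed=0.0, n_frames=8)
        kymo = build_kymograph(s, [[0.3, 2.0], [12.0, 2.0]], line_width=0.5)
        for j in range(1, kymo.data.shape[1]):
            np.testing.assert_allclose(kymo.data[:, j], kymo.data[:, 0])

    def test_ridge_slope_equals_cluster_speed(self):
        s = self._extended(speed=0.0075, n_frames=120)
        kymo = build_kymograph(s, [[0.3, 2.0], [12.0, 2.0]], line_width=0.5)
        speed, n_used = kymograph_feature_speed(kymo, (0.2, 2.2))
        assert speed == pytest.approx(7.5, rel=0.02)
        assert n_used == 120

    def test_line_width_irrelevant_on_noiseless_data(self):
        s = self._extended(speed=0.005, n_frames=40)
        k1 = build_kymograph(s, [[0.3, 2.0], [12.0, 2.0]], line_width=0.1)
        k5 = build_kymograph(s, [[0.3, 2.0], [12.0, 2.0]], line_width=0.5)
        s1, _ = kymograph_feature_speed(k1, (0.2, 2.2))
        s5, _ = kymograph_feature_speed(k5, (0.2, 2.2))
        assert s1 == pytest.approx(s5, rel=0.02)

    def test_time_reversal_negates_speed(self):
        s = self._extended(speed=0.0075, n_frames=60)
        kymo = build_kymograph(s, [[0.3, 2.0], [12.0, 2.0]], line_width=0.5)
        fwd, _ = kymograph_feature_speed(kymo, (0.2, 2.2))
        end = fwd * 1e-3 * kymo.times[-1]
        rev, _ = kymograph_feature_speed(
            kymo.time_reversed(), (0.2 + end, 2.2 + end))
        assert rev == pytest.approx(-fwd, rel=0.05)

    def test_static_feature_zero_speed(self):
        s = self._extended(speed=0.0, n_frames=40,
                           noise=NoiseModel(1.0, 2.0))
        kymo = build_kymograph(s, [[0.3, 2.0], [12.0, 2.0]], line_width=0.5)
        speed, _ = kymograph_feature_speed(kymo, (0.2, 2.2))
        assert abs(speed) < 0.4  # nm/s

    @pytest.mark.parametrize("true_speed", [2.0, 7.5, 20.0])
    def test_speed_recovery_across_magnitudes(self, true_speed):
        # unbiased within 5% at fixture noise across the nm/s decade
        s = self._extended(speed=true_speed * 1e-3, n_frames=120,
                           noise=NoiseModel(2.0, 5.0))
        kymo = build_kymograph(s, [[0.3, 2.0], [12.0, 2.0]], line_width=0.5)
        speed, _ = kymograph_feature_speed(kymo, (0.2, 2.2))
        assert speed == pytest.approx(true_speed, rel=0.05)

    def test_path_outside_frame_rejected(self):
        s = self._extended(speed=0.0, n_frames=5)
        with pytest.raises(ValueError, match="bounds"):
            build_kymograph(s, [[0.0, 2.0], [50.0, 2.0]])


class TestManders:
    def test_identical_images_full_overlap(self):
        img = _spot_frame([(10.0, 10.0), (25.0, 30.0)])
        res = manders_coefficients(img, img, thresholds=(0.0, 0.0))
        assert res.M1 == pytest.approx(1.0, abs=1e-6)
        assert res.M2 == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_supports_zero_overlap(self):
        a = np.zeros((40, 40))
        b = np.zeros((40, 40))
        a[5:10, 5:10] = 100.0
        b[25:30, 25:30] = 100.0
        res = manders_coefficients(a, b, thresholds=(50.0, 50.0))
        assert res.M1 == 0.0
        assert res.M2 == 0.0

    def test_empty_channel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            manders_coefficients(np.zeros((8, 8)), np.ones((8, 8)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            manders_coefficients(np.zeros((8, 8)), np.zeros((9, 8)))

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_m1_invariant_under_a_rescaling(self, c):
        # M1 = Σ c·A [B>T] / Σ c·A is scale-free in the A channel
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 100, (32, 32))
        b = rng.uniform(0, 100, (32, 32))
        base = manders_coefficients(a, b, thresholds=(50.0, 50.0))
        scaled = manders_coefficients(c * a, b, thresholds=(50.0, 50.0))
        assert scaled.M1 == pytest.approx(base.M1, rel=1e-9)

    def test_otsu_convention_recorded(self):
        img = _spot_frame([(10.0, 10.0)])
        res = manders_coefficients(img, img)
        assert res.threshold_method == "otsu"
        assert res.threshold_a > 0


class TestClusterTimecourse:
    def test_coalescence_count_down_size_up(self):
        series = generate_cluster_timelapse(
            n0=30, D_cluster=0.05, coalescence_radius=0.8, duration=300.0,
            noise=QUIET, seed=2)
        table = cluster_timecourse(series, threshold_method=1.0,
                                   min_area=0.05)
        counts = table.groupby("frame").size()
        areas = table.groupby("frame")["area_um2"].mean()
        assert counts.iloc[-1] < counts.iloc[0]
        assert areas.iloc[-1] > areas.iloc[0]

    def test_copy_number_exact_for_known_spot(self):
        img = np.zeros((48, 48))
        img[20:25, 20:25] = 40.0  # integrated 1000 counts
        series = ImageSeries(frames=img[None], pixel_size=0.1,
                             frame_interval=1.0)
        table = cluster_timecourse(series, threshold_method=10.0,
                                   unit_intensity=100.0)
        assert len(table) == 1
        assert table["copy_number"].iloc[0] == 10

    def test_min_area_filters_everything(self):
        img = np.zeros((32, 32))
        img[10:12, 10:12] = 50.0
        series = ImageSeries(frames=img[None], pixel_size=0.1,
                             frame_interval=1.0)
        table = cluster_timecourse(series, threshold_method=10.0,
                                   min_area=1.0)
        assert len(table) == 0

    def test_blank_frames_give_empty_rows_not_error(self):
        series = ImageSeries(frames=np.zeros((3, 16, 16)), pixel_size=0.1,
                             frame_interval=1.0)
        table = cluster_timecourse(series, threshold_method=5.0)
        assert len(table) == 0


class TestMSD:
    def _brownian(self, d_um2_s, n, length, seed, dt=0.1):
        rng = np.random.default_rng(seed)
        rows = []
        for pid in range(n):
            steps = rng.normal(0, np.sqrt(2 * d_um2_s * dt), (length, 2))
            pos = np.cumsum(steps, axis=0)
            for k in range(length):
                rows.append({"particle_id": pid, "t": k * dt,
                             "x": pos[k, 0], "y": pos[k, 1], "z": 0.0})
        return TrajectorySet(pd.DataFrame(rows), frame_interval=dt)

    def test_brownian_exponent_near_one(self):
        res = msd_exponent(self._brownian(0.1, 50, 100, seed=1))
        assert res.alpha == pytest.approx(1.0, abs=0.2)
        assert res.D_fit == pytest.approx(0.1, rel=0.3)

    def test_ballistic_exponent_two(self):
        rows = [{"particle_id": 0, "t": 0.1 * k, "x": 0.3 * k, "y": 0.1 * k,
                 "z": 0.0} for k in range(60)]
        traj = TrajectorySet(pd.DataFrame(rows), frame_interval=0.1)
        res = msd_exponent(traj)
        assert res.alpha == pytest.approx(2.0, abs=0.05)

    def test_stationary_track_zero_msd(self):
        rows = [{"particle_id": 0, "t": 0.1 * k, "x": 1.0, "y": 2.0, "z": 0.0}
                for k in range(40)]
        traj = TrajectorySet(pd.DataFrame(rows), frame_interval=0.1)
        res = msd_exponent(traj)
        assert np.all(res.msd < 1e-12)

    def test_short_track_rejected(self):
        rows = [{"particle_id": 0, "t": 0.1 * k, "x": float(k), "y": 0.0,
                 "z": 0.0} for k in range(5)]
        traj = TrajectorySet(pd.DataFrame(rows), frame_interval=0.1)
        with pytest.raises(ValueError, match="20"):
            msd_exponent(traj)
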