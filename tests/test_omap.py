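"""Optical-mapping analysis: filtering, activation, isochrones, APD, CV, block."""

import numpy as np
import pytest

from cardioep import syngen
from cardioep.omap import (ActivationMap, Movie, activation_brute_force,
                           activation_map, detect_block, isochrones,
                           measure_apd, measure_cv, normalize_polarity,
                           preprocess)
from cardioep.syngen import MapSimParams, gen_map_movie


def _act_from(movie):
    return activation_map(normalize_polarity(movie))


class TestPreprocess:
    def test_spatially_constant_frame_unchanged_by_median(self):
        data = np.tile(np.linspace(0, 1, 20)[:, None, None], (1, 8, 8))
        movie = Movie(data, 2.0, 80.0, [10.0], (4, 4))
        out = preprocess(movie, band=None)
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_single_pixel_impulse_removed(self):
        data = np.zeros((10, 9, 9))
        data[5, 4, 4] = 100.0
        movie = Movie(data, 2.0, 80.0, [4.0], (4, 4))
        out = preprocess(movie, band=None)
        assert out.data[5, 4, 4] == 0.0

    def test_noise_attenuated_vs_noise_free_twin(self):
        p = MapSimParams(n_rows=24, n_cols=24, pacing_site=(12, 12),
                         n_frames=120, noise_sd=0.1, seed=2)
        noisy, _ = gen_map_movie(p)
        clean, _ = gen_map_movie(syngen.MapSimParams(
            **{**p.__dict__, "noise_sd": 0.0}))
        out = preprocess(noisy)
        resid = out.data - preprocess(clean).data
        assert resid.std() < 0.1

    def test_polarity_normalized(self):
        p = MapSimParams(n_rows=16, n_cols=16, pacing_site=(8, 8), n_frames=110)
        movie, _ = gen_map_movie(p)
        inverted = Movie(-movie.data, movie.frame_interval, movie.pixel_size,
                         movie.stim_times, movie.pacing_site, polarity=-1)
        np.testing.assert_allclose(preprocess(inverted, band=None).data,
                                   preprocess(movie, band=None).data, atol=1e-12)

    def test_cutoffs_above_nyquist_rejected(self):
        p = MapSimParams(n_rows=8, n_cols=8, pacing_site=(4, 4), n_frames=50)
        movie, _ = gen_map_movie(p)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess(movie, band=(0.5, 300.0))


class TestActivationMap:
    def test_step_trace_activates_at_step_frame(self):
        data = np.zeros((60, 4, 4))
        data[30:] = 1.0          # step between frames 29 and 30
        movie = Movie(data, 2.0, 80.0, [10.0], (2, 2))
        act = activation_map(movie)
        # the forward difference localizes the edge at the interval center
        expected = 29.5 * 2.0 - 10.0
        np.testing.assert_allclose(act.activation_time, expected, atol=1e-9)

    def test_matches_brute_force_oracle_within_one_frame(self, small_movie):
        movie, truth, p = small_movie
        filtered = normalize_polarity(movie)
        act = activation_map(filtered)
        oracle = activation_brute_force(filtered)
        diff = np.abs(act.activation_time - oracle)[act.valid_mask]
        assert np.max(diff) < p.frame_interval

    def test_recovers_truth_activation(self, sham_movie):
        movie, truth, p = sham_movie
        act = _act_from(movie)
        rel = act.activation_time + act.reference_stim
        err = np.abs(rel - truth.activation_time)[act.valid_mask]
        assert np.median(err) < 0.1
        assert np.max(err) < p.frame_interval

    def test_blocked_pixels_invalid_low_snr(self):
        mask = np.zeros((40, 40), bool)
        mask[5:15, 5:15] = True
        p = MapSimParams(n_rows=40, n_cols=40, pacing_site=(25, 25),
                         block_mask=mask, n_frames=120, noise_sd=0.02, seed=4)
        movie, truth = gen_map_movie(p)
        act = _act_from(movie)
        assert np.mean(act.valid_mask[mask]) < 0.1
        assert act.invalid_reason["low SNR"][mask].mean() > 0.9
        assert np.mean(act.valid_mask[~mask]) > 0.95

    def test_time_translation_equivariance(self):
        """Delaying the movie by one cycle shifts activation by exactly that."""
        p = MapSimParams(n_rows=16, n_cols=16, pacing_site=(8, 8),
                         n_frames=110, first_stim=10.0)
        movie, _ = gen_map_movie(p)
        shift = 10                     # frames
        delayed_data = np.concatenate([np.zeros((shift, 16, 16)),
                                       movie.data[:-shift]], axis=0)
        delayed = Movie(delayed_data, movie.frame_interval, movie.pixel_size,
                        [movie.stim_times[0] + shift * movie.frame_interval],
                        movie.pacing_site)
        a1 = activation_map(movie)
        a2 = activation_map(delayed)
        np.testing.assert_allclose(a2.activation_time[a1.valid_mask & a2.valid_mask],
                                   a1.activation_time[a1.valid_mask & a2.valid_mask],
                                   atol=1e-9)

    def test_bad_stimulus_index_rejected(self, small_movie):
        movie, _, _ = small_movie
        with pytest.raises(ValueError, match="out of range"):
            activation_map(movie, stim_index=5)


class TestIsochrones:
    def test_band_indices_cover_range(self):
        t = np.tile(np.linspace(0, 19.99, 50), (10, 1))
        act = ActivationMap(t, np.ones_like(t), np.ones_like(t, bool), 0.0, 80.0)
        iso = isochrones(act, band_width=2.0)
        assert set(np.unique(iso.band_index)) == set(range(10))

    def test_uniform_field_single_band(self):
        t = np.full((6, 6), 7.0)
        act = ActivationMap(t, np.ones_like(t), np.ones_like(t, bool), 0.0, 80.0)
        iso = isochrones(act, band_width=2.0)
        assert np.all(iso.band_index == 3)

    def test_band_count_matches_truth_range(self, sham_movie):
        movie, truth, p = sham_movie
        act = _act_from(movie)
        iso = isochrones(act, band_width=2.0)
        trange = np.ptp(truth.activation_time)
        n_bands = len(np.unique(iso.band_index[iso.band_index >= 0]))
        assert abs(n_bands - np.ceil(trange / 2.0)) <= 1

    def test_invalid_pixels_get_sentinel(self):
        t = np.full((6, 6), 5.0)
        valid = np.ones((6, 6), bool)
        valid[0, 0] = False
        act = ActivationMap(t, np.ones_like(t), valid, 0.0, 80.0)
        assert isochrones(act).band_index[0, 0] == -1


class TestMeasureApd:
    def test_square_pulse_apds_equal_pulse_width(self):
        """A d-ms square pulse has APD50 = APD90 = d exactly."""
        d_frames = 25                 # 50 ms at 2 ms/frame
        data = np.zeros((120, 6, 6))
        data[30:30 + d_frames] = 1.0
        movie = Movie(data, 2.0, 80.0, [10.0], (3, 3))
        act = activation_map(movie)
        res = measure_apd(movie, act, {"all": (0, 6, 0, 6)})["all"]
        assert res.apd50 == pytest.approx(50.0, abs=1e-9)
        assert res.apd90 == pytest.approx(50.0, abs=1e-9)

    def test_template_apds_recovered(self, sham_movie):
        movie, truth, p = sham_movie
        act = _act_from(movie)
        res = measure_apd(normalize_polarity(movie), act,
                          {"c": (55, 65, 45, 55)})["c"]
        assert res.apd50 == pytest.approx(p.apd50, abs=2.0)
        assert res.apd90 == pytest.approx(p.apd90, abs=2.0)

    def test_apd90_never_below_apd50(self, rng):
        for seed in range(6):
            apd50 = float(rng.uniform(35, 80))
            apd90 = apd50 + float(rng.uniform(5, 45))
            p = MapSimParams(n_rows=16, n_cols=16, pacing_site=(8, 8),
                             apd50=apd50, apd90=apd90, n_frames=140,
                             noise_sd=0.03, seed=seed)
            movie, _ = gen_map_movie(p)
            act = _act_from(movie)
            res = measure_apd(normalize_polarity(movie), act,
                              {"c": (4, 12, 4, 12)})["c"]
            assert res.apd90 >= res.apd50 > 0

    def test_fully_invalid_roi_rejected(self):
        mask = np.zeros((30, 30), bool)
        mask[0:10, 0:10] = True
        p = MapSimParams(n_rows=30, n_cols=30, pacing_site=(20, 20),
                         block_mask=mask, n_frames=120, noise_sd=0.02)
        movie, _ = gen_map_movie(p)
        act = _act_from(movie)
        with pytest.raises(ValueError, match="no valid pixels"):
            measure_apd(movie, act, {"blocked": (1, 9, 1, 9)})


class TestMeasureCv:
    def test_isotropic_wave_recovered(self):
        p = MapSimParams(cv_long=50.0, cv_trans=50.0, n_frames=120, seed=1)
        movie, _ = gen_map_movie(p)
        cv = measure_cv(_act_from(movie))
        assert cv.cv_max == pytest.approx(50.0, rel=0.05)
        assert cv.cv_min == pytest.approx(50.0, rel=0.05)
        assert cv.anisotropy == pytest.approx(1.0, abs=0.05)

    def test_mild_preset_anisotropic_wave(self):
        p = MapSimParams(cv_long=184.0, cv_trans=32.0, fiber_angle=30.0,
                         n_frames=160)
        movie, _ = gen_map_movie(p)
        cv = measure_cv(_act_from(movie))
        assert cv.cv_max == pytest.approx(184.0, rel=0.05)
        assert cv.cv_min == pytest.approx(32.0, rel=0.05)
        assert abs(cv.angle_max - 30.0) <= 5.0
        assert cv.anisotropy == pytest.approx(184.0 / 32.0, rel=0.10)
        assert abs(cv.angle_max - cv.angle_min) % 180 == 90.0

    def test_flat_field_degenerate(self):
        t = np.full((60, 60), 12.0)
        act = ActivationMap(t, np.ones_like(t), np.ones_like(t, bool), 0.0,
                            80.0, pacing_site=(30, 30))
        with pytest.warns(UserWarning, match="non-positive slope"):
            with pytest.raises(ValueError, match="insufficient coverage"):
                measure_cv(act)

    def test_scaling_and_offset_invariance(self, sham_movie):
        """CV is unchanged by uniform fluorescence scaling and offsets."""
        movie, _, _ = sham_movie
        scaled = Movie(movie.data * 37.5 + 120.0, movie.frame_interval,
                       movie.pixel_size, movie.stim_times, movie.pacing_site)
        cv1 = measure_cv(_act_from(movie))
        cv2 = measure_cv(_act_from(scaled))
        assert cv2.cv_max == pytest.approx(cv1.cv_max, rel=1e-9)
        assert cv2.cv_min == pytest.approx(cv1.cv_min, rel=1e-9)

    def test_finer_sampling_consistent(self):
        """Halving the frame interval moves CV by less than the one-frame
        quantization bound."""
        base = dict(n_rows=60, n_cols=60, pacing_site=(30, 30),
                    cv_long=60.0, cv_trans=20.0, fiber_angle=0.0)
        p1 = MapSimParams(**base, frame_interval=2.0, n_frames=120)
        p2 = MapSimParams(**base, frame_interval=1.0, n_frames=240,
                          upstroke_rise=2.0)
        cv1 = measure_cv(_act_from(gen_map_movie(p1)[0]))
        cv2 = measure_cv(_act_from(gen_map_movie(p2)[0]))
        assert cv2.cv_max == pytest.approx(cv1.cv_max, rel=0.08)
        assert cv2.cv_min == pytest.approx(cv1.cv_min, rel=0.08)


class TestDetectBlock:
    def test_homogeneous_map_has_no_components(self, sham_movie):
        movie, _, _ = sham_movie
        assert detect_block(_act_from(movie)) == []

    def test_single_block_recovered_with_overlap(self):
        mask = np.zeros((100, 100), bool)
        mask[20:35, 60:75] = True              # 15×15 pixels
        p = MapSimParams(block_mask=mask, noise_sd=0.05, n_frames=160, seed=8)
        movie, truth = gen_map_movie(p)
        comps = detect_block(_act_from(movie))
        assert len(comps) >= 1
        overlap = (comps[0].mask & mask).sum() / mask.sum()
        assert overlap >= 0.9

    def test_two_disjoint_masks_two_components(self):
        mask = np.zeros((100, 100), bool)
        mask[10:22, 10:22] = True
        mask[70:82, 70:82] = True
        p = MapSimParams(block_mask=mask, noise_sd=0.05, n_frames=160, seed=9)
        movie, _ = gen_map_movie(p)
        comps = detect_block(_act_from(movie))
        assert len(comps) == 2
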