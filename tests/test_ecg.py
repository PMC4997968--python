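"""Beat detection, classification, averaging, delineation and measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioep import syngen
from cardioep.ecg import (AveragedBeat, DelineationConfig, EcgRecording,
                          analyze_recording, average_beats, classify_beats,
                          delineate, detect_beats, measure)
from cardioep.syngen import ECG_PRESETS, EcgSimParams, gen_ecg


def _r_truth_samples(truth, fs=1000.0):
    return np.round(truth.r_peak * fs / 1000.0).astype(int)


class TestDetectBeats:
    def test_clean_trace_finds_every_beat(self, sham_recording):
        (rec, truth), _ = sham_recording
        beats = detect_beats(rec)
        assert len(beats) == truth.n_beats
        diffs = np.abs(beats.r_peak_indices - _r_truth_samples(truth))
        assert diffs.max() <= 1

    def test_all_zero_trace_yields_empty_set(self):
        rec = EcgRecording(np.zeros(5000), 1000.0)
        with pytest.warns(UserWarning, match="no beats"):
            beats = detect_beats(rec)
        assert len(beats) == 0

    def test_inverted_beat_missed_or_flagged(self):
        rec, truth = gen_ecg(EcgSimParams(rr_jitter_frac=0.0))
        x = rec.samples.copy()
        r = _r_truth_samples(truth)
        lo, hi = r[5] - 60, r[5] + 90
        x[lo:hi] = -x[lo:hi]
        beats = detect_beats(EcgRecording(x, rec.sampling_rate))
        beats = classify_beats(EcgRecording(x, rec.sampling_rate), beats)
        near = np.abs(beats.r_peak_indices - r[5]) < 25
        # either the inverted beat is not detected as an R peak, or it is bad
        assert (not near.any()) or (not beats.quality[near].any())


class TestClassifyBeats:
    def test_identical_beats_all_good(self, sham_recording):
        (rec, truth), _ = sham_recording
        beats = classify_beats(rec, detect_beats(rec))
        # all beats whose window fits inside the recording are good
        assert beats.n_good >= truth.n_beats - 2
        # beats are sampled at different sub-sample phases, so correlations
        # sit just below 1 but well above the 0.9 acceptance threshold
        assert np.all(beats.template_correlation[beats.quality] > 0.95)

    def test_doubled_amplitude_beat_flagged_bad(self):
        rec, truth = gen_ecg(EcgSimParams(rr_jitter_frac=0.0))
        x = rec.samples.copy()
        r = _r_truth_samples(truth)
        lo, hi = r[10] - 60, r[10] + 90
        x[lo:hi] *= -2.0        # doubled and inverted: correlation collapses
        rec2 = EcgRecording(x, rec.sampling_rate)
        beats = classify_beats(rec2, detect_beats(rec2))
        j = int(np.argmin(np.abs(beats.r_peak_indices - r[10])))
        assert not beats.quality[j]

    def test_dropped_beat_flags_gap_neighbors(self):
        rec, truth = gen_ecg(EcgSimParams(rr_jitter_frac=0.0))
        x = rec.samples.copy()
        r = _r_truth_samples(truth)
        # blank out beat 20 entirely -> 2×RR gap between beats 19 and 21
        x[r[20] - 70:r[20] + 100] = 0.0
        rec2 = EcgRecording(x, rec.sampling_rate)
        beats = classify_beats(rec2, detect_beats(rec2))
        for rr_true in (r[19], r[21]):
            j = int(np.argmin(np.abs(beats.r_peak_indices - rr_true)))
            assert not beats.quality[j]

    def test_too_few_beats_all_bad(self):
        rec, _ = gen_ecg(EcgSimParams(duration=0.4, rr_jitter_frac=0.0))
        beats = detect_beats(rec)
        out = classify_beats(rec, beats)
        assert out.n_good == 0
        assert any("insufficient" in r for r in out.reasons)


class TestAverageBeats:
    def test_single_beat_average_is_that_beat(self):
        rec, truth = gen_ecg(EcgSimParams(rr_jitter_frac=0.0))
        beats = classify_beats(rec, detect_beats(rec))
        # keep exactly one good beat
        q = np.zeros(len(beats), bool)
        q[5] = beats.quality[5]
        beats.quality = q
        avg = average_beats(rec, beats, n_target=10)
        i = beats.r_peak_indices[5]
        np.testing.assert_array_equal(avg.samples, rec.samples[i - 80:i + 121])
        assert avg.n_averaged == 1

    def test_noise_reduction_follows_sqrt_n(self):
        """White-noise residual of the N-beat average shrinks as σ/√N."""
        sigma = 20.0
        base = EcgSimParams(rr_jitter_frac=0.0, duration=31.0)
        noisy, _ = gen_ecg(syngen.EcgSimParams(**{**base.__dict__,
                                                 "noise_sd": sigma}))
        clean, _ = gen_ecg(base)
        beats = classify_beats(noisy, detect_beats(noisy))
        avg = average_beats(noisy, beats, n_target=200)
        beats_c = classify_beats(clean, detect_beats(clean))
        avg_c = average_beats(clean, beats_c, n_target=200)
        resid = avg.samples - avg_c.samples
        expected = sigma / np.sqrt(avg.n_averaged)
        assert np.std(resid) == pytest.approx(expected, rel=0.10)

    def test_alignment_index_is_r_peak(self, sham_recording):
        (rec, truth), _ = sham_recording
        beats = classify_beats(rec, detect_beats(rec))
        avg = average_beats(rec, beats)
        assert int(np.argmax(avg.samples)) == avg.alignment_index

    def test_zero_good_beats_raises(self):
        rec, _ = gen_ecg(EcgSimParams(rr_jitter_frac=0.0))
        beats = classify_beats(rec, detect_beats(rec))
        beats.quality = np.zeros(len(beats), bool)
        with pytest.raises(ValueError, match="zero good beats"):
            average_beats(rec, beats)


class TestDelineate:
    @pytest.mark.parametrize("group", ["sham", "mild", "moderate", "severe"])
    def test_noise_free_fiducials_within_2ms(self, group):
        params = syngen.EcgSimParams(
            **{**ECG_PRESETS[group].__dict__, "rr_jitter_frac": 0.0, "seed": 1})
        rec, truth = gen_ecg(params)
        _, _, meas = analyze_recording(rec)
        assert meas.p_duration == pytest.approx(params.p_duration, abs=2.0)
        assert meas.pr_duration == pytest.approx(params.pr_interval, abs=2.0)
        assert meas.qrs_duration == pytest.approx(params.qrs_duration, abs=2.0)
        assert meas.qt_duration == pytest.approx(params.qt_interval, abs=2.0)

    def test_severe_inverted_t_reported_negative(self):
        params = syngen.EcgSimParams(
            **{**ECG_PRESETS["severe"].__dict__, "rr_jitter_frac": 0.0})
        rec, _ = gen_ecg(params)
        _, delin, meas = analyze_recording(rec)
        assert delin.t_peak is not None
        assert meas.t_amplitude == pytest.approx(-10.0, abs=3.0)

    def test_shift_equivariance(self, sham_recording):
        (rec, _), _ = sham_recording
        avg, delin, _ = analyze_recording(rec)
        shifted = AveragedBeat(avg.samples + 250.0, avg.alignment_index,
                               avg.n_averaged, avg.window, avg.sampling_rate)
        d2 = delineate(shifted)
        assert d2.isoelectric_level == pytest.approx(
            delin.isoelectric_level + 250.0, abs=1e-9)
        for name in ("p_onset", "qrs_onset", "qrs_offset", "t_end"):
            assert getattr(d2, name) == getattr(delin, name)

    def test_scale_equivariance(self, sham_recording):
        (rec, _), _ = sham_recording
        avg, delin, _ = analyze_recording(rec)
        mean_rr = 60000.0 / 414.0
        m1 = measure(delin, avg, mean_rr)
        scaled = AveragedBeat(avg.samples * 3.0, avg.alignment_index,
                              avg.n_averaged, avg.window, avg.sampling_rate)
        d2 = delineate(scaled)
        m2 = measure(d2, scaled, mean_rr)
        assert m2.qrs_duration == m1.qrs_duration
        assert m2.qt_duration == m1.qt_duration
        assert m2.p_amplitude == pytest.approx(3 * m1.p_amplitude, rel=1e-6)
        assert m2.qrs_sum == pytest.approx(3 * m1.qrs_sum, rel=1e-6)

    def test_flat_beat_raises_no_qrs(self):
        flat = AveragedBeat(np.zeros(200), 80, 1, (80.0, 120.0), 1000.0)
        with pytest.raises(ValueError, match="no QRS"):
            delineate(flat)

    def test_st_index_is_15ms_after_alignment(self, sham_recording):
        (rec, _), _ = sham_recording
        avg, delin, _ = analyze_recording(rec)
        assert delin.st_index == avg.alignment_index + 15


class TestMeasure:
    def _delin_beat(self):
        rec, _ = gen_ecg(EcgSimParams(rr_jitter_frac=0.0))
        beats = classify_beats(rec, detect_beats(rec))
        avg = average_beats(rec, beats)
        return delineate(avg), avg

    def test_bazett_identity_at_rr_1s(self):
        delin, avg = self._delin_beat()
        m = measure(delin, avg, 1000.0)
        assert m.qtc == pytest.approx(m.qt_duration, abs=1e-12)

    def test_bazett_sham_value(self):
        """QT 78 ms at 414 bpm gives QTc = 78/√(60/414) = 204.9 ms."""
        qtc = 78.0 / np.sqrt((60000.0 / 414.0) / 1000.0)
        assert qtc == pytest.approx(204.9, abs=0.05)
        delin, avg = self._delin_beat()
        m = measure(delin, avg, 60000.0 / 414.0)
        assert m.qtc == pytest.approx(m.qt_duration / np.sqrt(60.0 / 414.0),
                                      rel=1e-12)

    def test_qrs_sum_is_sum_of_absolute_deviations(self):
        from cardioep.ecg import Delineation
        samples = np.zeros(300)
        samples[140], samples[150], samples[160] = -100.0, 300.0, -150.0
        beat = AveragedBeat(samples, 150, 1, (150.0, 149.0), 1000.0)
        delin = Delineation(isoelectric_level=0.0, qrs_onset=138,
                            q_trough=140, r_peak=150, s_trough=160,
                            qrs_offset=162, st_index=165)
        m = measure(delin, beat, 1000.0)
        assert m.qrs_sum == pytest.approx(550.0, abs=1e-9)

    def test_nonpositive_rr_rejected(self):
        delin, avg = self._delin_beat()
        with pytest.raises(ValueError):
            measure(delin, avg, 0.0)


class TestRecoveryProperties:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        hr=st.floats(330, 440),
        p_dur=st.floats(12, 20),
        pr_extra=st.floats(18, 40),
        qrs=st.floats(14, 26),
        qt_extra=st.floats(40, 70),
        t_amp=st.floats(-80, 80).filter(lambda a: abs(a) > 15),
    )
    def test_delineation_ordering_invariant(self, hr, p_dur, pr_extra, qrs,
                                            qt_extra, t_amp):
        """Present fiducials are strictly ordered for randomized morphologies."""
        params = EcgSimParams(heart_rate=hr, p_duration=p_dur,
                              pr_interval=p_dur + pr_extra, qrs_duration=qrs,
                              qt_interval=qrs + qt_extra, t_amplitude=t_amp,
                              rr_jitter_frac=0.0, duration=4.0)
        rec, _ = gen_ecg(params)
        _, delin, _ = analyze_recording(rec, n_target=20)
        present = delin.ordered_present()
        vals = [v for _, v in present]
        assert vals == sorted(vals)
        pairs = dict(present)
        if "p_onset" in pairs and "p_peak" in pairs:
            assert pairs["p_onset"] < pairs["p_peak"] < pairs["qrs_onset"]

    def test_interval_recovery_over_seeded_presets(self):
        """Median |error| ≤ 2 ms per interval over seeded noise-free runs."""
        errs = {k: [] for k in ("p", "pr", "qrs", "qt")}
        for i in range(12):
            preset = ECG_PRESETS[list(ECG_PRESETS)[i % 4]]
            params = syngen.EcgSimParams(**{**preset.__dict__, "seed": i})
            rec, _ = gen_ecg(params)
            _, _, m = analyze_recording(rec)
            errs["p"].append(abs(m.p_duration - params.p_duration))
            errs["pr"].append(abs(m.pr_duration - params.pr_interval))
            errs["qrs"].append(abs(m.qrs_duration - params.qrs_duration))
            errs["qt"].append(abs(m.qt_duration - params.qt_interval))
        for k, v in errs.items():
            assert np.median(v) <= 2.0, (k, v)
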