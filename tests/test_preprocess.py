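"""Filter chain, rectification, the three normalization methods and
75 %-overlap windowing, each against an independent oracle."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from semgnet.io_emg import EmgRecording
from semgnet.preprocess import (FilterSpec, NormalizationStats, WindowSet,
                                apply_normalization, bandpass_notch,
                                fit_normalization, load_window_set, rectify,
                                save_window_set, window_signal)
from tests.conftest import tiny_recording


def _tone_rec(freq, fs=2000.0, n=4000, n_ch=2):
    t = np.arange(n) / fs
    emg = np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, n_ch))
    return EmgRecording(emg=emg, fs=fs,
                        stimulus=np.ones(n, dtype=np.int64),
                        repetition=np.ones(n, dtype=np.int64),
                        subject_id="T")


def _dft_amplitude(x, freq, fs):
    n = len(x)
    k = int(round(freq * n / fs))
    return 2 * np.abs(np.fft.rfft(x)[k]) / n


class TestFilterChain:
    def test_zero_in_zero_out(self):
        rec = _tone_rec(50.0)
        rec = replace(rec, emg=np.zeros_like(rec.emg))
        out = bandpass_notch(rec, FilterSpec())
        assert np.allclose(out.emg, 0.0)

    def test_notch_attenuates_50hz_by_20db(self):
        rec = _tone_rec(50.0)
        out = bandpass_notch(rec, FilterSpec())
        # skip filter edges when measuring steady-state amplitude
        a_in = _dft_amplitude(rec.emg[1000:3000, 0], 50.0, rec.fs)
        a_out = _dft_amplitude(out.emg[1000:3000, 0], 50.0, rec.fs)
        assert 20 * np.log10(a_in / a_out) >= 20.0

    def test_passband_100hz_within_1db(self):
        rec = _tone_rec(100.0)
        out = bandpass_notch(rec, FilterSpec())
        a_in = _dft_amplitude(rec.emg[1000:3000, 0], 100.0, rec.fs)
        a_out = _dft_amplitude(out.emg[1000:3000, 0], 100.0, rec.fs)
        assert abs(20 * np.log10(a_out / a_in)) <= 1.0

    def test_labels_and_shape_untouched(self, tiny_rec):
        out = bandpass_notch(tiny_rec, FilterSpec(band_high=45.0))
        assert out.emg.shape == tiny_rec.emg.shape
        assert np.array_equal(out.stimulus, tiny_rec.stimulus)

    def test_band_above_nyquist_clipped_with_warning(self, tiny_rec):
        with pytest.warns(UserWarning, match="Nyquist"):
            bandpass_notch(tiny_rec, FilterSpec(band_high=500.0))  # fs=100


class TestRectify:
    def test_absolute_value_and_idempotence(self, tiny_rec):
        out = rectify(tiny_rec)
        assert np.array_equal(out.emg, np.abs(tiny_rec.emg))
        assert np.array_equal(rectify(out).emg, out.emg)

    def test_mean_of_rectified_noise_positive(self):
        rec = tiny_recording(seed=11)
        assert abs(rec.emg.mean()) < 0.1          # zero-mean input
        assert rectify(rec).emg.mean() > 0.5


class TestNormalization:
    def test_unknown_method_or_scope_rejected(self, tiny_rec):
        with pytest.raises(ValueError, match="method"):
            fit_normalization([tiny_rec], "minmax", "subject")
        with pytest.raises(ValueError, match="scope"):
            fit_normalization([tiny_rec], "zscore", "channel")

    def test_zscore_per_channel_moments(self, tiny_rec):
        stats = fit_normalization([tiny_rec], "zscore", "subject_channel",
                                  labelled_only=False)
        out = apply_normalization(tiny_rec, stats["S00"])
        assert np.all(np.abs(out.emg.mean(axis=0)) < 1e-6)
        assert np.all(np.abs(out.emg.std(axis=0) - 1) < 1e-4)

    @pytest.mark.parametrize("method,lo,hi", [("range01", 0.0, 1.0),
                                              ("range_pm1", -1.0, 1.0)])
    @pytest.mark.parametrize("scope", ["subject", "subject_channel"])
    def test_range_methods_hit_extremes_on_fit_data(self, tiny_rec, method,
                                                    lo, hi, scope):
        stats = fit_normalization([tiny_rec], method, scope,
                                  labelled_only=False)
        out = apply_normalization(tiny_rec, stats["S00"])
        axis = None if scope == "subject" else 0
        assert np.allclose(out.emg.min(axis=axis), lo, atol=1e-6)
        assert np.allclose(out.emg.max(axis=axis), hi, atol=1e-6)

    def test_constant_signal_zscore_guarded_to_zeros(self):
        rec = tiny_recording()
        rec = replace(rec, emg=np.full_like(rec.emg, 3.5))
        with pytest.warns(UserWarning, match="eps"):
            stats = fit_normalization([rec], "zscore", "subject",
                                      labelled_only=False)
        assert stats["S00"].degenerate
        out = apply_normalization(rec, stats["S00"])
        assert np.allclose(out.emg, 0.0)

    def test_identity_stats_are_identity(self, tiny_rec):
        st_ = NormalizationStats(method="zscore", scope="subject",
                                 mean=np.array(0.0), std=np.array(1.0),
                                 min=np.array(-1.0), max=np.array(1.0),
                                 subject_id="S00", eps=0.0)
        out = apply_normalization(tiny_rec, st_)
        assert np.array_equal(out.emg, tiny_rec.emg)

    @pytest.mark.parametrize("method", ["range01", "zscore"])
    def test_invertible_given_stats(self, tiny_rec, method):
        stats = fit_normalization([tiny_rec], method, "subject_channel",
                                  labelled_only=False)["S00"]
        out = apply_normalization(tiny_rec, stats)
        if method == "range01":
            back = out.emg * (stats.max - stats.min + stats.eps) + stats.min
        else:
            back = out.emg * (stats.std + stats.eps) + stats.mean
        assert np.allclose(back, tiny_rec.emg, atol=1e-9)

    def test_subject_mismatch_guarded(self, tiny_rec):
        stats = fit_normalization([tiny_rec], "zscore", "subject")["S00"]
        other = replace(tiny_rec, subject_id="S99")
        with pytest.raises(ValueError, match="subject"):
            apply_normalization(other, stats)
        apply_normalization(other, stats, allow_subject_mismatch=True)

    def test_channel_shape_mismatch_rejected(self, tiny_rec):
        stats = fit_normalization([tiny_rec], "zscore", "subject_channel")["S00"]
        narrow = replace(tiny_rec, emg=tiny_rec.emg[:, :2])
        with pytest.raises(ValueError, match="channel"):
            apply_normalization(narrow, stats)

    def test_stats_respect_repetition_filter(self, tiny_rec):
        all_reps = fit_normalization([tiny_rec], "zscore", "subject")["S00"]
        train = fit_normalization([tiny_rec], "zscore", "subject",
                                  repetitions={1})["S00"]
        assert not np.allclose(all_reps.mean, train.mean)


class TestWindowing:
    def test_150ms_at_2khz_gives_300_samples_stride_75(self):
        rec = tiny_recording(run_len=800, fs=2000.0)
        ws = window_signal(rec, 150.0, 0.75)
        assert ws.window_len == 300
        assert ws.stride == 75

    def test_counts_match_bruteforce_enumeration(self):
        rec = tiny_recording(n_gestures=3, n_reps=2, run_len=137, fs=100.0)
        ws = window_signal(rec, 300.0, 0.75)   # 30 samples, stride 8
        wl, stride = ws.window_len, ws.stride
        # oracle: naive scan over every label-pure placement
        expected = 0
        stim, rep = rec.stimulus, rec.repetition
        for start in range(0, rec.n_samples - wl + 1):
            seg_s, seg_r = stim[start:start + wl], rep[start:start + wl]
            if seg_s[0] > 0 and len(set(seg_s)) == 1 and len(set(seg_r)) == 1:
                run_start = start
                while run_start > 0 and stim[run_start - 1] == seg_s[0] \
                        and rep[run_start - 1] == seg_r[0]:
                    run_start -= 1
                if (start - run_start) % stride == 0:
                    expected += 1
        assert len(ws) == expected
        # per-run closed form
        run_len = 137
        per_run = (run_len - wl) // stride + 1
        assert len(ws) == per_run * 3 * 2

    def test_windows_are_label_pure(self):
        rec = tiny_recording(n_gestures=2, n_reps=3, run_len=50, fs=100.0)
        ws = window_signal(rec, 200.0, 0.75)
        # re-read the label stream at each window's span
        pos = 0
        spans = []
        stim, rep = rec.stimulus, rec.repetition
        from semgnet.preprocess import _label_runs
        for s, e, g, r in _label_runs(stim, rep):
            for start in range(s, e - ws.window_len + 1, ws.stride):
                spans.append((start, g, r))
        assert len(spans) == len(ws)
        for (start, g, r), lab, rid in zip(spans, ws.labels, ws.repetition_ids):
            seg = stim[start:start + ws.window_len]
            assert set(seg) == {g} and lab == g - 1 and rid == r

    def test_run_shorter_than_window_yields_nothing(self):
        rec = tiny_recording(run_len=10, fs=100.0)
        with pytest.warns(UserWarning, match="empty"):
            ws = window_signal(rec, 500.0, 0.75)   # 50 > 10
        assert len(ws) == 0

    @settings(deadline=None, max_examples=25)
    @given(run_len=st.integers(5, 120), window_ms=st.integers(40, 600),
           overlap=st.sampled_from([0.0, 0.5, 0.75]))
    def test_count_formula_property(self, run_len, window_ms, overlap):
        rec = tiny_recording(n_gestures=1, n_reps=1, run_len=run_len,
                             rest_len=5, fs=100.0)
        wl = int(round(window_ms * rec.fs / 1000.0))
        stride = max(1, int(round(wl * (1 - overlap))))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ws = window_signal(rec, window_ms, overlap)
        expected = 0 if run_len < wl else (run_len - wl) // stride + 1
        assert len(ws) == expected

    def test_window_set_round_trip(self, tmp_path):
        rec = tiny_recording(run_len=60, fs=100.0)
        ws = window_signal(rec, 200.0, 0.75)
        p = tmp_path / "ws.h5"
        save_window_set(ws, p)
        back = load_window_set(p)
        assert np.array_equal(back.windows, ws.windows)
        assert np.array_equal(back.labels, ws.labels)
        assert list(back.subject_ids) == list(ws.subject_ids)
        assert back.stride == ws.stride
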