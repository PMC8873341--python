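"""MBLL inversion, filtering, epoching and normalization."""

import numpy as np
import pytest

from fnirs_transfer.exceptions import EmptyEpochsError, ValidationError
from fnirs_transfer.paradigm import REST_CODE, build_schedule
from fnirs_transfer.preprocess import (
    filter_magnitude_response,
    lowpass_filter,
    mbll_invert,
    normalize_examples,
    segment_epochs,
)
from fnirs_transfer.recordings import HemoRecording, OpticalRecording
from fnirs_transfer.simulate import hemodynamic_forward, make_cohort, mbll_forward
from fnirs_transfer.simulate import SubjectProfile


def hemo_from(data, schedule, fs=10.0):
    return HemoRecording(
        data=data, sampling_rate=fs, subject_id="X", schedule=schedule
    )


class TestMbllInvert:
    def test_zero_od_zero_concentration(self, short_schedule):
        rec = OpticalRecording(
            data=np.zeros((4, 2, short_schedule.n_samples)),
            sampling_rate=10.0, subject_id="X", schedule=short_schedule,
        )
        hemo = mbll_invert(rec)
        assert np.all(hemo.data == 0)

    def test_hand_solved_two_by_two_system(self, short_schedule):
        """eps=[[2,0],[0,4]], unit pathlength, dOD=(2,4) -> dc=(1,1)."""
        n = short_schedule.n_samples
        od = np.zeros((1, 2, n))
        od[0, 0], od[0, 1] = 2.0, 4.0
        rec = OpticalRecording(
            data=od, sampling_rate=10.0, subject_id="X", schedule=short_schedule,
            source_detector_mm=1.0,
        )
        hemo = mbll_invert(
            rec, extinction=np.array([[2.0, 0.0], [0.0, 4.0]]), dpf=(1.0, 1.0)
        )
        np.testing.assert_allclose(hemo.data[0, 0], 1.0)
        np.testing.assert_allclose(hemo.data[0, 1], 1.0)

    def test_round_trip_inverts_forward(self, short_schedule):
        """mbll_invert(mbll_forward(x)) == x to < 1e-9 relative error."""
        prof = SubjectProfile(
            subject_id="T", class_amplitudes=np.array([0.2, 0.5, 0.7]),
            channel_gains=np.ones(5), noise_white=0.1, noise_mayer=0.1, rng_seed=0,
        )
        hemo = hemodynamic_forward(short_schedule, prof)
        optical = mbll_forward(hemo)
        recovered = mbll_invert(optical)
        scale = np.abs(hemo.data).max()
        assert np.abs(recovered.data - hemo.data).max() / scale < 1e-9


class TestLowpassFilter:
    def test_constant_signal_unchanged(self, short_schedule):
        data = np.full((2, 2, short_schedule.n_samples), 3.7)
        out = lowpass_filter(hemo_from(data, short_schedule))
        np.testing.assert_allclose(out.data, data, atol=1e-9)
        assert out.filtered

    def test_stopband_attenuation_matches_analytic_response(self, short_schedule):
        """A 1 Hz sinusoid is attenuated by |H(1 Hz)|^2 of the filter."""
        n = short_schedule.n_samples
        t = np.arange(n) / 10.0
        data = np.sin(2 * np.pi * 1.0 * t)[None, None, :] * np.ones((1, 2, 1))
        out = lowpass_filter(hemo_from(data, short_schedule))
        mid = out.data[0, 0, n // 4 : 3 * n // 4]
        t_mid = t[n // 4 : 3 * n // 4]
        # amplitude via quadrature projection on the probe frequency
        amp = 2 * np.abs(np.mean(mid * np.exp(-2j * np.pi * 1.0 * t_mid)))
        expected = filter_magnitude_response(1.0)
        assert amp == pytest.approx(expected, rel=0.01)

    def test_passband_near_unity(self, short_schedule):
        n = short_schedule.n_samples
        t = np.arange(n) / 10.0
        data = np.sin(2 * np.pi * 0.05 * t)[None, None, :] * np.ones((1, 2, 1))
        out = lowpass_filter(hemo_from(data, short_schedule))
        mid = out.data[0, 0, n // 4 : 3 * n // 4]
        amp = 2 * np.abs(np.mean(mid * np.exp(-2j * np.pi * 0.05 * t[n // 4 : 3 * n // 4])))
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_idempotent_in_passband(self, short_schedule):
        """Filtering twice changes a 0.05 Hz tone's amplitude by < 2%."""
        n = short_schedule.n_samples
        t = np.arange(n) / 10.0
        data = np.sin(2 * np.pi * 0.05 * t)[None, None, :] * np.ones((1, 2, 1))
        once = lowpass_filter(hemo_from(data, short_schedule))
        twice = lowpass_filter(once)
        sl = slice(n // 4, 3 * n // 4)
        a1 = np.ptp(once.data[0, 0, sl])
        a2 = np.ptp(twice.data[0, 0, sl])
        assert abs(a2 - a1) / a1 < 0.02

    def test_cutoff_beyond_nyquist_rejected(self, short_schedule):
        data = np.zeros((1, 2, short_schedule.n_samples))
        with pytest.raises(ValidationError):
            lowpass_filter(hemo_from(data, short_schedule), cutoff_hz=5.0)


class TestSegmentEpochs:
    def test_task_segment_window_count(self, short_schedule):
        """40 s task segments at window 10 s / step 5 s give 7 windows each."""
        data = np.zeros((3, 2, short_schedule.n_samples))
        eps = segment_epochs(hemo_from(data, short_schedule), window_s=10, step_s=5)
        # 3 series x 7 windows, rest excluded in 3-class mode
        assert eps.n_examples == 21
        assert set(np.unique(eps.y)) == {0, 1, 2}

    def test_window_equal_to_segment_gives_one(self, short_schedule):
        data = np.zeros((2, 2, short_schedule.n_samples))
        eps = segment_epochs(hemo_from(data, short_schedule), window_s=40, step_s=5)
        assert eps.n_examples == 3

    def test_four_class_mode_includes_rest(self, short_schedule):
        data = np.zeros((2, 2, short_schedule.n_samples))
        eps = segment_epochs(
            hemo_from(data, short_schedule), window_s=10, step_s=5, class_mode="4class"
        )
        # + 3 rest segments of 20 s -> 3 windows each
        assert eps.n_examples == 21 + 9
        assert REST_CODE in eps.y

    def test_window_longer_than_every_segment_errors(self, short_schedule):
        data = np.zeros((2, 2, short_schedule.n_samples))
        with pytest.raises(EmptyEpochsError):
            segment_epochs(hemo_from(data, short_schedule), window_s=50, step_s=5)

    def test_count_formula_and_no_straddling(self, default_schedule):
        """Counts follow floor((L-W)/S)+1 and windows stay inside segments."""
        fs = 10.0
        n = default_schedule.n_samples
        # encode the sample index so window content reveals its position
        data = np.arange(n, dtype=float)[None, None, :] * np.ones((1, 2, 1))
        for window_s, step_s, mode in [(10, 5, "3class"), (10, 10, "4class"), (7, 3, "3class")]:
            eps = segment_epochs(
                hemo_from(data, default_schedule), window_s=window_s, step_s=step_s,
                class_mode=mode,
            )
            win = int(window_s * fs)
            step = int(step_s * fs)
            include_rest = mode == "4class"
            expected = sum(
                max((seg.n_samples - win) // step + 1, 0)
                for seg in default_schedule.segments(include_rest=include_rest)
            )
            assert eps.n_examples == expected
            track = default_schedule.label_track()
            for i in range(eps.n_examples):
                start = int(eps.X[i, 0, 0, 0])
                labels = track[start : start + win]
                assert np.all(labels == eps.y[i]), "window straddles a segment boundary"

    def test_deterministic_ordering(self, short_schedule):
        data = np.random.default_rng(0).normal(size=(2, 2, short_schedule.n_samples))
        a = segment_epochs(hemo_from(data, short_schedule))
        b = segment_epochs(hemo_from(data, short_schedule))
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.series_idx, b.series_idx)


class TestNormalizeExamples:
    def test_none_is_identity(self, subject_epochs):
        out = normalize_examples(subject_epochs, "none")
        assert out is subject_epochs

    def test_zscore_moments_on_training_fold(self, subject_epochs):
        n = subject_epochs.n_examples
        train = np.arange(n // 2)
        out = normalize_examples(subject_epochs, "zscore", train_idx=train)
        fit = out.X[train]
        np.testing.assert_allclose(fit.mean(axis=(0, 3)), 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.std(axis=(0, 3)), 1.0, atol=1e-10)

    def test_heldout_shift_survives(self, subject_epochs):
        """Train statistics applied to shifted held-out data keep the shift."""
        n = subject_epochs.n_examples
        train = np.arange(n // 2)
        shifted = subject_epochs.subset(np.arange(n))
        shifted.X[n // 2 :] += 5.0
        out = normalize_examples(shifted, "zscore", train_idx=train)
        assert abs(out.X[n // 2 :].mean()) > 1.0

    def test_zero_variance_channel_warns(self, short_schedule):
        data = np.zeros((2, 2, short_schedule.n_samples))
        eps = segment_epochs(hemo_from(data, short_schedule))
        with pytest.warns(UserWarning, match="zero-variance"):
            normalize_examples(eps, "zscore")

    def test_unknown_scheme_rejected(self, subject_epochs):
        with pytest.raises(ValidationError):
            normalize_examples(subject_epochs, "minmax")
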