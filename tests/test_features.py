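import numpy as np
import pytest

from vocalrisk.audio_io import PhonationClip, frame_signal
from vocalrisk import features as F
from vocalrisk.errors import (ConfigurationError, DataIntegrityError,
                              InsufficientPeriodicityError)
from vocalrisk.synth import VoiceParams, standardize_clip, synthesize_vowel

FS = 16_000


def sawtooth(f0, seconds=1.0, amp=0.5):
    t = np.arange(int(seconds * FS)) / FS
    return amp * (2 * ((t * f0) % 1.0) - 1.0)


class TestPitch:
    def test_sawtooth_fully_voiced_at_true_f0(self):
        frames = frame_signal(PhonationClip(sawtooth(100.0)))
        track = F.estimate_pitch(frames)
        assert track.voicing_flags.all()
        assert np.all((track.frame_f0 >= 99) & (track.frame_f0 <= 101))

    def test_white_noise_mostly_unvoiced(self, rng):
        frames = frame_signal(PhonationClip(0.3 * rng.standard_normal(FS)))
        track = F.estimate_pitch(frames)
        assert np.mean(~track.voicing_flags) >= 0.9

    def test_synth_round_trip_220(self):
        p = VoiceParams(f0=220, jitter_pct=0.0, shimmer_pct=0.0,
                        target_hnr_db=40, drift_pct=0.0, seed=3)
        fv = F.clip_features(standardize_clip(synthesize_vowel(p)))
        assert 219 <= fv["F0_mean"] <= 221

    def test_max_pitch_bounds_mean(self, typical_clip):
        fv = F.clip_features(typical_clip)
        assert fv["Max_Pitch"] >= fv["F0_mean"] >= fv["Min_Pitch"]


class TestCycles:
    def test_pulse_train_marks_spacing(self):
        x = np.zeros(FS)
        x[::160] = 1.0  # 100 Hz pulse train
        clip = PhonationClip(0.5 * np.convolve(x, np.hanning(9), "same"))
        track = F.estimate_pitch(frame_signal(clip))
        cycles = F.mark_cycles(clip, track)
        periods = np.diff(cycles.period_marks)
        assert np.all(np.abs(periods - 160) <= 1.0)

    def test_planted_jitter_recovered_in_period_cv(self):
        cvs = []
        for seed in range(5):
            p = VoiceParams(f0=140, jitter_pct=2.0, shimmer_pct=1.0,
                            target_hnr_db=30, seed=seed)
            clip = standardize_clip(synthesize_vowel(p))
            track = F.estimate_pitch(frame_signal(clip))
            t = F.mark_cycles(clip, track).periods_s
            cvs.append(np.std(t) / np.mean(t))
        assert 0.015 <= np.mean(cvs) <= 0.025

    def test_unvoiced_noise_rejected(self, rng):
        clip = PhonationClip(0.3 * rng.standard_normal(FS))
        track = F.estimate_pitch(frame_signal(clip))
        with pytest.raises(InsufficientPeriodicityError):
            F.mark_cycles(clip, track)


class TestPerturbation:
    def test_perfect_periodicity_zero(self):
        marks = np.arange(20) * 160.0
        cycles = F.CycleSequence(period_marks=marks,
                                 cycle_peak_amplitudes=np.ones(19))
        jit, rap, shim = F.perturbation_features(cycles)
        assert jit == 0.0 and rap == 0.0 and shim == 0.0

    def test_alternating_periods_hand_values(self):
        # periods 9, 11, 9, 11 ms: jitter = 2/10, RAP = mean(4/3, 4/3)/10
        periods_s = np.array([0.009, 0.011, 0.009, 0.011])
        marks = np.concatenate([[0.0], np.cumsum(periods_s)]) * FS
        cycles = F.CycleSequence(period_marks=marks,
                                 cycle_peak_amplitudes=np.ones(4))
        jit, rap, _ = F.perturbation_features(cycles)
        assert jit == pytest.approx(0.2, abs=1e-9)
        assert rap == pytest.approx(0.13333, abs=1e-4)

    def test_non_positive_period_rejected(self):
        cycles = F.CycleSequence(period_marks=np.array([0.0, 160.0, 150.0]),
                                 cycle_peak_amplitudes=np.ones(2))
        with pytest.raises(DataIntegrityError):
            F.perturbation_features(cycles)

    def test_scale_invariance_through_normalization(self, typical_clip):
        from vocalrisk.audio_io import normalize
        fv1 = F.clip_features(typical_clip)
        rescaled = PhonationClip(normalize(typical_clip.samples * 0.37))
        fv2 = F.clip_features(rescaled)
        for k in ("Jitter_local", "Shimmer_local", "RAP", "HNR_mean"):
            assert fv2[k] == pytest.approx(fv1[k], rel=1e-9)


class TestHNR:
    def test_closed_form_mapping(self):
        assert F.hnr_db_from_r(0.5) == pytest.approx(0.0, abs=1e-12)
        assert F.hnr_db_from_r(0.99) == pytest.approx(19.956, abs=1e-2)
        assert F.hnr_db_from_r(1.0) == pytest.approx(40.0, abs=0.01)  # clamp
        assert F.hnr_db_from_r(1e-9) == -10.0                         # clamp

    def test_planted_hnr_round_trip(self):
        vals = []
        for seed in range(5):
            p = VoiceParams(f0=140, jitter_pct=0.3, shimmer_pct=1.0,
                            target_hnr_db=10.0, seed=seed)
            fv = F.clip_features(standardize_clip(synthesize_vowel(p)))
            vals.append(fv["HNR_mean"])
        assert 8.0 <= np.mean(vals) <= 12.0

    def test_no_voiced_frames_rejected(self, rng):
        frames = frame_signal(PhonationClip(0.1 * rng.standard_normal(FS)))
        track = F.estimate_pitch(frames)
        track.voicing_flags[:] = False
        with pytest.raises(InsufficientPeriodicityError):
            F.hnr_track(frames, track)


class TestCPP:
    def test_periodicity_ordering(self, rng):
        saw = sawtooth(150.0)
        noise = rng.standard_normal(FS)
        noise *= np.sqrt(np.mean(saw ** 2) / np.mean(noise ** 2))
        cpp_saw, _ = F.cpp_stats(frame_signal(PhonationClip(saw)))
        cpp_noise, cpp_noise_std = F.cpp_stats(frame_signal(PhonationClip(noise)))
        assert cpp_saw > cpp_noise
        assert cpp_noise_std > 0.0

    def test_peak_quefrency_matches_period(self):
        p = VoiceParams(f0=200, jitter_pct=0.0, shimmer_pct=0.0,
                        target_hnr_db=40, drift_pct=0.0, seed=2)
        clip = standardize_clip(synthesize_vowel(p))
        _, quefrency = F.cpp_track(frame_signal(clip))
        assert np.median(quefrency) == pytest.approx(1 / 200, abs=2e-4)

    def test_fft_shorter_than_frame_rejected(self, clean_clip):
        with pytest.raises(ConfigurationError):
            F.cpp_track(frame_signal(clean_clip), nfft=256)


class TestHarmonics:
    def test_pure_sinusoid_hits_floor(self):
        t = np.arange(FS) / FS
        frames = frame_signal(PhonationClip(0.5 * np.sin(2 * np.pi * 150 * t)))
        track = F.estimate_pitch(frames)
        assert np.mean(F.hrf_track(frames, track)) <= -30.0 + 1e-9

    def test_two_equal_partials_ratio_one(self):
        t = np.arange(FS) / FS
        x = 0.4 * np.sin(2 * np.pi * 150 * t) + 0.4 * np.sin(2 * np.pi * 300 * t)
        frames = frame_signal(PhonationClip(x))
        track = F.estimate_pitch(frames)
        assert abs(np.mean(F.hrf_track(frames, track))) <= 1.0

    def test_symmetric_triangular_flow_qoq_half(self):
        # triangle spanning each full cycle: above-half duration is T/2
        period = 160
        cycles = 12
        one = np.concatenate([np.linspace(0, 1, period // 2, endpoint=False),
                              np.linspace(1, 0, period // 2, endpoint=False)])
        flow = np.tile(one, cycles)
        marks = np.arange(cycles + 1) * period
        qoq = F.quasi_open_quotient(flow, marks)
        assert np.allclose(qoq, 0.5, atol=0.02)
        assert np.std(qoq) == pytest.approx(0.0, abs=1e-12)


class TestClipFeatures:
    def test_clean_synthesis_floors(self, clean_clip):
        fv = F.clip_features(clean_clip)
        assert fv["Jitter_local"] < 0.001
        assert fv["Shimmer_local"] < 0.001
        assert fv["HNR_mean"] > 30.0

    def test_single_feature_panel(self, typical_clip):
        fv = F.clip_features(typical_clip, panel=["F0_mean"])
        assert list(fv) == ["F0_mean"]

    def test_unregistered_name_rejected(self, typical_clip):
        with pytest.raises(ConfigurationError, match="Jitter_bogus"):
            F.clip_features(typical_clip, panel=["Jitter_bogus"])

    def test_rising_contour_max_pitch(self):
        maxp, mean = [], []
        for seed in range(3):
            p = VoiceParams(f0=180, f0_end=220, jitter_pct=0.3,
                            shimmer_pct=1.0, target_hnr_db=30, seed=seed)
            fv = F.clip_features(standardize_clip(synthesize_vowel(p)))
            maxp.append(fv["Max_Pitch"])
            mean.append(fv["F0_mean"])
        assert 218 <= np.mean(maxp) <= 222
        assert 180 < np.mean(mean) < 220


class TestAggregation:
    def _pat(self):
        return F.PatientRecord("p1", 70.0, "male", "high")

    def test_single_clip_identity(self):
        pf = F.aggregate_patient([{"Jitter_local": 0.01}], self._pat())
        assert pf.features == {"Jitter_local": 0.01}
        assert pf.n_clips == 1

    def test_arithmetic_mean(self):
        pf = F.aggregate_patient([{"Jitter_local": 0.01, "HNR_mean": 10.0},
                                  {"Jitter_local": 0.03, "HNR_mean": 20.0},
                                  {"Jitter_local": 0.02, "HNR_mean": 30.0}],
                                 self._pat())
        assert pf.features["Jitter_local"] == pytest.approx(0.02)
        assert pf.features["HNR_mean"] == pytest.approx(20.0)

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(Exception):
            F.aggregate_patient([], self._pat())
        with pytest.raises(Exception):
            F.aggregate_patient([{"a": 1.0}, {"b": 2.0}], self._pat())

    def test_frame_round_trip(self):
        pats = [F.PatientFeatures("p1", 70.0, "male", "high",
                                  {"Jitter_local": 0.01, "HNR_mean": 15.0}, 2)]
        df = F.patients_to_frame(pats)
        back = F.frame_to_patients(df)
        assert back[0].features == pats[0].features
        assert back[0].risk_label == "high"
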