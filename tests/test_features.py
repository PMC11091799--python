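"""Acoustic feature extractors checked against construction-time ground
truth of synthetic signals and against hand-enumerated oracles."""

import numpy as np
import pytest

from voicescreen.features import (FEATURE_CODES, FeatureConfig, SyllableAnnotation,
                                  VoicingMap, detect_syllables, detect_voicing,
                                  extract_all, periodicity_features, shimmer,
                                  spectral_features, syllabic_features)
from voicescreen.synth import VoiceSpec, gen_voice_signal

from conftest import make_segment


def harmonic(f0: float, dur: float = 5.0, rate: int = 16000) -> np.ndarray:
    t = np.arange(int(dur * rate)) / rate
    return sum((1 / k) * np.sin(2 * np.pi * k * f0 * t) for k in range(1, 6))


class TestVoicing:
    def test_pure_harmonic_all_voiced_with_accurate_pitch(self):
        vm = detect_voicing(make_segment(harmonic(150.0)))
        assert vm.voiced_flags.all()
        f0 = vm.f0_track[np.isfinite(vm.f0_track)]
        assert np.abs(f0 - 150.0).max() < 1.0

    def test_white_noise_mostly_unvoiced(self):
        x = np.random.default_rng(0).standard_normal(5 * 16000)
        vm = detect_voicing(make_segment(x))
        assert np.mean(~vm.voiced_flags) >= 0.95

    def test_voiced_fraction_matches_schedule(self):
        spec = VoiceSpec(duration=5.0, voiced_intervals=[(0.0, 2.0)], f0=150.0)
        x, _ = gen_voice_signal(spec)
        vm = detect_voicing(make_segment(x))
        assert np.mean(vm.voiced_flags) == pytest.approx(0.4, abs=0.02)

    def test_pulses_once_per_period(self):
        vm = detect_voicing(make_segment(harmonic(150.0, dur=2.0), length_s=5))
        gaps = np.diff(vm.pulses)
        assert np.abs(gaps - 1 / 150).max() < 1.5e-3
        assert abs(len(vm.pulses) - 2.0 * 150) < 8


class TestPeriodicity:
    def test_unvoiced_percentage_from_silence_schedule(self):
        spec = VoiceSpec(duration=5.0, voiced_intervals=[(0.0, 2.0)], f0=140.0)
        x, _ = gen_voice_signal(spec)
        seg = make_segment(x)
        f = periodicity_features(detect_voicing(seg), seg)
        assert f["F1"] == pytest.approx(60.0, abs=2.0)

    def test_voice_breaks_zero_for_strictly_periodic_pulses(self):
        pulses = np.arange(100) * 0.010  # 10 ms < 17.86 ms threshold
        vm = VoicingMap(np.array([]), np.array([], dtype=bool), np.array([]),
                        pulses, np.ones(100), 0.01, 0.04)
        f = periodicity_features(vm, make_segment(np.zeros(80000)))
        assert f["F10"] == 0.0

    def test_voice_breaks_count_single_long_interval(self):
        # 100 intervals, exactly one of 50 ms -> 1.0%
        pulses = np.cumsum([0.0] + [0.010] * 99 + [0.050])
        vm = VoicingMap(np.array([]), np.array([], dtype=bool), np.array([]),
                        pulses, np.ones(101), 0.01, 0.04)
        f = periodicity_features(vm, make_segment(np.zeros(80000)))
        assert f["F10"] == pytest.approx(1.0)

    def test_duration_statistics_ordering(self, rich_voicing):
        vm, seg, _ = rich_voicing
        f = periodicity_features(vm, seg)
        assert f["F4"] <= f["F3"] <= f["F5"]  # voiced p15 <= median <= p85
        assert f["F4"] <= f["F2"] <= f["F5"]
        assert f["F8"] <= f["F7"] <= f["F9"]  # unvoiced family
        assert f["F1"] + 100 * np.mean(vm.voiced_flags) == pytest.approx(100.0)

    def test_no_voiced_runs_propagates_missing(self):
        x = np.random.default_rng(1).standard_normal(5 * 16000) * 1e-3
        seg = make_segment(x)
        f = periodicity_features(detect_voicing(seg), seg)
        assert f["F1"] == 100.0
        assert np.isnan(f["F2"]) and np.isnan(f["F10"])


class TestShimmer:
    def test_constant_amplitudes_zero(self):
        vm = VoicingMap(np.array([]), np.array([], dtype=bool), np.array([]),
                        np.arange(10) * 0.007, np.full(10, 2.0), 0.01, 0.04)
        assert shimmer(vm) == 0.0

    def test_alternating_amplitudes_closed_form(self):
        amps = np.tile([1.0, 0.9], 25)
        vm = VoicingMap(np.array([]), np.array([], dtype=bool), np.array([]),
                        np.arange(50) * 0.007, amps, 0.01, 0.04)
        assert shimmer(vm) == pytest.approx(100 * 0.1 / 0.95, rel=1e-6)

    def test_scale_invariance(self):
        amps = np.random.default_rng(0).uniform(0.8, 1.2, 40)
        base = VoicingMap(np.array([]), np.array([], dtype=bool), np.array([]),
                          np.arange(40) * 0.007, amps, 0.01, 0.04)
        doubled = VoicingMap(np.array([]), np.array([], dtype=bool), np.array([]),
                             np.arange(40) * 0.007, 2 * amps, 0.01, 0.04)
        assert shimmer(base) == pytest.approx(shimmer(doubled))

    def test_too_few_pulses_missing(self):
        vm = VoicingMap(np.array([]), np.array([], dtype=bool), np.array([]),
                        np.array([0.0, 0.01]), np.ones(2), 0.01, 0.04)
        assert np.isnan(shimmer(vm))

    def test_recovers_injected_shimmer_on_waveform(self, rich_voicing):
        vm, _, gt = rich_voicing
        assert shimmer(vm) == pytest.approx(gt.shimmer_percent, rel=0.05)


class TestSyllables:
    def test_burst_count_recovered(self):
        times = [0.15 + 0.25 * k for k in range(8)]
        spec = VoiceSpec(duration=5.0, voiced_intervals=[(0.0, 2.2)],
                         f0=150.0, syllable_times=times)
        x, _ = gen_voice_signal(spec)
        seg = make_segment(x)
        sa = detect_syllables(seg, detect_voicing(seg))
        assert sa.nuclei_times.size == 8

    def test_all_silence_is_one_pause(self):
        x = np.random.default_rng(0).standard_normal(5 * 16000) * 1e-3
        seg = make_segment(x)
        sa = detect_syllables(seg, detect_voicing(seg))
        assert sa.nuclei_times.size == 0
        assert sa.pause_intervals == [(0.0, 5.0)]
        assert sa.phonation_time == 0.0

    def test_pause_between_bursts_detected(self):
        # two voiced stretches separated by 300 ms of silence
        spec = VoiceSpec(duration=5.0,
                         voiced_intervals=[(0.2, 2.0), (2.3, 4.4)], f0=150.0,
                         syllable_times=[0.3 + 0.25 * k for k in range(7)]
                         + [2.4 + 0.25 * k for k in range(8)],
                         pause_intervals=[(2.0, 2.3)], noise_snr_db=40.0,
                         seed=2)
        x, _ = gen_voice_signal(spec)
        seg = make_segment(x)
        sa = detect_syllables(seg, detect_voicing(seg))
        inner = [p for p in sa.pause_intervals if 1.5 < p[0] < 2.5]
        assert len(inner) == 1
        a, b = inner[0]
        assert b - a == pytest.approx(0.3, abs=0.08)


class TestSyllabicFeatures:
    def test_rates_in_fully_phonated_segment(self):
        sa = SyllableAnnotation(nuclei_times=np.linspace(0.1, 1.9, 8),
                                pause_intervals=[], phonation_time=2.0)
        seg = make_segment(np.zeros(2 * 16000), length_s=5)
        f = syllabic_features(sa, seg)
        assert f["F12"] == pytest.approx(4.0)
        assert f["F14"] == pytest.approx(4.0)
        assert f["F13"] == pytest.approx(100.0)

    def test_no_long_gaps_leaves_f15_missing(self):
        sa = SyllableAnnotation(nuclei_times=np.arange(10) * 0.2,
                                pause_intervals=[], phonation_time=2.0)
        f = syllabic_features(sa, make_segment(np.zeros(2 * 16000), length_s=5))
        assert np.isnan(f["F15"]) and f["F17"] == 0 and np.isnan(f["F18"])

    def test_hand_enumerated_schedule(self):
        sa = SyllableAnnotation(nuclei_times=np.array([0.2, 0.5, 0.8]),
                                pause_intervals=[(1.0, 1.4)],
                                phonation_time=1.6)
        f = syllabic_features(sa, make_segment(np.zeros(2 * 16000), length_s=5))
        assert f["F17"] == 1 and f["F18"] == pytest.approx(0.4)
        assert f["F15"] == pytest.approx(0.3)  # both nucleus gaps exceed 250 ms

    def test_zero_phonation_leaves_articulation_missing(self):
        sa = SyllableAnnotation(nuclei_times=np.array([]),
                                pause_intervals=[(0.0, 2.0)], phonation_time=0.0)
        f = syllabic_features(sa, make_segment(np.zeros(2 * 16000), length_s=5))
        assert np.isnan(f["F14"])


class TestSpectral:
    def test_pure_tone_pitch_stats(self):
        seg = make_segment(np.sin(2 * np.pi * 150 * np.arange(80000) / 16000))
        vm = detect_voicing(seg)
        f = spectral_features(seg, vm)
        assert f["F19"] == pytest.approx(150.0, abs=1.0)
        assert f["F20"] <= 2.0

    def test_narrowband_centroid(self):
        seg = make_segment(np.sin(2 * np.pi * 800 * np.arange(80000) / 16000))
        f = spectral_features(seg, detect_voicing(seg))
        assert f["F23"] == pytest.approx(800.0, abs=20.0)

    def test_regular_envelope_scores_higher_than_jittered(self):
        rng = np.random.default_rng(4)
        regular = [0.15 + 0.25 * k for k in range(18)]
        jittered = sorted(0.15 + 4.3 * rng.random() for _ in range(18))
        out = {}
        for name, times in (("reg", regular), ("jit", jittered)):
            spec = VoiceSpec(duration=5.0, voiced_intervals=[(0.0, 4.6)],
                             f0=150.0, syllable_times=times, seed=5)
            x, _ = gen_voice_signal(spec)
            seg = make_segment(x)
            out[name] = spectral_features(seg, detect_voicing(seg))["F22"]
        assert out["reg"] > out["jit"]

    def test_no_voiced_frames_leaves_pitch_missing(self):
        x = np.random.default_rng(2).standard_normal(5 * 16000)
        seg = make_segment(x)
        f = spectral_features(seg, detect_voicing(seg))
        assert np.isnan(f["F19"]) and np.isnan(f["F20"]) and np.isnan(f["F21"])


class TestExtractAll:
    def test_exactly_23_codes(self, rich_signal):
        seg, _ = rich_signal
        f = extract_all(seg)
        assert list(f) == list(FEATURE_CODES)

    def test_deterministic(self, rich_signal):
        seg, _ = rich_signal
        a, b = extract_all(seg), extract_all(seg)
        for k in a:
            assert (np.isnan(a[k]) and np.isnan(b[k])) or a[k] == b[k]

    def test_all_silence_segment(self):
        x = np.random.default_rng(3).standard_normal(5 * 16000) * 1e-3
        f = extract_all(make_segment(x))
        assert f["F1"] == 100.0
        assert np.isnan(f["F2"])  # voiced-family stats missing

    def test_amplitude_scaling_leaves_features_unchanged(self, rich_signal):
        """All operators are scale-invariant after standardization: a
        recording-level gain change must not move any feature."""
        seg, _ = rich_signal
        scaled = make_segment(seg.samples * 3.7)
        a, b = extract_all(seg), extract_all(scaled)
        for k in a:
            if np.isnan(a[k]):
                assert np.isnan(b[k])
            else:
                assert b[k] == pytest.approx(a[k], rel=1e-6)

    def test_ground_truth_recovery(self, rich_signal):
        seg, gt = rich_signal
        f = extract_all(seg)
        assert f["F1"] == pytest.approx(100 * gt.unvoiced_fraction, abs=2.0)
        assert f["F19"] == pytest.approx(gt.f0, abs=1.0)
        assert f["F11"] == pytest.approx(gt.shimmer_percent, rel=0.05)
        assert f["F17"] == gt.n_pauses
        assert f["F18"] == pytest.approx(gt.mean_pause_duration, abs=0.08)
        assert f["F12"] == pytest.approx(len(gt.syllable_times) / gt.duration,
                                         rel=0.15)
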