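"""Beat detection, segmentation, quality filtering and ensembling."""

import numpy as np
import pytest

from ppgkit import beats
from ppgkit import synthetic as sy
from ppgkit.core import PPGSignal, PulseWave
from ppgkit.errors import CyclicityError, InsufficientBeatsError

from conftest import clean_profile


class TestDetectBeats:
    def test_sixty_bpm_sixty_seconds(self, clean_signal_60bpm):
        onsets, peaks = beats.detect_beats(clean_signal_60bpm)
        assert abs(len(peaks) - 60) <= 1
        assert np.all(np.diff(onsets) > 0)
        assert np.all(np.diff(peaks) > 0)
        assert len(onsets) == len(peaks)

    def test_raised_sinusoid(self, raised_sinusoid):
        _, peaks = beats.detect_beats(raised_sinusoid)
        assert abs(len(peaks) - 30) <= 1

    def test_constant_signal_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            beats.detect_beats(PPGSignal(np.ones(1000), 100.0))

    def test_white_noise_rejected(self):
        sig = PPGSignal(np.random.default_rng(0).normal(0, 1, 3000), 100.0)
        with pytest.raises(InsufficientBeatsError):
            beats.detect_beats(sig)

    @pytest.mark.parametrize("hr", [40, 60, 100, 140, 180])
    def test_beat_count_across_heart_rates(self, hr):
        sig = sy.synth_signal(clean_profile(hr=hr, seed=2), 30, 500)
        onsets, _ = beats.detect_beats(sig)
        # one fewer onset than full beats is fine at the window edge
        assert abs(len(onsets) - 30 * hr / 60) <= 2

    def test_robust_to_mild_noise(self):
        sig = sy.synth_signal(clean_profile(hr=70, cv=0.05, seed=4,
                                            noise_sd=0.02), 60, 250)
        _, peaks = beats.detect_beats(sig)
        assert abs(len(peaks) - 70) <= 2


class TestSegmentPulses:
    def test_count_and_partition(self, clean_signal_60bpm):
        onsets, _ = beats.detect_beats(clean_signal_60bpm)
        pulses = beats.segment_pulses(clean_signal_60bpm, onsets)
        assert len(pulses) == len(onsets) - 1
        concat = np.concatenate([p.samples for p in pulses])
        span = clean_signal_60bpm.samples[onsets[0]:onsets[-1]]
        assert np.array_equal(concat, span)

    def test_zero_hrv_pulses_equal_length(self, clean_signal_60bpm):
        onsets, _ = beats.detect_beats(clean_signal_60bpm)
        pulses = beats.segment_pulses(clean_signal_60bpm, onsets)
        # edge beats may carry filter transients; interior beats must agree
        lengths = [p.n_samples for p in pulses[1:-1]]
        assert max(lengths) - min(lengths) <= 1


class TestPulseQuality:
    def _identical_pulses(self, n=8):
        shape = sy.age_to_shape(45)
        return [sy.synth_pulse(shape, 0.9, 250) for _ in range(n)]

    def test_identical_pulses_all_accepted(self):
        pulses = self._identical_pulses()
        scores, accepted = beats.pulse_quality(pulses)
        assert np.allclose(scores, 1.0)
        assert len(accepted) == len(pulses)

    def test_noise_pulse_rejected(self):
        pulses = self._identical_pulses()
        rng = np.random.default_rng(1)
        pulses[3] = PulseWave(rng.normal(0, 1, pulses[3].n_samples), 250.0)
        scores, accepted = beats.pulse_quality(pulses)
        assert scores[3] < 0.9
        assert len(accepted) == len(pulses) - 1

    def test_zero_threshold_accepts_all(self):
        pulses = self._identical_pulses()
        rng = np.random.default_rng(1)
        pulses[0] = PulseWave(rng.normal(0, 1, pulses[0].n_samples), 250.0)
        _, accepted = beats.pulse_quality(pulses, threshold=0.0)
        assert len(accepted) == len(pulses)

    def test_permutation_equivariance(self):
        pulses = self._identical_pulses(6)
        rng = np.random.default_rng(2)
        pulses[1] = PulseWave(rng.normal(0, 1, pulses[1].n_samples), 250.0)
        scores, _ = beats.pulse_quality(pulses)
        perm = [5, 1, 3, 0, 4, 2]
        scores_p, _ = beats.pulse_quality([pulses[i] for i in perm])
        assert np.allclose(scores_p, scores[perm], atol=1e-12)


class TestMeanCycleLength:
    def test_75_bpm(self):
        sig = sy.synth_signal(clean_profile(hr=75, seed=1), 60, 500)
        assert beats.mean_cycle_length(sig) == pytest.approx(0.8, abs=1/500)

    def test_sinusoid(self, raised_sinusoid):
        cyc = beats.mean_cycle_length(raised_sinusoid)
        assert cyc == pytest.approx(1.0, abs=1/100)

    def test_white_noise_raises(self):
        sig = PPGSignal(np.random.default_rng(3).normal(0, 1, 3000), 100.0)
        with pytest.raises(CyclicityError):
            beats.mean_cycle_length(sig)

    @pytest.mark.parametrize("hr", [40, 70, 120, 180])
    def test_cycle_times_rate_is_unity(self, hr):
        sig = sy.synth_signal(clean_profile(hr=hr, seed=2), 30, 500)
        assert beats.mean_cycle_length(sig) * hr / 60 == \
            pytest.approx(1.0, rel=0.02)


class TestEnsembleAverage:
    def test_identical_pulses_mean_equals_pulse(self):
        shape = sy.age_to_shape(35)
        pulses = [sy.synth_pulse(shape, 0.8, 125) for _ in range(5)]
        ens = beats.ensemble_average(pulses)
        ref = beats._normalize_pulse(pulses[0])
        assert np.allclose(ens.mean_shape, ref)
        assert np.allclose(ens.sd_shape, 0.0, atol=1e-12)
        assert ens.n_beats == 5

    def test_constant_pulses_mean_and_sd(self):
        p0 = PulseWave(np.zeros(80), 100.0)
        p2 = PulseWave(np.full(80, 2.0), 100.0)
        ens = beats.ensemble_average([p0, p2])
        assert np.allclose(ens.mean_shape, 1.0)
        assert np.allclose(ens.sd_shape, 1.0)

    def test_output_length_is_n_norm(self):
        pulses = [PulseWave(np.sin(np.linspace(0, 3, n)), 100.0)
                  for n in (80, 120)]
        ens = beats.ensemble_average(pulses)
        assert ens.mean_shape.size == beats.N_NORM
        assert ens.sd_shape.size == beats.N_NORM
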