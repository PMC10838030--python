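"""Fiducial location and the 48-index FPA catalogue."""

from dataclasses import replace

import numpy as np
import pytest

from ppgkit import fpa
from ppgkit import synthetic as sy
from ppgkit.core import PulseWave
from ppgkit.errors import MalformedPulseError, ResolutionError

from conftest import AGES
from oracles import brute_force_fiducials


class TestDerivatives:
    def test_sinusoid_second_derivative_analytic(self):
        fs = 500.0
        t = np.arange(0, 1, 1 / fs)
        pulse = PulseWave(np.sin(2 * np.pi * t), fs)
        _, d2 = fpa.derivatives(pulse)
        expected = -(2 * np.pi) ** 2 * np.sin(2 * np.pi * t)
        edge = 30
        rel = np.abs(d2[edge:-edge] - expected[edge:-edge]) / (2 * np.pi) ** 2
        assert rel.max() < 0.01

    def test_linear_ramp_and_constant(self):
        fs = 100.0
        ramp = PulseWave(np.linspace(0, 5, 200), fs)
        d1, d2 = fpa.derivatives(ramp)
        assert np.abs(d2).max() < 1e-6 * 5 * fs / 200 * fs
        assert np.allclose(d1, 5 / 199 * fs, rtol=1e-6)
        const = PulseWave(np.full(50, 2.0), fs)
        d1c, d2c = fpa.derivatives(const)
        assert np.abs(d1c).max() < 1e-9
        assert np.abs(d2c).max() < 1e-9

    def test_too_short_raises(self):
        with pytest.raises(ResolutionError):
            fpa.derivatives(PulseWave(np.zeros(8), 100.0))


class TestLocateFiducials:
    def test_all_waves_present_on_study_pulses(self, age_pulses):
        for age, pulse in age_pulses.items():
            fid = fpa.locate_fiducials(pulse)
            missing = [n for n in fid.NAMES if not fid.has(n)]
            assert not missing, f"age {age}: missing {missing}"

    def test_diastolic_peak_is_a_raw_local_maximum(self, age25_pulse):
        fid = fpa.locate_fiducials(age25_pulse)
        i = fid["diastolic_peak"].index
        x = age25_pulse.samples
        k = 3
        assert x[i - k:i + k + 1].max() >= x[i - 20:i + 21].max() - 1e-12

    def test_sdppg_ordering(self, age_pulses):
        for pulse in age_pulses.values():
            fid = fpa.locate_fiducials(pulse)
            times = [fid.time(w) for w in "abcdef"]
            assert np.all(np.diff(times) > 0)

    def test_missing_diastolic_wave_is_flagged(self):
        shape = replace(sy.age_to_shape(45), diastolic_amp_ratio=0.0)
        pulse = sy.synth_pulse(shape, 1.0, 500)
        fid = fpa.locate_fiducials(pulse)
        pt = fid.points["diastolic_peak"]
        assert pt.missing or pt.method != "primary"

    def test_flat_pulse_is_malformed(self):
        with pytest.raises(MalformedPulseError):
            fpa.locate_fiducials(PulseWave(np.ones(200), 100.0))

    @pytest.mark.parametrize("age", AGES)
    def test_matches_brute_force_scan(self, age_pulses, age):
        """All located indices equal an independent explicit scan."""
        pulse = age_pulses[age]
        fid = fpa.locate_fiducials(pulse)
        oracle = brute_force_fiducials(pulse)
        for name, want in oracle.items():
            if want is None:
                assert not fid.has(name), name
            else:
                assert fid[name].index == want, \
                    f"{name}: got {fid[name].index}, oracle {want}"


class TestIndices:
    def test_catalogue_is_complete_and_ordered(self, age25_pulse):
        idx = fpa.compute_fpa_indices(age25_pulse,
                                      fpa.locate_fiducials(age25_pulse))
        names = [d.name for d in fpa.fpa_registry()]
        assert list(idx.values.keys()) == names
        assert len(idx) == 48

    def test_registry_contract(self):
        reg = fpa.fpa_registry()
        names = [d.name for d in reg]
        assert len(reg) == 48
        assert len(set(names)) == 48
        keys = {d.name for d in reg if d.key}
        assert keys == set(fpa.FPA_KEY_INDICES)
        assert len(keys) == 5

    def test_augmentation_index_on_constructed_pulse(self):
        # widely separated p1 (amp 1.0) and p2 (amp 0.6)
        shape = sy.PulseShape(systolic_frac=0.12, late_systolic_frac=0.30,
                              late_systolic_amp_ratio=0.6,
                              diastolic_frac=0.48, diastolic_amp_ratio=0.4,
                              component_widths=(0.035, 0.025, 0.05))
        pulse = sy.synth_pulse(shape, 1.0, 500)
        idx = fpa.compute_fpa_indices(pulse, fpa.locate_fiducials(pulse))
        # brute-force peak measurement (onset-baseline corrected)
        x = pulse.samples
        p1 = x[40:80].max() - x[0]
        p2 = x[130:170].max() - x[0]
        assert idx["AI"] == pytest.approx(p2 / p1, abs=1e-9)
        assert idx["AI"] == pytest.approx(0.60, abs=0.02)

    def test_ratio_indices_scale_invariant(self, age25_pulse):
        fid = fpa.locate_fiducials(age25_pulse)
        base = fpa.compute_fpa_indices(age25_pulse, fid)
        scaled_pulse = PulseWave(age25_pulse.samples * 7.3,
                                 age25_pulse.fs_hz)
        scaled = fpa.compute_fpa_indices(scaled_pulse,
                                         fpa.locate_fiducials(scaled_pulse))
        absolute = {"pulse_amp", "area_total", "A1", "A2", "ms_amp",
                    "dia_slope_min", "a_amp"}
        for d in fpa.fpa_registry():
            if d.name in absolute:
                continue
            assert scaled[d.name] == pytest.approx(base[d.name], abs=1e-9), \
                d.name

    def test_sin_squared_hump_b_over_a(self):
        fs = 500.0
        t = np.arange(0, 1, 1 / fs)
        pulse = PulseWave(np.sin(np.pi * t) ** 2, fs)
        idx = fpa.compute_fpa_indices(pulse, fpa.locate_fiducials(pulse))
        assert idx["b/a"] == pytest.approx(-1.0, abs=0.02)

    def test_aging_trends(self, aging_sweep):
        ages = sorted(aging_sweep)
        ai = [aging_sweep[a][0]["AI"] for a in ages]
        t_dia = [aging_sweep[a][0]["t_dia_frac"] for a in ages]
        assert np.all(np.diff(ai) > 0)
        assert np.all(np.diff(t_dia) < 0)

    def test_per_beat_median_of_identical_beats(self, age25_pulse):
        single = fpa.compute_fpa_indices(age25_pulse,
                                         fpa.locate_fiducials(age25_pulse))
        med = fpa.fpa_for_pulses([age25_pulse] * 4, mode="per_beat_median")
        for name, value in single.items():
            assert med[name] == pytest.approx(value, nan_ok=True)

    def test_ensemble_mode_runs(self, age25_pulse):
        out = fpa.fpa_for_pulses([age25_pulse] * 4, mode="ensemble")
        assert len(out) == 48
        assert np.isfinite(out["AI"])
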