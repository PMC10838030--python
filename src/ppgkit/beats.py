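"""Beat detection, pulse segmentation, quality filtering and ensembling.

The detector is a slope-sum based peak finder: the PPG is band-limited to
the cardiac band, transformed by a windowed sum of positive slopes (which
sharpens the systolic upstroke into a single hump per beat), and peaks are
taken above an adaptive rolling 75th-percentile threshold with a
refractory period of 0.35 x the current cycle estimate. Onsets are the
pulse feet: the signal minimum preceding each systolic peak.

A post-hoc cyclicity guard rejects detections on signals whose
autocorrelation at the detected period is negligible (white noise can
otherwise produce spurious, plausibly spaced "beats").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .core import EnsemblePulse, PPGSignal, PulseWave
from .errors import CyclicityError, InsufficientBeatsError

__all__ = ["detect_beats", "segment_pulses", "pulse_quality",
           "mean_cycle_length", "ensemble_average", "N_NORM"]

N_NORM = 100          # samples per time-normalized pulse
REFRACTORY_FRAC = 0.35
QUALITY_THRESHOLD = 0.9
_MIN_QUALITY_AUTOCORR = 0.15


def _cardiac_band(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase band-pass to the cardiac band (0.4-8 Hz)."""
    hi = min(8.0, 0.45 * fs)
    b, a = butter(2, [0.4 / (fs / 2), hi / (fs / 2)], btype="band")
    return filtfilt(b, a, x)


def _slope_sum(x: np.ndarray, fs: float) -> np.ndarray:
    w = max(int(round(0.128 * fs)), 2)
    dx = np.diff(x, prepend=x[0])
    pos = np.maximum(dx, 0.0)
    c = np.cumsum(pos)
    ssf = np.empty_like(c)
    ssf[:w] = c[:w]
    ssf[w:] = c[w:] - c[:-w]
    return ssf


def _autocorr(x: np.ndarray) -> np.ndarray:
    """Unbiased normalized autocorrelation (finite-window corrected)."""
    n = x.size
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0:
        return np.zeros(n)
    ac = np.correlate(x, x, mode="full")[n - 1:]
    lags = np.arange(n)
    return ac / denom * (n / np.maximum(n - lags, 1))


def _cycle_estimate_autocorr(x: np.ndarray, fs: float):
    """First autocorrelation peak in the physiological lag band.

    Returns (lag_seconds, peak_height) or (None, 0.0).
    """
    ac = _autocorr(x)
    lo = max(int(0.25 * fs), 1)
    hi = min(int(2.0 * fs), ac.size - 2)
    if hi <= lo:
        return None, 0.0
    peaks, _ = find_peaks(ac[lo:hi])
    if peaks.size == 0:
        return None, 0.0
    # the fundamental is the first substantial peak; spiky waveforms put
    # small side-lobes before it, harmonics only after it
    heights = ac[lo + peaks]
    cands = peaks[heights >= max(0.5 * heights.max(), 0.05)]
    k = lo + int(cands[0]) if cands.size else lo + int(peaks[0])
    return k / fs, float(ac[k])


def detect_beats(signal: PPGSignal):
    """Detect beats; returns (onset_indices, peak_indices).

    Raises InsufficientBeatsError if fewer than 3 credible beats are found.
    """
    x = signal.samples
    fs = signal.fs_hz
    if signal.duration_s < 3:
        raise InsufficientBeatsError("signal shorter than 3 s")
    if np.ptp(x) == 0:
        raise InsufficientBeatsError("constant signal")
    xb = _cardiac_band(x, fs)
    ssf = _slope_sum(xb, fs)

    cycle_s, _ = _cycle_estimate_autocorr(xb, fs)
    if cycle_s is None:
        cycle_s = 0.8
    distance = max(int(REFRACTORY_FRAC * cycle_s * fs), 1)
    thresh = (pd.Series(ssf)
              .rolling(int(3 * fs), center=True, min_periods=1)
              .quantile(0.75).to_numpy())
    pk, _ = find_peaks(ssf, distance=distance, height=thresh)
    if pk.size < 3:
        raise InsufficientBeatsError(f"only {pk.size} candidate beats")

    # refine: systolic peak = local max of the band-passed signal near the
    # slope-sum peak; onset = minimum in the preceding fractional cycle
    w = max(int(round(0.15 * cycle_s * fs)), 2)
    back = max(int(round(0.6 * cycle_s * fs)), 2)
    peaks, onsets = [], []
    for p in pk:
        a, b = max(p - w, 0), min(p + w, x.size)
        peak = a + int(np.argmax(xb[a:b]))
        o0 = max(peak - back, 0)
        if peak - o0 < 2:
            continue
        onset = o0 + int(np.argmin(xb[o0:peak]))
        peaks.append(peak)
        onsets.append(onset)
    keep_p, keep_o = [], []
    for o, p in zip(onsets, peaks):
        if keep_p and p <= keep_p[-1]:
            continue
        if keep_o and o <= keep_o[-1]:
            # same foot found twice -> keep the taller peak
            if xb[p] > xb[keep_p[-1]]:
                keep_p[-1] = p
            continue
        keep_o.append(o)
        keep_p.append(p)
    onsets = np.asarray(keep_o, dtype=int)
    peaks = np.asarray(keep_p, dtype=int)
    if onsets.size < 3:
        raise InsufficientBeatsError(f"only {onsets.size} beats after"
                                     " refinement")

    # cyclicity guard against spurious detections on noise
    med = float(np.median(np.diff(onsets))) / fs
    ac = _autocorr(xb)
    lag = int(round(med * fs))
    lo, hi = max(lag - 2, 1), min(lag + 3, ac.size)
    if hi <= lo or float(np.max(ac[lo:hi])) < _MIN_QUALITY_AUTOCORR:
        raise InsufficientBeatsError(
            "detected intervals are not supported by signal autocorrelation")
    return onsets, peaks


def segment_pulses(signal: PPGSignal, onsets) -> list:
    """Split the signal into pulses spanning [onset_i, onset_{i+1})."""
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size < 2:
        raise ValueError("need at least 2 onsets")
    return [PulseWave(signal.samples[a:b].copy(), signal.fs_hz,
                      onset_index=int(a))
            for a, b in zip(onsets[:-1], onsets[1:])]


def _normalize_pulse(p: PulseWave, n: int = N_NORM) -> np.ndarray:
    src = np.linspace(0.0, 1.0, p.n_samples)
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, p.samples)


def pulse_quality(pulses, threshold: float = QUALITY_THRESHOLD,
                  template_window: int = 11):
    """Score each pulse against a running-median template.

    Each pulse is time-normalized and correlated (Pearson) with the
    pointwise median of the time-normalized pulses in a centred window of
    ``template_window`` beats. Scores are clipped to [0, 1]; a pulse is
    accepted iff score >= threshold.

    Returns (scores, accepted) with ``accepted`` a list of the accepted
    PulseWave objects.
    """
    if len(pulses) < 3:
        raise ValueError("need at least 3 pulses to build a template")
    norm = np.stack([_normalize_pulse(p) for p in pulses])
    half = template_window // 2
    scores = np.empty(len(pulses))
    for i in range(len(pulses)):
        a, b = max(i - half, 0), min(i + half + 1, len(pulses))
        template = np.median(norm[a:b], axis=0)
        u = norm[i] - norm[i].mean()
        v = template - template.mean()
        denom = np.sqrt(np.dot(u, u) * np.dot(v, v))
        r = float(np.dot(u, v) / denom) if denom > 0 else 1.0
        scores[i] = min(max(r, 0.0), 1.0)
    accepted = [p for p, s in zip(pulses, scores) if s >= threshold]
    return scores, accepted


def mean_cycle_length(signal: PPGSignal) -> float:
    """Median inter-onset interval in seconds.

    Falls back to the first autocorrelation peak when beat detection
    fails; raises CyclicityError when both estimators fail.
    """
    try:
        onsets, _ = detect_beats(signal)
        return float(np.median(np.diff(onsets))) / signal.fs_hz
    except InsufficientBeatsError:
        pass
    xb = _cardiac_band(signal.samples, signal.fs_hz)
    lag_s, height = _cycle_estimate_autocorr(xb, signal.fs_hz)
    if lag_s is None or height < _MIN_QUALITY_AUTOCORR:
        raise CyclicityError("no credible cycle length (beat detection and"
                             " autocorrelation both failed)")
    return float(lag_s)


def ensemble_average(pulses, n_norm: int = N_NORM) -> EnsemblePulse:
    """Time-normalize pulses to ``n_norm`` samples; pointwise mean and SD."""
    if len(pulses) < 1:
        raise ValueError("need at least 1 pulse")
    norm = np.stack([_normalize_pulse(p, n_norm) for p in pulses])
    mean_dur = float(np.mean([p.duration_s for p in pulses]))
    return EnsemblePulse(mean_shape=norm.mean(axis=0),
                         sd_shape=norm.std(axis=0, ddof=0),
                         n_beats=len(pulses),
                         fs_equivalent=n_norm / mean_dur)
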