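"""Fiducial point analysis (FPA) of single PPG pulses.

FPA locates landmarks on the pulse wave and its first and second
derivatives and derives a catalogue of 48 scalar indices from their
timings and amplitudes. Landmarks:

* on the pulse: onset, early systolic peak p1, late systolic peak p2,
  systolic maximum, dicrotic notch, diastolic peak;
* on the first derivative: the maximum-slope point ms;
* on the second derivative (SDPPG): the conventional waves a-f.

Because numerical differentiation amplifies noise, all derivatives use
Savitzky-Golay local-polynomial smoothing (window 0.05 s, order 3 by
default, both configurable).

Missing landmarks are data, not failures: every fiducial carries an
explicit ``missing`` flag, and indices that depend on a missing fiducial
are NaN.

Five key indices (field notation): AI (augmentation index, the late/early
systolic amplitude ratio), IPAD (inflection-point area ratio plus d/a),
and the SDPPG amplitude ratios c/a, d/a, e/a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .core import PulseWave
from .errors import MalformedPulseError, ResolutionError

__all__ = ["FiducialPoint", "FiducialSet", "IndexSet", "IndexDescriptor",
           "derivatives", "locate_fiducials", "compute_fpa_indices",
           "fpa_registry", "fpa_for_pulses", "FPA_KEY_INDICES"]

SMOOTH_WINDOW_S = 0.05
SMOOTH_ORDER = 3

FPA_KEY_INDICES = ("AI", "IPAD", "c/a", "d/a", "e/a")

# SDPPG search windows as fractions of the pulse duration. The a-wave is
# additionally confined to precede the systolic maximum; the e-wave is
# anchored to the dicrotic notch when one is found (the two events
# coincide physiologically).
A_WINDOW_END = 0.25
B_WINDOW_END = 0.4
B_FALLBACK_END = 0.75
E_WINDOW_END = 0.6
E_NOTCH_WINDOW_END = 0.75
NOTCH_WINDOW_END = 0.8
#: Relative prominence below which pulse-domain extrema are treated as
#: numerical wiggle, not landmarks.
PROMINENCE_FRAC = 1e-3


@dataclass
class FiducialPoint:
    """One landmark: sample index, time from pulse onset, raw amplitude."""

    index: int
    time_s: float
    amplitude: float
    missing: bool = False
    method: str = "primary"

    @classmethod
    def absent(cls) -> "FiducialPoint":
        return cls(-1, np.nan, np.nan, missing=True, method="none")


@dataclass
class FiducialSet:
    """Named landmarks of one pulse; absent landmarks are flagged."""

    points: dict = field(default_factory=dict)

    NAMES = ("onset", "p1", "p2", "systolic_max", "dicrotic_notch",
             "diastolic_peak", "ms", "a", "b", "c", "d", "e", "f")

    def __getitem__(self, name: str) -> FiducialPoint:
        return self.points[name]

    def has(self, name: str) -> bool:
        p = self.points.get(name)
        return p is not None and not p.missing

    def time(self, name: str) -> float:
        return self.points[name].time_s if self.has(name) else np.nan

    def amp(self, name: str) -> float:
        return self.points[name].amplitude if self.has(name) else np.nan


@dataclass(frozen=True)
class IndexDescriptor:
    name: str
    unit: str
    family: str
    description: str
    key: bool = False


@dataclass
class IndexSet:
    """Ordered mapping of index name -> value for one method catalogue."""

    method: str
    values: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)

    def items(self):
        return self.values.items()


def _smooth_window(fs: float, n: int, window_s: float) -> int:
    win = int(round(window_s * fs))
    win = max(win, SMOOTH_ORDER + 2)
    if win % 2 == 0:
        win += 1
    if win >= n:
        win = n - 1 if n % 2 == 0 else n - 2
    return max(win, 5)


def derivatives(pulse: PulseWave, window_s: float = SMOOTH_WINDOW_S,
                polyorder: int = SMOOTH_ORDER):
    """Smoothed first and second derivatives (units au/s, au/s^2)."""
    x = pulse.samples
    if x.size < 11:
        raise ResolutionError("pulse shorter than 11 samples")
    win = _smooth_window(pulse.fs_hz, x.size, window_s)
    dt = 1.0 / pulse.fs_hz
    d1 = savgol_filter(x, win, polyorder, deriv=1, delta=dt)
    d2 = savgol_filter(x, win, polyorder, deriv=2, delta=dt)
    return d1, d2


def _smoothed(pulse: PulseWave, window_s: float = SMOOTH_WINDOW_S,
              polyorder: int = SMOOTH_ORDER) -> np.ndarray:
    win = _smooth_window(pulse.fs_hz, pulse.n_samples, window_s)
    return savgol_filter(pulse.samples, win, polyorder)


def _local_maxima(x: np.ndarray, lo: int, hi: int,
                  prominence: float | None = None) -> np.ndarray:
    """Indices of interior local maxima of x within [lo, hi)."""
    if hi - lo < 3:
        return np.empty(0, dtype=int)
    pk, _ = find_peaks(x[lo:hi], prominence=prominence)
    return pk + lo


def _local_minima(x: np.ndarray, lo: int, hi: int,
                  prominence: float | None = None) -> np.ndarray:
    return _local_maxima(-x, lo, hi, prominence)


def locate_fiducials(pulse: PulseWave, derivs=None,
                     window_s: float = SMOOTH_WINDOW_S,
                     polyorder: int = SMOOTH_ORDER) -> FiducialSet:
    """Locate all fiducial points on a pulse and its derivatives.

    Landmarks that cannot be located are flagged missing; the SDPPG
    a-wave is always present for a physiologically shaped pulse.
    """
    x = pulse.samples
    n = x.size
    fs = pulse.fs_hz
    if derivs is None:
        derivs = derivatives(pulse, window_s, polyorder)
    d1, d2 = derivs
    xs = _smoothed(pulse, window_s, polyorder)

    # landmarks are *located* on the smoothed trace / smoothed
    # derivatives; pulse-domain *amplitudes* are measured as the raw
    # extremum within half a smoothing window of the landmark, so
    # smoothing cannot bias amplitude ratios
    half = _smooth_window(fs, n, window_s) // 2

    def pt(i: int, arr: np.ndarray = None, method: str = "primary",
           kind: str = "max"):
        i = int(i)
        if arr is None:
            a, b = max(i - half, 0), min(i + half + 1, n)
            amp = float(np.max(x[a:b]) if kind == "max" else np.min(x[a:b]))
        else:
            amp = float(arr[i])
        return FiducialPoint(i, i / fs, amp, method=method)

    fid = FiducialSet()
    fid.points["onset"] = pt(0, x)

    if np.ptp(x) <= 1e-12 * max(abs(float(np.mean(x))), 1.0):
        raise MalformedPulseError("flat pulse has no systolic maximum")
    i_sys = int(np.argmax(xs))
    if i_sys == 0 or i_sys == n - 1:
        raise MalformedPulseError("no interior systolic maximum")
    fid.points["systolic_max"] = pt(i_sys)

    prom = PROMINENCE_FRAC * float(np.ptp(xs))

    # --- dicrotic notch (pulse domain) -------------------------------
    # the most prominent local minimum after the *last* systolic peak:
    # prominence (not depth) separates the incisura from noise dips in
    # the low-amplitude diastolic tail, and anchoring past the final
    # systolic maximum excludes the p1-p2 saddle
    sys_peaks = _local_maxima(xs, 1, max(int(0.35 * n), 3),
                              prominence=prom)
    anchor = int(sys_peaks[-1]) if sys_peaks.size else i_sys
    anchor = max(anchor, i_sys)
    notch_hi = max(int(NOTCH_WINDOW_END * n), anchor + 2)
    i_notch = None
    if notch_hi - (anchor + 1) >= 3:
        cand, props = find_peaks(-xs[anchor + 1:notch_hi], prominence=prom)
        if cand.size:
            i_notch = anchor + 1 + int(cand[np.argmax(props["prominences"])])

    # --- maximum slope -----------------------------------------------
    i_ms = int(np.argmax(d1[:i_sys + 1]))
    fid.points["ms"] = pt(i_ms, d1)

    # --- second-derivative waves -------------------------------------
    # the a-wave sits at the systolic foot: first prominent SDPPG
    # maximum in the early window (argmax fallback covers single-hump
    # pulses whose SDPPG peaks at the window edge)
    a_hi = int(min(max(A_WINDOW_END * n, 2), i_sys + 1))
    d2_prom = 0.05 * float(np.ptp(d2))
    maxs_a = _local_maxima(d2, 0, max(a_hi, 2), prominence=d2_prom)
    i_a = int(maxs_a[0]) if maxs_a.size \
        else int(np.argmax(d2[:max(a_hi, 2)]))
    fid.points["a"] = pt(i_a, d2)

    # noise floor for SDPPG extrema: smaller wiggles are not waves
    d2_wave_prom = 0.02 * float(np.ptp(d2))

    b_hi = max(int(B_WINDOW_END * n), i_a + 2)
    mins_b = _local_minima(d2, i_a + 1, b_hi, prominence=d2_wave_prom)
    if mins_b.size:
        i_b = int(mins_b[0])
        fid.points["b"] = pt(i_b, d2)
    else:
        # no interior minimum inside the window: take the global SDPPG
        # minimum after a (symmetric single-hump pulses land here)
        fb_hi = max(int(B_FALLBACK_END * n), i_a + 2)
        i_b = i_a + 1 + int(np.argmin(d2[i_a + 1:fb_hi]))
        fid.points["b"] = pt(i_b, d2, method="global_min_fallback")

    if i_notch is not None:
        # the e-wave accompanies the incisura: take the prominent SDPPG
        # maximum nearest the pulse-domain notch
        e_hi = max(int(E_NOTCH_WINDOW_END * n), i_b + 2)
        maxs_e = _local_maxima(d2, i_b + 1, e_hi, prominence=d2_wave_prom)
        i_e = int(maxs_e[np.argmin(np.abs(maxs_e - i_notch))]) \
            if maxs_e.size else None
    else:
        e_hi = max(int(E_WINDOW_END * n), i_b + 2)
        maxs_e = _local_maxima(d2, i_b + 1, e_hi, prominence=d2_wave_prom)
        i_e = int(maxs_e[np.argmax(d2[maxs_e])]) if maxs_e.size else None
    fid.points["e"] = pt(i_e, d2) if i_e is not None \
        else FiducialPoint.absent()

    if i_e is not None:
        maxs_c = _local_maxima(d2, i_b + 1, i_e,
                               prominence=d2_wave_prom)
        if maxs_c.size:
            i_c = int(maxs_c[np.argmax(d2[maxs_c])])
            fid.points["c"] = pt(i_c, d2)
            i_d = i_c + 1 + int(np.argmin(d2[i_c + 1:i_e + 1])) \
                if i_e - i_c >= 2 else None
            if i_d is not None:
                fid.points["d"] = pt(i_d, d2)
            else:
                fid.points["d"] = FiducialPoint.absent()
        else:
            fid.points["c"] = FiducialPoint.absent()
            fid.points["d"] = FiducialPoint.absent()
        mins_f = _local_minima(d2, i_e + 1, n, prominence=d2_wave_prom)
        fid.points["f"] = pt(int(mins_f[0]), d2) if mins_f.size \
            else FiducialPoint.absent()
    else:
        for name in ("c", "d", "f"):
            fid.points[name] = FiducialPoint.absent()

    # notch fallback: the e-wave marks the incisura when the pulse
    # domain shows no prominent minimum — but only if it actually falls
    # on the downstroke past the systolic complex
    if i_notch is not None:
        fid.points["dicrotic_notch"] = pt(i_notch, kind="min")
    elif fid.has("e") and fid["e"].index > anchor:
        i_notch = fid["e"].index
        fid.points["dicrotic_notch"] = pt(i_notch, kind="min",
                                          method="fallback_e")
    else:
        fid.points["dicrotic_notch"] = FiducialPoint.absent()

    # --- p1, p2, diastolic peak --------------------------------------
    maxs_pre = _local_maxima(xs, 1, i_sys + 2, prominence=prom)
    i_p1 = int(maxs_pre[0]) if maxs_pre.size else i_sys
    fid.points["p1"] = pt(i_p1)

    if i_notch is not None:
        maxs_p2 = _local_maxima(xs, i_sys, i_notch + 1, prominence=prom)
        maxs_p2 = maxs_p2[maxs_p2 != i_p1]
        if i_sys != i_p1:
            maxs_p2 = np.append(maxs_p2, i_sys)
        if maxs_p2.size:
            fid.points["p2"] = pt(int(maxs_p2[np.argmax(xs[maxs_p2])]))
        else:
            i_p2 = _shoulder_after(d2, fid["b"].index, i_notch)
            if i_p2 is not None:
                fid.points["p2"] = pt(i_p2, method="shoulder")
            else:
                fid.points["p2"] = pt(i_sys, method="coincides_sys_max")
        maxs_dia = _local_maxima(xs, i_notch + 1, n - 1, prominence=prom)
        if maxs_dia.size:
            i_dia = int(maxs_dia[np.argmax(xs[maxs_dia])])
            fid.points["diastolic_peak"] = pt(i_dia)
        else:
            i_infl = _inflection_after(d1, i_notch, n)
            if i_infl is not None:
                fid.points["diastolic_peak"] = pt(i_infl, x,
                                                  method="inflection")
            else:
                fid.points["diastolic_peak"] = FiducialPoint.absent()
    else:
        # no notch to delimit the systolic complex: search p2 among
        # prominent maxima in the first half of the pulse
        maxs_p2 = _local_maxima(xs, i_sys, int(0.5 * n), prominence=prom)
        maxs_p2 = maxs_p2[maxs_p2 != i_p1]
        if maxs_p2.size:
            fid.points["p2"] = pt(int(maxs_p2[np.argmax(xs[maxs_p2])]))
        else:
            fid.points["p2"] = pt(i_sys, method="coincides_sys_max")
        fid.points["diastolic_peak"] = FiducialPoint.absent()
    return fid


def _shoulder_after(d2: np.ndarray, i_b: int, i_hi: int):
    """Late-systolic shoulder: downward zero-crossing of the third
    derivative after the b-wave (slope of SDPPG turns negative)."""
    d3 = np.gradient(d2)
    for i in range(i_b + 1, i_hi - 1):
        if d3[i] >= 0 > d3[i + 1]:
            return i
    return None


def _inflection_after(d1: np.ndarray, i_from: int, n: int):
    """Deceleration inflection on the diastolic decay (local max of d1)."""
    pks = _local_maxima(d1, i_from + 1, n - 1)
    return int(pks[0]) if pks.size else None


# ---------------------------------------------------------------------
# index catalogue
# ---------------------------------------------------------------------

def _build_registry():
    T, A = "timing", "amplitude"
    reg = [
        IndexDescriptor("t_p1", "s", T, "time of early systolic peak"),
        IndexDescriptor("t_p2", "s", T, "time of late systolic peak"),
        IndexDescriptor("t_sys_max", "s", T, "time of systolic maximum"),
        IndexDescriptor("t_ms", "s", T, "time of maximum slope"),
        IndexDescriptor("t_notch", "s", T, "time of dicrotic notch"),
        IndexDescriptor("t_dia", "s", T, "time of diastolic peak"),
        IndexDescriptor("t_a", "s", T, "time of SDPPG a-wave"),
        IndexDescriptor("t_b", "s", T, "time of SDPPG b-wave"),
        IndexDescriptor("t_c", "s", T, "time of SDPPG c-wave"),
        IndexDescriptor("t_d", "s", T, "time of SDPPG d-wave"),
        IndexDescriptor("t_e", "s", T, "time of SDPPG e-wave"),
        IndexDescriptor("t_f", "s", T, "time of SDPPG f-wave"),
        IndexDescriptor("dt_p2_dia", "s", T,
                        "late systolic peak to diastolic peak interval"),
        IndexDescriptor("dt_a_b", "s", T, "SDPPG a-to-b interval"),
        IndexDescriptor("t_p1_frac", "-", T, "t_p1 / pulse duration"),
        IndexDescriptor("t_sys_frac", "-", T, "t_sys_max / pulse duration"),
        IndexDescriptor("t_notch_frac", "-", T, "t_notch / pulse duration"),
        IndexDescriptor("t_dia_frac", "-", T, "t_dia / pulse duration"),
        IndexDescriptor("dt_p2_dia_frac", "-", T,
                        "(t_dia - t_p2) / pulse duration"),
        IndexDescriptor("stiffness_ratio", "-", T,
                        "pulse duration / (t_dia - t_sys_max)"),
        IndexDescriptor("pulse_amp", "au", A,
                        "systolic amplitude above onset baseline"),
        IndexDescriptor("AI", "-", A,
                        "augmentation index amp(p2)/amp(p1)", key=True),
        IndexDescriptor("reflection_index", "-", A,
                        "diastolic / systolic amplitude"),
        IndexDescriptor("notch_rel", "-", A,
                        "notch amplitude / systolic amplitude"),
        IndexDescriptor("dicrotic_wave_rel", "-", A,
                        "(diastolic - notch amplitude) / systolic"),
        IndexDescriptor("p1_rel", "-", A, "amp(p1) / systolic amplitude"),
        IndexDescriptor("p2_rel", "-", A, "amp(p2) / systolic amplitude"),
        IndexDescriptor("width50_s", "s", A, "pulse width at 50% amplitude"),
        IndexDescriptor("width75_s", "s", A, "pulse width at 75% amplitude"),
        IndexDescriptor("area_total", "au*s", "area",
                        "baseline-corrected pulse area"),
        IndexDescriptor("A1", "au*s", "area", "area onset to notch"),
        IndexDescriptor("A2", "au*s", "area", "area notch to pulse end"),
        IndexDescriptor("IPA", "-", "area",
                        "inflection point area ratio A2/A1"),
        IndexDescriptor("IPAD", "-", "area", "IPA + d/a", key=True),
        IndexDescriptor("ms_amp", "au/s", "first_derivative",
                        "maximum upstroke slope"),
        IndexDescriptor("ms_norm", "-", "first_derivative",
                        "max slope * duration / systolic amplitude"),
        IndexDescriptor("dia_slope_min", "au/s", "first_derivative",
                        "steepest downstroke slope after systole"),
        IndexDescriptor("t_ms_frac", "-", "first_derivative",
                        "t_ms / pulse duration"),
        IndexDescriptor("a_amp", "au/s^2", "second_derivative",
                        "SDPPG a-wave amplitude"),
        IndexDescriptor("b/a", "-", "second_derivative",
                        "SDPPG b/a amplitude ratio"),
        IndexDescriptor("c/a", "-", "second_derivative",
                        "SDPPG c/a amplitude ratio", key=True),
        IndexDescriptor("d/a", "-", "second_derivative",
                        "SDPPG d/a amplitude ratio", key=True),
        IndexDescriptor("e/a", "-", "second_derivative",
                        "SDPPG e/a amplitude ratio", key=True),
        IndexDescriptor("f/a", "-", "second_derivative",
                        "SDPPG f/a amplitude ratio"),
        IndexDescriptor("aging_index", "-", "second_derivative",
                        "(b - c - d - e)/a"),
        IndexDescriptor("agi_mod", "-", "second_derivative",
                        "modified aging index (b - e)/a"),
        IndexDescriptor("agi_bcd", "-", "second_derivative",
                        "(b - c - d)/a"),
        IndexDescriptor("t_ae", "s", "second_derivative",
                        "SDPPG a-to-e interval"),
    ]
    return tuple(reg)


_FPA_REGISTRY = _build_registry()
assert len(_FPA_REGISTRY) == 48


def fpa_registry():
    """Ordered, immutable catalogue of the 48 FPA index descriptors."""
    return _FPA_REGISTRY


def _width_at(x: np.ndarray, baseline: float, i_sys: int, level: float,
              fs: float) -> float:
    """Width of the systolic wave at a fractional amplitude level."""
    thr = baseline + level * (x[i_sys] - baseline)
    above = x >= thr
    i = i_sys
    while i > 0 and above[i - 1]:
        i -= 1
    j = i_sys
    while j < x.size - 1 and above[j + 1]:
        j += 1
    return (j - i) / fs


def compute_fpa_indices(pulse: PulseWave, fid: FiducialSet,
                        fs: float | None = None) -> IndexSet:
    """Evaluate the 48-index FPA catalogue for one pulse.

    Amplitudes are measured relative to the onset baseline; indices whose
    fiducials are missing come out NaN.
    """
    fs = fs or pulse.fs_hz
    x = pulse.samples
    n = x.size
    T = n / fs
    baseline = fid["onset"].amplitude

    def amp(name: str) -> float:
        return fid.amp(name) - baseline

    t = fid.time
    v: dict = {}
    v["t_p1"] = t("p1")
    v["t_p2"] = t("p2")
    v["t_sys_max"] = t("systolic_max")
    v["t_ms"] = t("ms")
    v["t_notch"] = t("dicrotic_notch")
    v["t_dia"] = t("diastolic_peak")
    for w in "abcdef":
        v[f"t_{w}"] = t(w)
    v["dt_p2_dia"] = t("diastolic_peak") - t("p2")
    v["dt_a_b"] = t("b") - t("a")
    v["t_p1_frac"] = v["t_p1"] / T
    v["t_sys_frac"] = v["t_sys_max"] / T
    v["t_notch_frac"] = v["t_notch"] / T
    v["t_dia_frac"] = v["t_dia"] / T
    v["dt_p2_dia_frac"] = v["dt_p2_dia"] / T
    dtsd = t("diastolic_peak") - t("systolic_max")
    v["stiffness_ratio"] = T / dtsd if dtsd and np.isfinite(dtsd) \
        and dtsd > 0 else np.nan

    pulse_amp = amp("systolic_max")
    v["pulse_amp"] = pulse_amp
    v["AI"] = amp("p2") / amp("p1") if amp("p1") else np.nan
    v["reflection_index"] = amp("diastolic_peak") / pulse_amp
    v["notch_rel"] = amp("dicrotic_notch") / pulse_amp
    v["dicrotic_wave_rel"] = (amp("diastolic_peak")
                              - amp("dicrotic_notch")) / pulse_amp
    v["p1_rel"] = amp("p1") / pulse_amp
    v["p2_rel"] = amp("p2") / pulse_amp
    i_sys = fid["systolic_max"].index
    v["width50_s"] = _width_at(x, baseline, i_sys, 0.5, fs)
    v["width75_s"] = _width_at(x, baseline, i_sys, 0.75, fs)

    xb = x - baseline
    dt = 1.0 / fs
    v["area_total"] = float(np.trapezoid(xb, dx=dt))
    if fid.has("dicrotic_notch"):
        i_n = fid["dicrotic_notch"].index
        v["A1"] = float(np.trapezoid(xb[:i_n + 1], dx=dt))
        v["A2"] = float(np.trapezoid(xb[i_n:], dx=dt))
        v["IPA"] = v["A2"] / v["A1"] if v["A1"] else np.nan
    else:
        v["A1"] = v["A2"] = v["IPA"] = np.nan

    a_val = fid.amp("a")
    sd = {w: fid.amp(w) / a_val if a_val else np.nan for w in "bcdef"}
    v["IPAD"] = v["IPA"] + sd["d"]

    v["ms_amp"] = fid.amp("ms")
    v["ms_norm"] = v["ms_amp"] * T / pulse_amp
    d1, _ = derivatives(pulse)
    v["dia_slope_min"] = float(np.min(d1[i_sys:])) if i_sys < n - 1 \
        else np.nan
    v["t_ms_frac"] = v["t_ms"] / T

    v["a_amp"] = a_val
    v["b/a"] = sd["b"]
    v["c/a"] = sd["c"]
    v["d/a"] = sd["d"]
    v["e/a"] = sd["e"]
    v["f/a"] = sd["f"]
    v["aging_index"] = sd["b"] - sd["c"] - sd["d"] - sd["e"]
    v["agi_mod"] = sd["b"] - sd["e"]
    v["agi_bcd"] = sd["b"] - sd["c"] - sd["d"]
    v["t_ae"] = t("e") - t("a")

    ordered = {d.name: float(v[d.name]) for d in _FPA_REGISTRY}
    return IndexSet("FPA", ordered)


def fpa_for_pulses(pulses, mode: str = "per_beat_median",
                   window_s: float = SMOOTH_WINDOW_S,
                   polyorder: int = SMOOTH_ORDER) -> IndexSet:
    """Catalogue for a set of accepted pulses.

    ``per_beat_median`` computes indices on every pulse and takes the
    per-index median over beats where the index is defined (an index
    missing on more than half the beats stays NaN); ``ensemble`` computes
    them once on the ensemble-averaged pulse.
    """
    from .beats import ensemble_average

    if mode == "ensemble":
        ens = ensemble_average(pulses)
        p = ens.as_pulse()
        fid = locate_fiducials(p, window_s=window_s, polyorder=polyorder)
        return compute_fpa_indices(p, fid)
    if mode != "per_beat_median":
        raise ValueError(f"unknown FPA mode {mode!r}")
    rows = []
    for p in pulses:
        try:
            fid = locate_fiducials(p, window_s=window_s,
                                   polyorder=polyorder)
            rows.append(compute_fpa_indices(p, fid).values)
        except (MalformedPulseError, ResolutionError):
            continue
    if not rows:
        raise MalformedPulseError("no pulse yielded fiducials")
    names = [d.name for d in _FPA_REGISTRY]
    arr = np.array([[r[name] for name in names] for r in rows], dtype=float)
    defined = np.isfinite(arr).mean(axis=0) > 0.5
    med = np.full(len(names), np.nan)
    for j in range(len(names)):
        if defined[j]:
            med[j] = float(np.nanmedian(arr[:, j]))
    return IndexSet("FPA", dict(zip(names, med)))
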