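"""Independent brute-force oracles used by the test suite.

Everything here is written with plain loops and direct comparisons so it
shares no search code with the package (the smoothed input arrays are the
shared, well-defined starting point).
"""

import numpy as np

from ppgkit import fpa


def local_maxima(x):
    """Strict interior local maxima, by direct comparison."""
    return [i for i in range(1, len(x) - 1)
            if x[i] > x[i - 1] and x[i] > x[i + 1]]


def prominence(x, i):
    """Topographic prominence of the local maximum at i."""
    h = x[i]
    bases = []
    for step in (-1, 1):
        j = i
        low = h
        while 0 <= j + step < len(x):
            j += step
            if x[j] > h:
                break
            low = min(low, x[j])
        bases.append(low)
    return h - max(bases)


def prominent_maxima(x, lo, hi, prom):
    return [i for i in local_maxima(x[lo:hi])
            if prominence(np.asarray(x[lo:hi]), i) >= prom]


def brute_force_fiducials(pulse, window_s=fpa.SMOOTH_WINDOW_S,
                          polyorder=fpa.SMOOTH_ORDER):
    """Re-derive all fiducial sample indices by explicit scans.

    Mirrors the documented search conventions (windows, prominence
    floors, anchors) on the same smoothed arrays, but with none of the
    package's search code.
    """
    d1, d2 = fpa.derivatives(pulse, window_s, polyorder)
    xs = fpa._smoothed(pulse, window_s, polyorder)
    n = xs.size
    out = {"onset": 0}

    i_sys = max(range(n), key=lambda i: xs[i])
    out["systolic_max"] = i_sys
    prom = fpa.PROMINENCE_FRAC * (xs.max() - xs.min())

    # dicrotic notch: most prominent minimum after the last systolic peak
    sys_hi = max(int(0.35 * n), 3)
    sys_peaks = [i for i in local_maxima(xs[:sys_hi])
                 if i >= 1 and prominence(xs[:sys_hi], i) >= prom]
    anchor = max(sys_peaks[-1] if sys_peaks else i_sys, i_sys)
    notch_hi = max(int(fpa.NOTCH_WINDOW_END * n), anchor + 2)
    neg = -xs[anchor + 1:notch_hi]
    cands = [i for i in local_maxima(neg) if prominence(neg, i) >= prom]
    i_notch = (anchor + 1 + max(cands, key=lambda i: prominence(neg, i))
               if cands else None)

    # max slope
    i_ms = max(range(i_sys + 1), key=lambda i: d1[i])
    out["ms"] = i_ms

    # SDPPG a: first prominent max before the systolic apex
    a_hi = int(min(max(fpa.A_WINDOW_END * n, 2), i_sys + 1))
    d2_prom = 0.05 * (d2.max() - d2.min())
    seg = d2[:max(a_hi, 2)]
    a_cands = [i for i in local_maxima(seg) if prominence(seg, i) >= d2_prom]
    i_a = a_cands[0] if a_cands else int(max(range(len(seg)),
                                             key=lambda i: seg[i]))
    out["a"] = i_a

    wave_prom = 0.02 * (d2.max() - d2.min())
    # b: first prominent interior minimum after a (global-min fallback)
    b_hi = max(int(fpa.B_WINDOW_END * n), i_a + 2)
    neg2 = -d2[i_a + 1:b_hi]
    b_cands = [i for i in local_maxima(neg2)
               if prominence(neg2, i) >= wave_prom]
    if b_cands:
        i_b = i_a + 1 + b_cands[0]
    else:
        fb_hi = max(int(fpa.B_FALLBACK_END * n), i_a + 2)
        i_b = i_a + 1 + int(min(range(fb_hi - i_a - 1),
                                key=lambda i: d2[i_a + 1 + i]))
    out["b"] = i_b

    # e: prominent SDPPG max nearest the notch (or largest in window)
    if i_notch is not None:
        e_hi = max(int(fpa.E_NOTCH_WINDOW_END * n), i_b + 2)
    else:
        e_hi = max(int(fpa.E_WINDOW_END * n), i_b + 2)
    seg3 = d2[i_b + 1:e_hi]
    e_cands = [i for i in local_maxima(seg3)
               if prominence(seg3, i) >= wave_prom]
    if not e_cands:
        i_e = None
    elif i_notch is not None:
        i_e = i_b + 1 + min(e_cands,
                            key=lambda i: abs(i_b + 1 + i - i_notch))
    else:
        i_e = i_b + 1 + max(e_cands, key=lambda i: seg3[i])
    out["e"] = i_e

    if i_e is not None:
        seg4 = d2[i_b + 1:i_e]
        c_cands = [i for i in local_maxima(seg4)
                   if prominence(seg4, i) >= wave_prom]
        i_c = i_b + 1 + max(c_cands, key=lambda i: seg4[i]) if c_cands \
            else None
        out["c"] = i_c
        if i_c is not None and i_e - i_c >= 2:
            out["d"] = i_c + 1 + int(min(range(i_e - i_c),
                                         key=lambda i: d2[i_c + 1 + i]))
        else:
            out["d"] = None
        neg5 = -d2[i_e + 1:n]
        f_cands = [i for i in local_maxima(neg5)
                   if prominence(neg5, i) >= wave_prom]
        out["f"] = i_e + 1 + f_cands[0] if f_cands else None
    else:
        out["c"] = out["d"] = out["f"] = None

    if i_notch is None and i_e is not None:
        i_notch = i_e
    out["dicrotic_notch"] = i_notch

    # p1, p2, diastolic peak
    pre = xs[1:i_sys + 2]
    p1_cands = [i + 1 for i in local_maxima(pre)
                if prominence(pre, i) >= prom]
    i_p1 = p1_cands[0] if p1_cands else i_sys
    out["p1"] = i_p1
    if i_notch is not None:
        seg6 = xs[i_sys:i_notch + 1]
        p2_cands = [i_sys + i for i in local_maxima(seg6)
                    if prominence(seg6, i) >= prom]
        p2_cands = [i for i in p2_cands if i != i_p1]
        if i_sys != i_p1:
            p2_cands.append(i_sys)
        out["p2"] = max(p2_cands, key=lambda i: xs[i]) if p2_cands else None
        seg7 = xs[i_notch + 1:n - 1]
        dia_cands = [i_notch + 1 + i for i in local_maxima(seg7)
                     if prominence(seg7, i) >= prom]
        out["diastolic_peak"] = max(dia_cands, key=lambda i: xs[i]) \
            if dia_cands else None
    else:
        out["p2"] = None
        out["diastolic_peak"] = None
    return out


def brute_force_auc(a, b):
    """All-pairs AUC with half credit for ties."""
    a = [x for x in a if np.isfinite(x)]
    b = [x for x in b if np.isfinite(x)]
    wins = 0.0
    for xa in a:
        for xb in b:
            if xb > xa:
                wins += 1.0
            elif xb == xa:
                wins += 0.5
    return wins / (len(a) * len(b))
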