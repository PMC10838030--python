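"""Plain-text I/O, windowing and resampling for PPG signals.

On-disk format: a two-column CSV with header ``t_s,ppg_au`` (seconds,
arbitrary units), comma separator, dot decimal, UTF-8, Unix newlines,
9 significant digits — chosen for bit-exact interchange. Metadata travels
in an optional JSON sidecar ``<name>.meta.json`` next to the signal file.

Index tables use a long format ``subject_id,window_id,method,index_name,
value`` (plus a ``group`` column when labels are known) so that the
classification stage can consume them directly.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import resample_poly

from .core import PPGSignal
from .errors import BoundsError, FormatError

SPACING_TOL_S = 1e-6
INDEX_COLUMNS = ["subject_id", "window_id", "method", "index_name", "value"]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def read_signal(path) -> PPGSignal:
    """Read a ``t_s,ppg_au`` CSV (plus optional JSON sidecar).

    The sampling rate is inferred from the median sample spacing; any
    spacing deviating from it by more than 1e-6 s is a format error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if list(df.columns[:2]) != ["t_s", "ppg_au"]:
        raise FormatError(f"{path}: expected header 't_s,ppg_au',"
                          f" got {list(df.columns)}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    t = df["t_s"].to_numpy(dtype=float)
    x = df["ppg_au"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: t_s must be strictly increasing")
    dt_med = float(np.median(dt))
    if np.max(np.abs(dt - dt_med)) > SPACING_TOL_S:
        raise FormatError(f"{path}: non-uniform sampling (max deviation"
                          f" {np.max(np.abs(dt - dt_med)):.3g} s)")
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PPGSignal(x, 1.0 / dt_med, t0_s=float(t[0]), meta=meta)


def write_signal(signal: PPGSignal, path) -> Path:
    """Write a signal as CSV (9 significant digits) + JSON sidecar."""
    path = Path(path)
    t = signal.times_s
    lines = ["t_s,ppg_au"]
    lines += [f"{ti:.9g},{xi:.9g}" for ti, xi in zip(t, signal.samples)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    if signal.meta:
        _sidecar(path).write_text(json.dumps(signal.meta, indent=1,
                                             sort_keys=True))
    return path


def window(signal: PPGSignal, start_s: float, length_s: float) -> PPGSignal:
    """Extract a window of ``length_s`` seconds starting at ``start_s``.

    ``start_s`` is relative to the start of the signal. The window must lie
    entirely within the signal and contain at least 2 samples.
    """
    n = int(round(length_s * signal.fs_hz))
    i0 = int(round(start_s * signal.fs_hz))
    if length_s <= 0 or n < 2:
        raise BoundsError(f"window length {length_s} s is degenerate")
    if i0 < 0 or i0 + n > signal.n_samples:
        raise BoundsError(
            f"window [{start_s}, {start_s + length_s}] s exceeds signal of"
            f" {signal.duration_s:.3f} s")
    return PPGSignal(signal.samples[i0:i0 + n].copy(), signal.fs_hz,
                     t0_s=signal.t0_s + i0 / signal.fs_hz,
                     meta=dict(signal.meta))


def resample(signal: PPGSignal, fs_new: float) -> PPGSignal:
    """Resample to ``fs_new`` (>= 25 Hz), preserving duration.

    Rational rate ratios use zero-phase polyphase filtering; other ratios
    fall back to cubic-spline interpolation. A short edge region is
    spline-corrected after polyphase filtering to suppress end transients.
    """
    if fs_new < 25:
        raise ValueError("fs_new must be >= 25 Hz")
    if abs(fs_new - signal.fs_hz) < 1e-12 * signal.fs_hz:
        return PPGSignal(signal.samples.copy(), signal.fs_hz, signal.t0_s,
                         dict(signal.meta))
    n_new = int(round(signal.n_samples * fs_new / signal.fs_hz))
    t_old = np.arange(signal.n_samples) / signal.fs_hz
    t_new = np.arange(n_new) / fs_new
    spline = CubicSpline(t_old, signal.samples)
    frac = Fraction(fs_new / signal.fs_hz).limit_denominator(1000)
    if abs(float(frac) - fs_new / signal.fs_hz) < 1e-12:
        mean = float(signal.samples.mean())
        y = resample_poly(signal.samples - mean, frac.numerator,
                          frac.denominator, padtype="line") + mean
        y = y[:n_new]
        if y.size < n_new:
            y = np.concatenate([y, spline(t_new[y.size:])])
        # polyphase end transients: trust the local spline near the edges
        guard = min(max(int(0.05 * signal.fs_hz) * frac.numerator
                        // frac.denominator + 1, 4), n_new // 2)
        y[:guard] = spline(t_new[:guard])
        y[-guard:] = spline(t_new[-guard:])
    else:
        y = spline(t_new)
    return PPGSignal(y, fs_new, signal.t0_s, dict(signal.meta))


def write_index_table(df: pd.DataFrame, path) -> Path:
    """Write a long-format index table CSV."""
    cols = [c for c in INDEX_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, index=False, lineterminator="\n",
                    float_format="%.9g")
    return Path(path)


def read_index_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in INDEX_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: index table missing columns {missing}")
    return df


def write_density_map(dmap, path, tau_samples: int | None = None,
                      cycle_length_s: float | None = None) -> Path:
    """Write an attractor density map as a plain-text matrix + JSON header.

    Rows run along increasing w; the header sidecar records the extent,
    grid size and, when given, the embedding delay and cycle length.
    """
    path = Path(path)
    np.savetxt(path, dmap.grid.T, fmt="%.9g")
    header = dict(extent=dmap.extent, n_bins=int(dmap.n_bins))
    if tau_samples is not None:
        header["tau_samples"] = int(tau_samples)
    if cycle_length_s is not None:
        header["cycle_length_s"] = float(cycle_length_s)
    _sidecar(path).write_text(json.dumps(header, indent=1, sort_keys=True))
    return path


def read_density_map(path):
    """Read a density map written by :func:`write_density_map`."""
    from .spar import AttractorDensityMap

    path = Path(path)
    grid = np.loadtxt(path).T
    header = json.loads(_sidecar(path).read_text())
    extent = float(header["extent"])
    n_bins = int(header["n_bins"])
    edges = np.linspace(-extent, extent, n_bins + 1)
    return AttractorDensityMap(grid, extent, n_bins, edges, edges)
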