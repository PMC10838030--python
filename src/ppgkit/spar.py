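"""Symmetric Projection Attractor Reconstruction (SPAR).

A windowed, approximately cyclic signal x(t) is delay-embedded in 3D as
(x_i, x_{i-tau}, x_{i-2tau}) with tau equal to one-third of the average
cycle length, then projected onto the plane orthogonal to (1, 1, 1):

    v = (x + y - 2 z) / sqrt(6),    w = (x - y) / sqrt(2).

Because the projection coefficients sum to zero, any constant offset — and
hence slow baseline wander — is annihilated: a linear drift merely
translates the attractor without distorting it. Each beat traces one loop
about the origin, and a period-3tau signal gives the attractor an exact
three-fold rotational symmetry.

The point cloud is binned to a normalized density map, from which a
catalogue of 49 scalar indices is computed. The six key indices quantify
the central opening, rotation angle, arm angular width, outer-arm radial
bandwidth, three-fold symmetry, and density concentration (arm density);
denser attractors indicate lower beat-to-beat variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PPGSignal
from .errors import BoundsError, DegenerateAttractorError
from .fpa import IndexDescriptor, IndexSet

__all__ = ["AttractorEmbedding", "AttractorDensityMap", "embedding_delay",
           "embed_project", "density_map", "spar_indices",
           "attractor_quality", "spar_registry", "SPAR_KEY_INDICES"]

SPAR_KEY_INDICES = ("opening_5pct", "rotation_deg", "peak_width_deg",
                    "bandwidth", "symmetry", "arm_density")

GRID_BINS = 251
#: Fixed half-extent of the density grid for min-max normalized signals:
#: data in [0, 1] satisfy |v| <= 2/sqrt(6) ~ 0.8165 and |w| <= 1/sqrt(2).
GRID_EXTENT = 0.85
N_ANGULAR_BINS = 36
MIN_BIN_POINTS = 20
ARM_DENSITY_SCALE = 25.0


@dataclass
class AttractorEmbedding:
    """Projected 2D attractor point cloud with its embedding delay."""

    points2d: np.ndarray       # shape (n_points, 2): columns v, w
    tau_samples: int
    fs_hz: float
    cycle_length_s: float
    normalized: bool = True

    @property
    def n_points(self) -> int:
        return int(self.points2d.shape[0])

    @property
    def v(self) -> np.ndarray:
        return self.points2d[:, 0]

    @property
    def w(self) -> np.ndarray:
        return self.points2d[:, 1]


@dataclass
class AttractorDensityMap:
    """G x G density grid over a symmetric extent, total mass 1."""

    grid: np.ndarray
    extent: float
    n_bins: int
    v_edges: np.ndarray = field(repr=False, default=None)
    w_edges: np.ndarray = field(repr=False, default=None)

    @property
    def cell_size(self) -> float:
        return 2.0 * self.extent / self.n_bins


def embedding_delay(cycle_length_s: float, fs_hz: float) -> int:
    """Delay in samples: one-third of the average cycle length.

    Rounded to the nearest integer, minimum 1.
    """
    if not (cycle_length_s > 0):
        raise ValueError("cycle_length_s must be positive")
    return max(int(round(fs_hz * cycle_length_s / 3.0)), 1)


def embed_project(signal: PPGSignal, tau_samples: int,
                  normalize: bool = True,
                  cycle_length_s: float | None = None) -> AttractorEmbedding:
    """Delay-embed in 3D and project onto the symmetric 2D plane.

    With ``normalize`` the signal is min-max scaled to [0, 1] per window
    first (making density maps comparable across windows); turn it off to
    obtain the exact offset/drift invariances of the raw projection.
    """
    tau = int(tau_samples)
    x = signal.samples
    if x.size <= 2 * tau + 1:
        raise BoundsError(f"signal of {x.size} samples too short for"
                          f" tau = {tau}")
    if normalize:
        rng = np.ptp(x)
        x = (x - x.min()) / rng if rng > 0 else np.zeros_like(x)
    xi = x[2 * tau:]
    yi = x[tau:-tau]
    zi = x[:-2 * tau]
    v = (xi + yi - 2.0 * zi) / np.sqrt(6.0)
    w = (xi - yi) / np.sqrt(2.0)
    return AttractorEmbedding(np.column_stack([v, w]), tau, signal.fs_hz,
                              cycle_length_s if cycle_length_s is not None
                              else 3.0 * tau / signal.fs_hz,
                              normalized=normalize)


def density_map(embedding: AttractorEmbedding,
                n_bins: int = GRID_BINS,
                extent: float | None = None) -> AttractorDensityMap:
    """Bin the point cloud to a G x G histogram normalized to mass 1.

    For normalized embeddings the extent is fixed so maps from different
    windows are bit-comparable; otherwise it adapts to the data.
    """
    if embedding.n_points < 1:
        raise DegenerateAttractorError("empty embedding")
    if extent is None:
        if embedding.normalized:
            extent = GRID_EXTENT
        else:
            extent = 1.02 * max(float(np.max(np.abs(embedding.points2d))),
                                1e-12)
    edges = np.linspace(-extent, extent, n_bins + 1)
    grid, _, _ = np.histogram2d(embedding.v, embedding.w,
                                bins=[edges, edges])
    total = grid.sum()
    if total == 0:
        raise DegenerateAttractorError("no points inside the density extent")
    return AttractorDensityMap(grid / total, extent, n_bins, edges, edges)


def attractor_quality(signal: PPGSignal) -> float:
    """Cyclicity score in [0, 1]: height of the first non-zero-lag
    autocorrelation peak of the band-limited signal.

    Amplitudes are clipped at the 1st/99th percentiles first, so that
    rare large motion transients reduce the score gradually rather than
    dominating the signal energy.
    """
    if signal.duration_s < 5:
        raise ValueError("need at least 5 s of signal")
    from .beats import _cardiac_band, _cycle_estimate_autocorr
    xb = _cardiac_band(signal.samples, signal.fs_hz)
    lo_a, hi_a = np.percentile(xb, [1, 99])
    xb = np.clip(xb, lo_a, hi_a)
    lag_s, height = _cycle_estimate_autocorr(xb, signal.fs_hz)
    if lag_s is None:
        return 0.0
    return float(np.clip(height, 0.0, 1.0))


# ---------------------------------------------------------------------
# index catalogue
# ---------------------------------------------------------------------

def _build_registry():
    K = True
    reg = [
        IndexDescriptor("opening_5pct", "-", "opening",
                        "central opening r(5%)/r(95%)", key=K),
        IndexDescriptor("rotation_deg", "deg", "angular",
                        "attractor rotation angle in [0, 120)", key=K),
        IndexDescriptor("peak_width_deg", "deg", "angular",
                        "arm angular width (circular SD of folded angle)",
                        key=K),
        IndexDescriptor("bandwidth", "-", "radial",
                        "median per-arm radial spread (r90-r10)/r95", key=K),
        IndexDescriptor("symmetry", "-", "angular",
                        "1 - spread of the three 120-degree sector masses",
                        key=K),
        IndexDescriptor("arm_density", "-", "density",
                        "density concentration 1-exp(-(max/mean nz)/25)",
                        key=K),
        IndexDescriptor("opening_1pct", "-", "opening", "r(1%)/r(95%)"),
        IndexDescriptor("opening_2_5pct", "-", "opening", "r(2.5%)/r(95%)"),
        IndexDescriptor("opening_10pct", "-", "opening", "r(10%)/r(95%)"),
        IndexDescriptor("opening_25pct", "-", "opening", "r(25%)/r(95%)"),
        IndexDescriptor("opening_50pct", "-", "opening", "r(50%)/r(95%)"),
        IndexDescriptor("r_5", "au", "radial", "5th radius percentile"),
        IndexDescriptor("r_10", "au", "radial", "10th radius percentile"),
        IndexDescriptor("r_25", "au", "radial", "25th radius percentile"),
        IndexDescriptor("r_50", "au", "radial", "median radius"),
        IndexDescriptor("r_75", "au", "radial", "75th radius percentile"),
        IndexDescriptor("r_90", "au", "radial", "90th radius percentile"),
        IndexDescriptor("r_95", "au", "radial", "95th radius percentile"),
        IndexDescriptor("r_max", "au", "radial", "maximum radius"),
        IndexDescriptor("r_mean", "au", "radial", "mean radius"),
        IndexDescriptor("r_sd", "au", "radial", "radius SD"),
        IndexDescriptor("r_cv", "-", "radial", "radius CV"),
        IndexDescriptor("r_iqr_norm", "-", "radial", "(r75-r25)/r50"),
        IndexDescriptor("radial_skew", "-", "radial", "radius skewness"),
        IndexDescriptor("radial_kurt", "-", "radial",
                        "radius excess kurtosis"),
        IndexDescriptor("sector_mass_1", "-", "angular",
                        "mass of rotation-aligned sector 1"),
        IndexDescriptor("sector_mass_2", "-", "angular",
                        "mass of rotation-aligned sector 2"),
        IndexDescriptor("sector_mass_3", "-", "angular",
                        "mass of rotation-aligned sector 3"),
        IndexDescriptor("sector_r_spread_1", "-", "radial",
                        "radial SD / r95 within sector 1"),
        IndexDescriptor("sector_r_spread_2", "-", "radial",
                        "radial SD / r95 within sector 2"),
        IndexDescriptor("sector_r_spread_3", "-", "radial",
                        "radial SD / r95 within sector 3"),
        IndexDescriptor("sector_bw_1", "-", "radial",
                        "(r90-r10)/r95 within sector 1"),
        IndexDescriptor("sector_bw_2", "-", "radial",
                        "(r90-r10)/r95 within sector 2"),
        IndexDescriptor("sector_bw_3", "-", "radial",
                        "(r90-r10)/r95 within sector 3"),
        IndexDescriptor("angular_entropy", "nats", "angular",
                        "entropy of the angular mass distribution"),
        IndexDescriptor("angular_resultant", "-", "angular",
                        "resultant length of exp(i 3 theta)"),
        IndexDescriptor("folded_peak_count", "count", "angular",
                        "modes of the folded angular density"),
        IndexDescriptor("radial_entropy", "nats", "radial",
                        "entropy of the radial mass distribution"),
        IndexDescriptor("max_density", "-", "density", "largest bin mass"),
        IndexDescriptor("mean_nonzero_density", "-", "density",
                        "mean mass of occupied bins"),
        IndexDescriptor("occupied_fraction", "-", "density",
                        "fraction of bins occupied"),
        IndexDescriptor("density_gini", "-", "density",
                        "Gini coefficient of bin masses"),
        IndexDescriptor("core_mass", "-", "density",
                        "mass within 0.1 r(95%) of the origin"),
        IndexDescriptor("loop_count_est", "count", "trajectory",
                        "total winding about the origin in turns"),
        IndexDescriptor("loop_area_cv", "-", "trajectory",
                        "CV of per-cycle loop areas"),
        IndexDescriptor("mean_step_dist", "au", "trajectory",
                        "mean successive point distance"),
        IndexDescriptor("v_sd", "au", "moments", "SD of v coordinate"),
        IndexDescriptor("w_sd", "au", "moments", "SD of w coordinate"),
        IndexDescriptor("vw_corr", "-", "moments", "corr(v, w)"),
    ]
    return tuple(reg)


_SPAR_REGISTRY = _build_registry()
assert len(_SPAR_REGISTRY) == 49


def spar_registry():
    """Ordered, immutable catalogue of the 49 SPAR index descriptors."""
    return _SPAR_REGISTRY


def _circular_sd_deg(theta3: np.ndarray) -> float:
    """Circular SD (degrees) of the folded angle, expressed on the
    attractor scale (folded-space SD / 3)."""
    R = float(np.abs(np.mean(np.exp(1j * theta3))))
    R = min(max(R, 1e-300), 1.0)
    sd_folded = np.sqrt(max(-2.0 * np.log(R), 0.0))
    return float(np.degrees(sd_folded) / 3.0)


def _gini(masses: np.ndarray) -> float:
    m = np.sort(masses.ravel())
    n = m.size
    if n == 0 or m.sum() == 0:
        return 0.0
    cum = np.cumsum(m)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def _folded_peak_count(hist: np.ndarray) -> int:
    """Modes of the (circular) folded angular histogram."""
    n = hist.size
    if n < 3 or hist.sum() == 0:
        return 0
    thr = 0.5 * hist.max()
    count = 0
    for i in range(n):
        a, b, c = hist[i - 1], hist[i], hist[(i + 1) % n]
        if b > a and b >= c and b >= thr:
            count += 1
    return count


def spar_indices(embedding: AttractorEmbedding,
                 density: AttractorDensityMap | None = None) -> IndexSet:
    """Evaluate the 49-index SPAR catalogue.

    Radial/angular statistics are computed on the point cloud (each point
    carrying mass 1/n, identical to the normalized density in the limit of
    fine bins); density-grid statistics use the binned map.
    """
    if density is None:
        density = density_map(embedding)
    pts = embedding.points2d
    if pts.shape[0] < 3:
        raise DegenerateAttractorError("too few points")
    v, w = pts[:, 0], pts[:, 1]
    r = np.hypot(v, w)
    theta = np.arctan2(w, v)           # radians in (-pi, pi]
    theta3 = np.mod(3.0 * theta, 2.0 * np.pi)

    q = {p: float(np.percentile(r, p)) for p in
         (1, 2.5, 5, 10, 25, 50, 75, 90, 95)}
    r95 = q[95] if q[95] > 0 else np.nan

    iv: dict = {}
    iv["opening_1pct"] = q[1] / r95
    iv["opening_2_5pct"] = q[2.5] / r95
    iv["opening_5pct"] = q[5] / r95
    iv["opening_10pct"] = q[10] / r95
    iv["opening_25pct"] = q[25] / r95
    iv["opening_50pct"] = q[50] / r95
    for p in (5, 10, 25, 50, 75, 90, 95):
        iv[f"r_{p}".replace(".", "_")] = q[p]
    iv["r_max"] = float(r.max())
    iv["r_mean"] = float(r.mean())
    iv["r_sd"] = float(r.std())
    iv["r_cv"] = iv["r_sd"] / iv["r_mean"] if iv["r_mean"] > 0 else np.nan
    iv["r_iqr_norm"] = (q[75] - q[25]) / q[50] if q[50] > 0 else np.nan
    rs = r.std()
    if rs > 0:
        z = (r - r.mean()) / rs
        iv["radial_skew"] = float(np.mean(z ** 3))
        iv["radial_kurt"] = float(np.mean(z ** 4) - 3.0)
    else:
        iv["radial_skew"] = iv["radial_kurt"] = 0.0

    # rotation: direction of the mean folded phasor, mapped to [0, 120)
    mean_phasor = complex(np.mean(np.exp(1j * theta3)))
    rot = np.degrees(np.angle(mean_phasor)) / 3.0
    iv["rotation_deg"] = float(np.mod(rot, 120.0))
    iv["angular_resultant"] = float(abs(mean_phasor))
    # arm angular width: computed on the outer (arm) half of the mass —
    # points near the origin carry no angular information
    arm = r >= q[50]
    iv["peak_width_deg"] = _circular_sd_deg(theta3[arm]) if arm.any() \
        else _circular_sd_deg(theta3)

    # three 120-degree sectors aligned with the rotation angle
    rel = np.mod(np.degrees(theta) - iv["rotation_deg"] + 60.0, 360.0)
    sector = np.minimum((rel // 120.0).astype(int), 2)
    masses = np.array([np.mean(sector == k) for k in range(3)])
    iv["symmetry"] = float(np.clip(1.0 - (masses.max() - masses.min()),
                                   0.0, 1.0))
    for k in range(3):
        iv[f"sector_mass_{k + 1}"] = float(masses[k])
        rk = r[sector == k]
        if rk.size >= 2 and np.isfinite(r95):
            iv[f"sector_r_spread_{k + 1}"] = float(rk.std() / r95)
            iv[f"sector_bw_{k + 1}"] = float(
                (np.percentile(rk, 90) - np.percentile(rk, 10)) / r95)
        else:
            iv[f"sector_r_spread_{k + 1}"] = np.nan
            iv[f"sector_bw_{k + 1}"] = np.nan

    # bandwidth: median radial spread over occupied angular bins
    bin_idx = np.minimum((theta3 / (2 * np.pi) * N_ANGULAR_BINS).astype(int),
                         N_ANGULAR_BINS - 1)
    spreads = []
    ang_hist = np.zeros(N_ANGULAR_BINS)
    for k in range(N_ANGULAR_BINS):
        rk = r[bin_idx == k]
        ang_hist[k] = rk.size
        if rk.size >= MIN_BIN_POINTS and np.isfinite(r95):
            spreads.append((np.percentile(rk, 90) - np.percentile(rk, 10))
                           / r95)
    iv["bandwidth"] = float(np.clip(np.median(spreads), 0.0, 1.0)) \
        if spreads else np.nan
    ang_p = ang_hist / ang_hist.sum() if ang_hist.sum() else ang_hist
    nz = ang_p[ang_p > 0]
    iv["angular_entropy"] = float(-(nz * np.log(nz)).sum())
    iv["folded_peak_count"] = float(_folded_peak_count(ang_hist))

    if np.ptp(r) > 1e-9 * max(float(r.max()), 1e-30):
        rad_hist, _ = np.histogram(r, bins=24)
        rp = rad_hist / rad_hist.sum() if rad_hist.sum() else rad_hist
        nz = rp[rp > 0]
        iv["radial_entropy"] = float(-(nz * np.log(nz)).sum())
    else:
        iv["radial_entropy"] = 0.0  # degenerate: all mass on one radius

    grid = density.grid
    occupied = grid[grid > 0]
    iv["max_density"] = float(grid.max())
    iv["mean_nonzero_density"] = float(occupied.mean()) if occupied.size \
        else np.nan
    iv["occupied_fraction"] = float(occupied.size / grid.size)
    iv["density_gini"] = _gini(grid)
    concentration = (iv["max_density"] / iv["mean_nonzero_density"]
                     if occupied.size else np.nan)
    iv["arm_density"] = float(1.0 - np.exp(-concentration
                                           / ARM_DENSITY_SCALE))
    iv["core_mass"] = float(np.mean(r <= 0.1 * r95)) if np.isfinite(r95) \
        else np.nan

    # trajectory measures
    dtheta = np.diff(np.unwrap(theta))
    iv["loop_count_est"] = float(abs(dtheta.sum()) / (2 * np.pi))
    seg = 3 * embedding.tau_samples
    areas = []
    for i0 in range(0, pts.shape[0] - seg, seg):
        vv = v[i0:i0 + seg]
        ww = w[i0:i0 + seg]
        areas.append(0.5 * abs(np.dot(vv, np.roll(ww, -1))
                               - np.dot(ww, np.roll(vv, -1))))
    areas = np.asarray(areas)
    if areas.size >= 2 and areas.mean() > 0:
        iv["loop_area_cv"] = float(areas.std() / areas.mean())
    else:
        iv["loop_area_cv"] = np.nan
    iv["mean_step_dist"] = float(np.mean(np.hypot(np.diff(v), np.diff(w))))
    iv["v_sd"] = float(v.std())
    iv["w_sd"] = float(w.std())
    if v.std() > 0 and w.std() > 0:
        iv["vw_corr"] = float(np.corrcoef(v, w)[0, 1])
    else:
        iv["vw_corr"] = np.nan

    ordered = {d.name: float(iv[d.name]) for d in _SPAR_REGISTRY}
    return IndexSet("SPAR", ordered)
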