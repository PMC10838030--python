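"""Synthetic PPG pulses, signals and labelled cohorts.

The generator emulates the morphological structure of finger/wrist PPG
pulses — an early-systolic peak, a late-systolic shoulder produced by wave
reflection, a dicrotic notch and a diastolic peak — and the cohort-level
effects the downstream analysis assumes:

* vascular aging attenuates the diastolic peak, moves it earlier in the
  cycle, and augments the late-systolic shoulder;
* activity states (sleep, seated work, exercise) shift heart rate,
  beat-period variability and motion-artefact rate;
* recordings carry baseline wander, additive noise and transient motion
  artefacts.

The waveform model is a sum of three Gaussian components (early systolic,
late systolic, diastolic) minus a notch component placed at the trough
between the late-systolic and diastolic components. No haemodynamics are
solved; cardiac/vascular parameters are mapped directly to morphology.

All randomness flows through ``numpy.random.default_rng`` seeded from the
profile/spec, so identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import PPGSignal, PulseWave
from .errors import ConfigurationError, ResolutionError

__all__ = [
    "PulseShape",
    "SubjectProfile",
    "CohortSpec",
    "AgeMapping",
    "ACTIVITY_PRESETS",
    "age_to_shape",
    "synth_pulse",
    "synth_signal",
    "synth_cohort",
    "young_cohort_spec",
    "elderly_cohort_spec",
]

AGE_MIN, AGE_MAX = 25.0, 75.0


@dataclass(frozen=True)
class PulseShape:
    """Morphological degrees of freedom of a single PPG pulse.

    All timings are fractions of the beat period; all amplitudes are
    relative to the early-systolic peak amplitude (fixed at 1.0).
    """

    systolic_amp: float = 1.0
    systolic_frac: float = 0.15
    late_systolic_amp_ratio: float = 0.55
    late_systolic_frac: float = 0.26
    diastolic_amp_ratio: float = 0.45
    diastolic_frac: float = 0.46
    component_widths: tuple = (0.045, 0.025, 0.05)
    notch_depth: float = 0.05
    #: fall width of the diastolic wave (two-sided Gaussian): real PPG
    #: decays throughout diastole rather than returning flat to baseline
    diastolic_fall_width: float = 0.18

    def __post_init__(self) -> None:
        if not (0 < self.systolic_frac < self.late_systolic_frac
                < self.diastolic_frac < 1):
            raise ValueError(
                "require 0 < systolic_frac < late_systolic_frac"
                " < diastolic_frac < 1")
        for name in ("late_systolic_amp_ratio", "diastolic_amp_ratio",
                     "notch_depth"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if len(self.component_widths) != 3 or min(self.component_widths) <= 0:
            raise ValueError("component_widths must be three positive fractions")


@dataclass(frozen=True)
class SubjectProfile:
    """Everything needed to simulate one subject's recording."""

    age_years: float = 45.0
    hr_bpm: float = 70.0
    hrv_cv: float = 0.05          # CV of the beat period
    activity: str = "seated"      # sleep | seated | exercise
    wander_amp: float = 0.05      # fraction of pulse amplitude
    wander_freq_hz: float = 0.25  # respiratory-band drift
    noise_sd: float = 0.01        # fraction of pulse amplitude
    artefact_rate_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (AGE_MIN <= self.age_years <= AGE_MAX):
            raise ValueError(f"age_years must lie in [{AGE_MIN}, {AGE_MAX}]")
        if not (self.hr_bpm > 0):
            raise ValueError("hr_bpm must be positive")
        if self.activity not in ACTIVITY_PRESETS:
            raise ValueError(f"unknown activity {self.activity!r}")
        for name in ("hrv_cv", "wander_amp", "noise_sd",
                     "artefact_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Activity presets: heart rate, beat-period CV, artefact rate, and a
#: morphology shift (exercise raises the diastolic wave via vasodilation).
ACTIVITY_PRESETS: dict = {
    "sleep": dict(hr_bpm=55.0, hrv_cv=0.05, artefact_rate_per_min=0.0,
                  diastolic_boost=0.0),
    "seated": dict(hr_bpm=70.0, hrv_cv=0.07, artefact_rate_per_min=0.5,
                   diastolic_boost=0.0),
    "exercise": dict(hr_bpm=110.0, hrv_cv=0.12, artefact_rate_per_min=4.0,
                     diastolic_boost=0.15),
}


def profile_for_activity(activity: str, age_years: float = 45.0,
                         seed: int = 0, **overrides) -> SubjectProfile:
    """Build a SubjectProfile from an activity preset."""
    preset = ACTIVITY_PRESETS[activity]
    kw = dict(age_years=age_years, activity=activity, seed=seed,
              hr_bpm=preset["hr_bpm"], hrv_cv=preset["hrv_cv"],
              artefact_rate_per_min=preset["artefact_rate_per_min"])
    kw.update(overrides)
    return SubjectProfile(**kw)


@dataclass(frozen=True)
class AgeMapping:
    """Linear endpoints of the age -> morphology mapping over 25..75 years.

    Directions follow the physiology of vascular aging: the reflected
    diastolic wave attenuates and arrives earlier (stiffer arteries ->
    faster wave speed), while late-systolic augmentation grows.
    Magnitudes are a package choice and can be overridden here.
    """

    diastolic_amp_young: float = 0.45
    diastolic_amp_old: float = 0.15
    diastolic_frac_young: float = 0.46
    diastolic_frac_old: float = 0.36
    late_systolic_amp_young: float = 0.55
    late_systolic_amp_old: float = 0.95


DEFAULT_AGE_MAPPING = AgeMapping()


def age_to_shape(age_years: float,
                 mapping: AgeMapping = DEFAULT_AGE_MAPPING) -> PulseShape:
    """Deterministically map age (25..75 years) to a pulse morphology.

    Linear interpolation between the mapping's young/old endpoints:
    diastolic amplitude and timing strictly decrease with age, the
    late-systolic shoulder strictly increases.
    """
    if not (AGE_MIN <= age_years <= AGE_MAX):
        raise ValueError(f"age_years must lie in [{AGE_MIN}, {AGE_MAX}],"
                         f" got {age_years}")
    u = (age_years - AGE_MIN) / (AGE_MAX - AGE_MIN)

    def lerp(a: float, b: float) -> float:
        return a + u * (b - a)

    return PulseShape(
        diastolic_amp_ratio=lerp(mapping.diastolic_amp_young,
                                 mapping.diastolic_amp_old),
        diastolic_frac=lerp(mapping.diastolic_frac_young,
                            mapping.diastolic_frac_old),
        late_systolic_amp_ratio=lerp(mapping.late_systolic_amp_young,
                                     mapping.late_systolic_amp_old),
    )


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


NOTCH_WIDTH_FRAC = 0.02  # width of the dicrotic-notch component


def synth_pulse(shape: PulseShape, period_s: float, fs_hz: float) -> PulseWave:
    """Render one pulse over a single beat period.

    The three Gaussian components are summed on a time axis expressed in
    fractions of the period; the notch component is subtracted at the
    interior minimum of that base between the late-systolic and diastolic
    centres (if no interior minimum exists — e.g. with no diastolic wave —
    the notch is omitted, since there is no incisura to deepen).
    """
    if not (period_s > 0.3):
        raise ValueError("period_s must exceed 0.3 s")
    if not (fs_hz >= 50):
        raise ValueError("fs_hz must be >= 50")
    n = int(round(period_s * fs_hz))
    if min(shape.component_widths) * n < 2:
        raise ResolutionError(
            f"component width {min(shape.component_widths)} of period maps to"
            f" fewer than 2 samples at {fs_hz} Hz, period {period_s} s")
    t = np.arange(n) / n  # fraction of the beat period
    w1, w2, w3 = shape.component_widths
    # diastolic wave: Gaussian rise, wider Gaussian fall (slow runoff)
    dia_width = np.where(t <= shape.diastolic_frac, w3,
                         shape.diastolic_fall_width)
    dia = shape.diastolic_amp_ratio * np.exp(
        -0.5 * ((t - shape.diastolic_frac) / dia_width) ** 2)
    base = (shape.systolic_amp * _gauss(t, shape.systolic_frac, w1)
            + shape.systolic_amp * shape.late_systolic_amp_ratio
            * _gauss(t, shape.late_systolic_frac, w2)
            + shape.systolic_amp * dia)

    # place the notch at the interior trough between shoulder and
    # diastolic wave, but no later than 2.5 notch-widths before the
    # diastolic centre so the incisura does not erode the diastolic peak
    lo = int(np.ceil(shape.late_systolic_frac * n))
    hi = int(np.floor(shape.diastolic_frac * n))
    pulse = base
    if hi - lo > 2:
        seg = base[lo:hi + 1]
        k = int(np.argmin(seg))
        if 0 < k < seg.size - 1:  # interior trough only
            notch_center = min((lo + k) / n,
                               shape.diastolic_frac - 2.5 * NOTCH_WIDTH_FRAC)
            pulse = base - shape.notch_depth * _gauss(t, notch_center,
                                                      NOTCH_WIDTH_FRAC)
    return PulseWave(pulse, fs_hz)


def _shape_for_profile(profile: SubjectProfile,
                       mapping: AgeMapping = DEFAULT_AGE_MAPPING) -> PulseShape:
    shape = age_to_shape(profile.age_years, mapping)
    boost = ACTIVITY_PRESETS[profile.activity]["diastolic_boost"]
    if boost:
        shape = replace(shape, diastolic_amp_ratio=min(
            1.0, shape.diastolic_amp_ratio + boost))
    return shape


def synth_signal(profile: SubjectProfile, duration_s: float,
                 fs_hz: float = 500.0,
                 mapping: AgeMapping = DEFAULT_AGE_MAPPING) -> PPGSignal:
    """Simulate a continuous PPG recording for one subject.

    Beats are concatenated with i.i.d. lognormal periods (mean 60/hr,
    CV = hrv_cv; lognormal guarantees positivity), then sinusoidal baseline
    wander, white noise and Poisson-placed half-sine motion artefacts are
    added. Sample count is exactly ``round(duration_s * fs_hz)``.
    """
    if duration_s < 10:
        raise ValueError("duration_s must be >= 10 s")
    rng = np.random.default_rng(profile.seed)
    shape = _shape_for_profile(profile, mapping)
    n_total = int(round(duration_s * fs_hz))
    mean_period = 60.0 / profile.hr_bpm

    # lognormal with exact mean 60/hr and CV hrv_cv
    cv = profile.hrv_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        mu = np.log(mean_period) - 0.5 * sigma * sigma
    pieces = []
    total = 0
    while total < n_total:
        period = (mean_period if cv == 0
                  else float(rng.lognormal(mu, sigma)))
        period = max(period, 0.31)  # keep within the pulse model's domain
        beat = synth_pulse(shape, period, fs_hz).samples
        pieces.append(beat)
        total += beat.size
    x = np.concatenate(pieces)[:n_total]

    t = np.arange(n_total) / fs_hz
    if profile.wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + profile.wander_amp * np.sin(
            2 * np.pi * profile.wander_freq_hz * t + phase)
    if profile.noise_sd > 0:
        x = x + rng.normal(0.0, profile.noise_sd, n_total)
    if profile.artefact_rate_per_min > 0:
        n_art = rng.poisson(profile.artefact_rate_per_min * duration_s / 60.0)
        for _ in range(int(n_art)):
            amp = rng.uniform(1.0, 3.0)
            dur = rng.uniform(0.2, 1.0)
            start = rng.uniform(0.0, max(duration_s - dur, 0.0))
            i0 = int(round(start * fs_hz))
            m = max(int(round(dur * fs_hz)), 2)
            i1 = min(i0 + m, n_total)
            x[i0:i1] += amp * np.sin(np.pi * np.arange(i1 - i0) / m)

    meta = dict(age_years=profile.age_years, hr_bpm=profile.hr_bpm,
                hrv_cv=profile.hrv_cv, activity=profile.activity,
                seed=int(profile.seed))
    return PPGSignal(x, fs_hz, 0.0, meta)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling ranges for a labelled cohort of simulated subjects.

    ``profile_ranges`` maps SubjectProfile field names to (low, high)
    bounds; scalar fields are sampled uniformly within the bounds,
    ``activity`` may instead be a single string.
    """

    n_subjects: int
    group_label: str
    profile_ranges: dict = field(default_factory=dict)
    duration_s: float = 70.0
    fs_hz: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for name, rng_ in self.profile_ranges.items():
            if name == "activity":
                continue
            lo, hi = rng_
            if lo > hi:
                raise ConfigurationError(
                    f"empty range for {name}: ({lo}, {hi})")


def _sample_profile(ranges: dict, seed: int,
                    rng: np.random.Generator) -> SubjectProfile:
    kw = {"seed": seed}
    for name, bounds in ranges.items():
        if name == "activity":
            kw[name] = bounds if isinstance(bounds, str) \
                else str(rng.choice(list(bounds)))
        else:
            lo, hi = bounds
            kw[name] = float(rng.uniform(lo, hi))
    return SubjectProfile(**kw)


def synth_cohort(spec: CohortSpec,
                 mapping: AgeMapping = DEFAULT_AGE_MAPPING) -> list:
    """Simulate a labelled cohort: list of (PPGSignal, group_label).

    Each subject gets an independently sampled profile within the spec's
    ranges and a child seed drawn from the spec seed, so the whole cohort
    is reproducible from ``spec.seed`` alone.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_subjects):
        child_seed = int(rng.integers(0, 2 ** 31 - 1))
        profile = _sample_profile(spec.profile_ranges, child_seed, rng)
        sig = synth_signal(profile, spec.duration_s, spec.fs_hz, mapping)
        sig.meta.update(subject_id=f"{spec.group_label}_{i:03d}",
                        group=spec.group_label)
        out.append((sig, spec.group_label))
    return out


# Default study cohorts: disjoint age ranges map to disjoint diastolic
# morphology, and beat-period variability declines with age (heart-rate
# variability is well known to fall across adulthood), so the young
# cohort is both morphologically distinct and more variable.
_COMMON_RANGES = dict(
    hr_bpm=(60.0, 80.0), activity="seated",
    wander_amp=(0.02, 0.08), wander_freq_hz=(0.15, 0.3),
    noise_sd=(0.005, 0.02), artefact_rate_per_min=(0.0, 0.5),
)


def young_cohort_spec(n: int = 20, seed: int = 0, **kw) -> CohortSpec:
    ranges = dict(_COMMON_RANGES, age_years=(25.0, 35.0),
                  hrv_cv=(0.06, 0.10))
    return CohortSpec(n, "young", ranges, seed=seed, **kw)


def elderly_cohort_spec(n: int = 20, seed: int = 1, **kw) -> CohortSpec:
    ranges = dict(_COMMON_RANGES, age_years=(65.0, 75.0),
                  hrv_cv=(0.02, 0.04))
    return CohortSpec(n, "elderly", ranges, seed=seed, **kw)
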