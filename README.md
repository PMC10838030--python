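# ppgkit

Waveform analysis of the photoplethysmogram (PPG) beyond heart rate and
SpO₂. The PPG pulse wave carries morphological signatures of
cardiovascular state — vascular aging attenuates the diastolic peak and
moves it earlier in the cardiac cycle; physical activity raises
beat-to-beat variability — and `ppgkit` implements two complementary
ways of turning a raw PPG trace into scalar biomarkers:

* **Fiducial point analysis (FPA)** locates landmarks on each pulse and
  its first and second derivatives — onset, early/late systolic peaks
  p1/p2, dicrotic notch, diastolic peak, the maximum-slope point, and
  the second-derivative (SDPPG) waves *a*–*f* — and evaluates a
  catalogue of **48 indices** from their timings and amplitudes. Five
  key indices: **AI** = amp(p2)/amp(p1) (augmentation index), **IPAD**
  = IPA + d/a (inflection-point area ratio plus the normalized d-wave),
  and the SDPPG ratios **c/a**, **d/a**, **e/a**.
* **Symmetric Projection Attractor Reconstruction (SPAR)** delay-embeds
  the whole window x(t) in 3D as (xᵢ, xᵢ₋τ, xᵢ₋₂τ) with τ equal to one
  third of the mean cycle length, and projects onto the plane
  orthogonal to (1,1,1):

      v = (x + y − 2z)/√6,   w = (x − y)/√2.

  Constant offsets — and hence baseline wander — are annihilated by the
  projection; each beat traces one loop of a roughly three-fold
  symmetric attractor. The point cloud is binned to a density map and
  quantified by **49 indices**; the key six measure the central opening
  (`opening_5pct` = r(5%)/r(95%)), rotation angle, arm angular width,
  outer-arm radial bandwidth, three-fold symmetry, and density
  concentration (`arm_density`).
* **Univariate ROC-AUC screening** compares every index between two
  labelled cohorts with the rank-based (Mann–Whitney, midranks for
  ties) AUC; an index is flagged biologically significant when its
  direction-folded AUC exceeds 0.85.
* A **synthetic PPG generator** produces single pulses, continuous
  recordings, and labelled cohorts with the statistical structure the
  analysis assumes — age-mapped morphology, lognormal beat-period
  jitter, baseline wander, sensor noise, and half-sine motion
  artefacts — so the entire pipeline is testable without any recorded
  dataset.

## Worked example

```python
from ppgkit import synthetic, beats, fpa, spar

sig = synthetic.synth_signal(
    synthetic.SubjectProfile(age_years=45, hr_bpm=70, hrv_cv=0.05,
                             noise_sd=0.01, seed=1),
    duration_s=60, fs_hz=500)
onsets, peaks = beats.detect_beats(sig)
_, accepted = beats.pulse_quality(beats.segment_pulses(sig, onsets))
fpa_idx = fpa.fpa_for_pulses(accepted)
cycle = beats.mean_cycle_length(sig)
emb = spar.embed_project(sig, spar.embedding_delay(cycle, sig.fs_hz))
spar_idx = spar.spar_indices(emb)
print(round(fpa_idx["AI"], 3), round(spar_idx["opening_5pct"], 3))
```

The full study-scale analysis lives in `analysis/` as four numbered
drivers. `01_simulate_cohorts.py` writes 20 young (25–35 y) and 20
elderly (65–75 y) recordings; `02_extract_indices.py` reduces each to
97 index rows (48 FPA + 49 SPAR); `03_compare_cohorts.py` screens them,
printing

```
    index_name method  n_a  n_b    auc  auc_folded  significant
            AI    FPA   20   20 1.0000      1.0000         True
          IPAD    FPA   20   20 0.0000      1.0000         True
   arm_density   SPAR   20   20 0.6775      0.6775        False
     bandwidth   SPAR   20   20 0.0350      0.9650         True
           c/a    FPA   20   20 1.0000      1.0000         True
           d/a    FPA   20   20 0.0000      1.0000         True
           e/a    FPA   20   20 1.0000      1.0000         True
  opening_5pct   SPAR   20   20 0.0000      1.0000         True
peak_width_deg   SPAR   20   20 0.0000      1.0000         True
  rotation_deg   SPAR   20   20 0.0000      1.0000         True
      symmetry   SPAR   20   20 0.8625      0.8625         True
```

— ten of the eleven key indices separate the cohorts essentially
perfectly (a raw AUC of 0 folds to 1: the index simply runs in the
other direction). `04_aging_sweep.py` shows the underlying noise-free
trends, e.g. AI rising 0.604 → 1.020 and the diastolic/systolic
amplitude ratio falling 0.448 → 0.143 from age 25 to 75, both strictly
monotone (Spearman |ρ| = 1).

A `ppgkit` console command (`simulate`, `analyze`, `compare`) wraps the
same pipeline for shell use; every run is reproducible from its config
and seed.

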