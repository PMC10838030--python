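"""SPAR embedding geometry, density maps and the 49-index catalogue."""

import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff

from ppgkit import beats, spar
from ppgkit import synthetic as sy
from ppgkit.core import PPGSignal
from ppgkit.errors import BoundsError

from conftest import clean_profile


def ring_embedding(n=100_000, radius=1.0, seed=0):
    th = np.random.default_rng(seed).uniform(0, 2 * np.pi, n)
    pts = radius * np.column_stack([np.cos(th), np.sin(th)])
    return spar.AttractorEmbedding(pts, 10, 100.0, 0.3, normalized=False)


def disc_embedding(n=200_000, seed=0):
    rng = np.random.default_rng(seed)
    r = np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return spar.AttractorEmbedding(pts, 10, 100.0, 0.3, normalized=False)


class TestEmbeddingDelay:
    @pytest.mark.parametrize("cycle,fs,tau", [
        (0.9, 100, 30),
        (1.2, 125, 50),
        (0.8, 500, 133),
    ])
    def test_one_third_rule(self, cycle, fs, tau):
        assert spar.embedding_delay(cycle, fs) == tau

    def test_minimum_delay_is_one(self):
        assert spar.embedding_delay(0.01, 100) == 1

    def test_invalid_cycle(self):
        with pytest.raises(ValueError):
            spar.embedding_delay(0.0, 100)


class TestEmbedProject:
    def test_constant_signal_collapses_to_origin(self):
        sig = PPGSignal(np.full(500, 3.3), 100.0)
        emb = spar.embed_project(sig, 20, normalize=False)
        assert np.abs(emb.points2d).max() < 1e-12

    def test_offset_annihilation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 800)
        a = spar.embed_project(PPGSignal(x, 100.0), 25, normalize=False)
        b = spar.embed_project(PPGSignal(x + 17.0, 100.0), 25,
                               normalize=False)
        assert np.abs(a.points2d - b.points2d).max() < 1e-9

    def test_point_count(self):
        sig = PPGSignal(np.random.default_rng(1).normal(size=600), 100.0)
        emb = spar.embed_project(sig, 40)
        assert emb.n_points == 600 - 2 * 40

    def test_sinusoid_maps_to_circle(self):
        fs, T, A = 120.0, 1.2, 2.5
        t = np.arange(0, 24, 1 / fs)
        sig = PPGSignal(A * np.sin(2 * np.pi * t / T), fs)
        emb = spar.embed_project(sig, int(T * fs / 3), normalize=False)
        radius = np.hypot(emb.v, emb.w)
        expected = A * np.sqrt(1.5)
        assert np.abs(radius - expected).max() / expected < 0.005

    def test_linear_drift_translates_without_distortion(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 700)
        tau = 30
        a = spar.embed_project(PPGSignal(x, 100.0), tau, normalize=False)
        drift = x + 0.8 * np.arange(x.size) / x.size
        b = spar.embed_project(PPGSignal(drift, 100.0), tau, normalize=False)
        delta = b.points2d - a.points2d
        assert np.ptp(delta[:, 0]) < 1e-9 and np.ptp(delta[:, 1]) < 1e-9
        idx = rng.choice(a.n_points, size=200, replace=False)
        da = np.linalg.norm(a.points2d[idx, None] - a.points2d[None, idx],
                            axis=-1)
        db = np.linalg.norm(b.points2d[idx, None] - b.points2d[None, idx],
                            axis=-1)
        assert np.abs(da - db).max() < 1e-9

    def test_three_fold_symmetry_of_periodic_signal(self):
        rng = np.random.default_rng(3)
        period, tau = 150, 50
        cycle = np.cumsum(rng.normal(0, 1, period))
        cycle -= np.linspace(0, cycle[-1], period)
        sig = PPGSignal(np.tile(cycle, 20), 100.0)
        emb = spar.embed_project(sig, tau, normalize=True)
        ang = 2 * np.pi / 3
        rot = emb.points2d @ np.array([[np.cos(ang), np.sin(ang)],
                                       [-np.sin(ang), np.cos(ang)]])
        h = max(directed_hausdorff(emb.points2d, rot)[0],
                directed_hausdorff(rot, emb.points2d)[0])
        cell = 2 * spar.GRID_EXTENT / spar.GRID_BINS
        assert h < cell

    def test_too_short_signal(self):
        with pytest.raises(BoundsError):
            spar.embed_project(PPGSignal(np.zeros(50), 100.0), 25)


class TestDensityMap:
    def test_identical_points_single_bin(self):
        pts = np.zeros((500, 2))
        emb = spar.AttractorEmbedding(pts, 5, 100.0, 0.15, normalized=True)
        dmap = spar.density_map(emb)
        assert dmap.grid.max() == pytest.approx(1.0)
        assert np.count_nonzero(dmap.grid) == 1

    def test_mass_normalized(self):
        emb = disc_embedding(5000)
        dmap = spar.density_map(emb)
        assert dmap.grid.sum() == pytest.approx(1.0, abs=1e-12)
        assert (dmap.grid >= 0).all()

    def test_ring_sector_masses_are_thirds(self):
        idx = spar.spar_indices(ring_embedding())
        for k in (1, 2, 3):
            assert idx[f"sector_mass_{k}"] == pytest.approx(1 / 3, abs=0.02)


class TestSPARIndices:
    def test_registry_contract(self):
        reg = spar.spar_registry()
        names = [d.name for d in reg]
        assert len(reg) == 49
        assert len(set(names)) == 49
        keys = {d.name for d in reg if d.key}
        assert keys == set(spar.SPAR_KEY_INDICES)
        assert len(keys) == 6

    def test_catalogue_complete_and_in_range(self):
        sig = sy.synth_signal(clean_profile(cv=0.05, seed=1), 30, 250)
        cycle = beats.mean_cycle_length(sig)
        emb = spar.embed_project(sig, spar.embedding_delay(cycle, 250))
        idx = spar.spar_indices(emb)
        assert list(idx.values.keys()) == [d.name for d in
                                           spar.spar_registry()]
        assert 0 <= idx["opening_5pct"] <= 1
        assert 0 <= idx["bandwidth"] <= 1
        assert 0 <= idx["symmetry"] <= 1
        assert 0 <= idx["rotation_deg"] < 120

    def test_ring_opening_is_unity(self):
        idx = spar.spar_indices(ring_embedding())
        assert idx["opening_5pct"] == pytest.approx(1.0, abs=0.02)

    def test_uniform_disc_opening(self):
        idx = spar.spar_indices(disc_embedding())
        assert idx["opening_5pct"] == pytest.approx(np.sqrt(0.05 / 0.95),
                                                    abs=0.02)

    def test_three_point_arms_rotation_and_symmetry(self):
        pts = []
        for deg in (10, 130, 250):
            a = np.radians(deg)
            pts.append(np.tile([np.cos(a), np.sin(a)], (100, 1)))
        emb = spar.AttractorEmbedding(np.vstack(pts), 10, 100.0, 0.3,
                                      normalized=False)
        idx = spar.spar_indices(emb)
        assert idx["rotation_deg"] == pytest.approx(10.0, abs=1.0)
        assert idx["symmetry"] == pytest.approx(1.0, abs=0.01)

    def test_aging_opens_attractor_arms(self, aging_sweep):
        """Vascular aging: outer-arm looping recedes monotonically."""
        ages = sorted(aging_sweep)
        bw = [aging_sweep[a][1]["bandwidth"] for a in ages]
        assert np.all(np.diff(bw) < 0)

    def test_variability_diffuses_attractor(self, hrv_sweep):
        """Higher beat-period variability: arms blur and density drops."""
        cvs = sorted(hrv_sweep)
        arm = [hrv_sweep[cv]["arm_density"] for cv in cvs]
        width = [hrv_sweep[cv]["peak_width_deg"] for cv in cvs]
        assert np.all(np.diff(arm) < 0)
        assert np.all(np.diff(width) > 0)


class TestAttractorQuality:
    def test_periodic_signal_scores_high(self):
        sig = sy.synth_signal(clean_profile(hr=60, seed=1), 30, 100)
        assert spar.attractor_quality(sig) > 0.95

    def test_white_noise_scores_low(self):
        scores = [spar.attractor_quality(
            PPGSignal(np.random.default_rng(s).normal(0, 1, 1000), 100.0))
            for s in range(30)]
        assert max(scores) < 0.3

    def test_exercise_with_artefacts_scores_between(self):
        scores = []
        for seed in range(5):
            prof = sy.profile_for_activity("exercise", 45, seed=seed,
                                           noise_sd=0.03, wander_amp=0.1)
            scores.append(spar.attractor_quality(
                sy.synth_signal(prof, 60, 500)))
        assert 0.3 < np.mean(scores) < 0.95
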