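"""Generator contracts: determinism, coverage, Poisson statistics, remapping."""
import numpy as np
import pytest

from gridnet import synthetic
from gridnet.types import GroundTruth, SessionProtocol


class TestTrajectory:
    def test_bounds_and_shape(self, traj20):
        assert len(traj20.t) == 60_000
        assert traj20.x.min() >= 0 and traj20.x.max() <= 1.0
        assert traj20.y.min() >= 0 and traj20.y.max() <= 1.0
        assert np.allclose(np.diff(traj20.t), 0.02)

    def test_deterministic_under_seed(self):
        a = synthetic.generate_trajectory(60, seed=5)
        b = synthetic.generate_trajectory(60, seed=5)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        c = synthetic.generate_trajectory(60, seed=6)
        assert not np.array_equal(a.x, c.x)

    def test_mean_speed_within_ten_percent(self, traj20):
        assert abs(traj20.speed().mean() - 0.15) / 0.15 < 0.10

    def test_near_full_arena_coverage_at_2cm(self, traj20):
        occ, _, _ = np.histogram2d(traj20.x, traj20.y,
                                   bins=[np.arange(0, 1.02, 0.02)] * 2)
        assert (occ > 0).mean() > 0.98

    def test_full_coverage_in_thirty_minutes(self):
        tr = synthetic.generate_trajectory(1800.0, seed=2)
        occ, _, _ = np.histogram2d(tr.x, tr.y,
                                   bins=[np.arange(0, 1.02, 0.02)] * 2)
        assert (occ > 0).all()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            synthetic.generate_trajectory(-1.0)
        with pytest.raises(ValueError):
            synthetic.generate_trajectory(10.0, fs=0.0)


class TestGridSpikes:
    def test_zero_intensity_gives_empty_train(self, traj5):
        gt = GroundTruth(cell_type="grid", peak_rate=0.0, baseline_rate=0.0)
        spk = synthetic.generate_grid_spikes(traj5, gt, seed=1)
        assert len(spk) == 0

    def test_peak_below_baseline_rejected(self, traj5):
        gt = GroundTruth(cell_type="grid", peak_rate=1.0, baseline_rate=5.0)
        with pytest.raises(ValueError):
            synthetic.generate_grid_spikes(traj5, gt, seed=1)

    def test_spike_count_matches_intensity_integral(self, traj20, grid_gt):
        # Poisson property: N within 3 sd of the integral of the rate
        dt = 1.0 / traj20.fs
        lam = grid_gt.baseline_rate + (grid_gt.peak_rate - grid_gt.baseline_rate) \
            * synthetic.grid_intensity(traj20.x, traj20.y, grid_gt.spacing,
                                       grid_gt.orientation, grid_gt.phase)
        expected = lam.sum() * dt
        n = len(synthetic.generate_grid_spikes(traj20, grid_gt, seed=21))
        assert abs(n - expected) < 3 * np.sqrt(expected)

    def test_in_field_out_field_rate_ratio(self, traj20, grid_gt, grid_cell):
        # empirical rates in high- vs low-intensity regions track the rate map
        g = synthetic.grid_intensity(traj20.x, traj20.y, grid_gt.spacing,
                                     grid_gt.orientation, grid_gt.phase)
        sx = np.interp(grid_cell.times, traj20.t, traj20.x)
        sy = np.interp(grid_cell.times, traj20.t, traj20.y)
        gs = synthetic.grid_intensity(sx, sy, grid_gt.spacing,
                                      grid_gt.orientation, grid_gt.phase)
        dt = 1.0 / traj20.fs
        hi, lo = g > 0.6, g < 0.2
        rate_hi = (gs > 0.6).sum() / (hi.sum() * dt)
        rate_lo = (gs < 0.2).sum() / (lo.sum() * dt)
        lam = lambda m: grid_gt.baseline_rate \
            + (grid_gt.peak_rate - grid_gt.baseline_rate) * g[m].mean()
        assert abs(rate_hi - lam(hi)) / lam(hi) < 0.15
        assert abs(rate_lo - lam(lo)) / lam(lo) < 0.15

    def test_burst_injection_adds_short_isis(self, traj5):
        gt = GroundTruth(cell_type="grid", peak_rate=10.0, baseline_rate=1.0,
                         burst_prob=0.3)
        spk = synthetic.generate_spikes(traj5, gt, seed=4)
        isis = np.diff(spk.times)
        assert (isis < 0.006).mean() > 0.05


class TestProtocol:
    @pytest.fixture(scope="class")
    def population(self):
        rng = np.random.default_rng(0)
        return [GroundTruth(cell_type="grid", spacing=0.4,
                            phase=tuple(rng.uniform(0, 0.4, 2)),
                            peak_rate=12.0, baseline_rate=0.3)
                for _ in range(3)]

    def test_bundle_structure(self, population):
        proto = SessionProtocol(durations=(60.0,) * 5)
        b = synthetic.generate_session_protocol(proto, population, seed=1)
        assert [s["label"] for s in b["sessions"]] == list(proto.labels)
        assert all(len(s["spikes"]) == 3 for s in b["sessions"])

    def test_identity_remap_preserves_intensity(self, population):
        # rotation 0 / shift 0: Novel lattice equals the Familiar lattice
        proto = SessionProtocol(durations=(60.0,) * 5, remap_rotation=0.0,
                                remap_shift=(0.0, 0.0))
        b = synthetic.generate_session_protocol(proto, population, seed=1)
        x = np.linspace(0, 1, 40)
        gt = population[0]
        from gridnet.synthetic import grid_intensity
        base = grid_intensity(x, x, gt.spacing, gt.orientation, gt.phase)
        from gridnet.synthetic import _remap
        gt2 = _remap(gt, 0.0, (0.0, 0.0))
        assert np.allclose(
            base, grid_intensity(x, x, gt2.spacing, gt2.orientation, gt2.phase))

    def test_coherent_remap_preserves_pairwise_phase_offsets(self, population):
        # intensity-level invariant: relative phases rotate rigidly
        from gridnet.synthetic import _remap
        rot, shift = 0.7, (0.12, -0.05)
        remapped = [_remap(gt, rot, shift) for gt in population]
        c, s = np.cos(rot), np.sin(rot)
        rotmat = np.array([[c, -s], [s, c]])
        for a, b, ra, rb in zip(population[:-1], population[1:],
                                remapped[:-1], remapped[1:]):
            d0 = np.array(b.phase) - np.array(a.phase)
            d1 = np.array(rb.phase) - np.array(ra.phase)
            assert np.allclose(d1, rotmat @ d0, atol=1e-12)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_session_protocol(SessionProtocol(), [], seed=0)


class TestLfp:
    def test_pure_sine_and_determinism(self, traj5):
        lfp = synthetic.generate_lfp(traj5, f0=8.0, beta_f=0.0, a0=1.0,
                                     beta_a=0.0, noise_sd=0.0, seed=1)
        from scipy.signal import welch
        f, p = welch(lfp.samples, fs=lfp.fs, nperseg=4096)
        assert abs(f[np.argmax(p)] - 8.0) < 0.1
        lfp2 = synthetic.generate_lfp(traj5, f0=8.0, beta_f=0.0, a0=1.0,
                                      beta_a=0.0, noise_sd=0.0, seed=1)
        assert np.array_equal(lfp.samples, lfp2.samples)

    def test_nyquist_guard(self, traj5):
        with pytest.raises(ValueError):
            synthetic.generate_lfp(traj5, f0=8.0, beta_f=0.0, fs=10.0)


class TestWaveforms:
    def test_labels_and_templates(self):
        wfs, labels = synthetic.generate_waveforms(3, 4, noise_sd=0.0, seed=0)
        assert labels == ["narrow"] * 3 + ["broad"] * 4
        assert all(w.shape == (1, 50) for w in wfs)

    def test_amplitude_invariance_of_features(self):
        from gridnet.spike_metrics import waveform_features
        w = synthetic.waveform_template(0.6)
        f1 = waveform_features(w)
        f2 = waveform_features(2.0 * w)
        assert f1.trough_to_peak == pytest.approx(f2.trough_to_peak, abs=1e-9)
        assert f1.half_width == pytest.approx(f2.half_width, abs=1e-9)
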