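"""Firing-field segmentation and the field-based spatial statistics."""
import numpy as np
import pytest

from gridnet import fields, ratemaps
from gridnet.ratemaps import RateMap
from gridnet.types import SpikeTrain, Trajectory
from conftest import hex_bump_lattice


def _ratemap_from_values(values, occupancy=None):
    values = np.asarray(values, dtype=float)
    occ = np.ones_like(values) if occupancy is None else np.asarray(occupancy, float)
    return RateMap(values=values, occupancy=occ, spike_count=values * occ,
                   bin_size=0.02, sigma=0.0, arena_size=values.shape[0] * 0.02)


class TestIdentifyFields:
    def test_single_gaussian_bump_one_field(self):
        n = 30
        X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        bump = 5.0 * np.exp(-((X - 15) ** 2 + (Y - 15) ** 2) / (2 * 3.0 ** 2))
        fm = fields.identify_fields(_ratemap_from_values(bump),
                                    global_field_radius=5.0)
        assert fm.n_fields == 1
        assert fm.labels[15, 15] == 1

    def test_seven_bump_hexagonal_map(self):
        # central bump plus its six lattice neighbours, fully inside the map
        n, spacing, sigma = 48, 14.0, 2.0
        X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        img = np.zeros((n, n))
        centers = [(n / 2, n / 2)]
        for k in range(6):
            a = k * np.pi / 3
            centers.append((n / 2 + spacing * np.cos(a),
                            n / 2 + spacing * np.sin(a)))
        for cx, cy in centers:
            img += np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma ** 2))
        fm = fields.identify_fields(_ratemap_from_values(img),
                                    global_field_radius=0.7 * spacing / 2)
        assert fm.n_fields == 7

    def test_small_bump_excluded_by_area_rule(self):
        m = np.zeros((20, 20))
        m[10, 10] = 5.0
        m[10, 11] = 4.0
        m[11, 10] = 4.0  # 3-bin island, far below 9 bins
        fm = fields.identify_fields(_ratemap_from_values(m),
                                    global_field_radius=3.0)
        assert fm.n_fields == 0

    def test_fields_sorted_by_mean_rate(self):
        n = 40
        X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        weak = 2.0 * np.exp(-((X - 10) ** 2 + (Y - 10) ** 2) / 18.0)
        strong = 8.0 * np.exp(-((X - 30) ** 2 + (Y - 30) ** 2) / 18.0)
        fm = fields.identify_fields(_ratemap_from_values(weak + strong),
                                    global_field_radius=5.0)
        assert fm.n_fields == 2
        rates = [f["mean_rate"] for f in fm.fields]
        assert rates == sorted(rates, reverse=True)
        assert fm.fields[0]["peak"] == (30, 30)

    def test_labels_partition_without_overlap(self, grid_cell, traj20):
        rm = ratemaps.compute_rate_map(grid_cell, traj20)
        ac = ratemaps.compute_autocorrelogram(rm, normalize=True)
        fm = fields.identify_fields(rm, ac)
        assert fm.n_fields >= 1
        # each labelled bin belongs to exactly one field
        total = sum(len(f["bins"]) for f in fm.fields)
        assert total == np.count_nonzero(fm.labels)
        for f in fm.fields:
            assert f["area_bins"] >= 9


class TestInOutRates:
    def test_accounting_sums(self, grid_cell, traj20):
        rm = ratemaps.compute_rate_map(grid_cell, traj20)
        ac = ratemaps.compute_autocorrelogram(rm, normalize=True)
        fm = fields.identify_fields(rm, ac)
        io = fields.in_out_field_rates(grid_cell, traj20, fm)
        assert io.in_field_time + io.out_field_time == \
            pytest.approx(len(traj20.t) / traj20.fs)
        assert io.in_field_spikes + io.out_field_spikes == len(grid_cell)
        assert io.fr_in_field > io.fr_out_field  # tuned cell

    def test_hand_built_field_exact_ratio(self):
        # 4x4 arena of 1 m bins; field = single bin; constant trajectory dwell
        traj = Trajectory(t=np.arange(8) * 0.5, x=[0.5, 1.5, 2.5, 3.5] * 2,
                          y=[0.5] * 8, fs=2.0, arena_size=4.0)
        labels = np.zeros((4, 4), dtype=int)
        labels[1, 0] = 1
        fm = fields.FieldMap(labels=labels, fields=[{"id": 1}])
        spk = SpikeTrain("u", [0.5, 2.5, 0.1], 0.0, 4.0)  # 2 in-field, 1 out
        io = fields.in_out_field_rates(spk, traj, fm, bin_size=1.0)
        assert io.in_field_time == pytest.approx(1.0)  # 2 samples * 0.5 s
        assert io.out_field_time == pytest.approx(3.0)
        assert io.fr_in_field == pytest.approx(2.0)
        assert io.fr_out_field == pytest.approx(1.0 / 3.0)

    def test_homogeneous_cell_equal_rates(self, traj20):
        rng = np.random.default_rng(8)
        spk = SpikeTrain("u", np.sort(rng.uniform(0, 1199, 6000)), 0.0, 1200.0)
        labels = np.zeros((50, 50), dtype=int)
        labels[10:20, 10:20] = 1
        fm = fields.FieldMap(labels=labels, fields=[{"id": 1}])
        io = fields.in_out_field_rates(spk, traj20, fm)
        assert io.fr_in_field == pytest.approx(io.fr_out_field, rel=0.15)


class TestSpecificity:
    def test_equal_rates_give_zero(self):
        io = fields.InOutRates(2.0, 2.0, 10, 10, 20, 20)
        assert fields.spatial_specificity(io) == 0.0

    def test_tenfold_ratio_gives_one(self):
        io = fields.InOutRates(5.0, 0.5, 10, 10, 50, 5)
        assert fields.spatial_specificity(io) == pytest.approx(1.0)

    def test_arithmetic_example(self):
        io = fields.InOutRates(3.0, 0.6, 10, 10, 30, 6)
        assert fields.spatial_specificity(io) == pytest.approx(np.log10(5.0))

    def test_degenerate_rates_warn_with_inf(self):
        with pytest.warns(UserWarning):
            assert fields.spatial_specificity(
                fields.InOutRates(1.0, 0.0, 1, 1, 1, 0)) == np.inf
        with pytest.warns(UserWarning):
            assert fields.spatial_specificity(
                fields.InOutRates(0.0, 1.0, 1, 1, 0, 1)) == -np.inf


class TestSpatialInformation:
    def test_uniform_rate_gives_zero(self):
        rm = _ratemap_from_values(np.full((10, 10), 3.0))
        assert fields.spatial_information(rm) == pytest.approx(0.0)

    def test_two_bin_hand_example_is_one_bit(self):
        rm = _ratemap_from_values(np.array([[2.0], [0.0]]))
        assert fields.spatial_information(rm) == pytest.approx(1.0)

    def test_nonnegative_on_random_maps(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            rm = _ratemap_from_values(rng.uniform(size=(20, 20)),
                                      occupancy=rng.uniform(0.5, 2, (20, 20)))
            assert fields.spatial_information(rm) >= -1e-12

    def test_occupancy_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        v = rng.uniform(size=(15, 15))
        occ = rng.uniform(0.5, 2.0, size=(15, 15))
        a = fields.spatial_information(_ratemap_from_values(v, occ))
        b = fields.spatial_information(_ratemap_from_values(v, 7.3 * occ))
        assert a == pytest.approx(b)

    def test_bits_per_second_variant(self):
        rm = _ratemap_from_values(np.array([[2.0], [0.0]]))
        # mean rate 1 Hz: 0.5 * 2 * log2(2) = 1 bit/s
        assert fields.spatial_information(rm, per_second=True) == pytest.approx(1.0)

    def test_baseline_monotonicity(self, traj20, grid_gt):
        # raising the baseline rate lowers both specificity and information
        from gridnet import synthetic
        import dataclasses
        vals = []
        for base in (0.3, 2.0, 5.0):
            gt = dataclasses.replace(grid_gt, baseline_rate=base)
            spk = synthetic.generate_grid_spikes(traj20, gt, seed=33)
            rm = ratemaps.compute_rate_map(spk, traj20)
            ac = ratemaps.compute_autocorrelogram(rm, normalize=True)
            fm = fields.identify_fields(rm, ac)
            io = fields.in_out_field_rates(spk, traj20, fm)
            vals.append((fields.spatial_specificity(io),
                         fields.spatial_information(rm)))
        specs, infos = zip(*vals)
        assert specs[0] > specs[1] > specs[2]
        assert infos[0] > infos[1] > infos[2]
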