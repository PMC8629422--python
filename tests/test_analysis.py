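import math

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import surgecast as sc
from surgecast.analysis import MigrationMap, _coarsen, fit_piecewise_gain


def unit_map(values, cell=1.0, origin=(0.0, 0.0)):
    return MigrationMap(origin, cell, np.asarray(values, dtype=float))


class TestMigrationMap:
    def test_single_trial_marks_cells_binary(self, trialset_builder):
        path = [(0.5, 0.5), (1.5, 0.5), (1.5, 1.5)]
        ts = trialset_builder([path], plume_config=sc.PlumeConfig(
            field_bounds=(0.0, 4.0, 0.0, 4.0), source_position=(1.0, 1.0)))
        m = sc.migration_map(ts, cell_size=1.0)
        assert set(np.unique(m.values)) <= {0.0, 1.0}
        assert m.values[0, 0] == 1.0 and m.values[1, 0] == 1.0 and m.values[1, 1] == 1.0
        assert m.values.sum() == 3.0

    def test_two_trials_average(self, trialset_builder):
        pc = sc.PlumeConfig(field_bounds=(0.0, 4.0, 0.0, 4.0), source_position=(1, 1))
        ts = trialset_builder([[(0.5, 0.5)], [(0.5, 0.5), (2.5, 2.5)]], plume_config=pc)
        m = sc.migration_map(ts, cell_size=1.0)
        assert m.values[0, 0] == 1.0
        assert m.values[2, 2] == 0.5

    def test_revisits_not_double_counted(self, trialset_builder):
        pc = sc.PlumeConfig(field_bounds=(0.0, 4.0, 0.0, 4.0), source_position=(1, 1))
        ts = trialset_builder([[(0.5, 0.5)] * 10], plume_config=pc)
        m = sc.migration_map(ts, cell_size=1.0)
        assert m.values.max() == 1.0

    def test_values_bounded_and_sum_identity(self, plume_config):
        # simulated batch: P in [0,1]; n * average map = sum of binary maps
        ctrl = sc.MiM2Controller()
        ts = sc.run_batch(plume_config, ctrl, sc.TrialConfig(time_limit=20.0), 4, 0)
        m = sc.migration_map(ts, cell_size=10.0)
        assert (m.values >= 0).all() and (m.values <= 1).all()
        total = np.zeros_like(m.values)
        for tr in ts.trajectories:
            single = sc.migration_map(
                sc.TrialSet([tr], ts.plume_config, ts.trial_config), cell_size=10.0)
            total += single.values
        assert np.allclose(total, m.values * ts.n)

    def test_empty_set_rejected(self, plume_config):
        with pytest.raises(ValueError):
            sc.migration_map(sc.TrialSet([], plume_config, sc.TrialConfig()), 1.0)


class TestEMD:
    def test_identical_maps_zero(self):
        m = unit_map(np.random.default_rng(0).random((5, 5)))
        assert sc.emd(m, m, coarsen_to=None) == pytest.approx(0.0, abs=1e-9)

    def test_two_point_masses_give_distance(self):
        a = np.zeros((6, 6))
        b = np.zeros((6, 6))
        a[0, 0] = 1.0
        b[3, 4] = 1.0
        d = sc.emd(unit_map(a), unit_map(b), coarsen_to=None)
        assert d == pytest.approx(math.hypot(3.0, 4.0), abs=1e-9)

    def test_matches_assignment_oracle_on_random_pairs(self):
        # integral marginals: the transport optimum equals a unit assignment
        rng = np.random.default_rng(42)
        xs = np.arange(4) + 0.5
        pts = np.array([[x, y] for x in xs for y in xs])
        for _ in range(25):
            total = 10
            wa = rng.multinomial(total, np.ones(16) / 16)
            wb = rng.multinomial(total, np.ones(16) / 16)
            d = sc.emd(unit_map(wa.reshape(4, 4) / total),
                       unit_map(wb.reshape(4, 4) / total), coarsen_to=None)
            ua = np.repeat(np.arange(16), wa)
            ub = np.repeat(np.arange(16), wb)
            cost = np.linalg.norm(pts[ua][:, None] - pts[ub][None, :], axis=2)
            r, c = linear_sum_assignment(cost)
            assert d == pytest.approx(cost[r, c].sum() / total, abs=1e-6)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(7)
        maps = [unit_map(rng.random((4, 4))) for _ in range(3)]
        d01 = sc.emd(maps[0], maps[1], None)
        d10 = sc.emd(maps[1], maps[0], None)
        d02 = sc.emd(maps[0], maps[2], None)
        d12 = sc.emd(maps[1], maps[2], None)
        assert d01 == pytest.approx(d10, abs=1e-6)
        assert d02 <= d01 + d12 + 1e-6

    def test_coarsening_block_sums(self):
        v = np.arange(12.0).reshape(4, 3)
        c = _coarsen(v, (2, 3))
        assert c.shape == (2, 3)
        assert c[0, 0] == v[0, 0] + v[1, 0]

    def test_geometry_mismatch_and_zero_mass_rejected(self):
        a = unit_map(np.ones((4, 4)))
        with pytest.raises(ValueError):
            sc.emd(a, unit_map(np.ones((5, 4))))
        with pytest.raises(ValueError):
            sc.emd(a, unit_map(np.zeros((4, 4))))


class TestHeadingHistogram:
    def test_all_upwind_mass_in_zero_bin(self, trialset_builder):
        paths = [[(10.0, 0.0, math.pi)] * 50]
        ts = trialset_builder(paths)
        hh = sc.heading_histogram(ts, n_bins=36)
        zero_bin = np.digitize(0.0, hh.bin_edges) - 1
        assert hh.counts[zero_bin] == 50
        assert hh.counts.sum() == 50

    def test_frame_invariance_under_joint_rotation(self, trialset_builder):
        rng = np.random.default_rng(0)
        headings = rng.uniform(-math.pi, math.pi, 200)
        rot = 1.1
        paths = [[(0.0, 0.0, h) for h in headings]]
        paths_rot = [[(0.0, 0.0, (h + rot + math.pi) % (2 * math.pi) - math.pi)
                      for h in headings]]
        ts = trialset_builder(paths)
        ts_rot = trialset_builder(paths_rot)
        h1 = sc.heading_histogram(ts, 36, wind_direction=(1.0, 0.0))
        h2 = sc.heading_histogram(
            ts_rot, 36, wind_direction=(math.cos(rot), math.sin(rot)))
        assert (h1.counts == h2.counts).all()

    def test_uniform_headings_roughly_uniform(self, trialset_builder):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        headings = rng.uniform(-math.pi, math.pi, 20_000)
        ts = trialset_builder([[(0.0, 0.0, h) for h in headings]])
        hh = sc.heading_histogram(ts, 36)
        chi2, p = sps.chisquare(hh.counts)
        assert p > 0.01

    def test_too_few_bins_rejected(self, trialset_builder):
        ts = trialset_builder([[(0.0, 0.0, 0.0)]])
        with pytest.raises(ValueError):
            sc.heading_histogram(ts, n_bins=3)


class TestMetrics:
    def test_definition(self, trialset_builder):
        # 1 success of 2 at t = 99 * dt; spt = 50 / t
        ts = trialset_builder([[(0.0, 0.0)] * 100, [(5.0, 5.0)] * 100],
                              outcomes=["success", "failure"])
        m = sc.metrics(ts)
        t_succ = 99 * ts.trial_config.dt
        assert m.success_rate == 0.5
        assert m.spt == pytest.approx(50.0 / t_succ)

    def test_no_success_gives_zero_spt(self, trialset_builder):
        ts = trialset_builder([[(0.0, 0.0)] * 3], outcomes=["failure"])
        m = sc.metrics(ts)
        assert m.spt == 0.0 and m.success_rate == 0.0

    def test_all_success_at_common_time(self, trialset_builder):
        ts = trialset_builder([[(0.0, 0.0)] * 101] * 3, outcomes=["success"] * 3)
        m = sc.metrics(ts)
        assert m.spt == pytest.approx(100.0 / (100 * ts.trial_config.dt))


class TestPiecewiseFit:
    def test_recovers_printed_gain_from_noiseless_bins(self):
        f = np.round(np.arange(0.05, 1.2, 0.1), 3)
        table = sc.default_gain_table().v_matched
        y = np.array([table(x) for x in f])
        fit = fit_piecewise_gain(f, y, np.arange(0.45, 0.95, 0.1))
        # candidate grid at 0.45..0.85: 0.65/0.75 both split the data at the
        # true 0.7 boundary, recovering the printed coefficients exactly
        assert fit.a_low == pytest.approx(5.36, abs=1e-9)
        assert fit.b_low == pytest.approx(12.9, abs=1e-9)
        assert fit.a_high == pytest.approx(-11.4, abs=1e-9)
        assert fit.b_high == pytest.approx(24.6, abs=1e-9)
        assert abs(fit.breakpoint - 0.7) <= 0.05
        assert fit.sse == pytest.approx(0.0, abs=1e-18)

    def test_constant_data_gives_zero_slopes(self):
        f = np.linspace(0.0, 1.0, 11)
        fit = fit_piecewise_gain(f, np.full_like(f, 10.0), [0.5])
        assert fit.a_low == pytest.approx(0.0, abs=1e-9)
        assert fit.a_high == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovery_under_noise(self):
        rng = np.random.default_rng(0)
        f = np.round(np.arange(0.05, 1.2, 0.1), 3)
        table = sc.default_gain_table().v_matched
        truth = np.array([table(x) for x in f])
        slopes = []
        for _ in range(500):
            y = truth + rng.normal(0.0, 1.0, truth.shape)
            fit = fit_piecewise_gain(f, y, [0.65])
            slopes.append((fit.a_low, fit.a_high))
        mean_low, mean_high = np.mean(slopes, axis=0)
        assert mean_low == pytest.approx(5.36, rel=0.15)
        assert mean_high == pytest.approx(-11.4, rel=0.15)

    def test_insufficient_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_piecewise_gain([0.1, 0.2, 0.9, 1.0], [1, 2, 3, 4], [0.5])
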