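import numpy as np
import pytest

from fespath.io_formats import CVTrajectory, HillSeries
from fespath.landscape import fes_from_hills, profile_barrier
from fespath.reweight import (unbias_weights, reweight_to_new_cvs, block_error,
                              crossing_count, barrier_time_series)


def flat_traj(n=100, value=0.0):
    return CVTrajectory(times=np.arange(1, n + 1) * 0.05,
                        values=np.full((n, 1), value))


class TestUnbiasWeights:
    def test_zero_hills_uniform(self):
        traj = flat_traj(50)
        w = unbias_weights(traj, HillSeries.empty(1), 298.0)
        np.testing.assert_allclose(w, 1.0 / 50)

    def test_single_late_hill_preserves_early_ratios(self, rng):
        n = 40
        traj = CVTrajectory(times=np.arange(1, n + 1) * 0.05,
                            values=rng.normal(size=(n, 1)))
        hills = HillSeries(times=[1.9], centers=[[0.0]], widths=[[0.25]],
                           heights=[0.5], bias_factor=34.77)
        w = unbias_weights(traj, hills, 298.0)
        early = w[:37]  # frames before the hill at t = 1.9
        np.testing.assert_allclose(early / early[0], 1.0, rtol=1e-12)

    def test_frames_beyond_hill_record_error(self):
        traj = flat_traj(100)
        hills = HillSeries(times=[0.05], centers=[[0.0]], widths=[[0.25]],
                           heights=[0.5])
        with pytest.raises(ValueError, match="outside"):
            unbias_weights(traj, hills, 298.0)

    def test_weights_invariant_to_constant_bias_shift(self, double_well_run):
        """Adding a uniform hill field shifts V by a constant everywhere and
        must leave normalized weights unchanged (checked via wide kernels)."""
        _, traj, hills = double_well_run
        spec = [(-2.0, 2.0, 0.0625)]
        w0 = unbias_weights(traj, hills, 298.0, grid_spec=spec)
        wide = HillSeries(
            times=np.concatenate([[hills.times[0] / 2], hills.times]),
            centers=np.vstack([[[0.0]], hills.centers]),
            widths=np.vstack([[[1e6]], hills.widths]),  # flat over the domain
            heights=np.concatenate([[3.0], hills.heights]),
            bias_factor=hills.bias_factor)
        w1 = unbias_weights(traj, wide, 298.0, grid_spec=spec)
        np.testing.assert_allclose(w1, w0, rtol=1e-6)

    def test_double_well_two_estimators_and_truth(self, double_well_run,
                                                  double_well_weights):
        _, traj, hills = double_well_run
        w = double_well_weights
        rew = reweight_to_new_cvs(w, traj, [(-1.3, 1.3, 0.05)])
        hill_grid = fes_from_hills(hills, [(-1.3, 1.3, 0.05)], time_average=21)
        assert profile_barrier(rew.grid) == pytest.approx(5.0, abs=0.5)
        assert profile_barrier(hill_grid) == pytest.approx(5.0, abs=0.5)
        occupied = np.isfinite(rew.grid.values)
        mean_dev = np.mean(np.abs(rew.grid.values[occupied]
                                  - hill_grid.values[occupied]))
        assert mean_dev <= 0.3

    def test_final_bias_scheme_cross_check(self, double_well_run):
        """The simpler final-bias weights give the same barrier to within the
        sampling tolerance."""
        _, traj, hills = double_well_run
        w = unbias_weights(traj, hills, 298.0, scheme="final")
        rew = reweight_to_new_cvs(w, traj, [(-1.3, 1.3, 0.05)])
        assert profile_barrier(rew.grid) == pytest.approx(5.0, abs=0.7)


class TestReweightToNewCVs:
    def test_uniform_weights_single_bin(self):
        traj = flat_traj(20, value=0.42)
        res = reweight_to_new_cvs(np.full(20, 0.05), traj, [(0.0, 1.0, 0.1)])
        occupied = np.isfinite(res.grid.values)
        assert occupied.sum() == 1
        assert res.grid.values[occupied][0] == 0.0
        assert res.effective_sample_size == pytest.approx(20.0)

    def test_frame_permutation_invariance(self, rng):
        n = 200
        values = rng.normal(size=(n, 1))
        w = rng.uniform(0.1, 1.0, n)
        perm = rng.permutation(n)
        times = np.arange(1, n + 1) * 0.05
        r1 = reweight_to_new_cvs(w, CVTrajectory(times, values), [(-4, 4, 0.5)])
        r2 = reweight_to_new_cvs(w[perm], CVTrajectory(times, values[perm]),
                                 [(-4, 4, 0.5)])
        np.testing.assert_allclose(r1.grid.values, r2.grid.values, rtol=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="weights"):
            reweight_to_new_cvs(np.ones(3), flat_traj(4), [(0, 1, 0.1)])


class TestBlockError:
    def test_constant_series_zero_error(self):
        traj = flat_traj(100, value=1.0)
        res = block_error(np.full(100, 0.01), traj, 10)
        assert res.errors[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_iid_samples_error_flat_in_block_count(self, rng):
        n = 20000
        traj = CVTrajectory(np.arange(1, n + 1) * 0.01,
                            rng.normal(size=(n, 1)))
        res = block_error(np.full(n, 1.0 / n), traj, [50, 100, 200, 400],
                          n_bins=20)
        errs = res.errors[:, 0]
        assert np.all(np.isfinite(errs))
        assert errs.max() / errs.min() < 1.2

    def test_symmetric_halves_agree(self):
        x = np.concatenate([np.linspace(-1, 1, 500), np.linspace(-1, 1, 500)])
        traj = CVTrajectory(np.arange(1, 1001) * 0.01, x[:, None])
        res = block_error(np.full(1000, 1e-3), traj, 2, n_bins=10)
        # both halves trace the same sweep, so block profiles coincide
        assert res.errors[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_more_blocks_than_frames_errors(self):
        with pytest.raises(ValueError, match="blocks"):
            block_error(np.ones(10) / 10, flat_traj(10), 20)


class TestCrossingCount:
    def test_monotone_series_counts_once(self):
        series = np.linspace(-2.0, 2.0, 100)
        assert crossing_count(series, 0.0, hysteresis=0.25) == 1

    def test_series_never_reaching_divide(self):
        assert crossing_count(np.linspace(-2, -1, 50), 0.0) == 0

    def test_triangle_wave_three_penetrations(self):
        # three excursions well past the divide plus one grazing touch
        up = np.linspace(-1, 1, 20)
        wave = np.concatenate([up, up[::-1], up, up[::-1], up,
                               np.linspace(1, 0.1, 5), np.linspace(0.1, 1, 5)])
        assert crossing_count(wave, 0.0, hysteresis=0.25,
                              direction_insensitive=False) == 3

    def test_grazing_recrossings_suppressed(self):
        graze = np.array([-1.0, 0.1, -0.1, 0.1, -1.0, 1.0])
        assert crossing_count(graze, 0.0, hysteresis=0.25) == 1

    def test_invariant_under_affine_rescaling(self, rng):
        series = np.cumsum(rng.normal(size=500)) * 0.1
        base = crossing_count(series, 0.0, hysteresis=0.25)
        scaled = crossing_count(3.0 * series + 2.0, 2.0, hysteresis=0.75)
        assert scaled == base


class TestBarrierTimeSeries:
    GRID = [(-1.3, 1.3, 0.02)]
    R = [(-1.3, -0.5)]
    P = [(0.5, 1.3)]

    def test_final_checkpoint_matches_static_estimate(self, double_well_run):
        _, _, hills = double_well_run
        t_end = hills.times[-1]
        ts = barrier_time_series(hills, [t_end], self.GRID, self.R, self.P)
        from fespath.landscape import find_minima, minimum_energy_path
        grid = fes_from_hills(hills, self.GRID)
        minima = find_minima(grid)
        r = next(m for m in minima if m.location[0] < -0.5)
        p = next(m for m in minima if m.location[0] > 0.5)
        mep = minimum_energy_path(grid, r, p, smooth=False)
        assert ts.activation[0] == pytest.approx(mep.barrier, abs=1e-9)
        assert ts.reaction[0] == pytest.approx(mep.reaction_free_energy, abs=1e-9)

    def test_converged_tail_is_flat(self, double_well_run):
        _, _, hills = double_well_run
        t_end = hills.times[-1]
        ts = barrier_time_series(hills, np.array([0.6, 0.7, 0.8, 0.9, 1.0]) * t_end,
                                 self.GRID, self.R, self.P, time_average=21)
        assert np.ptp(ts.activation) <= 0.3
        assert np.ptp(ts.reaction) <= 0.5
        assert np.all(np.abs(ts.activation - 5.0) < 0.5)

    def test_missing_basin_marks_nan(self, double_well_run):
        _, _, hills = double_well_run
        # before any hill exists the estimate is undefined, not an error
        ts = barrier_time_series(hills, [hills.times[0] / 2, hills.times[-1]],
                                 self.GRID, self.R, self.P)
        assert np.isnan(ts.activation[0])
        assert np.isfinite(ts.activation[1])
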