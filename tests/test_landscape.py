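import numpy as np
import pytest
from scipy import ndimage

from fespath.io_formats import HillSeries
from fespath.landscape import (FESGrid, fes_from_hills, fes_from_grid,
                               find_minima, find_saddles, minimum_energy_path,
                               profile_barrier, _minimax_path)
from fespath.synthetic import double_well_1d


def grid_from_function(fn, axes):
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return FESGrid(axes=axes, values=fn(mesh))


class TestFESFromHills:
    def test_single_hill_far_field_plateau(self):
        hills = HillSeries(times=[0.05], centers=[[0.0]], widths=[[0.25]],
                           heights=[0.5], bias_factor=34.77)
        grid = fes_from_hills(hills, [(-5.0, 5.0, 0.1)])
        far = grid.values[0]       # > 6 sigma from the kernel
        assert far == pytest.approx(34.77 / 33.77 * 0.5, rel=1e-6)
        assert grid.values[50] == pytest.approx(0.0, abs=1e-12)  # well bottom

    def test_infinite_gamma_standard_limit(self):
        hills = HillSeries(times=[0.05], centers=[[0.0]], widths=[[0.25]],
                           heights=[0.5], bias_factor=34.77)
        grid = fes_from_hills(hills, [(-5.0, 5.0, 0.1)], gamma=np.inf)
        assert grid.values[0] == pytest.approx(0.5, rel=1e-6)

    def test_invalid_gamma(self):
        hills = HillSeries(times=[0.05], centers=[[0.0]], widths=[[0.25]],
                           heights=[0.5])
        with pytest.raises(ValueError):
            fes_from_hills(hills, [(-1.0, 1.0, 0.1)], gamma=0.9)

    def test_double_well_run_recovers_barrier(self, double_well_run):
        _, _, hills = double_well_run
        grid = fes_from_hills(hills, [(-1.3, 1.3, 0.05)], time_average=21)
        assert profile_barrier(grid, 0.0) == pytest.approx(5.0, abs=0.5)


class TestFESFromGrid:
    def test_double_well_three_nodes(self):
        grid = fes_from_grid(double_well_1d(5.0, 1.0), [(-1.0, 1.0, 1.0)])
        np.testing.assert_allclose(grid.values, [0.0, 5.0, 0.0], atol=1e-12)

    def test_reference_surface_min_zero_and_spacing(self, reference_grid):
        assert float(reference_grid.values.min()) == 0.0
        assert reference_grid.spacing == pytest.approx((0.02, 0.02))


class TestMinima:
    def test_paraboloid_single_minimum(self):
        axes = [np.linspace(-1, 1, 41), np.linspace(-1, 1, 41)]
        grid = grid_from_function(
            lambda m: m[..., 0] ** 2 + 2 * m[..., 1] ** 2, axes)
        minima = find_minima(grid)
        assert len(minima) == 1
        np.testing.assert_allclose(minima[0].location, [0.0, 0.0], atol=1e-8)
        assert minima[0].free_energy == pytest.approx(0.0, abs=1e-10)

    def test_monotone_plane_has_no_interior_minimum(self):
        axes = [np.linspace(0, 1, 21), np.linspace(0, 1, 21)]
        grid = grid_from_function(lambda m: m[..., 0] + 0.5 * m[..., 1], axes)
        assert find_minima(grid) == []

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            find_minima(FESGrid(axes=[[0.0, 1.0]], values=[0.0, 1.0]))


class TestSaddles:
    def test_hyperbolic_patch_saddle_at_origin(self):
        axes = [np.linspace(-1, 1, 41), np.linspace(-1, 1, 41)]
        grid = grid_from_function(
            lambda m: m[..., 0] ** 2 - m[..., 1] ** 2, axes)
        saddles = find_saddles(grid)
        assert len(saddles) == 1
        np.testing.assert_allclose(saddles[0].location, [0.0, 0.0], atol=1e-8)
        assert tuple(saddles[0].curvature_signs) == (-1, 1)

    def test_paraboloid_has_no_saddle(self):
        axes = [np.linspace(-1, 1, 41), np.linspace(-1, 1, 41)]
        grid = grid_from_function(
            lambda m: m[..., 0] ** 2 + m[..., 1] ** 2, axes)
        assert find_saddles(grid) == []

    def test_one_dimensional_input_rejected(self):
        grid = fes_from_grid(double_well_1d(), [(-1.0, 1.0, 0.1)])
        with pytest.raises(ValueError, match="2D"):
            find_saddles(grid)


class TestMEP:
    def test_same_endpoint_zero_path(self, reference_grid):
        minima = find_minima(reference_grid)
        path = minimum_energy_path(reference_grid, minima[0], minima[0])
        assert path.barrier == 0.0
        assert path.reaction_free_energy == 0.0
        assert len(path.points) == 1

    def test_double_well_path_barrier(self):
        grid = fes_from_grid(double_well_1d(5.0, 1.0), [(-1.5, 1.5, 0.01)])
        minima = find_minima(grid)
        assert len(minima) == 2
        path = minimum_energy_path(grid, minima[0], minima[1])
        assert path.barrier == pytest.approx(5.0, abs=0.02)
        assert path.reaction_free_energy == pytest.approx(0.0, abs=0.02)

    def test_reference_surface_activation_and_reaction(self, reference_grid):
        minima = find_minima(reference_grid)
        reactant = max(minima, key=lambda m: m.free_energy)
        product = min(minima, key=lambda m: m.free_energy)
        path = minimum_energy_path(reference_grid, reactant, product)
        assert path.barrier == pytest.approx(7.1, abs=0.15)
        assert path.reaction_free_energy == pytest.approx(-5.7, abs=0.15)
        # the path maximum coincides with the saddle value
        saddle = find_saddles(reference_grid)[0]
        assert np.max(path.energies) == pytest.approx(saddle.free_energy, abs=0.05)

    def test_barrier_invariant_under_constant_shift(self, reference_grid):
        shifted = FESGrid(axes=reference_grid.axes,
                          values=reference_grid.values + 7.3)
        m0 = find_minima(reference_grid)
        m1 = find_minima(shifted)
        p0 = minimum_energy_path(reference_grid, max(m0, key=lambda m: m.free_energy),
                                 min(m0, key=lambda m: m.free_energy), smooth=False)
        p1 = minimum_energy_path(shifted, max(m1, key=lambda m: m.free_energy),
                                 min(m1, key=lambda m: m.free_energy), smooth=False)
        assert p1.barrier == pytest.approx(p0.barrier, abs=1e-9)
        assert p1.reaction_free_energy == pytest.approx(p0.reaction_free_energy, abs=1e-9)

    def test_saddle_value_direction_independent(self, reference_grid):
        minima = find_minima(reference_grid)
        a, b = minima
        fwd = minimum_energy_path(reference_grid, a, b, smooth=False)
        rev = minimum_energy_path(reference_grid, b, a, smooth=False)
        top_fwd = fwd.barrier + a.free_energy
        top_rev = rev.barrier + b.free_energy
        assert top_fwd == pytest.approx(top_rev, abs=1e-9)

    def test_minimax_path_matches_flood_fill_oracle(self, rng):
        """The minimax path maximum equals the lowest level at which the two
        endpoints connect (checked by brute-force flood fill)."""
        values = ndimage.gaussian_filter(rng.normal(size=(24, 24)), 2.0)
        axes = [np.arange(24) * 0.1, np.arange(24) * 0.1]
        grid = FESGrid(axes=axes, values=values)
        start, goal = (2, 2), (21, 20)
        path = _minimax_path(grid, start, goal)
        cost = max(values[n] for n in path)
        levels = np.unique(values)
        lo, hi = 0, len(levels) - 1
        while lo < hi:
            mid = (lo + hi) // 2
            labels, _ = ndimage.label(
                values <= levels[mid],
                structure=np.ones((3, 3), dtype=int))
            if labels[start] != 0 and labels[start] == labels[goal]:
                hi = mid
            else:
                lo = mid + 1
        assert cost == pytest.approx(levels[lo], abs=1e-12)

    def test_disconnected_regions_error(self):
        values = np.zeros((5, 5))
        values[:, 2] = np.nan
        grid = FESGrid(axes=[np.arange(5.0), np.arange(5.0)], values=values)
        from fespath.landscape import StationaryPoint
        a = StationaryPoint("minimum", [0.0, 0.0], 0.0, node=(0, 0))
        b = StationaryPoint("minimum", [4.0, 4.0], 0.0, node=(4, 4))
        with pytest.raises(ValueError, match="connected"):
            minimum_energy_path(grid, a, b, smooth=False)


class TestSpacingConvergence:
    def test_stationary_points_improve_with_refinement(self):
        # anisotropic two-well surface with analytic minima at (+/-1, 0)
        def fn(m):
            x, y = m[..., 0], m[..., 1]
            return (x ** 2 - 1.0) ** 2 + 2.0 * y ** 2 + 0.3 * x * y

        from scipy import optimize
        truth = optimize.minimize(lambda p: fn(np.asarray(p)[None, :])[0],
                                  [1.0, 0.0], method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12}).x
        errs = []
        for spacing in (0.08, 0.04):
            axes = [np.arange(-1.6, 1.6 + spacing / 2, spacing),
                    np.arange(-0.8, 0.8 + spacing / 2, spacing)]
            grid = grid_from_function(fn, axes)
            minima = find_minima(grid)
            assert len(minima) == 2
            best = min(np.linalg.norm(m.location - truth)
                       for m in minima if m.location[0] > 0)
            errs.append(best)
        assert errs[1] <= errs[0] + 1e-9
        assert errs[1] < 0.01
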