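import numpy as np
import pytest

from neurovol.compressor import TrainConfig
from neurovol.metrics import MetricRecord
from neurovol.tradeoff import (SweepAxes, SweepGrid, TradeoffSpec, load_table_fixture,
                               marginal, objective, run_sweep, tradeoff_point)


def brute_force_tradeoff(grid, spec):
    """Independent oracle: exhaustive scan of the augmented objective with
    the same multiplier-update schedule, written from the math directly."""
    def norm(vals):
        lo, hi = min(vals), max(vals)
        return {v: 0.0 if hi == lo else (v - lo) / (hi - lo) for v in vals}

    nds, nnc, nsn = norm(grid.axes.ds), norm(grid.axes.nc), norm(grid.axes.sn)
    ds_max = spec.ds_max if spec.ds_max is not None else max(grid.axes.ds)
    nc_min = spec.nc_min if spec.nc_min is not None else min(grid.axes.nc)
    sn_min = spec.sn_min if spec.sn_min is not None else min(grid.axes.sn)
    corner = (nds[ds_max], nnc[nc_min], nsn[sn_min])
    alpha = list(spec.alpha)
    incumbent = None
    for _ in range(spec.iterations):
        best_val, best_key = None, None
        for d in grid.axes.ds:
            for n in grid.axes.nc:
                for s in grid.axes.sn:
                    cell = grid.cells[(d, n, s)]
                    c = (nds[d] - corner[0], nnc[n] - corner[1], nsn[s] - corner[2])
                    val = (objective(cell) - sum(a * ci for a, ci in zip(alpha, c))
                           + 0.5 * spec.beta * sum(ci * ci for ci in c))
                    if best_val is None or val < best_val - 1e-15:
                        best_val, best_key = val, (d, n, s)
        incumbent = best_key
        c = (nds[incumbent[0]] - corner[0], nnc[incumbent[1]] - corner[1],
             nsn[incumbent[2]] - corner[2])
        alpha = [a - spec.beta * ci for a, ci in zip(alpha, c)]
    return incumbent


def random_grid(rng, ds=(0.125, 0.25, 0.5), nc=(4, 8, 16), sn=(30, 50, 70)):
    grid = SweepGrid(axes=SweepAxes(ds=list(ds), nc=list(nc), sn=list(sn)))
    for key in grid.keys():
        grid.cells[key] = MetricRecord(
            psnr_db=rng.uniform(25, 50), ssim=rng.uniform(0.6, 1.0),
            bitrate_bpp=0.0, cr_percent=rng.uniform(-40, 99.5), n_params=1000)
    return grid


class TestObjective:
    def test_perfect_corner_is_zero(self):
        cell = MetricRecord(psnr_db=float("inf"), ssim=1.0, bitrate_bpp=0.0,
                            cr_percent=100.0, n_params=0)
        assert objective(cell) == 0.0

    def test_direct_arithmetic(self):
        cell = MetricRecord(psnr_db=40.052, ssim=0.961, bitrate_bpp=0.775,
                            cr_percent=97.578, n_params=6348)
        expected = 1 / 40.052 + (1 - 0.961) + (1 - 0.97578)
        assert objective(cell) == pytest.approx(expected, abs=1e-12)
        assert objective(cell) == pytest.approx(0.088188, abs=1e-5)

    def test_additivity_in_cr_term(self):
        a = MetricRecord(psnr_db=35.0, ssim=0.9, bitrate_bpp=0, cr_percent=90.0,
                         n_params=0)
        b = MetricRecord(psnr_db=35.0, ssim=0.9, bitrate_bpp=0, cr_percent=80.0,
                         n_params=0)
        assert objective(b) - objective(a) == pytest.approx(0.1, abs=1e-12)

    def test_nonpositive_psnr_rejected(self):
        cell = MetricRecord(psnr_db=-1.0, ssim=0.9, bitrate_bpp=0, cr_percent=50,
                            n_params=0)
        with pytest.raises(ValueError):
            objective(cell)


class TestFixture:
    def test_completeness(self):
        grid = load_table_fixture()
        assert len(grid.cells) == 99  # 3 scales x 3 channel counts x 11 widths
        grid.validate_complete()

    def test_known_cell(self):
        cell = load_table_fixture().cells[(0.5, 4, 30)]
        assert cell.cr_percent == 97.578
        assert cell.psnr_db == 33.885
        assert cell.n_params == 6348

    def test_bitrate_cr_identity(self):
        for cell in load_table_fixture().cells.values():
            assert cell.bitrate_bpp == pytest.approx(
                (1 - cell.cr_percent / 100) * 32, abs=2e-3)


class TestMarginals:
    def test_published_summary_column(self):
        """The SN = 30 marginal means reproduce the published summary."""
        grid = load_table_fixture()
        one_minus_cr = marginal(grid, "one_minus_cr", "SN")
        assert one_minus_cr.ticks[0] == 30
        assert one_minus_cr.values[0] == pytest.approx(0.25887, abs=1e-4)
        inv_psnr = marginal(grid, "inv_psnr", "SN")
        assert inv_psnr.values[0] == pytest.approx(0.02694, abs=1e-4)
        one_minus_ssim = marginal(grid, "one_minus_ssim", "SN")
        assert one_minus_ssim.values[0] == pytest.approx(0.09239, abs=1e-4)

    def test_ds_half_slice_mean(self):
        # published under the NC = 4 header, but computed over the DS = 1/2
        # slice (the summary table's first two headers are swapped)
        grid = load_table_fixture()
        curve = marginal(grid, "one_minus_cr", "DS")
        assert curve.ticks[-1] == 0.5
        assert curve.values[-1] == pytest.approx(0.23398, abs=1e-4)

    def test_identical_cells_constant_curve(self, rng):
        grid = random_grid(rng)
        cell = grid.cells[(0.125, 4, 30)]
        for key in grid.keys():
            grid.cells[key] = cell
        for axis in ("DS", "NC", "SN"):
            curve = marginal(grid, "inv_psnr", axis)
            assert np.allclose(curve.values, curve.values[0])

    def test_sum_reduction(self, rng):
        grid = random_grid(rng)
        mean_c = marginal(grid, "one_minus_cr", "NC", reduction="mean")
        sum_c = marginal(grid, "one_minus_cr", "NC", reduction="sum")
        np.testing.assert_allclose(np.array(sum_c.values) / 9, mean_c.values)


class TestTradeoffPoint:
    def test_published_selection(self):
        """On the published sweep the trade-off point is DS=1/2, NC=4, SN=30."""
        point = tradeoff_point(load_table_fixture())
        assert (point.ds, point.nc, point.sn) == (0.5, 4, 30)

    def test_single_cell_grid(self, rng):
        grid = random_grid(rng, ds=(0.5,), nc=(4,), sn=(30,))
        point = tradeoff_point(grid)
        assert (point.ds, point.nc, point.sn) == (0.5, 4, 30)

    def test_matches_exhaustive_oracle_on_random_grids(self):
        rng = np.random.default_rng(77)
        spec = TradeoffSpec()
        for _ in range(100):
            grid = random_grid(rng)
            point = tradeoff_point(grid, spec)
            assert (point.ds, point.nc, point.sn) == brute_force_tradeoff(grid, spec)

    def test_unconstrained_limit_is_plain_argmin(self, rng):
        grid = random_grid(rng)
        spec = TradeoffSpec(alpha=(0, 0, 0), beta=1e-12, iterations=1)
        point = tradeoff_point(grid, spec)
        best = min(grid.keys(), key=lambda k: objective(grid.cells[k]))
        assert (point.ds, point.nc, point.sn) == best

    def test_incomplete_grid_rejected(self, rng):
        grid = random_grid(rng)
        del grid.cells[(0.25, 8, 50)]
        with pytest.raises(ValueError, match="missing"):
            tradeoff_point(grid)

    def test_corner_off_axis_rejected(self, rng):
        grid = random_grid(rng)
        with pytest.raises(ValueError, match="ds_max"):
            tradeoff_point(grid, TradeoffSpec(ds_max=0.3))


class TestRunSweep:
    def test_single_cell(self, smooth_patch_16):
        axes = SweepAxes(ds=[0.5], nc=[4], sn=[20])
        grid = run_sweep(smooth_patch_16, axes, TrainConfig(epochs=3, seed=0))
        assert list(grid.cells) == [(0.5, 4, 20)]
        rec = grid.cells[(0.5, 4, 20)]
        assert np.isfinite(rec.psnr_db) and rec.n_params > 0

    def test_smoke_grid_and_cache(self, smooth_patch_16, tmp_path, monkeypatch):
        axes = SweepAxes(ds=[0.25, 0.5], nc=[4], sn=[10, 20])
        tc = TrainConfig(epochs=3, seed=0)
        grid = run_sweep(smooth_patch_16, axes, tc, cache_dir=tmp_path)
        assert len(grid.cells) == 4
        for rec in grid.cells.values():
            assert np.isfinite(rec.psnr_db) and np.isfinite(rec.ssim)
            assert rec.cr_percent == pytest.approx(
                (1 - rec.n_params / 16 ** 3) * 100)

        import neurovol.compressor as comp
        def boom(*a, **k):
            raise AssertionError("cache miss: retraining happened")
        monkeypatch.setattr(comp, "train_end_to_end", boom)
        again = run_sweep(smooth_patch_16, axes, tc, cache_dir=tmp_path)
        assert {k: v.psnr_db for k, v in again.cells.items()} == \
               {k: v.psnr_db for k, v in grid.cells.items()}


def test_sweep_grid_json_round_trip(rng, tmp_path):
    grid = random_grid(rng)
    path = tmp_path / "grid.json"
    grid.to_json(path)
    back = SweepGrid.from_json(path)
    assert back.axes == grid.axes
    for key in grid.keys():
        assert back.cells[key] == grid.cells[key]
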