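"""Quantile-mapping bias correction and thin-plate-spline spreading."""

import numpy as np
import pandas as pd
import pytest

from lfmckit import qmcorrect, synthetic
from lfmckit.grids import semimonthly_steps


@pytest.fixture(scope="module")
def steps():
    return semimonthly_steps("2001-01-01", "2009-12-31")


def seasonal_series(steps, seed, mean=110.0, amp=50.0, noise=8.0):
    rng = np.random.default_rng(seed)
    doy = steps.dayofyear.to_numpy(float)
    return pd.Series(
        mean + amp * np.cos(2 * np.pi * (doy - 90) / 365.25) + rng.normal(0, noise, len(steps)),
        index=steps,
    )


class TestAlign:
    def test_obs_on_step_assigned_unchanged(self, steps):
        obs = pd.DataFrame({"date": [steps[4]], "lfmc_percent": [123.0]})
        out = qmcorrect.align_obs_semimonthly(obs, steps, min_obs=1)
        assert out.loc[steps[4]] == pytest.approx(123.0)

    def test_same_step_obs_averaged(self, steps):
        obs = pd.DataFrame(
            {"date": [steps[4], steps[4] + pd.Timedelta(days=2)],
             "lfmc_percent": [100.0, 110.0]}
        )
        out = qmcorrect.align_obs_semimonthly(obs, steps, min_obs=1)
        assert out.loc[steps[4]] == pytest.approx(105.0)

    def test_three_step_gap_left_missing(self, steps):
        dates = list(steps[:6]) + list(steps[9:14])  # steps 6,7,8 missing
        obs = pd.DataFrame({"date": dates, "lfmc_percent": 100.0})
        out = qmcorrect.align_obs_semimonthly(obs, steps[:14], min_obs=1)
        assert out.iloc[6:9].isna().all()

    def test_two_step_gap_quadratic_fill(self, steps):
        t = (steps[:16] - steps[0]).days.to_numpy(float)
        vals = 100 + 0.2 * t + 0.002 * t**2
        keep = [i for i in range(16) if i not in (7, 8)]
        obs = pd.DataFrame({"date": steps[keep], "lfmc_percent": vals[keep]})
        out = qmcorrect.align_obs_semimonthly(obs, steps[:16], min_obs=1)
        np.testing.assert_allclose(out.iloc[[7, 8]], vals[[7, 8]], atol=1e-6)

    def test_too_few_obs_skipped(self, steps):
        obs = pd.DataFrame({"date": steps[:3], "lfmc_percent": 100.0})
        assert qmcorrect.align_obs_semimonthly(obs, steps, min_obs=8) is None


class TestQuantileTable:
    def test_identity_series_zero_corrections(self, steps):
        s = seasonal_series(steps, 1)
        table = qmcorrect.site_quantile_corrections(s, s, Q=30)
        np.testing.assert_allclose(table.corrections, 0.0, atol=1e-12)

    def test_constant_offset_recovered(self, steps):
        obs = seasonal_series(steps, 2)
        model = obs + 15.0
        table = qmcorrect.site_quantile_corrections(obs, model, Q=30)
        np.testing.assert_allclose(table.corrections, -15.0, atol=1e-9)

    def test_scaled_model_matches_empirical_quantile_oracle(self, steps):
        obs = seasonal_series(steps, 3)
        model = 1.2 * obs
        table = qmcorrect.site_quantile_corrections(obs, model, Q=30)
        levels = np.linspace(0, 1, 30)
        o = obs.to_numpy()
        want = np.quantile(o, levels) - np.quantile(1.2 * o, levels)
        np.testing.assert_allclose(table.corrections, want, atol=1e-9)

    def test_too_few_pairs_skipped(self, steps):
        s = seasonal_series(steps, 4).iloc[:10]
        assert qmcorrect.site_quantile_corrections(s, s, Q=30) is None

    def test_constant_model_single_bin(self, steps):
        obs = seasonal_series(steps, 5)
        model = pd.Series(100.0, index=steps)
        table = qmcorrect.site_quantile_corrections(obs, model, Q=30)
        assert len(table.corrections) == 1
        corrected = table.apply(np.array([100.0]))
        assert corrected[0] == pytest.approx(np.median(obs))


class TestApply:
    def test_identity_table_nodes_unchanged(self, steps):
        s = seasonal_series(steps, 6)
        table = qmcorrect.site_quantile_corrections(s, s, Q=30)
        np.testing.assert_allclose(table.apply(table.model_q), table.model_q, atol=1e-9)

    def test_offset_table_everywhere(self, steps):
        obs = seasonal_series(steps, 7)
        table = qmcorrect.site_quantile_corrections(obs, obs + 15.0, Q=30)
        vals = np.linspace(obs.min() + 15, obs.max() + 15, 50)
        np.testing.assert_allclose(table.apply(vals), vals - 15.0, atol=1e-9)

    def test_out_of_range_clamps_to_extreme_bins(self, steps):
        obs = seasonal_series(steps, 8)
        table = qmcorrect.site_quantile_corrections(obs, obs + 15.0, Q=30)
        below = table.model_q[0] - 100.0
        above = table.model_q[-1] + 100.0
        assert table.apply([below])[0] == pytest.approx(below + table.corrections[0])
        assert table.apply([above])[0] == pytest.approx(above + table.corrections[-1])

    def test_corrected_quantiles_match_obs_within_bin_width(self, steps):
        """The whole point of QM: after correction the corrected model's
        quantiles line up with the observation quantiles."""
        obs = seasonal_series(steps, 9)
        model = 1.25 * obs - 20.0
        table = qmcorrect.site_quantile_corrections(obs, model, Q=30)
        corrected = table.apply(model.to_numpy())
        levels = table.levels
        bin_width = np.diff(np.quantile(obs, levels)).max()
        got = np.quantile(corrected, levels)
        want = np.quantile(obs.to_numpy(), levels)
        assert np.max(np.abs(got - want)) <= bin_width


class TestChooseQ:
    def _pairs(self, steps, bias_fn, n_sites=6):
        pairs = {}
        for k in range(n_sites):
            obs = seasonal_series(steps, 20 + k)
            model = obs + bias_fn(obs, k)
            pairs[f"s{k}"] = (obs, model)
        return pairs

    def test_single_candidate(self, steps):
        pairs = self._pairs(steps, lambda o, k: 10.0)
        Q, _ = qmcorrect.choose_num_quantiles(pairs, candidates=[30])
        assert Q == 30

    def test_constant_bias_ties_give_smallest_q(self, steps):
        pairs = self._pairs(steps, lambda o, k: 5.0 + 2.0 * k)
        Q, scan = qmcorrect.choose_num_quantiles(pairs)
        # constant offsets are corrected exactly at every Q -> tie at ~0
        assert np.allclose(scan["mean_abs_mbe"], scan["mean_abs_mbe"].iloc[0], atol=1e-9)
        assert Q == 10

    def test_selected_q_minimizes_exhaustive_scan(self, steps):
        rng = np.random.default_rng(0)
        # tail-heavy quantile-dependent bias
        def bias(o, k):
            q = o.rank(pct=True).to_numpy()
            return 25.0 * (q - 0.5) ** 3 * 8 + rng.normal(0, 2, len(o))

        pairs = self._pairs(steps, bias)
        Q, scan = qmcorrect.choose_num_quantiles(pairs)
        best = scan.loc[scan["mean_abs_mbe"].idxmin(), "Q"]
        assert Q == best
        assert (scan.loc[scan["Q"] == Q, "mean_abs_mbe"].iloc[0]
                <= scan["mean_abs_mbe"].min() + 1e-12)


class TestInterpolation:
    def test_constant_corrections_reproduced(self, grid):
        sites = synthetic.make_sites(grid, 8, seed=3)
        coords = np.array([[s.lat, s.lon, s.elev] for s in sites])
        field = qmcorrect.interpolate_corrections(
            np.full(8, 4.2), coords, grid, smoothing=0.01
        )
        np.testing.assert_allclose(field[grid.land_mask], 4.2, atol=1e-6)

    def test_zero_smoothing_honors_site_values(self, grid):
        sites = synthetic.make_sites(grid, 6, seed=4)
        coords = np.array([[s.lat, s.lon, s.elev] for s in sites])
        rng = np.random.default_rng(5)
        corr = rng.uniform(-10, 10, 6)
        field = qmcorrect.interpolate_corrections(corr, coords, grid, smoothing=0.0)
        for (lat, lon, _), c in zip(coords, corr):
            i, j = grid.cell_index(lat, lon)
            assert field[i, j] == pytest.approx(c, abs=1e-6)

    def test_elevation_gradient_monotone(self, grid):
        """Two site groups at low/high elevation with corrections -10/+10:
        the fitted field increases with elevation along the gradient."""
        lats = grid.lats[[2, 3, 2, 3]]
        lons = grid.lons[[2, 2, 3, 3]]
        elevs = [100.0, 120.0, 1500.0, 1520.0]
        corr = np.array([-10.0, -10.0, 10.0, 10.0])
        coords = np.column_stack([lats, lons, elevs])
        rbf_field = qmcorrect.interpolate_corrections(corr, coords, grid, smoothing=0.0)
        # evaluate along an elevation transect at fixed lat/lon span
        land = np.argwhere(grid.land_mask)
        elev = grid.elevation[grid.land_mask]
        vals = rbf_field[grid.land_mask]
        lo = vals[elev < 200].mean()
        hi = vals[elev > 1200].mean() if (elev > 1200).any() else vals[elev > 800].mean()
        assert lo < hi

    def test_few_sites_fall_back_to_mean(self, grid):
        coords = np.array([[grid.lats[2], grid.lons[2], 100.0]])
        field = qmcorrect.interpolate_corrections(np.array([6.0]), coords, grid)
        np.testing.assert_allclose(field[grid.land_mask], 6.0)


class TestBiasCorrectCube:
    def _cube(self, grid, steps, value=100.0):
        import xarray as xr

        return xr.DataArray(
            np.full((len(steps), *grid.shape), value),
            dims=("time", "lat", "lon"),
            coords={"time": steps[: len(steps)], "lat": grid.lats, "lon": grid.lons},
            name="lfmc",
        )

    def test_zero_correction_identity(self, grid, steps):
        raw = self._cube(grid, steps[:10])
        corr = raw.copy(data=np.zeros_like(raw.values))
        out = qmcorrect.bias_correct_cube(raw, corr)
        np.testing.assert_array_equal(out.values, raw.values)

    def test_difference_equals_correction(self, grid, steps, rng):
        raw = self._cube(grid, steps[:10])
        corr = raw.copy(data=rng.normal(0, 5, raw.shape))
        out = qmcorrect.bias_correct_cube(raw, corr)
        np.testing.assert_allclose(out.values - raw.values, corr.values, atol=1e-12)

    def test_grid_mismatch_rejected(self, grid, steps):
        raw = self._cube(grid, steps[:10])
        corr = self._cube(grid, steps[:8])
        with pytest.raises(ValueError):
            qmcorrect.bias_correct_cube(raw, corr)


def test_planted_constant_bias_removed(steps):
    """Planted per-site biases ~ U(-20, 20) shrink to near zero MBE after
    per-site quantile mapping."""
    rng = np.random.default_rng(11)
    for k in range(6):
        bias = float(rng.uniform(-20, 20))
        obs = seasonal_series(steps, 40 + k)
        model = obs + bias  # model is biased relative to obs
        table = qmcorrect.site_quantile_corrections(obs, model, Q=30)
        corrected = table.apply(model.to_numpy())
        pre = abs(float(np.mean(model - obs)))
        post = abs(float(np.mean(corrected - obs.to_numpy())))
        assert post <= 0.1 * pre + 1.0
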