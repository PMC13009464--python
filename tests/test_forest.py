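"""Forest modeling: tuning, cross-validation, gridded prediction, intervals."""

import numpy as np
import pandas as pd
import pytest

from lfmckit import forest, synthetic
from lfmckit.features import DEFAULT_PREDICTORS
from lfmckit.grids import semimonthly_steps


from tests_support import make_gfun_rows


def make_training_rows(n, seed, n_sites=8, noise_sd=10.0):
    """Rows drawn from the planted generating function g() plus noise."""
    return make_gfun_rows(n, seed, noise_sd=noise_sd, n_sites=n_sites)


@pytest.fixture(scope="module")
def training_rows():
    return make_training_rows(800, seed=5)


@pytest.fixture(scope="module")
def small_hp():
    return forest.Hyperparams(n_trees=100, max_depth=20, max_features=3, bootstrap=True)


@pytest.fixture(scope="module")
def fitted(training_rows, small_hp):
    return forest.fit(training_rows, small_hp, seed=3)


class TestTune:
    def test_single_combination_returned(self, training_rows):
        grid = {k: [v] for k, v in
                dict(n_trees=50, min_samples_split=2, min_samples_leaf=1,
                     max_depth=10, max_features=3, bootstrap=True).items()}
        hp, scored = forest.tune(training_rows, grid, n_iter=5, seed=1)
        assert hp == forest.Hyperparams(50, 2, 1, 10, 3, True)
        assert len(scored) == 1

    def test_seeded_determinism(self, training_rows):
        grid = {"n_trees": [50, 100], "min_samples_split": [2, 5],
                "min_samples_leaf": [1, 2], "max_depth": [10, 20],
                "max_features": [3], "bootstrap": [True, False]}
        hp1, _ = forest.tune(training_rows, grid, n_iter=4, seed=9)
        hp2, _ = forest.tune(training_rows, grid, n_iter=4, seed=9)
        assert hp1 == hp2

    def test_selection_beats_median(self, training_rows):
        grid = {"n_trees": [10, 100], "min_samples_split": [2, 20],
                "min_samples_leaf": [1, 10], "max_depth": [3, 20],
                "max_features": [2, 3], "bootstrap": [True, False]}
        hp, scored = forest.tune(training_rows, grid, n_iter=6, seed=2)
        assert scored["cv_r2"].iloc[0] >= scored["cv_r2"].median()

    def test_empty_grid_rejected(self, training_rows):
        with pytest.raises(ValueError):
            forest.tune(training_rows, {"n_trees": []})


class TestCrossValidate:
    def test_by_site_one_fold_per_site(self, small_hp):
        rows = make_training_rows(200, seed=6, n_sites=3)
        rep = forest.cross_validate(rows, small_hp, mode="by_site", seed=1)
        assert len(rep.folds) == 3
        assert set(rep.folds["fold"]) == set(rows["site_id"].unique())

    def test_pooled_folds_partition_rows(self, training_rows, small_hp):
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=5, shuffle=True, random_state=1)
        seen = np.concatenate([te for _, te in splitter.split(training_rows)])
        assert sorted(seen) == list(range(len(training_rows)))
        rep = forest.cross_validate(training_rows, small_hp, mode="pooled", seed=1)
        assert rep.folds["n"].sum() == len(training_rows)

    def test_report_deterministic(self, training_rows, small_hp):
        r1 = forest.cross_validate(training_rows, small_hp, mode="pooled", seed=4)
        r2 = forest.cross_validate(training_rows, small_hp, mode="pooled", seed=4)
        pd.testing.assert_frame_equal(r1.folds, r2.folds)

    def test_single_site_by_site_rejected(self, small_hp):
        rows = make_training_rows(100, seed=6, n_sites=1)
        with pytest.raises(ValueError):
            forest.cross_validate(rows, small_hp, mode="by_site")


class TestFit:
    def test_same_seed_identical_predictions(self, training_rows, small_hp):
        m1 = forest.fit(training_rows, small_hp, seed=3)
        m2 = forest.fit(training_rows, small_hp, seed=3)
        test = make_training_rows(50, seed=8)
        np.testing.assert_array_equal(m1.predict(test), m2.predict(test))

    def test_in_sample_no_worse_than_held_out(self, fitted, training_rows):
        held = make_training_rows(400, seed=9)
        in_mae = np.mean(np.abs(fitted.predict(training_rows)
                                - training_rows["lfmc_percent"]))
        out_mae = np.mean(np.abs(fitted.predict(held) - held["lfmc_percent"]))
        assert in_mae <= out_mae

    def test_more_trees_help(self, training_rows):
        held = make_training_rows(400, seed=10)
        maes = {}
        for n in (1, 400):
            hp = forest.Hyperparams(n_trees=n, max_depth=30, max_features=3, bootstrap=True)
            m = forest.fit(training_rows, hp, seed=1)
            maes[n] = np.mean(np.abs(m.predict(held) - held["lfmc_percent"]))
        assert maes[400] <= maes[1]

    def test_predictions_bounded_by_training_range(self, fitted):
        extreme = make_training_rows(200, seed=11)
        extreme[DEFAULT_PREDICTORS] *= 3.0  # far outside training support
        pred = fitted.predict(extreme)
        lo, hi = fitted.training_range
        assert pred.min() >= lo - 1e-9 and pred.max() <= hi + 1e-9

    def test_averaging_flattens_extremes(self, fitted):
        """Predicted-vs-observed OLS slope < 1: forests over-predict low
        values and under-predict high values."""
        held = make_training_rows(600, seed=12)
        pred = fitted.predict(held)
        slope = np.polyfit(held["lfmc_percent"], pred, 1)[0]
        assert slope < 1.0

    def test_nonfinite_rows_rejected(self, training_rows, small_hp):
        bad = training_rows.copy()
        bad.loc[bad.index[3], "P90"] = np.nan
        with pytest.raises(ValueError):
            forest.fit(bad, small_hp, seed=1)

    def test_bundle_roundtrip(self, tmp_path, fitted):
        p = tmp_path / "model.joblib"
        forest.save_model(fitted, p)
        back = forest.load_model(p)
        test = make_training_rows(30, seed=13)
        np.testing.assert_array_equal(fitted.predict(test), back.predict(test))
        assert back.hyperparams == fitted.hyperparams
        assert back.fingerprint == fitted.fingerprint


class TestIntervals:
    def test_pi_is_mean_plus_minus_196_sigma(self, fitted):
        rows = make_training_rows(100, seed=14)
        mean, sd = fitted.predict_with_sigma(rows)
        np.testing.assert_allclose(mean - 1.96 * sd, mean - forest.Z95 * sd)
        # sigma = 5 -> half-width 9.8
        assert forest.Z95 * 5.0 == pytest.approx(9.8)

    def test_agreeing_trees_zero_width(self, training_rows):
        # a single tree trivially agrees with itself
        hp = forest.Hyperparams(n_trees=1, max_depth=30, max_features=9, bootstrap=False)
        m = forest.fit(training_rows, hp, seed=1)
        _, sd = m.predict_with_sigma(training_rows.head(20))
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_coverage_monotone_in_width(self, fitted):
        held = make_training_rows(400, seed=15)
        base = forest.interval_coverage(fitted, held)
        wide = forest.interval_coverage(fitted, held, width_factor=10.0)
        assert wide >= base
        assert 0.0 <= base <= 1.0

    def test_zero_width_zero_coverage_on_noisy_obs(self, training_rows):
        hp = forest.Hyperparams(n_trees=1, max_depth=30, max_features=9, bootstrap=False)
        m = forest.fit(training_rows, hp, seed=1)
        held = make_training_rows(300, seed=16, noise_sd=30.0)
        assert forest.interval_coverage(m, held) <= 0.05


class TestSpatialGapFill:
    def test_planar_hole_restored_exactly(self):
        mask = np.ones((10, 10), dtype=bool)
        ii, jj = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        plane = 2.0 + 0.5 * ii - 0.25 * jj
        holed = plane.copy()
        holed[4:6, 4:6] = np.nan
        out = forest.fill_spatial_gaps(holed, mask)
        np.testing.assert_allclose(out, plane, atol=1e-10)

    def test_single_hole_in_constant_field(self):
        mask = np.ones((6, 6), dtype=bool)
        field = np.full((6, 6), 7.0)
        field[3, 3] = np.nan
        out = forest.fill_spatial_gaps(field, mask)
        assert out[3, 3] == pytest.approx(7.0)

    def test_no_gaps_identity(self):
        mask = np.ones((5, 5), dtype=bool)
        field = np.arange(25, dtype=float).reshape(5, 5)
        np.testing.assert_array_equal(forest.fill_spatial_gaps(field, mask), field)

    def test_sea_cells_untouched(self):
        mask = np.ones((6, 6), dtype=bool)
        mask[:, 0] = False
        field = np.full((6, 6), 3.0)
        field[:, 0] = np.nan
        field[2, 2] = np.nan
        out = forest.fill_spatial_gaps(field, mask)
        assert np.isnan(out[:, 0]).all()
        assert out[2, 2] == pytest.approx(3.0)


class TestPredictGrid:
    def test_cube_contract(self, grid, forcing, predictor_cube):
        import xarray as xr

        steps = semimonthly_steps("2001-08-01", "2002-11-30")
        rows = make_training_rows(300, seed=17)
        hp = forest.Hyperparams(n_trees=50, max_depth=20, max_features=3, bootstrap=True)
        model = forest.fit(rows, hp, seed=2)
        nirv = xr.DataArray(
            np.full((len(steps), *grid.shape), 0.25),
            dims=("time", "lat", "lon"),
            coords={"time": steps, "lat": grid.lats, "lon": grid.lons},
        )
        cube = forest.predict_grid(model, predictor_cube, nirv, grid, steps)
        assert list(cube["time"].values) == list(steps.values)
        days = pd.DatetimeIndex(cube["time"].values).day
        assert set(days) <= {1, 15}
        land = grid.land_mask
        assert np.isfinite(cube["lfmc"].values[:, land]).all()
        assert np.isnan(cube["lfmc"].values[:, ~land]).all()
        np.testing.assert_allclose(
            cube["pi_high"].values[:, land] - cube["lfmc"].values[:, land],
            1.96 * cube["sigma"].values[:, land],
            atol=1e-9,
        )

    def test_missing_layer_named(self, grid, predictor_cube):
        import xarray as xr

        steps = semimonthly_steps("2001-08-01", "2001-12-31")
        rows = make_training_rows(200, seed=18)
        hp = forest.Hyperparams(n_trees=20, max_depth=10, max_features=3, bootstrap=True)
        model = forest.fit(rows, hp, seed=2)
        nirv = xr.DataArray(
            np.full((len(steps), *grid.shape), 0.25),
            dims=("time", "lat", "lon"),
            coords={"time": steps, "lat": grid.lats, "lon": grid.lons},
        )
        with pytest.raises(ValueError, match="P90"):
            forest.predict_grid(model, predictor_cube.drop_vars("P90"), nirv, grid, steps)
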