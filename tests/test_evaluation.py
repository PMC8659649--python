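import numpy as np
import pytest

from tsetse_sdm import (
    SpeciesObservation,
    auc,
    fit_ensemble,
    sampling_effort_kernel,
    split_holdout,
    summarize_timeseries,
    threshold_area,
    validate_holdout,
)
from tsetse_sdm.design import observations_from_traps, thin_per_pixel
from tsetse_sdm.errors import ConfigError, DataError
from tsetse_sdm.roc import auc_value


def brute_force_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]).auc == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 4, [0.5] * 6).auc == 0.5

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            pos = rng.uniform(size=30)
            neg = rng.uniform(size=30)
            # introduce ties sometimes
            if rng.uniform() < 0.5:
                pos = np.round(pos, 1)
                neg = np.round(neg, 1)
            assert auc_value(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_curve_endpoints_and_monotone(self, rng):
        res = auc(rng.uniform(size=20), rng.uniform(size=25))
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0
        assert np.all(np.diff(res.fpr) >= 0)
        assert np.all(np.diff(res.tpr) >= 0)

    def test_monotone_transform_invariance(self, rng):
        pos, neg = rng.normal(size=15), rng.normal(size=15)
        assert auc_value(pos, neg) == pytest.approx(
            auc_value(np.exp(pos), np.exp(neg))
        )

    def test_empty_class_rejected(self):
        with pytest.raises(DataError):
            auc([], [0.1])


class TestThresholdArea:
    def test_all_above(self):
        grid = np.ones((10, 10))
        assert threshold_area(grid, 0.5, cell_area_km2=0.25) == 25.0

    def test_strict_inequality_at_boundary(self):
        grid = np.full((5, 5), 0.5)
        assert threshold_area(grid, 0.5, cell_area_km2=0.25) == 0.0

    def test_matches_direct_count(self, rng):
        grid = rng.uniform(size=(20, 20))
        expected = sum(1 for v in grid.ravel() if v > 0.3) * 0.25
        assert threshold_area(grid, 0.3, 0.25) == pytest.approx(expected)

    def test_monotone_nonincreasing_in_threshold(self, rng):
        grid = rng.uniform(size=(15, 15))
        areas = [threshold_area(grid, t, 0.25) for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_region_mask_and_nan(self, rng):
        grid = np.ones((4, 4))
        grid[0, 0] = np.nan
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2] = True
        # 8 cells in the region, one NaN -> 7 count
        assert threshold_area(grid, 0.5, 1.0, region_mask=mask) == 7.0


class TestSummarizeTimeseries:
    def test_constant_series(self):
        series = np.full((5, 2, 2), 5.0)
        out = summarize_timeseries(series)
        np.testing.assert_allclose(out["mean"], 5.0)
        np.testing.assert_allclose(out["range"], 0.0)

    def test_gross_outlier_removed_by_boxplot_rule(self):
        # (1,1,1,1,100): Q1 = Q3 = 1, IQR = 0 -> 100 is outside the fence
        series = np.array([1.0, 1.0, 1.0, 1.0, 100.0]).reshape(5, 1, 1)
        out = summarize_timeseries(series)
        assert out["mean"][0, 0] == 1.0
        assert out["max"][0, 0] == 1.0

    def test_filter_disabled_matches_plain_stats(self, rng):
        series = rng.normal(size=(12, 3, 3))
        out = summarize_timeseries(series, outlier_filter=None)
        np.testing.assert_allclose(out["mean"], series.mean(axis=0))
        np.testing.assert_allclose(out["range"], series.max(axis=0) - series.min(axis=0))

    def test_too_short_series_rejected(self):
        with pytest.raises(DataError):
            summarize_timeseries(np.zeros((3, 2, 2)))


@pytest.fixture(scope="module")
def ensemble_setup(small_scenario, small_stack, small_records):
    observations = observations_from_traps(small_records, "sp1")
    thinned = thin_per_pixel(observations, small_stack.grid)
    presences = [o for o in thinned if o.presence]
    trap_xy = np.array([[r.x, r.y] for r in small_records])
    kernel = sampling_effort_kernel(trap_xy, small_stack.grid, bandwidth=1500.0, mask=small_stack.mask)
    return presences, kernel


class TestEnsemble:
    def test_identical_backgrounds_zero_cv(self, small_stack, ensemble_setup):
        presences, kernel = ensemble_setup
        ens = fit_ensemble(
            small_stack, presences, kernel, n_submodels=3, base_seed=1,
            force_identical_backgrounds=True,
        )
        valid = ~np.isnan(ens.cv_grid)
        np.testing.assert_allclose(ens.cv_grid[valid], 0.0, atol=1e-12)

    def test_mean_grid_is_cellwise_average(self, small_stack, ensemble_setup):
        presences, kernel = ensemble_setup
        ens = fit_ensemble(small_stack, presences, kernel, n_submodels=3, base_seed=2)
        np.testing.assert_allclose(ens.mean_grid, np.mean(ens.submodel_grids, axis=0))

    def test_reproducible_given_base_seed(self, small_stack, ensemble_setup):
        presences, kernel = ensemble_setup
        a = fit_ensemble(small_stack, presences, kernel, n_submodels=2, base_seed=5)
        b = fit_ensemble(small_stack, presences, kernel, n_submodels=2, base_seed=5)
        np.testing.assert_array_equal(a.mean_grid, b.mean_grid)

    def test_submodel_auc_spread_is_narrow(self, small_stack, ensemble_setup):
        presences, kernel = ensemble_setup
        ens = fit_ensemble(small_stack, presences, kernel, n_submodels=10, base_seed=3)
        assert max(ens.submodel_aucs) - min(ens.submodel_aucs) < 0.1

    def test_cv_stability_in_submodel_count(self, small_stack, ensemble_setup):
        presences, kernel = ensemble_setup
        cv10 = fit_ensemble(small_stack, presences, kernel, n_submodels=10, base_seed=7)
        cv40 = fit_ensemble(small_stack, presences, kernel, n_submodels=40, base_seed=7)
        m10 = np.nanmean(cv10.cv_grid)
        m40 = np.nanmean(cv40.cv_grid)
        assert abs(m40 - m10) / m10 < 0.2


class TestValidateHoldout:
    def test_overlap_with_training_cells_rejected(self, small_stack, ensemble_setup):
        presences, kernel = ensemble_setup
        ens = fit_ensemble(small_stack, presences, kernel, n_submodels=2, base_seed=1)
        fake_abs = [
            SpeciesObservation(x=presences[0].x, y=presences[0].y, species="sp1",
                               presence=False, trap_days=40)
        ]
        with pytest.raises(DataError, match="share training cells"):
            validate_holdout(ens, presences[:1], fake_abs, small_stack)

    def test_planted_separation_scores_high(self, small_stack, small_truth, ensemble_setup):
        presences, kernel = ensemble_setup
        ens = fit_ensemble(small_stack, presences, kernel, n_submodels=2, base_seed=1)
        # synthetic holdout drawn from the truth surface in cells unused by training
        grid = small_stack.grid
        s = small_truth.suitability
        free = [
            (r, c)
            for r in range(grid.nrows)
            for c in range(grid.ncols)
            if int(grid.flat_index(r, c)) not in ens.training_cells
        ]
        pres_pts, abs_pts = [], []
        for r, c in free:
            x, y = grid.cell_center(r, c)
            if s[r, c] > 0.8 and len(pres_pts) < 30:
                pres_pts.append(SpeciesObservation(x=x, y=y, species="sp1", presence=True, trap_days=30))
            elif s[r, c] < 0.2 and len(abs_pts) < 30:
                abs_pts.append(SpeciesObservation(x=x, y=y, species="sp1", presence=False, trap_days=30))
        roc = validate_holdout(ens, pres_pts, abs_pts, small_stack)
        assert roc.auc >= 0.9

    def test_constant_grid_gives_half(self, small_stack, ensemble_setup):
        presences, kernel = ensemble_setup
        ens = fit_ensemble(small_stack, presences, kernel, n_submodels=2, base_seed=1)
        ens.mean_grid = np.full_like(ens.mean_grid, 0.4)
        grid = small_stack.grid
        pts = []
        for r in range(grid.nrows):
            for c in range(grid.ncols):
                if int(grid.flat_index(r, c)) not in ens.training_cells and len(pts) < 20:
                    x, y = grid.cell_center(r, c)
                    pts.append(SpeciesObservation(x=x, y=y, species="sp1",
                                                  presence=len(pts) % 2 == 0, trap_days=30))
        roc = validate_holdout(ens, [p for p in pts if p.presence],
                               [p for p in pts if not p.presence], small_stack)
        assert roc.auc == 0.5


class TestSplitHoldout:
    def test_split_fraction_and_disjointness(self, small_stack, ensemble_setup):
        presences, _ = ensemble_setup
        train, hold = split_holdout(presences, small_stack.grid, frac=0.3, seed=0)
        assert len(train) + len(hold) == len(presences)
        assert not {id(o) for o in train} & {id(o) for o in hold}
        assert 0.15 <= len(hold) / len(presences) <= 0.6

    def test_invalid_fraction(self, small_stack, ensemble_setup):
        presences, _ = ensemble_setup
        with pytest.raises(ConfigError):
            split_holdout(presences, small_stack.grid, frac=1.5)
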