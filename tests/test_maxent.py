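import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from tsetse_sdm.errors import DataError
from tsetse_sdm.maxent import (
    FeatureExpansion,
    MaxEntModel,
    fit_maxent,
    maxent_objective,
    variable_contribution,
)


def fista_oracle(x_pres, x_bg, beta, max_iter=200_000, tol=1e-15):
    """Independent solver for the same penalized objective.

    Proximal-gradient (FISTA) with backtracking on
    logsumexp(bg @ lam) - mean(pres @ lam) + sum(beta * |lam|);
    shares no code with the L-BFGS-B implementation under test.
    """
    k = x_pres.shape[1]
    pres_mean = x_pres.mean(axis=0)

    def smooth(lam):
        return logsumexp(x_bg @ lam) - pres_mean @ lam

    def grad(lam):
        eta = x_bg @ lam
        q = np.exp(eta - logsumexp(eta))
        return q @ x_bg - pres_mean

    def prox(v, t):
        return np.sign(v) * np.maximum(np.abs(v) - t * beta, 0.0)

    lam = np.zeros(k)
    y = lam.copy()
    t_mom = 1.0
    step = 1.0
    f_prev = smooth(lam) + beta @ np.abs(lam)
    for _ in range(max_iter):
        g = grad(y)
        # backtracking line search on the smooth part
        while True:
            cand = prox(y - step * g, step)
            diff = cand - y
            if smooth(cand) <= smooth(y) + g @ diff + diff @ diff / (2 * step) + 1e-15:
                break
            step *= 0.5
        lam_new = cand
        t_new = (1 + np.sqrt(1 + 4 * t_mom**2)) / 2
        y = lam_new + (t_mom - 1) / t_new * (lam_new - lam)
        lam, t_mom = lam_new, t_new
        f = smooth(lam) + beta @ np.abs(lam)
        if abs(f_prev - f) < tol * max(1.0, abs(f)):
            break
        f_prev = f
    return lam


def random_instance(rng, n_features=None, n_bg=None, m=None):
    """Well-posed instance: presences are drawn from the background cells
    (tilted toward high values of the first feature), so the presence
    feature means are attainable by the Gibbs distribution and the
    penalized optimum is finite."""
    k = n_features or rng.integers(2, 6)
    b = n_bg or rng.integers(15, 51)
    m = m or rng.integers(5, 30)
    x_bg = rng.normal(size=(b, k))
    w = np.exp(x_bg[:, 0])
    idx = rng.choice(b, size=m, p=w / w.sum())
    x_pres = x_bg[idx]
    return x_pres, x_bg


class TestFeatureExpansion:
    def test_linear_quadratic_values(self):
        table = pd.DataFrame({"a": [3.0, -1.0]})
        exp = FeatureExpansion(kinds={"a": "continuous"}).fit(table)
        np.testing.assert_allclose(exp.transform(table), [[3, 9], [-1, 1]])

    def test_categorical_partition(self):
        table = pd.DataFrame({"veg": ["x", "y", "z", "y"]})
        exp = FeatureExpansion(kinds={"veg": "categorical"}).fit(table)
        feats = exp.transform(table)
        np.testing.assert_array_equal(feats.sum(axis=1), 1.0)

    def test_clamping_to_training_range(self):
        train = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        exp = FeatureExpansion(kinds={"a": "continuous"}, quadratic=False).fit(train)
        out = exp.transform(pd.DataFrame({"a": [5.0, -3.0]}))
        np.testing.assert_allclose(out.ravel(), [2.0, 0.0])

    def test_unseen_level_warns_and_zeroes(self):
        train = pd.DataFrame({"veg": ["x", "y"]})
        exp = FeatureExpansion(kinds={"veg": "categorical"}).fit(train)
        with pytest.warns(UserWarning, match="unseen"):
            out = exp.transform(pd.DataFrame({"veg": ["z"]}))
        np.testing.assert_array_equal(out, [[0.0, 0.0]])

    def test_serialization_roundtrip(self):
        table = pd.DataFrame({"a": [0.0, 2.0], "veg": ["x", "y"]})
        exp = FeatureExpansion(kinds={"a": "continuous", "veg": "categorical"}).fit(table)
        exp2 = FeatureExpansion.from_dict(exp.to_dict())
        np.testing.assert_array_equal(exp.transform(table), exp2.transform(table))


class TestFitMaxent:
    def test_two_cell_closed_form(self):
        # single binary feature, presence mean 0.75, two background cells:
        # matching q(f=1) = 0.75 requires lambda = ln 3
        x_bg = np.array([[0.0], [1.0]] * 5)  # 10 background points
        x_pres = np.array([[1.0]] * 3 + [[0.0]])
        model = fit_maxent(x_pres, x_bg, beta=0.0, tol=1e-10)
        assert model.lambda_[0] == pytest.approx(np.log(3), abs=1e-6)

    def test_infinite_shrinkage_gives_uniform(self, rng):
        x_pres, x_bg = random_instance(rng, 4, 30, 10)
        model = fit_maxent(x_pres, x_bg, beta=1e6)
        np.testing.assert_allclose(model.lambda_, 0.0, atol=1e-8)
        raw = model.raw(x_bg)
        np.testing.assert_allclose(raw, 1.0 / len(x_bg), rtol=1e-9)

    def test_matches_independent_convex_solver(self, rng):
        for _ in range(20):
            x_pres, x_bg = random_instance(rng)
            beta = np.full(x_pres.shape[1], 0.05)
            model = fit_maxent(x_pres, x_bg, beta=beta, tol=1e-10)
            lam_oracle = fista_oracle(x_pres, x_bg, beta)
            f_model = maxent_objective(model.lambda_, x_pres, x_bg, beta)
            f_oracle = maxent_objective(lam_oracle, x_pres, x_bg, beta)
            assert f_model == pytest.approx(f_oracle, abs=1e-5)
            np.testing.assert_allclose(model.lambda_, lam_oracle, atol=1e-5)

    def test_kkt_soft_matching_holds(self, rng):
        for _ in range(10):
            x_pres, x_bg = random_instance(rng)
            model = fit_maxent(x_pres, x_bg, beta0=1.0, tol=1e-9)
            assert np.all(model.kkt_gap <= 1e-6)

    def test_insufficient_background_rejected(self, rng):
        x_pres, x_bg = random_instance(rng, 3, 30, 5)
        with pytest.raises(DataError):
            fit_maxent(x_pres, x_bg[:5])


class TestPredict:
    def test_uniform_model_logistic_half(self, rng):
        x_pres, x_bg = random_instance(rng, 3, 40, 10)
        model = fit_maxent(x_pres, x_bg, beta=1e9)
        np.testing.assert_allclose(model.logistic(x_bg), 0.5, atol=1e-9)

    def test_raw_sums_to_one_over_background(self, rng):
        x_pres, x_bg = random_instance(rng, 4, 30, 12)
        model = fit_maxent(x_pres, x_bg, beta0=0.5)
        assert model.raw(x_bg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_logistic_monotone_in_score(self, rng):
        x_pres, x_bg = random_instance(rng, 2, 30, 10)
        model = fit_maxent(x_pres, x_bg, beta0=0.5)
        grid = np.linspace(-5, 5, 50)[:, None] * np.ones((1, 2))
        scores = grid @ model.lambda_
        logistic = model.logistic(grid)
        order = np.argsort(scores)
        assert np.all(np.diff(logistic[order]) >= -1e-12)

    def test_model_json_roundtrip_bit_for_bit(self, rng, tmp_path):
        table = pd.DataFrame({"a": rng.normal(size=40), "veg": rng.choice(["x", "y"], 40)})
        exp = FeatureExpansion(kinds={"a": "continuous", "veg": "categorical"}).fit(table)
        feats = exp.transform(table)
        model = fit_maxent(feats[:10], feats[10:], beta0=0.5, expansion=exp)
        model.to_json(tmp_path / "model.json")
        model2 = MaxEntModel.from_json(tmp_path / "model.json")
        np.testing.assert_array_equal(model.logistic(feats), model2.logistic(feats))


class TestVariableContribution:
    def test_zero_weight_covariate_contributes_nothing(self, rng):
        x_pres, x_bg = random_instance(rng, 3, 40, 20)
        model = fit_maxent(x_pres, x_bg, beta0=0.5)
        model.lambda_ = model.lambda_.copy()
        model.lambda_[2] = 0.0
        model.feature_names = ["f0", "f1", "f2"]
        contrib = variable_contribution(model, x_pres, x_bg, n_permutations=3, seed=0)
        assert contrib["f2"] == 0.0

    def test_contributions_sum_to_100(self, rng):
        x_pres, x_bg = random_instance(rng, 3, 40, 20)
        model = fit_maxent(x_pres, x_bg, beta0=0.2)
        contrib = variable_contribution(model, x_pres, x_bg, n_permutations=3, seed=0)
        if (contrib > 0).any():
            assert contrib.sum() == pytest.approx(100.0, abs=1e-6)

    def test_planted_informative_covariate_dominates(self, rng):
        # one covariate drives presence, three are noise
        n_bg, m = 2000, 500
        x_bg = rng.normal(size=(n_bg, 4))
        weights = np.exp(2.0 * x_bg[:, 0])
        idx = rng.choice(n_bg, size=m, p=weights / weights.sum())
        x_pres = x_bg[idx] + 0.01 * rng.normal(size=(m, 4))
        model = fit_maxent(x_pres, x_bg, beta0=1.0)
        model.feature_names = ["informative", "n1", "n2", "n3"]
        contrib = variable_contribution(model, x_pres, x_bg, n_permutations=5, seed=1)
        assert contrib["informative"] >= 80.0
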