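import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from burnprob.ignition import (OCCURRENCE_VARIABLES, SeparationError,
                               build_occurrence_sample, fit_logistic,
                               ignition_surface, mean_nn_distance, pseudo_r2,
                               roc_auc, sample_nonignitions,
                               screen_collinearity)

from conftest import make_uniform_landscape


class TestMeanNNDistance:
    def test_symmetric_pair(self):
        assert mean_nn_distance([[0, 0], [500, 0]]) == pytest.approx(500.0)

    def test_collinear_triple_hand_enumeration(self):
        # nearest neighbors: 0->100, 100->0 (d=100), 300->100 (d=200)
        pts = [[0, 0], [100, 0], [300, 0]]
        assert mean_nn_distance(pts) == pytest.approx((100 + 100 + 200) / 3)

    def test_isometry_invariance(self, rng):
        pts = rng.uniform(0, 1000, size=(40, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([123.0, -456.0])
        assert mean_nn_distance(moved) == pytest.approx(mean_nn_distance(pts))

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            mean_nn_distance([[0, 0]])


class TestNonignitionSampling:
    def test_zero_min_dist_plain_uniform(self, rng):
        grid = make_uniform_landscape(30, 30)
        pts = sample_nonignitions(np.array([[3000.0, 3000.0]]), grid, 50,
                                  rng, min_dist=0.0)
        assert len(pts) == 50
        assert pts["row"].between(0, 29).all()

    def test_exclusion_disc_is_respected(self, rng):
        grid = make_uniform_landscape(50, 50)
        center = np.array([[25 * 200.0 + 100, 25 * 200.0 + 100]])
        min_dist = 10 * 200.0
        pts = sample_nonignitions(center, grid, 1000, rng, min_dist=min_dist)
        d = np.hypot(pts["x"] - center[0, 0], pts["y"] - center[0, 1])
        assert (d >= min_dist).all()

    def test_infeasible_mask_rejected_with_diagnostic(self, rng):
        grid = make_uniform_landscape(20, 20)
        center = np.array([[2000.0, 2000.0]])
        with pytest.raises(RuntimeError, match="exclusion"):
            sample_nonignitions(center, grid, 10, rng,
                                min_dist=1e6, max_tries=5)


class TestCollinearityScreen:
    def test_identical_columns_keep_one(self, rng):
        x = rng.normal(size=200)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        retained, dropped = screen_collinearity(table)
        assert "c" in retained
        assert len(set(retained) & {"a", "b"}) == 1
        assert len(dropped) == 1

    def test_independent_columns_all_retained(self, rng):
        table = pd.DataFrame(rng.normal(size=(10_000, 5)),
                             columns=list("abcde"))
        retained, dropped = screen_collinearity(table)
        assert retained == list("abcde") and not dropped

    def test_threshold_one_keeps_all_but_duplicates(self, rng):
        x = rng.normal(size=300)
        table = pd.DataFrame({"a": x, "b": 2 * x + rng.normal(size=300),
                              "dup": x.copy()})
        retained, _ = screen_collinearity(table, threshold=1.0 - 1e-12)
        assert "b" in retained
        assert len(set(retained) & {"a", "dup"}) == 1

    def test_constant_column_excluded_with_warning(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=50),
                              "k": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            retained, _ = screen_collinearity(table)
        assert retained == ["a"]

    def test_priority_keeps_label_associated_member(self, rng):
        y = rng.integers(0, 2, size=2000).astype(float)
        signal = y + rng.normal(0, 0.5, size=2000)
        proxy = signal + rng.normal(0, 0.1, size=2000)  # correlated pair
        table = pd.DataFrame({"proxy": proxy, "signal": signal})
        retained, _ = screen_collinearity(table, label=y)
        assert retained == ["signal"]


def _simulate_logistic(rng, n, beta, intercept=0.0, p=None):
    p = p or len(beta)
    X = rng.normal(size=(n, p))
    prob = expit(intercept + X @ np.asarray(beta))
    y = (rng.random(n) < prob).astype(float)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["label"] = y
    return df


class TestLogisticFit:
    def test_identities_odds_ratio_and_wald(self, rng):
        df = _simulate_logistic(rng, 400, [0.8, -0.5, 0.0])
        fit = fit_logistic(df, ["x0", "x1", "x2"])
        assert np.allclose(fit.odds_ratios, np.exp(fit.params), atol=1e-12)
        assert np.allclose(fit.wald, (fit.params / fit.bse) ** 2, atol=1e-9)
        assert fit.llf >= fit.llnull

    def test_null_truth_coefficients_near_zero(self, rng):
        # under a zero-coefficient truth, fitted B should sit within 3 SE
        df = _simulate_logistic(rng, 2000, [0.0] * 5)
        fit = fit_logistic(df, [f"x{i}" for i in range(5)])
        z = (fit.params / fit.bse).drop("const")
        assert np.all(np.abs(z) < 3.5)

    def test_wald_interval_coverage_of_true_coefficients(self):
        # ~95% Wald intervals should cover the truth in >= ~90% of fits
        beta = np.array([0.8, -0.6, 0.4])
        covered = 0
        total = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            df = _simulate_logistic(rng, 450, beta)
            fit = fit_logistic(df, ["x0", "x1", "x2"])
            for i, b in enumerate(beta):
                lo = fit.params[f"x{i}"] - 1.96 * fit.bse[f"x{i}"]
                hi = fit.params[f"x{i}"] + 1.96 * fit.bse[f"x{i}"]
                covered += lo <= b <= hi
                total += 1
        assert covered / total >= 0.90

    def test_perfect_separation_raises(self):
        df = pd.DataFrame({"x0": np.r_[-np.arange(1, 21), np.arange(1, 21)],
                           "label": np.r_[np.zeros(20), np.ones(20)]})
        with pytest.raises(SeparationError):
            fit_logistic(df, ["x0"])

    def test_single_class_rejected(self, rng):
        df = _simulate_logistic(rng, 50, [0.5])
        df["label"] = 1.0
        with pytest.raises(ValueError):
            fit_logistic(df, ["x0"])


class TestPseudoR2:
    def test_null_model_gives_zero(self):
        from burnprob.ignition import LogisticFit
        fit = LogisticFit(variables=[], params=pd.Series({"const": 0.0}),
                          bse=pd.Series({"const": 1.0}), llf=-10.0,
                          llnull=-10.0, n=30)
        d = pseudo_r2(fit)
        assert d.cox_snell_r2 == pytest.approx(0.0)
        assert d.nagelkerke_r2 == pytest.approx(0.0)

    def test_hand_computed_case(self):
        from burnprob.ignition import LogisticFit
        fit = LogisticFit(variables=[], params=pd.Series({"const": 0.0}),
                          bse=pd.Series({"const": 1.0}),
                          llf=-0.693, llnull=-1.386, n=2)
        d = pseudo_r2(fit)
        assert d.cox_snell_r2 == pytest.approx(1 - np.exp(-0.693), abs=1e-9)

    def test_nagelkerke_dominates_cox_snell(self, rng):
        df = _simulate_logistic(rng, 300, [1.0, -1.0])
        d = pseudo_r2(fit_logistic(df, ["x0", "x1"]))
        assert d.nagelkerke_r2 >= d.cox_snell_r2 > 0


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_hand_computed_pairwise_wins(self):
        # pairs: 0.9>0.6, 0.9>0.2, 0.4<0.6, 0.4>0.2 -> 3/4
        assert roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_matches_brute_force_pairwise_probability(self, rng):
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, size=300)
        scores[labels == 1] += 0.5
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestIgnitionSurface:
    def test_zero_model_gives_half_everywhere(self):
        grid = make_uniform_landscape(10, 10)
        surf = ignition_surface(grid, {"const": 0.0})
        assert np.allclose(surf, 0.5)

    def test_nonburnable_masked_to_zero(self):
        burnable = np.ones((10, 10), dtype=bool)
        burnable[0, 0] = False
        grid = make_uniform_landscape(10, 10, burnable=burnable)
        surf = ignition_surface(grid, {"const": 0.0})
        assert surf[0, 0] == 0.0

    def test_monotone_in_humidity_with_negative_coefficient(self):
        grid = make_uniform_landscape(10, 10)
        coefs = {"const": 0.0, "rh": -0.1}
        lo = ignition_surface(grid, coefs, {"rh": 30.0})
        hi = ignition_surface(grid, coefs, {"rh": 90.0})
        assert np.all(hi < lo)

    def test_missing_weather_rejected(self):
        grid = make_uniform_landscape(10, 10)
        with pytest.raises(ValueError):
            ignition_surface(grid, {"const": 0.0, "rh": -0.1})


class TestParameterRecovery:
    def test_fitted_surface_tracks_generative_surface(self, small_world):
        # end-to-end: fit on the synthetic catalogue, compare spatial surfaces
        from scipy.stats import spearmanr

        from burnprob.ignition import spatial_linear_predictor

        world = small_world
        rng = np.random.default_rng(99)
        occ = build_occurrence_sample(world.landscape, world.archive,
                                      world.fires, rng)
        fit = fit_logistic(occ, OCCURRENCE_VARIABLES)
        est = spatial_linear_predictor(world.landscape, fit.coefficients())
        true = spatial_linear_predictor(world.landscape,
                                        world.config.ignition_coefs)
        rho = spearmanr(est.ravel(), true.ravel()).statistic
        assert rho > 0.9
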