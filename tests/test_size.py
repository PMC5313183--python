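import numpy as np
import pandas as pd
import pytest

from burnprob.size import (SIZE_VARIABLES, build_size_sample, default_mtry,
                           draw_stochastic_size, fit_ensemble, importance,
                           predict_size, tune_mtry)


def _synthetic_sample(rng, n=220, noise=1.0, planted=True):
    """Size sample with pine share and population as planted drivers."""
    data = {
        "prop_pine": rng.uniform(0, 1, n),
        "pop_density": rng.lognormal(3, 1, n),
        "slope": rng.uniform(0, 40, n),
        "prop_broadleaf": rng.uniform(0, 1, n),
        "dist_road": rng.uniform(0, 10, n),
        "aspect": rng.uniform(1, 360, n),
        "dominant_age": rng.gamma(2, 9, n),
        "prop_fir": rng.uniform(0, 1, n),
        "dist_settlement": rng.uniform(0, 10, n),
        "wind_max": rng.lognormal(0, 0.6, n),
        "rh": rng.uniform(40, 100, n),
        "t_max": rng.uniform(5, 40, n),
    }
    df = pd.DataFrame(data)
    mu = 1.0
    if planted:
        mu = mu + 2.0 * df["prop_pine"] + 0.5 * np.log1p(df["pop_density"])
    df["size_ha"] = np.exp(mu + noise * rng.standard_normal(n) * 0.3)
    return df


class TestTuneMtry:
    def test_regression_default_start(self):
        assert default_mtry(12) == 4
        assert default_mtry(2) == 1

    def test_pure_noise_returns_valid_mtry(self, rng):
        df = _synthetic_sample(rng, n=80, planted=False)
        df["size_ha"] = rng.permutation(df["size_ha"].to_numpy())
        m = tune_mtry(df, ntree=100, seed=0)
        assert 1 <= m <= 12

    def test_deterministic_given_seed(self, rng):
        df = _synthetic_sample(rng, n=80)
        assert tune_mtry(df, ntree=100, seed=3) == tune_mtry(df, ntree=100, seed=3)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            tune_mtry(_synthetic_sample(rng, n=20), ntree=50)


class TestEnsemble:
    def test_exact_linear_signal_recovered(self, rng):
        df = _synthetic_sample(rng, n=240, planted=False)
        df["size_ha"] = 3.0 + 5.0 * df["prop_pine"]  # noise-free signal
        ens = fit_ensemble(df, mtry=6, ntree=200, rng=rng)
        assert ens.variance_explained > 0.8

    def test_prediction_is_member_mean(self, rng):
        df = _synthetic_sample(rng, n=120)
        ens = fit_ensemble(df, ntree=100, rng=rng)
        X = df[list(SIZE_VARIABLES)].head(10)
        manual = np.mean([m.predict(X.to_numpy()) for m in ens.models], axis=0)
        assert np.allclose(predict_size(ens, X), manual)

    def test_member_training_fraction(self, rng):
        df = _synthetic_sample(rng, n=225)
        ens = fit_ensemble(df, ntree=50, rng=rng)
        assert len(ens.models) == 10
        for tr, te in zip(ens.train_idx, ens.test_idx):
            assert len(tr) == 150 and len(te) == 75
        assert len(ens.residuals) == 750

    def test_seed_reproducibility(self, rng):
        df = _synthetic_sample(rng, n=120)
        a = fit_ensemble(df, ntree=100, rng=np.random.default_rng(5))
        b = fit_ensemble(df, ntree=100, rng=np.random.default_rng(5))
        ia = importance(a, rng=np.random.default_rng(6))
        ib = importance(b, rng=np.random.default_rng(6))
        pd.testing.assert_frame_equal(ia, ib)

    def test_bad_train_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ensemble(_synthetic_sample(rng), train_frac=1.5)


class TestImportance:
    def test_planted_drivers_dominate_noise(self, rng):
        df = _synthetic_sample(rng, n=240)
        ens = fit_ensemble(df, mtry=4, ntree=300, rng=rng)
        table = importance(ens, rng=rng).set_index("variable")["pct_inc_mse"]
        # pure-noise covariate at least 5x below the planted signal
        assert table["prop_pine"] > 5 * abs(table["aspect"])
        assert table["prop_pine"] > 0

    def test_permuted_response_importances_near_zero(self, rng):
        df = _synthetic_sample(rng, n=200)
        df["size_ha"] = rng.permutation(df["size_ha"].to_numpy())
        ens = fit_ensemble(df, mtry=4, ntree=200, rng=rng)
        table = importance(ens, rng=rng)
        assert table["pct_inc_mse"].abs().max() < 15.0

    def test_table_sorted_descending(self, rng):
        df = _synthetic_sample(rng, n=150)
        ens = fit_ensemble(df, ntree=100, rng=rng)
        vals = importance(ens, rng=rng)["pct_inc_mse"].to_numpy()
        assert np.all(np.diff(vals) <= 0)

    def test_planted_ranks_recovered_across_seeds(self):
        # pine and population should occupy 2 of the top 3 ranks in
        # at least 8 of 10 seeded replicates
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            df = _synthetic_sample(rng, n=225)
            ens = fit_ensemble(df, mtry=4, ntree=200, rng=rng)
            top3 = set(importance(ens, rng=rng)["variable"].head(3))
            hits += len(top3 & {"prop_pine", "pop_density"}) >= 2
        assert hits >= 8


class TestPrediction:
    def test_constant_response(self, rng):
        df = _synthetic_sample(rng, n=100)
        df["size_ha"] = 7.0
        ens = fit_ensemble(df, ntree=50, rng=rng)
        assert np.allclose(predict_size(ens, df[list(SIZE_VARIABLES)]), 7.0)

    def test_prediction_within_training_range(self, rng):
        df = _synthetic_sample(rng, n=150)
        ens = fit_ensemble(df, ntree=100, rng=rng)
        preds = predict_size(ens, df[list(SIZE_VARIABLES)])
        assert preds.min() >= df["size_ha"].min() - 1e-9
        assert preds.max() <= df["size_ha"].max() + 1e-9

    def test_missing_covariate_rejected(self, rng):
        df = _synthetic_sample(rng, n=100)
        ens = fit_ensemble(df, ntree=50, rng=rng)
        with pytest.raises(ValueError, match="missing"):
            predict_size(ens, df[list(SIZE_VARIABLES)[:-1]])

    def test_signal_to_noise_mimics_observed_fit_quality(self, rng):
        # at the generative S/N the pooled holdout correlation is strong
        df = _synthetic_sample(rng, n=225, noise=1.0)
        ens = fit_ensemble(df, mtry=4, ntree=300, rng=rng)
        assert ens.holdout_correlation > 0.6


class TestStochasticSize:
    def test_zero_residual_pool_equals_prediction(self, rng):
        df = _synthetic_sample(rng, n=100)
        df["size_ha"] = 5.0 + 3.0 * df["prop_pine"]
        ens = fit_ensemble(df, ntree=100, rng=rng)
        X = df[list(SIZE_VARIABLES)].head(20)

        class ZeroResid(type(ens)):
            @property
            def residuals(self):
                return np.zeros(10)

        ens.__class__ = ZeroResid
        draws = draw_stochastic_size(ens, X, rng, min_size=0.0)
        assert np.allclose(draws, predict_size(ens, X))

    def test_monte_carlo_mean_matches_residual_shift(self, rng):
        df = _synthetic_sample(rng, n=150)
        ens = fit_ensemble(df, ntree=100, rng=rng)
        X = pd.concat([df[list(SIZE_VARIABLES)].head(1)] * 10_000,
                      ignore_index=True)
        draws = draw_stochastic_size(ens, X, rng, min_size=-1e9)
        expected = predict_size(ens, X)[0] + ens.residuals.mean()
        se = ens.residuals.std() / np.sqrt(10_000)
        assert abs(draws.mean() - expected) < 3 * se

    def test_floor_is_enforced(self, rng):
        df = _synthetic_sample(rng, n=100)
        ens = fit_ensemble(df, ntree=50, rng=rng)
        X = df[list(SIZE_VARIABLES)].head(50)
        draws = draw_stochastic_size(ens, X, rng, min_size=0.3,
                                     cell_area_ha=4.0)
        assert draws.min() >= 4.0


def test_build_size_sample_covariates(small_world):
    df = build_size_sample(small_world.landscape, small_world.archive,
                           small_world.fires)
    assert list(df.columns) == ["size_ha"] + list(SIZE_VARIABLES)
    assert len(df) == len(small_world.fires)
    assert df.notna().all().all()
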