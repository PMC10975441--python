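"""Calibration models and metrics: exact recovery, oracle equivalence, CV."""
import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from hsimoist import (
    SyntheticConfig,
    cross_validate,
    evaluate_grid,
    fit,
    generate_spectra,
    predict,
    r_squared,
    rmse,
    spxy_split,
)
from hsimoist.containers import SpectraMatrix
from hsimoist.errors import (
    ConfigurationError,
    ContractError,
    RankError,
    SchemeError,
    UndefinedStatisticError,
)


def sm(values):
    values = np.atleast_2d(values)
    return SpectraMatrix(values, np.arange(values.shape[1]) * 10.0 + 1000)


@pytest.fixture
def linear_data(rng):
    x = rng.random((20, 5))
    beta = np.array([1.0, -0.5, 2.0, 0.0, 0.3])
    y = 3.0 + x @ beta
    return x, y


class TestFit:
    def test_plsr_exact_recovery_noiseless(self, linear_data):
        x, y = linear_data
        model = fit("plsr", x, y, n_components=5)
        assert np.abs(predict(model, x) - y).max() < 1e-8

    def test_pcr_full_rank_equals_ols(self, linear_data, rng):
        x, y = linear_data
        y = y + rng.normal(0, 0.1, 20)
        model = fit("pcr", x, y, n_components=5)
        z = np.column_stack([np.ones(20), x])
        coef, *_ = np.linalg.lstsq(z, y, rcond=None)
        assert np.allclose(model.coef_, coef[1:], atol=1e-8)
        assert np.isclose(model.intercept_, coef[0], atol=1e-8)

    def test_plsr_full_rank_equals_ols(self, linear_data, rng):
        x, y = linear_data
        y = y + rng.normal(0, 0.1, 20)
        model = fit("plsr", x, y, n_components=5)
        z = np.column_stack([np.ones(20), x])
        coef, *_ = np.linalg.lstsq(z, y, rcond=None)
        assert np.allclose(model.coef_, coef[1:], atol=1e-6)

    def test_plsr_single_column_is_univariate_slope(self, rng):
        x = rng.random((15, 1))
        y = 2.0 + 4.0 * x[:, 0] + rng.normal(0, 0.05, 15)
        model = fit("plsr", x, y, n_components=1)
        slope = np.cov(x[:, 0], y)[0, 1] / np.var(x[:, 0], ddof=1)
        assert np.isclose(model.coef_[0], slope)

    def test_plsr_matches_sklearn(self, rng):
        # independent cross-check of the NIPALS implementation
        x = rng.random((25, 8))
        y = x @ rng.normal(size=8) + rng.normal(0, 0.1, 25)
        for a in (1, 3, 5):
            ours = fit("plsr", x, y, n_components=a)
            ref = PLSRegression(n_components=a, scale=False).fit(x, y)
            assert np.allclose(ours.coef_, ref.coef_.ravel(), atol=1e-8)

    def test_components_exceeding_rank_raise(self, rng):
        x = rng.random((6, 10))
        with pytest.raises(RankError):
            fit("pcr", rng.random((6, 10)), rng.random(6), n_components=8)

    def test_svmr_fits_strong_signal(self, rng):
        x = rng.random((40, 4))
        y = 9 + 2 * x[:, 0] - x[:, 2]
        model = fit("svmr", x, y, svm_params={"C": 100.0, "epsilon": 0.01})
        assert r_squared(y, predict(model, x)) > 0.95

    def test_prediction_rejects_wrong_band_axis(self, linear_data):
        x, y = linear_data
        model = fit("plsr", sm(x), y, n_components=2)
        with pytest.raises(ContractError):
            predict(model, sm(x[:, :4]))


class TestMetrics:
    def test_r_squared_perfect_and_sign_blind(self, rng):
        a = rng.random(10)
        assert r_squared(a, a) == pytest.approx(1.0)
        assert r_squared(a, -a + 0.3) == pytest.approx(1.0)

    def test_r_squared_hand_computed(self):
        actual = np.array([1.0, 2.0, 3.0, 4.0])
        predicted = np.array([1.1, 1.9, 3.2, 3.8])
        r = np.corrcoef(actual, predicted)[0, 1]
        assert r_squared(actual, predicted) == pytest.approx(r**2)

    def test_r_squared_constant_actual_raises(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_printed_formula_variant(self):
        actual = np.array([1.0, 2.0, 3.0, 4.0])
        predicted = np.array([1.1, 1.9, 3.2, 3.8])
        ac, pc = actual - actual.mean(), predicted - predicted.mean()
        expected = (ac @ pc) / (ac @ ac + pc @ pc)
        assert r_squared(actual, predicted, formula="printed") == pytest.approx(expected)

    def test_rmse_cases(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([0, 0], [2, 2]) == pytest.approx(2.0)
        assert rmse([0, 0, 0, 0], [1, 1, 1, 3]) == pytest.approx(np.sqrt(3.0))

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            rmse([1, 2], [1, 2, 3])


class TestCrossValidate:
    def test_loo_prediction_count(self, linear_data, rng):
        x, y = linear_data
        cv = cross_validate("plsr", x, y + rng.normal(0, 0.1, 20), scheme="loo")
        assert cv.predictions.shape == (20,)

    def test_loo_equals_naive_refit_loop(self, rng):
        x = rng.random((14, 4))
        y = x @ [1.0, 2.0, -1.0, 0.5] + rng.normal(0, 0.2, 14)
        a = 2
        cv = cross_validate("plsr", x, y, scheme="loo", components_grid=[a])
        naive = np.empty(14)
        for i in range(14):
            keep = np.delete(np.arange(14), i)
            model = fit("plsr", x[keep], y[keep], n_components=a)
            naive[i] = x[i] @ model.coef_ + model.intercept_
        assert np.allclose(cv.predictions, naive, atol=1e-10)
        assert cv.rmsecv == pytest.approx(rmse(y, naive))

    def test_rmsecv_flattens_at_true_rank(self, rng):
        # X of exact rank 3 with noiseless linear y: the RMSECV trace drops
        # until the rank is reached, then stays flat
        scores = rng.normal(size=(30, 3))
        loadings = rng.normal(size=(3, 10))
        x = scores @ loadings
        y = scores @ [1.0, 0.5, -0.7]
        cv = cross_validate("plsr", x, y, scheme="loo")
        trace = cv.rmsecv_by_components
        assert trace[2] < trace[0]
        assert trace[2] < 1e-8
        assert np.allclose(trace[2:], trace[2], atol=1e-8)

    def test_kfold_seeded(self, rng):
        x = rng.random((24, 6))
        y = x @ np.ones(6) + rng.normal(0, 0.1, 24)
        a = cross_validate("plsr", x, y, scheme="kfold", k=4, seed=1)
        b = cross_validate("plsr", x, y, scheme="kfold", k=4, seed=1)
        assert a.rmsecv == b.rmsecv

    def test_infeasible_scheme(self, rng):
        with pytest.raises(SchemeError):
            cross_validate("plsr", rng.random((5, 3)), rng.random(5), scheme="kfold", k=9)

    def test_rmsec_below_rmsecv_in_expectation(self):
        # fitting the training data beats out-of-fold prediction on average
        diffs = []
        for seed in range(20):
            cfg = SyntheticConfig(n_samples=25, seed=seed, n_bands=64)
            x, y = generate_spectra(cfg)
            cv = cross_validate("plsr", x, y, scheme="loo")
            model = fit("plsr", x, y, n_components=cv.best_components)
            diffs.append(cv.rmsecv - rmse(y, predict(model, x)))
        assert np.mean(diffs) > 0


class TestEvaluateGrid:
    def test_grid_rows_and_schema(self, study):
        from hsimoist import spa_select

        sel = spa_select(study["xcal"], study["ycal"], n_max=8)
        report = evaluate_grid(
            study["xcal"],
            study["ycal"],
            study["xpred"],
            study["ypred"],
            selections=[None, sel],
            kinds=("plsr", "pcr"),
        )
        assert len(report.table) == 4
        assert list(report.table.columns) == [
            "model", "bands", "PCs", "RC2", "RMSEC", "RCV2", "RMSECV", "RP2", "RMSEP",
        ]
        assert report.table["RMSEC"].min() >= 0
        assert report.table["RC2"].between(0, 1).all()
        full_row = report.table.iloc[0]
        assert full_row["bands"] == 218

    def test_strong_signal_prediction_quality(self, study):
        report = evaluate_grid(
            study["xcal"],
            study["ycal"],
            study["xpred"],
            study["ypred"],
            selections=[None],
            kinds=("plsr",),
        )
        assert report.table["RP2"].iloc[0] >= 0.99
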