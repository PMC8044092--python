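import numpy as np
import pandas as pd
import pytest

from ndrquant.coverage import FeatureMatrix
from ndrquant.model import (
    TrainedModel,
    complexity_sweep,
    consensus_purity,
    detection_metrics,
    evaluate,
    fit,
    predict,
    stability_select,
)


def matrix_from(X, y=None, prefix="f"):
    idx = [f"s{i}" for i in range(len(X))]
    cols = [f"{prefix}{j}" for j in range(X.shape[1])]
    resp = pd.Series(y, index=idx) if y is not None else None
    return FeatureMatrix(pd.DataFrame(X, index=idx, columns=cols), resp)


def planted_matrix(n=120, p=30, informative=1, noise=0.01, seed=0, slope=-0.5):
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 0.6, n)
    X = 1.0 + rng.normal(0, noise, (n, p))
    for j in range(informative):
        X[:, j] += slope * y
    return matrix_from(X, y)


class TestStabilitySelect:
    def test_single_informative_feature_is_always_selected(self):
        m = planted_matrix(informative=1, noise=0.01, seed=1)
        sel = stability_select(m, n_repeats=40, folds=5, seed=2)
        assert sel.frequency["f0"] == 1.0
        assert sel.selected == ["f0"]

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(3)
        m = planted_matrix(informative=1, noise=0.01, seed=1)
        shuffled = FeatureMatrix(m.values, pd.Series(
            rng.permutation(m.response.to_numpy()), index=m.values.index))
        sel = stability_select(shuffled, n_repeats=40, folds=5, seed=2)
        assert sel.selected == []

    def test_duplicated_feature_splits_selection(self):
        m = planted_matrix(informative=1, noise=0.02, seed=4)
        dup = m.values.copy()
        dup["f0_copy"] = dup["f0"] + np.random.default_rng(0).normal(0, 1e-6, len(dup))
        md = FeatureMatrix(dup, m.response)
        sel = stability_select(md, n_repeats=30, folds=5, seed=5)
        # the signal lands on the pair: combined frequency stays near one
        assert sel.frequency["f0"] + sel.frequency["f0_copy"] >= 0.9

    def test_reproducible_for_fixed_seed(self):
        m = planted_matrix(informative=2, seed=6)
        a = stability_select(m, n_repeats=20, folds=5, seed=7)
        b = stability_select(m, n_repeats=20, folds=5, seed=7)
        assert a.frequency.equals(b.frequency)

    def test_missing_cells_rejected(self):
        m = planted_matrix()
        m.values.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            stability_select(m, n_repeats=5, folds=5, seed=0)

    def test_needs_enough_samples(self):
        m = planted_matrix(n=12)
        with pytest.raises(ValueError, match="samples"):
            stability_select(m, folds=10)


class TestFit:
    def test_single_feature_recovers_line(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 0.4, 200)
        y = 2.0 * x + 0.1
        m = matrix_from(x[:, None], y)
        model = fit(m, folds=5, seed=0)
        assert model.coefficients[0] == pytest.approx(2.0, abs=0.05)
        assert model.intercept == pytest.approx(0.1, abs=0.02)

    def test_constant_response_gives_intercept_only(self):
        rng = np.random.default_rng(9)
        m = matrix_from(rng.normal(1, 0.1, (30, 3)), np.full(30, 0.25))
        model = fit(m, folds=5, seed=0)
        assert np.all(model.coefficients == 0)
        assert model.intercept == pytest.approx(0.25)

    def test_empty_feature_set_is_instructive_error(self):
        m = matrix_from(np.empty((30, 0)), np.linspace(0, 1, 30))
        with pytest.raises(ValueError, match="freq_threshold"):
            fit(m, folds=5)

    def test_coefficients_reported_on_original_scale(self):
        rng = np.random.default_rng(10)
        x1 = rng.uniform(0, 1, 300)
        x2 = rng.uniform(0, 100, 300)  # very different scale
        y = np.clip(0.3 * x1 + 0.002 * x2 + rng.normal(0, 0.005, 300), 0, 1)
        m = matrix_from(np.column_stack([x1, x2]), y)
        model = fit(m, folds=5, seed=1)
        assert model.coefficients[0] == pytest.approx(0.3, abs=0.03)
        assert model.coefficients[1] == pytest.approx(0.002, abs=0.0005)

    def test_json_round_trip(self, tmp_path):
        m = planted_matrix(informative=2, seed=12)
        model = fit(m, folds=5, seed=3)
        path = tmp_path / "model.json"
        model.to_json(str(path))
        back = TrainedModel.from_json(str(path))
        assert back.feature_ids == model.feature_ids
        assert np.allclose(back.coefficients, model.coefficients)
        assert back.intercept == model.intercept
        assert predict(back, m).equals(predict(model, m))


class TestPredict:
    def test_zero_coefficients_predict_clamped_intercept(self):
        m = planted_matrix(n=20)
        model = TrainedModel(list(m.values.columns), np.zeros(m.values.shape[1]), 0.4, 0.0)
        assert (predict(model, m) == 0.4).all()

    def test_negative_linear_value_clamps_to_zero(self):
        model = TrainedModel(["f0"], np.array([0.0]), -0.03, 0.0)
        m = matrix_from(np.ones((5, 1)))
        pred = predict(model, m)
        assert (pred == 0.0).all()

    def test_predictions_always_in_unit_interval(self):
        rng = np.random.default_rng(13)
        model = TrainedModel(["f0", "f1"], np.array([5.0, -5.0]), 0.1, 0.0)
        m = matrix_from(rng.normal(0, 2, (50, 2)))
        pred = predict(model, m)
        assert pred.between(0, 1).all()

    def test_missing_model_feature_is_error(self):
        model = TrainedModel(["f0", "nope"], np.array([1.0, 1.0]), 0.0, 0.0)
        m = matrix_from(np.ones((3, 1)))
        with pytest.raises(ValueError, match="absent"):
            predict(model, m)
        m2 = matrix_from(np.ones((3, 2)))
        m2.values.iloc[1, 1] = np.nan
        model2 = TrainedModel(["f0", "f1"], np.array([1.0, 1.0]), 0.0, 0.0)
        with pytest.raises(ValueError, match="missing"):
            predict(model2, m2)


class TestEvaluate:
    def test_perfect_prediction(self):
        y = pd.Series([0.1, 0.2, 0.5, 0.8])
        rep = evaluate(y, y)
        assert rep.mae == 0.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)

    def test_constant_offset(self):
        y = pd.Series([0.1, 0.2, 0.5, 0.8])
        rep = evaluate(y + 0.05, y)
        assert rep.mae == pytest.approx(0.05)
        assert rep.mae_percent == pytest.approx(5.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_ten_pair_fixture_matches_hand_computation(self):
        pred = [0.02, 0.05, 0.11, 0.19, 0.32, 0.41, 0.48, 0.63, 0.70, 0.88]
        truth = [0.01, 0.07, 0.10, 0.22, 0.30, 0.38, 0.50, 0.60, 0.75, 0.90]
        rep = evaluate(pred, truth)
        # independent arithmetic: mean of per-pair absolute differences
        mae = sum(abs(p - t) for p, t in zip(pred, truth)) / 10
        assert rep.mae == pytest.approx(mae)
        # Pearson from raw sums
        n = 10
        sp, st = sum(pred), sum(truth)
        spt = sum(p * t for p, t in zip(pred, truth))
        sp2 = sum(p * p for p in pred)
        st2 = sum(t * t for t in truth)
        r = (n * spt - sp * st) / np.sqrt((n * sp2 - sp**2) * (n * st2 - st**2))
        assert rep.pearson_r == pytest.approx(r)
        # both vectors already rank-sorted: Spearman is exactly one
        assert rep.spearman_rho == pytest.approx(1.0)

    def test_degenerate_variance_keeps_mae(self):
        rep = evaluate([0.2, 0.2, 0.2], [0.1, 0.2, 0.3])
        assert np.isnan(rep.pearson_r)
        assert rep.mae == pytest.approx(0.2 / 3)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            evaluate([0.1, 0.2], [0.1, 0.2])


class TestDetection:
    def test_perfect_separation(self):
        rep = detection_metrics([0.05, 0.9], [0.001, 0.01], 0.02)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_threshold_above_everything(self):
        rep = detection_metrics([0.05, 0.9], [0.001, 0.01], 0.95)
        assert rep.sensitivity == 0.0 and rep.specificity == 1.0

    def test_counting_oracle(self):
        rng = np.random.default_rng(14)
        pos = rng.uniform(0, 0.2, 60)
        neg = rng.uniform(0, 0.05, 40)
        t = 0.02
        rep = detection_metrics(pos, neg, t)
        assert rep.true_positives == sum(1 for p in pos if p >= t)
        assert rep.true_negatives == sum(1 for x in neg if x < t)
        assert rep.sensitivity == pytest.approx(rep.true_positives / 60)
        assert rep.specificity == pytest.approx(rep.true_negatives / 40)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(15)
        pos = rng.uniform(0, 0.3, 80)
        neg = rng.uniform(0, 0.1, 40)
        sens, spec = [], []
        for t in np.linspace(0.0, 0.3, 20):
            rep = detection_metrics(pos, neg, t)
            sens.append(rep.sensitivity)
            spec.append(rep.specificity)
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_empty_class_is_nan(self):
        rep = detection_metrics([], [0.01], 0.02)
        assert np.isnan(rep.sensitivity) and rep.specificity == 1.0


class TestComplexitySweep:
    def _matrices(self):
        rng = np.random.default_rng(16)
        n, p, k_inf = 180, 24, 6
        slopes = rng.uniform(-0.7, -0.4, k_inf)

        def make(n, seed):
            r = np.random.default_rng(seed)
            y = r.uniform(0, 0.5, n)
            X = 1.0 + r.normal(0, 0.05, (n, p))
            for j in range(k_inf):
                X[:, j] += slopes[j] * y
            return matrix_from(X, y)

        return make(n, 17), make(90, 18)

    def test_intercept_only_baseline(self):
        train, test = self._matrices()
        sweep = complexity_sweep(train, test, list(train.values.columns), [0], folds=5)
        base = float(np.abs(train.response - train.response.mean()).mean())
        assert sweep.loc[sweep["k"] == 0, "train_mae"].iloc[0] == pytest.approx(base)

    def test_full_k_reproduces_unrestricted_fit(self):
        train, test = self._matrices()
        ranking = list(train.values.columns)
        sweep = complexity_sweep(train, test, ranking, [len(ranking)], folds=5, seed=1)
        full = fit(train, folds=5, seed=1)
        rep = evaluate(predict(full, test), test.response)
        assert sweep["test_mae"].iloc[0] == pytest.approx(rep.mae)

    def test_informative_count_minimizes_test_error(self):
        train, test = self._matrices()
        ranking = list(train.values.columns)  # informative features ranked first
        ks = [0, 1, 2, 4, 6, 8, 10, 16, 24]
        sweep = complexity_sweep(train, test, ranking, ks, folds=5, seed=2)
        best_k = int(sweep.loc[sweep["test_mae"].idxmin(), "k"])
        assert 4 <= best_k <= 10

    def test_oversized_k_skipped(self):
        train, test = self._matrices()
        sweep = complexity_sweep(train, test, list(train.values.columns)[:4], [2, 99], folds=5)
        assert sweep["k"].tolist() == [2]


class TestConsensusPurity:
    @pytest.mark.parametrize(
        "estimates,expected",
        [
            ([0.4, 0.5, 0.6, 0.9], 0.55),
            ([0.7], 0.7),
            ([0.35, 0.86, 0.5], 0.5),
        ],
    )
    def test_median_rule(self, estimates, expected):
        assert consensus_purity(estimates) == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            consensus_purity([])
        with pytest.raises(ValueError):
            consensus_purity([1.2])
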