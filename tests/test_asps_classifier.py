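import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from asps import (
    LogisticModel,
    TrainingSet,
    auc,
    cross_validated_scores,
    cv_auc,
    fit_weighted_logistic,
    make_cv_plan,
    max_score_per_athlete,
    predict_asps,
    select_variables,
    standardise,
)
from asps.exceptions import (
    DegenerateLabelsError,
    PlanError,
    SchemaError,
    UndefinedAUCError,
)

from conftest import make_training_set


def tiny_set(X, y, weights=None, source=None) -> TrainingSet:
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    return TrainingSet(
        features=pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(p)],
                              index=[f"A{i:03d}" for i in range(n)]),
        labels=np.asarray(y, dtype=int),
        weights=np.ones(n) if weights is None else np.asarray(weights, float),
        source=np.array(["doping_control"] * n, dtype=object)
        if source is None else np.asarray(source, dtype=object),
    )


class TestStandardise:
    def test_two_point_column(self):
        ts = tiny_set([[1.0], [3.0]], [0, 1])
        transform, Xs = standardise(ts)
        assert transform["f00"] == pytest.approx((2.0, np.sqrt(2.0)))
        assert np.allclose(Xs["f00"], [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_constant_column_dropped(self, caplog):
        ts = tiny_set([[1.0, 5.0], [3.0, 5.0]], [0, 1])
        with caplog.at_level("WARNING"):
            transform, Xs = standardise(ts)
        assert "f01" not in transform
        assert list(Xs.columns) == ["f00"]
        assert "zero-variance" in caplog.text

    def test_round_trip_mean_zero_sd_one(self, rng):
        ts = make_training_set(n=40, n_features=5, seed=3)
        _, Xs = standardise(ts)
        assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Xs.std(axis=0, ddof=1), 1.0, rtol=1e-12)


def weighted_loss(beta, X, y, w, ridge):
    eta = X @ beta
    pen = np.zeros_like(beta)
    pen[1:] = ridge
    return (np.sum(w * (np.logaddexp(0, eta) - y * eta))
            + 0.5 * np.sum(pen * beta**2))


class TestFit:
    def test_symmetric_toy_zero_intercept(self):
        ts = tiny_set([[1.0], [-1.0]], [1, 0])
        model = fit_weighted_logistic(ts, ridge=1e-8)
        assert abs(model.intercept) < 1e-6

    def test_equal_weights_match_unweighted(self):
        ts = make_training_set(n=80, n_features=4, seed=1)
        ts_w = TrainingSet(features=ts.features, labels=ts.labels,
                           weights=np.full(len(ts.labels), 3.0),
                           source=ts.source)
        m1 = fit_weighted_logistic(ts, ridge=0.0)
        m2 = fit_weighted_logistic(ts_w, ridge=0.0)
        for name in m1.coefficients:
            assert m1.coefficients[name] == pytest.approx(
                m2.coefficients[name], abs=1e-6)

    def test_brute_force_optimiser_oracle(self):
        # 6-point hand dataset; compare against a generic optimiser on
        # the same standardised loss
        X = np.array([[0.5, 1.0], [1.5, -0.2], [-0.7, 0.3],
                      [0.2, -1.4], [-1.1, 0.8], [0.9, 0.1]])
        y = [1, 1, 0, 0, 0, 1]
        w = [1.0, 2.0, 1.0, 20.0, 1.0, 3.0]
        ts = tiny_set(X, y, weights=w)
        ridge = 1e-6
        model = fit_weighted_logistic(ts, ridge=ridge)
        # oracle: standardise in the test, then Nelder-Mead on the loss
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        D = np.column_stack([np.ones(len(Xs)), Xs])
        res = minimize(weighted_loss, np.zeros(3),
                       args=(D, np.array(y, float), np.array(w), ridge),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        assert model.intercept == pytest.approx(res.x[0], abs=1e-4)
        assert model.coefficients["f00"] == pytest.approx(res.x[1], abs=1e-4)
        assert model.coefficients["f01"] == pytest.approx(res.x[2], abs=1e-4)

    def test_integer_weight_equals_replication(self):
        # at the optimiser level a weight of 20 is exactly a 20-fold row
        # replication (same loss surface, same Newton path)
        from asps.asps_classifier import _newton_fit

        ts = make_training_set(n=50, n_features=3, seed=7)
        w = 20
        X = np.column_stack([np.ones(len(ts.labels)),
                             ts.features.to_numpy()])
        y = ts.labels.astype(float)
        beta_w, _, _, _ = _newton_fit(X, y, np.full(len(y), float(w)),
                                      ridge=1e-8)
        reps = np.repeat(np.arange(len(y)), w)
        beta_rep, _, _, _ = _newton_fit(X[reps], y[reps],
                                        np.ones(len(reps)), ridge=1e-8)
        assert np.allclose(beta_w, beta_rep, atol=1e-10)
        # the high-level fit differs only through the ddof=1 scale of the
        # replicated standardisation; predictions agree
        ts_w = TrainingSet(features=ts.features, labels=ts.labels,
                           weights=np.full(len(ts.labels), float(w)),
                           source=ts.source)
        m_w = fit_weighted_logistic(ts_w, ridge=1e-8)
        feats = ts.features.iloc[reps].reset_index(drop=True)
        feats.index = [f"R{i:05d}" for i in range(len(feats))]
        ts_rep = TrainingSet(features=feats, labels=ts.labels[reps],
                             weights=np.ones(len(reps)),
                             source=ts.source[reps])
        m_rep = fit_weighted_logistic(ts_rep, ridge=1e-8)
        assert np.allclose(m_w.predict(ts.features),
                           m_rep.predict(ts.features), atol=1e-6)

    def test_single_class_rejected(self):
        ts = tiny_set([[1.0], [2.0]], [1, 1])
        with pytest.raises(DegenerateLabelsError):
            fit_weighted_logistic(ts)

    def test_prediction_invariant_to_affine_feature_rescale(self):
        ts = make_training_set(n=60, n_features=4, seed=11)
        m1 = fit_weighted_logistic(ts, ridge=1e-8)
        feats2 = ts.features.copy()
        feats2["f01"] = 7.5 * feats2["f01"] - 3.0
        ts2 = TrainingSet(features=feats2, labels=ts.labels,
                          weights=ts.weights, source=ts.source)
        m2 = fit_weighted_logistic(ts2, ridge=1e-8)
        assert np.allclose(m1.predict(ts.features), m2.predict(feats2),
                           atol=1e-8)


class TestPredict:
    def test_intercept_only_matches_logistic_function(self):
        model = LogisticModel(intercept=-3.2, coefficients={},
                              standardisation={})
        p = predict_asps(model, pd.Series(dtype=float))
        assert p == pytest.approx(1.0 / (1.0 + np.exp(3.2)))
        assert p == pytest.approx(0.0392, abs=5e-5)

    def test_zero_intercept_no_features(self):
        model = LogisticModel(intercept=0.0, coefficients={},
                              standardisation={})
        assert predict_asps(model, {}) == pytest.approx(0.5)

    def test_monotone_in_positive_coefficient(self):
        model = LogisticModel(intercept=0.0, coefficients={"f00": 1.5},
                              standardisation={"f00": (0.0, 1.0)})
        xs = np.linspace(-2, 2, 9)
        ps = [predict_asps(model, {"f00": x}) for x in xs]
        assert np.all(np.diff(ps) > 0)

    def test_missing_feature_raises(self):
        model = LogisticModel(intercept=0.0, coefficients={"f00": 1.0},
                              standardisation={"f00": (0.0, 1.0)})
        with pytest.raises(SchemaError):
            predict_asps(model, {"other": 1.0})

    def test_serialisation_round_trip(self, tmp_path):
        ts = make_training_set(n=40, n_features=3, seed=5)
        model = fit_weighted_logistic(ts)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = LogisticModel.load(path)
        assert np.allclose(loaded.predict(ts.features),
                           model.predict(ts.features))


class TestSelectVariables:
    def test_noop_when_target_is_full_size(self):
        ts = make_training_set(n=60, n_features=4, seed=2)
        with pytest.warns(RuntimeWarning):
            model = select_variables(ts, target_size=4)
        assert len(model.coefficients) == 4

    def test_duplicate_feature_eliminated(self):
        ts = make_training_set(n=100, n_features=3, seed=4)
        feats = ts.features.copy()
        feats["f99"] = feats["f00"]  # exact duplicate
        ts2 = TrainingSet(features=feats, labels=ts.labels,
                          weights=ts.weights, source=ts.source)
        model = select_variables(ts2, target_size=3)
        kept = set(model.feature_names)
        assert len(kept & {"f00", "f99"}) <= 1

    def test_true_features_survive_selection(self):
        hits = 0
        n_reps = 50
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            n, p = 2000, 23
            X = rng.standard_normal((n, p))
            beta = np.zeros(p)
            beta[:3] = 1.0
            y = (rng.random(n) < expit(X @ beta)).astype(int)
            names = [f"f{i:02d}" for i in range(p)]
            ts = TrainingSet(
                features=pd.DataFrame(
                    X, columns=names,
                    index=[f"A{i:04d}" for i in range(n)]),
                labels=y, weights=np.ones(n),
                source=np.array(["doping_control"] * n, dtype=object))
            model = select_variables(ts, target_size=3)
            if {"f00", "f01", "f02"} <= set(model.feature_names):
                hits += 1
        assert hits >= int(0.95 * n_reps)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_are_guessing(self):
        assert auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_brute_force_pair_counting(self, rng):
        def brute(scores, labels):
            pos = [s for s, l in zip(scores, labels) if l == 1]
            neg = [s for s, l in zip(scores, labels) if l == 0]
            total = 0.0
            for p in pos:
                for n in neg:
                    total += 1.0 if p > n else (0.5 if p == n else 0.0)
            return total / (len(pos) * len(neg))

        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert auc(scores, labels) == pytest.approx(brute(scores, labels))
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(
                brute(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            auc([0.1, 0.2], [1, 1])

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31),
           a=st.floats(min_value=0.1, max_value=5.0),
           b=st.floats(min_value=-3.0, max_value=3.0))
    def test_invariant_under_monotone_transform(self, seed, a, b):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        transformed = np.exp(a * scores) + b
        assert auc(transformed, labels) == pytest.approx(auc(scores, labels))


class TestCVPlan:
    def test_divisible_case(self):
        ts = make_training_set(n=50, seed=0)
        ts.labels[:] = 0
        ts.labels[:10] = 1
        plan = make_cv_plan(ts, K=5, seed=0)
        for k in range(5):
            fold = plan.fold_ids(k)
            fold_labels = [ts.labels[list(ts.athlete_ids).index(a)]
                           for a in fold]
            assert sum(fold_labels) == 2
            assert len(fold) == 10

    def test_remainder_rule(self):
        ts = make_training_set(n=44, seed=0)
        ts.labels[:] = 0
        ts.labels[:11] = 1
        plan = make_cv_plan(ts, K=5, seed=3)
        counts = sorted(
            sum(1 for a in plan.fold_ids(k)
                if ts.labels[list(ts.athlete_ids).index(a)] == 1)
            for k in range(5))
        assert counts == [2, 2, 2, 2, 3]

    def test_determinism(self):
        ts = make_training_set(n=40, seed=0)
        ts.labels[:8] = 1
        assert make_cv_plan(ts, K=4, seed=9).assignment == \
            make_cv_plan(ts, K=4, seed=9).assignment

    def test_too_few_positives(self):
        ts = make_training_set(n=30, seed=0)
        ts.labels[:] = 0
        ts.labels[:2] = 1
        with pytest.raises(PlanError):
            make_cv_plan(ts, K=5, seed=0)

    def test_laboratory_excluded_from_folds(self):
        ts = make_training_set(n=40, seed=0, lab_frac=0.25)
        ts.labels[:] = 0
        ts.labels[-10:] = 1
        plan = make_cv_plan(ts, K=5, seed=0)
        lab_ids = set(ts.athlete_ids[ts.source == "laboratory"])
        assert not lab_ids & set(plan.assignment)


class TestCrossValidation:
    def test_leave_one_out_coverage(self):
        ts = make_training_set(n=12, n_features=2, seed=8)
        ts.labels[:] = 0
        ts.labels[:6] = 1
        plan = make_cv_plan(ts, K=6, seed=0)
        scores = cross_validated_scores(ts, plan)
        assert set(scores.index) == set(ts.athlete_ids)
        assert scores.notna().all()

    def test_laboratory_athletes_never_scored(self):
        ts = make_training_set(n=40, n_features=3, seed=8, lab_frac=0.2)
        ts.labels[: int(0.2 * 40)] = 1  # lab athletes doped
        ts.labels[-10:] = 1
        plan = make_cv_plan(ts, K=5, seed=0)
        scores = cross_validated_scores(ts, plan)
        lab_ids = set(ts.athlete_ids[ts.source == "laboratory"])
        assert not lab_ids & set(scores.index)

    def test_strong_signal_gives_high_auc(self):
        beta = np.array([2.5, 2.5, 0.0])
        ts = make_training_set(n=300, n_features=3, seed=21, beta=beta)
        plan = make_cv_plan(ts, K=5, seed=0)
        assert cv_auc(ts, plan) > 0.9


class TestMaxScore:
    def test_examples(self):
        scores = max_score_per_athlete([0.2, 0.9, 0.4], ["a", "a", "a"])
        assert scores["a"] == pytest.approx(0.9)
        single = max_score_per_athlete([0.3], ["b"])
        assert single["b"] == pytest.approx(0.3)

    def test_adding_occasion_monotone(self):
        base = max_score_per_athlete([0.2, 0.4], ["a", "a"])["a"]
        more = max_score_per_athlete([0.2, 0.4, 0.1], ["a", "a", "a"])["a"]
        assert more >= base
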