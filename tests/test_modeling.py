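"""Classifier bank: standardization, RFECV, grids, thresholds, stacking."""

import numpy as np
import pandas as pd
import pytest

from comos import modeling as md
from comos.evaluation import auc


def table_from(x, prefix="f"):
    x = np.atleast_2d(x)
    return pd.DataFrame(x, index=[f"s{i}" for i in range(x.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(x.shape[1])])


class TestStandardizer:
    def test_two_point_column(self):
        std = md.fit_standardizer(table_from([[1.0], [3.0]]))
        out = std.transform(table_from([[1.0], [3.0]]))
        np.testing.assert_allclose(out.to_numpy().ravel(), [-1.0, 1.0])

    def test_constant_column_flagged_and_centered(self):
        std = md.fit_standardizer(table_from([[5.0], [5.0], [5.0]]))
        assert std.degenerate == ["f0"]
        out = std.transform(table_from([[5.0], [6.0]]))
        np.testing.assert_allclose(out.to_numpy().ravel(), [0.0, 1.0])

    def test_train_moments_zero_one(self, rng):
        train = table_from(rng.normal(7, 3, (50, 6)))
        std = md.fit_standardizer(train)
        z = std.transform(train)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(ddof=0), 1.0, atol=1e-10)


class TestSelectFeatures:
    def test_informative_features_retained_among_noise(self, rng):
        n = 100
        y = rng.integers(0, 2, n)
        informative = np.column_stack([y + 0.3 * rng.normal(size=n),
                                       -y + 0.3 * rng.normal(size=n)])
        noise = rng.normal(size=(n, 20))
        table = table_from(np.column_stack([informative, noise]))
        chosen = md.select_features(table, y, cv_folds=5, seed=42)
        assert {"f0", "f1"} <= set(chosen)

    def test_single_feature_passthrough(self, rng):
        table = table_from(rng.normal(size=(20, 1)))
        y = rng.integers(0, 2, 20)
        assert md.select_features(table, y) == ["f0"]

    def test_deterministic_under_seed(self, rng):
        table = table_from(rng.normal(size=(40, 8)))
        y = np.array([0, 1] * 20)
        assert md.select_features(table, y, seed=42) == md.select_features(table, y, seed=42)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            md.select_features(table_from(rng.normal(size=(10, 3))), np.zeros(10, dtype=int))


class TestTuneAndTrain:
    def test_separable_data_scores_perfectly(self):
        x = np.concatenate([np.full(20, -2.0), np.full(20, 2.0)])[:, None]
        x = x + np.linspace(0, 0.1, 40)[:, None]
        y = np.array([0] * 20 + [1] * 20)
        _, _, cv_auc = md.tune_and_train(table_from(x), y, "logistic_regression",
                                         {"C": [1.0]}, cv_folds=5)
        assert cv_auc == 1.0

    def test_label_permuted_data_near_chance(self, rng):
        x = rng.normal(size=(100, 3))
        y = rng.permutation([0, 1] * 50)
        _, _, cv_auc = md.tune_and_train(table_from(x), y, "logistic_regression",
                                         {"C": [1.0]}, cv_folds=10, seed=42)
        assert 0.35 <= cv_auc <= 0.65

    def test_grid_of_size_one_returned(self, rng):
        x = rng.normal(size=(30, 2))
        y = np.array([0, 1] * 15)
        _, params, _ = md.tune_and_train(table_from(x), y, "random_forest",
                                         {"n_estimators": [17]}, cv_folds=3)
        assert params == {"n_estimators": 17}

    def test_invalid_grid_entry_rejected(self, rng):
        with pytest.raises(ValueError, match="invalid grid"):
            md.tune_and_train(table_from(rng.normal(size=(10, 2))), np.array([0, 1] * 5),
                              "logistic_regression", {"bogus_knob": [1]})

    def test_full_default_grids_run_on_small_case(self, rng):
        # full default grids on a tiny separable problem, all three families
        x = np.concatenate([rng.normal(-1, 0.5, (10, 2)), rng.normal(1, 0.5, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        grids = md.default_grids()
        for family in md.FAMILY_ORDER:
            est, params, cv_auc = md.tune_and_train(table_from(x), y, family,
                                                    grids[family], cv_folds=2)
            assert cv_auc > 0.8
            assert set(params) <= set(grids[family])


class TestPickBestFamily:
    def test_argmax(self):
        cands = {"logistic_regression": (None, {}, 0.8),
                 "random_forest": (None, {}, 0.9),
                 "adaboost": (None, {}, 0.85)}
        assert md.pick_best_family(cands) == "random_forest"

    def test_tie_goes_to_fixed_order(self):
        cands = {"logistic_regression": (None, {}, 0.9),
                 "random_forest": (None, {}, 0.9),
                 "adaboost": (None, {}, 0.9)}
        assert md.pick_best_family(cands) == "logistic_regression"

    def test_choice_matches_independent_rescoring(self, rng):
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        x = np.column_stack([rng.normal(size=60) + np.repeat([0, 1.5], 30),
                             rng.normal(size=60)])
        y = np.repeat([0, 1], 30)
        table = table_from(x)
        cands = {}
        for family in md.FAMILY_ORDER:
            grid = {k: [v[0]] for k, v in md.fast_grids()[family].items()}
            cands[family] = md.tune_and_train(table, y, family, grid, cv_folds=5, seed=42)
        best = md.pick_best_family(cands)
        # oracle: recompute each family's CV AUC from scratch
        rescored = {}
        for family in md.FAMILY_ORDER:
            est = md._make_estimator(family, 42)
            est.set_params(**cands[family][1])
            cv = StratifiedKFold(5, shuffle=True, random_state=42)
            rescored[family] = cross_val_score(est, x, y, scoring="roc_auc", cv=cv).mean()
        assert rescored[best] == pytest.approx(max(rescored.values()))


class TestCalibrateThreshold:
    def test_easy_negatives_keep_initial_threshold(self):
        probs = np.array([0.1, 0.2, 0.4, 0.9, 0.95])
        y = np.array([0, 0, 0, 1, 1])
        assert md.calibrate_threshold(probs, y) == 0.5

    def test_hand_enumerated_grid(self):
        probs = np.array([0.2, 0.6, 0.9, 0.95, 0.99])
        y = np.array([0, 0, 0, 1, 1])
        # negatives {0.2, 0.6, 0.9}; first grid point with all below is 0.91
        assert md.calibrate_threshold(probs, y, target_specificity=1.0) == pytest.approx(0.91)

    def test_unreachable_target_returns_argmax(self, caplog):
        probs = np.array([0.995, 0.2, 0.9])
        y = np.array([0, 0, 1])
        t = md.calibrate_threshold(probs, y, target_specificity=1.0)
        specs = [(probs[:2] < g).mean() for g in np.round(np.arange(0.5, 1.0, 0.01), 10)]
        assert (probs[:2] < t).mean() == max(specs)

    def test_postcondition_on_random_scores(self, rng):
        for _ in range(20):
            probs = rng.random(30)
            y = rng.integers(0, 2, 30)
            y[0] = 0
            t = md.calibrate_threshold(probs, y, target_specificity=0.99)
            neg = probs[y == 0]
            spec = (neg < t).mean()
            grid = np.round(np.arange(0.5, 1.0, 0.01), 10)
            best = max((neg < g).mean() for g in grid)
            assert spec >= 0.99 or spec == best

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            md.calibrate_threshold(np.array([0.5]), np.array([1]))


class TestLabels:
    def test_group_encodings(self):
        np.testing.assert_array_equal(md.encode_labels(["control", "case"]), [0, 1])
        np.testing.assert_array_equal(md.encode_labels(["PRCR", "PDSD"]), [0, 1])
        with pytest.raises(ValueError, match="unknown group"):
            md.encode_labels(["healthy"])


def make_model(rng, n_per_split=12, informative=("FSR",), task="early_dx", n_features=4):
    """Small multi-omics problem with chosen informative layers."""
    ids = [f"s{i}" for i in range(2 * n_per_split)]
    groups = ["control", "case"] * n_per_split
    splits = ["train"] * n_per_split + ["validation"] * n_per_split
    y = np.array([g == "case" for g in groups], dtype=float)
    tables = {}
    for omics in md.OMICS_ORDER:
        x = rng.normal(size=(len(ids), n_features))
        if omics in informative:
            x[:, 0] += 3 * y
        tables[omics] = pd.DataFrame(x, index=ids,
                                     columns=[f"{omics}_f{j}" for j in range(n_features)])
    samples = pd.DataFrame({"sample_id": ids, "group": groups, "split": splits})
    config = md.ModelConfig(cv_folds=5, grids=md.fast_grids())
    return md.ComosModel(tables, samples, task=task, config=config)


@pytest.fixture(scope="module")
def default_model():
    return make_model(np.random.default_rng(77), n_per_split=10, n_features=3)


@pytest.fixture(scope="module")
def default_results(default_model):
    return default_model.fit()


class TestComosModel:
    def test_stacked_input_has_seven_columns_in_fixed_order(self, default_model,
                                                            default_results):
        probs = default_results.omics_probabilities(default_model.train_ids)
        assert list(probs.columns) == list(md.OMICS_ORDER)
        assert probs.shape == (len(default_model.train_ids), 7)

    def test_identical_perfectly_separating_omics_stack_to_auc_one(self, rng):
        model = make_model(rng, n_per_split=10, informative=md.OMICS_ORDER, n_features=3)
        results = model.fit()
        val = results.predict(model.validation_ids)
        y = model.labels.loc[model.validation_ids].to_numpy()
        assert auc(val["probability"].to_numpy(), y) == 1.0

    def test_stack_tracks_single_informative_omics(self, rng):
        model = make_model(rng, n_per_split=20, informative=("CNA",), n_features=3)
        results = model.fit()
        y = model.labels.loc[model.validation_ids].to_numpy()
        probs = results.omics_probabilities(model.validation_ids)
        cna_auc = auc(probs["CNA"].to_numpy(), y)
        stack_auc = auc(results.stacked.predict_proba(probs).to_numpy(), y)
        assert stack_auc >= cna_auc - 0.05

    def test_treatment_task_uses_five_tree_integrator(self, rng, default_results):
        model = make_model(rng, n_per_split=8, task="treatment", n_features=2)
        results = model.fit()
        assert results.stacked.classifier.n_estimators == 5
        assert default_results.stacked.classifier.n_estimators == 100

    def test_full_determinism_across_runs(self, default_model, default_results):
        b = default_model.fit()
        a = default_results
        pd.testing.assert_frame_equal(a.predict(), b.predict())
        assert a.stacked.threshold == b.stacked.threshold
        for omics in md.OMICS_ORDER:
            assert a.omics_models[omics].features == b.omics_models[omics].features
            assert a.omics_models[omics].hyperparameters == b.omics_models[omics].hyperparameters
            assert a.omics_models[omics].threshold == b.omics_models[omics].threshold

    def test_predict_empty_and_call_replay(self, default_model, default_results):
        assert default_results.predict([]).empty
        preds = default_results.predict(default_model.validation_ids)
        replay = (preds["probability"] >= default_results.stacked.threshold).astype(int)
        np.testing.assert_array_equal(preds["call"].to_numpy(), replay.to_numpy())

    def test_unknown_feature_columns_rejected(self, default_model, default_results):
        bad = default_model.feature_tables["FSR"].rename(columns={"FSR_f0": "mystery"})
        with pytest.raises(ValueError, match="lacks trained features"):
            default_results.omics_models["FSR"].predict_proba(bad)

    def test_unknown_task_and_omics_rejected(self, rng):
        with pytest.raises(ValueError, match="task"):
            make_model(rng, task="prognosis")
        samples = pd.DataFrame({"sample_id": ["a", "b"], "group": ["case", "control"],
                                "split": ["train", "train"]})
        with pytest.raises(ValueError, match="unknown omics"):
            md.ComosModel({"XXX": pd.DataFrame(index=["a", "b"])}, samples)
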