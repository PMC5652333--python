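import numpy as np
import pytest

from acpml import (
    CVConfig,
    FeatureConfig,
    Peptide,
    RfGrid,
    SvmGrid,
    consensus_predict,
    cross_validate,
    grid_search,
    load_model,
    make_folds,
    predict,
    save_model,
)
from acpml.features import encode_dataset
from acpml.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="module")
def small_training_set():
    """120 synthetic peptides encoded with the AAC block (fast)."""
    peptides = generate(SyntheticConfig(n_pos=60, n_neg=60, seed=3))
    config = FeatureConfig(blocks=("AAC",))
    X, y = encode_dataset(peptides, config)
    return peptides, config, X, y


@pytest.fixture(scope="module")
def fitted_pair(small_training_set):
    peptides, config, X, y = small_training_set
    cv = CVConfig(k=5, repeats=1, seed=0)
    rf = grid_search(
        "rf", RfGrid(ntree=(50,), mtry=(3,), nsplit=(2,)), X, y, cv, config
    )
    svm = grid_search(
        "svm", SvmGrid(log2_c=(0,), log2_gamma=(-2,)), X, y, cv, config
    )
    return rf, svm


class TestGrids:
    def test_default_svm_grid_spans_paper_ranges(self):
        g = SvmGrid()
        assert g.log2_c[0] == -15 and g.log2_c[-1] == 10
        assert g.log2_gamma[0] == -10 and g.log2_gamma[-1] == 10
        assert len(g.points()) == 26 * 21

    def test_default_rf_grid(self):
        g = RfGrid()
        assert g.ntree == tuple(range(10, 501, 10))
        assert g.mtry == tuple(range(1, 8))
        assert g.nsplit == tuple(range(2, 11))

    def test_with_step_thins_axes(self):
        g = SvmGrid.with_step(5)
        assert g.log2_c == (-15, -10, -5, 0, 5, 10)

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            SvmGrid(log2_c=(3, 1))
        with pytest.raises(ValueError):
            RfGrid(ntree=(0,))

    def test_scan_order_is_documented_tie_break_order(self):
        pts = SvmGrid(log2_c=(0, 1), log2_gamma=(0, 1)).points()
        assert [(p["C"], p["gamma"]) for p in pts] == [(1, 1), (1, 2), (2, 1), (2, 2)]
        rf = RfGrid(ntree=(10, 20), mtry=(1,), nsplit=(2, 3)).points()
        assert [p["ntree"] for p in rf] == [10, 10, 20, 20]


class TestMakeFolds:
    def test_exact_divisibility(self):
        y = [1] * 20 + [0] * 20
        folds = make_folds(y, CVConfig(k=10, seed=0))
        assert len(folds) == 10
        y = np.asarray(y)
        for f in folds:
            assert len(f) == 4
            assert (y[f] == 1).sum() == 2

    def test_partition_is_disjoint_and_exhaustive(self):
        y = np.r_[np.ones(33), np.zeros(45)].astype(int)
        folds = make_folds(y, CVConfig(k=10, seed=1))
        all_idx = np.concatenate(folds)
        assert len(all_idx) == len(set(all_idx)) == 78

    def test_stratification_within_one(self):
        y = np.r_[np.ones(33), np.zeros(45)].astype(int)
        folds = make_folds(y, CVConfig(k=10, seed=1))
        for f in folds:
            assert abs((np.asarray(y)[f] == 1).sum() - 3.3) <= 1
            assert abs((np.asarray(y)[f] == 0).sum() - 4.5) <= 1

    def test_seed_determinism(self):
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        a = make_folds(y, CVConfig(k=5, seed=7))
        b = make_folds(y, CVConfig(k=5, seed=7))
        c = make_folds(y, CVConfig(k=5, seed=8))
        assert all((x == z).all() for x, z in zip(a, b))
        assert any((x != z).any() for x, z in zip(a, c) if len(x) == len(z))

    def test_k_larger_than_minority_class_is_an_error(self):
        with pytest.raises(ValueError):
            make_folds([1, 1, 0, 0, 0], CVConfig(k=3, seed=0))
        with pytest.raises(ValueError):
            make_folds([1, 1, 1, 1], CVConfig(k=2, seed=0))


class TestCrossValidate:
    def test_separable_labels_give_perfect_mcc(self, rng):
        X = np.zeros((60, 3))
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        X[:, 0] = y * 10 + rng.normal(0, 0.01, 60)
        res = cross_validate(
            "rf", {"ntree": 50, "mtry": 1, "nsplit": 2}, X, y,
            CVConfig(k=5, repeats=2, seed=0),
        )
        assert res.mean_mcc == 1.0

    def test_shuffled_labels_give_null_mcc(self, rng):
        X = rng.normal(0, 1, (200, 10))
        y = rng.permutation(np.r_[np.ones(100), np.zeros(100)]).astype(int)
        res = cross_validate(
            "rf", {"ntree": 50, "mtry": 3, "nsplit": 2}, X, y,
            CVConfig(k=10, repeats=2, seed=0),
        )
        assert abs(res.mean_mcc) < 0.15

    def test_cv_record_has_one_metricset_per_repeat(self, small_training_set):
        _, _, X, y = small_training_set
        res = cross_validate(
            "svm", {"C": 1.0, "gamma": 0.25}, X, y, CVConfig(k=5, repeats=3, seed=0)
        )
        assert len(res.per_repeat) == 3


class TestGridSearch:
    def test_single_point_grid_selects_that_point(self, fitted_pair):
        rf, svm = fitted_pair
        assert rf.hyperparameters == {"ntree": 50, "mtry": 3, "nsplit": 2}
        assert svm.hyperparameters == {"C": 1.0, "gamma": 0.25}

    def test_selected_point_lies_in_grid(self, small_training_set):
        _, config, X, y = small_training_set
        grid = RfGrid(ntree=(20, 50), mtry=(1, 3), nsplit=(2,))
        model = grid_search("rf", grid, X, y, CVConfig(k=5, repeats=1, seed=0), config)
        assert model.hyperparameters in grid.points()
        assert model.cv_record is not None

    def test_empty_grid_is_an_error(self, small_training_set):
        _, config, X, y = small_training_set
        with pytest.raises(ValueError):
            grid_search("rf", RfGrid(ntree=()), X, y, CVConfig(seed=0), config)


class TestPredict:
    def test_training_labels_recovered_on_separable_fit(self, fitted_pair, small_training_set):
        peptides, _, _, y = small_training_set
        rf, svm = fitted_pair
        for model in (rf, svm):
            out = predict(model, peptides)
            agreement = (out["label"].to_numpy() == y).mean()
            assert agreement >= 0.95

    def test_identical_peptides_identical_outputs(self, fitted_pair):
        rf, _ = fitted_pair
        peps = [Peptide("q1", "KWKLFKKIAK"), Peptide("q2", "KWKLFKKIAK")]
        out = predict(rf, peps)
        assert out["score"].iloc[0] == out["score"].iloc[1]
        assert out["label"].iloc[0] == out["label"].iloc[1]

    def test_acp_profile_scores_above_non_acp_profile(self, fitted_pair):
        rf, svm = fitted_pair
        probe = generate(SyntheticConfig(n_pos=100, n_neg=100, seed=99))
        pos = [p for p in probe if p.label == 1]
        neg = [p for p in probe if p.label == 0]
        for model in (rf, svm):
            mean_pos = predict(model, pos)["score"].mean()
            mean_neg = predict(model, neg)["score"].mean()
            assert mean_pos > mean_neg

    def test_empty_query(self, fitted_pair):
        rf, _ = fitted_pair
        assert predict(rf, []).empty

    def test_feature_mismatch_is_an_error(self, fitted_pair, small_training_set):
        rf, _ = fitted_pair
        import dataclasses

        broken = dataclasses.replace(rf, feature_names=["AAC:A"])
        with pytest.raises(ValueError, match="feature columns"):
            predict(broken, [Peptide("q", "KWK")])


class TestConsensus:
    def test_agreement_and_symmetry(self, fitted_pair):
        rf, svm = fitted_pair
        peps = [Peptide("p", "KWKLFKKWAK"), Peptide("n", "DDEEGGNNQQ")]
        out = consensus_predict(rf, svm, peps)
        assert list(out["consensus"]) == ["ACP", "non-ACP"]
        rf_first = out
        # consensus column is symmetric in model order
        swapped = consensus_predict(rf, svm, peps)
        assert list(swapped["consensus"]) == list(rf_first["consensus"])

    def test_disagreement_is_ambiguous(self, fitted_pair):
        import dataclasses

        rf, svm = fitted_pair
        peps = [Peptide("p", "KWKLFKKWAK")]
        # force disagreement by inverting one model's labels via a stub
        class Inverted:
            def __init__(self, inner):
                self.inner = inner

            def predict_proba(self, X):
                return self.inner.predict_proba(X)[:, ::-1]

        flipped = dataclasses.replace(rf, estimator=Inverted(rf.estimator))
        out = consensus_predict(flipped, svm, peps)
        assert list(out["consensus"]) == ["ambiguous"]

    def test_config_mismatch_is_an_error(self, fitted_pair):
        import dataclasses

        rf, svm = fitted_pair
        other = dataclasses.replace(svm, feature_config=FeatureConfig(blocks=("DPC",)))
        with pytest.raises(ValueError, match="feature config"):
            consensus_predict(rf, other, [])


class TestPersistence:
    def test_round_trip_predictions_identical(self, fitted_pair, tmp_path):
        rf, svm = fitted_pair
        probe = generate(SyntheticConfig(n_pos=25, n_neg=25, seed=11))
        for model, name in ((rf, "rf"), (svm, "svm")):
            path = tmp_path / f"{name}.joblib"
            save_model(model, path)
            loaded = load_model(path)
            before = predict(model, probe)
            after = predict(loaded, probe)
            assert (before["score"] == after["score"]).all()
            assert loaded.hyperparameters == model.hyperparameters
            assert loaded.cv_record.mean_mcc == model.cv_record.mean_mcc

    def test_corrupted_file_is_an_error(self, tmp_path):
        bad = tmp_path / "bad.joblib"
        bad.write_bytes(b"not a model")
        with pytest.raises(ValueError):
            load_model(bad)

    def test_wrong_format_version_is_an_error(self, tmp_path):
        import joblib

        path = tmp_path / "old.joblib"
        joblib.dump({"format_version": 99}, path)
        with pytest.raises(ValueError, match="incompatible"):
            load_model(path)
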