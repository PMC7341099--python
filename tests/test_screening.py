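import numpy as np
import pandas as pd
import pytest

from loopscreen.screening import (
    RF_HYPERPARAMETERS,
    DatasetError,
    SchemaError,
    build_dataset,
    build_estimator,
    compare_models,
    default_model_specs,
    feature_importance,
    load_interaction_table,
    load_model,
    predict_scores,
    rf_spec,
    save_model,
    split_dataset,
    train_model,
)
from loopscreen.synthetic import GeneratorConfig, generate_interaction_table

SMALL = dict(n_rna=24, n_molecules=24, n_positive=40, n_classes=12)


def _table(strength=1.0, seed=0, **kw):
    cfg = GeneratorConfig(motif_strength=strength, seed=seed, **{**SMALL, **kw})
    table, truth = generate_interaction_table(cfg)
    return table, truth


def _dataset(strength=1.0, seed=0, split=True):
    table, _ = _table(strength, seed)
    curated, _ = load_interaction_table(table)
    ds = build_dataset(curated, seed=seed)
    if split:
        split_dataset(ds, seed=seed)
    return ds


class TestCuration:
    def test_invalid_rows_removed_and_logged(self):
        table, truth = _table(seed=2, n_positive=10, invalid_smiles_fraction=0.2,
                              invalid_sequence_fraction=0.1)
        curated, log = load_interaction_table(table)
        assert len(curated) == 7
        assert sorted(log["row"]) == sorted(
            truth["corrupt_smiles_rows"] + truth["corrupt_sequence_rows"]
        )
        assert set(log["reason"]) == {"invalid_smiles", "invalid_sequence"}

    def test_empty_table_rejected(self):
        empty = pd.DataFrame(
            columns=["rna_id", "rna_sequence", "molecule_id", "smiles", "label"]
        )
        with pytest.raises(SchemaError):
            load_interaction_table(empty)

    def test_missing_columns_rejected(self):
        with pytest.raises(SchemaError, match="missing"):
            load_interaction_table(pd.DataFrame({"rna_id": ["a"]}))


class TestBuildDataset:
    def test_exact_negative_ratio_and_disjointness(self):
        table, _ = _table(seed=3)
        curated, _ = load_interaction_table(table)
        ds = build_dataset(curated, neg_ratio=3, seed=3)
        assert int(ds.y.sum()) == 40
        assert len(ds.y) == 160
        pos = set(
            zip(ds.records[ds.y == 1]["rna_id"], ds.records[ds.y == 1]["molecule_id"])
        )
        neg = set(
            zip(ds.records[ds.y == 0]["rna_id"], ds.records[ds.y == 0]["molecule_id"])
        )
        assert pos.isdisjoint(neg)
        assert len(neg) == 120  # sampled without replacement

    def test_zero_ratio_gives_positives_only(self):
        table, _ = _table(seed=3)
        curated, _ = load_interaction_table(table)
        ds = build_dataset(curated, neg_ratio=0, seed=3)
        assert ds.y.all()

    def test_seed_reproducibility(self):
        a, b = _dataset(seed=4, split=False), _dataset(seed=4, split=False)
        assert a.records.equals(b.records)
        assert np.array_equal(a.X, b.X)

    def test_infeasible_ratio_reports_maximum(self):
        table, _ = _table(seed=5, n_rna=4, n_molecules=4, n_positive=12)
        curated, _ = load_interaction_table(table)
        with pytest.raises(DatasetError, match="maximum feasible ratio"):
            build_dataset(curated, neg_ratio=3, seed=5)

    def test_feature_matrix_width(self):
        ds = _dataset(seed=3, split=False)
        assert ds.X.shape == (160, 1250)


class TestSplit:
    def test_four_fifths_train(self):
        ds = _dataset(seed=6)
        assert len(ds.train_indices) == 128
        assert len(ds.test_indices) == 32
        assert set(ds.train_indices).isdisjoint(ds.test_indices)

    def test_stratified_within_one_record(self):
        ds = _dataset(seed=6)
        global_rate = ds.y.mean()
        train_rate = ds.y[ds.train_indices].mean()
        assert abs(train_rate - global_rate) * len(ds.train_indices) <= 1.0

    def test_split_deterministic(self):
        a, b = _dataset(seed=7), _dataset(seed=7)
        assert np.array_equal(a.split, b.split)

    def test_tiny_dataset_rejected(self):
        ds = _dataset(seed=6)
        ds.X, ds.y = ds.X[:4], ds.y[:4]
        ds.records = ds.records.iloc[:4]
        with pytest.raises(DatasetError):
            split_dataset(ds)


class TestModelProtocol:
    def test_rf_defaults_reproduce_printed_hyperparameters(self):
        spec = rf_spec()
        assert spec.hyperparameters["criterion"] == "entropy"
        assert spec.hyperparameters["n_estimators"] == 200
        assert spec.hyperparameters["random_state"] == 100
        assert spec.hyperparameters["min_samples_leaf"] == 1
        assert spec.hyperparameters["min_samples_split"] == 2
        assert spec.hyperparameters["bootstrap"] is True
        assert spec.hyperparameters["max_features"] == "auto"
        est = build_estimator(spec)
        assert est.criterion == "entropy"
        assert est.n_estimators == 200
        assert est.random_state == 100
        assert est.max_features == "sqrt"  # the classical reading of "auto"

    def test_seven_families_available(self):
        specs = default_model_specs()
        assert len(specs) == 7
        for spec in specs:
            build_estimator(spec)  # constructible

    def test_selection_flag_matches_fold_table(self):
        ds = _dataset(seed=8)
        comp = compare_models(ds, specs=[rf_spec()], k=5, seed=8)
        row = comp.table.iloc[0]
        folds = comp.fold_metrics
        acc = folds["accuracy"].to_numpy()
        auc = folds["roc_auc"].to_numpy()
        assert row["mean_accuracy"] == pytest.approx(acc.mean())
        assert row["std_accuracy"] == pytest.approx(acc.std())
        expected = (
            acc.mean() > 0.8 and acc.std() < 0.2 and auc.mean() > 0.8 and auc.std() < 0.2
        )
        assert bool(row["selected"]) == expected

    def test_failing_family_recorded_not_dropped(self):
        from loopscreen.screening import ModelSpec

        ds = _dataset(seed=8)
        bad = ModelSpec(family="k_nearest_neighbors", hyperparameters={"n_neighbors": 10**6})
        comp = compare_models(ds, specs=[bad], k=5, seed=8)
        assert bool(comp.table.iloc[0]["failed"])

    def test_oversized_k_rejected(self):
        ds = _dataset(seed=8)
        with pytest.raises(DatasetError):
            compare_models(ds, k=1000, seed=8)


class TestTrainPredict:
    def test_training_deterministic_under_spec_seed(self):
        ds = _dataset(seed=9)
        p1 = train_model(ds, rf_spec()).estimator.predict_proba(ds.X)[:, 1]
        p2 = train_model(ds, rf_spec()).estimator.predict_proba(ds.X)[:, 1]
        assert np.array_equal(p1, p2)

    def test_save_load_round_trip(self, tmp_path):
        ds = _dataset(seed=9)
        artifact = train_model(ds, rf_spec())
        path = tmp_path / "model.joblib"
        save_model(artifact, path)
        back = load_model(path)
        assert back.spec == artifact.spec
        assert back.manifest.names == artifact.manifest.names
        a = artifact.estimator.predict_proba(ds.X)[:, 1]
        b = back.estimator.predict_proba(ds.X)[:, 1]
        assert np.array_equal(a, b)

    def test_training_positives_outscore_negative_median(self):
        ds = _dataset(seed=9)
        artifact = train_model(ds, rf_spec())
        train_pos = ds.records.iloc[[i for i in ds.train_indices if ds.y[i] == 1]]
        scored = predict_scores(artifact, train_pos.head(5))
        train_probs = artifact.estimator.predict_proba(ds.X[ds.train_indices])[:, 1]
        median_neg = np.median(train_probs[ds.y[ds.train_indices] == 0])
        assert (scored["probability"] > median_neg).all()

    def test_ranking_deterministic_tie_break_on_id(self):
        ds = _dataset(seed=9)
        artifact = train_model(ds, rf_spec())
        cands = ds.records.head(1)
        repeated = pd.concat([cands] * 4, ignore_index=True)
        repeated["molecule_id"] = ["M4", "M2", "M3", "M1"]
        scored = predict_scores(artifact, repeated)
        assert list(scored["molecule_id"]) == ["M1", "M2", "M3", "M4"]

    def test_candidate_schema_enforced(self):
        ds = _dataset(seed=9)
        artifact = train_model(ds, rf_spec())
        with pytest.raises(SchemaError):
            predict_scores(artifact, pd.DataFrame({"molecule_id": ["a"]}))


class TestImportances:
    def test_importances_normalized_with_category_shares(self):
        ds = _dataset(seed=10)
        rep = feature_importance(train_model(ds, rf_spec()))
        assert rep.table["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert set(rep.category_share) <= {"rna", "molecule"}
        assert sum(rep.category_share.values()) == pytest.approx(1.0, abs=1e-9)
        assert rep.n_above_threshold == int(
            (rep.table["importance"] > 0.001).sum()
        )

    def test_single_bit_label_dominates(self):
        # plant a label that depends on exactly one fingerprint bit
        ds = _dataset(seed=10, split=False)
        rng = np.random.default_rng(0)
        bit_values = ds.X[:, 226:]
        candidates = [
            b for b in range(bit_values.shape[1])
            if 0.3 < bit_values[:, b].mean() < 0.7
        ]
        bit = candidates[0]
        ds.y = bit_values[:, bit].astype(int)
        rep = feature_importance(train_model(ds, rf_spec()))
        # bits colinear with the planted one are indistinguishable carriers
        twins = {
            f"fp_bit_{b}"
            for b in range(bit_values.shape[1])
            if np.array_equal(bit_values[:, b], bit_values[:, bit])
        }
        assert rep.table.iloc[0]["feature"] in twins

    def test_families_without_importances_rejected(self):
        from loopscreen.screening import ModelSpec

        ds = _dataset(seed=10)
        artifact = train_model(ds, ModelSpec(family="naive_bayes"))
        with pytest.raises(ValueError):
            feature_importance(artifact)
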