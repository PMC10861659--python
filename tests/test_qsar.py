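"""Descriptors, useless-feature filter, forest training, CV, AD, screening."""

import numpy as np
import pandas as pd
import pytest

import hairscreen as hs
from hairscreen.descriptors import DESCRIPTOR_FAMILY, DescriptorTable
from hairscreen.qsar import DEFAULT_FOREST_SPEC


@pytest.fixture(scope="module")
def table(panel):
    return hs.build_descriptor_table(panel)


@pytest.fixture(scope="module")
def labels(panel):
    return {r.name: r.hair_label for r in panel}


@pytest.fixture(scope="module")
def model(table, labels):
    return hs.train_model(hs.remove_useless(table), labels)


SMALL_FOREST = {"n_trees": 25}


class TestDescriptorTable:
    def test_panel_table_shape(self, table):
        assert len(table.substances) == 17
        assert len(table.feature_names) >= 5
        assert not table.values.isna().any().any()
        assert table.excluded == ()

    def test_empty_substance_list(self):
        t = hs.build_descriptor_table([])
        assert t.substances == []

    def test_unparseable_structure_excluded_with_log(self, caplog):
        bad = hs.SubstanceRecord(
            name="broken", wada_class="S5", smiles="not-a-structure", logp=0.0,
            hair_label="unknown", matrix_detected={},
        )
        with caplog.at_level("WARNING"):
            t = hs.build_descriptor_table([bad])
        assert t.excluded == ("broken",)
        assert "broken" in caplog.text

    def test_external_csv_passthrough_bit_exact(self, table, tmp_path):
        path = tmp_path / "desc.csv"
        table.values.to_csv(path)
        loaded = hs.build_descriptor_table(descriptor_csv=path)
        assert loaded.provenance == "supplied"
        np.testing.assert_array_equal(
            loaded.values.to_numpy(), table.values.to_numpy()
        )

    def test_family_is_lipophilicity_charge_mass(self, table):
        assert set(table.feature_names) == set(DESCRIPTOR_FAMILY)


class TestUselessFeatureFilter:
    @staticmethod
    def _toy(n=17):
        rng = np.random.default_rng(3)
        return pd.DataFrame(
            {
                "logp": rng.normal(2, 1, n),
                "constant": np.full(n, 7.25),
                "near_constant": 7.25 + 1e-15 * rng.normal(size=n),
                "binary": rng.integers(0, 2, n).astype(float),
                "row_id": [f"cmpd{i}" for i in range(n)],  # one value per row
                "category": ["acid" if i % 2 else "base" for i in range(n)],
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_constant_numeric_removed(self):
        kept = hs.UselessFeatureFilter().fit(self._toy()).retained_features_
        assert "constant" not in kept and "near_constant" not in kept

    def test_identifier_like_categorical_removed(self):
        """17 distinct values in 17 rows exceeds 99% of the row count."""
        kept = hs.UselessFeatureFilter().fit(self._toy()).retained_features_
        assert "row_id" not in kept
        assert "category" in kept

    def test_two_valued_numeric_retained(self):
        kept = hs.UselessFeatureFilter().fit(self._toy()).retained_features_
        assert "binary" in kept and "logp" in kept

    def test_idempotent(self, table):
        once = hs.remove_useless(table)
        twice = hs.remove_useless(once)
        assert once.feature_names == twice.feature_names
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_order_preserved(self):
        kept = hs.UselessFeatureFilter().fit(self._toy()).retained_features_
        cols = [c for c in self._toy().columns if c in kept]
        assert kept == cols

    def test_all_removed_is_error(self):
        frame = pd.DataFrame({"c": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="all features removed"):
            hs.UselessFeatureFilter().fit(frame)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            hs.UselessFeatureFilter(threshold=0.0).fit(self._toy())


class TestTrainModel:
    def test_panel_training_accuracy_is_perfect(self, model):
        """500 trees on the 17-drug panel separate 14 positives from 3
        negatives with 100% training accuracy."""
        assert model.training_accuracy == 1.0

    def test_two_point_toy_single_tree(self):
        t = DescriptorTable(
            values=pd.DataFrame({"x": [0.0, 10.0]}, index=["a", "b"])
        )
        m = hs.train_model(t, {"a": "negative", "b": "positive"},
                           {"n_trees": 1, "max_features_rule": None,
                            "bootstrap": False})
        assert m.training_accuracy == 1.0

    def test_single_class_rejected(self, table):
        with pytest.raises(ValueError, match="both classes"):
            hs.train_model(table, {s: "positive" for s in table.substances})

    def test_ad_ranges_contain_all_training_values(self, model, table):
        filtered = hs.remove_useless(table)
        for f in model.retained_features:
            lo, hi = model.ad_ranges[f]
            col = filtered.values[f]
            assert (col >= lo).all() and (col <= hi).all()

    def test_ad_keys_match_retained_features(self, model):
        assert set(model.ad_ranges) == set(model.retained_features)


class TestCrossValidate:
    def test_separable_data_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-5, 0.1, 10), rng.normal(5, 0.1, 10)])
        t = DescriptorTable(values=pd.DataFrame({"x": x},
                                                index=[f"s{i}" for i in range(20)]))
        labels = {f"s{i}": ("negative" if i < 10 else "positive") for i in range(20)}
        for seed in (0, 7):
            _, acc, recall = hs.cross_validate(t, labels, k=5, seed=seed,
                                               forest_spec=SMALL_FOREST)
            assert acc == 1.0
            assert recall == {"negative": 1.0, "positive": 1.0}

    def test_same_seed_same_folds(self, table, labels):
        filtered = hs.remove_useless(table)
        f1, _, _ = hs.cross_validate(filtered, labels, seed=4, forest_spec=SMALL_FOREST)
        f2, _, _ = hs.cross_validate(filtered, labels, seed=4, forest_spec=SMALL_FOREST)
        np.testing.assert_array_equal(f1, f2)

    def test_k_larger_than_n_rejected(self, table, labels):
        with pytest.raises(ValueError, match="exceeds"):
            hs.cross_validate(table, labels, k=18)

    def test_folds_are_stratified(self, table, labels):
        filtered = hs.remove_useless(table)
        folds, _, _ = hs.cross_validate(filtered, labels, k=10, seed=4,
                                        forest_spec=SMALL_FOREST)
        y = np.array([labels[s] for s in filtered.substances])
        # 3 negatives in 10 folds: every fold holds 1 or 2 rows, and no fold
        # holds more than one negative
        for f in np.unique(folds):
            mask = folds == f
            assert 1 <= mask.sum() <= 2
            assert (y[mask] == "negative").sum() <= 1

    def test_permuted_labels_recover_majority_rate(self, table):
        """Label-permuted panel: mean CV accuracy sits at the majority-class
        rate (the permutation null for an overfit-prone learner)."""
        filtered = hs.remove_useless(table)
        rng = np.random.default_rng(55)
        names = filtered.substances
        base = np.array(["positive"] * 14 + ["negative"] * 3)
        accs = []
        for seed in range(20):
            perm = {n: l for n, l in zip(names, rng.permutation(base))}
            _, acc, _ = hs.cross_validate(filtered, perm, k=10, seed=seed,
                                          forest_spec=SMALL_FOREST)
            accs.append(acc)
        majority = 14 / 17
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - majority) < max(4 * se, 0.08)


class TestApplicabilityDomain:
    def test_every_training_row_inside(self, model, table):
        filtered = hs.remove_useless(table)
        for _, row in filtered.values.iterrows():
            assert hs.in_domain(model, row.to_dict())

    def test_epsilon_beyond_max_is_outside(self, model, table):
        filtered = hs.remove_useless(table)
        row = filtered.values.iloc[0].to_dict()
        f = model.retained_features[0]
        row[f] = model.ad_ranges[f][1] * (1 + 1e-6) + 1e-9
        assert not hs.in_domain(model, row)

    def test_boundary_value_is_inside(self, model, table):
        filtered = hs.remove_useless(table)
        row = filtered.values.iloc[0].to_dict()
        f = model.retained_features[0]
        row[f] = model.ad_ranges[f][0]
        assert hs.in_domain(model, row)

    def test_missing_feature_is_error(self, model):
        with pytest.raises(ValueError, match="missing feature"):
            hs.in_domain(model, {})

    def test_invariant_under_feature_order(self, model, table):
        filtered = hs.remove_useless(table)
        row = filtered.values.iloc[3]
        forward = hs.in_domain(model, dict(row.items()))
        backward = hs.in_domain(model, dict(reversed(list(row.items()))))
        assert forward == backward


class TestScreen:
    def test_training_set_screens_as_all_in_ad(self, model, table, panel):
        filtered = hs.remove_useless(table)
        results, summary = hs.screen(
            model, filtered, {r.name: r.wada_class for r in panel}
        )
        assert all(r.in_ad for r in results)
        assert summary["detectable"] == 14

    def test_counts_partition(self, model, table):
        filtered = hs.remove_useless(table)
        # push a few substances out of the AD to exercise all three branches
        shifted = filtered.values.copy()
        shifted.iloc[:3] = shifted.iloc[:3] * 1e6
        out_table = DescriptorTable(values=shifted,
                                    feature_kinds=filtered.feature_kinds)
        results, summary = hs.screen(model, out_table)
        assert summary["out_of_domain"] >= 3
        assert (
            summary["detectable"] + summary["undetectable"] + summary["out_of_domain"]
            == summary["n_input"] == len(results)
        )

    def test_out_of_ad_has_no_score(self, model, table):
        filtered = hs.remove_useless(table)
        shifted = filtered.values.copy()
        shifted.iloc[0] = shifted.iloc[0] * 1e6
        results, _ = hs.screen(
            model, DescriptorTable(values=shifted,
                                   feature_kinds=filtered.feature_kinds)
        )
        assert results[0].predicted == "out_of_domain"
        assert results[0].score is None
        assert not results[0].high_confidence

    def test_high_confidence_threshold_is_strict(self, model, table, monkeypatch):
        """A vote fraction of exactly 0.9 is NOT high confidence."""
        filtered = hs.remove_useless(table)
        two = DescriptorTable(values=filtered.values.iloc[:2],
                              feature_kinds=filtered.feature_kinds)
        monkeypatch.setattr(
            model.estimator, "vote_score", lambda X: np.array([0.9, 0.9 + 1e-9])
        )
        results, _ = hs.screen(model, two)
        assert results[0].predicted == "detectable" and not results[0].high_confidence
        assert results[1].high_confidence

    def test_unanimous_vote_is_high_confidence(self, model, table):
        filtered = hs.remove_useless(table)
        results, _ = hs.screen(model, filtered)
        unanimous = [r for r in results if r.score == 1.0]
        assert unanimous and all(r.high_confidence for r in unanimous)

    def test_score_deterministic(self, model, table):
        filtered = hs.remove_useless(table)
        s1 = model.estimator.vote_score(filtered.values)
        s2 = model.estimator.vote_score(filtered.values)
        np.testing.assert_array_equal(s1, s2)

    def test_default_forest_spec(self):
        assert DEFAULT_FOREST_SPEC["n_trees"] == 500
        assert DEFAULT_FOREST_SPEC["max_features_rule"] == "sqrt"
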