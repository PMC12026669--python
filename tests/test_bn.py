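"""Discretization and Bayesian-network classification."""

import numpy as np
import pandas as pd
import pytest

from kinchain import bn


def make_table(n_per_class, means, seed=0, classes=None, sd=1.0):
    """Gaussian a_ibs/x_ibs clusters, one per class."""
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    classes = classes or [f"c{i}" for i in range(len(means))]
    for cls, (ma, mx) in zip(classes, means):
        frames.append(pd.DataFrame({
            "a_ibs": rng.normal(ma, sd, n_per_class),
            "x_ibs": rng.normal(mx, sd, n_per_class),
        }))
        labels += [cls] * n_per_class
    return pd.concat(frames, ignore_index=True), np.array(labels)


class TestDiscretizer:
    def test_equal_frequency_bins(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"a_ibs": rng.random(1000)})
        model = bn.fit_discretizer(t, ["a_ibs"])
        assert bn.default_n_bins(1000) == 10
        codes = model.transform(t)[:, 0]
        counts = np.bincount(codes)
        assert len(counts) == 10
        assert counts.min() > 60 and counts.max() < 140

    def test_uniform_quantile_edges(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame({"a_ibs": rng.random(20_000)})
        model = bn.fit_discretizer(t, ["a_ibs"], n_bins=4)
        np.testing.assert_allclose(model.edges["a_ibs"],
                                   [0.25, 0.5, 0.75], atol=0.02)

    def test_constant_column_single_category_warns(self):
        t = pd.DataFrame({"a_ibs": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            model = bn.fit_discretizer(t, ["a_ibs"])
        assert model.n_categories["a_ibs"] == 1

    def test_missing_y_gets_inapplicable_category(self):
        t = pd.DataFrame({"y_ibs": [1.0, 2.0, np.nan, 40.0] * 10})
        model = bn.fit_discretizer(t, ["y_ibs"])
        codes = model.transform(t)[:, 0]
        missing = model.missing_code["y_ibs"]
        assert (codes[2::4] == missing).all()
        assert (codes[::4] != missing).all()

    def test_out_of_range_values_clamp(self):
        t = pd.DataFrame({"a_ibs": np.linspace(0, 1, 100)})
        model = bn.fit_discretizer(t, ["a_ibs"], n_bins=5)
        test = pd.DataFrame({"a_ibs": [-10.0, 10.0]})
        codes = model.transform(test)[:, 0]
        assert codes[0] == 0 and codes[1] == 4

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            bn.fit_discretizer(pd.DataFrame({"a_ibs": []}))


class TestFitPredict:
    def test_separated_classes_perfect_training_accuracy(self):
        # balanced classes and an even bin grid put a bin edge exactly at
        # the class boundary quantile
        table, y = make_table(500, [(0, 0), (50, 50)], sd=0.5)
        model = bn.fit_bn(table, y)
        assert (model.predict(table) == y).mean() == 1.0

    def test_uninformative_features_give_prior(self):
        table, y = make_table(2000, [(0, 0), (0, 0), (0, 0)], seed=3)
        model = bn.fit_bn(table, y)
        post = model.predict_proba(table).to_numpy()
        # class-independent features: posterior fluctuates around the prior
        # only through per-bin sampling noise
        assert np.abs(post - 1 / 3).mean() < 0.04
        assert np.abs(post - 1 / 3).max() < 0.15

    def test_posterior_normalized(self):
        table, y = make_table(100, [(0, 0), (3, 1), (1, 3)], seed=4)
        post = bn.predict(bn.fit_bn(table, y), table)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_accuracy_matches_exact_discrete_bayes(self):
        # three overlapping classes; compare with classification by the
        # exact empirical joint over the same discretized configurations
        table, y = make_table(3000, [(0, 0), (1.5, 0.5), (0.5, 1.5)], seed=5)
        disc = bn.fit_discretizer(table, ["a_ibs", "x_ibs"])
        model = bn.fit_bn(table, y, disc=disc)
        codes = disc.transform(table)
        classes = sorted(set(y))
        shape = (len(classes), disc.n_categories["a_ibs"],
                 disc.n_categories["x_ibs"])
        joint = np.ones(shape)
        yi = np.array([classes.index(c) for c in y])
        np.add.at(joint, (yi, codes[:, 0], codes[:, 1]), 1)
        brute = np.asarray(classes, dtype=object)[
            joint[:, codes[:, 0], codes[:, 1]].argmax(axis=0)]
        acc_model = (model.predict(table) == y).mean()
        acc_brute = (brute == y).mean()
        assert abs(acc_model - acc_brute) <= 0.02

    def test_row_order_invariance(self):
        table, y = make_table(300, [(0, 0), (2, 2)], seed=6)
        perm = np.random.default_rng(0).permutation(len(y))
        m1 = bn.fit_bn(table, y)
        m2 = bn.fit_bn(table.iloc[perm].reset_index(drop=True), y[perm])
        probe = table.iloc[:10]
        pd.testing.assert_frame_equal(m1.predict_proba(probe),
                                      m2.predict_proba(probe))

    def test_single_class_rejected(self):
        table, y = make_table(50, [(0, 0)])
        with pytest.raises(ValueError):
            bn.fit_bn(table, y)

    def test_learned_structure_recovers_dependence(self):
        rng = np.random.default_rng(7)
        n = 4000
        a = rng.normal(0, 1, n)
        table = pd.DataFrame({
            "a_ibs": a,
            "a_ibs0": -a + rng.normal(0, 0.1, n),  # strongly dependent
            "x_ibs": rng.normal(0, 1, n),          # independent
        })
        y = np.where(rng.random(n) < 0.5, "r", "u")
        model = bn.fit_bn(table, y, structure_mode="learned")
        assert model.parent["a_ibs0"] == "a_ibs" or \
            model.parent["a_ibs"] == "a_ibs0"
        assert model.parent["x_ibs"] is None


class TestCrossValidation:
    def test_chance_level_for_duplicate_features(self):
        table, y = make_table(300, [(0, 0)] * 4, seed=8)
        res = bn.cross_validate(table, y, seed=0)
        assert res.accuracy == pytest.approx(0.25, abs=0.08)

    def test_shuffled_labels_give_chance(self):
        table, y = make_table(400, [(0, 0), (4, 4)], seed=9)
        rng = np.random.default_rng(1)
        res = bn.cross_validate(table, rng.permutation(y), seed=0)
        assert res.accuracy == pytest.approx(0.5, abs=0.08)

    def test_report_contents(self):
        # an even bin grid puts an edge at the balanced class boundary
        table, y = make_table(100, [(0, 0), (9, 9)], seed=10)
        res = bn.cross_validate(table, y, seed=0, n_bins=10)
        assert res.accuracy > 0.99
        assert res.top2_accuracy == 1.0
        assert set(res.per_class.index) == {"c0", "c1"}
        assert res.confusion.to_numpy().sum() == len(y)
        assert len(res.fold_accuracies) == 5

    def test_small_class_rejected(self):
        table, y = make_table(3, [(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="smaller than k"):
            bn.cross_validate(table, y)

    def test_marker_ablation_table(self, simulator):
        table = simulator.simulate_dataset(["F→M", "F←M"], 150, 3)
        out = bn.marker_ablation(table, table["kc"].to_numpy(),
                                 marker_sets=["A", "A+X+Y+M"], seed=0)
        assert list(out["marker_set"]) == ["A", "A+X+Y+M"]
        # mother-son vs father-daughter is resolved by the mtDNA score
        a_only = out.loc[out.marker_set == "A", "accuracy"].item()
        full = out.loc[out.marker_set == "A+X+Y+M", "accuracy"].item()
        assert a_only < 0.65
        assert full > 0.9

    def test_empty_marker_sets_rejected(self):
        table, y = make_table(50, [(0, 0), (1, 1)])
        with pytest.raises(ValueError):
            bn.marker_ablation(table, y, marker_sets=[])


class TestPersistence:
    def test_model_roundtrip(self, simulator, tmp_path):
        table = simulator.simulate_dataset(["M→M", "MM"], 100, 5)
        y = table["kc"].to_numpy()
        model = bn.fit_bn(table, y)
        path = tmp_path / "model.json"
        bn.save_model(model, str(path))
        back = bn.load_model(str(path))
        pd.testing.assert_frame_equal(back.predict_proba(table),
                                      model.predict_proba(table))
        assert back.classes == model.classes
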