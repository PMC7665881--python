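"""Classifier training/evaluation and exact Shapley attribution."""

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from qpirbc import (
    EvalMetrics,
    FEATURE_COLUMNS,
    ShapleyResult,
    SplitPlan,
    balance_by_rotation,
    evaluate,
    global_importance,
    shapley_exact,
    split_dataset,
    train_classifier,
)
from qpirbc.classify import CellImage, features_from_records, xgb_margin_fn
from qpirbc.errors import ParameterError, ValidationError
from qpirbc.features2d import PHASE_FEATURES, TEXTURE_FEATURES


def _toy_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    rows = []
    for i in range(n):
        cls = "thal" if i < half else "healthy"
        shift = -1.0 if cls == "thal" else 1.0
        feats = rng.normal(shift * 0.8, 1.0, size=15)
        rows.append({"cell_id": i, "class": cls,
                     **dict(zip(FEATURE_COLUMNS, feats))})
    return pd.DataFrame(rows)


class TestSplitDataset:
    def test_grouped_four_to_one(self):
        # 100 cells x 10 augmented copies: 80 cells in train, 20 in test
        base = _toy_table(100, seed=1)
        copies = pd.concat([base] * 10, ignore_index=True)
        train, test = split_dataset(copies, SplitPlan(ratios=(0.8, 0.2), seed=3))
        train_ids = set(train["cell_id"])
        test_ids = set(test["cell_id"])
        assert len(train_ids) == 80 and len(test_ids) == 20
        assert not train_ids & test_ids
        assert len(train) == 800 and len(test) == 200

    def test_deterministic_given_seed(self):
        table = _toy_table(60)
        a = split_dataset(table, SplitPlan(ratios=(0.8, 0.2), seed=5))
        b = split_dataset(table, SplitPlan(ratios=(0.8, 0.2), seed=5))
        assert a[0]["cell_id"].tolist() == b[0]["cell_id"].tolist()

    def test_three_way_split(self):
        table = _toy_table(100)
        parts = split_dataset(table, SplitPlan(ratios=(0.6, 0.2, 0.2), seed=2))
        sizes = sorted(len(p["cell_id"].unique()) for p in parts)
        assert sizes == [20, 20, 60]

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValidationError):
            SplitPlan(ratios=(0.5, 0.4))


class TestBalanceByRotation:
    def _records(self, n_h, n_t, seed=0):
        from qpirbc.synth import render_cell, sample_population

        specs = sample_population((n_h, n_t), rng_seed=seed)
        recs = []
        for i, s in enumerate(specs):
            _, p, mask = render_cell(s)
            recs.append(CellImage(i, s.cell_class, p.phase, mask, 0.1))
        return recs

    def test_minority_upsampled_to_equality(self):
        recs = self._records(5, 10)
        out = balance_by_rotation(recs, rng_seed=1)
        counts = pd.Series([r.cell_class for r in out]).value_counts()
        assert counts["healthy"] == counts["thal"] == 10

    def test_already_balanced_unchanged(self):
        recs = self._records(4, 4)
        assert len(balance_by_rotation(recs, rng_seed=1)) == 8

    def test_copies_inherit_grouping_key(self):
        recs = self._records(3, 6)
        out = balance_by_rotation(recs, rng_seed=1)
        original_ids = {r.cell_id for r in recs}
        assert all(r.cell_id in original_ids for r in out)
        # augmented copies keep their source id, so a grouped split cannot leak
        table = features_from_records(out)
        train, test = split_dataset(table, SplitPlan(ratios=(0.67, 0.33), seed=0))
        assert not set(train["cell_id"]) & set(test["cell_id"])


class TestTrainEvaluate:
    def test_separable_classes_high_accuracy(self):
        table = _toy_table(300, seed=2)
        train, test = split_dataset(table, SplitPlan(ratios=(0.8, 0.2), seed=1))
        model = train_classifier(train, seed=0)
        assert evaluate(model, test).accuracy >= 0.9

    def test_shuffled_labels_chance_level(self):
        table = _toy_table(400, seed=3)
        rng = np.random.default_rng(0)
        table["class"] = rng.permutation(table["class"].to_numpy())
        train, test = split_dataset(table, SplitPlan(ratios=(0.8, 0.2), seed=1))
        model = train_classifier(train, seed=0)
        assert 0.4 <= evaluate(model, test).accuracy <= 0.6

    def test_deterministic_given_seed(self):
        table = _toy_table(200, seed=4)
        m1 = train_classifier(table, seed=9)
        m2 = train_classifier(table, seed=9)
        probe = table[FEATURE_COLUMNS].to_numpy()[:10]
        assert np.array_equal(
            m1.predict_proba(probe), m2.predict_proba(probe)
        )

    def test_single_class_rejected(self):
        table = _toy_table(50)
        with pytest.raises(ValidationError):
            train_classifier(table[table["class"] == "thal"])

    def test_metrics_counted_by_hand(self):
        m = EvalMetrics.from_counts(tp=3, fn=1, tn=4, fp=2)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.6667, abs=1e-4)
        assert m.accuracy == pytest.approx(0.70)

    def test_perfect_separation_all_ones(self):
        table = _toy_table(200, seed=5)
        table[FEATURE_COLUMNS[0]] = np.where(table["class"] == "thal", 5.0, -5.0)
        model = train_classifier(table, seed=0)
        m = evaluate(model, table)
        assert (m.sensitivity, m.specificity, m.accuracy, m.f1, m.auc) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_row_order_invariance(self):
        table = _toy_table(200, seed=6)
        model = train_classifier(table, seed=0)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert evaluate(model, table).to_dict() == evaluate(model, shuffled).to_dict()


# ---------------------------------------------------------------------------
# exact Shapley: closed forms, axioms, brute-force oracle
# ---------------------------------------------------------------------------

from oracles import brute_force_shapley  # noqa: E402


class TestShapleyExact:
    def test_linear_model_closed_form(self):
        fn = lambda X: 2 * X[:, 0] + 3 * X[:, 1]
        res = shapley_exact(fn, np.array([[1.0, 1.0]]), np.zeros((1, 2)))
        assert np.allclose(res.attributions[0], [2.0, 3.0], atol=1e-12)
        assert res.base_value == pytest.approx(0.0)

    def test_efficiency_axiom(self, rng):
        fn = lambda X: np.sin(X[:, 0]) * X[:, 1] + X[:, 2] ** 2
        inst = rng.normal(size=(5, 3))
        bg = rng.normal(size=(7, 3))
        res = shapley_exact(fn, inst, bg)
        total = res.attributions.sum(axis=1)
        assert np.allclose(total, fn(inst) - res.base_value, atol=1e-6)

    def test_symmetry_axiom(self):
        fn = lambda X: X[:, 0] + X[:, 1]
        res = shapley_exact(fn, np.array([[2.0, 2.0]]), np.zeros((3, 2)))
        assert res.attributions[0, 0] == pytest.approx(res.attributions[0, 1], abs=1e-12)

    def test_dummy_axiom(self, rng):
        fn = lambda X: X[:, 0] * 2.0  # ignores feature 1
        inst = rng.normal(size=(4, 2))
        bg = rng.normal(size=(6, 2))
        res = shapley_exact(fn, inst, bg)
        assert np.allclose(res.attributions[:, 1], 0.0, atol=1e-10)

    def test_matches_brute_force_on_tree_ensembles(self, rng):
        X = rng.normal(size=(120, 6))
        y = (X[:, 0] + 0.5 * X[:, 1] * X[:, 2] > 0).astype(int)
        model = xgb.XGBClassifier(
            max_depth=3, n_estimators=25, learning_rate=0.3, n_jobs=1, random_state=0
        )
        model.fit(X, y)
        fn = xgb_margin_fn(model)
        inst = X[:20]
        bg = X[40:48]
        res = shapley_exact(fn, inst, bg)
        for k in range(0, 20, 5):  # brute force is slow; spot-check instances
            phi = brute_force_shapley(fn, inst[k], bg)
            assert np.allclose(res.attributions[k], phi, atol=1e-10)

    def test_too_many_features_rejected(self):
        with pytest.raises(ParameterError, match="2\\^"):
            shapley_exact(lambda X: X.sum(1), np.zeros((1, 20)), np.zeros((1, 20)),
                          max_features=16)


class TestGlobalImportance:
    def test_mean_absolute_ranking(self):
        res = ShapleyResult(
            attributions=np.array([[1.0, -2.0], [-1.0, 2.0]]),
            base_value=0.0,
            feature_names=["f_a", "f_b"],
        )
        assert np.allclose(res.importance, [1.0, 2.0])
        assert res.ranking == ["f_b", "f_a"]

    def test_single_feature(self):
        res = ShapleyResult(np.array([[0.5]]), 0.0, ["only"])
        assert res.ranking == ["only"]

    def test_ties_broken_by_name(self):
        res = ShapleyResult(np.array([[1.0, 1.0]]), 0.0, ["z_f", "a_f"])
        assert res.ranking == ["a_f", "z_f"]


class TestImportanceOnPhantoms:
    def test_phase_statistics_dominate_texture(self, trained_model, split_tables):
        """Phase-shift statistics carry the classification signal; texture
        descriptors are unreliable under acquisition variability."""
        train, test = split_tables
        rng = np.random.default_rng(7)
        bg = train[FEATURE_COLUMNS].to_numpy()[
            rng.choice(len(train), 25, replace=False)
        ]
        res = shapley_exact(
            xgb_margin_fn(trained_model),
            test[FEATURE_COLUMNS].to_numpy()[:16],
            bg,
            feature_names=FEATURE_COLUMNS,
        )
        imp = dict(zip(res.feature_names, res.importance))
        assert res.ranking[0] in PHASE_FEATURES
        phase_mean = np.mean([imp[f] for f in PHASE_FEATURES])
        texture_mean = np.mean([imp[f] for f in TEXTURE_FEATURES])
        assert phase_mean > texture_mean

    def test_ranking_robust_to_segmentation_masks(self):
        """Training on watershed-segmented masks vs ground-truth masks yields
        the same leading discriminant features."""
        from qpirbc import PhaseMap, segment_cells
        from qpirbc.features2d import single_cell_features
        from qpirbc.synth import apply_imaging_effects, render_cell, sample_population

        specs = sample_population(250, rng_seed=31)
        rng = np.random.default_rng(31)
        rows_truth, rows_ws = [], []
        for i, s in enumerate(specs):
            _, p, mask = render_cell(s)
            phase = apply_imaging_effects(p.phase, rng)
            pm = PhaseMap(phase, pixel_size=0.1, provenance="synthetic")
            base = {"cell_id": i, "class": s.cell_class}
            rows_truth.append({**base, **single_cell_features(pm, mask)})
            pred = segment_cells(pm, threshold_method="fixed", fixed_threshold=0.1)
            if pred.n_instances == 0:
                continue
            areas = np.bincount(pred.labels.ravel())[1:]
            ws_mask = pred.labels == (int(np.argmax(areas)) + 1)
            rows_ws.append({**base, **single_cell_features(pm, ws_mask)})
        rankings = []
        for rows in (rows_truth, rows_ws):
            table = pd.DataFrame(rows)
            train, test = split_dataset(table, SplitPlan(ratios=(0.8, 0.2), seed=7))
            model = train_classifier(train, seed=7)
            bg = train[FEATURE_COLUMNS].to_numpy()[
                np.random.default_rng(7).choice(len(train), 20, replace=False)
            ]
            res = shapley_exact(
                xgb_margin_fn(model),
                test[FEATURE_COLUMNS].to_numpy()[:16],
                bg,
                feature_names=FEATURE_COLUMNS,
            )
            imp = dict(zip(res.feature_names, res.importance))
            rankings.append(res.ranking)
            # both models reach the same group-level conclusion
            assert np.mean([imp[f] for f in PHASE_FEATURES]) > np.mean(
                [imp[f] for f in TEXTURE_FEATURES]
            )
        # same dominant feature, and the two leading phase discriminators stay
        # in the top four of both models; exact rank order below the top is
        # within attribution noise
        assert rankings[0][0] == rankings[1][0]
        for ranking in rankings:
            assert {"phase_p5_rad", "phase_sd_rad"} <= set(ranking[:4])
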