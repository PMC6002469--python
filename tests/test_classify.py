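"""NC rule, scaling, cascade training/prediction, cross-validation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hipptox as h


class TestNCRule:
    def test_all_below_threshold_is_nc(self):
        counts = {31.3: 0.9, 62.5: 0.8, 125: 0.2, 250: 0.1, 500: 0.05, 1000: 0.02, 2000: 0.01}
        assert h.call_nc(counts)

    def test_healthy_profile_is_not_nc(self):
        assert not h.call_nc({x: 1.0 for x in (125, 250, 500, 1000, 2000)})

    def test_universal_quantifier_above_floor(self):
        counts = {125: 0.29, 250: 0.31, 500: 0.1, 1000: 0.1, 2000: 0.1}
        assert not h.call_nc(counts)  # 250 µM sits at 31%

    def test_doses_below_floor_ignored(self):
        counts = {31.3: 1.0, 62.5: 1.0, 125: 0.1, 250: 0.1, 500: 0.1, 1000: 0.1, 2000: 0.1}
        assert h.call_nc(counts)

    def test_no_doses_at_floor_is_an_error(self):
        with pytest.raises(ValueError):
            h.call_nc({31.3: 0.1, 62.5: 0.1})


class TestScaler:
    def test_midpoint_maps_to_zero(self):
        s = h.fit_feature_scaler([2.0, 6.0])
        assert h.apply_scaler(s, 4.0) == 0.0
        assert h.apply_scaler(s, 2.0) == -1.0
        assert h.apply_scaler(s, 6.0) == 1.0

    def test_out_of_range_values_unclamped(self):
        s = h.fit_feature_scaler([2.0, 6.0])
        assert h.apply_scaler(s, 8.0) == 2.0

    def test_constant_feature_maps_to_zero(self):
        s = h.fit_feature_scaler([3.0, 3.0, 3.0])
        assert h.apply_scaler(s, 100.0) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=10).filter(
            lambda v: max(v) - min(v) > 1e-6
        )
    )
    def test_training_extremes_land_on_plus_minus_one(self, values):
        s = h.fit_feature_scaler(values)
        out = h.apply_scaler(s, np.array(values))
        assert np.min(out) == pytest.approx(-1.0)
        assert np.max(out) == pytest.approx(1.0)


def _one_feature_matrix(values: dict[str, float], feature="feat_001"):
    chems = list(values)
    return h.DeltaMatrix(
        feature_ids=[feature],
        chemical_ids=chems,
        values=np.array([[values[c] for c in chems]]),
    )


class TestCascade:
    def test_separable_training_predicts_new_chemical(self):
        values = {"p1": 1.2, "p2": 1.5, "p3": 1.1, "n1": 0.0, "n2": -0.1, "n3": 0.05}
        labels = {c: c.startswith("p") for c in values}
        m = _one_feature_matrix(values)
        model = h.train_cascade(m, labels, ["feat_001"], nc_flags={})
        assert h.predict_cascade(model, {"feat_001": 2.0}, nc_flag=False)
        assert not h.predict_cascade(model, {"feat_001": -0.5}, nc_flag=False)

    def test_nc_precedence_beats_any_decision_value(self):
        values = {"p1": 1.2, "p2": 1.5, "n1": 0.0, "n2": -0.1}
        labels = {c: c.startswith("p") for c in values}
        model = h.train_cascade(_one_feature_matrix(values), labels, ["feat_001"], {})
        assert h.predict_cascade(model, {"feat_001": -100.0}, nc_flag=True)

    def test_identical_inner_scores_pick_smallest_c(self):
        # perfectly separable 1-D data: every C scores 100% → C = 1
        values = {f"p{i}": 1.0 + 0.1 * i for i in range(5)}
        values.update({f"n{i}": -1.0 - 0.1 * i for i in range(5)})
        labels = {c: c.startswith("p") for c in values}
        model = h.train_cascade(_one_feature_matrix(values), labels, ["feat_001"], {})
        assert model.C == 1.0

    def test_nc_chemicals_excluded_from_margin_training(self):
        # NC chemical with a wildly negative value would flip a naive fit
        values = {"p1": 1.2, "p2": 1.5, "p3": -50.0, "n1": 0.0, "n2": -0.1}
        labels = {c: c.startswith("p") for c in values}
        flags = {"p3": True}
        model = h.train_cascade(_one_feature_matrix(values), labels, ["feat_001"], flags)
        assert -50.0 not in model.scaler["feat_001"]
        assert h.predict_cascade(model, {"feat_001": 1.3}, nc_flag=False)

    def test_class_missing_after_nc_exclusion_is_an_error(self):
        values = {"p1": 1.2, "p2": 1.4, "n1": 0.0, "n2": 0.1}
        labels = {c: c.startswith("p") for c in values}
        with pytest.raises(ValueError, match="class"):
            h.train_cascade(
                _one_feature_matrix(values),
                labels,
                ["feat_001"],
                {"p1": True, "p2": True},
            )

    def test_boundary_value_called_positive(self):
        model = h.CascadeModel(
            nc_params=h.NCRuleParams(),
            feature_ids=["f"],
            scaler={"f": (0.0, 2.0)},
            weights=np.array([1.0]),
            bias=0.0,
            C=1.0,
        )
        # value 1.0 scales to 0 → decision value exactly 0 → positive
        assert h.predict_cascade(model, {"f": 1.0}, nc_flag=False)

    def test_missing_feature_named_in_error(self):
        model = h.CascadeModel(
            nc_params=h.NCRuleParams(),
            feature_ids=["f"],
            scaler={"f": (0.0, 2.0)},
            weights=np.array([1.0]),
            bias=0.0,
            C=1.0,
        )
        with pytest.raises(KeyError, match="f"):
            h.predict_cascade(model, {}, nc_flag=False)


class TestMetrics:
    def test_confusion_matrix_arithmetic(self):
        labels = {f"p{i}": True for i in range(13)}
        labels.update({f"n{i}": False for i in range(20)})
        preds = {f"p{i}": i < 11 for i in range(13)}  # TP=11, FN=2
        preds.update({f"n{i}": i >= 18 for i in range(20)})  # TN=18, FP=2
        ba, sens, spec = h.compute_metrics(preds, labels)
        assert sens == pytest.approx(100 * 11 / 13, abs=1e-9)  # 84.6%
        assert spec == pytest.approx(90.0)
        assert ba == pytest.approx((sens + spec) / 2)

    def test_small_confusion_example(self):
        labels = {"a": True, "b": True, "c": True, "d": True, "e": False, "f": False, "g": False, "h": False}
        preds = {"a": True, "b": True, "c": True, "d": False, "e": False, "f": False, "g": True, "h": True}
        ba, sens, spec = h.compute_metrics(preds, labels)
        assert (ba, sens, spec) == (62.5, 75.0, 50.0)

    def test_all_correct_and_empty_class_error(self):
        labels = {"a": True, "b": False}
        assert h.compute_metrics({"a": True, "b": False}, labels) == (100.0, 100.0, 100.0)
        with pytest.raises(ValueError):
            h.compute_metrics({"a": True}, {"a": True})


class TestCrossValidation:
    def test_separable_feature_scores_100(self, noisy_study):
        cfg, matrix, labels, nc_flags, truth = noisy_study
        res = h.crossvalidate_feature(
            matrix, labels, nc_flags, cfg.planted_feature_id, folds=10, seed=1
        )
        assert res.balanced_accuracy >= 95.0

    def test_determinism(self, noisy_study):
        cfg, matrix, labels, nc_flags, _ = noisy_study
        r1 = h.crossvalidate_feature(matrix, labels, nc_flags, "feat_002", folds=10, seed=4)
        r2 = h.crossvalidate_feature(matrix, labels, nc_flags, "feat_002", folds=10, seed=4)
        assert r1.predictions == r2.predictions
        assert r1.balanced_accuracy == r2.balanced_accuracy

    def test_folds_are_stratified(self, noisy_study):
        cfg, matrix, labels, nc_flags, _ = noisy_study
        res = h.crossvalidate_feature(
            matrix, labels, nc_flags, cfg.planted_feature_id, folds=10, seed=0
        )
        by_fold: dict[int, list[bool]] = {}
        for c, f in res.fold_assignments.items():
            by_fold.setdefault(f, []).append(labels[c])
        # 13 positives over 10 folds: 1 or 2 per fold
        assert all(1 <= sum(v) <= 2 for v in by_fold.values())

    def test_cv_honesty_held_out_corruption_is_inert(self, noisy_study):
        """Corrupting a held-out chemical's value changes only its own
        prediction, never the trained models (scaler, C)."""
        cfg, matrix, labels, nc_flags, _ = noisy_study
        fid = cfg.planted_feature_id
        res = h.crossvalidate_feature(matrix, labels, nc_flags, fid, folds=10, seed=2)
        victim = next(c for c in labels if not nc_flags.get(c, False))
        corrupted = h.DeltaMatrix(
            feature_ids=list(matrix.feature_ids),
            chemical_ids=list(matrix.chemical_ids),
            values=matrix.values.copy(),
            feature_kind=dict(matrix.feature_kind),
        )
        i = corrupted.feature_ids.index(fid)
        j = corrupted.chemical_ids.index(victim)
        corrupted.values[i, j] = 1e3
        res2 = h.crossvalidate_feature(corrupted, labels, nc_flags, fid, folds=10, seed=2)
        for c in labels:
            if c != victim:
                same_fold = res.fold_assignments[c] == res2.fold_assignments[c]
                assert same_fold
                if res.fold_assignments[c] != res.fold_assignments[victim]:
                    assert res.predictions[c] == res2.predictions[c]

    def test_permutation_null_centres_at_chance(self, noisy_study):
        cfg, matrix, labels, nc_flags, _ = noisy_study
        rng = np.random.default_rng(0)
        chems = list(labels)
        y = np.array([labels[c] for c in chems])
        scores = []
        for _ in range(30):
            perm = rng.permutation(len(chems))
            plabels = {c: bool(y[perm[i]]) for i, c in enumerate(chems)}
            res = h.crossvalidate_feature(
                matrix, plabels, nc_flags, cfg.planted_feature_id, folds=10, seed=3
            )
            scores.append(res.balanced_accuracy)
        assert abs(float(np.mean(scores)) - 50.0) < 8.0

    def test_repeats_average_is_deterministic(self, noisy_study):
        cfg, matrix, labels, nc_flags, _ = noisy_study
        r1 = h.crossvalidate_feature(
            matrix, labels, nc_flags, "feat_003", folds=10, seed=1, repeats=3
        )
        r2 = h.crossvalidate_feature(
            matrix, labels, nc_flags, "feat_003", folds=10, seed=1, repeats=3
        )
        assert r1.balanced_accuracy == r2.balanced_accuracy
        assert r1.balanced_accuracy == pytest.approx(
            (r1.sensitivity + r1.specificity) / 2, abs=1e-9
        )


class TestScreening:
    def test_planted_feature_ranked_first(self, noisy_study):
        cfg, matrix, labels, nc_flags, _ = noisy_study
        ranking = h.screen_features(
            matrix,
            labels,
            nc_flags,
            folds=10,
            seed=1,
            feature_ids=[f for f in matrix.feature_ids if f != h.CELL_COUNT_FEATURE],
        )
        assert ranking[0][0] == cfg.planted_feature_id

    def test_single_feature_matrix_trivially_first(self):
        values = {"p1": 1.0, "p2": 1.2, "p3": 0.9, "n1": 0.0, "n2": 0.1, "n3": -0.1}
        labels = {c: c.startswith("p") for c in values}
        ranking = h.screen_features(
            _one_feature_matrix(values), labels, {}, folds=3, seed=0
        )
        assert len(ranking) == 1 and ranking[0][0] == "feat_001"


class TestRFE:
    def _matrix_with_noise(self, seed=0):
        rng = np.random.default_rng(seed)
        chems = [f"p{i}" for i in range(6)] + [f"n{i}" for i in range(6)]
        labels = {c: c.startswith("p") for c in chems}
        informative = np.array([1.5] * 6 + [0.0] * 6) + rng.normal(0, 0.1, 12)
        noise = rng.normal(0, 0.5, (3, 12))
        values = np.vstack([informative, noise])
        m = h.DeltaMatrix(
            feature_ids=["signal", "junk1", "junk2", "junk3"],
            chemical_ids=chems,
            values=values,
        )
        return m, labels

    def test_informative_feature_survives_to_singleton(self):
        m, labels = self._matrix_with_noise()
        sets = h.select_multifeature_rfe(m, labels, {}, max_features=4, folds=4, seed=0)
        assert sets[0][0] == ["signal", "junk1", "junk2", "junk3"]
        assert sets[-1][0] == ["signal"]

    def test_max_features_boundary(self):
        m, labels = self._matrix_with_noise(1)
        sets = h.select_multifeature_rfe(m, labels, {}, max_features=2, folds=4, seed=0)
        assert len(sets[0][0]) == 2
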