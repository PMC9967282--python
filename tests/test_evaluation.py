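"""Macro metrics, balanced splitting, subset evaluation and the grid."""

import numpy as np
import pytest

import fplselect as fp


def _brute_force_macro_precision(y_true, y_pred):
    """Independent oracle: enumerate the confusion matrix per class."""
    classes = sorted(set(y_true) | set(y_pred))
    per_class = []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp_ = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        per_class.append(tp / (tp + fp_) if tp + fp_ > 0 else 0.0)
    return sum(per_class) / len(per_class)


class TestMacroMetrics:
    def test_perfect_predictions(self):
        y = [0, 1, 0, 1]
        assert fp.macro_precision(y, y) == 1.0
        assert fp.macro_recall(y, y) == 1.0
        assert fp.macro_f1(y, y) == 1.0
        assert fp.accuracy(y, y) == 1.0

    def test_worked_confusion_example(self):
        # class0: TP=3 FP=1; class1: TP=2 FP=2 -> (0.75 + 0.5)/2
        y_true = [0, 0, 0, 1, 1, 1, 0, 0]
        y_pred = [0, 0, 0, 0, 1, 1, 1, 1]
        assert fp.macro_precision(y_true, y_pred) == pytest.approx(0.625)

    @pytest.mark.parametrize("seed", range(50))
    def test_agrees_with_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        y_true = rng.integers(0, 2, size=n)
        y_pred = rng.integers(0, 2, size=n)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ours = fp.macro_precision(y_true, y_pred)
        assert ours == pytest.approx(
            _brute_force_macro_precision(list(y_true), list(y_pred)))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import (accuracy_score, f1_score,
                                     precision_score, recall_score)

        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 2, size=200)
        y_pred = rng.integers(0, 2, size=200)
        assert fp.macro_precision(y_true, y_pred) == pytest.approx(
            precision_score(y_true, y_pred, average="macro",
                            zero_division=0))
        assert fp.macro_recall(y_true, y_pred) == pytest.approx(
            recall_score(y_true, y_pred, average="macro", zero_division=0))
        assert fp.macro_f1(y_true, y_pred) == pytest.approx(
            f1_score(y_true, y_pred, average="macro", zero_division=0))
        assert fp.accuracy(y_true, y_pred) == pytest.approx(
            accuracy_score(y_true, y_pred))

    def test_zero_predicted_positives_contributes_zero_with_warning(self):
        with pytest.warns(UserWarning):
            val = fp.macro_precision([0, 1, 1, 1], [1, 1, 1, 1])
        assert val == pytest.approx((0.0 + 3 / 4) / 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fp.macro_precision([], [])


class TestPseudoOverfitting:
    @pytest.mark.parametrize("tr,va,expected", [
        (0.90, 0.85, 0.05), (0.80, 0.80, 0.0), (0.80, 0.85, -0.05)])
    def test_signed_difference(self, tr, va, expected):
        assert fp.pseudo_overfitting(tr, va) == pytest.approx(expected)


class TestBalancedSplit:
    def test_contract_sizes_and_balance(self):
        fm, _ = fp.make_tabular(fp.TabularSpec(n_samples=2000, d0=5, k_informative=2,
                                               seed=0))
        spec = fp.SplitSpec(seed=0)
        train, val, test = fp.balanced_split(fm, spec)
        assert test.n_samples == 600
        assert val.n_samples == 140
        assert train.n_samples == 1260
        for part in (train, val, test):
            counts = np.bincount(part.labels, minlength=2)
            assert abs(int(counts[0]) - int(counts[1])) <= 20

    def test_disjoint_and_exhaustive(self, planted_small):
        fm, _ = planted_small
        train, val, test = fp.balanced_split(fm, fp.SplitSpec(seed=1))
        total = train.n_samples + val.n_samples + test.n_samples
        assert total == fm.n_samples
        rows = np.vstack([p.values for p in (train, val, test)])
        # every original row appears exactly once
        assert {tuple(r) for r in rows} == {tuple(r) for r in fm.values}

    def test_same_seed_identical_splits(self, planted_small):
        fm, _ = planted_small
        s1 = fp.balanced_split(fm, fp.SplitSpec(seed=5))
        s2 = fp.balanced_split(fm, fp.SplitSpec(seed=5))
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_single_class_rejected(self):
        fm = fp.FeatureMatrix(np.zeros((10, 2)), ["a", "b"], np.ones(10))
        with pytest.raises(ValueError):
            fp.balanced_split(fm, fp.SplitSpec())


class TestEvaluateSubset:
    def test_single_repeat_has_zero_std(self, planted_small, tiny_net):
        fm, planted = planted_small
        names = [fm.feature_names[i] for i in planted]
        report, runs = fp.evaluate_subset(
            fm, names, repeats=1, net_config=tiny_net,
            train_config=fp.TrainConfig(seed=0, epochs=5))
        assert len(runs) == 1
        assert all(v == 0.0 for v in report.std.values())

    def test_unknown_feature_name_rejected(self, planted_small):
        fm, _ = planted_small
        with pytest.raises(KeyError):
            fp.evaluate_subset(fm, ["ghost"], repeats=1)

    def test_identity_subset_reproduces_plain_base_training(
            self, planted_small, tiny_net):
        """Evaluating the full feature set must equal training the base net
        directly with the same derived seed — bitwise on the metrics."""
        from fplselect.evaluation import _train_base_and_report

        fm, _ = planted_small
        cfg = fp.TrainConfig(seed=3, epochs=5)
        report, runs = fp.evaluate_subset(
            fm, fm.feature_names, repeats=1, net_config=tiny_net,
            train_config=cfg, split_spec=fp.SplitSpec(seed=3))
        train, val, test = fp.balanced_split(fm, fp.SplitSpec(seed=3))
        direct = _train_base_and_report(train, val, test, tiny_net, cfg)
        assert runs[0].to_dict() == direct.to_dict()

    def test_planted_subset_beats_random_subset(self, planted_small,
                                                tiny_net):
        fm, planted = planted_small
        rng = np.random.default_rng(0)
        wins = 0
        trials = 5
        for t in range(trials):
            cfg = fp.TrainConfig(seed=t, epochs=8)
            good, _ = fp.evaluate_subset(
                fm, [fm.feature_names[i] for i in planted], repeats=1,
                net_config=tiny_net, train_config=cfg)
            rand_idx = rng.choice(fm.n_features, size=len(planted),
                                  replace=False)
            bad, _ = fp.evaluate_subset(
                fm, [fm.feature_names[i] for i in rand_idx], repeats=1,
                net_config=tiny_net, train_config=cfg)
            wins += good.precision >= bad.precision
        assert wins >= trials - 1


class TestHyperparameterGrid:
    def test_default_grid_has_32_cells(self):
        assert len(fp.enumerate_grid()) == 32

    def test_cell_count_is_product_of_ranges(self):
        assert len(fp.enumerate_grid((0.1,), (0.6,))) == 1
        assert len(fp.enumerate_grid((0.1, 0.3), (0.6, 0.7, 0.8))) == 6

    def test_best_cell_replays_with_evaluate_subset(self, planted_small,
                                                    tiny_net):
        """The winning cell's metrics must be reproducible by re-running
        evaluate_subset on its selected features with the same seeds."""
        fm, _ = planted_small
        cfg = fp.TrainConfig(seed=2, epochs=5)
        grid = fp.hyperparameter_grid(
            fm, fraction=0.2, f_range=(0.2, 0.3), prec_range=(0.75,),
            repeats=1, net_config=tiny_net, train_config=cfg,
            selection_kwargs={"stop": {"max_epochs_final": 30}})
        assert grid.n_cells == 2
        replay, _ = fp.evaluate_subset(fm, grid.best["selected"], repeats=1,
                                       net_config=tiny_net, train_config=cfg)
        assert replay.to_dict() == grid.best["report"].to_dict()
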