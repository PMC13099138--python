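import numpy as np
import pandas as pd
import pytest

from ppiscreen.errors import (
    ConfigError,
    DataError,
    GroupingError,
    MetricError,
    StratificationError,
)
from ppiscreen.interface import InterfaceMap, find_interface
from ppiscreen.mlpipe import (
    assign_splits,
    backward_select,
    baseline_scores,
    crossval_train,
    filter_training_actives,
    fit_final,
    roc_auc,
    score_complex,
    threshold_table,
    tune_hyperparams,
)
from ppiscreen.synth import make_confidence, make_feature_table


class TestAssignSplits:
    def test_ten_complexes_split_6_2_2(self):
        ids = [f"c{i}" for i in range(10)]
        splits = assign_splits(ids, seed=0)
        assert len(splits.ids("train")) == 6
        assert len(splits.ids("validation")) == 2
        assert len(splits.ids("test")) == 2
        table = pd.DataFrame({
            "complex_id": np.repeat(ids, 5),
            "model_rank": list(range(1, 6)) * 10,
        })
        part = splits.of_rows(table)
        assert (part == "train").sum() == 30
        assert (part == "validation").sum() == 10
        # group integrity: one assignment per complex
        assert table.assign(p=part).groupby("complex_id")["p"].nunique().max() == 1

    def test_same_seed_same_assignment(self):
        ids = [f"c{i}" for i in range(20)]
        assert assign_splits(ids, seed=5).assignment == assign_splits(ids, seed=5).assignment

    def test_too_few_complexes(self):
        with pytest.raises(ConfigError):
            assign_splits(["a", "b"])

    def test_bad_fractions(self):
        with pytest.raises(ConfigError):
            assign_splits([f"c{i}" for i in range(10)], fractions=(0.5, 0.2, 0.2))


class TestFilterTrainingActives:
    def _setup(self):
        ids = [f"c{i}" for i in range(10)]
        rows = []
        for cid in ids:
            label = "active" if int(cid[1:]) % 2 == 0 else "decoy"
            for rank in range(1, 6):
                rows.append(dict(complex_id=cid, model_rank=rank, label=label, f=0.0))
        table = pd.DataFrame(rows)
        splits = assign_splits(ids, seed=0)
        return table, splits

    def test_training_actives_below_threshold_dropped(self):
        table, splits = self._setup()
        scores = [0.9, 0.8, 0.1, 0.7, 0.05]
        dockq = {
            (cid, rank): scores[rank - 1]
            for cid in table["complex_id"].unique() for rank in range(1, 6)
        }
        filtered = filter_training_actives(table, dockq, splits)
        train_ids = set(splits.ids("train"))
        for cid in train_ids:
            sub = filtered[filtered.complex_id == cid]
            if sub["label"].iloc[0] == "active":
                assert len(sub) == 3  # 0.9, 0.8, 0.7 kept
            else:
                assert len(sub) == 5  # decoys untouched

    def test_test_rows_untouched(self):
        table, splits = self._setup()
        dockq = {(cid, rank): 0.0 for cid in table["complex_id"].unique()
                 for rank in range(1, 6)}
        filtered = filter_training_actives(table, dockq, splits)
        for cid in splits.ids("test") + splits.ids("validation"):
            assert (filtered.complex_id == cid).sum() == 5

    def test_all_models_bad_drops_whole_complex(self):
        table, splits = self._setup()
        dockq = {(cid, rank): 0.1 for cid in table["complex_id"].unique()
                 for rank in range(1, 6)}
        filtered = filter_training_actives(table, dockq, splits)
        for cid in splits.ids("train"):
            sub = filtered[filtered.complex_id == cid]
            label = table[table.complex_id == cid]["label"].iloc[0]
            assert len(sub) == (0 if label == "active" else 5)

    def test_missing_dockq_is_data_error(self):
        table, splits = self._setup()
        with pytest.raises(DataError):
            filter_training_actives(table, {}, splits)

    def test_boundary_inclusive(self):
        table, splits = self._setup()
        dockq = {(cid, rank): 0.23 for cid in table["complex_id"].unique()
                 for rank in range(1, 6)}
        filtered = filter_training_actives(table, dockq, splits)
        assert len(filtered) == len(table)  # 0.23 kept (inclusive)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], ["active", "active", "decoy", "decoy"]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, ["active"] * 3 + ["decoy"] * 3) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(MetricError):
            roc_auc([0.5, 0.6], ["active", "active"])

    def test_matches_concordant_pair_oracle_and_sklearn(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = 50
            scores = rng.uniform(size=n)
            scores[rng.random(n) < 0.3] = 0.5  # inject ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            pos = scores[y == 1]
            neg = scores[y == 0]
            concordant = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            oracle = concordant / (len(pos) * len(neg))
            assert roc_auc(scores, y) == pytest.approx(oracle)
            from sklearn.metrics import roc_auc_score

            assert roc_auc(scores, y) == pytest.approx(roc_auc_score(y, scores))


class TestThresholdTable:
    def test_threshold_zero_row(self):
        tab = threshold_table([0.9, 0.7, 0.4, 0.2], ["active", "active", "decoy", "decoy"],
                              thresholds=[0.0])
        row = tab.iloc[0]
        assert row["FPR"] == 1.0 and row["TPR"] == 1.0
        assert row["precision"] == 0.5
        assert row["F1"] == pytest.approx(2 * 0.5 / 1.5)

    def test_above_all_scores(self):
        tab = threshold_table([0.3, 0.2, 0.1, 0.05], ["active", "decoy"] * 2,
                              thresholds=[0.99])
        row = tab.iloc[0]
        assert row["TPR"] == 0.0 and row["FPR"] == 0.0
        assert row["precision"] == 1.0  # zero-predicted-positive convention

    def test_f1_identity_every_row(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=40)
        y = rng.integers(0, 2, 40)
        tab = threshold_table(scores, y)
        for _, r in tab.iterrows():
            p, q = r["precision"], r["recall"]
            expected = 2 * p * q / (p + q) if p + q > 0 else 0.0
            assert r["F1"] == pytest.approx(expected)

    def test_prevalence_at_zero_threshold(self):
        scores = [0.9, 0.8, 0.7, 0.1]
        y = ["active", "decoy", "decoy", "decoy"]
        row = threshold_table(scores, y, thresholds=[0.0]).iloc[0]
        assert row["precision"] == pytest.approx(0.25)


class TestCrossval:
    def test_separable_table_perfect_auc(self):
        tab = make_feature_table(20, 3, effect_size=6.0, seed=2)
        _, auc, oof = crossval_train(tab, folds=4, seed=2, model_spec="logistic")
        assert auc == 1.0

    def test_group_integrity_in_folds(self):
        tab = make_feature_table(20, 3, effect_size=1.0, seed=3)
        from ppiscreen.mlpipe import _grouped_folds

        groups = tab["complex_id"].to_numpy()
        for tr, te in _grouped_folds(tab, 4, seed=3):
            assert set(groups[tr]).isdisjoint(set(groups[te]))

    def test_single_class_fold_rejected(self):
        tab = make_feature_table(10, 2, effect_size=1.0, seed=1)
        tab["label"] = "active"
        with pytest.raises((StratificationError, MetricError, ValueError)):
            crossval_train(tab, folds=3, seed=1)


class TestBackwardSelect:
    def _noise_table(self, seed=0, effect=0.7, n=40, m=3):
        rng = np.random.default_rng(seed)
        rows = []
        for c in range(n):
            label = "active" if c % 2 == 0 else "decoy"
            mu = effect if label == "active" else -effect
            for k in range(1, m + 1):
                rows.append(dict(
                    complex_id=f"c{c}", model_rank=k, label=label,
                    sig1=mu + rng.normal(), sig2=mu + rng.normal(),
                    noise=rng.normal(),
                ))
        return pd.DataFrame(rows)

    def test_pure_noise_eliminated_first(self):
        tab = self._noise_table()
        trace, final = backward_select(tab, ["sig1", "sig2", "noise"],
                                       target_size=2, folds=4, seed=0,
                                       model_spec="logistic")
        assert trace[0][0] == "noise"
        assert set(final) == {"sig1", "sig2"}

    def test_target_equal_start_is_identity(self):
        tab = self._noise_table()
        trace, final = backward_select(tab, ["sig1", "sig2"], target_size=2,
                                       folds=4, seed=0, model_spec="logistic")
        assert trace == []
        assert final == ["sig1", "sig2"]

    def test_trace_length(self):
        tab = self._noise_table()
        trace, final = backward_select(tab, ["sig1", "sig2", "noise"],
                                       target_size=1, folds=4, seed=0,
                                       model_spec="logistic")
        assert len(trace) == 2
        assert len(final) == 1

    def test_selected_auc_within_tolerance_of_full(self):
        """Redundant features: selection keeps validation AUC near the full model."""
        tab = self._noise_table(effect=1.2)
        _, full_auc, _ = crossval_train(tab, folds=4, seed=0,
                                        model_spec="logistic",
                                        features=["sig1", "sig2", "noise"])
        trace, final = backward_select(tab, ["sig1", "sig2", "noise"],
                                       target_size=1, folds=4, seed=0,
                                       model_spec="logistic")
        assert trace[-1][1] >= full_auc - 0.1


class TestTuneHyperparams:
    _grid_point = dict(max_depth=[3], n_estimators=[30], learning_rate=[0.2],
                       gamma=[0.0], reg_lambda=[1.0], min_child_weight=[1.0])

    def test_single_point_grid_returned(self):
        tab = make_feature_table(12, 2, effect_size=2.0, seed=4)
        best = tune_hyperparams(tab, self._grid_point, folds=3, seed=4)
        assert best == {k: v[0] for k, v in self._grid_point.items()}

    def test_degenerate_config_not_selected(self):
        """A config whose trees cannot split (huge min_child_weight) scores
        AUC 0.5 on separable data and must lose the grid search."""
        tab = make_feature_table(16, 3, effect_size=3.0, seed=5)
        grid = dict(max_depth=[4], n_estimators=[50], learning_rate=[0.2],
                    gamma=[0.0], reg_lambda=[1.0], min_child_weight=[1.0, 1e6])
        best = tune_hyperparams(tab, grid, folds=3, seed=5)
        assert best["min_child_weight"] == 1.0

    def test_selection_matches_per_config_argmax(self):
        tab = make_feature_table(12, 3, effect_size=1.0, seed=8)
        grid = dict(max_depth=[2, 4], n_estimators=[10, 40], learning_rate=[0.3],
                    gamma=[0.0], reg_lambda=[1.0], min_child_weight=[1.0])
        best = tune_hyperparams(tab, grid, folds=3, seed=8)
        import itertools

        names = list(grid)
        aucs = {}
        for combo in itertools.product(*(grid[n] for n in names)):
            params = dict(zip(names, combo))
            _, auc, _ = crossval_train(tab, folds=3, seed=8, hyperparams=params)
            aucs[tuple(combo)] = auc
        assert aucs[tuple(best[n] for n in names)] == max(aucs.values())

    def test_deterministic_reruns(self):
        tab = make_feature_table(12, 2, effect_size=1.0, seed=6)
        grid = dict(max_depth=[2, 3], n_estimators=[20], learning_rate=[0.2, 0.4],
                    gamma=[0.0], reg_lambda=[1.0], min_child_weight=[1.0])
        assert tune_hyperparams(tab, grid, folds=3, seed=6) == \
            tune_hyperparams(tab, grid, folds=3, seed=6)

    def test_empty_grid_rejected(self):
        tab = make_feature_table(12, 2, seed=1)
        with pytest.raises(ConfigError):
            tune_hyperparams(tab, {}, folds=3)

    def test_missing_dimension_rejected(self):
        tab = make_feature_table(12, 2, seed=1)
        with pytest.raises(ConfigError):
            tune_hyperparams(tab, {"max_depth": [3]}, folds=3)


class TestScoreComplex:
    def _trained(self):
        tab = make_feature_table(12, 5, effect_size=4.0, seed=7)
        return fit_final(tab, seed=7), tab

    def test_max_rule(self):
        trained, tab = self._trained()
        rows = tab[tab.complex_id == tab.complex_id.iloc[0]]
        score, per_model = score_complex(trained, rows)
        assert score == per_model.max()
        assert len(per_model) == 5

    def test_single_row(self):
        trained, tab = self._trained()
        rows = tab[tab.complex_id == tab.complex_id.iloc[0]].head(1)
        score, per_model = score_complex(trained, rows)
        assert score == per_model[0]

    def test_mixed_complexes_rejected(self):
        trained, tab = self._trained()
        with pytest.raises(GroupingError):
            score_complex(trained, tab)


class TestBaselines:
    def test_iptm_passthrough(self, docked):
        conf = make_confidence(docked, "confident_interface", seed=1)
        iface = find_interface(docked)
        assert baseline_scores(conf, docked, iface)["iptm"] == conf.iptm

    def test_pdockq_zero_contacts_formula(self, docked):
        import math

        from ppiscreen.config import PDOCKQ_B, PDOCKQ_K, PDOCKQ_L, PDOCKQ_X0

        conf = make_confidence(docked, "confident_interface", seed=1)
        empty = InterfaceMap([])
        expected = PDOCKQ_L / (1 + math.exp(PDOCKQ_K * PDOCKQ_X0)) + PDOCKQ_B
        assert baseline_scores(conf, docked, empty)["pdockq"] == pytest.approx(expected)

    def test_pdockq_monotone_in_plddt(self, docked):
        iface = find_interface(docked)
        n = docked.n_residues
        lo = make_confidence(docked, "confident_interface", seed=1)
        import numpy as np

        from ppiscreen.structio import ConfidenceBundle

        hi = ConfidenceBundle(np.minimum(lo.plddt + 5.0, 100.0), lo.pae, lo.ptm, lo.iptm)
        assert baseline_scores(hi, docked, iface)["pdockq"] > \
            baseline_scores(lo, docked, iface)["pdockq"]
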