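"""Model/Results objects wrapping the training pipeline.

:class:`PPIScreenModel` is built from a labeled feature table and owns the
study design choices (split fractions, fold count, classifier family,
seed).  Its :meth:`fit` runs the full protocol — grouped 60/20/20 split,
optional training-set DockQ filtering, stratified grouped cross-validation,
optional backward feature selection and hyperparameter tuning on
train+validation, a final refit — and returns a :class:`PPIScreenResults`
carrying the fitted classifier, the cross-fold and held-out-test AUCs, the
per-complex max-aggregated scores, and an operating-point threshold table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_SEED, DEFAULT_THRESHOLDS
from .errors import ConfigError, DataError
from .manifest import all_features, manifest_version
from .mlpipe import (
    SplitAssignment,
    TrainedModel,
    assert_no_leakage,
    assign_splits,
    backward_select,
    crossval_train,
    filter_training_actives,
    fit_final,
    roc_auc,
    score_by_complex,
    threshold_table,
    tune_hyperparams,
)


class PPIScreenModel:
    """Screening classifier specification bound to a labeled feature table.

    Parameters
    ----------
    table : pandas.DataFrame
        Rows of (complex_id, model_rank, label) plus the manifest features.
    classifier : str
        "xgboost" (gradient-boosted trees, default) or "logistic".
    fractions : tuple
        Complex-level train/validation/test fractions (default 60/20/20).
    folds : int
        Stratified grouped cross-validation folds (default 5).
    seed : int
        Controls split, folds, and training randomness.
    """

    def __init__(self, table: pd.DataFrame, classifier: str = "xgboost",
                 fractions=(0.6, 0.2, 0.2), folds: int = 5,
                 seed: int = DEFAULT_SEED,
                 features: list[str] | None = None):
        missing = [c for c in ("complex_id", "model_rank", "label") if c not in table]
        if missing:
            raise DataError(f"feature table lacks id columns {missing}")
        self.table = table.reset_index(drop=True)
        self.classifier = classifier
        self.fractions = fractions
        self.folds = folds
        self.seed = seed
        self.features = features or [f for f in all_features() if f in table.columns]
        if not self.features:
            raise ConfigError("no manifest features present in the table")
        counts = self.table.groupby("complex_id").size()
        if (counts > 5).any():
            raise DataError("a complex has more than 5 model rows")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PPIScreenModel":
        return cls(df, **kwargs)

    def fit(self, dockq_by_row=None, select_to: int | None = None,
            tune_grid: dict | None = None) -> "PPIScreenResults":
        """Run the training protocol and return results.

        ``dockq_by_row`` (optional) maps (complex_id, model_rank) to DockQ and
        triggers the mis-docked-active filter on the training partition.
        ``select_to`` runs backward feature selection down to that size;
        ``tune_grid`` runs the hyperparameter grid search.  Both use only
        train+validation rows.
        """
        splits = assign_splits(self.table["complex_id"], self.fractions, self.seed)
        part = splits.of_rows(self.table)
        test = self.table.loc[part == "test"].reset_index(drop=True)
        trainval = self.table.loc[part != "test"].reset_index(drop=True)
        assert_no_leakage(trainval["complex_id"], test["complex_id"])

        if dockq_by_row is not None:
            trainval = filter_training_actives(trainval, dockq_by_row, splits)

        features = list(self.features)
        if select_to is not None and select_to < len(features):
            trace, features = backward_select(
                trainval, features, target_size=select_to, folds=self.folds,
                model_spec=self.classifier, seed=self.seed,
            )
        else:
            trace = []

        hyperparams = None
        if tune_grid is not None:
            hyperparams = tune_hyperparams(
                trainval, tune_grid, folds=self.folds, model_spec=self.classifier,
                seed=self.seed, features=features,
            )

        _, cv_auc, oof = crossval_train(
            trainval, self.folds, self.classifier, self.seed,
            features=features, hyperparams=hyperparams,
        )
        trained = fit_final(trainval, features, self.classifier, hyperparams,
                            self.seed, self.folds)

        test_scores = score_by_complex(trained, test) if len(test) else pd.DataFrame()
        test_auc = np.nan
        ttable = None
        if len(test_scores) and test_scores["label"].nunique() == 2:
            test_auc = roc_auc(test_scores["score"], test_scores["label"])
            ttable = threshold_table(test_scores["score"], test_scores["label"],
                                     DEFAULT_THRESHOLDS)
            trained.thresholds = ttable
        return PPIScreenResults(
            model=self, trained=trained, splits=splits, cv_auc=cv_auc,
            oof_scores=oof, test_scores=test_scores, test_auc=float(test_auc),
            thresholds=ttable, elimination_trace=trace,
        )


@dataclass
class PPIScreenResults:
    """Fitted screening classifier plus its evaluation artifacts."""

    model: PPIScreenModel
    trained: TrainedModel
    splits: SplitAssignment
    cv_auc: float
    oof_scores: pd.DataFrame
    test_scores: pd.DataFrame
    test_auc: float
    thresholds: pd.DataFrame | None = None
    elimination_trace: list = field(default_factory=list)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Per-model classifier scores in [0, 1]."""
        return self.trained.predict_scores(rows)

    def score_complexes(self, table: pd.DataFrame) -> pd.DataFrame:
        """Per-complex max-aggregated scores for new feature rows."""
        return score_by_complex(self.trained, table)

    def summary(self) -> str:
        lines = [
            "PPI screening classifier",
            "=" * 52,
            f"classifier:        {self.model.classifier}",
            f"manifest version:  {manifest_version()}",
            f"features used:     {len(self.trained.features)}",
            f"seed:              {self.model.seed}",
            f"folds:             {self.model.folds}",
            f"complexes (train/val/test): "
            f"{len(self.splits.ids('train'))}/{len(self.splits.ids('validation'))}/"
            f"{len(self.splits.ids('test'))}",
            f"cross-fold AUC:    {self.cv_auc:.3f}",
        ]
        if np.isfinite(self.test_auc):
            lines.append(f"test AUC (max-of-models, per complex): {self.test_auc:.3f}")
        if self.elimination_trace:
            lines.append(f"features eliminated: {len(self.elimination_trace)}")
        if self.thresholds is not None:
            lines.append("")
            lines.append("operating points (threshold / FPR / TPR / precision / F1):")
            for _, r in self.thresholds.iterrows():
                lines.append(
                    f"  {r['threshold']:>5.2f}  {r['FPR']:.2f}  {r['TPR']:.2f}"
                    f"  {r['precision']:.2f}  {r['F1']:.2f}"
                )
        return "\n".join(lines)
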