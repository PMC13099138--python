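"""Leakage-safe partitioning, training, and evaluation.

The screening classifier is trained on per-model feature rows, but the unit
of everything that could leak information is the *complex*: all five
predicted models of one protein pairing carry near-identical signal, so
splits and cross-validation folds are assigned at complex level (grouped,
stratified by label), never at row level.  At evaluation time a complex is
scored by the maximum classifier score over its models.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedGroupKFold

from .config import (
    DEFAULT_SEED,
    DEFAULT_THRESHOLDS,
    DOCKQ_ACCEPTABLE,
    PDOCKQ_B,
    PDOCKQ_K,
    PDOCKQ_L,
    PDOCKQ_X0,
)
from .errors import (
    ConfigError,
    DataError,
    GroupingError,
    MetricError,
    StratificationError,
)
from .manifest import all_features, manifest_version

LABEL_POSITIVE = "active"

# Hyperparameter names every tuning grid must cover.
TUNABLE_PARAMS = (
    "max_depth", "n_estimators", "learning_rate", "gamma", "reg_lambda",
    "min_child_weight",
)

_XGB_DEFAULTS = dict(
    n_estimators=100, max_depth=4, learning_rate=0.2, gamma=0.0,
    reg_lambda=1.0, min_child_weight=1.0,
)


def make_classifier(spec: str = "xgboost", seed: int = DEFAULT_SEED,
                    hyperparams: dict | None = None):
    """Classifier factory: gradient-boosted trees (default) or logistic baseline."""
    if spec == "xgboost":
        from xgboost import XGBClassifier

        params = dict(_XGB_DEFAULTS)
        if hyperparams:
            params.update(hyperparams)
        # exact split finding: thresholds land mid-gap between observed values,
        # which generalizes better than histogram bin edges on the small,
        # well-separated tables this tool trains on
        return XGBClassifier(
            objective="binary:logistic", eval_metric="logloss",
            tree_method="exact", n_jobs=1, random_state=seed, **params,
        )
    if spec == "logistic":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    raise ConfigError(f"unknown classifier spec {spec!r}")


def _labels01(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        return (arr == LABEL_POSITIVE).astype(int)
    return arr.astype(int)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    assignment: dict[str, str]   # complex_id -> train | validation | test
    seed: int

    def ids(self, which: str) -> list[str]:
        return sorted(c for c, s in self.assignment.items() if s == which)

    def of_rows(self, table: pd.DataFrame) -> pd.Series:
        return table["complex_id"].map(self.assignment)


def assign_splits(complex_ids, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = DEFAULT_SEED) -> SplitAssignment:
    """Complex-level random 60/20/20 assignment with group integrity.

    All rows (models) of a complex inherit its assignment, so no pairing can
    straddle sets.
    """
    ids = sorted(set(complex_ids))
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"split fractions must sum to 1, got {fractions}")
    n = len(ids)
    if n < 5:
        raise ConfigError(f"need >= 5 complexes to realize a 3-way split, got {n}")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ConfigError(f"fractions {fractions} leave an empty partition for n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = {}
    for pos, idx in enumerate(order):
        if pos < n_train:
            assignment[ids[idx]] = "train"
        elif pos < n_train + n_val:
            assignment[ids[idx]] = "validation"
        else:
            assignment[ids[idx]] = "test"
    return SplitAssignment(assignment, seed)


def assert_no_leakage(*id_groups) -> None:
    """Hard guard: no complex_id may appear in more than one group."""
    seen: dict[str, int] = {}
    for gi, group in enumerate(id_groups):
        for cid in set(group):
            if cid in seen and seen[cid] != gi:
                raise DataError(f"complex {cid!r} appears in two partitions")
            seen[cid] = gi


def filter_training_actives(table: pd.DataFrame, dockq_by_row,
                            splits: SplitAssignment,
                            threshold: float = DOCKQ_ACCEPTABLE) -> pd.DataFrame:
    """Drop mis-docked active models from the *training* partition only.

    Active complexes whose predicted models are badly built (DockQ below the
    acceptable threshold versus the native structure) would teach the
    classifier that wrong interfaces are actives.  Validation and test rows
    are untouched — in a prospective screen no native exists, so mis-docked
    actives must stay in the evaluation sets.

    ``dockq_by_row`` maps (complex_id, model_rank) to a DockQ score; it must
    cover every active training row.
    """
    part = splits.of_rows(table)
    keep = np.ones(len(table), dtype=bool)
    for pos, (_, row) in enumerate(table.iterrows()):
        if part.iloc[pos] != "train" or row["label"] != LABEL_POSITIVE:
            continue
        key = (row["complex_id"], row["model_rank"])
        try:
            score = dockq_by_row[key]
        except (KeyError, IndexError):
            raise DataError(f"missing DockQ for active training row {key}") from None
        if not (score >= threshold):
            keep[pos] = False
    return table.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Rank-based ROC AUC with half credit for ties (Mann-Whitney U / n+ n-)."""
    y = _labels01(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricError("ROC AUC undefined with a single class")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def threshold_table(scores, labels,
                    thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Confusion-matrix rates per threshold (prediction = score >= threshold).

    At thresholds above every score (zero predicted positives) precision is
    reported as 1.0 with recall 0.
    """
    y = _labels01(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricError("threshold table undefined with a single class")
    rows = []
    for t in thresholds:
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = n_pos - tp
        tn = n_neg - fp
        tpr = tp / n_pos
        fpr = fp / n_neg
        precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
        recall = tpr
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
        rows.append(dict(threshold=t, FPR=fpr, TPR=tpr, FNR=1 - tpr, TNR=1 - fpr,
                         precision=precision, recall=recall, F1=f1))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to apply it reproducibly."""

    estimator: object
    features: list[str]
    hyperparams: dict
    seed: int
    folds: int
    manifest_version: str = field(default_factory=manifest_version)
    thresholds: pd.DataFrame | None = None

    def predict_scores(self, rows: pd.DataFrame) -> np.ndarray:
        X = rows[self.features].to_numpy(dtype=float)
        return self.estimator.predict_proba(X)[:, 1]


def _grouped_folds(table: pd.DataFrame, folds: int, seed: int):
    """Stratified, group-integral row folds; errors on single-class folds."""
    y = _labels01(table["label"])
    groups = table["complex_id"].to_numpy()
    skf = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    out = []
    for tr, te in skf.split(np.zeros(len(y)), y, groups):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise StratificationError("a cross-validation fold contains one class only")
        assert_no_leakage(groups[tr], groups[te])
        out.append((tr, te))
    return out


def crossval_train(table: pd.DataFrame, folds: int = 5, model_spec: str = "xgboost",
                   seed: int = DEFAULT_SEED, features: list[str] | None = None,
                   hyperparams: dict | None = None):
    """Grouped stratified k-fold training; combined AUC on pooled held folds.

    Returns (per-fold fitted estimators, combined cross-fold AUC, out-of-fold
    score table).
    """
    features = features or [f for f in all_features() if f in table.columns]
    y = _labels01(table["label"])
    X = table[features].to_numpy(dtype=float)
    oof = np.full(len(y), np.nan)
    models = []
    for tr, te in _grouped_folds(table, folds, seed):
        clf = make_classifier(model_spec, seed=seed, hyperparams=hyperparams)
        clf.fit(X[tr], y[tr])
        oof[te] = clf.predict_proba(X[te])[:, 1]
        models.append(clf)
    mask = ~np.isnan(oof)
    auc = roc_auc(oof[mask], y[mask])
    oof_table = table.loc[mask, ["complex_id", "model_rank", "label"]].copy()
    oof_table["score"] = oof[mask]
    return models, auc, oof_table


def backward_select(table: pd.DataFrame, start_features: list[str],
                    target_size: int = 7, tolerance: float | None = None,
                    folds: int = 5, model_spec: str = "xgboost",
                    seed: int = DEFAULT_SEED):
    """Sequential backward feature elimination judged by cross-fold AUC.

    At each step the feature whose removal yields the highest validation
    cross-fold AUC is eliminated.  Stops at ``target_size`` features, or
    earlier when ``tolerance`` is set and the best candidate's AUC falls more
    than ``tolerance`` below the full-feature AUC.

    Returns (ordered elimination trace [(feature, auc_after_removal)], final
    feature subset).
    """
    if target_size < 1:
        raise ConfigError("target_size must be >= 1")
    current = list(start_features)
    _, full_auc, _ = crossval_train(table, folds, model_spec, seed, features=current)
    trace: list[tuple[str, float]] = []
    while len(current) > target_size:
        best_feat, best_auc = None, -np.inf
        for f in current:
            candidate = [g for g in current if g != f]
            _, auc, _ = crossval_train(table, folds, model_spec, seed, features=candidate)
            if auc > best_auc:
                best_feat, best_auc = f, auc
        if tolerance is not None and best_auc < full_auc - tolerance:
            break
        current.remove(best_feat)
        trace.append((best_feat, best_auc))
    return trace, current


def tune_hyperparams(table: pd.DataFrame, grid: dict[str, list],
                     folds: int = 5, model_spec: str = "xgboost",
                     seed: int = DEFAULT_SEED,
                     features: list[str] | None = None) -> dict:
    """Grid search over the six boosting hyperparameters by cross-fold AUC.

    The grid must cover max_depth, n_estimators, learning_rate, gamma,
    reg_lambda and min_child_weight (extra dimensions are allowed).  The
    search never sees test rows — pass only training+validation data.
    """
    if not grid:
        raise ConfigError("empty hyperparameter grid")
    missing = [p for p in TUNABLE_PARAMS if p not in grid]
    if missing:
        raise ConfigError(f"grid lacks required dimensions: {missing}")
    names = list(grid)
    best_params, best_auc = None, -np.inf
    for combo in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, combo))
        _, auc, _ = crossval_train(table, folds, model_spec, seed,
                                   features=features, hyperparams=params)
        if auc > best_auc:
            best_params, best_auc = params, auc
    return best_params


def fit_final(table: pd.DataFrame, features: list[str] | None = None,
              model_spec: str = "xgboost", hyperparams: dict | None = None,
              seed: int = DEFAULT_SEED, folds: int = 5) -> TrainedModel:
    """Fit on all provided rows (train+validation) with the chosen settings."""
    features = features or [f for f in all_features() if f in table.columns]
    clf = make_classifier(model_spec, seed=seed, hyperparams=hyperparams)
    clf.fit(table[features].to_numpy(dtype=float), _labels01(table["label"]))
    return TrainedModel(clf, features, hyperparams or {}, seed, folds)


def score_complex(trained: TrainedModel, rows: pd.DataFrame):
    """Max-of-models score for one complex: (complex_score, per-model scores)."""
    ids = rows["complex_id"].unique()
    if len(ids) != 1:
        raise GroupingError(f"rows span multiple complexes: {sorted(ids)}")
    per_model = trained.predict_scores(rows)
    return float(per_model.max()), per_model


def score_by_complex(trained: TrainedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-complex max-aggregated scores over a whole feature table."""
    recs = []
    for cid, rows in table.groupby("complex_id", sort=True):
        score, _ = score_complex(trained, rows)
        recs.append(dict(complex_id=cid, label=rows["label"].iloc[0], score=score))
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def baseline_scores(conf, model=None, iface=None) -> dict[str, float]:
    """Reference discriminators: iPTM (read from the bundle) and pDockQ.

    pDockQ = L/(1+exp(-k (x - x0))) + b with x = mean interface pLDDT *
    log10(number of interface contacts); x = 0 when there are no contacts.
    """
    n_contacts = 0 if iface is None else len(iface.pairs)
    if n_contacts > 0:
        idx = sorted(iface.residue_set)
        mean_plddt = float(np.mean(conf.plddt[idx]))
        x = mean_plddt * math.log10(n_contacts)
    else:
        x = 0.0
    pdockq = PDOCKQ_L / (1.0 + math.exp(-PDOCKQ_K * (x - PDOCKQ_X0))) + PDOCKQ_B
    return {"iptm": float(conf.iptm), "pdockq": float(pdockq)}
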