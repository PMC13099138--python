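"""Family selectivity screening: all-vs-all ligand/receptor grids.

For a structurally conserved family (the motivating case: trimeric ligands
engaged by single-pass receptors at 3:3 stoichiometry, screened as three
ligand chains = entity 1 against one receptor chain = entity 2), every
ligand/receptor pairing is scored with the trained classifier and the
max-of-models rule, yielding a complete L x R score grid.  Evaluation against
a curated known-interaction mask uses per-ligand top-k hit rates and a
flattened-grid ROC.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, MetricError
from .mlpipe import TrainedModel, roc_auc, score_complex


def enumerate_pairings(ligands: list[str], receptors: list[str]) -> list[tuple[str, str]]:
    """Full Cartesian product in row-major (ligand-major) order."""
    if len(set(ligands)) != len(ligands) or len(set(receptors)) != len(receptors):
        raise DataError("ligand/receptor ids must be unique")
    if not ligands or not receptors:
        raise DataError("ligand and receptor lists must be non-empty")
    return [(l, r) for l in ligands for r in receptors]


@dataclass
class SelectivityGrid:
    ligands: list[str]
    receptors: list[str]
    scores: np.ndarray                    # L x R in [0, 1]
    known_mask: np.ndarray | None = None  # L x R boolean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.ligands, columns=self.receptors)


def screen_grid(rows_by_pairing: dict[tuple[str, str], pd.DataFrame],
                classifier: TrainedModel,
                ligands: list[str], receptors: list[str],
                known_mask: np.ndarray | None = None) -> SelectivityGrid:
    """Score every pairing's feature rows; cell = max score over its models.

    ``rows_by_pairing`` maps (ligand, receptor) to the 1-5 feature rows of
    that pairing's predicted models (features already extracted with the
    ligand chains grouped as entity 1).  Missing pairings raise an error
    listing the gaps — a selectivity screen is only interpretable complete.
    """
    pairings = enumerate_pairings(ligands, receptors)
    missing = [p for p in pairings if p not in rows_by_pairing]
    if missing:
        raise DataError(f"incomplete grid; missing pairings: {missing}")
    scores = np.zeros((len(ligands), len(receptors)))
    for i, l in enumerate(ligands):
        for j, r in enumerate(receptors):
            rows = rows_by_pairing[(l, r)]
            score, _ = score_complex(classifier, rows)
            scores[i, j] = score
    return SelectivityGrid(list(ligands), list(receptors), scores, known_mask)


def topk_hits(grid: SelectivityGrid, k: int = 1,
              known_mask: np.ndarray | None = None) -> tuple[dict[str, bool], int]:
    """Per-ligand: is any known receptor among the k top-scoring receptors?

    Score ties break lexicographically by receptor id.  Ligands with no known
    receptor are excluded with a warning.  Returns (per-ligand hit map,
    aggregate hit count).
    """
    mask = known_mask if known_mask is not None else grid.known_mask
    if mask is None:
        raise DataError("topk_hits requires a known-interaction mask")
    mask = np.asarray(mask, dtype=bool)
    hits: dict[str, bool] = {}
    lex_rank = np.empty(len(grid.receptors), dtype=int)
    for rank, j in enumerate(np.argsort(grid.receptors)):
        lex_rank[j] = rank
    for i, lig in enumerate(grid.ligands):
        if not mask[i].any():
            warnings.warn(f"ligand {lig!r} has no known receptor; excluded", stacklevel=2)
            continue
        # sort by score descending, ties by receptor id ascending
        order = sorted(range(len(grid.receptors)),
                       key=lambda j: (-grid.scores[i, j], lex_rank[j]))
        hits[lig] = bool(mask[i, order[:k]].any())
    return hits, sum(hits.values())


def grid_roc(grid: SelectivityGrid,
             known_mask: np.ndarray | None = None) -> tuple[float, pd.DataFrame]:
    """AUC (and ROC curve points) over the flattened grid cells."""
    mask = known_mask if known_mask is not None else grid.known_mask
    if mask is None:
        raise DataError("grid_roc requires a known-interaction mask")
    y = np.asarray(mask, dtype=bool).ravel().astype(int)
    s = grid.scores.ravel()
    if y.min() == y.max():
        raise MetricError("known-interaction mask has a single class")
    auc = roc_auc(s, y)
    order = np.argsort(-s, kind="stable")
    tps = np.cumsum(y[order])
    fps = np.cumsum(1 - y[order])
    curve = pd.DataFrame({
        "FPR": np.concatenate([[0.0], fps / max(1, fps[-1])]),
        "TPR": np.concatenate([[0.0], tps / max(1, tps[-1])]),
    })
    return auc, curve
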