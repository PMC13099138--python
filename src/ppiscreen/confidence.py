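"""Predictor-confidence feature block.

The two bespoke PAE statistics:

* ``ipae_top_quarter`` — PAE values over *interacting* residue pairs (the
  interface map); the highest quarter is averaged.  Low values mean the
  predictor is confident about the contacts it actually built.
* ``tpae_top_quarter`` — PAE values over *all* cross-entity residue pairs;
  the lowest (best) quarter is averaged.  Low values mean the predictor is
  confident about the relative placement of the two entities somewhere.

The quarter uses k = ceil(n/4) (minimum 1), and each pair value is the mean
of the two matrix directions pae[i, j] and pae[j, i].
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import PAE_MAX
from .errors import UndefinedStatisticError
from .interface import InterfaceMap
from .structio import ComplexModel, ConfidenceBundle


@dataclass
class PaePairValues:
    values: np.ndarray
    source: str  # "interacting_pairs" | "all_interchain"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def is_empty(self) -> bool:
        return self.values.size == 0


def _pair_value(pae: np.ndarray, i: np.ndarray, j: np.ndarray, policy: str) -> np.ndarray:
    if policy == "mean":
        return 0.5 * (pae[i, j] + pae[j, i])
    if policy == "ij":
        return pae[i, j]
    if policy == "max":
        return np.maximum(pae[i, j], pae[j, i])
    raise ValueError(f"unknown direction policy {policy!r}")


def interacting_pair_pae(conf: ConfidenceBundle, iface: InterfaceMap,
                         direction_policy: str = "mean") -> PaePairValues:
    """One PAE value per interface pair (symmetric mean of both directions)."""
    if iface.is_empty:
        return PaePairValues(np.empty(0), "interacting_pairs")
    idx = np.asarray(iface.pairs, dtype=int)
    vals = _pair_value(conf.pae, idx[:, 0], idx[:, 1], direction_policy)
    return PaePairValues(vals, "interacting_pairs")


def all_interchain_pae(conf: ConfidenceBundle, model: ComplexModel,
                       direction_policy: str = "mean") -> PaePairValues:
    """One PAE value per cross-entity residue pair (N1 x N2 values)."""
    i1 = model.entity_indices(1)
    i2 = model.entity_indices(2)
    ii, jj = np.meshgrid(i1, i2, indexing="ij")
    vals = _pair_value(conf.pae, ii.ravel(), jj.ravel(), direction_policy)
    return PaePairValues(vals, "all_interchain")


def top_quarter_mean(vals: PaePairValues | np.ndarray, mode: str) -> float:
    """Mean of the k = ceil(n/4) highest (or lowest) values."""
    v = vals.values if isinstance(vals, PaePairValues) else np.asarray(vals, dtype=float)
    n = v.size
    if n == 0:
        raise UndefinedStatisticError("top_quarter_mean undefined on empty input")
    k = max(1, math.ceil(n / 4))
    v = np.sort(v)
    if mode == "highest":
        return float(np.mean(v[n - k :]))
    if mode == "lowest":
        return float(np.mean(v[:k]))
    raise ValueError(f"unknown mode {mode!r}")


def confidence_feature_block(model: ComplexModel, conf: ConfidenceBundle,
                             iface: InterfaceMap,
                             direction_policy: str = "mean") -> dict[str, float]:
    """The 7 confidence features, manifest-ordered.

    Contact-free models get the sentinel PAE maximum (31.75 A) for PAE
    statistics and 0 for interface-pLDDT statistics, pushing them toward
    decoy-like scores.
    """
    inter = all_interchain_pae(conf, model, direction_policy)
    ipae = interacting_pair_pae(conf, iface, direction_policy)

    if ipae.is_empty:
        ipae_top = PAE_MAX
        mean_iface_plddt = 0.0
    else:
        ipae_top = top_quarter_mean(ipae, "highest")
        iface_idx = sorted(iface.residue_set)
        mean_iface_plddt = float(np.mean(conf.plddt[iface_idx]))

    tpae_top = top_quarter_mean(inter, "lowest") if not inter.is_empty else PAE_MAX
    mean_interchain = float(np.mean(inter.values)) if not inter.is_empty else PAE_MAX

    ent_means = [
        float(np.mean(conf.plddt[model.entity_indices(e)])) for e in (1, 2)
    ]
    return {
        "ipae_top_quarter": float(ipae_top),
        "tpae_top_quarter": float(tpae_top),
        "mean_interchain_pae": mean_interchain,
        "mean_iface_plddt": mean_iface_plddt,
        "min_entity_mean_plddt": min(ent_means),
        "ptm": float(conf.ptm),
        "iptm": float(conf.iptm),
    }
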