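"""Interface energy features.

Self-contained analogs of the classic molecular-mechanics interface terms:
a 12-6 Lennard-Jones potential split into attractive and repulsive parts, a
distance-dependent-dielectric Coulomb term, a Lazaridis–Karplus-style
Gaussian-occlusion solvation term, and a backbone hydrogen-bond term.  All
evaluation is heavy-atom only (predicted models vary in hydrogen placement)
and restricted to cross-entity contacts: the per-residue energy of an
interfacial residue is the sum of its atoms' interactions with the *other*
entity.

Parameters (per-atom-class sigma/epsilon, partial charges, solvation
constants) ship as JSON data; these are original CHARMM-like values, not a
port of any external scorer.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .config import (
    ELEC_CUTOFF,
    HBOND_ENERGY_CUTOFF,
    LJ_CUTOFF,
    SOLV_CUTOFF,
    SWITCH_WIDTH,
    COULOMB_CONSTANT,
)
from .errors import GeometryError
from .interface import InterfaceMap, hbond_energy_matrix
from .manifest import energy_features
from .structio import AA_ONE_TO_THREE, ComplexModel, Residue

_AROMATIC_CARBONS = {
    "F": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "Y": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "W": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "H": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
_O_HYDROXYL = {("S", "OG"), ("T", "OG1"), ("Y", "OH")}
_O_CHARGED = {("D", "OD1"), ("D", "OD2"), ("E", "OE1"), ("E", "OE2")}
_N_CHARGED = {("K", "NZ"), ("R", "NE"), ("R", "NH1"), ("R", "NH2")}


@dataclass(frozen=True)
class EnergyParams:
    """Atom-class parameter table plus partial charges and term weights."""

    classes: dict
    charges: dict
    weights: dict
    version: str

    @staticmethod
    @lru_cache(maxsize=1)
    def default() -> "EnergyParams":
        with resources.files("ppiscreen.data").joinpath("energy_params.json").open() as fh:
            raw = json.load(fh)
        return EnergyParams(raw["classes"], raw["charges"], raw["weights"], raw["version"])

    def atom_class(self, aa: str, atom_name: str, element: str) -> str:
        if atom_name in ("N",):
            return "N_amide"
        if atom_name in ("CA", "CB"):
            return "C_ali"
        if atom_name == "C":
            return "C_carbonyl"
        if atom_name in ("O", "OXT"):
            return "O_carbonyl"
        if atom_name in _AROMATIC_CARBONS.get(aa, ()) and element == "C":
            return "C_aro"
        if (aa, atom_name) in _O_HYDROXYL:
            return "O_hydroxyl"
        if (aa, atom_name) in _O_CHARGED:
            return "O_charged"
        if (aa, atom_name) in _N_CHARGED:
            return "N_charged"
        return {"C": "C_ali", "N": "N_amide", "O": "O_carbonyl", "S": "S"}.get(
            element, "C_ali"
        )

    def charge(self, aa: str, atom_name: str) -> float:
        q = self.charges["backbone"].get(atom_name)
        if q is not None and atom_name in ("N", "CA", "C", "O"):
            return q
        three = AA_ONE_TO_THREE.get(aa)
        if three and three in self.charges["sidechain"]:
            return self.charges["sidechain"][three].get(atom_name, 0.0)
        return 0.0

    def of(self, cls: str) -> dict:
        return self.classes[cls]


def _switch(d: float, cutoff: float) -> float:
    """Linear switch to zero over the last SWITCH_WIDTH before the cutoff."""
    if d >= cutoff:
        return 0.0
    lo = cutoff - SWITCH_WIDTH
    if d <= lo:
        return 1.0
    return (cutoff - d) / SWITCH_WIDTH


def pair_lj(d: float, sigma_ij: float, eps_ij: float) -> tuple[float, float]:
    """Split 12-6 Lennard-Jones: (attractive <= 0, repulsive >= 0).

    LJ(d) = eps*[(sigma/d)^12 - 2(sigma/d)^6] has its minimum -eps at
    d = sigma.  Below sigma the attractive part is pinned at -eps and the
    excess goes to the repulsive part, so clashes register only as repulsion.
    """
    if d <= 0:
        raise GeometryError("pair_lj requires d > 0")
    s = _switch(d, LJ_CUTOFF)
    if s == 0.0:
        return 0.0, 0.0
    x6 = (sigma_ij / d) ** 6
    lj = eps_ij * (x6 * x6 - 2.0 * x6)
    if d < sigma_ij:
        return -eps_ij * s, (lj + eps_ij) * s
    return lj * s, 0.0


def pair_elec(d: float, qi: float, qj: float) -> float:
    """Coulomb with distance-dependent dielectric eps(d) = d; hard 10 A cutoff."""
    if d <= 0:
        raise GeometryError("pair_elec requires d > 0")
    if d > ELEC_CUTOFF or qi == 0.0 or qj == 0.0:
        return 0.0
    return COULOMB_CONSTANT * qi * qj / (d * d)


def _solv_term(d: float, p_i: dict, v_j: float) -> float:
    """Desolvation of atom i (params p_i) by an occluding atom of volume v_j."""
    s = _switch(d, SOLV_CUTOFF)
    if s == 0.0:
        return 0.0
    lam = p_i["lambda_"]
    x = (d - p_i["radius"]) / lam
    pref = p_i["dg_free"] / (2.0 * np.pi ** 1.5 * lam * d * d)
    return pref * np.exp(-x * x) * v_j * s


@dataclass
class _AtomTable:
    coords: np.ndarray      # (M, 3)
    cls: list[str]
    charge: np.ndarray      # (M,)
    owner: np.ndarray       # residue positional index per atom
    entity: np.ndarray      # 1/2 per atom


def _atom_table(model: ComplexModel, params: EnergyParams) -> _AtomTable:
    coords, cls, charge, owner = [], [], [], []
    for i, res in enumerate(model.residues()):
        for a in res.atoms:
            if a.element == "H":
                continue
            coords.append(a.coords)
            cls.append(params.atom_class(res.aa_type, a.atom_name, a.element))
            charge.append(params.charge(res.aa_type, a.atom_name))
            owner.append(i)
    ent_of_res = model.entity_of_residue()
    owner = np.asarray(owner, dtype=int)
    return _AtomTable(np.asarray(coords, float), cls, np.asarray(charge, float),
                      owner, ent_of_res[owner])


def _atom_pair_terms(table: _AtomTable, params: EnergyParams,
                     ai: int, aj: int, d: float) -> tuple[float, float, float, float]:
    """(atr, rep, elec, solv_of_i_plus_j) for one cross-entity atom pair."""
    pi = params.of(table.cls[ai])
    pj = params.of(table.cls[aj])
    sigma_ij = 0.5 * (pi["sigma"] + pj["sigma"])
    eps_ij = float(np.sqrt(pi["eps"] * pj["eps"]))
    atr, rep = pair_lj(d, sigma_ij, eps_ij) if d <= LJ_CUTOFF else (0.0, 0.0)
    elec = pair_elec(d, table.charge[ai], table.charge[aj]) if d <= ELEC_CUTOFF else 0.0
    solv = 0.0
    if d <= SOLV_CUTOFF:
        solv = _solv_term(d, pi, pj["volume"]) + _solv_term(d, pj, pi["volume"])
    return atr, rep, elec, solv


def residue_solvation(residue: Residue, model: ComplexModel,
                      params: EnergyParams | None = None,
                      neighbors: str = "other_entity") -> float:
    """Gaussian-occlusion desolvation of one residue's atoms, kcal/mol.

    ``neighbors`` selects the occluding atom set: ``"other_entity"`` (the
    cross-entity convention used by the feature block) or ``"all"`` (every
    heavy atom outside the residue).
    """
    params = params or EnergyParams.default()
    table = _atom_table(model, params)
    residues = model.residues()
    try:
        ridx = next(i for i, r in enumerate(residues) if r is residue or r.key == residue.key)
    except StopIteration:
        raise GeometryError(f"residue {residue.key} not found in model") from None
    mine = np.where(table.owner == ridx)[0]
    if neighbors == "other_entity":
        my_ent = table.entity[mine[0]]
        others = np.where(table.entity != my_ent)[0]
    else:
        others = np.where(table.owner != ridx)[0]
    total = 0.0
    for ai in mine:
        pi = params.of(table.cls[ai])
        dists = np.linalg.norm(table.coords[others] - table.coords[ai], axis=1)
        for aj, d in zip(others[dists <= SOLV_CUTOFF], dists[dists <= SOLV_CUTOFF]):
            total += _solv_term(float(d), pi, params.of(table.cls[aj])["volume"])
    return float(total)


_TERMS = ("lj_atr", "lj_rep", "solv", "elec", "hbond")


def per_residue_energy(model: ComplexModel, iface: InterfaceMap,
                       params: EnergyParams | None = None) -> dict[int, dict[str, float]]:
    """Cross-entity term sums for every interface residue.

    Hydrogen-bond energy is split half/half between donor and acceptor so
    totals over residues count each bond once.
    """
    params = params or EnergyParams.default()
    table = _atom_table(model, params)
    out: dict[int, dict[str, float]] = {
        i: {t: 0.0 for t in _TERMS} for i in iface.residue_set
    }
    if not out:
        return out

    e2_mask = table.entity == 2
    tree2 = cKDTree(table.coords[e2_mask])
    idx2 = np.where(e2_mask)[0]
    idx1 = np.where(~e2_mask)[0]
    max_cut = max(LJ_CUTOFF, SOLV_CUTOFF, ELEC_CUTOFF)
    for ai in idx1:
        hits = tree2.query_ball_point(table.coords[ai], r=max_cut)
        for jj in hits:
            aj = int(idx2[jj])
            d = float(np.linalg.norm(table.coords[aj] - table.coords[ai]))
            if d <= 0:
                raise GeometryError("coincident cross-entity atoms")
            atr, rep, elec, solv = _atom_pair_terms(table, params, ai, aj, d)
            ri, rj = int(table.owner[ai]), int(table.owner[aj])
            # solvation of i by j / of j by i handled inside _atom_pair_terms as a
            # symmetric sum; split it by recomputing each side for attribution
            pi = params.of(table.cls[ai])
            pj = params.of(table.cls[aj])
            solv_i = _solv_term(d, pi, pj["volume"]) if d <= SOLV_CUTOFF else 0.0
            solv_j = _solv_term(d, pj, pi["volume"]) if d <= SOLV_CUTOFF else 0.0
            for r, my_atr, my_rep, my_elec, my_solv in (
                (ri, atr, rep, elec, solv_i),
                (rj, atr, rep, elec, solv_j),
            ):
                if r in out:
                    out[r]["lj_atr"] += my_atr
                    out[r]["lj_rep"] += my_rep
                    out[r]["elec"] += my_elec
                    out[r]["solv"] += my_solv

    # Cross-entity backbone hydrogen bonds.
    E = hbond_energy_matrix(model)
    ent = model.entity_of_residue()
    di, aj = np.where(E < HBOND_ENERGY_CUTOFF)
    for i, j in zip(di, aj):
        if ent[i] == ent[j]:
            continue
        for r in (int(i), int(j)):
            if r in out:
                out[r]["hbond"] += 0.5 * float(E[i, j])
    return out


def residue_pair_terms(model: ComplexModel, pair: tuple[int, int],
                       params: EnergyParams | None = None) -> dict[str, float]:
    """LJ/electrostatic terms between the atoms of one cross-entity residue pair."""
    params = params or EnergyParams.default()
    residues = model.residues()
    ri, rj = residues[pair[0]], residues[pair[1]]
    out = {"lj_atr": 0.0, "lj_rep": 0.0, "elec": 0.0}
    for a in ri.atoms:
        if a.element == "H":
            continue
        ca = params.atom_class(ri.aa_type, a.atom_name, a.element)
        qa = params.charge(ri.aa_type, a.atom_name)
        for b in rj.atoms:
            if b.element == "H":
                continue
            cb = params.atom_class(rj.aa_type, b.atom_name, b.element)
            qb = params.charge(rj.aa_type, b.atom_name)
            d = float(np.linalg.norm(a.coords - b.coords))
            if d <= 0:
                raise GeometryError("coincident atoms in residue pair")
            pa, pb = params.of(ca), params.of(cb)
            sigma_ij = 0.5 * (pa["sigma"] + pb["sigma"])
            eps_ij = float(np.sqrt(pa["eps"] * pb["eps"]))
            atr, rep = pair_lj(d, sigma_ij, eps_ij)
            out["lj_atr"] += atr
            out["lj_rep"] += rep
            out["elec"] += pair_elec(d, qa, qb)
    return out


def energy_feature_block(model: ComplexModel, iface: InterfaceMap,
                         params: EnergyParams | None = None) -> dict[str, float]:
    """The 17 energy features, manifest-ordered; all zero for empty interfaces."""
    params = params or EnergyParams.default()
    names = energy_features()
    if iface.is_empty:
        return {n: 0.0 for n in names}

    per_res = per_residue_energy(model, iface, params)
    n_res = len(per_res)
    totals = {t: sum(v[t] for v in per_res.values()) for t in _TERMS}
    w = params.weights
    weighted_of = {
        r: sum(w[t] * terms[t] for t in _TERMS) for r, terms in per_res.items()
    }
    weighted_total = sum(weighted_of.values())

    pair_terms = [residue_pair_terms(model, p, params) for p in iface.pairs]
    n_pairs = len(pair_terms)

    feats = {
        "total_lj_atr": totals["lj_atr"],
        "total_lj_rep": totals["lj_rep"],
        "total_solv": totals["solv"],
        "total_elec": totals["elec"],
        "total_hbond": totals["hbond"],
        "avg_lj_atr": totals["lj_atr"] / n_res,
        "avg_lj_rep": totals["lj_rep"] / n_res,
        "avg_solv": totals["solv"] / n_res,
        "avg_elec": totals["elec"] / n_res,
        "avg_hbond": totals["hbond"] / n_res,
        "weighted_total": weighted_total,
        "avg_weighted_total": weighted_total / n_res,
        "mean_pair_lj_atr": sum(p["lj_atr"] for p in pair_terms) / n_pairs,
        "mean_pair_lj_rep": sum(p["lj_rep"] for p in pair_terms) / n_pairs,
        "mean_pair_elec": sum(p["elec"] for p in pair_terms) / n_pairs,
        "min_residue_weighted": min(weighted_of.values()),
        "max_residue_rep": max(v["lj_rep"] for v in per_res.values()),
    }
    return {n: float(feats[n]) for n in names}
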