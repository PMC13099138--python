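"""Docking-model quality: Kabsch superposition, Fnat, iRMS, LRMS, DockQ.

DockQ combines three complementary measures of how well a modeled complex
reproduces a native (experimentally derived) structure:

    DockQ = ( Fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2) ) / 3

* Fnat — fraction of native cross-entity residue contacts (any heavy-atom
  pair within 5 A) that the model preserves;
* iRMS — backbone RMSD over the native interface residues (10 A heavy-atom
  definition) after superposing the model interface onto the native;
* LRMS — backbone RMSD of the ligand (smaller entity) after superposing on
  the receptor (larger entity) backbone.

A score of at least 0.23 is the conventional "acceptable-model" cutoff used
to filter predicted actives before training.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import (
    DOCKQ_ACCEPTABLE,
    DOCKQ_CONTACT_CUTOFF,
    DOCKQ_IFACE_CUTOFF,
    DOCKQ_IRMS_SCALE,
    DOCKQ_LRMS_SCALE,
)
from .errors import QualityError, SuperpositionError
from .structio import ComplexModel

BACKBONE = ("N", "CA", "C", "O")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, det = +1
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid transform of B onto A (proper rotation enforced)."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise SuperpositionError(f"coordinate shapes {A.shape} / {B.shape} incompatible")
    n = A.shape[0]
    if n < 3:
        raise SuperpositionError(f"need >= 3 points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, S, Vt = np.linalg.svd(H)
    # collinearity check: rank of the centered clouds
    if np.linalg.matrix_rank(A - ca) < 2:
        raise SuperpositionError("degenerate (collinear) coordinates")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd)


# ---------------------------------------------------------------------------
# Residue correspondence and contacts
# ---------------------------------------------------------------------------

def _residue_maps(model: ComplexModel):
    return {r.key: r for r in model.residues()}


def _entity_keys(model: ComplexModel, entity: int) -> set:
    res = model.residues()
    return {res[i].key for i in model.entity_indices(entity)}


def _contacts(model: ComplexModel, cutoff: float) -> set[tuple]:
    """Cross-entity residue-key pairs with any heavy-atom distance <= cutoff."""
    coords, owner = model.heavy_atoms()
    ent = model.entity_of_residue()[owner]
    res = model.residues()
    c1, c2 = coords[ent == 1], coords[ent == 2]
    o1, o2 = owner[ent == 1], owner[ent == 2]
    if len(c1) == 0 or len(c2) == 0:
        return set()
    t2 = cKDTree(c2)
    out = set()
    for a, hits in enumerate(cKDTree(c1).query_ball_tree(t2, r=cutoff)):
        for b in hits:
            out.add((res[o1[a]].key, res[o2[b]].key))
    return out


def fnat(model: ComplexModel, native: ComplexModel) -> float:
    """Fraction of native cross-entity contacts preserved in the model.

    Correspondence is by (chain_id, seq_index, insertion code).
    """
    native_contacts = _contacts(native, DOCKQ_CONTACT_CUTOFF)
    if not native_contacts:
        raise QualityError("native structure has no cross-entity contacts")
    model_contacts = _contacts(model, DOCKQ_CONTACT_CUTOFF)
    return len(native_contacts & model_contacts) / len(native_contacts)


def _paired_backbone(model: ComplexModel, native: ComplexModel, keys: list[tuple]):
    """Backbone coordinates present in both structures, in matching order."""
    bm, bn = _residue_maps(model), _residue_maps(native)
    cm, cn = [], []
    for k in keys:
        rm, rn = bm.get(k), bn.get(k)
        if rm is None or rn is None:
            continue
        for name in BACKBONE:
            a, b = rm.coord(name), rn.coord(name)
            if a is not None and b is not None:
                cm.append(a)
                cn.append(b)
    return np.asarray(cm, float), np.asarray(cn, float)


def irms(model: ComplexModel, native: ComplexModel) -> float:
    """Backbone RMSD over native-interface residues after interface superposition."""
    iface_contacts = _contacts(native, DOCKQ_IFACE_CUTOFF)
    if not iface_contacts:
        raise QualityError("native structure has no interface (10 A)")
    keys = sorted({k for pair in iface_contacts for k in pair})
    cm, cn = _paired_backbone(model, native, keys)
    if len(cm) < 3:
        raise QualityError("too few corresponding interface backbone atoms")
    return kabsch_superpose(cn, cm).rmsd


def lrms(model: ComplexModel, native: ComplexModel) -> float:
    """Ligand backbone RMSD after superposing on the receptor backbone.

    Receptor = larger entity by residue count (entity 1 on ties).
    """
    n1 = native.entity_residue_count(1)
    n2 = native.entity_residue_count(2)
    receptor, ligand = (1, 2) if n1 >= n2 else (2, 1)
    rec_keys = sorted(_entity_keys(native, receptor))
    lig_keys = sorted(_entity_keys(native, ligand))
    rm, rn = _paired_backbone(model, native, rec_keys)
    if len(rm) < 3:
        raise QualityError("too few receptor backbone atoms for superposition")
    sup = kabsch_superpose(rn, rm)  # model receptor onto native receptor
    lm, ln = _paired_backbone(model, native, lig_keys)
    if len(lm) == 0:
        raise QualityError("no corresponding ligand backbone atoms")
    moved = sup.apply(lm)
    return float(np.sqrt(np.mean(np.sum((moved - ln) ** 2, axis=1))))


def dockq_from_components(fnat_val: float, irms_val: float, lrms_val: float) -> float:
    """DockQ composite from its three components."""
    return (
        fnat_val
        + 1.0 / (1.0 + (irms_val / DOCKQ_IRMS_SCALE) ** 2)
        + 1.0 / (1.0 + (lrms_val / DOCKQ_LRMS_SCALE) ** 2)
    ) / 3.0


def dockq(model: ComplexModel, native: ComplexModel) -> float:
    """DockQ score of a model against its native structure, in [0, 1]."""
    return dockq_from_components(
        fnat(model, native), irms(model, native), lrms(model, native)
    )


def is_acceptable(dockq_score: float, threshold: float = DOCKQ_ACCEPTABLE) -> bool:
    """Acceptable-model filter (inclusive boundary)."""
    return dockq_score >= threshold
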