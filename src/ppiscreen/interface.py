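"""Interface detection, residue classification and secondary structure.

A residue is *interfacial* when its representative atom — the C-beta, or the
C-alpha for glycine — lies within a cutoff (default 12 A, inclusive) of a
representative atom on the other entity.  Secondary structure is assigned
from backbone hydrogen-bond patterns using the Kabsch–Sander electrostatic
energy, so interface beta-sheet content can be computed without an external
assignment program.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import HBOND_ENERGY_CUTOFF, HBOND_Q1Q2_FACTOR, INTERFACE_CUTOFF
from .errors import DataError, GeometryError
from .structio import ComplexModel, Residue

# Residue class table.  Charged = {D,E,K,R}; histidine is treated as polar.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset({"hydrophobic"}),
    "C": frozenset({"polar"}),
    "D": frozenset({"charged-"}),
    "E": frozenset({"charged-"}),
    "F": frozenset({"hydrophobic", "aromatic"}),
    "G": frozenset({"special"}),
    "H": frozenset({"polar", "aromatic"}),
    "I": frozenset({"hydrophobic"}),
    "K": frozenset({"charged+"}),
    "L": frozenset({"hydrophobic"}),
    "M": frozenset({"hydrophobic"}),
    "N": frozenset({"polar"}),
    "P": frozenset({"special"}),
    "Q": frozenset({"polar"}),
    "R": frozenset({"charged+"}),
    "S": frozenset({"polar"}),
    "T": frozenset({"polar"}),
    "V": frozenset({"hydrophobic"}),
    "W": frozenset({"hydrophobic", "aromatic"}),
    "Y": frozenset({"polar", "aromatic"}),
    "X": frozenset(),
}

CHARGED = frozenset("DEKR")


def classify_residue(aa: str) -> frozenset[str]:
    """Class membership of a one-letter code (may be multi-class, e.g. F)."""
    try:
        return RESIDUE_CLASSES[aa]
    except KeyError:
        raise DataError(f"unknown amino-acid code {aa!r}") from None


def primary_class(aa: str) -> str:
    """Single-class assignment used for contact-pair counting."""
    classes = classify_residue(aa)
    if classes & {"charged+", "charged-"}:
        return "charged"
    if "special" in classes:
        return "special"
    if "hydrophobic" in classes:
        return "hydrophobic"
    return "polar"  # polar, aromatic-polar, and X


def representative_atom(residue: Residue) -> np.ndarray:
    """C-beta coordinate; C-alpha for glycine; C-alpha fallback with warning."""
    if residue.aa_type == "G":
        ca = residue.coord("CA")
        if ca is None:
            raise GeometryError(f"glycine {residue.key} lacks CA")
        return ca
    cb = residue.coord("CB")
    if cb is not None:
        return cb
    ca = residue.coord("CA")
    if ca is not None:
        warnings.warn(
            f"residue {residue.key} ({residue.aa_type}) lacks CB; using CA", stacklevel=2
        )
        return ca
    raise GeometryError(f"residue {residue.key} has neither CB nor CA")


@dataclass
class InterfaceMap:
    """Cross-entity residue pairs within the cutoff, plus per-entity index sets."""

    pairs: list[tuple[int, int]]          # (entity-1 index, entity-2 index), positional
    iface_set1: set[int] = field(default_factory=set)
    iface_set2: set[int] = field(default_factory=set)
    cutoff: float = INTERFACE_CUTOFF

    @property
    def is_empty(self) -> bool:
        return not self.pairs

    @property
    def residue_set(self) -> set[int]:
        return self.iface_set1 | self.iface_set2


def find_interface(model: ComplexModel, cutoff: float = INTERFACE_CUTOFF) -> InterfaceMap:
    """All cross-entity residue pairs whose representative atoms are <= cutoff apart."""
    residues = model.residues()
    rep = np.array([representative_atom(r) for r in residues])
    idx1 = model.entity_indices(1)
    idx2 = model.entity_indices(2)
    t1 = cKDTree(rep[idx1])
    t2 = cKDTree(rep[idx2])
    hits = t1.query_ball_tree(t2, r=cutoff)  # inclusive boundary
    pairs, s1, s2 = [], set(), set()
    for a, js in zip(idx1, hits):
        for b in sorted(int(idx2[j]) for j in js):
            pairs.append((int(a), b))
            s1.add(int(a))
            s2.add(b)
    return InterfaceMap(pairs, s1, s2, cutoff)


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch–Sander style H-bond patterns)
# ---------------------------------------------------------------------------

def _amide_hydrogens(residues: list[Residue]) -> np.ndarray:
    """Approximate amide-H positions (NaN where undefined, e.g. chain starts/PRO)."""
    n = len(residues)
    H = np.full((n, 3), np.nan)
    for i, r in enumerate(residues):
        if r.aa_type == "P":
            continue
        nN = r.coord("N")
        ca = r.coord("CA")
        if nN is None or ca is None or i == 0:
            continue
        prev = residues[i - 1]
        if prev.chain_id != r.chain_id:
            continue
        c_prev = prev.coord("C")
        if c_prev is None:
            continue
        v1 = nN - c_prev
        v2 = nN - ca
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-9 or n2 < 1e-9:
            continue
        d = v1 / n1 + v2 / n2
        dn = np.linalg.norm(d)
        if dn < 1e-9:
            continue
        H[i] = nN + 1.01 * d / dn
    return H


def hbond_energy_matrix(model: ComplexModel | list[Residue]) -> np.ndarray:
    """E[i, j] = Kabsch–Sander energy of N-H(i) donating to C=O(j), kcal/mol.

    Entries are +inf where the bond is undefined (missing atoms, i == j,
    or sequence neighbors in the same chain).  Accepts a full model or a
    plain residue list (e.g. a single chain).
    """
    residues = model.residues() if isinstance(model, ComplexModel) else model
    n = len(residues)
    N = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    for i, r in enumerate(residues):
        for arr, name in ((N, "N"), (C, "C"), (O, "O")):
            c = r.coord(name)
            if c is not None:
                arr[i] = c
    H = _amide_hydrogens(residues)

    E = np.full((n, n), np.inf)
    donors = np.where(~np.isnan(H[:, 0]) & ~np.isnan(N[:, 0]))[0]
    acceptors = np.where(~np.isnan(O[:, 0]) & ~np.isnan(C[:, 0]))[0]
    if donors.size == 0 or acceptors.size == 0:
        return E
    # Restrict to donor/acceptor pairs with N..O within 5.2 A (KS bonds are short).
    tree = cKDTree(O[acceptors])
    for i in donors:
        for jj in tree.query_ball_point(N[i], r=5.2):
            j = int(acceptors[jj])
            if i == j:
                continue
            ri, rj = residues[i], residues[j]
            if ri.chain_id == rj.chain_id and abs(i - j) < 2:
                continue
            r_on = np.linalg.norm(O[j] - N[i])
            r_ch = np.linalg.norm(C[j] - H[i])
            r_oh = np.linalg.norm(O[j] - H[i])
            r_cn = np.linalg.norm(C[j] - N[i])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                E[i, j] = -9.9  # clash convention: strongly bonded
                continue
            E[i, j] = HBOND_Q1Q2_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    return E


def assign_secondary_structure(model: ComplexModel | list[Residue]) -> list[str]:
    """Per-residue labels in {H, E, C} from backbone H-bond patterns.

    H: residues covered by runs of >=2 consecutive i -> i+4 hydrogen bonds
    (donor i+4, acceptor i).  E: residues in parallel or antiparallel bridge
    ladders of length >=2.  Everything else (including residues with missing
    backbone) degrades to C.
    """
    residues = model.residues() if isinstance(model, ComplexModel) else model
    n = len(residues)
    labels = ["C"] * n
    if n < 4:
        return labels
    E = hbond_energy_matrix(model)
    hb = E < HBOND_ENERGY_CUTOFF  # hb[d, a]: N-H of d bonds to C=O of a

    def same_chain(i: int, j: int) -> bool:
        return residues[i].chain_id == residues[j].chain_id

    # Alpha helix: hb(i+4 -> i) and hb(i+5 -> i+1) => residues i+1 .. i+5.
    turn = [
        i
        for i in range(n - 4)
        if same_chain(i, i + 4) and hb[i + 4, i]
    ]
    turn_set = set(turn)
    helix = set()
    for i in turn:
        if i + 1 in turn_set:
            helix.update(range(i + 1, i + 6))
    for i in helix:
        if i < n:
            labels[i] = "H"

    # Beta bridges.
    bridges: set[tuple[int, int]] = set()
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(i - j) < 3 and same_chain(i, j):
                continue
            parallel = (hb[i, j - 1] and hb[j + 1, i]) or (hb[j, i - 1] and hb[i + 1, j])
            antiparallel = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if parallel or antiparallel:
                bridges.add((min(i, j), max(i, j)))
    # Ladders: a bridge extended by an adjacent bridge (length >= 2).
    for (i, j) in bridges:
        for (di, dj) in ((1, 1), (1, -1)):
            if (min(i + di, j + dj), max(i + di, j + dj)) in bridges:
                for k in (i, j, i + di, j + dj):
                    if 0 <= k < n and labels[k] != "H":
                        labels[k] = "E"
    return labels
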