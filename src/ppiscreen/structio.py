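"""Structure and confidence-file I/O.

Parses predicted complex models (PDB or mmCIF, via gemmi) into a light
in-memory representation partitioned into exactly two screening *entities*
(chain groups).  An entity may comprise several chains — e.g. the three
copies of a trimeric ligand screened against a single receptor chain — and
every downstream "interchain" definition (interface, PAE statistics, energy
terms) means *cross-entity*.

Also reads the per-model confidence bundle (per-residue pLDDT, the N x N
predicted-aligned-error matrix in Angstrom, pTM and iPTM) from a JSON score
file, validating that its dimension matches the paired structure.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    DialectError,
    EntitySpecError,
    PairingError,
    ParseError,
    RecordError,
    StructuralError,
    ValidationError,
)

logger = logging.getLogger(__name__)

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}
AA_ALPHABET = set(AA_THREE_TO_ONE.values()) | {"X"}


@dataclass
class AtomRecord:
    atom_name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    temp_factor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.atom_name!r}: coords must be a finite 3-vector")
        if not self.atom_name:
            raise ValidationError("atom_name must be non-empty")


@dataclass
class Residue:
    chain_id: str
    seq_index: int          # author numbering
    aa_type: str            # one-letter code or X
    atoms: list[AtomRecord] = field(default_factory=list)
    icode: str = ""         # insertion code, ordered after the base residue

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coords

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_index, self.icode)


@dataclass
class ComplexModel:
    """A multi-chain model partitioned into two screening entities."""

    complex_id: str
    model_rank: int
    chains: dict[str, list[Residue]]          # insertion order = chain order
    entity_of_chain: dict[str, int]           # chain_id -> {1, 2}

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ents = set(self.entity_of_chain.values())
        if ents != {1, 2}:
            raise StructuralError(
                f"model {self.complex_id!r}: must have exactly two entities, got {sorted(ents)}"
            )
        for cid in self.chains:
            if cid not in self.entity_of_chain:
                raise EntitySpecError(f"chain {cid!r} missing from entity spec")
        for e in (1, 2):
            if self.entity_residue_count(e) == 0:
                raise StructuralError(f"entity {e} has no residues")

    # -- residue bookkeeping (positional, concatenated chain order) ---------

    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        for cid in self.chains:
            out.extend(self.chains[cid])
        return out

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def entity_indices(self, entity: int) -> np.ndarray:
        """0-based positional indices (concatenated chain order) of one entity."""
        idx, pos = [], 0
        for cid in self.chains:
            n = len(self.chains[cid])
            if self.entity_of_chain[cid] == entity:
                idx.extend(range(pos, pos + n))
            pos += n
        return np.asarray(idx, dtype=int)

    def entity_residue_count(self, entity: int) -> int:
        return sum(
            len(res) for cid, res in self.chains.items() if self.entity_of_chain[cid] == entity
        )

    def entity_of_residue(self) -> np.ndarray:
        ent = np.empty(self.n_residues, dtype=int)
        ent[self.entity_indices(1)] = 1
        ent[self.entity_indices(2)] = 2
        return ent

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa_type for r in self.chains[chain_id])

    def entity_sequence(self, entity: int) -> str:
        return "".join(
            self.sequence(cid) for cid in self.chains if self.entity_of_chain[cid] == entity
        )

    def heavy_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """(coords M x 3, residue positional index per atom) over all chains."""
        coords, owner = [], []
        for i, res in enumerate(self.residues()):
            for a in res.atoms:
                if a.element != "H":
                    coords.append(a.coords)
                    owner.append(i)
        return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexModel":
        """Rigid copy: x -> R x + t applied to every atom."""
        chains = {}
        for cid, residues in self.chains.items():
            chains[cid] = [
                Residue(
                    r.chain_id, r.seq_index, r.aa_type,
                    [
                        AtomRecord(a.atom_name, a.element, rotation @ a.coords + translation,
                                   a.temp_factor)
                        for a in r.atoms
                    ],
                    r.icode,
                )
                for r in residues
            ]
        return ComplexModel(self.complex_id, self.model_rank, chains,
                            dict(self.entity_of_chain))


@dataclass
class ConfidenceBundle:
    """Per-model predictor confidence: pLDDT, PAE matrix, pTM, iPTM."""

    plddt: np.ndarray   # (N,), 0-100
    pae: np.ndarray     # (N, N), Angstrom >= 0
    ptm: float          # [0, 1]
    iptm: float         # [0, 1]

    def __post_init__(self):
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = self.plddt.shape[0]
        if self.pae.shape != (n, n):
            raise PairingError(
                f"PAE matrix shape {self.pae.shape} does not pair with {n} residues"
            )
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValidationError("pLDDT values must lie in [0, 100]")
        if np.any(self.pae < 0):
            raise ValidationError("PAE values must be non-negative")
        for name in ("ptm", "iptm"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")

    @property
    def n(self) -> int:
        return self.plddt.shape[0]


# ---------------------------------------------------------------------------
# Structure reading / writing
# ---------------------------------------------------------------------------

def _default_entity_spec(chain_ids: list[str]) -> dict[str, int]:
    # Heterodimer default: first chain is entity 1, every other chain entity 2.
    return {cid: (1 if i == 0 else 2) for i, cid in enumerate(chain_ids)}


def read_structure(path: str | Path, fmt: str | None = None,
                   complex_id: str | None = None, model_rank: int = 1,
                   entity_spec: dict[str, int] | None = None) -> ComplexModel:
    """Parse a PDB or mmCIF file into a two-entity :class:`ComplexModel`.

    Altloc handling keeps the highest-occupancy conformer per atom name;
    insertion-coded residues stay ordered after their base residue.  Without
    an explicit ``entity_spec`` the first chain becomes entity 1 and all
    remaining chains entity 2.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            raise ParseError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    st.setup_entities()
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if not any(a.element.name != "H" for a in res):
                continue
            one = AA_THREE_TO_ONE.get(res.name, "X")
            # keep best-occupancy conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for a in res:
                prev = best.get(a.name)
                if prev is None or a.occ > prev.occ:
                    best[a.name] = a
            atoms = [
                AtomRecord(a.name, a.element.name,
                           np.array([a.pos.x, a.pos.y, a.pos.z]), a.b_iso)
                for a in best.values()
            ]
            if not atoms:
                continue
            residues.append(
                Residue(ch.name, res.seqid.num, one, atoms,
                        res.seqid.icode.strip())
            )
        if residues:
            chains[ch.name] = residues
    if len(chains) < 2:
        raise StructuralError(f"{path}: need at least 2 chains, found {len(chains)}")

    spec = entity_spec or _default_entity_spec(list(chains))
    return ComplexModel(complex_id or path.stem, model_rank, chains, spec)


def write_structure(model: ComplexModel, path: str | Path) -> None:
    """Write a ComplexModel as a PDB file (round-trips residue/atom inventory)."""
    st = gemmi.Structure()
    st.name = model.complex_id
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        ch = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = AA_ONE_TO_THREE.get(r.aa_type, "UNK")
            gr.seqid = gemmi.SeqId(r.seq_index, r.icode or " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.atom_name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.b_iso = a.temp_factor
                ga.occ = 1.0
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.write_pdb(str(path))


def group_entities(model: ComplexModel, spec: dict[str, int]) -> ComplexModel:
    """Re-partition chains into two entities (e.g. 3 ligand chains vs 1 receptor).

    Idempotent; preserves the residue inventory.  Raises
    :class:`EntitySpecError` when the spec misses a chain or leaves an
    entity empty.
    """
    for cid in model.chains:
        if cid not in spec:
            raise EntitySpecError(f"chain {cid!r} missing from entity spec")
    for cid, e in spec.items():
        if e not in (1, 2):
            raise EntitySpecError(f"chain {cid!r}: entity must be 1 or 2, got {e}")
    ents = {spec[cid] for cid in model.chains}
    if ents != {1, 2}:
        raise EntitySpecError(f"spec must produce two non-empty entities, got {sorted(ents)}")
    return ComplexModel(model.complex_id, model.model_rank, model.chains,
                        {cid: spec[cid] for cid in model.chains})


# ---------------------------------------------------------------------------
# Confidence bundles
# ---------------------------------------------------------------------------

# Adapter: common score-file key variants mapped onto the canonical dialect.
_PLDDT_KEYS = ("plddt", "pLDDT")
_PAE_KEYS = ("pae", "predicted_aligned_error", "PAE")
_PTM_KEYS = ("ptm", "pTM")
_IPTM_KEYS = ("iptm", "ipTM", "i_ptm")


def _first_key(d: dict, keys: tuple[str, ...]):
    for k in keys:
        if k in d:
            return d[k]
    return None


def read_confidence(path: str | Path, expected_n: int) -> ConfidenceBundle:
    """Read a confidence JSON (canonical keys ``plddt``/``pae``/``ptm``/``iptm``).

    Common predictor score-file variants (``pLDDT``, ``predicted_aligned_error``,
    ``ipTM`` ...) are mapped onto the canonical dialect.  Missing pTM/iPTM are
    imputed as 0 with a warning; a missing pLDDT or PAE key is an error, as is
    any dimension mismatch with ``expected_n``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    plddt = _first_key(raw, _PLDDT_KEYS)
    if plddt is None:
        raise DialectError("confidence file lacks key 'plddt'")
    pae = _first_key(raw, _PAE_KEYS)
    if pae is None:
        raise DialectError("confidence file lacks key 'pae'")
    plddt = np.asarray(plddt, dtype=float)
    pae = np.asarray(pae, dtype=float)
    if plddt.shape[0] != expected_n or pae.shape != (expected_n, expected_n):
        raise PairingError(
            f"confidence dimensions (plddt {plddt.shape[0]}, pae {pae.shape}) "
            f"do not pair with model of {expected_n} residues"
        )
    ptm = _first_key(raw, _PTM_KEYS)
    iptm = _first_key(raw, _IPTM_KEYS)
    if ptm is None:
        warnings.warn("confidence file lacks pTM; imputing 0.0", stacklevel=2)
        ptm = 0.0
    if iptm is None:
        warnings.warn("confidence file lacks iPTM; imputing 0.0", stacklevel=2)
        iptm = 0.0
    return ConfidenceBundle(plddt, pae, float(ptm), float(iptm))


def write_confidence(bundle: ConfidenceBundle, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "plddt": bundle.plddt.tolist(),
                "pae": bundle.pae.tolist(),
                "ptm": bundle.ptm,
                "iptm": bundle.iptm,
            },
            fh,
        )


# ---------------------------------------------------------------------------
# FASTA + dataset metadata filter
# ---------------------------------------------------------------------------

def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) records as FASTA with 60-character line wrapping."""
    lines = []
    for rid, seq in records:
        if not seq:
            raise RecordError(f"record {rid!r}: empty sequence")
        bad = set(seq.upper()) - AA_ALPHABET
        if bad:
            raise RecordError(f"record {rid!r}: non-amino-acid characters {sorted(bad)}")
        lines.append(f">{rid}")
        for i in range(0, len(seq), 60):
            lines.append(seq[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n")


def filter_complex_metadata(resolution: float, pct_identity: float, total_len: int,
                            min_chain_len: int, is_homodimer: bool,
                            is_antibody: bool) -> str:
    """Dataset admission predicate for a candidate heterodimeric complex.

    Returns ``"drop"`` (resolution > 3 A, >30% identity to the set, total
    length > 1550 aa, homodimer, or antibody/antigen), ``"route_peptide"``
    (shortest chain < 50 aa — belongs to the protein-peptide branch), or
    ``"keep_protein_protein"``.
    """
    if (
        resolution > 3.0
        or pct_identity > 30.0
        or total_len > 1550
        or is_homodimer
        or is_antibody
    ):
        return "drop"
    if min_chain_len < 50:
        return "route_peptide"
    return "keep_protein_protein"
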