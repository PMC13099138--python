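"""Synthetic fixtures: idealized structures, confidence bundles, feature tables.

Every pipeline stage is testable without downloads:

* :func:`make_chain` builds a backbone (N, CA, C, O, + CB) from ideal bond
  geometry and per-residue phi/psi set by a secondary-structure pattern.
* :func:`make_complex` poses chains as docked / clashed / separated pairs
  with asserted geometric predicates.
* :func:`make_confidence` emulates predictor confidence with a controllable
  cross-entity PAE signal (confident vs uncertain interface).
* :func:`make_feature_table` draws labeled 57-feature tables with a stated
  class-conditional effect size and within-complex correlation.

All generators are deterministic for a fixed seed.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .config import PAE_MAX
from .decoygen import ChainStructure
from .errors import GenerationError, LengthError
from .interface import representative_atom
from .manifest import ID_COLUMNS, all_features, confidence_features, energy_features
from .structio import AtomRecord, ComplexModel, ConfidenceBundle, Residue

# Ideal backbone geometry (bond lengths in A, angles in degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = 111.2, 116.2, 121.7, 120.8, 110.5
_OMEGA = 180.0

PHI_PSI = {"H": (-57.0, -47.0), "E": (-139.0, 135.0)}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position D with |CD| = bond, angle(B,C,D), torsion(A,B,C,D)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_chain(length: int, ss_pattern: str = "H", seed: int = 0,
               sequence: str | None = None, chain_id: str = "A") -> ChainStructure:
    """Idealized chain with per-residue torsions set by the SS pattern.

    ``ss_pattern`` is tiled to the chain length; H and E use ideal helix /
    strand torsions, C draws polyproline-II-like torsions (no hydrogen-bond
    ladders) from the seeded generator.  Sequence defaults to poly-alanine.
    """
    if length < 15:
        raise LengthError(f"chain length must be >= 15, got {length}")
    rng = np.random.default_rng(seed)
    ss = (ss_pattern * (length // len(ss_pattern) + 1))[:length]
    seq = (sequence or "A" * length)[:length].ljust(length, "A")

    # torsion lists per residue
    phis, psis = [], []
    for s in ss:
        if s in PHI_PSI:
            phi, psi = PHI_PSI[s]
        else:
            phi = float(rng.uniform(-100.0, -60.0))
            psi = float(rng.uniform(110.0, 160.0))
        phis.append(phi)
        psis.append(psi)

    # seed first three backbone atoms
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(180.0 - _A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, length):
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psis[i - 1]))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA))
        C.append(_place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phis[i]))

    residues = []
    for i in range(length):
        atoms = [
            AtomRecord("N", "N", N[i]),
            AtomRecord("CA", "C", CA[i]),
            AtomRecord("C", "C", C[i]),
        ]
        psi_for_o = psis[i] if i < length - 1 else 180.0
        atoms.append(AtomRecord("O", "O", _place_atom(N[i], CA[i], C[i], _B_C_O,
                                                      _A_CA_C_O, psi_for_o + 180.0)))
        if seq[i] != "G":
            atoms.append(AtomRecord("CB", "C", _place_atom(C[i], N[i], CA[i], _B_CA_CB,
                                                           _A_N_CA_CB, -122.6)))
        residues.append(Residue(chain_id, i + 1, seq[i], atoms))
    return ChainStructure(chain_id, residues)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _chain_arrays(chains: list[ChainStructure]):
    heavy, rep = [], []
    for ch in chains:
        for r in ch.residues:
            rep.append(representative_atom(r))
            for a in r.atoms:
                if a.element != "H":
                    heavy.append(a.coords)
    return np.asarray(heavy), np.asarray(rep)


def _min_dist(A: np.ndarray, B: np.ndarray) -> float:
    d, _ = cKDTree(B).query(A, k=1)
    return float(np.min(d))


def _assemble(chains: list[ChainStructure], entity_of_chain: dict[str, int],
              rot: np.ndarray, shift: np.ndarray, complex_id: str,
              model_rank: int) -> ComplexModel:
    out: dict[str, list[Residue]] = {}
    for ch in chains:
        moved = entity_of_chain[ch.chain_id] == 2
        out[ch.chain_id] = [
            Residue(ch.chain_id, r.seq_index, r.aa_type,
                    [AtomRecord(a.atom_name, a.element,
                                (rot @ a.coords + shift) if moved else a.coords.copy(),
                                a.temp_factor) for a in r.atoms],
                    r.icode)
            for r in ch.residues
        ]
    return ComplexModel(complex_id, model_rank, out, entity_of_chain)


def make_complex(chains: list[ChainStructure], mode: str, seed: int = 0,
                 entity_of_chain: dict[str, int] | None = None,
                 complex_id: str = "synthetic", model_rank: int = 1,
                 max_retries: int = 60) -> ComplexModel:
    """Pose chains as one of three cross-entity geometries.

    docked — minimum cross-entity representative-atom distance in [4, 8] A
    with no heavy-atom pair closer than 2.5 A; clashed — at least 5
    heavy-atom pairs under 2.0 A; separated — everything beyond 30 A.
    The defining predicate is asserted post-generation.
    """
    if len(chains) < 2:
        raise GenerationError("need at least two chains")
    if entity_of_chain is None:
        entity_of_chain = {ch.chain_id: (1 if i == 0 else 2) for i, ch in enumerate(chains)}
    e1 = [c for c in chains if entity_of_chain[c.chain_id] == 1]
    e2 = [c for c in chains if entity_of_chain[c.chain_id] == 2]
    if not e1 or not e2:
        raise GenerationError("both entities must be non-empty")
    h1, r1 = _chain_arrays(e1)
    h2_0, r2_0 = _chain_arrays(e2)
    c1 = r1.mean(axis=0)
    rng = np.random.default_rng(seed)

    for _ in range(max_retries):
        rot = _random_rotation(rng)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        c2 = (rot @ r2_0.T).T.mean(axis=0)

        def placed(t: float):
            shift = c1 - c2 + t * u
            h2 = (rot @ h2_0.T).T + shift
            r2 = (rot @ r2_0.T).T + shift
            return shift, h2, r2

        if mode == "separated":
            span = np.linalg.norm(r1 - c1, axis=1).max() + \
                np.linalg.norm(r2_0 - r2_0.mean(axis=0), axis=1).max()
            shift, h2, r2 = placed(span + 50.0)
            if _min_dist(h1, h2) > 30.0:
                return _assemble(chains, entity_of_chain, rot, shift, complex_id, model_rank)
            continue

        # scan the separation axis from far to near; for docked poses keep the
        # deepest placement that still satisfies the no-overlap predicate, so
        # real van-der-Waals contacts form at the interface
        ts = np.arange(120.0, 0.0, -0.25)
        chosen = None
        for t in ts:
            shift, h2, r2 = placed(float(t))
            min_rep = _min_dist(r1, r2)
            min_heavy = _min_dist(h1, h2)
            if mode == "docked":
                if min_heavy < 2.5 or min_rep < 4.0:
                    break
                if 4.0 <= min_rep <= 8.0:
                    chosen = shift
            elif mode == "clashed":
                d, _ = cKDTree(h2).query(h1, k=1)
                n_clash = int(np.sum(d < 2.0))
                if n_clash >= 5:
                    chosen = shift
                    break
            else:
                raise GenerationError(f"unknown mode {mode!r}")
        if chosen is not None:
            return _assemble(chains, entity_of_chain, rot, chosen, complex_id, model_rank)
    raise GenerationError(f"could not realize mode {mode!r} after {max_retries} retries")


def make_confidence(model: ComplexModel, scenario: str, noise_sd: float = 1.0,
                    seed: int = 0) -> ConfidenceBundle:
    """Confidence bundle with a controllable cross-entity PAE signal.

    Intra-entity PAE centers at 2 A; cross-entity PAE at 4 A (confident
    interface) or 25 A (uncertain), clipped to [0, 31.75].  pLDDT is drawn
    from 85-95; iPTM is 0.8 / 0.2 per scenario.
    """
    if scenario not in ("confident_interface", "uncertain_interface"):
        raise GenerationError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    n = model.n_residues
    ent = model.entity_of_residue()
    cross = ent[:, None] != ent[None, :]
    base = np.where(cross, 4.0 if scenario == "confident_interface" else 25.0, 2.0)
    pae = np.clip(base + rng.normal(0.0, noise_sd, size=(n, n)), 0.0, PAE_MAX)
    np.fill_diagonal(pae, np.clip(np.abs(rng.normal(0.3, 0.1, size=n)), 0.0, 1.0))
    plddt = rng.uniform(85.0, 95.0, size=n)
    if scenario == "confident_interface":
        ptm, iptm = 0.85, 0.8
    else:
        ptm, iptm = 0.5, 0.2
    return ConfidenceBundle(plddt, pae, ptm, iptm)


# Informative columns for the synthetic feature table: the signal-bearing
# confidence features plus the seven retained screening features.
_INFORMATIVE = [
    "ipae_top_quarter", "tpae_top_quarter", "mean_interchain_pae",
    "mean_iface_plddt", "iptm", "n_charged_interface", "prop_iface_beta",
    "avg_lj_atr", "avg_lj_rep", "avg_solv", "avg_elec",
]
# Features where actives score LOWER (errors/energies), so the sign flips.
_NEGATIVE_DIRECTION = {
    "ipae_top_quarter", "tpae_top_quarter", "mean_interchain_pae",
    "avg_lj_atr", "avg_solv", "avg_elec",
}


def make_feature_table(n_complexes: int, models_per_complex: int = 5,
                       effect_size: float = 2.0, seed: int = 0,
                       complex_effect_sd: float = 0.5):
    """Labeled 57-feature table with balanced classes and grouped rows.

    Informative features separate the classes by ``effect_size`` standard
    deviations (total variance 1, shared within-complex effect of sd
    ``complex_effect_sd``); nuisance features are label-independent noise.
    """
    import pandas as pd

    if n_complexes < 10:
        raise GenerationError("need at least 10 complexes")
    rng = np.random.default_rng(seed)
    feats = all_features()
    informative = set(_INFORMATIVE)
    resid_sd = math.sqrt(max(1e-9, 1.0 - complex_effect_sd ** 2))

    rows = []
    for c in range(n_complexes):
        label = "active" if c % 2 == 0 else "decoy"
        sign = 1.0 if label == "active" else -1.0
        cid = f"cpx{c:04d}"
        complex_shift = rng.normal(0.0, complex_effect_sd, size=len(feats))
        for m in range(1, models_per_complex + 1):
            row = {"complex_id": cid, "model_rank": m, "label": label}
            noise = rng.normal(0.0, resid_sd, size=len(feats))
            for k, f in enumerate(feats):
                if f in informative:
                    direction = -1.0 if f in _NEGATIVE_DIRECTION else 1.0
                    mu = sign * direction * effect_size / 2.0
                else:
                    mu = 0.0
                row[f] = mu + complex_shift[k] + noise[k]
            rows.append(row)
    return pd.DataFrame(rows, columns=ID_COLUMNS + feats)


def make_sheet_pair(length: int = 16, seed: int = 0) -> ComplexModel:
    """Two-strand antiparallel sheet fixture (one strand per entity).

    The second strand is the first rotated 180 degrees about the mean
    carbonyl direction (which reverses the strand direction) and shifted
    across the hydrogen-bonding face; offset and register are chosen by a
    deterministic grid search maximizing Kabsch-Sander hydrogen bonds.
    """
    from .config import HBOND_ENERGY_CUTOFF
    from .interface import hbond_energy_matrix

    strand = make_chain(length, "E", seed=seed, chain_id="A")
    ca = strand.ca_coords()
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    # mean carbonyl direction, sign-alternated to follow the pleat, projected
    # perpendicular to the strand axis: this is the hydrogen-bonding face
    co = []
    for i, r in enumerate(strand.residues):
        w = r.coord("O") - r.coord("C")
        w /= np.linalg.norm(w)
        co.append(w if i % 2 == 0 else -w)
    v = np.mean(co, axis=0)
    v -= (v @ axis) * axis
    v /= np.linalg.norm(v)
    center = ca.mean(axis=0)

    def rot_pi(u: np.ndarray) -> np.ndarray:
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        return np.eye(3) + 2.0 * (K @ K)

    def candidate(R: np.ndarray, dy: float, dx: float) -> ComplexModel:
        shift = dy * v + dx * axis
        chains = {
            "A": strand.residues,
            "B": [
                Residue("B", r.seq_index, r.aa_type,
                        [AtomRecord(a.atom_name, a.element,
                                    R @ (a.coords - center) + center + shift,
                                    a.temp_factor) for a in r.atoms],
                        r.icode)
                for r in strand.residues
            ],
        }
        return ComplexModel("sheet_pair", 1, chains, {"A": 1, "B": 2})

    n_atoms_a = sum(len(r.atoms) for r in strand.residues)
    best, best_n = None, -1
    for u in (v, axis):  # antiparallel and parallel arrangements
        R = rot_pi(u)
        for dy in np.arange(3.8, 6.01, 0.2):
            for dx in np.arange(-4.0, 4.01, 0.25):
                m = candidate(R, float(dy), float(dx))
                coords, _ = m.heavy_atoms()
                if _min_dist(coords[:n_atoms_a], coords[n_atoms_a:]) < 2.2:
                    continue
                nb = int(np.sum(hbond_energy_matrix(m) < HBOND_ENERGY_CUTOFF))
                if nb > best_n:
                    best, best_n = m, nb
    if best is None or best_n < 2:
        raise GenerationError("could not realize an H-bonded sheet pair")
    return best
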