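"""Compelling-decoy construction by nearest-structural-analog swapping.

Given a library of single-chain structures and an index of which pairs form
*active* complexes, each active complex serves as a template: both component
proteins are replaced by their closest structural analog (ranked by
TM-score, normalized by the replaced protein's length) and the analogs are
rigidly superposed onto the components they replace.  The product is a crude
model of two presumably non-interacting proteins that geometrically mimics a
real complex.  When the two chosen analogs would jointly reconstitute an
active pairing, lower-ranked analogs are substituted (second-best first)
until the pairing is novel — no emitted recipe may reconstitute an active.

The TM-score here is a self-contained implementation: seed correspondences
come from gapless C-alpha fragment superpositions and a secondary-structure
string alignment, then are refined by iterative superpose/re-align.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import TM_D0_FLOOR, TM_MIN_LENGTH
from .errors import AnalogError, LengthError, SuperpositionError
from .interface import assign_secondary_structure
from .quality import SuperpositionResult, kabsch_superpose
from .structio import ComplexModel, Residue


@dataclass
class ChainStructure:
    """A single protein chain used as a library member."""

    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        coords = [r.coord("CA") for r in self.residues]
        if any(c is None for c in coords):
            raise LengthError(f"{self.chain_id}: missing CA atoms")
        return np.asarray(coords, dtype=float)

    def sequence(self) -> str:
        return "".join(r.aa_type for r in self.residues)

    def ss_string(self) -> str:
        return "".join(assign_secondary_structure(self.residues))


def entity_chain_structure(model: ComplexModel, entity: int,
                           chain_id: str | None = None) -> ChainStructure:
    """One entity of a complex flattened into a library chain."""
    res = model.residues()
    picked = [res[i] for i in model.entity_indices(entity)]
    return ChainStructure(chain_id or f"{model.complex_id}_e{entity}", picked)


def tm_d0(l_ref: int) -> float:
    """Length-dependent normalization distance, floored at 0.5 A."""
    if l_ref < TM_MIN_LENGTH:
        raise LengthError(f"reference length {l_ref} below d0 formula domain")
    return max(TM_D0_FLOOR, 1.24 * (l_ref - TM_MIN_LENGTH) ** (1.0 / 3.0) - 1.8)


def _nw_align(a: str, b: str, match: float = 2.0, mismatch: float = -1.0,
              gap: float = -2.0) -> list[tuple[int, int]]:
    """Needleman-Wunsch on two strings; returns aligned index pairs."""
    n, m = len(a), len(b)
    F = np.zeros((n + 1, m + 1))
    F[:, 0] = gap * np.arange(n + 1)
    F[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        s = np.where(np.frombuffer(b.encode(), dtype=np.uint8) == ord(a[i - 1]),
                     match, mismatch)
        for j in range(1, m + 1):
            F[i, j] = max(F[i - 1, j - 1] + s[j - 1], F[i - 1, j] + gap, F[i, j - 1] + gap)
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        sc = match if a[i - 1] == b[j - 1] else mismatch
        if F[i, j] == F[i - 1, j - 1] + sc:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif F[i, j] == F[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def _refine_tm(q: np.ndarray, r: np.ndarray, mapping: list[tuple[int, int]],
               d0: float, max_iter: int = 20) -> float:
    """Iterative superpose/re-align; returns the best TM over the full mapping."""
    if len(mapping) < 3:
        return 0.0
    qi = np.array([p[0] for p in mapping])
    ri = np.array([p[1] for p in mapping])
    subset = np.ones(len(mapping), dtype=bool)
    cutoff = max(4.5, d0)
    best_tm = 0.0
    prev = None
    for _ in range(max_iter):
        if subset.sum() < 3:
            break
        try:
            sup = kabsch_superpose(r[ri[subset]], q[qi[subset]])
        except SuperpositionError:
            break
        moved = sup.apply(q[qi])
        d = np.linalg.norm(moved - r[ri], axis=1)
        tm_terms = 1.0 / (1.0 + (d / d0) ** 2)
        best_tm = max(best_tm, float(tm_terms.sum()))
        new_subset = d <= cutoff
        if prev is not None and np.array_equal(new_subset, prev):
            break
        prev = subset
        subset = new_subset
    return best_tm


def tm_score(query: ChainStructure, reference: ChainStructure,
             window: int = 20, stride: int = 5) -> float:
    """TM-score of query against reference, normalized by the reference length.

    TM = (1/L_ref) * sum over aligned pairs of 1/(1 + (d_i/d0)^2), with
    d0 = 1.24 (L_ref - 15)^(1/3) - 1.8 (floored at 0.5 A).  Identical
    structures score 1; below ~0.5 two folds are no more similar than random
    protein pairs.  The score is invariant under rigid motion of either
    argument.  Normalization is asymmetric: tm_score(A, B) != tm_score(B, A)
    in general.
    """
    lq, lr = len(query), len(reference)
    if lq < TM_MIN_LENGTH or lr < TM_MIN_LENGTH:
        raise LengthError(f"chains must have >= {TM_MIN_LENGTH} residues")
    q = query.ca_coords()
    r = reference.ca_coords()
    d0 = tm_d0(lr)
    w = min(window, lq, lr)

    best = 0.0
    seen_offsets: set[int] = set()
    # Gapless fragment seeds: every (query offset, reference offset) window pair
    # defines a diagonal correspondence i -> i + (b - a).
    for a in range(0, lq - w + 1, stride):
        for b in range(0, lr - w + 1, stride):
            off = b - a
            if off in seen_offsets:
                continue
            seen_offsets.add(off)
            lo = max(0, -off)
            hi = min(lq, lr - off)
            mapping = [(i, i + off) for i in range(lo, hi)]
            best = max(best, _refine_tm(q, r, mapping, d0))
    # Secondary-structure string seed (handles register shifts with gaps).
    try:
        ss_pairs = _nw_align(query.ss_string(), reference.ss_string())
        best = max(best, _refine_tm(q, r, ss_pairs, d0))
    except Exception:  # SS undefined (missing backbone) -> fragment seeds only
        pass
    return min(1.0, best / lr)


@dataclass
class DecoyRecipe:
    template_complex_id: str
    analog_id_1: str
    analog_id_2: str
    tm_score_1: float
    tm_score_2: float
    rank_used_1: int   # 0 = best, 1 = second_best, ...
    rank_used_2: int
    transforms: list[SuperpositionResult] = field(default_factory=list)

    @staticmethod
    def rank_name(rank: int) -> str:
        return {0: "best", 1: "second_best"}.get(rank, f"rank_{rank + 1}")


PairingIndex = set[frozenset]


def make_pairing_index(pairs: list[tuple[str, str]]) -> PairingIndex:
    return {frozenset(p) for p in pairs}


def rank_analogs(protein_id: str, library: dict[str, ChainStructure],
                 pairing_index: PairingIndex) -> list[tuple[str, float]]:
    """Candidates for replacing ``protein_id``, best TM first.

    Excludes the protein itself and its own binding partners; TM is
    normalized by the template protein's length.  Ties (to 1e-6) break on
    the lexicographically lower id.
    """
    if len(library) < 3:
        raise AnalogError("library must contain at least 3 proteins")
    partners = {
        other
        for pair in pairing_index
        if protein_id in pair
        for other in pair
        if other != protein_id
    }
    template = library[protein_id]
    scored = []
    for cid, cand in library.items():
        if cid == protein_id or cid in partners:
            continue
        scored.append((cid, tm_score(cand, template)))
    if not scored:
        raise AnalogError(f"no candidate analogs for {protein_id!r}")
    scored.sort(key=lambda t: (-round(t[1] * 1e6), t[0]))
    return scored


def nearest_analog(protein_id: str, library: dict[str, ChainStructure],
                   pairing_index: PairingIndex) -> tuple[str, float, int]:
    """The best-TM admissible analog for one protein (id, tm, rank=0)."""
    aid, tm = rank_analogs(protein_id, library, pairing_index)[0]
    return aid, tm, 0


def select_decoy_analogs(id1: str, id2: str, library: dict[str, ChainStructure],
                         pairing_index: PairingIndex) -> tuple[tuple[str, float, int],
                                                               tuple[str, float, int]]:
    """Analog choice for both slots of a template complex.

    Combinations are tried in order of total rank (then slot-1 rank); any
    combination that reconstitutes an active pairing, or picks the same
    protein twice, is skipped.
    """
    r1 = rank_analogs(id1, library, pairing_index)
    r2 = rank_analogs(id2, library, pairing_index)
    combos = sorted(
        ((k, l) for k in range(len(r1)) for l in range(len(r2))),
        key=lambda kl: (kl[0] + kl[1], kl[0]),
    )
    for k, l in combos:
        a1, t1 = r1[k]
        a2, t2 = r2[l]
        if a1 == a2 or frozenset((a1, a2)) in pairing_index:
            continue
        return (a1, t1, k), (a2, t2, l)
    raise AnalogError(f"no admissible analog pair for template ({id1}, {id2})")


def _superpose_by_alignment(analog: ChainStructure,
                            template: ChainStructure) -> SuperpositionResult:
    """Rigid placement of an analog onto the template component it replaces."""
    if len(analog) == len(template):
        return kabsch_superpose(template.ca_coords(), analog.ca_coords())
    pairs = _nw_align(analog.ss_string(), template.ss_string())
    if len(pairs) < 3:
        raise SuperpositionError("alignment too short to superpose analog")
    q = analog.ca_coords()
    r = template.ca_coords()
    return kabsch_superpose(
        np.array([r[j] for _, j in pairs]), np.array([q[i] for i, _ in pairs])
    )


def build_decoy(template: ComplexModel, analog1: ChainStructure,
                analog2: ChainStructure,
                tm1: float = float("nan"), tm2: float = float("nan"),
                rank1: int = 0, rank2: int = 0) -> tuple[ComplexModel,
                                                         list[tuple[str, str]],
                                                         DecoyRecipe]:
    """Place both analogs onto the template geometry.

    Returns the crude decoy structure (for inspection — the canonical decoy
    for screening is a re-predicted model of the sequence pair), the two
    FASTA-ready sequences, and the recipe with the recovered transforms.
    """
    transforms = []
    chains: dict[str, list[Residue]] = {}
    entity_of_chain: dict[str, int] = {}
    for slot, analog in ((1, analog1), (2, analog2)):
        comp = entity_chain_structure(template, slot)
        sup = _superpose_by_alignment(analog, comp)
        transforms.append(sup)
        cid = "A" if slot == 1 else "B"
        chains[cid] = [
            Residue(cid, r.seq_index, r.aa_type,
                    [type(a)(a.atom_name, a.element, sup.rotation @ a.coords + sup.translation,
                             a.temp_factor) for a in r.atoms],
                    r.icode)
            for r in analog.residues
        ]
        entity_of_chain[cid] = slot
    decoy_id = f"decoy_{template.complex_id}_{analog1.chain_id}_{analog2.chain_id}"
    decoy = ComplexModel(decoy_id, 1, chains, entity_of_chain)
    seqs = [
        (f"{decoy_id}_A", analog1.sequence()),
        (f"{decoy_id}_B", analog2.sequence()),
    ]
    recipe = DecoyRecipe(template.complex_id, analog1.chain_id, analog2.chain_id,
                         tm1, tm2, rank1, rank2, transforms)
    return decoy, seqs, recipe


def build_decoy_recipes(complexes: list[tuple[str, str, str]],
                        library: dict[str, ChainStructure],
                        pairing_index: PairingIndex | None = None
                        ) -> list[DecoyRecipe]:
    """Analog selection for a whole library of (complex_id, id1, id2) templates."""
    if pairing_index is None:
        pairing_index = make_pairing_index([(c[1], c[2]) for c in complexes])
    recipes = []
    for complex_id, id1, id2 in complexes:
        (a1, t1, k1), (a2, t2, k2) = select_decoy_analogs(id1, id2, library, pairing_index)
        recipes.append(DecoyRecipe(complex_id, a1, a2, t1, t2, k1, k2))
    return recipes


def size_bias_report(recipes: list[DecoyRecipe],
                     library: dict[str, ChainStructure],
                     templates: dict[str, tuple[str, str]] | None = None,
                     feature_table=None, length_column: str = "total_length",
                     corr_threshold: float = 0.5) -> dict:
    """Analog-length / template-length ratio distribution (+ optional feature flags).

    Analog-swapping slightly favors larger proteins (larger folds more often
    contain a good match to the template), so the ratio distribution is worth
    monitoring; with a decoy feature table carrying a total-length column,
    features correlating with length beyond ``corr_threshold`` are flagged.
    """
    if not recipes:
        raise AnalogError("size_bias_report requires at least one recipe")
    ratios = []
    for rec in recipes:
        if templates is not None:
            t1, t2 = templates[rec.template_complex_id]
        else:
            t1 = t2 = None
        for aid, tid in ((rec.analog_id_1, t1), (rec.analog_id_2, t2)):
            if tid is None:
                continue
            ratios.append(len(library[aid]) / len(library[tid]))
    ratios = np.asarray(ratios, dtype=float)
    report: dict = {
        "n_recipes": len(recipes),
        "mean_ratio": float(ratios.mean()) if ratios.size else float("nan"),
        "median_ratio": float(np.median(ratios)) if ratios.size else float("nan"),
        "ratios": ratios.tolist(),
    }
    if feature_table is not None and length_column in feature_table:
        lengths = feature_table[length_column].to_numpy(dtype=float)
        flags = {}
        from .manifest import all_features
        for feat in all_features():
            if feat not in feature_table:
                continue
            v = feature_table[feat].to_numpy(dtype=float)
            if np.std(v) == 0 or np.std(lengths) == 0:
                continue
            r = float(np.corrcoef(v, lengths)[0, 1])
            if abs(r) >= corr_threshold:
                flags[feat] = r
        report["length_correlated_features"] = flags
    return report
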