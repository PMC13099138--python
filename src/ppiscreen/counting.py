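"""Structural counting features over the interface.

All 33 features are functions of the interface alone — counts of interface
residues by physicochemical class, contact-pair counts by class pair,
secondary-structure composition of the interface, and density statistics.
None scales with the total size of the component proteins: the decoy
construction has a slight bias toward larger analogs, and size-coupled
features would let a classifier exploit that artifact instead of the
interface itself.
"""
from __future__ import annotations

from collections import Counter

from .interface import CHARGED, InterfaceMap, classify_residue, primary_class
from .manifest import counting_features
from .structio import ComplexModel

_PRIMARY = ("charged", "polar", "hydrophobic", "special")


_CLASS_ORDER = {c: i for i, c in enumerate(_PRIMARY)}


def _pair_key(a: str, b: str) -> str:
    # unordered pair, named in fixed class order (charged, polar, hydrophobic, special)
    if _CLASS_ORDER[a] > _CLASS_ORDER[b]:
        a, b = b, a
    return f"contact_{a}_{b}"


def contact_pair_counts(model: ComplexModel, iface: InterfaceMap) -> dict[str, int]:
    """Interface contact pairs tallied by unordered primary-class pair."""
    residues = model.residues()
    counts = Counter()
    for i, j in iface.pairs:
        counts[_pair_key(primary_class(residues[i].aa_type),
                         primary_class(residues[j].aa_type))] += 1
    out = {}
    for x in range(len(_PRIMARY)):
        for y in range(x, len(_PRIMARY)):
            key = _pair_key(_PRIMARY[x], _PRIMARY[y])
            out[key] = counts.get(key, 0)
    return out


def counting_feature_block(model: ComplexModel, iface: InterfaceMap,
                           ss_labels: list[str]) -> dict[str, float]:
    """The 33 counting features, manifest-ordered.

    Empty interfaces yield 0 for every count and 0 for every proportion.
    """
    residues = model.residues()
    union = sorted(iface.residue_set)
    n_union = len(union)

    def class_count(cls: str) -> int:
        return sum(1 for i in union if cls in classify_residue(residues[i].aa_type))

    feats: dict[str, float] = {
        "n_iface_res_total": float(n_union),
        "n_iface_res_e1": float(len(iface.iface_set1)),
        "n_iface_res_e2": float(len(iface.iface_set2)),
        "n_charged_interface": float(
            sum(1 for i in union if residues[i].aa_type in CHARGED)
        ),
        "n_positive_iface": float(class_count("charged+")),
        "n_negative_iface": float(class_count("charged-")),
        "n_polar_iface": float(class_count("polar")),
        "n_hydrophobic_iface": float(class_count("hydrophobic")),
        "n_aromatic_iface": float(class_count("aromatic")),
        "n_gly_iface": float(sum(1 for i in union if residues[i].aa_type == "G")),
        "n_pro_iface": float(sum(1 for i in union if residues[i].aa_type == "P")),
    }
    feats.update({k: float(v) for k, v in contact_pair_counts(model, iface).items()})

    for ent, iset in ((1, iface.iface_set1), (2, iface.iface_set2)):
        n_e = len(iset)
        for lab in ("H", "E", "C"):
            frac = (
                sum(1 for i in iset if ss_labels[i] == lab) / n_e if n_e else 0.0
            )
            feats[f"prop_iface_{lab}_e{ent}"] = frac

    feats["prop_iface_beta"] = (
        sum(1 for i in union if ss_labels[i] == "E") / n_union if n_union else 0.0
    )
    feats["n_contact_pairs"] = float(len(iface.pairs))
    feats["mean_pairs_per_iface_res"] = (
        len(iface.pairs) / n_union if n_union else 0.0
    )
    feats["prop_charged_iface"] = feats["n_charged_interface"] / n_union if n_union else 0.0
    feats["prop_hydrophobic_iface"] = feats["n_hydrophobic_iface"] / n_union if n_union else 0.0
    feats["prop_polar_iface"] = feats["n_polar_iface"] / n_union if n_union else 0.0

    return {name: feats[name] for name in counting_features()}
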