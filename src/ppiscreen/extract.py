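"""Assembly of the full 57-feature vector for one predicted model."""
from __future__ import annotations

import pandas as pd

from .confidence import confidence_feature_block
from .counting import counting_feature_block
from .energetics import EnergyParams, energy_feature_block
from .interface import assign_secondary_structure, find_interface
from .manifest import ID_COLUMNS, all_features
from .structio import ComplexModel, ConfidenceBundle


def feature_vector(model: ComplexModel, conf: ConfidenceBundle,
                   label: str = "unlabeled",
                   params: EnergyParams | None = None) -> dict:
    """All 57 features (plus ids) for one model/confidence pair."""
    iface = find_interface(model)
    ss = assign_secondary_structure(model)
    row = {
        "complex_id": model.complex_id,
        "model_rank": model.model_rank,
        "label": label,
    }
    row.update(confidence_feature_block(model, conf, iface))
    row.update(counting_feature_block(model, iface, ss))
    row.update(energy_feature_block(model, iface, params))
    return row


def feature_table(pairs: list[tuple[ComplexModel, ConfidenceBundle, str]],
                  params: EnergyParams | None = None) -> pd.DataFrame:
    """Stack feature vectors for (model, confidence, label) triples."""
    rows = [feature_vector(m, c, lab, params) for m, c, lab in pairs]
    return pd.DataFrame(rows, columns=ID_COLUMNS + all_features())
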