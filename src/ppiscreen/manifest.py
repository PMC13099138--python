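"""Versioned feature manifest.

The classifier consumes a fixed, ordered roster of 57 features: 7 predictor
confidence measures, 33 structural counting features over the interface, and
17 interface energy terms.  The roster ships as JSON data so it can be
revised without code changes; every feature table and trained model records
the manifest version it was built against.
"""
from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=1)
def _raw() -> dict:
    with resources.files("ppiscreen.data").joinpath("feature_manifest.json").open() as fh:
        return json.load(fh)


def manifest_version() -> str:
    return _raw()["version"]


def confidence_features() -> list[str]:
    return list(_raw()["confidence"])


def counting_features() -> list[str]:
    return list(_raw()["counting"])


def energy_features() -> list[str]:
    return list(_raw()["energy"])


def all_features() -> list[str]:
    """The full ordered 57-feature roster (confidence, counting, energy)."""
    return confidence_features() + counting_features() + energy_features()


ID_COLUMNS = ["complex_id", "model_rank", "label"]
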