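"""Packaged reference datasets for the nine-member community."""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = [
    "load_endpoint_composition",
    "full_mix_proportions",
    "minus_cg_proportions",
    "SPECIES_ORDER",
]

#: Canonical species order (inoculation/reporting order).
SPECIES_ORDER = ("Rp", "Cm", "Cg", "Ri", "Ss", "Bm", "Pm", "Sp", "Bc")


def load_endpoint_composition() -> pd.DataFrame:
    """72-h percent compositions (+Cg and -Cg) with replicate SDs."""
    path = importlib.resources.files("commrobust.data") / "endpoint_composition.tsv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def _renormalized(column: str) -> pd.Series:
    df = load_endpoint_composition().set_index("abbrev")
    p = df[column].astype(float)
    return p / p.sum()


def full_mix_proportions() -> pd.Series:
    """Endpoint proportions of the full nine-species mix, renormalized."""
    return _renormalized("pct_full_mix")


def minus_cg_proportions() -> pd.Series:
    """Endpoint proportions of the community lacking C. gleum (Cg = 0)."""
    return _renormalized("pct_minus_cg")
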