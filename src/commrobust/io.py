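"""Provenance-stamped TSV input/output.

Every output table carries comment-prefixed header lines recording the
tool version, the run seed and the configuration hash, so a results
directory is traceable to the exact stochastic run that produced it.
Timestamps are deliberately omitted: two runs of the same seed and config
produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_tsv", "read_tsv"]


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    provenance: dict | None = None,
    float_format: str = "%.10g",
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
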