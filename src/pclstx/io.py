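"""TSV file contracts of the pipeline.

One fixed dialect everywhere: tab-separated, UTF-8, ``#``-prefixed
provenance comment lines, ``.`` decimal, missing values written ``NA``.
Every output carries a provenance header recording the package version, the
seed and a hash of the configuration, and is written deterministically so a
re-run with identical config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = [
    "FormatError",
    "write_tsv",
    "read_tsv",
    "provenance_header",
    "config_hash",
    "METADATA_COLUMNS",
    "EXCLUSION_COLUMNS",
    "ORTHOLOG_COLUMNS",
]

METADATA_COLUMNS = ["sample_id", "species", "subject_id", "medium", "timepoint_h", "status"]
EXCLUSION_COLUMNS = ["subject_id", "medium", "timepoint_h", "reason"]
ORTHOLOG_COLUMNS = ["gene_h", "gene_m", "pct_identity"]


class FormatError(ValueError):
    """A TSV does not match its documented column contract."""


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int | None = None, cfg_hash: str | None = None) -> str:
    parts = [f"pclstx={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return "# " + " ".join(parts)


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
    index: bool = False,
    float_format: str = "%.10g",
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(provenance_header(seed, cfg_hash) + "\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA", float_format=float_format,
                  lineterminator="\n")
    return path


def read_tsv(
    path: str | Path,
    required_columns: list[str] | None = None,
    index_col: str | None = None,
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise FormatError(f"{path.name}: missing required column(s) {missing}")
    if index_col is not None:
        df = df.set_index(index_col)
    return df
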