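"""Tabular I/O with provenance headers.

Every table the pipeline writes carries '#'-prefixed header lines recording
the package version, the run seed and checksums of its inputs, so that any
output file can be traced back to the exact inputs that produced it.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

import exprevo


def checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    meta: dict | None = None,
    index: bool = True,
    index_label: str | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# exprevo {exprevo.__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)
    return path


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
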