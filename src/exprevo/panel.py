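"""Expression panel container: genes x samples with sample metadata.

The panel is the unit of input for every cross-species analysis.  Values are
either TPM or raw counts (``units`` flag); metadata gives species, tissue,
sex and replicate per sample.  Species means are arithmetic means of TPM
across replicates, taken before any log transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ["species", "tissue", "sex", "replicate"]


@dataclass
class ExpressionPanel:
    values: pd.DataFrame  # genes x samples
    meta: pd.DataFrame  # samples x (species, tissue, sex, replicate)
    units: str = "tpm"  # "tpm" | "counts"

    def __post_init__(self):
        if self.units not in ("tpm", "counts"):
            raise ValueError("units must be 'tpm' or 'counts'")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("metadata index must match panel sample columns")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def species(self) -> list[str]:
        return sorted(self.meta["species"].unique())

    @property
    def tissues(self) -> list[str]:
        return sorted(self.meta["tissue"].unique())

    def subset(self, tissue=None, sex=None, species=None) -> "ExpressionPanel":
        mask = pd.Series(True, index=self.meta.index)
        if tissue is not None:
            mask &= self.meta["tissue"] == tissue
        if sex is not None:
            mask &= self.meta["sex"] == sex
        if species is not None:
            mask &= self.meta["species"].isin(
                [species] if isinstance(species, str) else species
            )
        meta = self.meta.loc[mask]
        return ExpressionPanel(self.values.loc[:, meta.index], meta, self.units)

    def species_means(
        self, tissue: str | None = None, sex: str | None = None, log2: bool = False
    ) -> pd.DataFrame:
        """Genes x species means (TPM averaged over replicates).

        With ``log2=True``, returns log2(mean TPM + 1).
        """
        sub = self.subset(tissue=tissue, sex=sex)
        groups = sub.meta.groupby("species").groups
        out = pd.DataFrame(
            {sp: sub.values[list(cols)].mean(axis=1) for sp, cols in groups.items()}
        )
        if log2:
            out = np.log2(out + 1.0)
        return out

    def replicate_matrix(self, tissue: str, sex: str | None = None) -> pd.DataFrame:
        """Genes x replicate samples for one tissue (optionally one sex)."""
        return self.subset(tissue=tissue, sex=sex).values

    # ---- IO --------------------------------------------------------------
    def write_tsv(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        vpath = prefix.with_suffix(".expr.tsv")
        mpath = prefix.with_suffix(".meta.tsv")
        self.values.to_csv(vpath, sep="\t", index_label="gene")
        self.meta.to_csv(mpath, sep="\t", index_label="sample")
        return vpath, mpath

    @classmethod
    def read_tsv(
        cls, values_path: str | Path, meta_path: str | Path, units: str = "tpm"
    ) -> "ExpressionPanel":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, meta, units)
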