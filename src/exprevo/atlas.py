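"""Single-cell atlas containers.

``Atlas`` holds cell-level expression (cells x genes, counts) with cluster
labels; ``AtlasSummary`` is the cluster-level view used for tau-by-cell-type
and homology scoring: cluster x gene mean expression and the fraction of
cells in which each gene is detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class AtlasSummary:
    mean_expression: pd.DataFrame  # clusters x genes (mean raw counts)
    fraction_expressing: pd.DataFrame  # clusters x genes in [0, 1]
    cell_counts: pd.Series  # cells per cluster

    def __post_init__(self):
        if not self.mean_expression.index.equals(self.fraction_expressing.index):
            raise ValueError("cluster indices differ between matrices")
        if not self.mean_expression.columns.equals(self.fraction_expressing.columns):
            raise ValueError("gene indices differ between matrices")
        fr = self.fraction_expressing.to_numpy()
        if (fr < 0).any() or (fr > 1).any():
            raise ValueError("fraction_expressing must lie in [0, 1]")

    @property
    def clusters(self) -> pd.Index:
        return self.mean_expression.index

    @property
    def genes(self) -> pd.Index:
        return self.mean_expression.columns

    def write_tsv(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        mpath = prefix.with_suffix(".mean.tsv")
        fpath = prefix.with_suffix(".frac.tsv")
        mean = self.mean_expression.copy()
        mean.insert(0, "n_cells", self.cell_counts)
        mean.to_csv(mpath, sep="\t", index_label="cluster")
        self.fraction_expressing.to_csv(fpath, sep="\t", index_label="cluster")
        return mpath, fpath

    @classmethod
    def read_tsv(cls, mean_path: str | Path, frac_path: str | Path) -> "AtlasSummary":
        mean = pd.read_csv(mean_path, sep="\t", index_col=0)
        cells = mean.pop("n_cells")
        frac = pd.read_csv(frac_path, sep="\t", index_col=0)
        return cls(mean, frac, cells)


@dataclass
class Atlas:
    """Cell-level expression counts with per-cell cluster labels."""

    counts: pd.DataFrame  # cells x genes
    clusters: pd.Series  # cell -> cluster label

    def __post_init__(self):
        if not self.counts.index.equals(self.clusters.index):
            raise ValueError("cluster labels must be indexed by cell")

    @property
    def cluster_labels(self) -> list:
        return sorted(self.clusters.unique())

    def summarize(self) -> AtlasSummary:
        grouped = self.counts.groupby(self.clusters)
        mean = grouped.mean()
        frac = grouped.apply(lambda g: (g > 0).mean())
        cells = self.clusters.value_counts().sort_index()
        cells = cells.reindex(mean.index)
        return AtlasSummary(mean, frac, cells)
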