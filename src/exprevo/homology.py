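"""Marker identification and cross-tissue cell-type homology scoring.

Markers are genes preferentially expressed in one cluster: detected in at
least ``min_frac`` of the cluster's cells, with log fold change vs all other
cells of at least ``min_lfc``, significant by a one-sided rank-sum test
(p < alpha), positive only, ranked by fold change, truncated at ``top_n``.

The homology score between cluster i (atlas A) and cluster j (atlas B) is

    score(i, j) = clip0(corr) x overlap
    corr    = Pearson correlation of log1p cluster-mean expression over the
              union of the two clusters' markers
    overlap = |M_i ∩ M_j| / min(|M_i|, |M_j|)

giving values in [0, 1]: 0 for unrelated cell types, 1 for identical ones.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from exprevo.atlas import Atlas, AtlasSummary

logger = logging.getLogger(__name__)


def find_markers(
    atlas: Atlas,
    min_frac: float = 0.25,
    min_lfc: float = 0.25,
    alpha: float = 0.001,
    top_n: int = 100,
    min_cells: int = 3,
) -> dict[str, list[str]]:
    """Positive marker genes per cluster from cell-level expression.

    ``min_lfc`` is a natural-log fold change of in-cluster vs rest mean
    expression (pseudocount 1).  Clusters with fewer than ``min_cells``
    cells are skipped with a warning.
    """
    if len(atlas.cluster_labels) < 2:
        raise ValueError("need at least 2 clusters to find markers")
    counts = atlas.counts
    markers: dict[str, list[str]] = {}
    for cluster in atlas.cluster_labels:
        mask = (atlas.clusters == cluster).to_numpy()
        if mask.sum() < min_cells:
            logger.warning("cluster %s has < %d cells; skipped", cluster, min_cells)
            continue
        inside = counts.loc[mask]
        outside = counts.loc[~mask]
        frac_in = (inside > 0).mean(axis=0)
        mean_in = inside.mean(axis=0)
        mean_out = outside.mean(axis=0)
        lfc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        cand = counts.columns[(frac_in >= min_frac) & (lfc >= min_lfc)]
        rows = []
        if len(cand):
            a = inside[cand].to_numpy()
            b = outside[cand].to_numpy()
            p = mannwhitneyu(a, b, alternative="greater", axis=0).pvalue
            for gene, pv, fc in zip(cand, p, lfc[cand]):
                if pv < alpha:
                    rows.append((gene, fc))
        rows.sort(key=lambda t: -t[1])
        markers[cluster] = [g for g, _ in rows[:top_n]]
    return markers


def homology_score(
    atlas_a: AtlasSummary,
    atlas_b: AtlasSummary,
    markers_a: dict[str, list[str]],
    markers_b: dict[str, list[str]],
) -> pd.DataFrame:
    """Cell-type homology score matrix (clusters of A x clusters of B).

    Pairs with no shared marker or an undefined correlation score 0; all
    entries lie in [0, 1].
    """
    shared_genes = atlas_a.genes.intersection(atlas_b.genes)
    if len(shared_genes) == 0:
        raise ValueError("no shared gene universe between the atlases")
    la = np.log1p(atlas_a.mean_expression[shared_genes])
    lb = np.log1p(atlas_b.mean_expression[shared_genes])
    clusters_a = [c for c in atlas_a.clusters if c in markers_a]
    clusters_b = [c for c in atlas_b.clusters if c in markers_b]
    out = pd.DataFrame(0.0, index=clusters_a, columns=clusters_b)
    gene_pos = set(shared_genes)
    for ca in clusters_a:
        ma = [g for g in markers_a[ca] if g in gene_pos]
        for cb in clusters_b:
            mb = [g for g in markers_b[cb] if g in gene_pos]
            if not ma or not mb:
                continue
            inter = set(ma) & set(mb)
            if not inter:
                continue
            overlap = len(inter) / min(len(ma), len(mb))
            union = sorted(set(ma) | set(mb))
            xa = la.loc[ca, union].to_numpy()
            xb = lb.loc[cb, union].to_numpy()
            if len(union) < 2 or xa.std() == 0 or xb.std() == 0:
                corr = 1.0 if np.allclose(xa, xb) and len(union) >= 1 else 0.0
            else:
                corr = float(np.corrcoef(xa, xb)[0, 1])
            out.loc[ca, cb] = max(corr, 0.0) * overlap
    return out.clip(0.0, 1.0)


def best_matches(score: pd.DataFrame) -> pd.Series:
    """Argmax homolog in B for each cluster of A (NaN row -> no match)."""
    return score.idxmax(axis=1)
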