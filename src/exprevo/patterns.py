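"""Multi-tissue patterns of expression changes and the coincidental index.

A ChangeEvent is one (gene, tissue, branch, direction) record.  Genes are
binned by the exact set of tissues in which they changed (UpSet-style
overlap tables), and each gene's changes are summarized by the coincidental
index

    CI = sum_t n_obs(t) / sum_t n_max(t)

where t runs over the branches carrying at least one event for the gene,
n_obs(t) is the number of tissues with an event on branch t and n_max(t) is
the number of tissues analyzed (T).  CI = 1 means every change involved all
tissues on the same branch (coincidental); 1/T means each change involved a
single tissue (dispersed); a gene without events scores 0.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from exprevo.tree import SpeciesTree

EVENT_COLUMNS = ["gene", "tissue", "edge", "direction"]


def _check_events(events: pd.DataFrame, tissues: list[str] | None) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    if tissues is not None:
        unknown = set(events["tissue"]) - set(tissues)
        if unknown:
            raise ValueError(f"unknown tissues in events: {sorted(unknown)}")
    return events


def tissue_overlap(
    events: pd.DataFrame,
    tissues: list[str],
    scope_edge: str | None = None,
) -> pd.Series:
    """Gene counts per exact tissue-set combination (UpSet semantics).

    ``scope_edge`` restricts the events to a single branch ("one_branch"
    scope); default uses all branches.  Every changed gene is counted in
    exactly one combination.
    """
    events = _check_events(events, tissues)
    if scope_edge is not None:
        events = events[events["edge"] == scope_edge]
    sets = events.groupby("gene")["tissue"].agg(lambda t: frozenset(t))
    index = [
        frozenset(c) for k in range(1, len(tissues) + 1) for c in combinations(sorted(tissues), k)
    ]
    counts = sets.value_counts()
    out = pd.Series(0, index=index, dtype=int)
    for comb, n in counts.items():
        out[comb] = n
    out.index = ["+".join(sorted(c)) for c in index]
    return out


def coincidental_index(gene_events: pd.DataFrame, n_tissues: int) -> float:
    """Coincidental index for one gene's events; 0 if the gene never changed."""
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    if len(gene_events) == 0:
        return 0.0
    _check_events(gene_events, None)
    n_obs = gene_events.groupby("edge")["tissue"].nunique()
    return float(n_obs.sum() / (n_tissues * len(n_obs)))


def coincidental_index_table(
    events: pd.DataFrame, n_tissues: int, genes: list[str] | None = None
) -> pd.Series:
    """Per-gene coincidental index; genes without events score 0."""
    _check_events(events, None)
    grouped = {
        g: coincidental_index(sub, n_tissues) for g, sub in events.groupby("gene")
    }
    if genes is None:
        genes = sorted(grouped)
    return pd.Series({g: grouped.get(g, 0.0) for g in genes}, name="coincidental_index")


def coincidence_vs_branch_length(
    events: pd.DataFrame,
    tree: SpeciesTree,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_tissues: int = 2,
) -> dict:
    """Association between coincidental-event counts per branch and length.

    Coincidental events are (gene, edge) pairs with >= ``min_tissues``
    tissues changed on the same branch.  Returns the Spearman correlation
    between per-edge counts and edge lengths plus a permutation p-value
    (events reassigned to edges uniformly at random, preserving the total).
    """
    _check_events(events, None)
    edges = [tree.edge_label(e) for e in tree.edges]
    lengths = np.array([tree.lengths[e] for e in tree.edges], dtype=float)
    if len(set(lengths)) < 2 or len(edges) < 3:
        return {"statistic": float("nan"), "p_value": float("nan"), "applicable": False}
    per = (
        events.groupby(["gene", "edge"])["tissue"]
        .nunique()
        .reset_index(name="n_tissues")
    )
    coin = per[per["n_tissues"] >= min_tissues]
    counts = coin.groupby("edge").size().reindex(edges).fillna(0).to_numpy()
    total = int(counts.sum())
    stat = spearmanr(counts, lengths).statistic if total else 0.0
    if np.isnan(stat):
        stat = 0.0
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        perm = np.bincount(
            rng.integers(0, len(edges), total), minlength=len(edges)
        ).astype(float)
        s = spearmanr(perm, lengths).statistic if total else 0.0
        null[k] = 0.0 if np.isnan(s) else s
    p = float((np.abs(null) >= abs(stat)).mean()) if total else 1.0
    return {
        "statistic": float(stat),
        "p_value": p,
        "applicable": True,
        "n_coincidental": total,
        "seed": seed,
    }
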