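"""Expression specificity (tau), expression calls and gain/loss parsimony.

tau measures how restricted a gene's expression is across n entities
(tissues or cell clusters):

    tau = sum_i (1 - x_hat_i) / (n - 1),   x_hat_i = x_i / max(x_i)

0 for perfectly uniform expression, 1 for expression confined to a single
entity.  Values are log-transformed (log1p) before the formula by default.

TPM-based presence calls use the study thresholds: mean TPM > 3 means
expressed, < 0.5 unexpressed, in between ambiguous.  Binary calls across
species are mapped to gains and losses on the species tree by Fitch
parsimony; edges that change state in every most-parsimonious labeling are
reported as events, the rest as unresolved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from exprevo.atlas import AtlasSummary
from exprevo.tree import SpeciesTree

EXPRESSED_TPM = 3.0
UNEXPRESSED_TPM = 0.5


def tau(x, log_transform: bool = True) -> float:
    """Expression-specificity index in [0, 1] over >= 2 entities.

    Raises on all-zero input (specificity undefined for an unexpressed
    gene); see :func:`tau_table` for the vectorized, NaN-propagating form.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau needs a 1-d vector with n >= 2 entities")
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    if x.max() == 0:
        raise ValueError("tau undefined for an all-zero vector (gene not expressed)")
    if log_transform:
        x = np.log1p(x)
    xhat = x / x.max()
    return float((1.0 - xhat).sum() / (len(x) - 1))


def tau_table(values: pd.DataFrame, log_transform: bool = True) -> pd.Series:
    """tau per gene (rows) over entities (columns); all-zero genes get NaN."""
    x = values.to_numpy(dtype=float)
    if log_transform:
        x = np.log1p(x)
    mx = x.max(axis=1)
    ok = mx > 0
    xhat = np.divide(x, mx[:, None], out=np.zeros_like(x), where=mx[:, None] > 0)
    t = (1.0 - xhat).sum(axis=1) / (x.shape[1] - 1)
    t[~ok] = np.nan
    return pd.Series(t, index=values.index, name="tau")


def cell_tau(
    atlas: AtlasSummary, gene: str, variant: str = "mean", log_transform: bool = True
) -> float:
    """tau over cell clusters, using cluster means or fractions expressing."""
    if variant not in ("mean", "fraction"):
        raise ValueError("variant must be 'mean' or 'fraction'")
    source = (
        atlas.mean_expression if variant == "mean" else atlas.fraction_expressing
    )
    if gene not in source.columns:
        raise KeyError(f"gene {gene!r} not in atlas")
    return tau(source[gene].to_numpy(), log_transform=log_transform)


def expression_call(mean_tpm: float) -> str:
    """expressed (> 3 TPM) / unexpressed (< 0.5 TPM) / ambiguous."""
    if mean_tpm < 0:
        raise ValueError("TPM must be non-negative")
    if mean_tpm > EXPRESSED_TPM:
        return "expressed"
    if mean_tpm < UNEXPRESSED_TPM:
        return "unexpressed"
    return "ambiguous"


def call_table(mean_tpm: pd.DataFrame) -> pd.DataFrame:
    """Elementwise expression calls for a genes x species mean-TPM table."""
    arr = mean_tpm.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM must be non-negative")
    out = np.where(
        arr > EXPRESSED_TPM,
        "expressed",
        np.where(arr < UNEXPRESSED_TPM, "unexpressed", "ambiguous"),
    )
    return pd.DataFrame(out, index=mean_tpm.index, columns=mean_tpm.columns)


# --------------------------------------------------------------------------
# gain / loss parsimony
# --------------------------------------------------------------------------


INF = 10**9


def _parsimony_tables(tree: SpeciesTree, tips: dict[int, int]):
    """Sankoff-style DP for binary states.

    up[v][s]   = min changes within the subtree of v given state s at v;
    down[v][s] = min changes outside the subtree of v given state s at v.
    Tips without a call contribute (0, 0) so their pendant edge is free.
    """
    up = np.zeros((tree.n_nodes, 2), dtype=np.int64)
    for node in tree.postorder():
        if node < tree.n_taxa:
            if node in tips:
                up[node] = [0 if tips[node] == 0 else INF, 0 if tips[node] == 1 else INF]
        else:
            for s in (0, 1):
                up[node, s] = sum(
                    min(up[c, 0] + (s != 0), up[c, 1] + (s != 1))
                    for c in tree.children(node)
                )
    down = np.zeros((tree.n_nodes, 2), dtype=np.int64)
    for node in tree.preorder():
        if node == tree.root:
            continue
        p = tree.parent[node]
        for s in (0, 1):
            best = INF
            for sp in (0, 1):
                sib = sum(
                    min(up[c, 0] + (sp != 0), up[c, 1] + (sp != 1))
                    for c in tree.children(p)
                    if c != node
                )
                best = min(best, down[p, sp] + (s != sp) + sib)
            down[node, s] = best
    return up, down


def gain_loss(
    calls: dict[str, str] | pd.Series, tree: SpeciesTree
) -> pd.DataFrame:
    """Map expressed/unexpressed calls to gain/loss events by parsimony.

    Binary states are reconstructed on the fixed species topology with a
    Fitch/Sankoff dynamic program; ambiguous species are excluded (their
    pendant edges carry no cost).  Returns one row per edge that changes
    state in at least one most-parsimonious labeling: ``event`` is 'gain'
    or 'loss' when every optimal labeling changes that edge in the same
    direction, 'unresolved' otherwise.  Fewer than two unambiguous species
    -> empty result.
    """
    calls = dict(calls)
    states = {
        sp: 1 if c == "expressed" else 0
        for sp, c in calls.items()
        if c in ("expressed", "unexpressed")
    }
    out_cols = ["edge", "event"]
    if len(states) < 2 or len(set(states.values())) == 1:
        return pd.DataFrame(columns=out_cols)
    tips = {int(tree.tip_index([sp])[0]): s for sp, s in states.items()}
    up, down = _parsimony_tables(tree, tips)
    best_total = int(min(up[tree.root, 0], up[tree.root, 1]))
    known_tips = set(tips)
    rows = []
    for e in tree.edges:
        child, parent = e, tree.parent[e]
        if child < tree.n_taxa and child not in known_tips:
            continue
        optimal_combos = set()
        for sp in (0, 1):
            sib = sum(
                min(up[c, 0] + (sp != 0), up[c, 1] + (sp != 1))
                for c in tree.children(parent)
                if c != child
            )
            for sc in (0, 1):
                total = down[parent, sp] + (sc != sp) + up[child, sc] + sib
                if total == best_total:
                    optimal_combos.add((sp, sc))
        changes = {c for c in optimal_combos if c[0] != c[1]}
        if not changes:
            continue
        if optimal_combos - changes:
            rows.append({"edge": tree.edge_label(e), "event": "unresolved"})
        elif changes == {(0, 1)}:
            rows.append({"edge": tree.edge_label(e), "event": "gain"})
        elif changes == {(1, 0)}:
            rows.append({"edge": tree.edge_label(e), "event": "loss"})
        else:
            rows.append({"edge": tree.edge_label(e), "event": "unresolved"})
    out = pd.DataFrame(rows, columns=out_cols)
    out.attrs["parsimony_cost"] = best_total
    return out


def compare_specificity(tau_a, tau_b, alternative: str = "two-sided") -> dict:
    """Two-sample Wilcoxon rank-sum comparison of tau between gene groups."""
    a = np.asarray(pd.Series(tau_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(tau_b).dropna(), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(set(a)) == 1 and set(a) == set(b):
        return {"statistic": float("nan"), "p_value": 1.0, "direction": "none"}
    res = mannwhitneyu(a, b, alternative=alternative)
    direction = (
        "A_greater" if np.median(a) > np.median(b) else "B_greater"
        if np.median(b) > np.median(a)
        else "none"
    )
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "direction": direction,
        "n_a": len(a),
        "n_b": len(b),
    }
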