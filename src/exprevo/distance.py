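"""Whole-transcriptome expression distances, NJ trees and relative-rate tests.

Under a stationary OU model of expression evolution the correlation of
log-expression profiles between two species decays exponentially with their
divergence time, so

    D(i, j) = -ln rho(i, j)

(with rho the Pearson correlation of log2(TPM+1) species-mean vectors) is
linear in time and serves as the stationary-OU transcriptome distance.
Distance matrices per tissue are turned into expression trees by
neighbor-joining with gene-resampling bootstrap supports, and lineage-wise
rates are compared with relative-rate tests against an outgroup:

    Z = (D(A, O) - D(B, O)) / SE,   SE by bootstrap over genes,

positive Z meaning lineage A diverged faster.  The subsampled significance
procedure draws many fixed-size gene subsamples per species pair, pools the
subsample Z distributions of the non-significant pairs to form empirical
lower/upper null bounds, and tests each pair's Z distribution against those
bounds with one-sample Wilcoxon tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

RHO_MIN = 1e-6


def _log2_means(species_means: pd.DataFrame, min_tpm: float) -> pd.DataFrame:
    """Filter genes by mean TPM and move to log2(TPM+1)."""
    keep = species_means.mean(axis=1) > min_tpm
    return np.log2(species_means.loc[keep] + 1.0)


def sou_distance(species_means: pd.DataFrame, min_tpm: float = 1.0) -> pd.DataFrame:
    """Stationary-OU distance matrix from a genes x species TPM table.

    Genes with mean TPM <= ``min_tpm`` are dropped; D = -ln(Pearson rho) on
    log2(TPM+1) vectors, with rho floored at 1e-6.
    """
    if species_means.shape[1] < 2:
        raise ValueError("need at least 2 species")
    logx = _log2_means(species_means, min_tpm)
    if len(logx) < 30:
        raise ValueError(f"only {len(logx)} genes pass the TPM filter (need >= 30)")
    rho = np.corrcoef(logx.to_numpy().T)
    if (rho <= 0).any():
        raise ValueError(
            "non-positive expression correlation between samples; "
            "inspect the input (expected only on adversarial data)"
        )
    D = -np.log(np.maximum(rho, RHO_MIN))
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return pd.DataFrame(D, index=species_means.columns, columns=species_means.columns)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------


@dataclass
class ExpressionTree:
    """NJ expression tree with bootstrap supports per split."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)
    n_bootstrap: int = 0

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def splits(self) -> set[frozenset]:
        return tree_splits(self.tree)


def nj_tree(dist: pd.DataFrame, outgroup: str | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; optionally rooted on the outgroup."""
    if outgroup is not None and outgroup not in dist.index:
        raise ValueError(f"outgroup {outgroup!r} not among labels")
    dm = _SkbioDM(dist.to_numpy(), ids=list(dist.index))
    newick = str(_skbio_nj(dm))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    if outgroup is not None:
        og = tree.find_node_with_taxon_label(outgroup)
        tree.reroot_at_edge(og.edge, update_bipartitions=True)
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the smaller side's labels."""
    labels = {t.label for t in tree.taxon_namespace}
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = frozenset(labels - side)
        if 1 < len(side) < len(labels) - 1:
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def nj_tree_with_support(
    species_means: pd.DataFrame,
    outgroup: str,
    n_bootstrap: int = 100,
    min_tpm: float = 1.0,
    seed: int = 0,
) -> ExpressionTree:
    """NJ tree from TPM species means, with gene-bootstrap split supports."""
    tree = nj_tree(sou_distance(species_means, min_tpm), outgroup)
    ref_splits = tree_splits(tree)
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    logx = _log2_means(species_means, min_tpm).to_numpy()
    n = len(logx)
    labels = list(species_means.columns)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        rho = np.corrcoef(logx[idx].T)
        D = -np.log(np.maximum(rho, RHO_MIN))
        np.fill_diagonal(D, 0.0)
        D = (D + D.T) / 2.0
        boot = nj_tree(pd.DataFrame(D, index=labels, columns=labels), outgroup)
        for s in tree_splits(boot):
            if s in counts:
                counts[s] += 1
    supports = {
        s: 100.0 * c / n_bootstrap if n_bootstrap else float("nan")
        for s, c in counts.items()
    }
    _annotate_supports(tree, supports)
    return ExpressionTree(tree, supports, n_bootstrap)


def _annotate_supports(tree: dendropy.Tree, supports: dict[frozenset, float]) -> None:
    labels = {t.label for t in tree.taxon_namespace}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = min(side, frozenset(labels - side), key=lambda s: (len(s), sorted(s)))
        if key in supports:
            node.label = f"{supports[key]:.0f}"


# --------------------------------------------------------------------------
# relative-rate tests
# --------------------------------------------------------------------------


def _pairwise_neglog_corr(x: np.ndarray, y: np.ndarray) -> float:
    rho = np.corrcoef(x, y)[0, 1]
    return float(-np.log(max(rho, RHO_MIN)))


def _bootstrap_delta(a, b, o, n_boot, rng):
    """Bootstrap-over-genes draws of D(A,O) - D(B,O); vectorized."""
    n = len(a)
    idx = rng.integers(0, n, (n_boot, n))
    out = np.empty(n_boot)
    for k in range(n_boot):
        i = idx[k]
        out[k] = _pairwise_neglog_corr(a[i], o[i]) - _pairwise_neglog_corr(b[i], o[i])
    return out


def relative_rate(
    species_means: pd.DataFrame,
    a: str,
    b: str,
    outgroup: str,
    min_tpm: float = 1.0,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Relative-rate Z for lineages a vs b against the outgroup.

    Z = (D(a,O) - D(b,O)) / SE with SE from ``n_boot`` gene bootstraps;
    positive Z means lineage ``a`` diverged faster.  Exactly 0 when the two
    lineages have identical expression matrices.
    """
    if len({a, b, outgroup}) != 3:
        raise ValueError("a, b and outgroup must be distinct")
    logx = _log2_means(species_means[[a, b, outgroup]], min_tpm)
    if len(logx) < 30:
        raise ValueError(f"only {len(logx)} genes pass the TPM filter (need >= 30)")
    av, bv, ov = (logx[c].to_numpy() for c in (a, b, outgroup))
    delta = _pairwise_neglog_corr(av, ov) - _pairwise_neglog_corr(bv, ov)
    if delta == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    draws = _bootstrap_delta(av, bv, ov, n_boot, rng)
    se = draws.std(ddof=1)
    if se == 0:
        return 0.0
    return float(delta / se)


@dataclass
class RateTestResult:
    pair: tuple[str, str]
    outgroup: str
    z_full: float
    z_subsamples: np.ndarray
    z_mean: float
    z_sd: float
    p_upper: float  # right-tailed Wilcoxon vs the upper null bound
    p_lower: float  # left-tailed Wilcoxon vs the lower null bound
    verdict: str  # elevated_A | elevated_B | ns
    n_genes: int = 0
    n_reps: int = 0
    seed: int = 0


def subsampled_rate_test(
    species_means: pd.DataFrame,
    pairs: list[tuple[str, str]],
    outgroup: str,
    n_genes: int = 1000,
    n_reps: int = 1000,
    min_tpm: float = 1.0,
    alpha: float = 0.001,
    z_crit: float = 1.96,
    seed: int = 0,
) -> list[RateTestResult]:
    """Subsampled relative-rate significance procedure.

    For every pair, ``n_reps`` subsamples of ``n_genes`` genes give a Z
    distribution (each subsample's Z uses the full-set bootstrap SE rescaled
    by sqrt(N_full / n_genes)).  Pairs whose full-set |Z| <= ``z_crit``
    are pooled to form the non-significant null; its min and max are the
    bounds against which each pair's Z distribution is tested (one-sample
    Wilcoxon, right-tailed vs the max and left-tailed vs the min).
    """
    logx = _log2_means(species_means, min_tpm)
    n_universe = len(logx)
    if n_universe < n_genes:
        raise ValueError(
            f"gene universe ({n_universe}) smaller than subsample size ({n_genes})"
        )
    rng = np.random.default_rng(seed)
    data = {}
    for a, b in pairs:
        av, bv, ov = (logx[c].to_numpy() for c in (a, b, outgroup))
        delta = _pairwise_neglog_corr(av, ov) - _pairwise_neglog_corr(bv, ov)
        se_full = _bootstrap_delta(av, bv, ov, 200, rng).std(ddof=1)
        se_sub = se_full * np.sqrt(n_universe / n_genes)
        z_full = delta / se_full if se_full > 0 else 0.0
        zs = np.empty(n_reps)
        for k in range(n_reps):
            i = rng.integers(0, n_universe, n_genes)
            d = _pairwise_neglog_corr(av[i], ov[i]) - _pairwise_neglog_corr(
                bv[i], ov[i]
            )
            zs[k] = d / se_sub if se_sub > 0 else 0.0
        data[(a, b)] = (z_full, zs)

    nonsig = [zs for (zf, zs) in data.values() if abs(zf) <= z_crit]
    if not nonsig:
        raise ValueError(
            "all pairs significant at |Z| > z_crit; the non-significant null "
            "bounds cannot be formed"
        )
    pooled = np.concatenate(nonsig)
    lo, hi = pooled.min(), pooled.max()

    results = []
    for (a, b), (z_full, zs) in data.items():
        p_up = _wilcoxon_one_sided(zs - hi, "greater")
        p_lo = _wilcoxon_one_sided(zs - lo, "less")
        if p_up < alpha:
            verdict = "elevated_A"
        elif p_lo < alpha:
            verdict = "elevated_B"
        else:
            verdict = "ns"
        results.append(
            RateTestResult(
                (a, b),
                outgroup,
                float(z_full),
                zs,
                float(zs.mean()),
                float(zs.std(ddof=1)),
                p_up,
                p_lo,
                verdict,
                n_genes,
                n_reps,
                seed,
            )
        )
    return results


def _wilcoxon_one_sided(diffs: np.ndarray, alternative: str) -> float:
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        return 1.0
    return float(wilcoxon(diffs, alternative=alternative).pvalue)


def rate_test_table(results: list[RateTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lineage_A": r.pair[0],
                "lineage_B": r.pair[1],
                "outgroup": r.outgroup,
                "z_full": r.z_full,
                "z_mean": r.z_mean,
                "z_sd": r.z_sd,
                "p_upper": r.p_upper,
                "p_lower": r.p_lower,
                "verdict": r.verdict,
                "n_genes": r.n_genes,
                "n_reps": r.n_reps,
                "seed": r.seed,
            }
            for r in results
        ]
    )
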