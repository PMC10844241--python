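"""Negative-binomial Wald engine and sex-bias classification.

A compact NB GLM differential-expression engine: median-of-ratios size
factors, a low-count expression filter, gene-wise method-of-moments
dispersion, an NB GLM (log link, size-factor offsets) under the design
~ tissue + sex + tissue:sex, and a Wald test on the per-tissue sex
contrast with Benjamini-Hochberg adjustment across genes.

Sex-biased genes are called at >= 1.5-fold change (male vs female) with
adjusted p < 0.01.  Overlap utilities count genes sharing the same bias
direction across species or tissues and test annotation enrichment with the
hypergeometric upper tail.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom, norm as norm_dist

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample column).

    Ratios are taken to the geometric-mean pseudo-reference over genes
    nonzero in all samples; factors are rescaled so their median is 1
    (identical samples get factor 1; an exactly doubled sample gets 2).
    Falls back to library-size scaling with a warning when no gene is
    nonzero everywhere.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if allpos.sum() == 0:
        logger.warning(
            "no gene nonzero in all samples; falling back to library-size scaling"
        )
        lib = arr.sum(axis=0)
        f = lib / np.median(lib)
    else:
        sub = arr[allpos]
        logref = np.log(sub).mean(axis=1)
        f = np.exp(np.median(np.log(sub) - logref[:, None], axis=0))
        f = f / np.median(f)
    return pd.Series(f, index=counts.columns, name="size_factor")


def filter_expressed(
    norm_counts: pd.DataFrame, min_count: float = 5.0, min_samples: int = 3
) -> pd.Series:
    """Keep genes with normalized count >= min_count in >= min_samples samples."""
    mask = (norm_counts >= min_count).sum(axis=1) >= min_samples
    return pd.Series(mask, index=norm_counts.index, name="expressed")


def _design_matrix(meta: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Treatment-coded design for ~ tissue + sex + tissue:sex."""
    tissues = sorted(meta["tissue"].unique())
    sexes = sorted(meta["sex"].unique())
    if len(sexes) != 2:
        raise ValueError("exactly two sexes required")
    ref_t = tissues[0]
    male = (meta["sex"] == sexes[1]).to_numpy(dtype=float)  # second level = "male" term
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for t in tissues[1:]:
        cols.append((meta["tissue"] == t).to_numpy(dtype=float))
        names.append(f"tissue[{t}]")
    cols.append(male)
    names.append("sex")
    for t in tissues[1:]:
        cols.append(((meta["tissue"] == t).to_numpy(dtype=float)) * male)
        names.append(f"tissue[{t}]:sex")
    return np.column_stack(cols), names, tissues


def _gene_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments NB dispersion per gene, pooled over design cells."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += v - m
        den += m**2
    disp = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return np.maximum(disp, DISPERSION_FLOOR)


def nb_wald(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_count: float = 5.0,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Per-gene NB Wald tests of the sex effect within each tissue.

    ``meta`` must carry 'tissue' and 'sex' per sample (matching the count
    columns).  Returns one row per (gene, tissue) with the male-vs-female
    log2 fold change, Wald p and BH-adjusted p (across genes, within each
    tissue).  Non-convergent genes are flagged and excluded.
    """
    if list(counts.columns) != list(meta.index):
        raise ValueError("metadata index must match count columns")
    sf = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    keep = filter_expressed(
        pd.DataFrame(norm, index=counts.index, columns=counts.columns),
        min_count,
        min_samples,
    )
    genes = counts.index[keep]
    X, names, tissues = _design_matrix(meta)
    cells = [
        np.flatnonzero((meta["tissue"] == t) & (meta["sex"] == s))
        for t in tissues
        for s in sorted(meta["sex"].unique())
    ]
    for idx in cells:
        if len(idx) < 2:
            raise ValueError("need >= 2 replicates per sex x tissue cell")
    disp = _gene_dispersion(norm[keep.to_numpy()], cells)
    offset = np.log(sf.to_numpy())
    carr = counts.loc[genes].to_numpy(dtype=float)

    # per-tissue contrast vectors on the coefficient space
    contrasts = {}
    for t in tissues:
        c = np.zeros(X.shape[1])
        c[names.index("sex")] = 1.0
        key = f"tissue[{t}]:sex"
        if key in names:
            c[names.index(key)] = 1.0
        contrasts[t] = c

    rows = []
    for gi, gene in enumerate(genes):
        y = carr[gi]
        fam = sm.families.NegativeBinomial(alpha=float(disp[gi]))
        try:
            with np.errstate(all="ignore"):
                res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite coefficients")
        except Exception:
            logger.warning("gene %s: NB GLM failed to converge; excluded", gene)
            continue
        cov = res.cov_params()
        for t in tissues:
            c = contrasts[t]
            est = float(c @ res.params)
            var = float(c @ cov @ c)
            if var <= 0 or not np.isfinite(var):
                continue
            z = est / np.sqrt(var)
            p = 2.0 * norm_dist.sf(abs(z))
            rows.append(
                {
                    "gene": gene,
                    "tissue": t,
                    "log2fc": est / np.log(2.0),
                    "z": z,
                    "pvalue": p,
                }
            )
    out = pd.DataFrame(rows, columns=["gene", "tissue", "log2fc", "z", "pvalue"])
    if len(out):
        out["padj"] = np.nan
        for t, sub in out.groupby("tissue"):
            out.loc[sub.index, "padj"] = _bh(sub["pvalue"].to_numpy())
    else:
        out["padj"] = []
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def classify_bias(
    results: pd.DataFrame, fc_min: float = 1.5, alpha: float = 0.01
) -> pd.DataFrame:
    """Assign male / female / none per (gene, tissue) test result.

    male if fold change (male/female) >= fc_min and padj < alpha; female if
    fold change <= 1/fc_min and padj < alpha; none otherwise.
    """
    lfc_min = np.log2(fc_min)
    out = results.copy()
    sig = out["padj"] < alpha
    out["bias"] = np.where(
        sig & (out["log2fc"] >= lfc_min),
        "male",
        np.where(sig & (out["log2fc"] <= -lfc_min), "female", "none"),
    )
    return out


def bias_overlap(
    bias_sets: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Pairwise counts of genes sharing the same bias direction.

    ``bias_sets`` maps a label (species or tissue) to a classified result
    frame (gene, bias).  Returns a square frame of same-direction overlap
    counts; the diagonal holds each set's biased-gene count.
    """
    directions = {}
    for label, df in bias_sets.items():
        biased = df[df["bias"].isin(["male", "female"])]
        directions[label] = dict(zip(biased["gene"], biased["bias"]))
    labels = list(directions)
    out = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for a in labels:
        for b in labels:
            if a == b:
                out.loc[a, b] = len(directions[a])
            else:
                out.loc[a, b] = sum(
                    1
                    for g, d in directions[a].items()
                    if directions[b].get(g) == d
                )
    return out


def hypergeom_enrichment(
    universe: set[str], annotated: set[str], drawn: set[str]
) -> dict:
    """Upper-tail hypergeometric enrichment of an annotation among drawn genes.

    Genes outside the universe are trimmed with a warning.
    """
    extra = (annotated | drawn) - set(universe)
    if extra:
        logger.warning("%d query genes outside the universe; trimmed", len(extra))
    annotated = set(annotated) & set(universe)
    drawn = set(drawn) & set(universe)
    M, K, N = len(universe), len(annotated), len(drawn)
    hits = len(annotated & drawn)
    p = float(hypergeom.sf(hits - 1, M, K, N))
    return {"universe": M, "annotated": K, "drawn": N, "hits": hits, "p_value": p}
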