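"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: multi-tissue
expression panels evolved on the species tree under BM / OU / multi-optimum
OU with planted shifts, negative-binomial count sampling, sex-effect
spiking, toy single-cell atlas pairs with planted homologous clusters and
markers, and toy anchored alignments with planted gap runs.  All generators
are pure functions of (spec, seed).

Traits are simulated on the log2(TPM+1) scale — where the OU likelihoods are
exactly Gaussian — and exponentiated for TPM output.  Expected tip means of
shifted (OUM) genes use the exact conditional OU mean propagation along
edges, so planted shifts have analytically known tip effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from exprevo.atlas import Atlas, AtlasSummary
from exprevo.panel import ExpressionPanel
from exprevo.regions import AnchoredAlignment, SpeciesAnchor
from exprevo.tree import (
    OUParams,
    SpeciesTree,
    bm_covariance,
    drosophila_tree,
    ou_covariance,
    oum_design_weights,
    regime_from_shifts,
)

DEFAULT_TISSUES = ["antenna", "proboscis", "foreleg", "ovipositor", "larva"]
DEFAULT_SEXED = ("antenna", "proboscis", "foreleg")


@dataclass
class SexEffectSpec:
    """Planted sex-biased expression: a log2 fold change added to one sex."""

    fraction: float = 0.0  # fraction of genes with a sex effect
    fold_change: float = 4.0  # linear fold change (male/female or inverse)

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")


@dataclass
class SimSpec:
    """Study design for a simulated panel.

    Defaults mirror the study design this package emulates: six species on
    the calibrated tree, five tissues of which three are sampled in both
    sexes, three replicates per species x tissue (x sex).  ``model_probs``
    gives the per-gene mixture over BM / OU1 / OUM; OUM genes carry planted
    optimum shifts of ``shift_size_sd`` stationary standard deviations, on a
    branch drawn with probability proportional to branch length (events
    arise uniformly in evolutionary time).  ``coincidental_fraction`` is the
    probability that a multi-tissue changer lands all its shifts on the same
    branch.
    """

    tree: SpeciesTree = field(default_factory=drosophila_tree)
    n_genes: int = 1000
    n_replicates: int = 3
    model_probs: dict[str, float] = field(
        default_factory=lambda: {"BM": 0.4, "OU1": 0.5, "OUM": 0.1}
    )
    params: OUParams = field(default_factory=lambda: OUParams(0.5, 0.25, 0.1))
    bm_sigma2: float = 0.02  # neutral genes drift slowly (~1.5-fold over 15 My)
    tissues: list[str] = field(default_factory=lambda: list(DEFAULT_TISSUES))
    sexed_tissues: tuple[str, ...] = DEFAULT_SEXED
    shift_size_sd: float = 4.0
    coincidental_fraction: float = 0.1
    sex_effect: SexEffectSpec = field(default_factory=SexEffectSpec)
    root_mean: float = 5.0  # log2(TPM+1) grand mean (~31 TPM)
    gene_mean_sd: float = 2.0  # between-gene baseline SD (genes span ~0.5-4000 TPM)
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0 <= self.coincidental_fraction <= 1:
            raise ValueError("coincidental_fraction must be in [0, 1]")
        if abs(sum(self.model_probs.values()) - 1.0) > 1e-9:
            raise ValueError("model_probs must sum to 1")
        if set(self.model_probs) - {"BM", "OU1", "OUM"}:
            raise ValueError("model_probs keys must be BM/OU1/OUM")


def _bm_params(spec: SimSpec) -> OUParams:
    """Parameters used for the neutral (BM) gene class."""
    return OUParams(0.0, spec.bm_sigma2, spec.params.sigma2_e)


def simulate_gene_means(
    tree: SpeciesTree,
    model: str,
    params: OUParams,
    rng: np.random.Generator,
    n_genes: int = 1,
    root_mean: float = 0.0,
    shift_edges=(),
    shift_deltas=(),
) -> np.ndarray:
    """Species trait means (n_genes x n_taxa) under one model.

    ``shift_deltas`` are optimum displacements (same order as
    ``shift_edges``); tip means follow the exact OU mean propagation.
    """
    if model == "BM":
        cov = (
            bm_covariance(tree, params.sigma2)
            if params.sigma2 > 0
            else np.zeros((tree.n_taxa, tree.n_taxa))
        )
        mean = np.full(tree.n_taxa, root_mean)
    elif model == "OU1":
        cov = ou_covariance(tree, params, stationary=True)
        mean = np.full(tree.n_taxa, root_mean)
    elif model == "OUM":
        if not shift_edges:
            raise ValueError("OUM gene requires a regime (shift edges)")
        cov = ou_covariance(tree, params, stationary=True)
        regime = regime_from_shifts(tree, shift_edges)
        # optima ordered by sorted(shift_edges) inside regime_from_shifts
        theta = np.empty(regime.n_optima)
        theta[0] = root_mean
        delta_by_edge = dict(zip(shift_edges, shift_deltas))
        for k, e in enumerate(sorted(set(shift_edges))):
            theta[k + 1] = root_mean + delta_by_edge[e]
        W = oum_design_weights(tree, regime, params.alpha)
        mean = W @ theta
    else:
        raise ValueError(f"unknown model {model!r}")
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(tree.n_taxa))
    z = rng.standard_normal((n_genes, tree.n_taxa))
    return mean[None, :] + z @ L.T


def _draw_shift_edge(tree: SpeciesTree, rng: np.random.Generator) -> int:
    lengths = np.array([tree.lengths[e] for e in tree.edges])
    return int(rng.choice(tree.edges, p=lengths / lengths.sum()))


def simulate_panel(spec: SimSpec) -> tuple[ExpressionPanel, dict]:
    """Simulate a TPM panel plus ground truth.

    Returns ``(panel, truth)`` where ``truth`` has:

    * ``genes``: DataFrame gene -> model;
    * ``events``: planted shifts (gene, tissue, edge label, direction, delta);
    * ``sex_effects``: planted sex-biased genes (gene, tissue, direction);
    * ``seed``: the generator seed.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    models = rng.choice(
        list(spec.model_probs), size=spec.n_genes, p=list(spec.model_probs.values())
    )
    # per-gene baseline expression level, shared across tissues; without it
    # cross-species profile correlations (and -ln rho distances) degenerate
    baselines = rng.normal(spec.root_mean, spec.gene_mean_sd, spec.n_genes)
    sd = spec.params.stationary_var**0.5

    # plan shifts for OUM genes
    event_rows = []
    plans: dict[int, dict[str, tuple[int, float]]] = {}
    for gi in np.flatnonzero(models == "OUM"):
        n_t = int(rng.integers(1, len(spec.tissues) + 1))
        affected = list(rng.choice(spec.tissues, size=n_t, replace=False))
        coincidental = rng.random() < spec.coincidental_fraction
        shared_edge = _draw_shift_edge(tree, rng)
        plan: dict[str, tuple[int, float]] = {}
        for tis in affected:
            edge = shared_edge if coincidental else _draw_shift_edge(tree, rng)
            delta = spec.shift_size_sd * sd * (1 if rng.random() < 0.5 else -1)
            plan[tis] = (edge, delta)
            event_rows.append(
                {
                    "gene": genes[gi],
                    "tissue": tis,
                    "edge": tree.edge_label(edge),
                    "direction": "up" if delta > 0 else "down",
                    "delta": delta,
                }
            )
        plans[gi] = plan

    # simulate per tissue
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    sex_rows = []
    sexed_genes = (
        set(
            rng.choice(
                spec.n_genes,
                size=int(round(spec.sex_effect.fraction * spec.n_genes)),
                replace=False,
            )
        )
        if spec.sex_effect.fraction > 0
        else set()
    )
    log_fc = np.log2(spec.sex_effect.fold_change)

    for tis in spec.tissues:
        means = np.empty((spec.n_genes, tree.n_taxa))
        for model in ("BM", "OU1", "OUM"):
            idx = np.flatnonzero(models == model)
            if idx.size == 0:
                continue
            if model in ("BM", "OU1"):
                pp = _bm_params(spec) if model == "BM" else spec.params
                means[idx] = simulate_gene_means(
                    tree, model, pp, rng, len(idx), 0.0
                ) + baselines[idx, None]
            else:
                for gi in idx:
                    if tis in plans[gi]:
                        edge, delta = plans[gi][tis]
                        means[gi] = (
                            simulate_gene_means(
                                tree,
                                "OUM",
                                spec.params,
                                rng,
                                1,
                                0.0,
                                shift_edges=[edge],
                                shift_deltas=[delta],
                            )
                            + baselines[gi]
                        )
                    else:
                        means[gi] = (
                            simulate_gene_means(tree, "OU1", spec.params, rng, 1, 0.0)
                            + baselines[gi]
                        )
        sexes = ["female", "male"] if tis in spec.sexed_tissues else ["mixed"]
        gene_sex_dir = {}
        if tis in spec.sexed_tissues:
            for gi in sexed_genes:
                direction = "male" if rng.random() < 0.5 else "female"
                gene_sex_dir[gi] = direction
                sex_rows.append(
                    {"gene": genes[gi], "tissue": tis, "direction": direction}
                )
        for sp_i, sp in enumerate(tree.tip_names):
            for sex in sexes:
                for rep in range(1, spec.n_replicates + 1):
                    x = means[:, sp_i] + rng.normal(
                        0, spec.params.sigma2_e**0.5, spec.n_genes
                    )
                    if gene_sex_dir:
                        for gi, direction in gene_sex_dir.items():
                            if direction == "male" and sex == "male":
                                x[gi] += log_fc
                            elif direction == "female" and sex == "female":
                                x[gi] += log_fc
                    name = f"{sp}_{tis}_{sex}_r{rep}"
                    columns[name] = np.maximum(np.exp2(x) - 1.0, 0.0)
                    meta_rows.append(
                        {
                            "sample": name,
                            "species": sp,
                            "tissue": tis,
                            "sex": sex,
                            "replicate": rep,
                        }
                    )

    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    panel = ExpressionPanel(values, meta, units="tpm")
    truth = {
        "genes": pd.DataFrame({"gene": genes, "model": models}).set_index("gene"),
        "events": pd.DataFrame(
            event_rows, columns=["gene", "tissue", "edge", "direction", "delta"]
        ),
        "sex_effects": pd.DataFrame(sex_rows, columns=["gene", "tissue", "direction"]),
        "seed": spec.seed,
    }
    return panel, truth


def panel_to_counts(
    panel: ExpressionPanel,
    nb_dispersion: float = 0.05,
    library_sizes: dict[str, float] | float | None = None,
    seed: int = 0,
) -> ExpressionPanel:
    """Sample negative-binomial counts from a TPM panel.

    Mean counts are ``TPM / 1e6 x library size``; variance is
    ``mu + dispersion * mu^2`` (dispersion -> 0 recovers Poisson).
    """
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    if panel.units != "tpm":
        raise ValueError("panel must be in TPM units")
    rng = np.random.default_rng(seed)
    if library_sizes is None:
        library_sizes = 5e6
    if np.isscalar(library_sizes):
        library_sizes = {s: float(library_sizes) for s in panel.values.columns}
    counts = {}
    for sample in panel.values.columns:
        mu = panel.values[sample].to_numpy() / 1e6 * library_sizes[sample]
        if nb_dispersion == 0:
            c = rng.poisson(mu)
        else:
            n = 1.0 / nb_dispersion
            lam = rng.gamma(shape=n, scale=mu / n)
            c = rng.poisson(lam)
        counts[sample] = c
    values = pd.DataFrame(counts, index=panel.values.index)
    return ExpressionPanel(values, panel.meta.copy(), units="counts")


def simulate_atlas_pair(
    n_clusters: int = 8,
    n_genes: int = 400,
    n_shared_clusters: int = 4,
    n_markers: int = 15,
    profile_corr: float = 0.9,
    cells_per_cluster: int = 60,
    marker_fold: float = 8.0,
    seed: int = 0,
) -> tuple[Atlas, Atlas, dict[str, str]]:
    """Two toy cell atlases with planted homologous clusters.

    Shared clusters (the first ``n_shared_clusters``) have log-scale
    expression profiles correlated at ``profile_corr`` and share their
    planted marker genes; non-shared clusters have independent profiles and
    disjoint marker sets.  Returns (atlasA, atlasB, truth map A->B).
    """
    if n_shared_clusters > n_clusters:
        raise ValueError("n_shared_clusters must be <= n_clusters")
    total_marker_sets = n_shared_clusters + 2 * (n_clusters - n_shared_clusters)
    if total_marker_sets * n_markers > n_genes:
        raise ValueError("marker sets exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    marker_pool = rng.permutation(n_genes)
    pool_pos = 0

    def take_markers():
        nonlocal pool_pos
        out = marker_pool[pool_pos : pool_pos + n_markers]
        pool_pos += n_markers
        return out

    def base_profile():
        # sparse droplet-style expression: median ~0.14 counts per cell
        return rng.normal(-2.0, 1.5, n_genes)

    profiles_a, profiles_b = [], []
    markers_a, markers_b = [], []
    for k in range(n_clusters):
        pa = base_profile()
        if k < n_shared_clusters:
            noise = rng.normal(0, 1.0, n_genes)
            pb = profile_corr * (pa + 2.0) + np.sqrt(1 - profile_corr**2) * 1.5 * noise - 2.0
            m = take_markers()
            ma = mb = m
        else:
            pb = base_profile()
            ma, mb = take_markers(), take_markers()
        boost = np.log(marker_fold)
        pa = pa.copy()
        pb = pb.copy()
        pa[ma] += boost
        pb[mb] += boost
        profiles_a.append(pa)
        profiles_b.append(pb)
        markers_a.append(ma)
        markers_b.append(mb)

    def build(profiles, prefix):
        rows, labels = [], []
        for k, prof in enumerate(profiles):
            mu = np.exp(prof)
            lam = mu[None, :] * rng.lognormal(0, 0.1, (cells_per_cluster, 1))
            rows.append(rng.poisson(lam))
            labels.extend([f"{prefix}{k}"] * cells_per_cluster)
        counts = pd.DataFrame(
            np.vstack(rows),
            index=[f"{prefix}cell{i}" for i in range(n_clusters * cells_per_cluster)],
            columns=genes,
        )
        return Atlas(counts, pd.Series(labels, index=counts.index, name="cluster"))

    atlas_a = build(profiles_a, "A")
    atlas_b = build(profiles_b, "B")
    truth = {f"A{k}": f"B{k}" for k in range(n_shared_clusters)}
    return atlas_a, atlas_b, truth


@dataclass
class GapRun:
    """A planted gap run: ``length`` columns of '-' in one species."""

    species: str
    start: int  # alignment column, 0-based
    length: int


def simulate_alignment(
    species: list[str],
    n_columns: int,
    gap_runs: list[GapRun] = (),
    gene_id: str = "gene1",
    offsets: dict[str, int] | None = None,
    strands: dict[str, str] | None = None,
    seed: int = 0,
) -> AnchoredAlignment:
    """Toy multi-species alignment with planted gap runs and anchors."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=n_columns)
    seqs = {sp: base.copy() for sp in species}
    seen: dict[str, list[tuple[int, int]]] = {sp: [] for sp in species}
    for run in gap_runs:
        if run.species not in seqs:
            raise ValueError(f"unknown species {run.species!r}")
        if run.start < 0 or run.start + run.length > n_columns:
            raise ValueError("gap run outside alignment bounds")
        for s, e in seen[run.species]:
            if run.start < e and s < run.start + run.length:
                raise ValueError("overlapping gap runs for one species")
        seen[run.species].append((run.start, run.start + run.length))
        seqs[run.species][run.start : run.start + run.length] = "-"
    offsets = offsets or {}
    strands = strands or {}
    anchors = {
        sp: SpeciesAnchor(offsets.get(sp, 1001), strands.get(sp, "+"))
        for sp in species
    }
    return AnchoredAlignment(
        {sp: "".join(s) for sp, s in seqs.items()}, anchors, gene_id
    )
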