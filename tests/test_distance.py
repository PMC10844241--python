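import numpy as np
import pandas as pd
import pytest

from exprevo.distance import (
    nj_tree,
    nj_tree_with_support,
    relative_rate,
    sou_distance,
    subsampled_rate_test,
    tree_splits,
)
from exprevo.simulate import SimSpec, simulate_panel
from exprevo.tree import OUParams, ou_covariance


def synth_means(tree, params, n_genes, rng, extra_var=None):
    """TPM species means under stationary OU with per-gene baselines."""
    cov = ou_covariance(tree, params)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(tree.n_taxa))
    base = rng.normal(5, 2, n_genes)
    x = base[:, None] + rng.standard_normal((n_genes, tree.n_taxa)) @ L.T
    if extra_var:
        for sp, v in extra_var.items():
            j = tree.tip_index([sp])[0]
            x[:, j] += rng.normal(0, v**0.5, n_genes)
    return pd.DataFrame(np.maximum(np.exp2(x) - 1, 0), columns=tree.tip_names)


class TestSouDistance:
    def test_identical_profiles_distance_zero(self, tree, rng):
        v = rng.uniform(1, 100, 200)
        means = pd.DataFrame({sp: v for sp in tree.tip_names})
        D = sou_distance(means)
        assert np.allclose(D.to_numpy(), 0.0, atol=1e-12)

    def test_label_permutation_consistency(self, tree, rng):
        means = synth_means(tree, OUParams(0.5, 0.25, 0.0), 300, rng)
        D = sou_distance(means)
        perm = list(reversed(means.columns))
        D2 = sou_distance(means[perm])
        assert np.allclose(D.loc[perm, perm].to_numpy(), D2.to_numpy())

    def test_distance_increases_with_divergence_time(self, tree, rng):
        from scipy.stats import spearmanr

        means = synth_means(tree, OUParams(0.05, 0.1, 0.0), 5000, rng)
        D = sou_distance(means).to_numpy()
        T = tree.patristic_matrix()
        iu = np.triu_indices(6, 1)
        rho = spearmanr(D[iu], T[iu]).statistic
        # the tree has many tied patristic distances, which caps Spearman at
        # ~0.95 even for perfectly monotone D; additionally require that the
        # mean distance is strictly increasing across distinct times
        assert rho > 0.9
        times = np.unique(T[iu])
        mean_d = [D[iu][T[iu] == t].mean() for t in times]
        assert (np.diff(mean_d) > 0).all()

    def test_too_few_genes_raises(self, tree, rng):
        means = synth_means(tree, OUParams(0.5, 0.25, 0.0), 20, rng)
        with pytest.raises(ValueError):
            sou_distance(means)


class TestNJ:
    def test_additive_four_taxon_exact_recovery(self):
        # unrooted tree with internal edge 1: (A:2,B:3)-(C:4,D:5)
        D = pd.DataFrame(
            [
                [0.0, 5.0, 7.0, 8.0],
                [5.0, 0.0, 8.0, 9.0],
                [7.0, 8.0, 0.0, 9.0],
                [8.0, 9.0, 9.0, 0.0],
            ],
            index=list("ABCD"),
            columns=list("ABCD"),
        )
        t = nj_tree(D)
        assert tree_splits(t) == {frozenset({"A", "B"})}
        # branch lengths exact on additive input
        lengths = {
            l.taxon.label: l.edge.length for l in t.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(3.0)

    def test_duplicated_taxon_is_sibling_of_twin(self, tree, rng):
        means = synth_means(tree, OUParams(0.5, 0.25, 0.0), 300, rng)
        means["Dsim2"] = means["Dsim"]
        D = sou_distance(means)
        t = nj_tree(D, outgroup="Dsuz")
        assert frozenset({"Dsim", "Dsim2"}) in tree_splits(t)

    def test_simulated_panel_recovers_species_topology_with_support(self, tree, rng):
        means = synth_means(tree, OUParams(0.05, 0.1, 0.0), 5000, rng)
        et = nj_tree_with_support(means, "Dsuz", n_bootstrap=50, seed=1)
        labels = set(tree.tip_names)

        def canon(s):
            other = frozenset(labels - s)
            return min(frozenset(s), other, key=lambda x: (len(x), sorted(x)))

        expected = {
            canon({"Dsim", "Dsec"}),
            canon({"Dmel", "Dsim", "Dsec"}),
            canon({"Dsan", "Dere"}),
        }
        assert expected <= et.splits()
        assert all(0 <= v <= 100 for v in et.supports.values())
        assert all(v >= 95 for s, v in et.supports.items() if s in expected)

    def test_unknown_outgroup_raises(self, tree, rng):
        means = synth_means(tree, OUParams(0.5, 0.25, 0.0), 100, rng)
        with pytest.raises(ValueError):
            nj_tree(sou_distance(means), outgroup="Dxxx")


class TestRelativeRate:
    def test_identical_lineages_z_exactly_zero(self, tree, rng):
        means = synth_means(tree, OUParams(0.5, 0.25, 0.0), 200, rng)
        means["Dsim"] = means["Dmel"]
        z = relative_rate(means, "Dmel", "Dsim", "Dsuz")
        assert z == 0.0

    def test_swap_flips_sign(self, tree, rng):
        means = synth_means(tree, OUParams(0.5, 0.25, 0.0), 400, rng)
        z1 = relative_rate(means, "Dsan", "Dere", "Dsuz", seed=3)
        z2 = relative_rate(means, "Dere", "Dsan", "Dsuz", seed=3)
        assert np.sign(z1) == -np.sign(z2)
        assert abs(abs(z1) - abs(z2)) < 0.5  # bootstrap SE varies slightly

    def test_near_invariance_to_global_scaling(self, tree, rng):
        # correlations on logs are shift-invariant; the +1 pseudocount makes
        # global TPM scaling only approximately neutral
        means = synth_means(tree, OUParams(0.5, 0.25, 0.0), 400, rng)
        z1 = relative_rate(means, "Dsan", "Dere", "Dsuz", seed=5)
        z2 = relative_rate(means * 10.0, "Dsan", "Dere", "Dsuz", seed=5, min_tpm=10.0)
        assert abs(z1 - z2) < 1.0

    def test_distinct_species_required(self, tree, rng):
        means = synth_means(tree, OUParams(0.5, 0.25, 0.0), 100, rng)
        with pytest.raises(ValueError):
            relative_rate(means, "Dmel", "Dmel", "Dsuz")


class TestSubsampledTest:
    def test_fixed_seed_reproducible(self, tree, rng):
        means = synth_means(tree, OUParams(0.5, 0.25, 0.0), 600, rng)
        kw = dict(n_genes=100, n_reps=40, seed=11)
        r1 = subsampled_rate_test(means, [("Dsan", "Dere")], "Dsuz", **kw)
        r2 = subsampled_rate_test(means, [("Dsan", "Dere")], "Dsuz", **kw)
        assert np.array_equal(r1[0].z_subsamples, r2[0].z_subsamples)
        assert r1[0].verdict == r2[0].verdict

    def test_equal_rates_mostly_ns(self, tree):
        rng = np.random.default_rng(20)
        ingroup = [s for s in drosophila_names() if s != "Dsuz"]
        pairs = [(a, b) for i, a in enumerate(ingroup) for b in ingroup[i + 1 :]]
        ok = 0
        runs = 8
        for k in range(runs):
            means = synth_means(tree, OUParams(0.5, 0.25, 0.0), 1200, rng)
            res = subsampled_rate_test(
                means, pairs, "Dsuz", n_genes=400, n_reps=120, seed=k
            )
            if all(r.verdict == "ns" for r in res):
                ok += 1
        assert ok >= 6  # >= 90% expected; floor allows binomial noise at 8 runs

    def test_elevated_lineage_detected(self, tree):
        rng = np.random.default_rng(21)
        ingroup = [s for s in drosophila_names() if s != "Dsuz"]
        pairs = [(a, b) for i, a in enumerate(ingroup) for b in ingroup[i + 1 :]]
        hits = trials = 0
        for k in range(8):
            # lineage variance tripled: add twice the stationary variance
            means = synth_means(
                tree, OUParams(0.5, 0.25, 0.0), 1200, rng, extra_var={"Dsan": 0.5}
            )
            res = subsampled_rate_test(
                means, pairs, "Dsuz", n_genes=400, n_reps=120, seed=100 + k
            )
            for r in res:
                if "Dsan" in r.pair:
                    trials += 1
                    want = "elevated_A" if r.pair[0] == "Dsan" else "elevated_B"
                    hits += r.verdict == want
        assert hits / trials >= 0.9

    def test_degenerate_null_raises(self, tree, rng):
        means = synth_means(
            tree,
            OUParams(0.5, 0.25, 0.0),
            600,
            rng,
            extra_var={"Dsan": 3.0},
        )
        with pytest.raises(ValueError):
            subsampled_rate_test(
                means, [("Dsan", "Dere")], "Dsuz", n_genes=200, n_reps=40, z_crit=0.0
            )


def drosophila_names():
    return ["Dmel", "Dsim", "Dsec", "Dsan", "Dere", "Dsuz"]
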