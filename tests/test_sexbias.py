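import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from exprevo.sexbias import (
    bias_overlap,
    classify_bias,
    filter_expressed,
    hypergeom_enrichment,
    nb_wald,
    size_factors,
)
from exprevo.simulate import SexEffectSpec, SimSpec, panel_to_counts, simulate_panel


def counts_frame(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestSizeFactors:
    def test_identical_samples_all_one(self, rng):
        col = rng.poisson(50, 200).astype(float) + 1
        counts = counts_frame(np.column_stack([col] * 4))
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_gets_factor_two(self, rng):
        col = rng.poisson(50, 200).astype(float) + 1
        counts = counts_frame(np.column_stack([col, col, col, 2 * col]))
        sf = size_factors(counts)
        # median rescaling: three identical samples pin the median at 1
        assert sf.iloc[:3].tolist() == pytest.approx([1.0, 1.0, 1.0])
        assert sf.iloc[3] == pytest.approx(2.0)

    def test_insensitive_to_de_minority(self, rng):
        # a handful of strongly DE genes should not move the factors
        col = rng.poisson(50, 500).astype(float) + 1
        a, b = col.copy(), col.copy()
        b[:10] *= 20  # 2% of genes strongly up in sample b
        sf = size_factors(counts_frame(np.column_stack([a, a, b])))
        assert abs(sf.iloc[2] - 1.0) < 0.05

    def test_fallback_warns_when_no_common_gene(self, caplog):
        counts = counts_frame([[5.0, 0.0], [0.0, 5.0]])
        with caplog.at_level("WARNING"):
            sf = size_factors(counts)
        assert "library-size" in caplog.text
        assert np.all(sf > 0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            size_factors(counts_frame([[1.0], [2.0]]))


class TestFilterExpressed:
    def test_threshold_boundaries(self):
        norm = counts_frame(
            [
                [5, 5, 5, 0],  # 3 samples >= 5 -> kept
                [5, 5, 0, 0],  # only 2 -> dropped
                [0, 0, 0, 0],  # silent -> dropped
                [4.9, 4.9, 4.9, 4.9],  # below min_count everywhere -> dropped
            ]
        )
        keep = filter_expressed(norm, min_count=5.0, min_samples=3)
        assert keep.tolist() == [True, False, False, False]

    def test_relaxed_thresholds_monotone(self, rng):
        norm = counts_frame(rng.poisson(3.0, (300, 6)).astype(float))
        strict = filter_expressed(norm, min_count=5, min_samples=3)
        loose = filter_expressed(norm, min_count=1, min_samples=1)
        assert (loose | ~strict).all()  # strict implies loose


def two_sex_panel(n_genes=300, frac=0.2, seed=17):
    from exprevo.panel import ExpressionPanel

    spec = SimSpec(
        n_genes=n_genes,
        n_replicates=4,
        seed=seed,
        model_probs={"BM": 0.0, "OU1": 1.0, "OUM": 0.0},
        sex_effect=SexEffectSpec(fraction=frac, fold_change=4.0),
    )
    panel, truth = simulate_panel(spec)
    counts = panel_to_counts(panel, seed=seed + 1)
    m = counts.meta
    mask = (m["species"] == "Dmel") & (m["tissue"].isin(["antenna", "foreleg"]))
    sub = ExpressionPanel(
        counts.values.loc[:, m.index[mask]], m.loc[mask], units="counts"
    )
    truth["sex_effects"] = truth["sex_effects"][
        truth["sex_effects"]["tissue"].isin(["antenna", "foreleg"])
    ]
    return sub, truth


class TestNBWald:
    def test_planted_effects_found_null_controlled(self):
        sub, truth = two_sex_panel()
        res = nb_wald(pd.DataFrame(sub.values, index=sub.genes, columns=sub.meta.index), sub.meta)
        called = classify_bias(res)
        eff = truth["sex_effects"]
        planted = set(eff["gene"])
        hits = called[(called["bias"] != "none") & called["gene"].isin(planted)]
        # power: most planted 4-fold effects recovered in the tissue planted
        per_gene = called[called["gene"].isin(planted) & (called["bias"] != "none")]
        assert len(set(per_gene["gene"])) / len(planted) >= 0.8
        # type-I: few unplanted genes called (Wald + MoM dispersion is mildly
        # anti-conservative at 4 replicates; allow up to 3% of null tests)
        fps = called[(called["bias"] != "none") & ~called["gene"].isin(planted)]
        tested_null = called[~called["gene"].isin(planted)]
        assert len(fps) / max(len(tested_null), 1) < 0.03
        del hits

    def test_direction_matches_truth(self):
        sub, truth = two_sex_panel(seed=23)
        res = nb_wald(pd.DataFrame(sub.values, index=sub.genes, columns=sub.meta.index), sub.meta)
        called = classify_bias(res)
        eff = truth["sex_effects"].set_index(["gene", "tissue"])
        ok = tot = 0
        for _, row in called[called["bias"] != "none"].iterrows():
            key = (row["gene"], row["tissue"])
            if key in eff.index:
                tot += 1
                want = "male" if eff.loc[key, "direction"] == "male" else "female"
                ok += row["bias"] == want
        assert tot > 0 and ok / tot >= 0.95

    def test_label_swap_flips_log2fc(self):
        sub, _ = two_sex_panel(n_genes=120, seed=31)
        counts = pd.DataFrame(sub.values, index=sub.genes, columns=sub.meta.index)
        res1 = nb_wald(counts, sub.meta)
        meta2 = sub.meta.copy()
        meta2["sex"] = meta2["sex"].map({"male": "female", "female": "male"})
        res2 = nb_wald(counts, meta2)
        merged = res1.merge(res2, on=["gene", "tissue"], suffixes=("_a", "_b"))
        assert len(merged) > 50
        assert np.allclose(merged["log2fc_a"], -merged["log2fc_b"], atol=1e-4)

    def test_metadata_mismatch_rejected(self):
        counts = counts_frame(np.ones((10, 4)))
        meta = pd.DataFrame(
            {"tissue": ["a"] * 4, "sex": ["male", "male", "female", "female"]},
            index=["x0", "x1", "x2", "x3"],
        )
        with pytest.raises(ValueError):
            nb_wald(counts, meta)


class TestClassifyBias:
    def frame(self, log2fc, padj):
        return pd.DataFrame(
            {"gene": ["g"], "tissue": ["t"], "log2fc": [log2fc], "padj": [padj]}
        )

    @pytest.mark.parametrize(
        "log2fc,padj,want",
        [
            (np.log2(2.0), 0.001, "male"),
            (np.log2(1.4), 0.001, "none"),  # below fold threshold
            (np.log2(0.5), 0.005, "female"),
            (np.log2(4.0), 0.05, "none"),  # not significant
            (np.log2(1.5), 0.0099, "male"),  # exactly at fc_min
        ],
    )
    def test_thresholds(self, log2fc, padj, want):
        out = classify_bias(self.frame(log2fc, padj))
        assert out["bias"].iloc[0] == want

    def test_partition_property(self, rng):
        res = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(200)],
                "tissue": "t",
                "log2fc": rng.normal(0, 2, 200),
                "padj": rng.uniform(0, 1, 200),
            }
        )
        out = classify_bias(res)
        assert set(out["bias"]) <= {"male", "female", "none"}
        assert len(out) == len(res)

    def test_fc_min_monotone(self, rng):
        res = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(200)],
                "tissue": "t",
                "log2fc": rng.normal(0, 2, 200),
                "padj": rng.uniform(0, 0.02, 200),
            }
        )
        loose = (classify_bias(res, fc_min=1.2)["bias"] != "none").sum()
        strict = (classify_bias(res, fc_min=3.0)["bias"] != "none").sum()
        assert strict <= loose


class TestBiasOverlap:
    @staticmethod
    def biased(genes_dirs):
        return pd.DataFrame(
            {
                "gene": list(genes_dirs),
                "bias": [genes_dirs[g] for g in genes_dirs],
            }
        )

    def test_counts_same_direction_only(self):
        a = self.biased({"g1": "male", "g2": "female", "g3": "male", "g4": "none"})
        b = self.biased({"g1": "male", "g2": "male", "g5": "female"})
        out = bias_overlap({"A": a, "B": b})
        assert out.loc["A", "A"] == 3  # g4 is 'none', excluded
        assert out.loc["B", "B"] == 3
        assert out.loc["A", "B"] == 1  # only g1 shares direction
        assert out.loc["B", "A"] == 1

    def test_disjoint_sets_zero(self):
        a = self.biased({"g1": "male"})
        b = self.biased({"g2": "male"})
        out = bias_overlap({"A": a, "B": b})
        assert out.loc["A", "B"] == 0


class TestHypergeomEnrichment:
    def test_matches_closed_form_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        annotated = {f"g{i}" for i in range(10)}
        drawn = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(50, 62)}
        out = hypergeom_enrichment(universe, annotated, drawn)
        assert out["hits"] == 8
        assert out["p_value"] == pytest.approx(hypergeom.sf(7, 100, 10, 20))

    def test_no_enrichment_p_near_one(self):
        universe = {f"g{i}" for i in range(100)}
        out = hypergeom_enrichment(universe, {"g0", "g1"}, {"g50", "g51"})
        assert out["hits"] == 0
        assert out["p_value"] == pytest.approx(1.0)

    def test_outside_universe_trimmed_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = hypergeom_enrichment({"g1", "g2"}, {"g1", "zz"}, {"g1"})
        assert "trimmed" in caplog.text
        assert out["annotated"] == 1 and out["hits"] == 1
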