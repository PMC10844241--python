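from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exprevo.simulate import simulate_atlas_pair
from exprevo.specificity import (
    call_table,
    cell_tau,
    compare_specificity,
    expression_call,
    gain_loss,
    tau,
    tau_table,
)


class TestTau:
    def test_uniform_vector_is_zero(self):
        assert tau([3.0, 3.0, 3.0, 3.0]) == pytest.approx(0.0)

    def test_single_nonzero_entry_is_one(self):
        assert tau([0, 0, 7.0, 0, 0]) == pytest.approx(1.0)

    def test_hand_example_without_transform(self):
        assert tau([1.0, 0.5], log_transform=False) == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tau([0.0, 0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tau([1.0, -1.0])

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=12).filter(
            lambda x: max(x) > 0
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_range_and_permutation_invariance(self, x):
        t = tau(x)
        assert 0.0 <= t <= 1.0 + 1e-12
        assert tau(sorted(x)) == pytest.approx(t)

    def test_monotone_under_concentration(self):
        # nested vectors concentrating the same mass into fewer tissues
        vectors = [
            [10, 10, 10, 10, 10],
            [20, 10, 10, 5, 5],
            [40, 5, 2, 2, 1],
            [50, 0, 0, 0, 0],
        ]
        taus = [tau(v) for v in vectors]
        assert all(np.diff(taus) > 0)

    def test_table_nan_for_silent_genes(self):
        df = pd.DataFrame([[1, 2, 3], [0, 0, 0]], index=["a", "b"])
        t = tau_table(df)
        assert np.isfinite(t["a"])
        assert np.isnan(t["b"])


class TestCellTau:
    def test_single_cluster_marker_is_one_both_variants(self):
        a, _, _ = simulate_atlas_pair(n_clusters=4, n_shared_clusters=0, n_genes=120, seed=3)
        s = a.summarize()
        gene = s.genes[0]
        # construct an exact single-cluster gene
        s.mean_expression[gene] = [5.0, 0.0, 0.0, 0.0]
        s.fraction_expressing[gene] = [1.0, 0.0, 0.0, 0.0]
        assert cell_tau(s, gene, "mean") == pytest.approx(1.0)
        assert cell_tau(s, gene, "fraction") == pytest.approx(1.0)

    def test_variants_correlate_on_simulated_atlases(self):
        from scipy.stats import spearmanr

        a, _, _ = simulate_atlas_pair(n_clusters=6, n_shared_clusters=0, n_genes=300, seed=4)
        s = a.summarize()
        tm = tau_table(s.mean_expression.T)
        tf = tau_table(s.fraction_expressing.T)
        both = pd.concat([tm, tf], axis=1).dropna()
        rho = spearmanr(both.iloc[:, 0], both.iloc[:, 1]).statistic
        assert rho > 0.8

    def test_missing_gene_raises(self):
        a, _, _ = simulate_atlas_pair(n_clusters=3, n_shared_clusters=0, n_genes=100, seed=5)
        with pytest.raises(KeyError):
            cell_tau(a.summarize(), "nope")


class TestExpressionCall:
    @pytest.mark.parametrize(
        "tpm,call",
        [(3.5, "expressed"), (0.4, "unexpressed"), (1.0, "ambiguous"),
         (3.0, "ambiguous"), (0.5, "ambiguous"), (100.0, "expressed"), (0.0, "unexpressed")],
    )
    def test_thresholds(self, tpm, call):
        assert expression_call(tpm) == call

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            expression_call(-0.1)

    def test_call_table_matches_scalar(self):
        df = pd.DataFrame([[3.5, 0.4, 1.0]], index=["g"], columns=list("abc"))
        out = call_table(df)
        assert list(out.loc["g"]) == ["expressed", "unexpressed", "ambiguous"]


def exhaustive_min_changes(tree, states):
    """Brute-force parsimony oracle: enumerate all internal labelings."""
    tips = {int(tree.tip_index([sp])[0]): s for sp, s in states.items()}
    internal = [n for n in range(tree.n_nodes) if n >= tree.n_taxa]
    best_cost, labelings = None, []
    for combo in product((0, 1), repeat=len(internal)):
        lab = dict(tips)
        lab.update(dict(zip(internal, combo)))
        cost = 0
        for e in tree.edges:
            child, parent = e, tree.parent[e]
            if child in lab:
                cost += lab[child] != lab[parent]
        if best_cost is None or cost < best_cost:
            best_cost, labelings = cost, [lab]
        elif cost == best_cost:
            labelings.append(lab)
    return best_cost, labelings


class TestGainLoss:
    def test_single_species_gain_on_terminal_edge(self, tree):
        calls = {sp: "unexpressed" for sp in tree.tip_names}
        calls["Dsec"] = "expressed"
        out = gain_loss(calls, tree)
        assert list(out["edge"]) == ["Dsec"]
        assert list(out["event"]) == ["gain"]

    def test_all_expressed_no_events(self, tree):
        out = gain_loss({sp: "expressed" for sp in tree.tip_names}, tree)
        assert len(out) == 0

    def test_clade_gain_on_stem_edge(self, tree):
        calls = {sp: "unexpressed" for sp in tree.tip_names}
        for sp in ("Dmel", "Dsim", "Dsec"):
            calls[sp] = "expressed"
        out = gain_loss(calls, tree)
        assert list(out["edge"]) == ["Dmel+Dsec+Dsim"]
        assert list(out["event"]) == ["gain"]

    def test_ambiguous_species_excluded(self, tree):
        calls = {sp: "unexpressed" for sp in tree.tip_names}
        calls["Dsec"] = "expressed"
        calls["Dsim"] = "ambiguous"
        out = gain_loss(calls, tree)
        assert "Dsec" in set(out["edge"])

    def test_fewer_than_two_calls_no_result(self, tree):
        calls = {sp: "ambiguous" for sp in tree.tip_names}
        calls["Dmel"] = "expressed"
        assert len(gain_loss(calls, tree)) == 0

    def test_matches_exhaustive_enumeration_oracle(self, tree):
        rng = np.random.default_rng(7)
        for _ in range(40):
            states = {sp: int(rng.integers(2)) for sp in tree.tip_names}
            if len(set(states.values())) == 1:
                continue
            calls = {
                sp: "expressed" if s else "unexpressed" for sp, s in states.items()
            }
            out = gain_loss(calls, tree)
            cost_oracle, labelings = exhaustive_min_changes(tree, states)
            assert out.attrs["parsimony_cost"] == cost_oracle
            # forced events must change in every optimal labeling with one direction
            for _, row in out.iterrows():
                e = tree.edge_by_label(row["edge"])
                p = tree.parent[e]
                dirs = {
                    ("gain" if lab[e] == 1 else "loss")
                    if lab[e] != lab[p]
                    else "none"
                    for lab in labelings
                }
                if row["event"] in ("gain", "loss"):
                    assert dirs == {row["event"]}
                else:
                    assert len(dirs) > 1


class TestCompareSpecificity:
    def test_shifted_group_detected_in_direction(self, rng):
        a = rng.beta(5, 2, 300)
        b = rng.beta(2, 5, 300)
        out = compare_specificity(a, b)
        assert out["p_value"] < 1e-6
        assert out["direction"] == "A_greater"

    def test_identical_draws_null(self, rng):
        ps = []
        for _ in range(20):
            x = rng.uniform(0, 1, 100)
            ps.append(compare_specificity(x, rng.permutation(x))["p_value"])
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_single_element_groups_no_crash(self):
        out = compare_specificity([0.4], [0.9])
        assert 0 <= out["p_value"] <= 1

    def test_identical_constant_groups_degenerate(self):
        out = compare_specificity([0.5, 0.5], [0.5, 0.5])
        assert out["p_value"] == 1.0
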