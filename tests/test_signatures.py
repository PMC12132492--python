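import numpy as np
import pandas as pd
import pytest
from scipy import stats

from resistsig import signatures
from resistsig.signatures import (
    GeneSignature,
    RankedGeneList,
    consensus_majority,
    differential_expression,
    filter_up,
    map_orthologs,
    rra_aggregate,
    rra_rho,
    rra_table,
    top_n_signature,
)
from resistsig.synthetic_data import simulate_ranked_lists

from conftest import make_matrix


def ranked(genes, lfc=None, p=None):
    n = len(genes)
    lfc = np.asarray(lfc, dtype=float) if lfc is not None else np.linspace(3, 0.1, n)
    p = np.asarray(p, dtype=float) if p is not None else np.linspace(1e-6, 0.5, n)
    return RankedGeneList(pd.DataFrame(
        {"gene_id": genes, "log2fc": lfc, "p": p, "p_adj": np.minimum(p * n, 1)}
    ))


class TestDifferentialExpression:
    def lognorm(self, values):
        return make_matrix(np.asarray(values, dtype=float), layer="lognorm")

    def test_identical_groups_null(self):
        vals = np.tile([[1.0, 2.0]], (6, 1))
        m = self.lognorm(vals)
        with pytest.warns(UserWarning):
            rl = differential_expression(m, [f"cell{i}" for i in range(3)],
                                         [f"cell{i}" for i in range(3, 6)])
        assert (rl.entries["log2fc"] == 0).all()
        assert (rl.entries["p"] == 1).all()

    def test_exact_ranksum_p(self):
        # one gene: {1,2,3} vs {4,5,6} -> two-sided exact p = 2/20 = 0.1
        vals = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        m = self.lognorm(vals)
        rl = differential_expression(m, ["cell0", "cell1", "cell2"],
                                     ["cell3", "cell4", "cell5"])
        assert rl.entries["p"].iloc[0] == pytest.approx(0.1)

    def test_overlapping_groups_raise(self):
        m = self.lognorm(np.random.default_rng(0).random((6, 2)))
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(m, ["cell0", "cell1", "cell2"],
                                    ["cell2", "cell3", "cell4"])

    def test_planted_program_ranks_top(self, sim_small_lognorm):
        m, truth = sim_small_lognorm
        line = m.cell_lines()[0]
        sub = m.subset_cells((m.cell_meta["cell_line"] == line).to_numpy())
        clusters = sub.cell_meta["cluster"].astype(str)
        active = clusters.isin(truth.active_clusters).to_numpy()
        ids = np.array(sub.cell_ids)
        rl = differential_expression(sub, list(ids[active]), list(ids[~active]))
        # program genes of this line's active clusters should lead the ranking
        progs = {truth.cluster_programs[c] for c in truth.active_clusters
                 if c.startswith(line)}
        prog_genes = set().union(*(truth.programs[p] for p in progs))
        top = set(rl.genes[: len(prog_genes)])
        recall = len(top & prog_genes) / len(prog_genes)
        assert recall >= 0.95

    def test_sort_is_deterministic_on_ties(self):
        df = pd.DataFrame({
            "gene_id": ["b", "a", "c"],
            "log2fc": [1.0, 1.0, 1.0],
            "p": [0.5, 0.5, 0.1],
            "p_adj": [1.0, 1.0, 0.3],
        })
        rl = RankedGeneList(df)
        assert rl.genes == ["c", "a", "b"]


class TestFilterUp:
    def test_strict_lfc_boundary(self):
        rl = ranked(["a"], lfc=[0.0], p=[0.001])
        assert len(filter_up(rl)) == 0

    def test_strict_padj_boundary(self):
        rl = RankedGeneList(pd.DataFrame(
            {"gene_id": ["a"], "log2fc": [2.0], "p": [0.04], "p_adj": [0.05]}))
        assert len(filter_up(rl)) == 0

    def test_empty_input(self):
        rl = ranked([])
        assert len(filter_up(rl)) == 0

    def test_keeps_and_preserves_order(self):
        rl = ranked(["a", "b", "c"], lfc=[3.0, 2.0, -1.0], p=[1e-6, 1e-5, 1e-6])
        out = filter_up(rl)
        assert out.genes == ["a", "b"]


class TestRraRho:
    def test_single_list_identity(self):
        assert rra_rho([0.2], 1) == pytest.approx(0.2)

    def test_two_list_hand_computed(self):
        # beta_1 = 1 - 0.99^2 = 0.0199, beta_2 = 0.01^2 = 1e-4
        assert rra_rho([0.01, 0.01], 2) == pytest.approx(1e-4)
        assert stats.binom.sf(0, 2, 0.01) == pytest.approx(0.0199)

    def test_worst_case(self):
        assert rra_rho([1.0, 1.0, 1.0], 3) == 1.0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            rra_rho([0.0], 1)
        with pytest.raises(ValueError):
            rra_rho([1.2], 1)

    @pytest.mark.parametrize("m,k,seed", [(3, 3, 0), (4, 2, 1), (6, 6, 2), (5, 3, 3)])
    def test_matches_monte_carlo_order_statistic_oracle(self, m, k, seed):
        """rho = P-ish of the best order statistic; check each beta_j against
        simulated uniform ranks (binomial tail vs empirical frequency)."""
        rng = np.random.default_rng(seed)
        r = np.sort(rng.random(k) * 0.5 + 0.05)
        n_mc = 200_000
        draws = np.sort(rng.random((n_mc, m)), axis=1)
        rho = rra_rho(r, m)
        betas = [stats.binom.sf(j - 1, m, r[j - 1]) for j in range(1, k + 1)]
        for j in range(1, k + 1):
            emp = np.mean(draws[:, j - 1] <= r[j - 1])
            se = np.sqrt(emp * (1 - emp) / n_mc) + 1e-12
            assert abs(emp - betas[j - 1]) <= 3 * se + 1e-3
        assert rho == pytest.approx(min(betas))


from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    ranks=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=6),
    extra=st.integers(min_value=0, max_value=4),
)
def test_rra_rho_bounds_and_monotonicity(ranks, extra):
    """rho lies in (0,1] and improving any single rank never increases rho."""
    m = len(ranks) + extra
    rho = rra_rho(ranks, m)
    assert 0 < rho <= 1
    improved = sorted(ranks)
    improved[0] = improved[0] / 2
    assert rra_rho(improved, m) <= rho + 1e-12


class TestRraAggregate:
    def test_gene_first_in_all_lists_retained(self):
        rng = np.random.default_rng(0)
        lists = []
        others = [f"g{i}" for i in range(1, 1000)]
        for k in range(6):
            genes = ["hit"] + list(rng.permutation(others))
            lists.append(ranked(genes))
        sig = rra_aggregate(lists)
        assert "hit" in sig.genes

    def test_median_rank_gene_excluded(self):
        rng = np.random.default_rng(1)
        others = [f"g{i}" for i in range(999)]
        lists = []
        for k in range(6):
            perm = list(rng.permutation(others))
            perm.insert(500, "mid")
            lists.append(ranked(perm))
        sig = rra_aggregate(lists)
        assert "mid" not in sig.genes

    def test_input_order_invariance(self):
        lists, _ = simulate_ranked_lists(n_lists=4, list_len=300, n_consensus=15,
                                         seed=11)
        a = rra_aggregate(lists)
        b = rra_aggregate(lists[::-1])
        assert a.genes == b.genes

    def test_planted_consensus_recovery(self):
        lists, truth = simulate_ranked_lists(n_lists=6, list_len=1000,
                                             n_consensus=50,
                                             consensus_top_frac=0.05, seed=21)
        sig = rra_aggregate(lists)
        recall = len(sig.genes & truth.consensus_genes) / len(truth.consensus_genes)
        background = sig.genes - truth.consensus_genes
        fpr = len(background) / (1000 - len(truth.consensus_genes))
        assert recall >= 0.9
        assert fpr <= 0.05

    def test_universe_size_restores_power_for_filtered_lists(self):
        # two filtered lists of 20 genes out of a 1000-gene universe
        genes = [f"g{i}" for i in range(20)]
        lists = [ranked(genes), ranked(genes)]
        without = rra_table(lists)
        with_universe = rra_table(lists, universe_size=1000)
        assert with_universe["rank_p"].min() < without["rank_p"].min()


class TestConsensusAndTopN:
    def sigs(self, memberships):
        return [GeneSignature(f"s{i}", frozenset(g), "up")
                for i, g in enumerate(memberships)]

    def test_majority_boundary(self):
        lists = self.sigs([{"a", "b"}] * 5 + [{"b"}] * 4)
        out = consensus_majority(lists, min_support=5)
        assert out.genes == {"a", "b"}  # a in exactly 5 of 9 -> included

    def test_four_of_nine_excluded(self):
        lists = self.sigs([{"a"}] * 4 + [{"b"}] * 5)
        out = consensus_majority(lists, min_support=5)
        assert "a" not in out.genes and "b" in out.genes

    def test_min_support_one_is_union(self):
        lists = self.sigs([{"a"}, {"b"}, {"c"}])
        assert consensus_majority(lists, 1).genes == {"a", "b", "c"}

    def test_support_above_count_warns_empty(self):
        with pytest.warns(UserWarning):
            out = consensus_majority(self.sigs([{"a"}]), min_support=2)
        assert len(out) == 0

    def test_top_n(self):
        rl = ranked([f"g{i}" for i in range(500)])
        assert len(top_n_signature(rl, 200)) == 200
        assert len(top_n_signature(ranked([f"g{i}" for i in range(50)]), 200)) == 50
        with pytest.warns(UserWarning):
            assert len(top_n_signature(rl, 0)) == 0


class TestMapOrthologs:
    def test_empty_mapping_raises(self):
        sig = GeneSignature("s", frozenset({"x"}), "up")
        with pytest.raises(ValueError, match="unmapped"):
            map_orthologs(sig, {})

    def test_one_to_many(self):
        sig = GeneSignature("s", frozenset({"x"}), "up")
        out, rep = map_orthologs(sig, {"x": {"A", "B"}})
        assert out.genes == {"A", "B"}
        assert rep.n_mapped == 1

    def test_partial_mapping_set_arithmetic(self):
        genes = {f"s{i}" for i in range(10)}
        mapping = {f"s{i}": {f"t{i % 4}"} for i in range(7)}
        sig = GeneSignature("s", frozenset(genes), "up")
        out, rep = map_orthologs(sig, mapping)
        assert out.genes == {f"t{i}" for i in range(4)}
        assert rep.n_mapped == 7 and len(rep.unmapped) == 3

    def test_table_reader(self, tmp_path):
        (tmp_path / "ortho.tsv").write_text("x\tA\nx\tB\ny\tC\n")
        mapping = signatures.read_ortholog_table(tmp_path / "ortho.tsv")
        assert mapping == {"x": {"A", "B"}, "y": {"C"}}
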