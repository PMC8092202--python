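"""COG assignment, erosion trends, state matrices, clustering and the rank-sum test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import complete_linkage_merges
from panerosion import erosion
from panerosion.orthology import GeneRecord, OrthoGroup


class TestAssignCog:
    def test_single_and_multi_letter(self):
        df = pd.DataFrame({"gene_id": ["g1", "g2"], "categories": ["L", "KL"]})
        cog = erosion.assign_cog(["g1", "g2", "g3"], df)
        assert cog["g1"] == {"L"}
        assert cog["g2"] == {"K", "L"}
        assert cog["g3"] == frozenset()

    def test_malformed_rows_rejected(self):
        df = pd.DataFrame({"gene_id": ["g1", "g2"], "categories": ["K1", "L"]})
        cog = erosion.assign_cog(["g1", "g2"], df)
        assert cog["g1"] == frozenset()
        assert cog["g2"] == {"L"}

    def test_coverage_counts_distinct_genes(self):
        df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(7)], "categories": ["K"] * 7})
        cog = erosion.assign_cog([f"g{i}" for i in range(10)], df)
        assert sum(1 for v in cog.values() if v) == 7


def _calls(rows):
    return pd.DataFrame(rows, columns=["genome_id", "gene_id", "is_pseudogene"])


class TestProportions:
    def test_gene_proportion_arithmetic(self):
        calls = _calls([("G", f"g{i}", False) for i in range(10)])
        cog = {f"g{i}": frozenset("K") if i < 2 else frozenset() for i in range(10)}
        table = erosion.build_erosion_table(calls, cog, pd.Series({"G": 1000}))
        assert table.gene_prop.at["G", "K"] == pytest.approx(0.2)

    def test_pseudo_proportion_arithmetic(self):
        calls = _calls([("G", f"g{i}", i < 4) for i in range(8)])
        cog = {f"g{i}": frozenset("L") if i == 0 else frozenset("E") for i in range(8)}
        table = erosion.build_erosion_table(calls, cog, pd.Series({"G": 1000}))
        assert table.pseudo_prop.at["G", "L"] == pytest.approx(0.25)

    def test_no_pseudogenes_gives_nan_profile(self):
        calls = _calls([("G", "g0", False)])
        table = erosion.build_erosion_table(calls, {"g0": frozenset("K")}, pd.Series({"G": 10}))
        assert np.isnan(table.pseudo_prop.at["G", "K"])

    def test_double_count_oracle(self):
        rng = np.random.default_rng(1)
        letters = list("KLNE")
        genes = [f"g{i}" for i in range(60)]
        cog = {
            g: frozenset(rng.choice(letters, size=rng.integers(1, 3), replace=False))
            for g in genes
        }
        calls = _calls([("G", g, False) for g in genes])
        table = erosion.build_erosion_table(calls, cog, pd.Series({"G": 10}))
        # per-category tallies computed independently by expanding genes
        for cat in letters:
            expected = sum(1 for g in genes if cat in cog[g]) / len(genes)
            assert table.gene_prop.at["G", cat] == pytest.approx(expected)

    def test_single_category_pseudo_rows_sum_to_one(self):
        genes = [f"g{i}" for i in range(9)]
        cog = {g: frozenset("KLN"[i % 3]) for i, g in enumerate(genes)}
        calls = _calls([("G", g, True) for g in genes])
        table = erosion.build_erosion_table(calls, cog, pd.Series({"G": 10}))
        assert table.pseudo_prop.loc["G"].sum() == pytest.approx(1.0)

    def test_zero_gene_genome_rejected(self):
        with pytest.raises(ValueError):
            erosion.build_erosion_table(_calls([]), {}, pd.Series(dtype=float))
        # a genome whose genes are all COG-unmapped has zero countable genes
        with pytest.raises(ValueError):
            erosion.build_erosion_table(
                _calls([("G", "g0", False)]),
                {"g0": frozenset()},
                pd.Series({"G": 10}),
                include_unmapped=False,
            )


def _table(sizes, props, category="K"):
    genomes = [f"G{i}" for i in range(len(sizes))]
    return erosion.ErosionTable(
        genomes=genomes,
        genome_size=pd.Series(sizes, index=genomes, dtype=float),
        gene_prop=pd.DataFrame({category: props}, index=genomes),
        pseudo_prop=pd.DataFrame({category: props}, index=genomes),
        categories=[category],
    )


class TestErosionTrend:
    def test_perfect_monotone_gives_rho_one(self):
        sizes = np.arange(10) * 1000 + 2e6
        table = _table(sizes, np.linspace(0.01, 0.1, 10))
        t = erosion.erosion_trend(table, "K")
        assert t.spearman_rho == pytest.approx(1.0)
        assert t.verdict == "eroded"

    def test_constant_proportions_give_none(self):
        table = _table(np.arange(6) * 1000.0, [0.05] * 6)
        t = erosion.erosion_trend(table, "K")
        assert t.verdict == "none"
        assert np.isnan(t.spearman_rho)

    def test_exact_permutation_p_small_n(self):
        # perfect monotone increase over 5 genomes: only the two extreme
        # permutations reach |rho| = 1, so the exact p is 2/5! = 1/60
        table = _table([1.0, 2.0, 3.0, 4.0, 5.0], [0.1, 0.2, 0.3, 0.4, 0.5])
        t = erosion.erosion_trend(table, "K")
        assert t.spearman_p == pytest.approx(2 / 120)

    def test_approximation_used_for_larger_n(self):
        rng = np.random.default_rng(3)
        sizes = np.linspace(1e6, 3e6, 12)
        props = 0.02 + 1e-8 * sizes + rng.normal(0, 0.002, 12)
        table = _table(sizes, props)
        t = erosion.erosion_trend(table, "K")
        rho, p = stats.spearmanr(sizes, props)
        assert t.spearman_rho == pytest.approx(rho)
        assert t.spearman_p == pytest.approx(p)

    def test_negative_trend_is_preserved_verdict(self):
        table = _table(np.arange(10) * 1000.0 + 1e6, np.linspace(0.1, 0.01, 10))
        assert erosion.erosion_trend(table, "K").verdict == "preserved"

    def test_ols_matches_linregress(self):
        sizes = np.linspace(1e6, 2e6, 8)
        props = np.linspace(0.02, 0.06, 8)
        t = erosion.erosion_trend(_table(sizes, props), "K")
        ols = stats.linregress(sizes, props)
        assert t.ols_slope == pytest.approx(ols.slope)
        assert t.ols_intercept == pytest.approx(ols.intercept)

    def test_too_few_genomes_rejected(self):
        with pytest.raises(ValueError):
            erosion.erosion_trend(_table([1.0, 2.0, 3.0], [0.1, 0.2, 0.3]), "K")


def _member(genome, gene):
    return GeneRecord(genome_id=genome, gene_id=gene, annotation="", nt_seq="", aa_seq="M")


class TestStateMatrix:
    def _groups(self):
        g1 = OrthoGroup("OG1", [_member("A", "a1"), _member("B", "b1")], {"K"})
        g2 = OrthoGroup("OG2", [_member("A", "a2"), _member("A", "a2b"), _member("B", "b2")], {"L"})
        g3 = OrthoGroup("OG3", [_member("A", "a3")], {"E"})
        return [g1, g2, g3]

    def test_intact_everywhere_is_all_gene(self):
        m = erosion.state_matrix(self._groups(), {}, ["A", "B"])
        assert list(m.loc["OG1"]) == ["gene", "gene"]

    def test_pseudogene_precedence_over_paralog(self):
        # genome A has an intact paralog a2b next to pseudogene a2
        m = erosion.state_matrix(self._groups(), {"a2": True}, ["A", "B"])
        assert m.at["OG2", "A"] == "pseudogene"
        assert m.at["OG2", "B"] == "gene"

    def test_absent_state_and_row_selection(self):
        m = erosion.state_matrix(self._groups(), {}, ["A", "B"])
        # OG3 carries E only, which is outside the default K/L/N selection
        assert list(m.index) == ["OG1", "OG2"]
        m_all = erosion.state_matrix(self._groups(), {}, ["A", "B"], categories={"K", "L", "E"})
        assert m_all.at["OG3", "B"] == "absent"


class TestHcluster:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame(
            [[2, 2, 2], [2, 2, 2], [0, 1, 0]], index=["r1", "r2", "r3"], columns=list("abc")
        )
        d = erosion.hcluster_rows(m)
        assert d.merges[0, 2] == 0.0
        # the identical rows are adjacent leaves
        assert abs(d.leaf_order.index("r1") - d.leaf_order.index("r2")) == 1

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.integers(0, 3, size=(8, 5)), index=[f"r{i}" for i in range(8)])
        d = erosion.hcluster_rows(m)
        heights = d.merges[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_merge_sequence_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(5, 4))
        labels = [f"r{i}" for i in range(5)]
        m = pd.DataFrame(data, index=labels)
        d = erosion.hcluster_rows(m)
        oracle = complete_linkage_merges(data, labels)
        # reconstruct merged leaf sets from the scipy linkage matrix
        clusters = {i: frozenset([labels[i]]) for i in range(5)}
        steps = []
        for k, (a, b, h, _) in enumerate(d.merges):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[5 + k] = merged
            steps.append((merged, h))
        assert [s[0] for s in steps] == [o[0] for o in oracle]
        for (_, h), (_, oh) in zip(steps, oracle):
            assert h == pytest.approx(oh)

    def test_single_row_trivial_tree(self):
        d = erosion.hcluster_rows(pd.DataFrame([[1, 2]], index=["only"]))
        assert d.leaf_order == ["only"]
        assert erosion.dendrogram_newick(d) == "only;"

    def test_newick_contains_all_leaves(self):
        m = pd.DataFrame(np.eye(4), index=list("wxyz"))
        nwk = erosion.dendrogram_newick(erosion.hcluster_rows(m))
        assert all(leaf in nwk for leaf in "wxyz")


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        w, p = erosion.wilcoxon_ranksum([5, 6, 7], [5, 6, 7])
        assert p == 1.0

    def test_fully_separated_exact_enumeration(self):
        w, p = erosion.wilcoxon_ranksum([1, 2, 3], [10, 11, 12])
        assert w == 6.0
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)

    def test_exact_and_asymptotic_paths_agree(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1.5, 1, 6)
        _, p_exact = erosion.wilcoxon_ranksum(a, b)
        p_approx = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_approx) < 0.02

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 15)
        b = rng.normal(1, 1, 15)
        _, p = erosion.wilcoxon_ranksum(a, b)
        expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            erosion.wilcoxon_ranksum([], [1, 2])

    def test_phenotype_wrapper(self):
        meta = pd.DataFrame(
            {
                "genome_size_bp": [3.0e6, 3.1e6, 3.2e6, 2.0e6, 2.1e6, 2.2e6],
                "phenotype": ["motile"] * 3 + ["immobile"] * 3,
            },
            index=[f"G{i}" for i in range(6)],
        )
        w, p = erosion.wilcoxon_by_phenotype(meta)
        assert p == pytest.approx(0.1)


class TestPlantedGradient:
    def test_high_loss_pathway_eroded_low_preserved(self):
        from panerosion.simulate import SimulationConfig, simulate_pangenome

        cfg = SimulationConfig(seed=21)
        sim = simulate_pangenome(cfg, with_sequences=False)
        rows = [
            (genome, gene, st.startswith("pseudogene"))
            for (genome, gene), st in sim.truth.status.items()
        ]
        calls = pd.DataFrame(rows, columns=["genome_id", "gene_id", "is_pseudogene"])
        cog = {g: sim.truth.cog_map[g.split("_", 1)[1]] for g in calls["gene_id"]}
        table = erosion.build_erosion_table(calls, cog, sim.genome_meta["genome_size_bp"])
        t_high = erosion.erosion_trend(table, "K")  # planted loss rate 0.8
        t_zero = erosion.erosion_trend(table, "J")  # planted loss rate 0.0
        assert t_high.verdict == "eroded"
        assert t_zero.spearman_rho < t_high.spearman_rho
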