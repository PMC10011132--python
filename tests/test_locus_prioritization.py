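import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from netexpand.locus_prioritization import (
    GeneFootprint,
    GwasSummary,
    Locus,
    PercentileResult,
    _percentiles_vs_null,
    candidate_gene_filter,
    loo_network_percentiles,
    merge_loci,
    min_snp_pvalue_per_gene,
    read_loci_tsv,
    seed_vs_locus_test,
    snp_pvalue_enrichment,
    write_loci_tsv,
)
from netexpand import generate_planted_network, generate_synthetic_gwas, \
    generate_trait_seeds


class TestMergeLoci:
    def loc(self, lid, pos, genes):
        return Locus(lid, [("chr1", pos)], genes)

    def test_within_window_merged(self):
        out = merge_loci([self.loc("L1", 100_000, {"A": 0.6}),
                          self.loc("L2", 280_000, {"A": 0.8, "B": 0.2})])
        assert len(out) == 1
        assert out[0].genes["A"] == pytest.approx(0.7)   # mean across loci
        assert out[0].genes["B"] == pytest.approx(0.2)

    def test_outside_window_not_merged(self):
        out = merge_loci([self.loc("L1", 100_000, {"A": 0.6}),
                          self.loc("L2", 400_000, {"B": 0.8})])
        assert len(out) == 2

    def test_chain_merges_transitively(self):
        out = merge_loci([self.loc("L1", 100_000, {"A": 0.5}),
                          self.loc("L2", 280_000, {"B": 0.5}),
                          self.loc("L3", 460_000, {"C": 0.5})])
        assert len(out) == 1 and set(out[0].genes) == {"A", "B", "C"}

    def test_different_chromosomes_never_merge(self):
        out = merge_loci([Locus("L1", [("chr1", 100)], {"A": 0.5}),
                          Locus("L2", [("chr2", 100)], {"B": 0.5})])
        assert len(out) == 2

    def test_malformed_chromosome_errors(self):
        with pytest.raises(ValueError, match="chromosome"):
            merge_loci([Locus("L1", [("", 100)], {"A": 0.5})])


class TestPercentileArithmetic:
    def test_above_all_nulls_is_100(self):
        scores = np.array([[5.0]])
        nulls = np.arange(1.0, 5.0)[None, :]
        assert _percentiles_vs_null(scores, nulls)[0, 0] == 100.0

    def test_at_median_is_50(self):
        scores = np.array([[2.5]])
        nulls = np.array([[1.0, 2.0, 3.0, 4.0]])
        assert _percentiles_vs_null(scores, nulls)[0, 0] == 50.0

    def test_ties_half_credit(self):
        scores = np.array([[2.0]])
        nulls = np.array([[1.0, 2.0, 2.0, 3.0]])
        # 1 below + half of the 2 ties = 2 of 4 -> 50
        assert _percentiles_vs_null(scores, nulls)[0, 0] == 50.0


class TestLooPercentiles:
    def test_planted_scenario(self, planted):
        net, truth, _ = planted
        seeds = generate_trait_seeds(truth, n_traits=1, noise_frac=0.0,
                                     rng_seed=81)[0]
        pct = loo_network_percentiles(net, seeds.genes(), n_null=200, rng_seed=82)
        assert ((pct.percentile >= 0) & (pct.percentile <= 100)).all()
        for g in seeds.genes():
            assert pct.provenance[g] == "seed_loo"
        non_seed = [g for g in pct.percentile.index if g not in seeds.genes()]
        assert all(pct.provenance[g] == "median_across_runs" for g in non_seed)
        # held-out seeds score above typical genes from unseeded blocks
        block = truth.trait_block[seeds.trait_id]
        other = [g for g in non_seed if truth.block_of[g] != block]
        assert np.median(pct.percentile[sorted(seeds.genes())]) > \
            np.median(pct.percentile[other])

    def test_requires_two_seeds(self, planted):
        net, _, _ = planted
        with pytest.raises(ValueError, match="at least 2"):
            loo_network_percentiles(net, {"G0000"}, n_null=10)

    def test_unknown_seeds_dropped(self, planted, caplog):
        net, truth, _ = planted
        seeds = set(net.sorted_nodes()[:3]) | {"NOT_A_GENE"}
        with caplog.at_level("WARNING"):
            pct = loo_network_percentiles(net, seeds, n_null=20, rng_seed=1)
        assert "NOT_A_GENE" not in pct.percentile.index or \
            pct.provenance.get("NOT_A_GENE") != "seed_loo"


class TestSeedVsLocusTest:
    def pct_of(self, values, seeds):
        prov = {g: ("seed_loo" if g in seeds else "median_across_runs")
                for g in values}
        return PercentileResult(pd.Series(values), prov)

    def test_complete_separation_exact_p(self):
        vals = {f"S{i}": 90.0 + i for i in range(5)}
        vals.update({f"O{i}": 10.0 + i for i in range(5)})
        loci = [Locus("L", [("chr1", 1)], {g: 0.5 for g in vals})]
        stat, p = seed_vs_locus_test(self.pct_of(vals, {f"S{i}" for i in range(5)}), loci)
        assert p == pytest.approx(1.0 / comb(10, 5, exact=True), rel=1e-9)

    def test_identical_distributions_p_half(self):
        rng = np.random.default_rng(91)
        vals = {f"G{i}": float(v) for i, v in enumerate(rng.random(40) * 100)}
        seeds = set(list(vals)[::2])
        loci = [Locus("L", [("chr1", 1)], {g: 0.5 for g in vals})]
        _, p = seed_vs_locus_test(self.pct_of(vals, seeds), loci)
        assert 0.05 < p < 0.95

    def test_empty_group_errors(self):
        vals = {"A": 90.0, "B": 80.0}
        loci = [Locus("L", [("chr1", 1)], {"A": 0.5, "B": 0.5})]
        with pytest.raises(ValueError):
            seed_vs_locus_test(self.pct_of(vals, {"A", "B"}), loci)


class TestCandidateFilter:
    def pct_of(self, values):
        return PercentileResult(pd.Series(values), {})

    def test_clear_winner_selected(self):
        loci = [Locus("L", [("chr1", 1)], {"G1": 0.4, "G2": 0.6})]
        pct = self.pct_of({"G1": 95.0, "G2": 40.0})
        assert candidate_gene_filter(loci, pct) == [("L", "G1")]

    def test_competitor_blocks_selection(self):
        loci = [Locus("L", [("chr1", 1)], {"G1": 0.4, "G2": 0.2})]
        pct = self.pct_of({"G1": 95.0, "G2": 85.0})
        assert candidate_gene_filter(loci, pct) == []

    def test_low_l2g_competitor_ignored(self):
        loci = [Locus("L", [("chr1", 1)], {"G1": 0.4, "G2": 0.05})]
        pct = self.pct_of({"G1": 95.0, "G2": 85.0})
        assert candidate_gene_filter(loci, pct) == [("L", "G1")]

    def test_engineered_five_locus_fixture(self):
        # exactly the loci engineered to pass contribute candidates
        loci = [
            Locus("L1", [("chr1", 1)], {"T1": 0.5, "D1": 0.05}),    # winner
            Locus("L2", [("chr1", 2)], {"T2": 0.3, "D2": 0.2}),     # competitor
            Locus("L3", [("chr1", 3)], {"T3": 0.9, "D3": 0.02}),    # winner
            Locus("L4", [("chr1", 4)], {"T4": 0.05, "D4": 0.05}),   # L2G too low
            Locus("L5", [("chr1", 5)], {"T5": 0.5, "D5": 0.3}),     # pct too low
        ]
        pct = self.pct_of({
            "T1": 99.0, "D1": 95.0,
            "T2": 95.0, "D2": 85.0,
            "T3": 92.0, "D3": 10.0,
            "T4": 97.0, "D4": 20.0,
            "T5": 88.0, "D5": 15.0,
        })
        assert candidate_gene_filter(loci, pct) == [("L1", "T1"), ("L3", "T3")]


class TestSnpEnrichment:
    def test_min_p_window_and_coordinates(self):
        fps = [GeneFootprint("A", "chr1", 1000, 2000)]
        # 1-based pos 990 -> 0-based 989: inside [1000-10, 2000+10)
        gwas = GwasSummary(pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1"],
            "pos": [990, 1500, 5000],
            "pval": [0.5, 0.01, 1e-8],
        }))
        minp = min_snp_pvalue_per_gene(fps, gwas, window_bp=10)
        assert minp["A"] == pytest.approx(0.01)

    def test_gene_without_snps_excluded(self):
        fps = [GeneFootprint("A", "chr1", 0, 10), GeneFootprint("B", "chr2", 0, 10)]
        gwas = GwasSummary(pd.DataFrame({"chrom": ["chr1"], "pos": [5], "pval": [0.2]}))
        minp = min_snp_pvalue_per_gene(fps, gwas, window_bp=0)
        assert "B" not in minp.index and "A" in minp.index

    def test_two_by_two_arithmetic(self):
        # bin 9/10 low-p vs reference 10/70 low-p: OR = (9*60)/(1*10) = 54
        genes, percs, pvals = [], {}, {}
        for i in range(10):
            g = f"H{i}"
            genes.append(g)
            percs[g] = 97.0
            pvals[g] = 1e-6 if i < 9 else 0.5
        for i in range(70):
            g = f"L{i}"
            genes.append(g)
            percs[g] = 10.0
            pvals[g] = 1e-6 if i < 10 else 0.5
        fps = [GeneFootprint(g, "chr1", 1000 * k, 1000 * k + 500)
               for k, g in enumerate(genes)]
        gwas = GwasSummary(pd.DataFrame({
            "chrom": "chr1",
            "pos": [1000 * k + 250 for k in range(len(genes))],
            "pval": [pvals[g] for g in genes],
        }))
        pct = PercentileResult(pd.Series(percs), {})
        table = snp_pvalue_enrichment(pct, fps, gwas, window_bp=0,
                                      p_threshold=1e-3,
                                      pct_bins=((95.0, 100.0),))
        assert len(table) == 1
        assert table.iloc[0].odds_ratio == pytest.approx(54.0)

    def test_empty_bin_skipped_and_inf_branch(self):
        percs = {f"H{i}": 97.0 for i in range(10)}
        percs.update({f"L{i}": 10.0 for i in range(10)})
        fps = [GeneFootprint(g, "chr1", 1000 * k, 1000 * k + 500)
               for k, g in enumerate(sorted(percs))]
        gwas = GwasSummary(pd.DataFrame({
            "chrom": "chr1",
            "pos": [1000 * k + 250 for k in range(len(percs))],
            "pval": [1e-6 if g.startswith("H") else 0.5 for g in sorted(percs)],
        }))
        pct = PercentileResult(pd.Series(percs), {})
        table = snp_pvalue_enrichment(pct, fps, gwas, window_bp=0, p_threshold=1e-3,
                                      pct_bins=((50.0, 70.0), (95.0, 100.0)))
        assert list(table.bin_low) == [95.0]      # the empty 50-70 bin is skipped
        assert np.isinf(table.iloc[0].odds_ratio)


def test_loci_tsv_round_trip(tmp_path, planted):
    net, truth, _ = planted
    seeds = generate_trait_seeds(truth, n_traits=1, noise_frac=0.0, rng_seed=83)[0]
    _, loci = generate_synthetic_gwas(truth, seeds.trait_id, rng_seed=84)
    path = tmp_path / "loci.tsv"
    write_loci_tsv(loci, path)
    again = read_loci_tsv(path)
    assert {l.locus_id for l in again} == {l.locus_id for l in loci}
    by_id = {l.locus_id: l for l in again}
    for loc in loci:
        assert by_id[loc.locus_id].genes == pytest.approx(loc.genes)
        assert by_id[loc.locus_id].lead_positions == sorted(loc.lead_positions)
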