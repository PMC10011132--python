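"""Synthetic fixtures with the statistical structure the pipeline assumes.

A planted-partition interactome (dense within blocks, sparse between) stands
in for the modular structure of real protein networks; traits draw seed genes
mostly from one causal block with locus-to-gene-like weights in [0.5, 1];
gold standards are the causal-block genes never used as seeds; and GWAS
summaries plant low p-values (Beta(alpha, 1), alpha < 1) at SNPs near
causal-block gene footprints laid out on a linear genome.  Every generator is
a pure function of its seed, so downstream tests are parameter-recovery
exercises against known ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_core import Interactome
from .locus_prioritization import GeneFootprint, GwasSummary, Locus
from .propagation import SeedSet
from .benchmark import GoldStandard

logger = logging.getLogger(__name__)

# Default desk-scale scenario: small enough for an end-to-end run in well
# under two minutes, structured enough for every recovery test to have power.
DEFAULT_N_BLOCKS = 5
DEFAULT_BLOCK_SIZE = 60
DEFAULT_P_IN = 0.2
DEFAULT_P_OUT = 0.01
DEFAULT_N_TRAITS = 20
DEFAULT_SEEDS_PER_TRAIT = 8
DEFAULT_NOISE_FRAC = 0.2
DEFAULT_L2G_LOW = 0.5
DEFAULT_L2G_HIGH = 1.0

# Linear genome layout: fixed-size footprints with fixed inter-gene gaps, in
# an order decorrelated from block membership so loci mix causal and decoy
# genes.
GENE_LENGTH_BP = 20_000
GENE_GAP_BP = 30_000
CHROM = "chr1"


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic scenario, for parameter-recovery tests."""

    block_of: dict[str, int]
    blocks: dict[int, set[str]] = field(default_factory=dict)
    trait_block: dict[str, int] = field(default_factory=dict)
    causal_genes: dict[str, set[str]] = field(default_factory=dict)
    genome_layout: dict[str, GeneFootprint] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.block_of)


def generate_planted_network(
    n_blocks: int = DEFAULT_N_BLOCKS,
    block_size: int = DEFAULT_BLOCK_SIZE,
    p_in: float = DEFAULT_P_IN,
    p_out: float = DEFAULT_P_OUT,
    rng_seed: int = 0,
) -> tuple[Interactome, SyntheticTruth]:
    """Planted-partition graph plus a non-overlapping linear genome layout.

    Within-block edges appear with probability ``p_in``, between-block edges
    with ``p_out`` (requires 0 <= p_out <= p_in <= 1, p_in > 0).  Isolated
    nodes are retained.  Gene order along the genome is a seeded permutation,
    so genomic neighbours are usually from different blocks.
    """
    if not (0 <= p_out <= p_in <= 1) or p_in == 0:
        raise ValueError("need 0 <= p_out <= p_in <= 1 with p_in > 0")
    if n_blocks < 1 or block_size < 1:
        raise ValueError("n_blocks and block_size must be positive")
    rng = np.random.default_rng(rng_seed)
    n = n_blocks * block_size
    genes = [f"G{i:04d}" for i in range(n)]
    block_of = {g: i // block_size for i, g in enumerate(genes)}
    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(n, k=1)
    same = (iu // block_size) == (ju // block_size)
    probs = np.where(same, p_in, p_out)
    keep = rng.random(len(iu)) < probs
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(genes[i], genes[j], sources=("synthetic",), confidence=None)
    order = rng.permutation(n)
    layout = {}
    for slot, gi in enumerate(order):
        start = slot * (GENE_LENGTH_BP + GENE_GAP_BP)
        layout[genes[gi]] = GeneFootprint(genes[gi], CHROM, start, start + GENE_LENGTH_BP)
    blocks: dict[int, set[str]] = {}
    for gene, b in block_of.items():
        blocks.setdefault(b, set()).add(gene)
    net = Interactome(g)
    net.validate()
    return net, SyntheticTruth(block_of=block_of, blocks=blocks, genome_layout=layout)


def generate_trait_seeds(
    truth: SyntheticTruth,
    n_traits: int = DEFAULT_N_TRAITS,
    seeds_per_trait: int = DEFAULT_SEEDS_PER_TRAIT,
    l2g_low: float = DEFAULT_L2G_LOW,
    l2g_high: float = DEFAULT_L2G_HIGH,
    noise_frac: float = DEFAULT_NOISE_FRAC,
    rng_seed: int = 0,
) -> list[SeedSet]:
    """Per-trait seed sets concentrated in one causal block.

    Each trait draws a causal block uniformly; ``round(noise_frac * k)`` of
    its ``k`` seeds are drawn uniformly from outside the block, the rest from
    inside.  Weights are U(l2g_low, l2g_high).  The causal block and the seed
    set of every trait are recorded on ``truth``.
    """
    if seeds_per_trait < 2:
        raise ValueError("each trait needs at least 2 seed genes")
    block_sizes = {b: len(m) for b, m in truth.blocks.items()}
    if seeds_per_trait > min(block_sizes.values()):
        raise ValueError("seeds_per_trait exceeds the smallest block size")
    rng = np.random.default_rng(rng_seed)
    genes = truth.genes()
    out = []
    for t in range(n_traits):
        trait_id = f"T{t:03d}"
        block = int(rng.integers(0, len(truth.blocks)))
        inside = sorted(truth.blocks[block])
        outside = [g for g in genes if truth.block_of[g] != block]
        n_noise = int(round(noise_frac * seeds_per_trait))
        n_causal = seeds_per_trait - n_noise
        picked = list(rng.choice(inside, size=n_causal, replace=False))
        if n_noise:
            picked += list(rng.choice(outside, size=n_noise, replace=False))
        weights = {g: float(w) for g, w in
                   zip(picked, rng.uniform(l2g_low, l2g_high, size=len(picked)))}
        truth.trait_block[trait_id] = block
        truth.causal_genes[trait_id] = set(picked)
        out.append(SeedSet(trait_id, weights))
    return out


def generate_gold_standard(
    truth: SyntheticTruth,
    trait_id: str,
    holdout_frac: float = 1.0,
    rng_seed: int = 0,
    min_positives: int = 10,
) -> GoldStandard:
    """Held-out causal-block genes as a seed-disjoint gold standard."""
    if not 0 < holdout_frac <= 1:
        raise ValueError("holdout_frac must lie in (0, 1]")
    block = truth.trait_block[trait_id]
    candidates = sorted(truth.blocks[block] - truth.causal_genes[trait_id])
    rng = np.random.default_rng(rng_seed)
    k = int(round(holdout_frac * len(candidates)))
    if k < min_positives:
        raise ValueError(
            f"block {block} leaves only {k} held-out genes (< {min_positives})"
        )
    positives = set(rng.choice(candidates, size=k, replace=False))
    return GoldStandard(disease_id=f"{trait_id}_gs", positives=positives,
                        tier="synthetic_heldout")


def generate_synthetic_gwas(
    truth: SyntheticTruth,
    trait_id: str,
    n_snps_per_gene: int = 5,
    signal_window_bp: int = 10_000,
    alpha_signal: float = 0.05,
    locus_window_bp: int = 200_000,
    decoy_l2g_high: float = 0.3,
    rng_seed: int = 0,
) -> tuple[GwasSummary, list[Locus]]:
    """GWAS summary statistics with low p-values planted near causal genes.

    SNPs are placed uniformly within each gene's footprint extended by
    ``signal_window_bp``; p-values are U(0, 1) for genes outside the trait's
    causal block and Beta(alpha_signal, 1) (concentrated near 0 for
    alpha_signal < 1) for causal-block genes.  One locus is built around the
    lowest-p SNP of each seed gene: every gene whose footprint lies within
    ``locus_window_bp`` of the lead joins the locus, the seed getting an
    L2G weight in [0.5, 1] and decoys in [0, decoy_l2g_high].
    """
    import pandas as pd

    _check_layout(truth)
    rng = np.random.default_rng(rng_seed)
    block = truth.trait_block[trait_id]
    rows = []
    min_p_snp: dict[str, tuple[int, float]] = {}
    for gene in truth.genes():
        fp = truth.genome_layout[gene]
        if n_snps_per_gene == 0:
            continue
        lo = max(0, fp.start - signal_window_bp)
        hi = fp.end + signal_window_bp
        positions = np.sort(rng.integers(lo, hi, size=n_snps_per_gene)) + 1
        if truth.block_of[gene] == block:
            pvals = rng.beta(alpha_signal, 1.0, size=n_snps_per_gene)
        else:
            pvals = rng.uniform(0.0, 1.0, size=n_snps_per_gene)
        pvals = np.clip(pvals, 1e-300, 1.0)
        best = int(np.argmin(pvals))
        min_p_snp[gene] = (int(positions[best]), float(pvals[best]))
        for pos, p in zip(positions, pvals):
            rows.append((fp.chrom, int(pos), float(p)))
    gwas = GwasSummary(pd.DataFrame(rows, columns=["chrom", "pos", "pval"])
                       .sort_values(["chrom", "pos"], ignore_index=True))
    loci = []
    for i, seed_gene in enumerate(sorted(truth.causal_genes[trait_id])):
        if seed_gene not in min_p_snp:
            continue
        lead_pos, _ = min_p_snp[seed_gene]
        chrom = truth.genome_layout[seed_gene].chrom
        genes: dict[str, float] = {}
        for gene in truth.genes():
            fp = truth.genome_layout[gene]
            if fp.chrom != chrom:
                continue
            if fp.start - locus_window_bp <= lead_pos - 1 < fp.end + locus_window_bp:
                if gene == seed_gene:
                    genes[gene] = float(rng.uniform(0.5, 1.0))
                else:
                    genes[gene] = float(rng.uniform(0.0, decoy_l2g_high))
        loci.append(Locus(f"{trait_id}_L{i:03d}", [(chrom, lead_pos)], genes))
    return gwas, loci


def _check_layout(truth: SyntheticTruth) -> None:
    by_chrom: dict[str, list[GeneFootprint]] = {}
    for fp in truth.genome_layout.values():
        by_chrom.setdefault(fp.chrom, []).append(fp)
    for fps in by_chrom.values():
        fps = sorted(fps, key=lambda f: f.start)
        for a, b in zip(fps, fps[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping footprints: {a.gene_id} and {b.gene_id}")


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "block_of": truth.block_of,
        "trait_block": truth.trait_block,
        "causal_genes": {t: sorted(s) for t, s in truth.causal_genes.items()},
        "genome_layout": {
            g: {"chrom": fp.chrom, "start": fp.start, "end": fp.end}
            for g, fp in truth.genome_layout.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
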