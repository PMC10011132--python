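"""Candidate gene scoring at GWAS loci via leave-one-out propagation percentiles.

Each seed gene is left out of the input in turn and the remaining seeds are
propagated; a gene's score in a run is ranked against an ensemble of runs
seeded with equally many randomly drawn genes, giving a PageRank percentile
in [0, 100].  A seed's reported percentile comes from the single run that
excluded it; every other gene gets the median percentile across the
leave-one-out runs.  Loci whose lead variants fall within 200 kb are merged
(averaging per-gene locus-to-gene scores), seeds are compared to their locus
neighbours with a one-tailed Wilcoxon rank-sum test, candidates are filtered
by percentile/L2G thresholds with a no-strong-competitor rule, and low GWAS
p-values near high-percentile genes are quantified with binned one-sided
Fisher tests against the percentile < 50 reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph_core import Interactome
from .propagation import run_ppr_batch

logger = logging.getLogger(__name__)

DEFAULT_MERGE_WINDOW_BP = 200_000
DEFAULT_SNP_WINDOW_BP = 10_000
DEFAULT_N_NULL = 1000
DEFAULT_PCT_HI = 90.0
DEFAULT_PCT_COMPETITOR = 80.0
DEFAULT_L2G_MIN = 0.1
DEFAULT_REF_MAX_PCT = 50.0
DEFAULT_PCT_BINS = ((50.0, 70.0), (70.0, 80.0), (80.0, 90.0), (90.0, 95.0), (95.0, 100.0))
DEFAULT_P_THRESHOLD = 5e-8


@dataclass
class Locus:
    """A GWAS locus: lead variant position(s) and candidate genes with L2G."""

    locus_id: str
    lead_positions: list[tuple[str, int]]
    genes: dict[str, float]


@dataclass
class GeneFootprint:
    """Genomic interval of a gene, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid footprint for {self.gene_id}: [{self.start}, {self.end})")


@dataclass
class GwasSummary:
    """SNP-level summary statistics: (chrom, 1-based pos, p-value) records."""

    records: pd.DataFrame  # columns chrom, pos, pval

    def __post_init__(self) -> None:
        df = self.records
        if not {"chrom", "pos", "pval"}.issubset(df.columns):
            raise ValueError("GWAS summary needs columns chrom, pos, pval")
        if ((df.pval <= 0) | (df.pval > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if (df.pos < 0).any():
            raise ValueError("positions must be non-negative")


@dataclass
class PercentileResult:
    """Per-gene PageRank percentiles with leave-one-out provenance."""

    percentile: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)


def merge_loci(loci: Sequence[Locus], window_bp: int = DEFAULT_MERGE_WINDOW_BP) -> list[Locus]:
    """Single-linkage merge of loci whose lead variants lie within the window.

    Merged per-gene L2G is the mean across the contributing loci that report
    the gene; lead positions are pooled.
    """
    for loc in loci:
        for chrom, _ in loc.lead_positions:
            if not isinstance(chrom, str) or not chrom:
                raise ValueError(f"malformed chromosome label in locus {loc.locus_id}")
    n = len(loci)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            close = any(
                ca == cb and abs(pa - pb) <= window_bp
                for ca, pa in loci[i].lead_positions
                for cb, pb in loci[j].lead_positions
            )
            if close:
                parent[find(i)] = find(j)
    groups: dict[int, list[Locus]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(loci[i])
    out = []
    for members in groups.values():
        members = sorted(members, key=lambda l: l.locus_id)
        if len(members) == 1:
            out.append(members[0])
            continue
        l2g_lists: dict[str, list[float]] = {}
        leads: list[tuple[str, int]] = []
        for loc in members:
            leads.extend(loc.lead_positions)
            for g, v in loc.genes.items():
                l2g_lists.setdefault(g, []).append(v)
        out.append(Locus(
            locus_id="+".join(loc.locus_id for loc in members),
            lead_positions=sorted(set(leads)),
            genes={g: float(np.mean(v)) for g, v in l2g_lists.items()},
        ))
    return sorted(out, key=lambda l: l.locus_id)


def _percentiles_vs_null(scores: np.ndarray, null_scores: np.ndarray) -> np.ndarray:
    """Per-gene percentile of each run's score within that gene's null scores.

    ``scores``: (n_genes, n_runs); ``null_scores``: (n_genes, n_null).
    Ties against null values receive half credit.
    """
    n_null = null_scores.shape[1]
    out = np.empty_like(scores)
    for i in range(scores.shape[0]):
        null_sorted = np.sort(null_scores[i])
        lo = np.searchsorted(null_sorted, scores[i], side="left")
        hi = np.searchsorted(null_sorted, scores[i], side="right")
        out[i] = 100.0 * (lo + 0.5 * (hi - lo)) / n_null
    return out


def loo_network_percentiles(
    net: Interactome,
    seeds: set[str],
    n_null: int = DEFAULT_N_NULL,
    rng_seed: int = 0,
    damping: float = 0.85,
    weights: Mapping[str, float] | None = None,
) -> PercentileResult:
    """Leave-one-out PPR percentiles against a random-seed null ensemble.

    Runs one propagation per held-out seed (uniform weights on the remaining
    seeds by default, or the supplied L2G weights renormalized) plus ``n_null``
    propagations seeded by equally sized random gene sets drawn uniformly
    from the network.  Seed genes are scored from the single run excluding
    them; all other genes get the median percentile across the runs.
    """
    nodes = net.sorted_nodes()
    index = {g: i for i, g in enumerate(nodes)}
    in_net = sorted(seeds & set(nodes))
    dropped = seeds - set(in_net)
    if dropped:
        logger.warning("%d seed genes not in network dropped: %s",
                       len(dropped), sorted(dropped)[:10])
    if len(in_net) < 2:
        raise ValueError("need at least 2 seed genes mapped to the network")
    n_seeds = len(in_net)
    run_size = n_seeds - 1
    rng = np.random.default_rng(rng_seed)

    def restart(genes: Sequence[str]) -> np.ndarray:
        p = np.zeros(len(nodes))
        for g in genes:
            p[index[g]] = 1.0 if weights is None else float(weights[g])
        return p / p.sum()

    cols = [restart([g for g in in_net if g != held_out]) for held_out in in_net]
    null_sets = [rng.choice(len(nodes), size=run_size, replace=False)
                 for _ in range(n_null)]
    for idx in null_sets:
        p = np.zeros(len(nodes))
        p[idx] = 1.0
        cols.append(p / p.sum())
    all_scores = run_ppr_batch(net, np.column_stack(cols), damping=damping)
    loo = all_scores[:, :n_seeds]
    null = all_scores[:, n_seeds:]
    pct = _percentiles_vs_null(loo, null)
    percentile = np.median(pct, axis=1)
    provenance = {g: "median_across_runs" for g in nodes}
    for run_idx, held_out in enumerate(in_net):
        percentile[index[held_out]] = pct[index[held_out], run_idx]
        provenance[held_out] = "seed_loo"
    return PercentileResult(pd.Series(percentile, index=nodes), provenance)


def seed_vs_locus_test(
    pct: PercentileResult, loci: Sequence[Locus]
) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum: seed percentiles vs locus co-gene percentiles.

    Seeds are the genes with leave-one-out provenance; the comparison group is
    every other locus gene with a computed percentile.
    """
    seed_vals, other_vals = [], []
    seen: set[str] = set()
    for loc in loci:
        for g in loc.genes:
            if g in seen or g not in pct.percentile.index:
                continue
            seen.add(g)
            if pct.provenance.get(g) == "seed_loo":
                seed_vals.append(float(pct.percentile[g]))
            else:
                other_vals.append(float(pct.percentile[g]))
    if not seed_vals or not other_vals:
        raise ValueError("both seed and non-seed locus genes are required")
    res = stats.mannwhitneyu(seed_vals, other_vals, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def candidate_gene_filter(
    loci: Sequence[Locus],
    pct: PercentileResult,
    pct_hi: float = DEFAULT_PCT_HI,
    pct_competitor: float = DEFAULT_PCT_COMPETITOR,
    l2g_min: float = DEFAULT_L2G_MIN,
) -> list[tuple[str, str]]:
    """Loci where exactly one gene stands out by network percentile and L2G.

    A candidate must have percentile > ``pct_hi`` and L2G > ``l2g_min`` while
    no other gene at the locus has percentile > ``pct_competitor`` and
    L2G > ``l2g_min``.
    """
    out = []
    for loc in sorted(loci, key=lambda l: l.locus_id):
        def p_of(g: str) -> float:
            return float(pct.percentile.get(g, np.nan))

        for g, l2g in sorted(loc.genes.items()):
            if not (p_of(g) > pct_hi and l2g > l2g_min):
                continue
            competitor = any(
                other != g and loc.genes[other] > l2g_min
                and p_of(other) > pct_competitor
                for other in loc.genes
            )
            if not competitor:
                out.append((loc.locus_id, g))
    return out


def min_snp_pvalue_per_gene(
    footprints: Sequence[GeneFootprint],
    gwas: GwasSummary,
    window_bp: int = DEFAULT_SNP_WINDOW_BP,
) -> pd.Series:
    """Minimum SNP p-value within ``window_bp`` of each gene footprint.

    Footprints are 0-based half-open; GWAS positions are 1-based and are
    converted internally.  Genes with no SNP in the window are absent from
    the output (and logged).
    """
    df = gwas.records
    pos0 = df.pos.to_numpy() - 1
    pvals = df.pval.to_numpy()
    chroms = df.chrom.to_numpy()
    out: dict[str, float] = {}
    skipped = 0
    for fp in footprints:
        mask = (chroms == fp.chrom) & (pos0 >= fp.start - window_bp) & (pos0 < fp.end + window_bp)
        if not mask.any():
            skipped += 1
            continue
        out[fp.gene_id] = float(pvals[mask].min())
    if skipped:
        logger.info("%d genes had no SNP within %d bp and were excluded", skipped, window_bp)
    return pd.Series(out, dtype=float)


def snp_pvalue_enrichment(
    pct: PercentileResult,
    footprints: Sequence[GeneFootprint],
    gwas: GwasSummary,
    window_bp: int = DEFAULT_SNP_WINDOW_BP,
    pct_bins: Sequence[tuple[float, float]] = DEFAULT_PCT_BINS,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    ref_max_pct: float = DEFAULT_REF_MAX_PCT,
) -> pd.DataFrame:
    """Enrichment of low minimum-SNP-p genes in each network percentile bin.

    Per bin, a one-sided Fisher exact test compares the odds of carrying a
    minimum SNP p below ``p_threshold`` against the reference of genes with
    percentile < ``ref_max_pct``.  Zero-cell odds ratios are reported as the
    0 / ``inf`` sentinels; the confidence interval is a Woolf (log) interval
    computed with a 0.5 continuity correction.  Bins containing no gene are
    skipped.  The last bin is closed at 100.
    """
    minp = min_snp_pvalue_per_gene(footprints, gwas, window_bp)
    genes = [g for g in minp.index if g in pct.percentile.index]
    percs = pct.percentile.reindex(genes).to_numpy()
    low = (minp.reindex(genes) < p_threshold).to_numpy()
    ref_mask = percs < ref_max_pct
    c = int(low[ref_mask].sum())
    d = int((~low[ref_mask]).sum())
    rows = []
    top = max(hi for _, hi in pct_bins)
    for lo_edge, hi_edge in pct_bins:
        if hi_edge == top:
            mask = (percs >= lo_edge) & (percs <= hi_edge)
        else:
            mask = (percs >= lo_edge) & (percs < hi_edge)
        n_bin = int(mask.sum())
        if n_bin == 0:
            continue
        a = int(low[mask].sum())
        b = n_bin - a
        if b * c > 0:
            odds = (a * d) / (b * c)
        else:
            odds = 0.0 if a == 0 else math.inf
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        se = math.sqrt(sum(1.0 / (x + 0.5) for x in (a, b, c, d)))
        log_or = math.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
        rows.append({
            "bin_low": lo_edge, "bin_high": hi_edge, "n_genes": n_bin,
            "n_low_p": a, "odds_ratio": odds,
            "ci_low": math.exp(log_or - 1.96 * se),
            "ci_high": math.exp(log_or + 1.96 * se),
            "p": float(p),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: BED footprints, GWAS TSV, loci TSV, percentile TSV

def read_bed_footprints(path) -> list[GeneFootprint]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id"],
                     dtype={"chrom": str, "gene_id": str})
    return [GeneFootprint(r.gene_id, r.chrom, int(r.start), int(r.end))
            for r in df.itertuples()]


def write_bed_footprints(footprints: Sequence[GeneFootprint], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fp in sorted(footprints, key=lambda f: (f.chrom, f.start)):
            fh.write(f"{fp.chrom}\t{fp.start}\t{fp.end}\t{fp.gene_id}\n")


def read_gwas_tsv(path) -> GwasSummary:
    return GwasSummary(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_gwas_tsv(gwas: GwasSummary, path) -> None:
    gwas.records.to_csv(path, sep="\t", index=False)


def write_loci_tsv(loci: Sequence[Locus], path) -> None:
    rows = []
    for loc in sorted(loci, key=lambda l: l.locus_id):
        leads = ";".join(f"{c}:{p}" for c, p in loc.lead_positions)
        for g, v in sorted(loc.genes.items()):
            rows.append((loc.locus_id, leads, g, v))
    pd.DataFrame(rows, columns=["locus_id", "lead_positions", "gene_id", "l2g"]).to_csv(
        path, sep="\t", index=False
    )


def read_loci_tsv(path) -> list[Locus]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "gene_id": str})
    out = []
    for locus_id, grp in df.groupby("locus_id", sort=True):
        leads = []
        for token in str(grp.lead_positions.iloc[0]).split(";"):
            chrom, pos = token.rsplit(":", 1)
            leads.append((chrom, int(pos)))
        out.append(Locus(locus_id, leads, dict(zip(grp.gene_id, grp.l2g.astype(float)))))
    return out


def write_percentiles_tsv(pct: PercentileResult, path) -> None:
    pd.DataFrame({
        "gene_id": pct.percentile.index,
        "percentile": pct.percentile.to_numpy(),
        "provenance": [pct.provenance.get(g, "") for g in pct.percentile.index],
    }).to_csv(path, sep="\t", index=False)
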