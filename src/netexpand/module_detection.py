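"""Trait-linked gene module detection among high-propagation genes.

Genes scoring above the third quartile of the genome-wide PPR distribution
are clustered with the walktrap random-walk community algorithm (communities
larger than 300 genes re-clustered recursively), and each candidate module
with >= 10 genes and >= 2 seed genes is tested for association with the trait
by a one-sided two-sample KS test asking whether module genes have greater
PPR ranks than the background of all clustered genes, with BH correction
within the trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment_stats import bh_adjust
from .graph_core import Interactome
from .propagation import PropagationResult, SeedSet

logger = logging.getLogger(__name__)

DEFAULT_MAX_MODULE_SIZE = 300
DEFAULT_WALKTRAP_STEPS = 8
DEFAULT_MIN_GENES = 10
DEFAULT_MIN_SEEDS = 2
DEFAULT_ALPHA = 0.05
RECURSION_GUARD_ATTEMPTS = 3


@dataclass
class GeneModule:
    """A community of high-propagation genes for one trait."""

    module_id: str
    trait_id: str
    genes: set[str]
    seed_genes: set[str] = field(default_factory=set)
    ks_p: float | None = None
    adj_p: float | None = None


@dataclass
class ModuleTraitAssociation:
    """A significant module-trait link (adj_p < alpha after BH)."""

    trait_id: str
    module_id: str
    n_genes: int
    n_seeds: int
    ks_p: float
    adj_p: float
    genes: set[str] = field(default_factory=set)


def top_quartile_nodes(res: PropagationResult) -> set[str]:
    """Genes with PPR score strictly greater than Q3 over all network nodes.

    Q3 uses the linear-interpolation (type-7) quantile convention.  A constant
    score vector yields an empty set with a warning.
    """
    scores = res.score.to_numpy()
    q3 = float(np.quantile(scores, 0.75))
    mask = scores > q3
    if not mask.any():
        logger.warning("trait %s: no gene exceeds Q3 (constant scores?)", res.trait_id)
        return set()
    return set(np.asarray(res.score.index)[mask])


def _to_igraph(sub: Interactome) -> tuple[ig.Graph, list[str]]:
    nodes = sub.sorted_nodes()
    index = {g: i for i, g in enumerate(nodes)}
    edges = sorted((index[a], index[b]) if index[a] < index[b] else (index[b], index[a])
                   for a, b in sub.graph.edges)
    return ig.Graph(n=len(nodes), edges=edges), nodes


def walktrap_partition(
    sub: Interactome, steps: int = DEFAULT_WALKTRAP_STEPS
) -> dict[str, int]:
    """Walktrap communities on a subgraph, cut at maximum modularity.

    Isolated nodes become singleton communities.  Deterministic for a given
    node set (nodes are indexed in sorted order before clustering).
    """
    if sub.n_nodes == 0:
        raise ValueError("cannot cluster an empty subgraph")
    g, nodes = _to_igraph(sub)
    isolated = [i for i in range(g.vcount()) if g.degree(i) == 0]
    labels: dict[str, int] = {}
    if g.ecount() == 0:
        return {nodes[i]: i for i in range(len(nodes))}
    if isolated:
        keep = [i for i in range(g.vcount()) if g.degree(i) > 0]
        core = g.induced_subgraph(keep)
        membership = core.community_walktrap(steps=steps).as_clustering().membership
        for local, orig in enumerate(keep):
            labels[nodes[orig]] = membership[local]
        next_label = max(membership) + 1
        for orig in isolated:
            labels[nodes[orig]] = next_label
            next_label += 1
        return labels
    membership = g.community_walktrap(steps=steps).as_clustering().membership
    return {nodes[i]: membership[i] for i in range(len(nodes))}


def recursive_partition(
    sub: Interactome,
    max_size: int = DEFAULT_MAX_MODULE_SIZE,
    steps: int = DEFAULT_WALKTRAP_STEPS,
) -> list[set[str]]:
    """Walktrap partition with oversized communities re-clustered in place.

    Communities larger than ``max_size`` are re-clustered on their induced
    subgraph until all are small enough; a community that walktrap cannot
    split (e.g. a large clique) is accepted after a bounded number of
    attempts.  The output is a partition of the subgraph's nodes, returned in
    deterministic (sorted-min-gene) order.
    """
    out: list[set[str]] = []

    def split(genes: set[str], attempts: int) -> None:
        part = walktrap_partition(sub.subgraph(genes), steps=steps)
        groups: dict[int, set[str]] = {}
        for gene, lab in part.items():
            groups.setdefault(lab, set()).add(gene)
        if len(groups) == 1:
            if len(genes) <= max_size:
                out.append(genes)
            elif attempts + 1 >= RECURSION_GUARD_ATTEMPTS:
                logger.warning(
                    "community of %d genes could not be split below %d; accepted",
                    len(genes), max_size,
                )
                out.append(genes)
            else:
                split(genes, attempts + 1)
            return
        for comm in groups.values():
            if len(comm) <= max_size:
                out.append(comm)
            else:
                split(comm, 0)

    split(set(sub.sorted_nodes()), 0)
    return sorted(out, key=lambda s: min(s))


def ks_module_test(
    module_genes: set[str],
    background_ranks: Mapping[str, int],
    include_module_in_background: bool = False,
) -> float:
    """One-sided KS p-value that module PPR ranks exceed the background ranks.

    The background is the set of genes that entered the clustering; by
    default the module's own genes are excluded from the background sample,
    which preserves power when a module spans a large fraction of the
    clustered genes.  Larger rank = larger PPR score, so the alternative is
    that the module rank CDF lies below the background CDF.
    """
    if len(module_genes) < 2:
        raise ValueError("module must have at least 2 genes for the KS test")
    mod = np.asarray([background_ranks[g] for g in module_genes], dtype=float)
    if include_module_in_background:
        bg = np.asarray(list(background_ranks.values()), dtype=float)
    else:
        bg = np.asarray(
            [r for g, r in background_ranks.items() if g not in module_genes],
            dtype=float,
        )
    if len(bg) < 2:
        raise ValueError("background must have at least 2 genes")
    return float(stats.ks_2samp(mod, bg, alternative="less").pvalue)


def call_significant_modules(
    modules: Sequence[GeneModule],
    alpha: float = DEFAULT_ALPHA,
    min_genes: int = DEFAULT_MIN_GENES,
    min_seeds: int = DEFAULT_MIN_SEEDS,
) -> list[ModuleTraitAssociation]:
    """Filter to eligible modules, BH-adjust per trait, keep adj_p < alpha."""
    eligible = [
        m for m in modules
        if len(m.genes) >= min_genes and len(m.seed_genes) >= min_seeds
    ]
    out: list[ModuleTraitAssociation] = []
    by_trait: dict[str, list[GeneModule]] = {}
    for m in eligible:
        if m.ks_p is None:
            raise ValueError(f"module {m.module_id} has no KS p-value")
        by_trait.setdefault(m.trait_id, []).append(m)
    for trait_id in sorted(by_trait):
        fam = by_trait[trait_id]
        adj = bh_adjust([m.ks_p for m in fam])
        for m, ap in zip(fam, adj):
            m.adj_p = float(ap)
            if ap < alpha:
                out.append(ModuleTraitAssociation(
                    trait_id=m.trait_id, module_id=m.module_id,
                    n_genes=len(m.genes), n_seeds=len(m.seed_genes),
                    ks_p=m.ks_p, adj_p=float(ap), genes=set(m.genes),
                ))
    return out


def detect_trait_modules(
    net: Interactome,
    res: PropagationResult,
    seeds: SeedSet,
    max_size: int = DEFAULT_MAX_MODULE_SIZE,
    steps: int = DEFAULT_WALKTRAP_STEPS,
    alpha: float = DEFAULT_ALPHA,
    min_genes: int = DEFAULT_MIN_GENES,
    min_seeds: int = DEFAULT_MIN_SEEDS,
) -> tuple[list[GeneModule], list[ModuleTraitAssociation]]:
    """Full per-trait module workflow: Q3 cut, walktrap, KS, BH, filtering."""
    top = top_quartile_nodes(res)
    if not top:
        return [], []
    sub = net.subgraph(top)
    communities = recursive_partition(sub, max_size=max_size, steps=steps)
    bg_ranks = {g: int(res.rank[g]) for g in top}
    seed_genes = seeds.genes()
    modules: list[GeneModule] = []
    for i, comm in enumerate(communities):
        m = GeneModule(
            module_id=f"{res.trait_id}.m{i}",
            trait_id=res.trait_id,
            genes=comm,
            seed_genes=comm & seed_genes,
        )
        if len(comm) >= min(2, min_genes):
            m.ks_p = ks_module_test(comm, bg_ranks)
        modules.append(m)
    assocs = call_significant_modules(
        [m for m in modules if m.ks_p is not None],
        alpha=alpha, min_genes=min_genes, min_seeds=min_seeds,
    )
    return modules, assocs


# ---------------------------------------------------------------------------
# TSV I/O

def write_modules_tsv(modules: Sequence[GeneModule], path) -> None:
    rows = [
        (m.trait_id, m.module_id, g, int(g in m.seed_genes))
        for m in modules for g in sorted(m.genes)
    ]
    pd.DataFrame(rows, columns=["trait_id", "module_id", "gene_id", "is_seed"]).to_csv(
        path, sep="\t", index=False
    )


def write_associations_tsv(assocs: Sequence[ModuleTraitAssociation], path) -> None:
    rows = [
        (a.trait_id, a.module_id, a.n_genes, a.n_seeds, a.ks_p, a.adj_p,
         ";".join(sorted(a.genes)))
        for a in assocs
    ]
    pd.DataFrame(
        rows,
        columns=["trait_id", "module_id", "n_genes", "n_seeds", "ks_p", "adj_p", "genes"],
    ).to_csv(path, sep="\t", index=False)


def read_associations_tsv(path) -> list[ModuleTraitAssociation]:
    df = pd.read_csv(path, sep="\t", dtype={"trait_id": str, "module_id": str})
    return [
        ModuleTraitAssociation(
            trait_id=r.trait_id, module_id=r.module_id, n_genes=int(r.n_genes),
            n_seeds=int(r.n_seeds), ks_p=float(r.ks_p), adj_p=float(r.adj_p),
            genes=set(str(r.genes).split(";")) if r.genes else set(),
        )
        for r in df.itertuples()
    ]
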