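"""Cross-trait analysis: pleiotropy map, trait similarity trees, sub-group tests.

Significant modules from different traits are collapsed into equivalence
classes wherever their gene overlap reaches a Jaccard index of 0.70
(connected components of the overlap relation); classes linked to two or more
traits are the pleiotropic modules.  Trait-trait similarity is the Manhattan
distance between genome-wide PPR rank-score vectors, cut into clusters and
sub-groups by hierarchical clustering, and module specificity to a sub-group
is scored with one-sided Fisher tests under BH control.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .enrichment_stats import bh_adjust
from .module_detection import ModuleTraitAssociation
from .propagation import PropagationResult

logger = logging.getLogger(__name__)

DEFAULT_JACCARD_THRESHOLD = 0.70
DEFAULT_LINKAGE = "complete"
DEFAULT_MIN_TRAITS = 3


@dataclass
class CollapsedModule:
    """An equivalence class of highly overlapping modules across traits."""

    collapsed_id: str
    member_modules: list[tuple[str, str]]
    genes: set[str]
    traits: set[str]

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def jaccard_index(a: set, b: set) -> float:
    """|a & b| / |a | b|; both sets empty is an error."""
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def collapse_modules(
    assocs: Sequence[ModuleTraitAssociation],
    threshold: float = DEFAULT_JACCARD_THRESHOLD,
    gene_mode: str = "union",
) -> list[CollapsedModule]:
    """Collapse module-trait associations into cross-trait equivalence classes.

    Builds the module overlap graph (edge wherever pairwise Jaccard >=
    threshold) and takes connected components, i.e. single linkage over the
    overlap relation.  The collapsed gene set is the union of the members
    (``gene_mode="intersection"`` switches to the shared core).  Output order
    and identifiers are deterministic (sorted by member module ids).
    """
    if gene_mode not in ("union", "intersection"):
        raise ValueError(f"unknown gene_mode {gene_mode!r}")
    keys = [(a.trait_id, a.module_id) for a in assocs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (trait_id, module_id) pairs in associations")
    g = nx.Graph()
    g.add_nodes_from(keys)
    for i in range(len(assocs)):
        for j in range(i + 1, len(assocs)):
            if jaccard_index(assocs[i].genes, assocs[j].genes) >= threshold:
                g.add_edge(keys[i], keys[j])
    by_key = {k: a for k, a in zip(keys, assocs)}
    components = sorted((sorted(c) for c in nx.connected_components(g)),
                        key=lambda c: c[0])
    out = []
    for idx, comp in enumerate(components):
        gene_sets = [by_key[k].genes for k in comp]
        genes = set.union(*gene_sets) if gene_mode == "union" else set.intersection(*gene_sets)
        out.append(CollapsedModule(
            collapsed_id=f"CM{idx:04d}",
            member_modules=list(comp),
            genes=genes,
            traits={t for t, _ in comp},
        ))
    return out


def pleiotropic(collapsed: Sequence[CollapsedModule]) -> list[CollapsedModule]:
    """Collapsed modules linked to two or more traits."""
    return [c for c in collapsed if c.n_traits >= 2]


def trait_distance_matrix(
    results: Sequence[PropagationResult], use: str = "rank_score"
) -> pd.DataFrame:
    """Pairwise Manhattan distance between traits' propagation vectors.

    ``use`` selects the vector: ``rank_score`` (rank / n, the default, robust
    to score scale) or ``score`` (raw PPR probabilities).
    """
    if use not in ("rank_score", "score"):
        raise ValueError(f"unknown vector choice {use!r}")
    if not results:
        raise ValueError("no propagation results")
    node_sets = {frozenset(r.score.index) for r in results}
    if len(node_sets) != 1:
        raise ValueError("all results must cover the same node set")
    nodes = results[0].score.index.sort_values()
    mat = np.vstack([
        (r.rank_score if use == "rank_score" else r.score).reindex(nodes).to_numpy()
        for r in results
    ])
    traits = [r.trait_id for r in results]
    d = np.abs(mat[:, None, :] - mat[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=traits, columns=traits)


def cut_tree_clusters(
    matrix: pd.DataFrame,
    linkage_method: str = DEFAULT_LINKAGE,
    height: float = 1.0,
    normalize: str | None = None,
) -> dict[str, int]:
    """Agglomerative clustering of traits cut at a height threshold.

    ``normalize="max"`` rescales the distance matrix to [0, 1] by its maximum
    before cutting, so height thresholds are comparable across datasets of
    different scale; ``None`` cuts the raw Manhattan distances.
    """
    if height < 0:
        raise ValueError("height must be non-negative")
    d = matrix.to_numpy(dtype=float).copy()
    if normalize == "max":
        peak = d.max()
        if peak > 0:
            d = d / peak
    elif normalize is not None:
        raise ValueError(f"unknown normalization {normalize!r}")
    if len(matrix) == 1:
        return {matrix.index[0]: 1}
    z = linkage(squareform(d, checks=False), method=linkage_method)
    labels = fcluster(z, t=height, criterion="distance")
    return {t: int(c) for t, c in zip(matrix.index, labels)}


def subgroup_module_enrichment(
    collapsed: Sequence[CollapsedModule],
    clusters: Mapping[str, int],
    min_traits: int = DEFAULT_MIN_TRAITS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of each collapsed module in each sub-group.

    For every (module, sub-group) pair the 2x2 table is membership of each
    trait in the sub-group crossed with linkage of the trait to the module,
    over all clustered traits.  Sub-groups with fewer than ``min_traits``
    traits are skipped; BH is applied across all tested pairs.
    """
    all_traits = sorted(clusters)
    n = len(all_traits)
    sizes: dict[int, int] = {}
    for t in all_traits:
        sizes[clusters[t]] = sizes.get(clusters[t], 0) + 1
    rows = []
    for cm in sorted(collapsed, key=lambda c: c.collapsed_id):
        linked = {t for t in cm.traits if t in clusters}
        for cluster_id in sorted(sizes):
            if sizes[cluster_id] < min_traits:
                continue
            in_cluster = {t for t in all_traits if clusters[t] == cluster_id}
            a = len(linked & in_cluster)
            b = len(in_cluster) - a
            c = len(linked) - a
            d = n - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append((cm.collapsed_id, cluster_id, a, len(in_cluster), odds, p))
    df = pd.DataFrame(
        rows, columns=["collapsed_id", "cluster", "n_linked_in_cluster",
                       "cluster_size", "odds_ratio", "p"],
    )
    if len(df):
        df["adj_p"] = bh_adjust(df["p"])
        df["significant"] = df["adj_p"] < alpha
    return df


# ---------------------------------------------------------------------------
# I/O

def write_pleiotropy_json(collapsed: Sequence[CollapsedModule], path) -> None:
    payload = {
        c.collapsed_id: {
            "genes": sorted(c.genes),
            "traits": sorted(c.traits),
            "members": [list(m) for m in c.member_modules],
            "n_traits": c.n_traits,
        }
        for c in collapsed
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_clusters_tsv(
    clusters_h1: Mapping[str, int], clusters_h07: Mapping[str, int], path
) -> None:
    traits = sorted(set(clusters_h1) | set(clusters_h07))
    pd.DataFrame({
        "trait_id": traits,
        "cluster_at_h1": [clusters_h1.get(t, "") for t in traits],
        "subgroup_at_h07": [clusters_h07.get(t, "") for t in traits],
    }).to_csv(path, sep="\t", index=False)
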