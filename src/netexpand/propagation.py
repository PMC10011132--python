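"""Personalized PageRank diffusion of weighted seed genes.

GWAS-linked genes (locus-to-gene score >= 0.5) act as restart targets of a
random walk with restart on the interactome: the stationary distribution

    s = (1 - alpha) * p + alpha * W @ s

with ``W`` the column-normalized adjacency and ``p`` the seed weights
normalized to a probability vector, scores every gene by network proximity to
the seeds.  Mass arriving at degree-zero nodes is redistributed according to
``p`` so the scores always sum to one.  Scores are then rank-transformed
(rank 1 = lowest score, lexicographic gene-id tie-break) into the rank score
``rank / n_nodes`` used by all downstream module and trait-similarity stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph_core import Interactome

logger = logging.getLogger(__name__)

DEFAULT_DAMPING = 0.85
DEFAULT_TOL = 1e-12


@dataclass
class SeedSet:
    """Per-trait seed genes with locus-to-gene weights in [0.5, 1.0]."""

    trait_id: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"trait {self.trait_id!r}: empty seed set")
        for g, w in self.weights.items():
            if not 0.5 <= w <= 1.0:
                raise ValueError(
                    f"trait {self.trait_id!r}: seed {g!r} weight {w} outside [0.5, 1.0]"
                )

    def genes(self) -> set[str]:
        return set(self.weights)


@dataclass
class PropagationResult:
    """Genome-wide PPR scores and their rank transforms for one trait."""

    trait_id: str
    score: pd.Series
    rank: pd.Series | None = None
    rank_score: pd.Series | None = None
    seed_genes: set[str] = field(default_factory=set)


def _column_stochastic(net: Interactome) -> tuple[sp.csr_matrix, list[str]]:
    """Column-normalized adjacency in the deterministic sorted node order."""
    nodes = net.sorted_nodes()
    a = nx_adjacency(net, nodes)
    deg = np.asarray(a.sum(axis=0)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return (a @ sp.diags(inv)).tocsr(), nodes


def nx_adjacency(net: Interactome, nodes: Sequence[str]) -> sp.csr_matrix:
    import networkx as nx

    return nx.to_scipy_sparse_array(net.graph, nodelist=nodes, format="csr", dtype=float)


def _ppr_batch(
    w: sp.csr_matrix,
    p: np.ndarray,
    damping: float,
    tol: float,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Power iteration for one or many restart vectors (columns of ``p``).

    Dangling-node mass is redistributed to the restart vector of the same
    column, which keeps each column summing to exactly one.
    """
    dangling = np.asarray(w.sum(axis=0)).ravel() == 0
    s = p.copy()
    for _ in range(max_iter):
        lost = s[dangling].sum(axis=0)
        s_new = (1.0 - damping) * p + damping * (w @ s + p * lost)
        delta = np.abs(s_new - s).sum(axis=0).max()
        s = s_new
        if delta < tol:
            return s
    logger.warning("PPR did not reach tol=%g in %d iterations", tol, max_iter)
    return s


def seed_restart_vector(
    net_nodes: Sequence[str], seeds: SeedSet, node_index: Mapping[str, int]
) -> np.ndarray:
    """Seed weights as a probability vector over the network nodes."""
    p = np.zeros(len(net_nodes))
    dropped = []
    for g, wgt in seeds.weights.items():
        i = node_index.get(g)
        if i is None:
            dropped.append(g)
        else:
            p[i] = wgt
    if dropped:
        logger.warning(
            "trait %s: %d seed genes not in network dropped: %s",
            seeds.trait_id, len(dropped), sorted(dropped)[:10],
        )
    total = p.sum()
    if total == 0:
        raise ValueError(f"trait {seeds.trait_id!r}: no mapped seeds")
    return p / total


def run_ppr(
    net: Interactome,
    seeds: SeedSet,
    damping: float = DEFAULT_DAMPING,
    tol: float = DEFAULT_TOL,
) -> PropagationResult:
    """Diffuse one trait's weighted seeds; returns ranked genome-wide scores."""
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping {damping} outside (0, 1)")
    w, nodes = _column_stochastic(net)
    index = {g: i for i, g in enumerate(nodes)}
    p = seed_restart_vector(nodes, seeds, index)
    s = _ppr_batch(w, p[:, None], damping, tol)[:, 0]
    res = PropagationResult(
        trait_id=seeds.trait_id,
        score=pd.Series(s, index=nodes),
        seed_genes=seeds.genes() & set(nodes),
    )
    return rank_percentile_transform(res)


def run_ppr_batch(
    net: Interactome,
    restart_columns: np.ndarray,
    damping: float = DEFAULT_DAMPING,
    tol: float = DEFAULT_TOL,
) -> np.ndarray:
    """Raw PPR scores for many restart vectors at once (columns in, columns out).

    Node order is ``net.sorted_nodes()``; each column must already be a
    probability vector.  Used for leave-one-out and random-seed null ensembles
    where thousands of propagations are needed.
    """
    w, _ = _column_stochastic(net)
    return _ppr_batch(w, np.asarray(restart_columns, dtype=float), damping, tol)


def rank_percentile_transform(res: PropagationResult) -> PropagationResult:
    """Fill ascending ranks (1 = lowest score) and rank_score = rank / n.

    Ties are broken lexicographically by gene id so results are identical
    across runs and platforms.
    """
    nodes = np.asarray(res.score.index)
    scores = res.score.to_numpy()
    order = np.lexsort((nodes, scores))
    ranks = np.empty(len(nodes), dtype=int)
    ranks[order] = np.arange(1, len(nodes) + 1)
    res.rank = pd.Series(ranks, index=res.score.index)
    res.rank_score = res.rank / len(nodes)
    return res


# ---------------------------------------------------------------------------
# TSV I/O

def read_seeds_tsv(path) -> list[SeedSet]:
    """Read per-trait seeds from a TSV with columns trait_id, gene_id, l2g."""
    df = pd.read_csv(path, sep="\t", dtype={"trait_id": str, "gene_id": str})
    out = []
    for trait_id, grp in df.groupby("trait_id", sort=True):
        out.append(SeedSet(trait_id, dict(zip(grp.gene_id, grp.l2g.astype(float)))))
    return out


def write_seeds_tsv(seed_sets: Sequence[SeedSet], path) -> None:
    rows = [
        (s.trait_id, g, w)
        for s in seed_sets
        for g, w in sorted(s.weights.items())
    ]
    pd.DataFrame(rows, columns=["trait_id", "gene_id", "l2g"]).to_csv(
        path, sep="\t", index=False
    )


def write_results_tsv(results: Sequence[PropagationResult], path) -> None:
    frames = []
    for r in results:
        frames.append(pd.DataFrame({
            "trait_id": r.trait_id,
            "gene_id": r.score.index,
            "score": r.score.to_numpy(),
            "rank": r.rank.to_numpy(),
            "rank_score": r.rank_score.to_numpy(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_results_tsv(path) -> list[PropagationResult]:
    df = pd.read_csv(path, sep="\t", dtype={"trait_id": str, "gene_id": str})
    out = []
    for trait_id, grp in df.groupby("trait_id", sort=True):
        grp = grp.set_index("gene_id")
        out.append(PropagationResult(
            trait_id=trait_id,
            score=grp["score"],
            rank=grp["rank"].astype(int),
            rank_score=grp["rank_score"],
        ))
    return out
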