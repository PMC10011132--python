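"""Interactome construction, validation, serialization and degree-preserving nulls.

The interactome is an undirected simple graph over opaque gene identifiers.
Edges carry the set of evidence sources that reported them and, where a source
provides one, a confidence in [0, 1].  Confidence filtering is applied
per source (functional-association databases are score-thresholded; physical
interaction sources typically are not), after which edges from all sources are
collapsed into a single simple graph with no self-loops or duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default per-source confidence thresholds: only functional-association
#: edges are score-filtered; physical-interaction sources pass unfiltered.
DEFAULT_MIN_CONFIDENCE = {"string": 0.75}


@dataclass
class EdgeRecord:
    """One raw edge as read from an evidence source."""

    gene_a: str
    gene_b: str
    source: str
    confidence: float | None = None


@dataclass
class Interactome:
    """Undirected simple graph over gene identifiers with edge provenance.

    Wraps a :class:`networkx.Graph`; each edge stores ``sources`` (a sorted
    tuple of evidence tags) and ``confidence`` (max confidence seen across
    sources, or ``None``).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)

    def sorted_nodes(self) -> list[str]:
        """Deterministic node order used by every numeric routine."""
        return sorted(self.graph.nodes)

    def validate(self) -> None:
        """Assert the simple-graph invariants; raise ``ValueError`` on breach."""
        for a, b in self.graph.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
        degsum = sum(d for _, d in self.graph.degree())
        if degsum != 2 * self.n_edges:
            raise ValueError("degree sum does not equal twice the edge count")

    def subgraph(self, genes: Iterable[str]) -> "Interactome":
        return Interactome(nx.Graph(self.graph.subgraph(genes)))

    def to_records(self) -> list[EdgeRecord]:
        """Re-express the graph as one record per (edge, source) pair."""
        out = []
        for a, b, meta in self.graph.edges(data=True):
            x, y = sorted((a, b))
            for src in meta.get("sources", ("unknown",)):
                out.append(EdgeRecord(x, y, src, meta.get("confidence")))
        return out


def build_interactome(
    edge_records: Iterable[EdgeRecord | tuple],
    min_confidence_by_source: Mapping[str, float] | None = None,
) -> Interactome:
    """Assemble a simple interactome from raw per-source edge records.

    Records whose source has a configured threshold and whose confidence falls
    below it are dropped; duplicate edges across sources are collapsed keeping
    every source tag; self-loops are removed.  Records with a missing gene
    identifier are rejected with a logged warning.  A confidence outside
    [0, 1] is an error.
    """
    if min_confidence_by_source is None:
        min_confidence_by_source = DEFAULT_MIN_CONFIDENCE
    g = nx.Graph()
    for rec in edge_records:
        if not isinstance(rec, EdgeRecord):
            rec = EdgeRecord(*rec)
        a, b = rec.gene_a, rec.gene_b
        if not a or not b or pd.isna(a) or pd.isna(b):
            logger.warning("edge record with missing gene id rejected: %r", rec)
            continue
        conf = rec.confidence
        if conf is not None and not pd.isna(conf):
            conf = float(conf)
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"confidence {conf} outside [0, 1] for edge {a}-{b}")
        else:
            conf = None
        thr = min_confidence_by_source.get(rec.source)
        if thr is not None and (conf is None or conf < thr):
            continue
        if a == b:
            continue
        if g.has_edge(a, b):
            meta = g[a][b]
            meta["sources"] = tuple(sorted(set(meta["sources"]) | {rec.source}))
            prev = meta.get("confidence")
            if conf is not None:
                meta["confidence"] = conf if prev is None else max(prev, conf)
        else:
            g.add_edge(a, b, sources=(rec.source,), confidence=conf)
    net = Interactome(g)
    net.validate()
    return net


def degree_preserving_randomization(
    net: Interactome,
    rng_seed: int,
    method: str = "permute",
    n_swaps_per_edge: int = 10,
) -> Interactome:
    """Randomize node placement while preserving every node's degree exactly.

    ``method="permute"`` (default) keeps the edge structure identical and
    permutes node labels only within classes of equal degree, so the degree of
    every gene is unchanged and the topology is untouched.
    ``method="swap"`` instead rewires by double-edge swaps
    (``n_swaps_per_edge * |E|`` attempted swaps), preserving the degree
    sequence but not the topology.
    """
    rng = np.random.default_rng(rng_seed)
    if method == "swap":
        g = nx.Graph(net.graph)
        nswap = n_swaps_per_edge * g.number_of_edges()
        if g.number_of_edges() >= 2:
            nx.double_edge_swap(
                g, nswap=nswap, max_tries=100 * nswap + 100,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        return Interactome(g)
    if method != "permute":
        raise ValueError(f"unknown randomization method {method!r}")
    degrees: dict[int, list[str]] = {}
    for node in net.sorted_nodes():
        degrees.setdefault(net.graph.degree(node), []).append(node)
    mapping: dict[str, str] = {}
    for _, members in sorted(degrees.items()):
        perm = rng.permutation(len(members))
        for i, node in enumerate(members):
            mapping[node] = members[perm[i]]
    return Interactome(nx.relabel_nodes(net.graph, mapping, copy=True))


# ---------------------------------------------------------------------------
# Edge TSV I/O: columns gene_a, gene_b, source, confidence (empty allowed)

def read_edge_tsv(path, min_confidence_by_source=None) -> Interactome:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "source": str})
    required = {"gene_a", "gene_b", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    if "confidence" not in df.columns:
        df["confidence"] = np.nan
    records = [
        EdgeRecord(r.gene_a, r.gene_b, r.source,
                   None if pd.isna(r.confidence) else float(r.confidence))
        for r in df.itertuples()
    ]
    return build_interactome(records, min_confidence_by_source)


def write_edge_tsv(net: Interactome, path) -> None:
    rows = [
        (r.gene_a, r.gene_b, r.source, "" if r.confidence is None else r.confidence)
        for r in sorted(net.to_records(), key=lambda r: (r.gene_a, r.gene_b, r.source))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "source", "confidence"]).to_csv(
        path, sep="\t", index=False
    )
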