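"""Set-enrichment statistics shared across the pipeline.

One-sided Fisher/hypergeometric enrichment with Benjamini-Hochberg control,
and a signed two-sided KS rank-enrichment statistic (signed -log10 p, the
sign given by the foreground-vs-background median difference).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCollection:
    """Named gene sets over a common annotation universe.

    Sets are trimmed to the universe on construction; anything removed is
    logged rather than raised, mirroring how annotation files routinely
    contain genes absent from the network.
    """

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        trimmed = {}
        for set_id, genes in self.sets.items():
            kept = set(genes) & self.universe
            if len(kept) < len(set(genes)):
                logger.warning(
                    "annotation set %s: %d genes outside universe trimmed",
                    set_id, len(set(genes)) - len(kept),
                )
            trimmed[set_id] = kept
        self.sets = trimmed


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, output in input order.

    adj_p[i] = min over j with p_(j) >= p_(i) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def hypergeom_test(overlap: int, query_size: int, set_size: int, universe_size: int) -> float:
    """One-sided (enrichment) hypergeometric tail P(X >= overlap)."""
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def fisher_enrichment(
    query: set[str],
    collection: AnnotationCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of a query set against every annotation set.

    Returns a table (set_id, set_size, overlap, odds_ratio, p, adj_p) sorted
    by set_id; BH is applied across the whole collection.  Zero-cell odds
    ratios are reported as ``inf`` / 0 sentinels.
    """
    universe = collection.universe
    q = set(query) & universe
    if len(q) < len(set(query)):
        logger.warning("query: %d genes outside universe trimmed", len(set(query)) - len(q))
    if not q:
        raise ValueError("query empty after trimming to universe")
    n_u = len(universe)
    rows = []
    for set_id in sorted(collection.sets):
        genes = collection.sets[set_id]
        a = len(q & genes)
        b = len(q) - a
        c = len(genes) - a
        d = n_u - a - b - c
        p = hypergeom_test(a, len(q), len(genes), n_u)
        if b * c == 0:
            odds = math.inf if a * d > 0 else (0.0 if a == 0 else math.inf)
        else:
            odds = (a * d) / (b * c)
        rows.append((set_id, len(genes), a, odds, p))
    df = pd.DataFrame(rows, columns=["set_id", "set_size", "overlap", "odds_ratio", "p"])
    df["adj_p"] = bh_adjust(df["p"])
    df["significant"] = df["adj_p"] < alpha
    return df


def signed_rank_gsea(
    gene_values: Mapping[str, float], gene_set: set[str]
) -> tuple[float, float]:
    """Signed KS enrichment of a gene set within a genome-wide value vector.

    Two-sided two-sample KS of foreground (set members) values against the
    background (all other genes); returns ``(signed_logp, p)`` where
    signed_logp = -log10(p) signed by median(foreground) - median(background)
    (0 when the medians are equal).  BH across sets is the caller's job.
    """
    fg = np.asarray([v for g, v in gene_values.items() if g in gene_set], dtype=float)
    bg = np.asarray([v for g, v in gene_values.items() if g not in gene_set], dtype=float)
    if len(fg) < 2 or len(bg) < 2:
        raise ValueError("need at least 2 foreground and 2 background genes")
    if np.ptp(fg) == 0 and np.ptp(bg) == 0 and fg[0] == bg[0]:
        return 0.0, 1.0
    p = float(stats.ks_2samp(fg, bg, alternative="two-sided").pvalue)
    diff = float(np.median(fg) - np.median(bg))
    sign = 0.0 if diff == 0 else math.copysign(1.0, diff)
    logp = -math.log10(max(p, 1e-300))
    return sign * logp, p


# ---------------------------------------------------------------------------
# GMT I/O (one set per line: set_id <tab> description <tab> gene ...)

def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: Mapping[str, set[str]], path, descriptions=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(sets):
            desc = (descriptions or {}).get(set_id, "na")
            genes = "\t".join(sorted(sets[set_id]))
            fh.write(f"{set_id}\t{desc}\t{genes}\n")
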