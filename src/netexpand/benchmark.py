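"""Benchmarking propagation scores against gold-standard gene sets.

Gold standards (curated disease genes or phase>=II drug targets) are first
purged of the trait's own seed genes to avoid circularity; ROC AUC is then
computed over the remaining evaluable genes (positives vs all other evaluable
genes), and calibrated against two permutation nulls: redrawing the true
positives at random, and re-propagating on degree-preserving randomized
networks.  Trait-pair similarity is likewise scored as the AUC of negative
trait-trait distance for labeled related pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph_core import Interactome, degree_preserving_randomization
from .propagation import PropagationResult, SeedSet, run_ppr

logger = logging.getLogger(__name__)

MIN_POSITIVES = 10
DEFAULT_N_PERM = 1000


@dataclass
class GoldStandard:
    """Curated positives for one disease, optionally tiered by evidence."""

    disease_id: str
    positives: set[str]
    tier: str = "default"


def exclude_seed_overlap(gs: GoldStandard, seeds: SeedSet) -> GoldStandard:
    """Remove the trait's seed genes from the positives (anti-circularity)."""
    return GoldStandard(gs.disease_id, gs.positives - seeds.genes(), gs.tier)


def _auc_from_scores(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """Mann-Whitney AUC with half-credit ties: U / (n1 * n2)."""
    n_pos = int(is_positive.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positives and negatives")
    ranks = stats.rankdata(scores)
    u = ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_auc(
    res: PropagationResult,
    gs: GoldStandard,
    evaluable: set[str] | None = None,
    min_positives: int = MIN_POSITIVES,
) -> float | None:
    """AUC of the PPR score for gold-standard positives among evaluable genes.

    The evaluable universe defaults to all network genes minus the trait's
    seeds.  Returns ``None`` (with a logged reason) when fewer than
    ``min_positives`` positives remain evaluable.
    """
    if evaluable is None:
        evaluable = set(res.score.index) - res.seed_genes
    ev = sorted(evaluable & set(res.score.index))
    pos = gs.positives & set(ev)
    if len(pos) < min_positives:
        logger.info(
            "%s/%s skipped: %d evaluable positives < %d",
            res.trait_id, gs.disease_id, len(pos), min_positives,
        )
        return None
    scores = res.score.reindex(ev).to_numpy()
    is_pos = np.asarray([g in pos for g in ev])
    return _auc_from_scores(scores, is_pos)


def permutation_null_z(
    observed_auc: float,
    gs: GoldStandard,
    mode: str = "tp_permute",
    res: PropagationResult | None = None,
    net: Interactome | None = None,
    seeds: SeedSet | None = None,
    evaluable: set[str] | None = None,
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
) -> tuple[np.ndarray, float | None]:
    """Null AUC distribution and Z-score for an observed AUC.

    ``mode="tp_permute"`` redraws |positives| genes uniformly from the
    evaluable universe each repetition (requires ``res``).
    ``mode="net_randomize"`` re-propagates the same seeds on a fresh
    degree-preserving randomization of the network each repetition and
    re-scores the original positives (requires ``net`` and ``seeds``).
    Z uses the sample (n-1) standard deviation; a degenerate null returns
    ``(nulls, None)`` with a warning.
    """
    rng = np.random.default_rng(rng_seed)
    nulls = np.empty(n_perm)
    if mode == "tp_permute":
        if res is None:
            raise ValueError("tp_permute requires a PropagationResult")
        if evaluable is None:
            evaluable = set(res.score.index) - res.seed_genes
        ev = sorted(evaluable & set(res.score.index))
        scores = res.score.reindex(ev).to_numpy()
        ranks = stats.rankdata(scores)
        n_pos = len(gs.positives & set(ev))
        n_neg = len(ev) - n_pos
        if n_pos == 0 or n_neg == 0:
            raise ValueError("degenerate evaluable universe")
        for i in range(n_perm):
            idx = rng.choice(len(ev), size=n_pos, replace=False)
            u = ranks[idx].sum() - n_pos * (n_pos + 1) / 2
            nulls[i] = u / (n_pos * n_neg)
    elif mode == "net_randomize":
        if net is None or seeds is None:
            raise ValueError("net_randomize requires net and seeds")
        for i in range(n_perm):
            rnet = degree_preserving_randomization(
                net, rng_seed=int(rng.integers(0, 2**31 - 1))
            )
            rres = run_ppr(rnet, seeds)
            auc = roc_auc(rres, gs, evaluable=evaluable)
            nulls[i] = np.nan if auc is None else auc
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")
    valid = nulls[~np.isnan(nulls)]
    sd = valid.std(ddof=1) if len(valid) > 1 else 0.0
    if sd == 0:
        logger.warning("null AUC distribution degenerate; Z undefined")
        return nulls, None
    return nulls, float((observed_auc - valid.mean()) / sd)


def trait_pair_similarity_auc(
    distance_matrix: pd.DataFrame,
    labeled_pairs: Iterable[tuple[str, str]],
    universe: Iterable[tuple[str, str]] | None = None,
) -> float:
    """AUC of negative trait-trait distance as a classifier of related pairs."""
    labeled = {frozenset(p) for p in labeled_pairs}
    if len(labeled) < 2:
        raise ValueError("need at least 2 labeled pairs")
    if universe is None:
        universe = itertools.combinations(sorted(distance_matrix.index), 2)
    pairs = [frozenset(p) for p in universe]
    if not labeled <= set(pairs):
        raise ValueError("labeled pairs must be inside the pair universe")
    scores, is_pos = [], []
    for pair in pairs:
        a, b = sorted(pair)
        scores.append(-float(distance_matrix.loc[a, b]))
        is_pos.append(pair in labeled)
    return _auc_from_scores(np.asarray(scores), np.asarray(is_pos))


# ---------------------------------------------------------------------------
# Report I/O

def write_benchmark_tsv(rows: Sequence[dict], path) -> None:
    cols = ["trait_id", "disease_id", "tier", "n_pos", "auc", "z_tp", "z_net"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df[cols].to_csv(path, sep="\t", index=False)
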