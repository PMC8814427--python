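"""Preranked gene-set enrichment and hypergeometric over-representation.

The enrichment statistic is the classic weighted Kolmogorov-Smirnov-style
running sum: walking down a ranked gene list, membership in the query set
increments the sum by the gene's |score|**weight (normalized over the
set's total), non-membership decrements it by 1/(N - N_hits), and the
enrichment score (ES) is the extremal deviation of the running sum.
Significance comes from a gene-label permutation null (scores stay fixed
at their positions, set membership is drawn at random), with a same-sign
tail p-value (add-one corrected), NES = ES / mean |same-sign null ES|, and
Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes with real-valued scores in strictly decreasing score order.

    Ties in the score are broken lexicographically by gene id, so the
    ordering — and everything downstream of it — is reproducible.
    """

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores in ranked list")

    def __len__(self) -> int:
        return len(self.genes)


def rank_by_coefficient(records: pd.DataFrame) -> RankedList:
    """Rank genes decreasingly by their AS coefficient (``beta2``).

    Flagged records and missing coefficients are excluded before ranking;
    ties are broken by gene id.
    """
    ok = records[(records["flag"] == "") & records["beta2"].notna()]
    if ok.empty:
        raise ValueError("rank_by_coefficient: no usable records")
    if ok["beta2"].nunique() == 1:
        logger.warning("rank_by_coefficient: all coefficients equal; "
                       "order is lexicographic")
    ordered = ok.assign(_g=ok.index.astype(str)).sort_values(
        ["beta2", "_g"], ascending=[False, True])
    return RankedList(list(ordered.index),
                      ordered["beta2"].to_numpy(dtype=float))


def enrichment_score(ranked: RankedList, gene_set: set[str],
                     weight: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one gene set.

    Raises if the set misses the ranked list entirely or covers it (the
    miss decrement would be undefined).  A set whose total hit mass is
    zero (every member's score is 0 under a positive weight) raises
    ``ValueError`` — callers flag such sets non-evaluable.
    """
    n = len(ranked)
    hit = np.fromiter((g in gene_set for g in ranked.genes), bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("enrichment_score: set does not intersect ranking")
    if n_hit == n:
        raise ValueError("enrichment_score: set covers the whole ranking")
    hit_mass = np.abs(ranked.scores) ** weight * hit
    total = hit_mass.sum()
    if total == 0:
        raise ValueError("enrichment_score: zero total hit mass")
    steps = np.where(hit, hit_mass / total, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    return _extremum(running.max(), running.min()), running


def _extremum(max_dev: float, min_dev: float) -> float:
    """The signed extremal deviation; the larger magnitude wins, positive
    on exact ties."""
    return float(max_dev) if abs(max_dev) >= abs(min_dev) else float(min_dev)


def _null_es(scores: np.ndarray, set_size: int, nperm: int, weight: float,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized null ES for random same-size gene sets.

    Exploits that the running sum attains local maxima only immediately
    after hits and local minima only immediately before hits, so the
    extremum is computable from the (sorted) hit positions alone.
    """
    n = len(scores)
    w = np.abs(scores) ** weight
    miss_dec = 1.0 / (n - set_size)
    # random k-subsets of positions, one row per permutation
    pos = np.argsort(rng.random((nperm, n)), axis=1)[:, :set_size]
    pos.sort(axis=1)
    mass = w[pos]
    total = mass.sum(axis=1, keepdims=True)
    valid = total[:, 0] > 0
    total[~valid] = 1.0
    ch = np.cumsum(mass / total, axis=1)
    j = np.arange(1, set_size + 1)[None, :]
    r_after = ch - (pos + 1 - j) * miss_dec
    r_before = (ch - mass / total) - (pos - (j - 1)) * miss_dec
    max_dev = np.maximum(r_after.max(axis=1), 0.0)
    min_dev = np.minimum(r_before.min(axis=1), 0.0)
    es = np.where(np.abs(max_dev) >= np.abs(min_dev), max_dev, min_dev)
    es[~valid] = np.nan
    return es


@dataclass
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_perm: float
    q: float
    leading_edge: list[str]
    nperm: int
    seed: int
    flag: str = ""


def leading_edge(ranked: RankedList, gene_set: set[str],
                 running: np.ndarray, es: float) -> list[str]:
    """Set members at or before the running-sum peak (after the trough for
    a negative ES), in ranking order."""
    if es >= 0:
        peak = int(np.argmax(running))
        return [g for g in ranked.genes[:peak + 1] if g in gene_set]
    trough = int(np.argmin(running))
    return [g for g in ranked.genes[trough:] if g in gene_set]


def gsea_permutation(ranked: RankedList, sets: dict[str, list[str]],
                     nperm: int = 1000, seed: int = 0,
                     weight: float = 1.0, min_size: int = 5
                     ) -> pd.DataFrame:
    """Permutation GSEA over a collection of gene sets.

    Sets smaller than ``min_size`` after intersection with the ranking are
    skipped with a flag, as are sets with zero hit mass.  The same-sign
    null tail gives the p-value (add-one corrected, so p >= 1/(nperm+1));
    NES divides ES by the mean |null ES| of the same sign; BH runs across
    the evaluated sets.
    """
    if nperm < 100:
        raise ValueError("gsea_permutation: nperm must be >= 100")
    rng = np.random.default_rng(seed)
    in_ranking = set(ranked.genes)
    rows: list[EnrichmentResult] = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        eff = sorted(set(members) & in_ranking)
        k = len(eff)
        if k < min_size or k == len(ranked):
            rows.append(EnrichmentResult(name, k, np.nan, np.nan, np.nan,
                                         np.nan, [], nperm, seed,
                                         flag="size"))
            continue
        try:
            es, running = enrichment_score(ranked, set(eff), weight)
        except ValueError:
            rows.append(EnrichmentResult(name, k, np.nan, np.nan, np.nan,
                                         np.nan, [], nperm, seed,
                                         flag="zero_hit_mass"))
            continue
        if k not in null_cache:
            null_cache[k] = _null_es(ranked.scores, k, nperm, weight, rng)
        null = null_cache[k]
        null = null[np.isfinite(null)]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) \
            / (1.0 + len(same_sign))
        mean_null = np.abs(same_sign).mean() if len(same_sign) else np.nan
        nes = es / mean_null if mean_null and np.isfinite(mean_null) else np.nan
        rows.append(EnrichmentResult(
            name, k, es, nes, p, np.nan,
            leading_edge(ranked, set(eff), running, es), nperm, seed))
    out = pd.DataFrame([vars(r) for r in rows]).set_index("set_name")
    out["q"] = bh_adjust(out["p_perm"])
    return out


def ora_hypergeometric(hit_genes: set[str], universe: set[str],
                       sets: dict[str, list[str]]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``hit_genes`` in
    each set, with BH adjustment across sets.

    Hits and sets are intersected with the universe before testing.
    """
    if not universe:
        raise ValueError("ora_hypergeometric: empty universe")
    hits = set(hit_genes) & universe
    rows = []
    for name, members in sets.items():
        s = set(members) & universe
        overlap = len(hits & s)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(s),
                                     len(hits)))
        rows.append({"set_name": name, "set_size": len(s),
                     "n_hits": len(hits), "overlap": overlap, "p": p})
    out = pd.DataFrame(rows).set_index("set_name")
    out["q"] = bh_adjust(out["p"])
    return out
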