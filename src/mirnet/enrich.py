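"""Enrichment statistics: GSEA running-sum ES and right-sided hypergeometric test.

The GSEA statistic is the weighted Kolmogorov-Smirnov running sum over a
ranked gene list: stepping down the list, set members ("hits") increment the
sum by |metric|^p normalized over hits, non-members decrement it by
1/(N - K). The enrichment score (ES) is the signed maximum deviation of the
running sum from zero. Significance uses gene-set permutation: null scores
from random sets of the same size drawn from the ranked universe, with the
standard +1 correction so permutation p-values are never zero. The
normalized ES divides by the mean |null ES| of matching sign.

The GO test is the right-tailed hypergeometric probability P(X >= k) of
seeing k annotated genes in a query of size n from a universe of N with K
annotated, BH-corrected across terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    GOAnnotationTable,
    MirnetError,
    SampleDesign,
    TransformState,
)
from .diffexp import bh_adjust

#: additive floor applied to each group's standard deviation in the
#: signal-to-noise metric: sd -> max(sd, 0.2 * |mean|, 0.2)
SD_FLOOR_FRACTION = 0.2
SD_FLOOR_MIN = 0.2


@dataclass
class RankedList:
    """Gene ids ordered by a descending real-valued metric (ties by id)."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise MirnetError("ranked list ids must be unique")
        if not np.all(np.isfinite(self.metric)):
            raise MirnetError("ranking metric must be finite")
        if len(self.genes) != len(self.metric):
            raise MirnetError("genes and metric length mismatch")


def rank_by_metric(
    expr: ExpressionMatrix, stage: str, design: SampleDesign | None = None, metric: str = "s2n"
) -> RankedList:
    """Rank genes by MI-vs-sham signal-to-noise at one stage.

    s2n = (mean_MI - mean_sham) / (sd_MI + sd_sham), each sd floored at
    max(0.2 |group mean|, 0.2) so the denominator never vanishes. Ties are
    broken by gene id for determinism.
    """
    if metric != "s2n":
        raise MirnetError(f"unknown ranking metric {metric!r}")
    expr.require_state(TransformState.LOG2P1_QUANTILE)
    design = design or expr.design
    design.require_stage(stage)
    sham_cols = design.samples("sham", stage)
    mi_cols = design.samples("MI", stage)
    if len(sham_cols) < 2 or len(mi_cols) < 2:
        raise MirnetError("signal-to-noise needs >=2 samples per group")
    sham = expr.values[sham_cols].to_numpy(dtype=float)
    mi = expr.values[mi_cols].to_numpy(dtype=float)

    def floored_sd(x: np.ndarray) -> np.ndarray:
        sd = x.std(axis=1, ddof=1)
        mean = x.mean(axis=1)
        return np.maximum(sd, np.maximum(SD_FLOOR_FRACTION * np.abs(mean), SD_FLOOR_MIN))

    s2n = (mi.mean(axis=1) - sham.mean(axis=1)) / (floored_sd(mi) + floored_sd(sham))
    order = sorted(range(len(s2n)), key=lambda i: (-s2n[i], expr.values.index[i]))
    return RankedList(
        genes=[expr.values.index[i] for i in order], metric=np.asarray([s2n[i] for i in order])
    )


def enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score over the ranked list.

    Returns (ES, running_sum) where running_sum[i] is the value after
    position i. ES is the extreme of the running sum with the largest
    absolute value (ties broken toward the positive extreme). A set covering
    the whole universe is degenerate (the miss decrement is undefined) and
    returns ES = 1 on a monotone ramp.
    """
    members = set(gene_set.members if hasattr(gene_set, "members") else gene_set)
    n = len(ranked.genes)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise MirnetError("gene set has no overlap with the ranked universe")
    if n_hits == n:
        # degenerate: every gene is a hit, so the miss decrement 1/(N-K) is
        # undefined; the running sum climbs monotonically to 1
        warnings.warn("gene set covers the whole ranked universe; ES defined as 1")
        running = np.cumsum(np.abs(ranked.metric) ** weight)
        running = running / running[-1] if running[-1] > 0 else np.linspace(1 / n, 1.0, n)
        return 1.0, running
    w = np.abs(ranked.metric) ** weight
    hit_weight = np.where(hit, w, 0.0)
    total = hit_weight.sum()
    if total == 0:
        # all hit metrics are exactly zero (possible when weight > 0):
        # fall back to equal hit increments, the unweighted statistic
        hit_weight = hit.astype(float)
        total = hit_weight.sum()
    miss = (~hit).astype(float) / (n - n_hits)
    running = np.cumsum(hit_weight) / total - np.cumsum(miss)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    return float(es), running


def _es_from_hit_positions(w: np.ndarray, positions: np.ndarray, n: int) -> float:
    """ES from sorted hit positions without materializing the running sum.

    Exactly equivalent to :func:`enrichment_score` (the running sum is
    piecewise linear between hits, so its extremes occur just before or just
    after a hit, or at the trailing zero).
    """
    s = len(positions)
    if s == n:
        return 1.0
    hw = w[positions]
    total = hw.sum()
    if total == 0:
        hw = np.ones(s)
        total = float(s)
    miss = 1.0 / (n - s)
    cum = np.cumsum(hw) / total
    j = np.arange(s)
    after = cum - (positions - j) * miss
    before = np.concatenate(([0.0], cum[:-1])) - (positions - j) * miss
    max_cand = max(float(after.max()), 0.0)
    min_cand = min(float(before.min()), 0.0)
    return max_cand if max_cand >= -min_cand else min_cand


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_perm: float
    q: float


def permutation_significance(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Gene-set-permutation significance for every set in the collection.

    Null scores come from ``n_perm`` random same-size sets drawn from the
    ranked universe; p_perm = (1 + #{|ES_null| >= |ES|}) / (1 + n_perm);
    NES = ES / mean(|ES_null| of matching sign); q = BH across the
    collection. Fixed seed => identical output.
    """
    if n_perm < 1:
        raise MirnetError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = np.asarray(ranked.genes)
    universe_set = set(ranked.genes)
    n = len(universe)
    w = np.abs(ranked.metric) ** weight
    rows = []
    for gene_set in collection:
        overlap = [g for g in gene_set.members if g in universe_set]
        size = len(overlap)
        if size == 0:
            raise MirnetError(f"gene set {gene_set.name!r} has no overlap with the universe")
        es, _ = enrichment_score(ranked, frozenset(overlap), weight)
        null = np.empty(n_perm)
        for i in range(n_perm):
            positions = np.sort(rng.choice(n, size=size, replace=False))
            null[i] = _es_from_hit_positions(w, positions, n)
        p = (1 + int(np.sum(np.abs(null) >= abs(es)))) / (1 + n_perm)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.mean(np.abs(same_sign)) if same_sign.size else np.mean(np.abs(null))
        nes = es / denom if denom > 0 else 0.0
        rows.append(
            {"set": gene_set.name, "size": size, "es": es, "nes": nes, "p_perm": p}
        )
    df = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p_perm"])
    df["q"] = bh_adjust(df["p_perm"].to_numpy()) if len(df) else []
    return df


def hypergeometric_enrich(
    query: set[str] | list[str],
    annotation: GOAnnotationTable,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Right-sided hypergeometric enrichment of GO terms, BH-corrected.

    For each term with >= 1 annotated gene in the universe:
    p = P(X >= k) with X ~ Hypergeometric(N=|universe|, K=|term in universe|,
    n=|query|), k = |query in term|.
    """
    universe = set(universe)
    query = set(query)
    stray = query - universe
    if stray:
        raise MirnetError(f"query genes absent from universe: {sorted(stray)[:10]}")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for term in annotation.terms():
        term_genes = annotation.genes_for(term) & universe
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append(
            {"term": term, "N": n_universe, "K": big_k, "n": n_query, "k": k, "p_raw": p}
        )
    df = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p_raw"])
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy()) if len(df) else []
    return df
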