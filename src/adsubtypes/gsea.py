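"""Gene set enrichment analysis with phenotype permutation.

The ranked list orders all genes by a signed rank metric comparing two sample
groups (default: signal-to-noise, (mean_a - mean_b)/(sd_a + sd_b) with each
sd floored; alternatively a signed t statistic). The enrichment score is the
signed extremum of the weighted Kolmogorov-Smirnov running sum: walking the
list, gene-set hits increment by |metric|^p normalized over hits, misses
decrement by 1/(N - N_hits). Significance comes from phenotype-label
permutations (exhaustive enumeration when the label splits are few), NES is
ES normalized by the mean |permuted ES| of the same sign, and the FDR q value
is the standard NES-ratio estimate across the evaluated collection.

The leading edge ("core enrichment") holds the set members at or before the
running-sum extremum (for positive ES), and hub genes are the top-k
leading-edge genes by |rank metric|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from adsubtypes.errors import ConfigError


@dataclass
class RankedList:
    """All genes ordered by a signed rank metric, descending."""

    genes: list[str]
    scores: np.ndarray
    metric: str
    groups: tuple[str, str] = ("A", "B")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str]
    running_sum: np.ndarray
    es_permuted: np.ndarray = field(default_factory=lambda: np.array([]))
    exhaustive: bool = False


def rank_metric(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    metric: str = "signal_to_noise",
) -> RankedList:
    """Rank every gene by a signed two-group statistic, descending.

    ``signal_to_noise`` floors each group sd at max(0.2 * |group mean|, 1e-8)
    (the conventional guard against near-constant genes); ``t`` uses the
    Welch t statistic. Ties are broken by gene id so the order is total and
    deterministic.
    """
    group_a, group_b = list(group_a), list(group_b)
    for name, g in (("group_a", group_a), ("group_b", group_b)):
        if len(g) < 3:
            raise ConfigError(f"rank_metric: {name} has {len(g)} samples; need >= 3")
    A = matrix[group_a].to_numpy(dtype=float)
    B = matrix[group_b].to_numpy(dtype=float)
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    if metric == "signal_to_noise":
        sa = np.maximum(A.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(ma), 1e-8))
        sb = np.maximum(B.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mb), 1e-8))
        scores = (ma - mb) / (sa + sb)
    elif metric == "t":
        va = A.var(axis=1, ddof=1) / A.shape[1]
        vb = B.var(axis=1, ddof=1) / B.shape[1]
        denom = np.sqrt(np.maximum(va + vb, 1e-16))
        scores = (ma - mb) / denom
    else:
        raise ConfigError(f"unknown metric {metric!r}")
    gene_arr = matrix.index.to_numpy(dtype=object)
    order = np.lexsort((gene_arr, -scores))  # metric descending, gene id ascending
    return RankedList(
        genes=list(gene_arr[order]),
        scores=scores[order],
        metric=metric,
    )


def enrichment_score(
    ranked: RankedList, gene_set: Sequence[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum.

    The running sum returns exactly to 0 at the last position (the hit and
    miss increments are separately normalized); ES is its signed extremum.
    """
    hit = np.isin(np.asarray(ranked.genes, dtype=object), list(set(gene_set)))
    n_hits = int(hit.sum())
    n = len(ranked.genes)
    if n_hits == 0 or n_hits == n:
        raise ConfigError(
            "enrichment_score: gene set must overlap the ranked list and its complement"
        )
    w = np.abs(ranked.scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total <= 0:
        # all hit metrics are exactly 0 (e.g. identical groups): equal weights
        hit_w = hit.astype(float)
        total = hit_w.sum()
    steps = np.where(hit, hit_w / total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _observed_and_permuted_es(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    gene_set: Sequence[str],
    n_permutations: int,
    seed: int,
    metric: str,
    weight: float,
) -> tuple[float, np.ndarray, RankedList, np.ndarray, bool]:
    ranked = rank_metric(matrix, group_a, group_b, metric)
    es_obs, running = enrichment_score(ranked, gene_set, weight)

    samples = group_a + group_b
    n_a = len(group_a)
    n_total = len(samples)
    from math import comb

    exhaustive = comb(n_total, n_a) <= n_permutations
    es_perm = []
    if exhaustive:
        for combo in itertools.combinations(range(n_total), n_a):
            pa = [samples[i] for i in combo]
            pb = [samples[i] for i in range(n_total) if i not in set(combo)]
            r = rank_metric(matrix, pa, pb, metric)
            es_perm.append(enrichment_score(r, gene_set, weight)[0])
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        idx = np.arange(n_total)
        for _ in range(n_permutations):
            rng.shuffle(idx)
            pa = [samples[i] for i in idx[:n_a]]
            pb = [samples[i] for i in idx[n_a:]]
            r = rank_metric(matrix, pa, pb, metric)
            es_perm.append(enrichment_score(r, gene_set, weight)[0])
    return es_obs, running, ranked, np.array(es_perm), exhaustive


def gsea_significance(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    gene_set: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
    metric: str = "signal_to_noise",
    weight: float = 1.0,
    set_name: str = "set",
) -> GseaResult:
    """Phenotype-permutation significance of one gene set.

    Nominal p is the add-one-smoothed fraction of same-sign permuted ES with
    |ES_perm| >= |ES_obs|; NES divides ES by the mean |same-sign permuted
    ES|. When the distinct label splits are no more than ``n_permutations``
    they are enumerated exhaustively instead of sampled. ``fdr_q`` is set to
    the nominal p here; use :func:`gsea_collection` for the NES-based FDR
    across a set collection.
    """
    if n_permutations < 1:
        raise ConfigError("n_permutations must be >= 1")
    group_a, group_b = list(group_a), list(group_b)
    es_obs, running, ranked, es_perm, exhaustive = _observed_and_permuted_es(
        matrix, group_a, group_b, gene_set, n_permutations, seed, metric, weight
    )
    same_sign = es_perm * np.sign(es_obs) >= 0 if es_obs != 0 else np.ones_like(es_perm, bool)
    n_same = int(same_sign.sum())
    n_extreme = int((np.abs(es_perm[same_sign]) >= abs(es_obs)).sum())
    p_nominal = (1 + n_extreme) / (1 + n_same)
    denom = np.abs(es_perm[same_sign]).mean() if n_same else np.nan
    nes = float(es_obs / denom) if denom and np.isfinite(denom) and denom > 0 else 0.0
    result = GseaResult(
        set_name=set_name,
        es=es_obs,
        nes=nes,
        p_nominal=float(p_nominal),
        fdr_q=float(p_nominal),
        leading_edge=[],
        running_sum=running,
        es_permuted=es_perm,
        exhaustive=exhaustive,
    )
    result.leading_edge = leading_edge(result, ranked, gene_set)
    return result


def leading_edge(
    result: GseaResult, ranked: RankedList, gene_set: Sequence[str]
) -> list[str]:
    """Core-enrichment genes of a GSEA result.

    For positive ES: set members at or before the running-sum maximum; for
    negative ES: members at or after the minimum. Order follows the ranked
    list.
    """
    if result.es == 0:
        raise ConfigError("leading_edge undefined for ES = 0")
    members = set(gene_set)
    running = result.running_sum
    if result.es > 0:
        peak = int(np.argmax(running))
        span = range(0, peak + 1)
    else:
        trough = int(np.argmin(running))
        span = range(trough, len(running))
    return [ranked.genes[i] for i in span if ranked.genes[i] in members]


def select_hub_genes(
    result: GseaResult, ranked: RankedList, k: int = 10
) -> list[tuple[str, float]]:
    """Top-k leading-edge genes by |rank metric| (ties broken by gene id)."""
    if not result.leading_edge:
        raise ConfigError("select_hub_genes: empty leading edge")
    score_of = dict(zip(ranked.genes, ranked.scores))
    order = sorted(result.leading_edge, key=lambda g: (-abs(score_of[g]), g))
    return [(g, float(score_of[g])) for g in order[: min(k, len(order))]]


def gsea_collection(
    matrix: pd.DataFrame,
    comparisons: dict[str, tuple[Sequence[str], Sequence[str], Sequence[str]]],
    n_permutations: int = 1000,
    seed: int = 0,
    metric: str = "signal_to_noise",
    weight: float = 1.0,
) -> dict[str, GseaResult]:
    """GSEA over a collection; FDR q by the standard NES-ratio estimate.

    ``comparisons`` maps set name -> (group_a, group_b, gene_set). The FDR
    for a set with observed NES* is the ratio of the fraction of pooled
    same-sign permuted NES at least as extreme to the fraction of observed
    same-sign NES at least as extreme, capped at 1.
    """
    results: dict[str, GseaResult] = {}
    for i, (name, (ga, gb, gs)) in enumerate(sorted(comparisons.items())):
        results[name] = gsea_significance(
            matrix, ga, gb, gs, n_permutations, seed + i, metric, weight, set_name=name
        )
    # pool normalized permuted scores
    pooled: list[float] = []
    for res in results.values():
        perm = res.es_permuted
        for sign in (1, -1):
            side = perm[perm * sign > 0]
            if side.size:
                pooled.extend(sign * np.abs(side) / np.abs(side).mean())
    pooled_arr = np.array(pooled)
    obs = np.array([r.nes for r in results.values()])
    for res in results.values():
        sign = np.sign(res.nes) or 1.0
        perm_side = pooled_arr[pooled_arr * sign >= 0]
        obs_side = obs[obs * sign >= 0]
        frac_perm = (
            float((np.abs(perm_side) >= abs(res.nes)).mean()) if perm_side.size else 1.0
        )
        frac_obs = (
            float((np.abs(obs_side) >= abs(res.nes)).mean()) if obs_side.size else 1.0
        )
        res.fdr_q = float(min(1.0, frac_perm / max(frac_obs, 1e-12)))
    return results


def ora_test(
    selected: Sequence[str],
    collection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Over-representation of ``selected`` genes in each set of a collection.

    Upper-tail hypergeometric p per set (probability of an overlap at least
    as large), BH-adjusted q across the collection. A generic replacement for
    database-backed pathway enrichment: sets come from user-supplied GMT
    files.
    """
    from adsubtypes.diffexp import bh_adjust

    universe_set = set(universe)
    selected_set = set(selected)
    if not universe_set or not selected_set:
        raise ConfigError("ora_test: universe and selected must be non-empty")
    if not selected_set <= universe_set:
        raise ConfigError("ora_test: selected genes must lie in the universe")
    rows = []
    for gs in collection:
        members = set(gs.genes) & universe_set
        overlap = len(members & selected_set)
        # hypergeom.sf(k-1) = P(X >= k)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe_set), len(members), len(selected_set))
        )
        rows.append((gs.name, len(members), overlap, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df
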