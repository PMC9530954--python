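"""Rank-sum differential expression with a dual significance threshold.

Genes are called differential between two groups when both conditions hold:
Benjamini-Hochberg adjusted Wilcoxon rank-sum P < alpha (default 0.05) and
absolute difference of group means > delta (default 0.2 on the log2 scale).
The mean difference is oriented as group mean minus reference mean (the
reference is the ND group or the compared subgroup).

Subgroup-specific upregulated genes are genes that pass the dual threshold
upward against *every* other subgroup; by construction the per-subgroup
signatures are pairwise disjoint.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from adsubtypes.errors import ConfigError

#: Largest per-group size for which the exact rank-sum null is enumerated.
EXACT_MAX_N = 8


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups have at most
    ``EXACT_MAX_N`` observations and there are no ties, and the normal
    approximation with midrank tie correction and continuity correction
    otherwise. Returns the Mann-Whitney U statistic of ``x`` and the p value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigError("rank_sum_test: both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.unique(combined).size == 1:
        warnings.warn("rank_sum_test: all values identical; p = 1", stacklevel=2)
        return float(x.size * y.size / 2), 1.0
    has_ties = np.unique(combined).size < combined.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ConfigError("bh_adjust: p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_genes(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    delta: float = 0.2,
) -> pd.DataFrame:
    """Per-gene rank-sum test of ``group_a`` against reference ``group_b``.

    Returns a DataFrame indexed by gene with columns ``p_raw``, ``p_adj``
    (BH over all genes tested jointly), ``mean_diff`` (mean_a - mean_b),
    ``direction`` (up/down) and ``significant`` (dual threshold).
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ConfigError("differential_genes: both groups need >= 2 samples")
    A = matrix[group_a].to_numpy(dtype=float)
    B = matrix[group_b].to_numpy(dtype=float)

    if min(len(group_a), len(group_b)) > EXACT_MAX_N:
        with np.errstate(invalid="ignore", divide="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.mannwhitneyu(
                    A, B, axis=1, alternative="two-sided",
                    method="asymptotic", use_continuity=True,
                )
        p_raw = np.asarray(res.pvalue, dtype=float)
        # rows where every value ties across both groups have a zero-variance
        # null; define p = 1 there
        constant = np.array(
            [np.unique(np.concatenate([a, b])).size == 1 for a, b in zip(A, B)]
        )
        p_raw[constant | np.isnan(p_raw)] = 1.0
    else:
        p_raw = np.array([rank_sum_test(a, b)[1] for a, b in zip(A, B)])

    mean_diff = A.mean(axis=1) - B.mean(axis=1)
    p_adj = bh_adjust(p_raw)
    out = pd.DataFrame(
        {
            "p_raw": p_raw,
            "p_adj": p_adj,
            "mean_diff": mean_diff,
            "direction": np.where(mean_diff >= 0, "up", "down"),
            "significant": (p_adj < alpha) & (np.abs(mean_diff) > delta),
        },
        index=matrix.index.copy(),
    )
    return out


def subgroup_specific_upregulated(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    alpha: float = 0.05,
    delta: float = 0.2,
    mode: str = "pairwise",
) -> dict[str, list[str]]:
    """Subgroup-specific upregulated gene signatures.

    In the default ``pairwise`` mode a gene belongs to subgroup s's signature
    iff it passes the dual threshold with mean_diff > +delta against *every*
    other subgroup; signatures are therefore pairwise disjoint. The
    alternative ``rest`` mode compares each subgroup against all other AD
    samples pooled.

    Signatures are ordered by the weakest pairwise mean difference
    (descending; a gene's most conservative margin), ties broken by gene id.
    """
    if mode not in ("pairwise", "rest"):
        raise ConfigError(f"unknown mode {mode!r}")
    sub = annot["subgroup"].dropna()
    labels = sorted(sub.unique())
    if len(labels) < 2:
        raise ConfigError("subgroup_specific_upregulated needs >= 2 subgroups")
    members = {s: list(sub.index[sub == s]) for s in labels}
    for s, ids in members.items():
        if len(ids) < 2:
            raise ConfigError(f"subgroup {s!r} has fewer than 2 samples")

    signatures: dict[str, list[str]] = {}
    for s in labels:
        if mode == "pairwise":
            passing: pd.Series | None = None
            margin: pd.Series | None = None
            for t in labels:
                if t == s:
                    continue
                res = differential_genes(matrix, members[s], members[t], alpha, delta)
                up = res["significant"] & (res["mean_diff"] > delta)
                passing = up if passing is None else (passing & up)
                margin = (
                    res["mean_diff"]
                    if margin is None
                    else np.minimum(margin, res["mean_diff"])
                )
        else:
            rest = [i for t in labels if t != s for i in members[t]]
            res = differential_genes(matrix, members[s], rest, alpha, delta)
            passing = res["significant"] & (res["mean_diff"] > delta)
            margin = res["mean_diff"]
        genes = matrix.index[np.asarray(passing)]
        order = sorted(genes, key=lambda g: (-float(margin.loc[g]), g))
        signatures[s] = order
    return signatures


def subgroup_vs_reference(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    reference_condition: str = "ND",
    alpha: float = 0.05,
    delta: float = 0.2,
) -> dict[str, pd.DataFrame]:
    """Each subgroup tested against the reference (ND) samples.

    The companion comparison family to the subgroup-vs-subgroup signatures;
    returned as full per-gene tables keyed by subgroup label.
    """
    sub = annot["subgroup"].dropna()
    ref = list(annot.index[annot["condition"] == reference_condition])
    if len(ref) < 2:
        raise ConfigError(f"reference condition {reference_condition!r} has < 2 samples")
    out = {}
    for s in sorted(sub.unique()):
        out[s] = differential_genes(matrix, list(sub.index[sub == s]), ref, alpha, delta)
    return out
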