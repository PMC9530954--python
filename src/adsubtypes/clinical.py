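"""Clinical-trait association for subgroups and hub genes.

Covers the trait comparisons reported alongside molecular subtypes: pairwise
rank-sum tests of continuous traits across ND and subgroups, the pairwise
two-proportion test for the female fraction, Spearman correlation (between
traits, and between gene expression or module eigengenes and traits), and the
Kruskal-Wallis test of hub-gene expression across groups. Missing trait
values are always handled pairwise-complete, never imputed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from adsubtypes.errors import ConfigError


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class TraitComparison:
    trait: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test: str
    statistic: float
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def compare_traits(
    annot: pd.DataFrame,
    grouping: pd.Series,
    traits: Sequence[str],
) -> list[TraitComparison]:
    """Pairwise rank-sum comparison of each trait across grouping levels.

    ``grouping`` maps sample id -> group label (e.g. ND plus subgroup
    labels). Missing trait values are dropped per pair; pairs where a side
    has fewer than 2 non-missing values are skipped. Group sample sizes are
    recorded per trait (real cohorts report varying per-trait n).
    """
    from adsubtypes.diffexp import rank_sum_test

    levels = sorted(grouping.dropna().unique())
    if len(levels) < 2:
        raise ConfigError("compare_traits needs >= 2 grouping levels")
    out: list[TraitComparison] = []
    for trait in traits:
        if trait not in annot.columns:
            continue
        values = annot[trait]
        for a, b in itertools.combinations(levels, 2):
            xa = values[grouping == a].dropna().to_numpy()
            xb = values[grouping == b].dropna().to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue  # level effectively missing this trait
            stat, p = rank_sum_test(xa, xb)
            out.append(
                TraitComparison(trait, str(a), str(b), len(xa), len(xb), "rank-sum", stat, p)
            )
    return out


def proportion_test(
    successes_a: int, n_a: int, successes_b: int, n_b: int, continuity: bool = False
) -> tuple[float, float]:
    """Pooled two-proportion chi-square test (continuity correction optional).

    The statistic equals the squared pooled z statistic
    z^2 = (p_a - p_b)^2 / (p(1-p)(1/n_a + 1/n_b)).
    """
    if n_a < 1 or n_b < 1:
        raise ConfigError("proportion_test: group sizes must be >= 1")
    if successes_a > n_a or successes_b > n_b or min(successes_a, successes_b) < 0:
        raise ConfigError("proportion_test: successes must lie in [0, n]")
    pooled = successes_a + successes_b
    if pooled == 0 or pooled == n_a + n_b:
        raise ConfigError("proportion_test: undefined (all successes or all failures)")
    table = np.array(
        [[successes_a, n_a - successes_a], [successes_b, n_b - successes_b]]
    )
    res = stats.chi2_contingency(table, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def compare_female_proportion(
    annot: pd.DataFrame, grouping: pd.Series, continuity: bool = False
) -> list[TraitComparison]:
    """Pairwise proportion test of the female fraction across groups."""
    if "sex" not in annot.columns:
        raise ConfigError("annotation lacks a 'sex' column")
    levels = sorted(grouping.dropna().unique())
    out: list[TraitComparison] = []
    for a, b in itertools.combinations(levels, 2):
        sa = annot.loc[grouping == a, "sex"].dropna()
        sb = annot.loc[grouping == b, "sex"].dropna()
        if len(sa) < 1 or len(sb) < 1:
            continue
        stat, p = proportion_test(
            int((sa == "F").sum()), len(sa), int((sb == "F").sum()), len(sb), continuity
        )
        out.append(
            TraitComparison(
                "female_proportion", str(a), str(b), len(sa), len(sb),
                "proportion-chi2", stat, p,
            )
        )
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks.

    p via the t approximation, except for n <= 7 without ties where the exact
    permutation null of rho is enumerated. Pairs with a missing value are
    dropped first; constant vectors are an error (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ConfigError("spearman needs >= 3 paired non-missing observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ConfigError("spearman undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if n <= 7 and no_ties:
        count = 0
        total = 0
        base = rx - rx.mean()
        denom = math.sqrt((base**2).sum())
        for perm in itertools.permutations(ry):
            r = float(np.dot(base, np.asarray(perm) - ry.mean())) / denom**2
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with midrank tie correction; chi-square p, k-1 df."""
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    cleaned = [g[~np.isnan(g)] for g in cleaned]
    if len(cleaned) < 2:
        raise ConfigError("kruskal_wallis needs >= 2 groups")
    if any(g.size == 0 for g in cleaned):
        raise ConfigError("kruskal_wallis: empty group")
    if sum(g.size for g in cleaned) < 3:
        raise ConfigError("kruskal_wallis needs total n >= 3")
    allv = np.concatenate(cleaned)
    if np.unique(allv).size == 1:
        return 0.0, 1.0
    res = stats.kruskal(*cleaned)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EigengeneProfile:
    """First-principal-component summary of a gene set's expression."""

    genes: list[str]
    scores: pd.Series  # per-sample eigengene, zero mean
    variance_explained: float
    orientation: int  # +1/-1 sign applied so mean gene correlation >= 0


def module_eigengene(matrix: pd.DataFrame) -> EigengeneProfile:
    """Module eigengene of a gene set: the first right-singular vector.

    ``matrix`` is the expression block restricted to the set's genes. Genes
    are standardized (zero mean, unit variance) before the decomposition, and
    the eigengene's sign is oriented so its mean correlation with member
    genes is non-negative.
    """
    if matrix.shape[0] < 1 or matrix.shape[1] < 3:
        raise ConfigError("module_eigengene needs >= 1 gene and >= 3 samples")
    Y = matrix.to_numpy(dtype=float)
    sd = Y.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ConfigError("module_eigengene: all genes constant")
    keep = sd > 0
    Z = (Y[keep] - Y[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = Vt[0]
    scores = scores - scores.mean()
    corr_mean = 0.0
    for row in Z:
        denom = np.linalg.norm(row - row.mean()) * np.linalg.norm(scores)
        if denom > 0:
            corr_mean += float(np.dot(row - row.mean(), scores) / denom)
    orientation = 1 if corr_mean >= 0 else -1
    scores = orientation * scores
    var_exp = float(s[0] ** 2 / (s**2).sum())
    return EigengeneProfile(
        genes=list(matrix.index[keep]),
        scores=pd.Series(scores, index=matrix.columns, name="eigengene"),
        variance_explained=var_exp,
        orientation=orientation,
    )


def trait_correlation_table(
    features: pd.DataFrame,
    annot: pd.DataFrame,
    traits: Sequence[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman (rho, p) of each feature against each trait, pairwise-complete.

    ``features`` has one row per gene or eigengene and one column per sample.
    Cells with fewer than 3 complete pairs are marked missing. With
    ``adjust=True`` a BH-adjusted q is added across the whole table.
    """
    records = []
    for feat in features.index:
        fvals = features.loc[feat]
        for trait in traits:
            if trait not in annot.columns:
                continue
            tvals = annot.loc[features.columns, trait]
            pair = pd.concat([fvals, tvals], axis=1).dropna()
            if len(pair) < 3 or pair.iloc[:, 0].nunique() == 1 or pair.iloc[:, 1].nunique() == 1:
                records.append((feat, trait, np.nan, np.nan))
                continue
            rho, p = spearman(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            records.append((feat, trait, rho, p))
    df = pd.DataFrame(records, columns=["feature", "trait", "rho", "p"])
    if adjust:
        from adsubtypes.diffexp import bh_adjust

        mask = df["p"].notna()
        q = np.full(len(df), np.nan)
        q[np.asarray(mask)] = bh_adjust(df.loc[mask, "p"].to_numpy())
        df["q"] = q
    return df.set_index(["feature", "trait"])


def trait_spearman_matrix(annot: pd.DataFrame, traits: Sequence[str]) -> pd.DataFrame:
    """Trait x trait Spearman rho matrix (pairwise-complete)."""
    present = [t for t in traits if t in annot.columns]
    out = pd.DataFrame(np.nan, index=present, columns=present, dtype=float)
    for a in present:
        out.loc[a, a] = 1.0
    for a, b in itertools.combinations(present, 2):
        pair = annot[[a, b]].dropna()
        if len(pair) < 3 or pair[a].nunique() == 1 or pair[b].nunique() == 1:
            continue
        rho, _ = spearman(pair[a].to_numpy(), pair[b].to_numpy())
        out.loc[a, b] = out.loc[b, a] = rho
    return out
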