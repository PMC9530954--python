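"""Exhaustive diagnostic-panel search over hub-gene subsets.

Every non-empty subset of each subgroup's hub panel is fitted as a logistic
combination score on training samples and scored by ROC AUC on held-out
validation samples; with three 10-gene panels this is 3 x (2^10 - 1) = 3,069
candidate panels. AUC bands follow the conventional interpretation: above
0.9 outstanding discrimination, 0.7-0.9 acceptable.

Positives for a subgroup's panels are that subgroup's AD samples; negatives
are the ND controls. Evaluating on a held-out stratified split avoids the
optimistic bias of in-sample best-subset selection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from adsubtypes.errors import ConfigError

MAX_PANEL_SIZE = 20


@dataclass
class PanelEvaluation:
    subgroup: str
    genes: tuple[str, ...]
    coefficients: np.ndarray  # per-gene coefficients
    intercept: float
    auc: float
    band: str
    ridge_fallback: bool = False
    error: str | None = None


@dataclass
class PanelSearchReport:
    evaluations: dict[str, list[PanelEvaluation]]  # subgroup -> sorted by AUC desc
    best: dict[str, PanelEvaluation] = field(default_factory=dict)

    @property
    def total_evaluations(self) -> int:
        return sum(len(v) for v in self.evaluations.values())


def enumerate_panels(genes: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets of a hub panel, by size then lexicographically."""
    genes = list(genes)
    k = len(genes)
    if not 1 <= k <= MAX_PANEL_SIZE:
        raise ConfigError(
            f"panel size {k} outside [1, {MAX_PANEL_SIZE}]; use a greedy search "
            "for larger panels"
        )
    ordered = sorted(genes)
    out: list[tuple[str, ...]] = []
    for size in range(1, k + 1):
        out.extend(itertools.combinations(ordered, size))
    return out


def fit_panel_score(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    genes: Sequence[str],
    ridge: bool = False,
) -> tuple[np.ndarray, float, bool]:
    """Maximum-likelihood logistic combination of a gene subset.

    Returns (coefficients, intercept, ridge_fallback). On non-convergence
    (the lbfgs signature of perfect separation) the fit falls back to a
    ridge-stabilized logistic model with a notice. The fit path has no
    randomness: identical data and subset give identical coefficients.
    """
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ConfigError("fit_panel_score: training labels are single-class")
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ConfigError(f"fit_panel_score: genes not in matrix: {missing}")
    X = matrix.loc[list(genes)].to_numpy(dtype=float).T
    fallback = False
    if ridge:
        model = LogisticRegression(penalty="l2", C=1.0, solver="lbfgs", max_iter=1000)
        model.fit(X, y)
        fallback = True
    else:
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=500)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X, y)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                model = LogisticRegression(
                    penalty="l2", C=100.0, solver="lbfgs", max_iter=1000
                )
                model.fit(X, y)
                fallback = True
    return model.coef_[0].copy(), float(model.intercept_[0]), fallback


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC in the Mann-Whitney form: P(random positive outranks a random
    negative), ties counting 1/2; equals the trapezoidal area under the
    empirical ROC curve."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not np.isfinite(s).all():
        raise ConfigError("roc_auc: scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigError("roc_auc: both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def band(auc: float) -> str:
    """AUC interpretation band: > 0.9 outstanding, [0.7, 0.9] acceptable."""
    if not 0 <= auc <= 1:
        raise ConfigError(f"AUC {auc} outside [0, 1]")
    if auc > 0.9:
        return "outstanding"
    if auc >= 0.7:
        return "acceptable"
    return "none"


def _labels_for(annot: pd.DataFrame, subgroup: str | None) -> pd.Series:
    """1 for positive samples, 0 for ND; excludes other AD samples when a
    subgroup is given."""
    cond = annot["condition"]
    if subgroup is None:
        keep = cond.isin(["AD", "ND"])
        y = (cond == "AD").astype(int)
        return y[keep]
    sub = annot["subgroup"]
    pos = (cond == "AD") & (sub == subgroup)
    neg = cond == "ND"
    y = pd.Series(np.nan, index=annot.index)
    y[pos] = 1
    y[neg] = 0
    return y.dropna().astype(int)


def search_best_panels(
    train: tuple[pd.DataFrame, pd.DataFrame],
    validation: tuple[pd.DataFrame, pd.DataFrame],
    hub_panels: dict[str, Sequence[str]],
    ridge: bool = False,
    positives: str = "subgroup",
) -> PanelSearchReport:
    """Exhaustive subset search per subgroup hub panel.

    Each subset is fitted on the training split and scored by AUC on the
    validation split; the best panel per subgroup is the maximum AUC, ties
    broken by smaller subset then lexicographic gene order. Fit errors for
    individual subsets are recorded and skipped, never aborting the search.

    With ``positives="subgroup"`` (default) each subgroup's classifiers
    separate that subgroup's samples from ND; ``positives="AD"`` uses all AD
    samples.
    """
    if not hub_panels:
        raise ConfigError("search_best_panels: no hub panels supplied")
    (Xtr, atr), (Xva, ava) = train, validation
    report = PanelSearchReport(evaluations={})
    for subgroup in sorted(hub_panels):
        genes = list(hub_panels[subgroup])
        sg = subgroup if positives == "subgroup" else None
        ytr = _labels_for(atr, sg)
        yva = _labels_for(ava, sg)
        if yva.nunique() < 2:
            raise ConfigError(
                f"validation split lacks both classes for subgroup {subgroup!r}"
            )
        evals: list[PanelEvaluation] = []
        for subset in enumerate_panels(genes):
            try:
                coef, intercept, fellback = fit_panel_score(
                    Xtr[ytr.index], ytr.to_numpy(), subset, ridge=ridge
                )
                val_scores = (
                    coef @ Xva.loc[list(subset), yva.index].to_numpy(dtype=float)
                    + intercept
                )
                auc = roc_auc(val_scores, yva.to_numpy())
                evals.append(
                    PanelEvaluation(
                        subgroup, subset, coef, intercept, auc, band(auc), fellback
                    )
                )
            except ConfigError as exc:
                evals.append(
                    PanelEvaluation(
                        subgroup, subset, np.array([]), np.nan, np.nan, "none",
                        error=str(exc),
                    )
                )
        ok = [e for e in evals if e.error is None]
        if not ok:
            raise ConfigError(f"no subset could be evaluated for subgroup {subgroup!r}")
        # max AUC; ties favor smaller subsets, then lexicographic order
        best = min(ok, key=lambda e: (-e.auc, len(e.genes), e.genes))
        report.evaluations[subgroup] = sorted(
            evals, key=lambda e: (-(e.auc if np.isfinite(e.auc) else -1), len(e.genes), e.genes)
        )
        report.best[subgroup] = best
    return report
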