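"""Parametric empirical-Bayes location/scale batch correction.

Implements the three-step parametric ComBat scheme for log2 expression data
merged across platform batches, plus a PCA-based check that batch structure
has been removed.

Model: for gene g, sample j of batch i,

    Y_ijg = alpha_g + X beta_g + gamma_ig + delta_ig * eps_ijg

Step 1 standardizes the data,

    Z_ijg = (Y_ijg - alpha_hat_g - X beta_hat_g) / sigma_hat_g,

with alpha_hat/beta_hat from gene-wise least squares (the grand mean is the
batch-size-weighted combination of per-batch means) and sigma_hat_g the pooled
residual scale.

Step 2 places conjugate priors on the batch effects,

    gamma_ig ~ N(gamma_bar_i, tau_bar2_i),
    delta2_ig ~ InverseGamma(lambda_bar_i, theta_bar_i),

with hyperparameters moment-matched across genes within each batch, and
solves the coupled posterior (empirical-Bayes) equations by fixed-point
iteration:

    gamma*_ig  = (n_i tau_bar2_i gamma_hat_ig + delta2*_ig gamma_bar_i)
                 / (n_i tau_bar2_i + delta2*_ig)
    delta2*_ig = (theta_bar_i + 0.5 * sum_j (Z_ijg - gamma*_ig)^2)
                 / (n_i / 2 + lambda_bar_i - 1)

Step 3 adjusts the data,

    Y*_ijg = sigma_hat_g / delta*_ig * (Z_ijg - gamma*_ig)
             + alpha_hat_g + X beta_hat_g,

removing the shrunken batch location/scale while re-adding the biological
covariate signal (by default the AD/ND condition indicator is protected).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from adsubtypes.errors import ConfigError

logger = logging.getLogger(__name__)

#: Relative convergence tolerance of the empirical-Bayes fixed point. Tight
#: enough that the converged (gamma*, delta2*) substituted back into the two
#: posterior equations reproduce themselves to well below 1e-6.
EB_TOL = 1e-10
EB_MAX_ITER = 500


@dataclass
class ComBatModel:
    """Fitted parameters of the location/scale batch model.

    Arrays are aligned with ``gene_ids`` (fitted genes only; constant genes
    are listed in ``excluded_genes`` and passed through unchanged) and with
    ``batch_ids``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    batch_ids: list[str]
    batch_of_sample: np.ndarray  # (N,) int index into batch_ids
    batch_sizes: np.ndarray  # (B,)
    covariate: str | None
    alpha: np.ndarray  # (G,) grand mean
    beta: np.ndarray  # (G, p) covariate coefficients
    sigma2: np.ndarray  # (G,) pooled variance
    stand_mean: np.ndarray  # (G, N) alpha + X beta per sample
    Z: np.ndarray  # (G, N) standardized data
    excluded_genes: list[str]
    excluded_values: pd.DataFrame | None
    gamma_hat: np.ndarray | None = None  # (B, G)
    delta2_hat: np.ndarray | None = None  # (B, G)
    gamma_bar: np.ndarray | None = None  # (B,)
    tau_bar2: np.ndarray | None = None  # (B,)
    lambda_bar: np.ndarray | None = None  # (B,)
    theta_bar: np.ndarray | None = None  # (B,)
    gamma_star: np.ndarray | None = None  # (B, G)
    delta2_star: np.ndarray | None = None  # (B, G)
    shrunk_batches: list[bool] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return self.gamma_star is not None and self.delta2_star is not None


@dataclass
class BatchCheckReport:
    """PCA summary of residual batch structure.

    ``separation`` is the share of total variance of the first two principal
    component scores explained by batch membership (between-batch sum of
    squares over total sum of squares); near 0 means batches are mixed.
    """

    variance_shares: np.ndarray
    separation: float
    n_samples: int
    n_batches: int


def _design(annot: pd.DataFrame, batch_ids: list[str], covariate: str | None) -> np.ndarray:
    n = len(annot)
    batch_cols = np.zeros((n, len(batch_ids)))
    for i, b in enumerate(batch_ids):
        batch_cols[np.asarray(annot["batch"] == b), i] = 1.0
    if covariate is None:
        return batch_cols
    if covariate not in annot.columns:
        raise ConfigError(f"covariate column {covariate!r} not in annotation")
    levels = sorted(annot[covariate].dropna().unique())
    if len(levels) < 2:
        return batch_cols  # constant covariate carries no signal
    # Reference-coded indicators (first level is the reference).
    cov_cols = np.column_stack(
        [np.asarray(annot[covariate] == lev, dtype=float) for lev in levels[1:]]
    )
    return np.hstack([batch_cols, cov_cols])


def standardize(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    covariate: str | None = "condition",
) -> tuple[pd.DataFrame, ComBatModel]:
    """Step 1: gene-wise standardization against the batch-free model.

    Returns the standardized matrix Z (fitted genes only) and a partial
    :class:`ComBatModel`. Genes with zero pooled variance are excluded with a
    warning and later passed through :func:`adjust` unchanged.
    """
    if not matrix.columns.equals(annot.index):
        if set(matrix.columns) != set(annot.index):
            raise ConfigError("matrix samples and annotation samples differ")
        annot = annot.loc[matrix.columns]
    if "batch" not in annot.columns:
        raise ConfigError("annotation lacks a 'batch' column")
    batch_ids = list(dict.fromkeys(annot["batch"]))
    sizes = np.array([(annot["batch"] == b).sum() for b in batch_ids])
    if (sizes < 2).any():
        small = batch_ids[int(np.argmin(sizes))]
        raise ConfigError(f"batch {small!r} has fewer than 2 samples")

    X = _design(annot, batch_ids, covariate)
    n_batches = len(batch_ids)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigError(
            f"covariate {covariate!r} is confounded with batch (design not full rank)"
        )

    Y = matrix.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ConfigError("expression matrix contains missing values")
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (B+p, G)
    resid = Y - (X @ coef).T
    sigma2 = (resid**2).mean(axis=1)  # pooled over all N samples

    keep = sigma2 > 1e-12 * max(1.0, float(np.abs(Y).max()) ** 2)
    excluded = [g for g, k in zip(matrix.index, keep) if not k]
    if excluded:
        logger.warning("excluding %d zero-variance gene(s): %s", len(excluded), excluded[:10])
    gene_ids = [g for g, k in zip(matrix.index, keep) if k]

    coef = coef[:, keep]
    sigma2 = sigma2[keep]
    alpha = (sizes / sizes.sum()) @ coef[:n_batches]  # weighted grand mean, (G,)
    beta = coef[n_batches:].T  # (G, p)
    cov_part = (X[:, n_batches:] @ coef[n_batches:]).T if X.shape[1] > n_batches else 0.0
    stand_mean = alpha[:, None] + cov_part  # (G, N)
    Z = (Y[keep] - stand_mean) / np.sqrt(sigma2)[:, None]

    model = ComBatModel(
        gene_ids=gene_ids,
        sample_ids=list(matrix.columns),
        batch_ids=batch_ids,
        batch_of_sample=np.array([batch_ids.index(b) for b in annot["batch"]]),
        batch_sizes=sizes,
        covariate=covariate,
        alpha=alpha,
        beta=beta,
        sigma2=sigma2,
        stand_mean=stand_mean,
        Z=Z,
        excluded_genes=excluded,
        excluded_values=matrix.loc[excluded] if excluded else None,
    )
    z_df = pd.DataFrame(Z, index=pd.Index(gene_ids, name="gene_id"), columns=matrix.columns)
    return z_df, model


def fit_empirical_bayes(model: ComBatModel, shrink: bool = True) -> ComBatModel:
    """Step 2: moment-matched priors and fixed-point posterior estimates.

    With ``shrink=False`` the priors are treated as non-informative and the
    raw per-batch estimates are used (gamma* = gamma_hat, delta2* =
    delta2_hat); :func:`adjust` then reduces to plain per-batch location/scale
    standardization restored to the pooled scale.
    """
    B, G = len(model.batch_ids), len(model.gene_ids)
    Z = model.Z
    gamma_hat = np.empty((B, G))
    delta2_hat = np.empty((B, G))
    for i in range(B):
        cols = model.batch_of_sample == i
        Zi = Z[:, cols]
        gamma_hat[i] = Zi.mean(axis=1)
        delta2_hat[i] = Zi.var(axis=1, ddof=1)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gamma_bar = gamma_hat.mean(axis=1)
        tau_bar2 = gamma_hat.var(axis=1, ddof=1)
        m = delta2_hat.mean(axis=1)
        s2 = delta2_hat.var(axis=1, ddof=1)
    # Inverse-gamma moment matching: for IG(lambda, theta), mean = theta/(lambda-1)
    # and variance = theta^2 / ((lambda-1)^2 (lambda-2)); solving for the mean m
    # and variance s2 of delta2_hat across genes gives:
    with np.errstate(divide="ignore", invalid="ignore"):
        lambda_bar = (m**2 + 2 * s2) / s2
        theta_bar = (m**3 + m * s2) / s2

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    shrunk = [False] * B
    if shrink:
        for i in range(B):
            degenerate = (
                not np.isfinite(tau_bar2[i])
                or tau_bar2[i] <= 0
                or not np.isfinite(lambda_bar[i])
                or not np.isfinite(theta_bar[i])
                or s2[i] <= 0
            )
            if degenerate:
                warnings.warn(
                    f"batch {model.batch_ids[i]!r}: degenerate hyperprior "
                    "(zero variance across genes); no shrinkage applied",
                    stacklevel=2,
                )
                continue
            cols = model.batch_of_sample == i
            Zi = Z[:, cols]
            n_i = int(model.batch_sizes[i])
            s1 = Zi.sum(axis=1)
            ss = (Zi**2).sum(axis=1)
            g = gamma_hat[i].copy()
            d2 = delta2_hat[i].copy()
            converged = False
            for _ in range(EB_MAX_ITER):
                g_new = (n_i * tau_bar2[i] * gamma_hat[i] + d2 * gamma_bar[i]) / (
                    n_i * tau_bar2[i] + d2
                )
                sse = ss - 2 * g_new * s1 + n_i * g_new**2
                d2_new = (theta_bar[i] + 0.5 * sse) / (n_i / 2 + lambda_bar[i] - 1)
                change = max(
                    np.max(np.abs(g_new - g) / np.maximum(np.abs(g), 1e-8)),
                    np.max(np.abs(d2_new - d2) / np.maximum(np.abs(d2), 1e-8)),
                )
                g, d2 = g_new, d2_new
                if change < EB_TOL:
                    converged = True
                    break
            if not converged:
                warnings.warn(
                    f"batch {model.batch_ids[i]!r}: EB fixed point hit the "
                    f"{EB_MAX_ITER}-iteration cap",
                    stacklevel=2,
                )
            gamma_star[i] = g
            delta2_star[i] = d2
            shrunk[i] = True

    model.gamma_hat = gamma_hat
    model.delta2_hat = delta2_hat
    model.gamma_bar = gamma_bar
    model.tau_bar2 = tau_bar2
    model.lambda_bar = lambda_bar
    model.theta_bar = theta_bar
    model.gamma_star = gamma_star
    model.delta2_star = delta2_star
    model.shrunk_batches = shrunk
    return model


def adjust(matrix: pd.DataFrame, model: ComBatModel) -> pd.DataFrame:
    """Step 3: remove the shrunken batch effects and restore the pooled scale.

    Excluded constant genes are passed through unchanged; with a single batch
    the input is returned as-is (passthrough — there is no second batch to
    align to).
    """
    if list(matrix.columns) != model.sample_ids:
        raise ConfigError("matrix samples do not match the fitted model")
    if set(matrix.index) != set(model.gene_ids) | set(model.excluded_genes):
        raise ConfigError("matrix genes do not match the fitted model")
    if len(model.batch_ids) == 1:
        return matrix.copy()
    if not model.complete:
        raise ConfigError("model is incomplete; run fit_empirical_bayes first")

    b = model.batch_of_sample
    gamma = model.gamma_star[b].T  # (G, N)
    dstar = np.sqrt(model.delta2_star[b]).T
    corrected = (
        np.sqrt(model.sigma2)[:, None] / dstar * (model.Z - gamma) + model.stand_mean
    )
    out = pd.DataFrame(
        corrected, index=pd.Index(model.gene_ids, name="gene_id"), columns=model.sample_ids
    )
    if model.excluded_genes:
        out = pd.concat([out, model.excluded_values])
    return out.loc[matrix.index]


def correct(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    covariate: str | None = "condition",
    shrink: bool = True,
) -> tuple[pd.DataFrame, ComBatModel]:
    """Run all three steps; returns the corrected matrix and the model."""
    _, model = standardize(matrix, annot, covariate)
    if len(model.batch_ids) == 1:
        return matrix.copy(), model
    fit_empirical_bayes(model, shrink=shrink)
    return adjust(matrix, model), model


def batch_check(matrix: pd.DataFrame, annot: pd.DataFrame, n_components: int = 10) -> BatchCheckReport:
    """PCA check of residual batch structure.

    Samples are projected on principal components of the gene-centered
    matrix; the separation statistic is the batch-membership R^2 of the first
    two component scores.
    """
    if matrix.shape[1] < 3:
        raise ConfigError("batch_check needs at least 3 samples")
    batches = annot.loc[matrix.columns, "batch"]
    if batches.nunique() < 2:
        raise ConfigError("batch_check needs at least 2 batches")
    Y = matrix.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    # economy SVD: samples x rank scores
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    scores = (Vt.T * s)  # (N, r)
    total_var = (s**2).sum()
    shares = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    top = scores[:, :2]
    grand = top.mean(axis=0)
    ss_tot = ((top - grand) ** 2).sum()
    ss_between = 0.0
    for b in batches.unique():
        mask = np.asarray(batches == b)
        ss_between += mask.sum() * ((top[mask].mean(axis=0) - grand) ** 2).sum()
    separation = float(ss_between / ss_tot) if ss_tot > 0 else 0.0
    return BatchCheckReport(
        variance_shares=shares[:n_components],
        separation=separation,
        n_samples=matrix.shape[1],
        n_batches=int(batches.nunique()),
    )
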