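"""Synthetic multi-batch expression cohorts with planted AD subtypes.

The generator emulates the structure of merged post-mortem brain microarray
cohorts: log2-scale expression, several platform batches carrying additive and
multiplicative per-gene batch effects, roughly 40% non-demented (ND) controls,
three planted AD subtypes marked by disjoint blocks of upregulated genes, and
clinical traits statistically coupled to subtype (high CDR/NFT in subtypes I
and III, elevated plaque density and lowered tissue pH in all AD).

Every downstream stage of the pipeline has a ground-truth recovery test built
on these cohorts: the returned :class:`GroundTruth` records the planted marker
blocks, the per-sample subtype labels, and the per-(batch, gene) location and
scale effects.

The generative model per gene g, sample j in batch i is

    Y_ijg = mu_g + effect * 1[g is a marker of j's subtype]
            + gamma_ig + delta_ig * eps_jg,      eps ~ N(0, noise_sd^2)

i.e. exactly the location/scale family that the empirical-Bayes batch
correction assumes. Expression noise is Gaussian on the log2 scale, matching
log2-transformed microarray intensities.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from adsubtypes.errors import ConfigError

SUBTYPES = ("I", "II", "III")

#: Continuous clinical traits produced by the default trait model.
CONTINUOUS_TRAITS = ("CDR", "Braak", "NFT", "CERAD", "NPD", "pH", "age")


@dataclass(frozen=True)
class TraitSpec:
    """One continuous clinical trait.

    ``baseline`` is the ND mean; AD samples of subtype k get
    ``baseline + subtype_offsets[k]``. Values are drawn from a Gaussian with
    standard deviation ``sd`` truncated to ``bounds`` (bounds are kept at
    least ~2 sd away from every group mean so truncation bias is negligible
    relative to sampling error).
    """

    baseline: float
    subtype_offsets: tuple[float, float, float]
    sd: float
    bounds: tuple[float, float] = (-math.inf, math.inf)


@dataclass(frozen=True)
class SexSpec:
    """Bernoulli female-proportion model: ND level plus per-subtype levels."""

    nd_female_prob: float = 0.55
    subtype_female_probs: tuple[float, float, float] = (0.65, 0.65, 0.55)


def default_trait_model() -> dict[str, TraitSpec]:
    """Default clinical-trait model.

    Offsets mirror the qualitative pattern reported for real AD subgroups:
    CDR/Braak/NFT elevated strongly in subtypes I and III and mildly in II;
    CERAD/NPD (plaque burden) elevated equally in all AD; pH lowered in all
    AD; subtype III slightly younger (suspected familial presentation).
    """
    return {
        "CDR": TraitSpec(1.0, (1.5, 0.5, 1.5), 0.5, (0.0, 5.0)),
        "Braak": TraitSpec(2.0, (2.5, 1.5, 2.5), 0.8, (0.0, 6.0)),
        "NFT": TraitSpec(10.0, (15.0, 5.0, 15.0), 4.0, (0.0, math.inf)),
        "CERAD": TraitSpec(1.5, (1.5, 1.5, 1.5), 0.6, (0.0, 4.0)),
        "NPD": TraitSpec(6.0, (8.0, 8.0, 8.0), 3.0, (0.0, math.inf)),
        "pH": TraitSpec(6.6, (-0.3, -0.3, -0.3), 0.25, (5.6, 7.4)),
        "age": TraitSpec(78.0, (2.0, 2.0, -3.0), 8.0, (55.0, 105.0)),
    }


def _default_batches() -> tuple[tuple[str, int, int], ...]:
    # 240 AD + 160 ND across three platform batches -> 40% controls.
    return (("batch1", 80, 54), ("batch2", 80, 53), ("batch3", 80, 53))


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Parameters
    ----------
    n_genes
        Total genes in the matrix.
    n_marker_genes_per_subtype
        Size of each subtype's planted upregulated block (three disjoint
        blocks in total).
    batches
        Sequence of ``(batch_id, n_AD, n_ND)``.
    subtype_proportions
        Multinomial probabilities used to label each AD sample with a subtype.
    marker_effect
        Log2 mean shift applied to a subtype's markers in its own samples.
    batch_location_sd
        Std. dev. of the additive per-(batch, gene) offsets gamma_ig.
    batch_scale_range
        Uniform interval for the multiplicative per-(batch, gene) noise
        scale factors delta_ig.
    noise_sd
        Residual log2 noise sd (before batch scaling).
    baseline_mean, baseline_sd
        Law of the per-gene baseline expression mu_g (log2 intensity scale).
    dropout_rate
        Optional uniform missingness rate applied to the final matrix.
    trait_model, sex_model
        Clinical-trait generation; see :class:`TraitSpec` / :class:`SexSpec`.
    seed
        Single integer governing all randomness; per-stage sub-streams are
        derived deterministically from it.
    """

    n_genes: int = 2000
    n_marker_genes_per_subtype: int = 50
    batches: Sequence[tuple[str, int, int]] = field(default_factory=_default_batches)
    subtype_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    marker_effect: float = 1.0
    batch_location_sd: float = 0.5
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    dropout_rate: float = 0.0
    trait_model: dict[str, TraitSpec] = field(default_factory=default_trait_model)
    sex_model: SexSpec = field(default_factory=SexSpec)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ConfigError(
                f"subtype_proportions must sum to 1, got {self.subtype_proportions}"
            )
        if any(p < 0 for p in self.subtype_proportions):
            raise ConfigError("subtype_proportions must be non-negative")
        if 3 * self.n_marker_genes_per_subtype > self.n_genes:
            raise ConfigError(
                "3 * n_marker_genes_per_subtype exceeds n_genes "
                f"({3 * self.n_marker_genes_per_subtype} > {self.n_genes})"
            )
        if self.noise_sd <= 0 or self.batch_location_sd < 0:
            raise ConfigError("noise_sd must be > 0 and batch_location_sd >= 0")
        lo, hi = self.batch_scale_range
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid batch_scale_range {self.batch_scale_range}")
        if not self.batches:
            raise ConfigError("at least one batch required")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        for name, spec in self.trait_model.items():
            if spec.sd <= 0:
                raise ConfigError(f"trait {name}: sd must be > 0")


@dataclass
class GroundTruth:
    """What was planted: marker blocks, subtype labels, batch effects."""

    marker_map: dict[str, tuple[str, ...]]
    true_subtype: pd.Series  # sample id -> subtype label; NaN for ND
    batch_location: pd.DataFrame  # batches x genes, additive gamma_ig
    batch_scale: pd.DataFrame  # batches x genes, multiplicative delta_ig

    def marker_genes(self) -> set[str]:
        return set().union(*self.marker_map.values())


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a synthetic cohort.

    Returns
    -------
    matrix : DataFrame
        Genes x samples log2 expression.
    annot : DataFrame
        Per-sample annotation indexed by sample id, with columns ``batch``,
        ``condition`` (AD/ND), ``subgroup`` (empty; filled by subtyping),
        the continuous traits and ``sex``.
    truth : GroundTruth
    """
    if not isinstance(config, CohortConfig):
        raise ConfigError("generate_cohort expects a CohortConfig")
    # Deterministic per-stage sub-streams from the one seed.
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_expr, rng_batch, rng_trait = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    batch_ids = [b[0] for b in config.batches]
    if len(set(batch_ids)) != len(batch_ids):
        raise ConfigError("duplicate batch ids")

    # Sample layout: per batch, AD samples then ND samples.
    sample_ids: list[str] = []
    sample_batch: list[str] = []
    sample_cond: list[str] = []
    for batch_id, n_ad, n_nd in config.batches:
        for j in range(n_ad):
            sample_ids.append(f"{batch_id}_AD{j:03d}")
            sample_batch.append(batch_id)
            sample_cond.append("AD")
        for j in range(n_nd):
            sample_ids.append(f"{batch_id}_ND{j:03d}")
            sample_batch.append(batch_id)
            sample_cond.append("ND")
    n_samples = len(sample_ids)
    cond = np.array(sample_cond)
    ad_mask = cond == "AD"

    # Planted subtype labels (iid multinomial over AD samples).
    subtype_idx = rng_assign.choice(
        3, size=int(ad_mask.sum()), p=list(config.subtype_proportions)
    )
    true_subtype = pd.Series(pd.NA, index=pd.Index(sample_ids, name="sample_id"), dtype=object)
    true_subtype.iloc[np.flatnonzero(ad_mask)] = [SUBTYPES[k] for k in subtype_idx]

    # Disjoint marker blocks, placed at random gene positions.
    m = config.n_marker_genes_per_subtype
    marker_pos = rng_assign.choice(config.n_genes, size=3 * m, replace=False)
    marker_map = {
        SUBTYPES[k]: tuple(sorted(gene_ids[p] for p in marker_pos[k * m : (k + 1) * m]))
        for k in range(3)
    }

    # Expression: baseline + subtype shift + batch location + scaled noise.
    mu = rng_expr.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = np.tile(mu[:, None], (1, n_samples))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    ad_positions = np.flatnonzero(ad_mask)
    for k, label in enumerate(SUBTYPES):
        rows = np.array([gene_index[g] for g in marker_map[label]])
        cols = ad_positions[subtype_idx == k]
        if rows.size and cols.size:
            values[np.ix_(rows, cols)] += config.marker_effect

    gamma = rng_batch.normal(
        0.0, config.batch_location_sd, size=(len(batch_ids), config.n_genes)
    )
    lo, hi = config.batch_scale_range
    delta = rng_batch.uniform(lo, hi, size=(len(batch_ids), config.n_genes))
    eps = rng_expr.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    batch_of = np.array([batch_ids.index(b) for b in sample_batch])
    for i in range(len(batch_ids)):
        cols = np.flatnonzero(batch_of == i)
        values[:, cols] += gamma[i][:, None] + delta[i][:, None] * eps[:, cols]

    if config.dropout_rate > 0:
        drop = rng_expr.random(values.shape) < config.dropout_rate
        values = np.where(drop, np.nan, values)

    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)

    # Clinical traits conditional on condition and subtype.
    annot = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    annot["batch"] = sample_batch
    annot["condition"] = sample_cond
    annot["subgroup"] = pd.NA
    for trait, spec in config.trait_model.items():
        means = np.full(n_samples, spec.baseline)
        for k, label in enumerate(SUBTYPES):
            means[np.asarray(true_subtype == label)] += spec.subtype_offsets[k]
        lo_b, hi_b = spec.bounds
        a = (lo_b - means) / spec.sd
        b = (hi_b - means) / spec.sd
        annot[trait] = stats.truncnorm.rvs(
            a, b, loc=means, scale=spec.sd, random_state=rng_trait
        )
    p_female = np.full(n_samples, config.sex_model.nd_female_prob)
    for k, label in enumerate(SUBTYPES):
        p_female[np.asarray(true_subtype == label)] = (
            config.sex_model.subtype_female_probs[k]
        )
    annot["sex"] = np.where(rng_trait.random(n_samples) < p_female, "F", "M")

    truth = GroundTruth(
        marker_map=marker_map,
        true_subtype=true_subtype,
        batch_location=pd.DataFrame(gamma, index=batch_ids, columns=gene_ids),
        batch_scale=pd.DataFrame(delta, index=batch_ids, columns=gene_ids),
    )
    return matrix, annot, truth


def holdout_split(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    fraction: float,
    seed: int,
) -> tuple[tuple[pd.DataFrame, pd.DataFrame], tuple[pd.DataFrame, pd.DataFrame]]:
    """Stratified train/validation split by condition.

    ``fraction`` of each condition (rounded to the nearest integer) goes to
    the validation part. Partitions are disjoint and jointly exhaustive, and
    deterministic given ``seed``. Stands in for an external validation cohort
    in diagnostic-panel evaluation.
    """
    if not 0 < fraction < 1:
        raise ConfigError(f"fraction must be in (0, 1), got {fraction}")
    conditions = annot["condition"]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    val_ids: list[str] = []
    for level in ("AD", "ND"):
        ids = annot.index[conditions == level].to_numpy()
        if len(ids) < 2:
            raise ConfigError(
                f"condition {level!r} has {len(ids)} sample(s); need >= 2 to split"
            )
        n_val = int(round(fraction * len(ids)))
        n_val = min(max(n_val, 1), len(ids) - 1)  # both parts non-empty
        chosen = rng.choice(ids, size=n_val, replace=False)
        val_ids.extend(chosen)
    val_set = set(val_ids)
    train_cols = [s for s in matrix.columns if s not in val_set]
    val_cols = [s for s in matrix.columns if s in val_set]
    return (
        (matrix[train_cols], annot.loc[train_cols]),
        (matrix[val_cols], annot.loc[val_cols]),
    )


def save_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize ground truth as a plain-text key/value sidecar."""
    with open(path, "w") as fh:
        for label, genes in truth.marker_map.items():
            fh.write(f"markers.{label}\t{','.join(genes)}\n")
        for sample, label in truth.true_subtype.items():
            if pd.notna(label):
                fh.write(f"subtype.{sample}\t{label}\n")
        for batch in truth.batch_location.index:
            loc = ",".join(f"{v:.6g}" for v in truth.batch_location.loc[batch])
            scl = ",".join(f"{v:.6g}" for v in truth.batch_scale.loc[batch])
            fh.write(f"batch_location.{batch}\t{loc}\n")
            fh.write(f"batch_scale.{batch}\t{scl}\n")


def _replace(config: CohortConfig, **kwargs) -> CohortConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return dataclasses.replace(config, **kwargs)
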