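import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from adsubtypes import combat
from adsubtypes.cohort import CohortConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest 3-batch cohort with planted subtypes and batch effects."""
    config = CohortConfig(
        n_genes=600,
        n_marker_genes_per_subtype=30,
        batches=[("b1", 40, 20), ("b2", 40, 20), ("b3", 40, 20)],
        marker_effect=1.0,
        seed=42,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def corrected_cohort(small_cohort):
    """Batch-corrected small cohort with ground-truth subgroups filled in."""
    matrix, annot, truth = small_cohort
    corrected, _ = combat.correct(matrix, annot)
    labelled = annot.copy()
    labelled["subgroup"] = truth.true_subtype
    return corrected, labelled, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def two_batch_shift(n_per_batch=50, n_genes=40, shift=2.0, noise=0.5, seed=0):
    """Two batches, batch 2 = batch 1 law + constant additive shift."""
    rng = np.random.default_rng(seed)
    base = rng.normal(7.0, 1.0, size=n_genes)
    y1 = base[:, None] + rng.normal(0, noise, size=(n_genes, n_per_batch))
    y2 = base[:, None] + shift + rng.normal(0, noise, size=(n_genes, n_per_batch))
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"a{i}" for i in range(n_per_batch)] + [f"b{i}" for i in range(n_per_batch)]
    matrix = pd.DataFrame(np.hstack([y1, y2]), index=genes, columns=samples)
    annot = pd.DataFrame(
        {
            "batch": ["b1"] * n_per_batch + ["b2"] * n_per_batch,
            "condition": (["AD", "ND"] * n_per_batch)[:n_per_batch]
            + (["AD", "ND"] * n_per_batch)[:n_per_batch],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return matrix, annot
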