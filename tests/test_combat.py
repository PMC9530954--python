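"""Empirical-Bayes batch correction: printed-equation fidelity and oracles."""

import numpy as np
import pandas as pd
import pytest

from adsubtypes import combat
from adsubtypes.errors import ConfigError
from tests.conftest import two_batch_shift


def random_instance(n_genes=5, batches=(6, 8), seed=0, covariate=False):
    rng = np.random.default_rng(seed)
    n = sum(batches)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n)]
    matrix = pd.DataFrame(
        rng.normal(5, 1.5, size=(n_genes, n)), index=genes, columns=samples
    )
    batch = np.repeat([f"b{i}" for i in range(len(batches))], batches)
    annot = pd.DataFrame({"batch": batch}, index=pd.Index(samples, name="sample_id"))
    annot["condition"] = np.where(rng.random(n) < 0.5, "AD", "ND") if covariate else "AD"
    return matrix, annot


class TestStandardize:
    def test_single_batch_no_covariates_is_zscore(self):
        matrix, annot = random_instance(batches=(10,), seed=1)
        z, model = combat.standardize(matrix, annot, covariate=None)
        expected = matrix.sub(matrix.mean(axis=1), axis=0).div(
            matrix.std(axis=1, ddof=0), axis=0
        )
        np.testing.assert_allclose(z.to_numpy(), expected.to_numpy(), atol=1e-10)

    def test_additive_shift_recovers_symmetric_batch_locations(self):
        """Batch 2 = batch 1 + 2 per gene: the batch means of Z sit at
        -shift/2 and +shift/2 in standardized units (direct-mean oracle)."""
        matrix, annot = two_batch_shift(n_per_batch=100, shift=2.0, noise=0.4, seed=2)
        z, model = combat.standardize(matrix, annot, covariate=None)
        model = combat.fit_empirical_bayes(model, shrink=False)
        # oracle: per-batch mean of Z computed directly
        b1 = z.loc[:, np.asarray(annot["batch"] == "b1")].mean(axis=1)
        b2 = z.loc[:, np.asarray(annot["batch"] == "b2")].mean(axis=1)
        np.testing.assert_allclose(model.gamma_hat[0], b1.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(model.gamma_hat[1], b2.to_numpy(), atol=1e-12)
        # scaled back to expression units the offsets are -1 and +1
        sigma = np.sqrt(model.sigma2)
        np.testing.assert_allclose(model.gamma_hat[0] * sigma, -1.0, atol=0.2)
        np.testing.assert_allclose(model.gamma_hat[1] * sigma, +1.0, atol=0.2)

    def test_constant_gene_excluded_and_passed_through(self):
        matrix, annot = random_instance(seed=3)
        matrix.loc["g0"] = 4.0
        z, model = combat.standardize(matrix, annot, covariate=None)
        assert model.excluded_genes == ["g0"]
        assert "g0" not in z.index
        model = combat.fit_empirical_bayes(model)
        out = combat.adjust(matrix, model)
        assert (out.loc["g0"] == 4.0).all()
        assert list(out.index) == list(matrix.index)

    def test_pooled_moments_of_z(self):
        # pooled mean is exactly 0 by construction; pooled variance is 1 up
        # to the batch-mean sampling deviations that remain inside Z
        matrix, annot = random_instance(n_genes=30, batches=(100, 100), seed=4, covariate=True)
        z, _ = combat.standardize(matrix, annot)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.to_numpy().var(axis=1), 1.0, atol=0.06)

    def test_confounded_design_rejected(self):
        matrix, annot = random_instance(batches=(6, 6), seed=5)
        annot["condition"] = np.where(annot["batch"] == "b0", "AD", "ND")
        with pytest.raises(ConfigError, match="confounded"):
            combat.standardize(matrix, annot)

    def test_small_batch_rejected(self):
        matrix, annot = random_instance(batches=(1, 13), seed=6)
        with pytest.raises(ConfigError):
            combat.standardize(matrix, annot, covariate=None)


class TestEmpiricalBayes:
    def test_converged_estimates_satisfy_both_posterior_equations(self):
        """Substituting (gamma*, delta2*) back into the two fixed-point
        equations reproduces them to 1e-6 on random 5-gene instances."""
        for seed in range(5):
            matrix, annot = random_instance(n_genes=5, batches=(6, 8), seed=seed)
            _, model = combat.standardize(matrix, annot, covariate=None)
            model = combat.fit_empirical_bayes(model)
            for i in range(len(model.batch_ids)):
                if not model.shrunk_batches[i]:
                    continue
                cols = model.batch_of_sample == i
                Zi = model.Z[:, cols]
                n_i = model.batch_sizes[i]
                g, d2 = model.gamma_star[i], model.delta2_star[i]
                g_rhs = (
                    n_i * model.tau_bar2[i] * model.gamma_hat[i] + d2 * model.gamma_bar[i]
                ) / (n_i * model.tau_bar2[i] + d2)
                sse = ((Zi - g[:, None]) ** 2).sum(axis=1)
                d2_rhs = (model.theta_bar[i] + 0.5 * sse) / (
                    n_i / 2 + model.lambda_bar[i] - 1
                )
                np.testing.assert_allclose(g, g_rhs, atol=1e-6)
                np.testing.assert_allclose(d2, d2_rhs, atol=1e-6)

    def test_gamma_star_is_convex_combination_of_estimate_and_prior_mean(self):
        matrix, annot = random_instance(n_genes=40, batches=(10, 12), seed=7)
        _, model = combat.standardize(matrix, annot, covariate=None)
        model = combat.fit_empirical_bayes(model)
        for i in range(2):
            lo = np.minimum(model.gamma_hat[i], model.gamma_bar[i]) - 1e-12
            hi = np.maximum(model.gamma_hat[i], model.gamma_bar[i]) + 1e-12
            assert np.all(model.gamma_star[i] >= lo)
            assert np.all(model.gamma_star[i] <= hi)

    def test_identical_batches_shrink_to_null_effects(self):
        """Two batches drawn from one law at large n: gamma* ~ 0, delta2* ~ 1."""
        rng = np.random.default_rng(8)
        n_genes, n_i = 2000, 500
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"s{i}" for i in range(2 * n_i)]
        matrix = pd.DataFrame(
            rng.normal(0, 1, size=(n_genes, 2 * n_i)), index=genes, columns=samples
        )
        annot = pd.DataFrame(
            {"batch": ["b1"] * n_i + ["b2"] * n_i},
            index=pd.Index(samples, name="sample_id"),
        )
        _, model = combat.standardize(matrix, annot, covariate=None)
        model = combat.fit_empirical_bayes(model)
        assert np.abs(model.gamma_star).max() < 0.05 + 0.2  # individual genes
        assert abs(model.gamma_star.mean()) < 0.05
        assert abs(model.delta2_star.mean() - 1.0) < 0.05

    def test_degenerate_prior_falls_back_to_no_shrinkage(self):
        # one gene per batch: variance of gamma_hat across genes is undefined
        matrix, annot = random_instance(n_genes=1, batches=(5, 5), seed=9)
        _, model = combat.standardize(matrix, annot, covariate=None)
        with pytest.warns(UserWarning, match="degenerate"):
            model = combat.fit_empirical_bayes(model)
        np.testing.assert_array_equal(model.gamma_star, model.gamma_hat)
        np.testing.assert_array_equal(model.delta2_star, model.delta2_hat)


def no_eb_oracle(model):
    """Per-batch location/scale standardization restored to pooled scale."""
    out = np.empty_like(model.Z)
    for i in range(len(model.batch_ids)):
        cols = model.batch_of_sample == i
        Zi = model.Z[:, cols]
        out[:, cols] = (Zi - model.gamma_hat[i][:, None]) / np.sqrt(
            model.delta2_hat[i]
        )[:, None]
    return out * np.sqrt(model.sigma2)[:, None] + model.stand_mean


class TestAdjust:
    def test_single_batch_passthrough(self):
        matrix, annot = random_instance(batches=(12,), seed=10)
        corrected, _ = combat.correct(matrix, annot, covariate=None)
        np.testing.assert_allclose(corrected.to_numpy(), matrix.to_numpy(), atol=1e-9)

    def test_no_shrinkage_equals_location_scale_oracle(self):
        for seed in (11, 12):
            matrix, annot = random_instance(n_genes=25, batches=(8, 10, 6), seed=seed)
            _, model = combat.standardize(matrix, annot, covariate=None)
            model = combat.fit_empirical_bayes(model, shrink=False)
            out = combat.adjust(matrix, model)
            np.testing.assert_allclose(out.to_numpy(), no_eb_oracle(model), atol=1e-8)

    def test_planted_shift_removed(self):
        matrix, annot = two_batch_shift(n_per_batch=200, shift=2.0, noise=0.5, seed=13)

        def max_batch_mean_diff(m):
            b1 = m.loc[:, np.asarray(annot["batch"] == "b1")].mean(axis=1)
            b2 = m.loc[:, np.asarray(annot["batch"] == "b2")].mean(axis=1)
            return float(np.abs(b1 - b2).max())

        assert max_batch_mean_diff(matrix) > 1.9
        # no-shrinkage mode removes the empirical batch locations exactly
        oracle_mode, _ = combat.correct(matrix, annot, covariate=None, shrink=False)
        assert max_batch_mean_diff(oracle_mode) < 0.01
        # EB mode shrinks toward the common shift: residual differences stay
        # within the batch-mean sampling noise (sd ~ noise*sqrt(2/n))
        corrected, _ = combat.correct(matrix, annot, covariate=None)
        assert max_batch_mean_diff(corrected) < 0.2

    def test_second_pass_estimates_shrink_tenfold(self):
        matrix, annot = two_batch_shift(n_per_batch=200, shift=2.0, noise=0.5, seed=14)
        _, model1 = combat.standardize(matrix, annot, covariate=None)
        model1 = combat.fit_empirical_bayes(model1)
        corrected = combat.adjust(matrix, model1)
        _, model2 = combat.standardize(corrected, annot, covariate=None)
        model2 = combat.fit_empirical_bayes(model2, shrink=False)
        first = np.abs(model1.gamma_hat).mean()
        second = np.abs(model2.gamma_hat).mean()
        assert second < first / 10

    def test_id_mismatch_rejected(self):
        matrix, annot = random_instance(seed=15)
        _, model = combat.standardize(matrix, annot, covariate=None)
        model = combat.fit_empirical_bayes(model)
        with pytest.raises(ConfigError):
            combat.adjust(matrix.iloc[:, ::-1], model)


class TestBatchCheck:
    def test_identical_batches_near_null_separation(self):
        matrix, annot = random_instance(n_genes=80, batches=(50, 50), seed=16)
        report = combat.batch_check(matrix, annot)
        assert report.separation <= 0.1

    def test_planted_shift_separates_then_mixes(self):
        matrix, annot = two_batch_shift(n_per_batch=200, shift=2.0, noise=0.5, seed=17)
        before = combat.batch_check(matrix, annot)
        corrected, _ = combat.correct(matrix, annot, covariate=None)
        after = combat.batch_check(corrected, annot)
        assert before.separation > 0.5
        assert after.separation < 0.1

    def test_constant_orthogonal_shift_fully_separates(self):
        genes = ["g1", "g2"]
        matrix = pd.DataFrame(
            [[0.0, 0.1, 5.0, 5.1], [0.1, 0.0, 5.1, 5.0]],
            index=genes,
            columns=["a1", "a2", "b1", "b2"],
        )
        annot = pd.DataFrame(
            {"batch": ["b1", "b1", "b2", "b2"]},
            index=pd.Index(matrix.columns, name="sample_id"),
        )
        report = combat.batch_check(matrix, annot)
        assert report.separation > 0.95

    def test_variance_shares_non_increasing(self, small_cohort):
        matrix, annot, _ = small_cohort
        report = combat.batch_check(matrix, annot)
        assert np.all(np.diff(report.variance_shares) <= 1e-12)
        assert np.all((report.variance_shares >= 0) & (report.variance_shares <= 1))
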