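"""Generator checks: genotype law, LD oracle, outcomes, missingness, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import multivariate_normal, norm

import rxremit as rx
from rxremit.exceptions import ConfigurationError
from rxremit.simulate import (
    SimulationConfig,
    hardy_weinberg_thresholds,
    inject_missingness,
    linear_predictor,
    simulate_clinical,
    simulate_genotypes,
    simulate_outcomes,
)


def dosage_correlation_oracle(maf: float, rho: float) -> float:
    """Expected Pearson correlation of two thresholded AR(1) latent Gaussians
    sharing MAF ``maf``, by numerical integration of the bivariate normal."""
    t0, t1 = hardy_weinberg_thresholds(np.array([maf]))
    t0, t1 = float(t0[0]), float(t1[0])
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])

    def psurv(a, b):
        return 1.0 - norm.cdf(a) - norm.cdf(b) + mvn.cdf([a, b])

    e12 = sum(psurv(a, b) for a in (t0, t1) for b in (t0, t1))
    e = 2.0 * maf
    var = (norm.sf(t0) + 3.0 * norm.sf(t1)) - e**2
    return (e12 - e * e) / var


class TestGenotypes:
    def test_allele_frequency_matches_target(self):
        cfg = SimulationConfig(
            n_participants=5000, n_snps=20, ld_block_size=1, ld_rho=0.0,
            maf_range=(0.3, 0.3), n_clinical=0, seed=1,
        )
        dosage, maf = simulate_genotypes(cfg)
        assert np.allclose(maf, 0.3)
        freq = dosage.mean(axis=0) / 2.0
        assert np.all(np.abs(freq - 0.3) < 0.02)
        assert set(np.unique(dosage)) <= {0.0, 1.0, 2.0}

    def test_adjacent_snps_independent_without_ld(self):
        cfg = SimulationConfig(
            n_participants=5000, n_snps=10, ld_block_size=5, ld_rho=0.0,
            maf_range=(0.2, 0.4), n_clinical=0, seed=2,
        )
        dosage, _ = simulate_genotypes(cfg)
        r = np.corrcoef(dosage, rowvar=False)
        adjacent = np.diag(r, k=1)
        assert np.all(np.abs(adjacent) < 0.03)

    def test_within_block_correlation_matches_gaussian_oracle(self):
        cfg = SimulationConfig(
            n_participants=10000, n_snps=40, ld_block_size=2, ld_rho=0.9,
            maf_range=(0.3, 0.3), n_clinical=0, seed=3,
        )
        dosage, _ = simulate_genotypes(cfg)
        pair_corrs = [
            np.corrcoef(dosage[:, j], dosage[:, j + 1])[0, 1]
            for j in range(0, 40, 2)
        ]
        expected = dosage_correlation_oracle(0.3, 0.9)
        assert abs(np.mean(pair_corrs) - expected) < 0.01
        assert np.all(np.abs(np.asarray(pair_corrs) - expected) < 0.05)

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ConfigurationError):
            SimulationConfig(maf_range=(0.1, 0.6))


class TestClinical:
    def test_zero_clinical_columns(self):
        cfg = SimulationConfig(n_participants=50, n_snps=10, n_clinical=0, seed=0)
        X, meta = simulate_clinical(cfg)
        assert X.shape == (50, 0)
        assert len(meta) == 0

    def test_ordinal_values_within_declared_range(self):
        cfg = SimulationConfig(n_participants=500, n_snps=10, n_clinical=9, seed=4)
        X, meta = simulate_clinical(cfg)
        for i, (name, row) in enumerate(meta.iterrows()):
            if row["vtype"] in ("ordinal", "binary"):
                assert set(np.unique(X[:, i])) <= set(row["levels"])

    def test_continuous_moments_match_declared(self):
        cfg = SimulationConfig(n_participants=4000, n_snps=10, n_clinical=6, seed=5)
        X, meta = simulate_clinical(cfg)
        for i, (name, row) in enumerate(meta.iterrows()):
            if row["vtype"] == "continuous":
                se = row["sd"] / np.sqrt(cfg.n_participants)
                assert abs(X[:, i].mean() - row["mean"]) < 3 * se


class TestOutcomes:
    def test_null_model_prevalence_half(self):
        cfg = SimulationConfig(n_participants=2000, n_snps=10, n_clinical=0, seed=6)
        cohort = rx.generate_cohort(cfg)
        assert abs(cohort.outcome.mean() - 0.5) < 0.03

    def test_single_snp_odds_ratio_recovered(self):
        import statsmodels.api as sm

        cfg = SimulationConfig(
            n_participants=5000, n_snps=10, n_clinical=0, missing_rate=0.0,
            causal_features_per_drug={"A": ["snp_00000"], "B": ["snp_00000"]},
            effect_sizes={"snp_00000": np.log(2.0)},
            maf_range=(0.3, 0.4), seed=7,
        )
        cohort = rx.generate_cohort(cfg)
        x = cohort.features["snp_00000"].to_numpy()
        fit = sm.Logit(cohort.outcome, sm.add_constant(x)).fit(disp=0)
        assert abs(np.exp(fit.params[1]) - 2.0) < 0.25

    def test_hrsd_mode_remission_fraction(self):
        cfg = SimulationConfig(
            n_participants=4000, n_snps=10, n_clinical=0,
            outcome_mode="hrsd_score", seed=8,
        )
        cohort = rx.generate_cohort(cfg)
        assert cohort.outcome.min() >= 0 and cohort.outcome.max() <= 52
        assert abs(np.mean(cohort.outcome <= 7) - 0.5) < 0.03

    def test_missing_causal_feature_is_error(self):
        cfg = SimulationConfig(
            n_participants=50, n_snps=5, ld_block_size=5, n_clinical=0,
            causal_features_per_drug={"A": ["snp_99999"], "B": []},
            effect_sizes={"snp_99999": 1.0}, seed=0,
        )
        with pytest.raises(ConfigurationError):
            rx.generate_cohort(cfg)

    def test_oracle_auc_of_true_linear_predictor(self):
        """AUC of logistic(eta) against simulated outcomes converges to the
        generating model's analytic AUC (Monte-Carlo oracle)."""
        causal = [f"snp_{i:05d}" for i in range(5)]
        kwargs = dict(
            n_snps=50, n_clinical=0, missing_rate=0.0, ld_rho=0.0,
            causal_features_per_drug={"A": causal, "B": causal},
            effect_sizes={k: 0.6 for k in causal},
            maf_range=(0.2, 0.4), intercept_per_drug="center",
        )
        cohort = rx.generate_cohort(SimulationConfig(n_participants=5000, seed=9, **kwargs))
        eta = linear_predictor(cohort.features, cohort.drug, cohort.config)
        observed = rx.roc_auc(expit(eta), cohort.outcome)
        # independent large-sample oracle under the same generative law
        big = rx.generate_cohort(SimulationConfig(n_participants=60000, seed=10, **kwargs))
        eta_big = linear_predictor(big.features, big.drug, big.config)
        oracle = rx.roc_auc(expit(eta_big), big.outcome)
        assert abs(observed - oracle) < 0.02


class TestMissingness:
    def test_zero_rate_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 5))
        out = inject_missingness(X, 0.0, np.ones(5, bool), rng)
        assert np.array_equal(out, X)

    def test_missing_count_binomial(self):
        rng = np.random.default_rng(1)
        X = np.zeros((1000, 10))
        out = inject_missingness(X, 0.1, np.ones(10, bool), rng)
        assert abs(np.isnan(out).sum() - 1000) < 100

    def test_genetic_columns_never_masked(self):
        cfg = SimulationConfig(n_participants=300, n_snps=50, n_clinical=6,
                               missing_rate=0.3, seed=11)
        cohort = rx.generate_cohort(cfg)
        G = cohort.features[cohort.genetic_columns]
        assert not G.isna().to_numpy().any()
        C = cohort.features[cohort.clinical_columns]
        assert C.isna().to_numpy().any()

    def test_rate_one_rejected(self):
        with pytest.raises(ConfigurationError):
            inject_missingness(np.zeros((2, 2)), 1.0, np.ones(2, bool),
                               np.random.default_rng(0))


class TestDeterminismAndRandomization:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_participants=120, n_snps=60, n_clinical=6, seed=13)
        a = rx.generate_cohort(cfg)
        b = rx.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.features, b.features)
        assert np.array_equal(a.drug, b.drug)
        assert np.array_equal(a.outcome, b.outcome)

    def test_drug_assignment_independent_of_features(self):
        """Pooled over 50 cohorts x all features, the two-sample t-test of
        each feature against drug arm rejects at ~ the nominal 5% rate."""
        from scipy.stats import ttest_ind

        rejections, total = 0, 0
        for seed in range(50):
            cfg = SimulationConfig(n_participants=200, n_snps=15, n_clinical=6,
                                   missing_rate=0.0, seed=1000 + seed)
            cohort = rx.generate_cohort(cfg)
            a = cohort.arm_mask("A")
            for col in cohort.features.columns:
                x = cohort.features[col].to_numpy()
                p = ttest_ind(x[a], x[~a]).pvalue
                rejections += p < 0.05
                total += 1
        rate = rejections / total
        assert abs(rate - 0.05) < 0.03
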