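import numpy as np
import pytest

from mortset import (
    FunctionalDataModel,
    GroundTruth,
    fit_fpca,
    fit_multilevel,
    fit_multivariate,
    fit_product_ratio,
    inject_outlier_years,
    integrated_squared_error,
    robust_refit,
    simulate_population_set,
    simulate_surface,
    smooth_log_rates,
)
from mortset.data import MortalityDataError


class TestSmoothing:
    def test_zero_penalty_is_identity(self, noisy_surface):
        Y = noisy_surface.log_rates()
        out = smooth_log_rates(Y, lam=0.0, monotone=False)
        np.testing.assert_allclose(out, Y, atol=1e-6)

    def test_monotone_projection_leaves_increasing_curve_alone(self):
        k = 30
        Y = np.linspace(-8, -1, k)[:, None]
        out = smooth_log_rates(Y, lam=0.0, monotone=True, monotone_from=None)
        np.testing.assert_allclose(out, Y, atol=1e-8)

    def test_large_penalty_approaches_straight_line(self, rng):
        y = rng.normal(size=(20, 1))
        out = smooth_log_rates(y, lam=1e9, monotone=False)
        x = np.arange(20)
        coef = np.polyfit(x, y[:, 0], 1)
        np.testing.assert_allclose(out[:, 0], np.polyval(coef, x), atol=1e-3)

    def test_too_few_ages_rejected(self):
        with pytest.raises(MortalityDataError):
            smooth_log_rates(np.zeros((3, 2)), lam=1.0)


class TestFpca:
    def test_rank_one_exact_recovery(self, rng):
        mu = rng.normal(size=6)
        phi = rng.normal(size=6)
        phi /= np.linalg.norm(phi)
        scores = rng.normal(size=9)
        scores -= scores.mean()
        X = mu[:, None] + np.outer(phi, scores)
        fit = fit_fpca(X, K=1)
        np.testing.assert_allclose(fit.reconstruction(), X, atol=1e-10)

    def test_k_zero_is_mean_only(self, rng):
        X = rng.normal(size=(5, 8))
        fit = fit_fpca(X, K=0)
        np.testing.assert_allclose(fit.mu, X.mean(axis=1))
        np.testing.assert_allclose(fit.resid_var, X.var(axis=1), atol=1e-12)

    def test_matches_brute_force_eigensolver(self, rng):
        X = rng.normal(size=(5, 8))
        fit = fit_fpca(X, K=3)
        # brute force: explicit covariance and eigendecomposition
        mu = np.array([sum(X[i]) / 8 for i in range(5)])
        Xc = X - mu[:, None]
        C = np.zeros((5, 5))
        for a in range(5):
            for b in range(5):
                C[a, b] = sum(Xc[a, t] * Xc[b, t] for t in range(8)) / 8
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:3]
        for j, col in enumerate(order):
            v = evecs[:, col]
            dot = abs(float(v @ fit.components[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-10)

    def test_components_orthonormal_and_scores_centred(self, noisy_surface):
        fit = fit_fpca(noisy_surface.log_rates(), K=4)
        gram = fit.components.T @ fit.components
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        np.testing.assert_allclose(fit.scores.mean(axis=0), 0.0, atol=1e-8)

    def test_explained_variance_nondecreasing_in_k(self, noisy_surface):
        X = noisy_surface.log_rates()
        total_resid = [
            fit_fpca(X, K=k).resid_var.sum() for k in range(0, 6)
        ]
        assert np.all(np.diff(total_resid) <= 1e-10)

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(MortalityDataError):
            fit_fpca(rng.normal(size=(5, 8)), K=1, weights=np.zeros(8))


class TestIntegratedSquaredError:
    def test_perfect_fit_gives_zero(self, rng):
        mu = rng.normal(size=6)
        phi = rng.normal(size=6)
        phi /= np.linalg.norm(phi)
        scores = rng.normal(size=9)
        scores -= scores.mean()
        X = mu[:, None] + np.outer(phi, scores)
        fit = fit_fpca(X, K=1)
        np.testing.assert_allclose(integrated_squared_error(fit), 0.0, atol=1e-20)

    def test_single_cell_shift_adds_delta_squared(self, rng):
        X = rng.normal(size=(5, 8))
        fit = fit_fpca(X, K=0)
        base = integrated_squared_error(fit, X)
        shifted = X.copy()
        shifted[2, 3] += 0.7
        bumped = integrated_squared_error(fit, shifted)
        # frozen fit, K=0: residual at that cell moves by exactly delta
        delta_term = (shifted[2, 3] - fit.mu[2]) ** 2 - (X[2, 3] - fit.mu[2]) ** 2
        assert bumped[3] - base[3] == pytest.approx(delta_term, abs=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        X = rng.normal(size=(6, 7))
        fit = fit_fpca(X, K=2)
        ise = integrated_squared_error(fit)
        for t in range(7):
            total = 0.0
            for x in range(6):
                recon = fit.mu[x] + sum(
                    fit.scores[t, k] * fit.components[x, k] for k in range(2)
                )
                total += (X[x, t] - recon) ** 2
            assert ise[t] == pytest.approx(total, abs=1e-12)


class TestRobustRefit:
    def test_injected_outlier_is_uniquely_flagged(self):
        s = simulate_surface(GroundTruth(seed=13))
        out = inject_outlier_years(s, [1990], 1.0)
        fit = robust_refit(out, K=6)
        assert list(fit.flagged_years_) == [1990]

    def test_clean_data_rarely_flagged(self):
        s = simulate_surface(GroundTruth(seed=14))
        fit = robust_refit(s, K=6)
        assert len(fit.flagged_years_) <= 1

    def test_flagged_years_have_zero_influence(self):
        s = simulate_surface(GroundTruth(seed=15))
        out = inject_outlier_years(s, [1990], 1.0)
        fit = robust_refit(out, K=4)
        assert list(fit.flagged_years_) == [1990]
        # deleting the flagged year's column reproduces mu and phi
        keep = out.years != 1990
        ref = fit_fpca(fit._smoothed(out)[:, keep], K=4)
        np.testing.assert_allclose(fit.mu_, ref.mu, atol=1e-10)
        np.testing.assert_allclose(
            np.abs(fit.components_), np.abs(ref.components), atol=1e-10
        )

    def test_invalid_level_rejected(self, noisy_surface):
        with pytest.raises(MortalityDataError):
            robust_refit(noisy_surface, K=2, level=1.5)


class TestProductRatio:
    def test_reconstruction_identity_pre_modeling(self, popset):
        mM = popset["M"].rates
        mF = popset["F"].rates
        p = np.sqrt(mM * mF)
        r = np.sqrt(mM / mF)
        np.testing.assert_allclose(p * r, mM, rtol=1e-12)
        np.testing.assert_allclose(p / r, mF, rtol=1e-12)

    def test_identical_populations_give_unit_ratio(self, noisy_surface):
        from dataclasses import replace
        from mortset import PopulationSet

        twin = PopulationSet(
            {
                "F": replace(noisy_surface, label="F"),
                "M": replace(noisy_surface, label="M"),
            }
        )
        fit = fit_product_ratio(twin, K=3)
        assert fit.ratio_fit_.K == 0
        np.testing.assert_allclose(fit.ratio_fit_.mu, 0.0, atol=1e-12)

    def test_product_scores_track_shared_trend(self):
        ps = simulate_population_set(
            GroundTruth(seed=21, exposure_scale=1e6, sex_gap=0.3), cross_corr=1.0
        )
        fit = fit_product_ratio(ps, K=2)
        shared = ps["F"].truth_kappa
        corr = abs(np.corrcoef(fit.product_fit_.scores[:, 0], shared)[0, 1])
        assert corr > 0.99

    def test_needs_exactly_two_populations(self, noisy_surface):
        with pytest.raises(MortalityDataError):
            fit_product_ratio(noisy_surface)


class TestMultivariate:
    def test_single_population_reduces_to_fpca(self, noisy_surface):
        from dataclasses import replace
        from mortset import PopulationSet

        single = PopulationSet({"only": replace(noisy_surface, label="only")})
        joint = fit_multivariate(single, K=3, lam=0.0, monotone=False)
        marginal = fit_fpca(noisy_surface.log_rates(), K=3)
        np.testing.assert_allclose(joint.fpca_.mu, marginal.mu, atol=1e-12)
        np.testing.assert_allclose(
            np.abs(joint.fpca_.components), np.abs(marginal.components), atol=1e-10
        )

    def test_identical_populations_have_identical_blocks(self, noisy_surface):
        from dataclasses import replace
        from mortset import PopulationSet

        twin = PopulationSet(
            {
                "a": replace(noisy_surface, label="a"),
                "b": replace(noisy_surface, label="b"),
            }
        )
        fit = fit_multivariate(twin, K=1)
        k = fit.block_size_
        block_a = fit.fpca_.components[:k, 0]
        block_b = fit.fpca_.components[k:, 0]
        cos = abs(block_a @ block_b) / (np.linalg.norm(block_a) * np.linalg.norm(block_b))
        assert cos > 1 - 1e-8

    def test_joint_subspace_contains_marginals(self, popset):
        # at K = w * K_marginal the joint reconstruction is at least as good
        joint = fit_multivariate(popset, K=4, lam=0.0, monotone=False)
        total_joint = joint.fpca_.resid_var.sum()
        marg_sum = sum(
            fit_fpca(popset[lab].log_rates(), K=2).resid_var.sum()
            for lab in popset.labels
        )
        assert total_joint <= marg_sum + 1e-9


class TestMultilevel:
    def test_identical_populations_have_no_specific_trend(self, noisy_surface):
        from dataclasses import replace
        from mortset import PopulationSet

        twin = PopulationSet(
            {
                "a": replace(noisy_surface, label="a"),
                "b": replace(noisy_surface, label="b"),
            }
        )
        fit = fit_multilevel(twin, K_common=2, K_specific=2)
        for lab in ("a", "b"):
            assert np.max(np.abs(fit.specific_fits_[lab].scores)) < 1e-8

    def test_additive_decomposition_reconstructs_input(self, popset):
        fit = fit_multilevel(popset, K_common=2, K_specific=2, lam=0.0, monotone=False)
        R = fit.common_fit_.reconstruction()
        for lab in popset.labels:
            U = fit.specific_fits_[lab].reconstruction()
            final = popset[lab].log_rates() - fit.mu_[lab][:, None] - R - U
            # remaining residual is exactly what the model stores
            recon = fit.mu_[lab][:, None] + R + U + final
            np.testing.assert_allclose(recon, popset[lab].log_rates(), atol=1e-12)

    def test_independent_populations_recover_specific_trends(self):
        ps = simulate_population_set(
            GroundTruth(seed=22, exposure_scale=1e6), cross_corr=0.0, deterministic=True
        )
        fit = fit_multilevel(ps, K_common=1, K_specific=1, lam=0.0, monotone=False)
        for lab in ps.labels:
            own = ps[lab].truth_kappa
            # common part holds the average trend; the specific score should
            # track the population's deviation from that average
            other = [p for p in ps.labels if p != lab][0]
            deviation = own - 0.5 * (own + ps[other].truth_kappa)
            corr = abs(np.corrcoef(fit.specific_fits_[lab].scores[:, 0], deviation)[0, 1])
            assert corr > 0.95

    def test_component_budget_validated(self, popset):
        with pytest.raises(MortalityDataError):
            fit_multilevel(popset, K_common=25, K_specific=20)


def test_in_sample_residual_means_vanish(noisy_surface):
    fit = FunctionalDataModel(K=4, lam=0.0, monotone=False).fit(noisy_surface)
    resid = noisy_surface.log_rates() - fit.fitted_log_rates_
    np.testing.assert_allclose(resid.mean(axis=1), 0.0, atol=1e-8)
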