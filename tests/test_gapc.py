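import copy

import numpy as np
import pytest

from mortset import (
    GAPC,
    GroundTruth,
    apply_constraints,
    estimate_xc,
    fit_gapc,
    simulate_surface,
)
from mortset.data import MortalityDataError
from mortset.gapc import _constrain, _spec

COHORT_MODELS = ["RH", "APC", "M6", "M7", "M8", "PLAT"]
ALL_MODELS = ["LC_POIS", "CBD"] + COHORT_MODELS


@pytest.fixture(scope="module")
def fits(noisy_surface):
    out = {}
    for name in ALL_MODELS:
        kwargs = {"xc": 105.0} if name == "M8" else {}
        out[name] = fit_gapc(name, noisy_surface, **kwargs)
    return out


def included_cohort_sums(fit):
    inc = fit.cohort_included_
    c = fit.cohorts_[inc].astype(float)
    g = fit.gamma_[inc]
    return g.sum(), (c * g).sum(), (c**2 * g).sum()


class TestConstraints:
    @pytest.mark.parametrize("name", ["LC_POIS", "RH"])
    def test_bilinear_normalization(self, fits, name):
        fit = fits[name]
        assert abs(fit.betas_[0].sum() - 1.0) < 1e-8
        assert abs(fit.kappas_[0].sum()) < 1e-6

    def test_rh_cohort_loading_and_level(self, fits):
        fit = fits["RH"]
        assert abs(fit.beta0_.sum() - 1.0) < 1e-8
        assert abs(included_cohort_sums(fit)[0]) < 1e-8

    @pytest.mark.parametrize(
        "name,n_constraints", [("APC", 2), ("M6", 2), ("M7", 3), ("M8", 1), ("PLAT", 3)]
    )
    def test_cohort_polynomial_constraints(self, fits, name, n_constraints):
        sums = included_cohort_sums(fits[name])
        scale = max(np.abs(fits[name].gamma_).max(), 1.0)
        for i in range(n_constraints):
            # normalize by the cohort-scale of each moment
            c_norm = np.abs(fits[name].cohorts_.astype(float)) ** i
            assert abs(sums[i]) / (scale * max(c_norm.sum(), 1.0)) < 1e-8

    def test_plat_kappas_centred(self, fits):
        for i in range(3):
            assert abs(fits["PLAT"].kappas_[i].sum()) < 1e-6

    def test_apc_kappa_centred(self, fits):
        assert abs(fits["APC"].kappas_[0].sum()) < 1e-6


class TestApplyConstraints:
    def test_predictor_invariance_after_perturbation(self, noisy_surface):
        fit = fit_gapc("LC_POIS", noisy_surface)
        pert = copy.deepcopy(fit)
        # representation change: beta scaled to sum 2, kappa mean 5
        pert.betas_[0] = pert.betas_[0] * 2.0
        pert.kappas_[0] = pert.kappas_[0] / 2.0 + 5.0
        pert.alpha_ = pert.alpha_ - pert.betas_[0] * 5.0
        before = pert.linear_predictor()
        fixed = apply_constraints(pert)
        after = fixed.linear_predictor()
        np.testing.assert_allclose(after, before, atol=1e-10)
        assert abs(fixed.betas_[0].sum() - 1.0) < 1e-12
        assert abs(fixed.kappas_[0].mean()) < 1e-10

    def test_linear_gamma_absorbed_exactly(self, noisy_surface):
        fit = fit_gapc("APC", noisy_surface)
        pert = copy.deepcopy(fit)
        c = pert.cohorts_.astype(float)
        pert.gamma_ = np.where(pert.cohort_included_, 0.3 + 0.01 * c, 0.0)
        before = pert.linear_predictor()
        fixed = apply_constraints(pert)
        assert np.max(np.abs(fixed.gamma_)) < 1e-9
        np.testing.assert_allclose(
            fixed.linear_predictor() * fit.weights_, before * fit.weights_, atol=1e-9
        )

    def test_idempotence(self, fits):
        for name in ("LC_POIS", "APC", "M7", "PLAT"):
            fit = fits[name]
            again = apply_constraints(fit)
            for i, kk in enumerate(fit.kappas_):
                np.testing.assert_allclose(again.kappas_[i], kk, atol=1e-10)
            if fit.gamma_ is not None:
                np.testing.assert_allclose(again.gamma_, fit.gamma_, atol=1e-10)

    def test_fitted_deaths_unchanged(self, fits, noisy_surface):
        for name in ("APC", "M7", "PLAT"):
            fit = fits[name]
            again = apply_constraints(fit)
            w = fit.weights_ > 0
            rel = np.abs(again.fitted_deaths_[w] / fit.fitted_deaths_[w] - 1.0)
            assert rel.max() < 1e-9


class TestFitQuality:
    def test_lc_poisson_recovers_noiseless_structure(self, noiseless_surface):
        fit = fit_gapc("LC_POIS", noiseless_surface)
        err = np.abs(fit.linear_predictor() - noiseless_surface.truth_log_rates)
        assert err.max() < 1e-6

    def test_cbd_predictor_at_mean_age(self, fits, noisy_surface):
        fit = fits["CBD"]
        assert fit.alpha_ is None
        assert len(fit.kappas_) == 2
        assert np.isfinite(fit.deviance_)
        xbar = noisy_surface.ages.mean()
        eta = fit.linear_predictor()
        # interpolate the predictor to x = xbar: equals kappa1 exactly
        w_hi = xbar - np.floor(xbar)
        i_lo = int(np.floor(xbar - noisy_surface.ages[0]))
        interp = (1 - w_hi) * eta[i_lo] + w_hi * eta[i_lo + 1]
        np.testing.assert_allclose(interp, fit.kappas_[0], atol=1e-10)

    def test_apc_gamma_near_zero_on_cohort_free_data(self, noisy_surface):
        # data has no cohort effects: each gamma_hat should sit within a few
        # multiples of its Poisson noise scale 1/sqrt(deaths in the cohort)
        fit = fit_gapc("APC", noisy_surface)
        deaths_per_cohort = np.bincount(
            fit.cohort_index_.ravel(),
            weights=noisy_surface.deaths.ravel(),
            minlength=fit.cohorts_.size,
        )
        inc = fit.cohort_included_
        scale = 1.0 / np.sqrt(np.maximum(deaths_per_cohort[inc], 1.0))
        assert np.max(np.abs(fit.gamma_[inc]) / scale) < 5.0

    def test_deviance_trace_monotone(self, fits):
        for fit in fits.values():
            trace = np.array(fit.deviance_trace_)
            assert np.all(np.diff(trace) <= 1e-9)

    def test_nested_models_fit_at_least_as_well(self, fits):
        assert fits["RH"].deviance_ <= fits["APC"].deviance_ + 1e-6
        assert fits["M6"].deviance_ <= fits["CBD"].deviance_ + 1e-6
        assert fits["M7"].deviance_ <= fits["M6"].deviance_ + 1e-6

    def test_missing_counts_rejected(self, noisy_surface):
        from dataclasses import replace

        bare = replace(noisy_surface, deaths=None, exposures=None)
        with pytest.raises(MortalityDataError):
            fit_gapc("LC_POIS", bare)


class TestEstimateXc:
    def test_single_candidate_returned(self, noisy_surface):
        best, profile = estimate_xc(noisy_surface, candidates=[107])
        assert best == 107
        assert len(profile) == 1

    def test_profile_has_entry_per_candidate(self, noisy_surface):
        cands = [102, 106, 110]
        best, profile = estimate_xc(noisy_surface, candidates=cands)
        assert [c for c, _ in profile] == cands
        assert best in cands

    def test_recovers_generating_constant_age(self):
        # synthesize M8-structured data with known x_c on a coarse grid
        ages = np.arange(60, 101)
        years = np.arange(1975, 2016)
        xbar = ages.mean()
        rng = np.random.default_rng(42)
        k1 = -4.5 - 0.02 * np.arange(years.size)
        k2 = np.full(years.size, 0.09)
        cohorts = np.arange(years[0] - ages[-1], years[-1] - ages[0] + 1)
        gamma = 0.002 * np.sin(np.arange(cohorts.size) / 4.0)
        gamma -= gamma.mean()
        xc_true = 110.0
        ci = (years[None, :] - ages[:, None]) - cohorts[0]
        eta = (
            k1[None, :]
            + (ages[:, None] - xbar) * k2[None, :]
            + (xc_true - ages[:, None]) * gamma[ci]
        )
        e = np.full(eta.shape, 1e6)
        d = rng.poisson(e * np.exp(eta)).astype(float)
        from mortset import MortalitySurface

        s = MortalitySurface(ages=ages, years=years, rates=d / e, deaths=d, exposures=e)
        best, _ = estimate_xc(s, candidates=[100, 105, 110, 115, 120])
        assert best == 110
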