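"""Functional time-series mortality models.

Age-specific log mortality curves are smoothed with a penalized
regression spline on the discrete age grid (optionally with a
monotonicity constraint at old ages), decomposed by functional principal
component analysis (FPCA) into a mean curve mu(x), orthonormal
components phi_k(x) and score series beta[t, k], and forecast by
extrapolating the scores with a random walk with drift.  Variants:

* plain functional data model (FDM);
* robust FDM — years whose integrated squared error exceeds a
  chi-squared critical value get zero weight and the model is refitted;
* product-ratio — joint two-population model of sqrt(m_M m_F) and
  sqrt(m_M / m_F), whose forecasts recombine into coherent male/female
  forecasts;
* multivariate — populations stacked into one long vector per year
  before a joint FPCA;
* multilevel — a common trend R_t(x) shared by all populations plus
  population-specific residual trends U_t^j(x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .base import MortalityForecaster
from .data import MortalityDataError, MortalitySurface, PopulationSet
from .forecast import ForecastResult, gaussian_interval, rwd_forecast

__all__ = [
    "smooth_log_rates",
    "FpcaFit",
    "fit_fpca",
    "integrated_squared_error",
    "FunctionalDataModel",
    "robust_refit",
    "ProductRatioModel",
    "MultivariateFdm",
    "MultilevelFdm",
    "fit_product_ratio",
    "fit_multivariate",
    "fit_multilevel",
]


# ---------------------------------------------------------------------------
# smoothing


def _whittaker_matrix(k, lam):
    D = np.diff(np.eye(k), n=2, axis=0)  # second differences
    return np.linalg.inv(np.eye(k) + lam * (D.T @ D))


def smooth_log_rates(
    surface_or_matrix,
    lam: float = 10.0,
    monotone: bool = True,
    monotone_from: int | None = 65,
) -> np.ndarray:
    """Penalized-spline smoothing of log rates over age, per year.

    A discrete penalized regression spline (second-difference penalty on
    the age grid) is solved per year; ``lam = 0`` reproduces the input,
    very large ``lam`` approaches the least-squares straight line in
    age.  With ``monotone`` on, the fitted curve is projected onto
    non-decreasing values (pool-adjacent-violators) from
    ``monotone_from`` upwards — old-age mortality rises with age.
    """
    if isinstance(surface_or_matrix, MortalitySurface):
        ages = surface_or_matrix.ages
        Y = surface_or_matrix.log_rates()
    else:
        Y = np.asarray(surface_or_matrix, dtype=float)
        ages = np.arange(Y.shape[0])
    k = Y.shape[0]
    if k < 5:
        raise MortalityDataError("need at least 5 ages for spline smoothing")
    if lam < 0:
        raise MortalityDataError("penalty must be non-negative")
    S = _whittaker_matrix(k, lam)
    fitted = S @ Y
    if monotone:
        start = 0
        if monotone_from is not None:
            start = int(np.searchsorted(ages, monotone_from))
        iso = IsotonicRegression(increasing=True)
        xs = np.arange(k - start)
        for j in range(fitted.shape[1]):
            fitted[start:, j] = iso.fit_transform(xs, fitted[start:, j])
    return fitted


# ---------------------------------------------------------------------------
# FPCA core


@dataclass
class FpcaFit:
    """A fitted (weighted, discretized) functional principal component basis."""

    mu: np.ndarray  # (k,)
    components: np.ndarray  # (k, K), orthonormal columns
    scores: np.ndarray  # (n, K)
    weights: np.ndarray  # (n,) 0/1 year weights
    resid_var: np.ndarray  # (k,)
    log_rates: np.ndarray = field(repr=False, default=None)  # data it was fitted to

    @property
    def K(self) -> int:
        return self.components.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.mu[:, None] + self.components @ self.scores.T


def fit_fpca(log_rates, K: int, weights=None) -> FpcaFit:
    """FPCA of a k x n log-rate matrix via the weighted sample covariance.

    ``mu`` is the weighted per-age mean, the components are the top-K
    eigenvectors of the weighted covariance of the centred year-curves,
    and the scores are projections (all years, including zero-weight
    ones, are scored).
    """
    X = np.asarray(log_rates, dtype=float)
    k, n = X.shape
    if weights is None:
        weights = np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        raise MortalityDataError("all year weights are zero")
    n_eff = int(np.sum(w > 0))
    if not 0 <= K < min(k, n_eff):
        raise MortalityDataError(f"K={K} out of range for a {k} x {n_eff} fit")
    mu = (X * w[None, :]).sum(axis=1) / w.sum()
    Xc = X - mu[:, None]
    if K > 0:
        C = (Xc * w[None, :]) @ Xc.T / w.sum()
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:K]
        components = evecs[:, order]
        # sign convention: make each component's largest-|.| entry positive
        for j in range(K):
            i = np.argmax(np.abs(components[:, j]))
            if components[i, j] < 0:
                components[:, j] = -components[:, j]
        scores = Xc.T @ components
    else:
        components = np.zeros((k, 0))
        scores = np.zeros((n, 0))
    resid = Xc - components @ scores.T
    resid_var = (resid**2 * w[None, :]).sum(axis=1) / w.sum()
    return FpcaFit(mu, components, scores, w, resid_var, log_rates=X)


def integrated_squared_error(fit: FpcaFit, log_rates=None) -> np.ndarray:
    """Per-year integrated squared error of the FPCA approximation.

    ISE_t = sum_x [ln m_t(x) - mu(x) - sum_k beta[t,k] phi_k(x)]^2 with
    unit age spacing.
    """
    X = fit.log_rates if log_rates is None else np.asarray(log_rates, dtype=float)
    resid = X - fit.mu[:, None] - fit.components @ fit.scores.T
    return np.sum(resid**2, axis=0)


def _flag_outlier_years(log_rates: np.ndarray, detection_K: int, level: float):
    """Flag outlying years by a leave-one-out integrated squared error.

    Each year is scored against the rank-``detection_K`` principal
    component basis fitted WITHOUT it (so an outlier cannot mask itself
    by attracting a component), on the unsmoothed log rates (smoothing
    would project level shifts into the model space).  Squared residuals
    are standardized by a per-age robust scale, summed over ages into an
    integrated squared error, and a year is flagged when the robust
    z-score of its log error exceeds the normal critical value at the
    Bonferroni-adjusted (familywise ``level``) tail.
    """
    Y = np.asarray(log_rates, dtype=float)
    k, n = Y.shape
    resid = np.empty_like(Y)
    for j in range(n):
        w = np.ones(n)
        w[j] = 0.0
        loo = fit_fpca(Y, detection_K, weights=w)
        resid[:, j] = Y[:, j] - (loo.mu + loo.components @ loo.scores[j])
    sigma2 = np.maximum(np.median(resid**2, axis=1) / stats.chi2.median(1), 1e-12)
    ise = np.sum(resid**2 / sigma2[:, None], axis=0)
    log_ise = np.log(ise)
    center = np.median(log_ise)
    spread = 1.4826 * np.median(np.abs(log_ise - center))
    z = (log_ise - center) / max(spread, 1e-12)
    threshold = stats.norm.ppf(1.0 - (1.0 - level) / n)
    return z > threshold


# ---------------------------------------------------------------------------
# single-population estimators


class FunctionalDataModel(MortalityForecaster):
    """Functional data model (optionally robust to outlying years).

    Parameters
    ----------
    K : int
        Number of principal components (default 6).
    lam : float
        Age-smoothing penalty; 0 disables smoothing.
    monotone : bool
        Monotone projection of the smoothed curves at old ages.
    robust : bool
        Downweight outlying years by the integrated-squared-error rule.
    level : float
        Familywise confidence of the outlier cut-off (robust variant).
    detection_K : int
        Rank of the leave-one-out basis used only for outlier scoring.
    """

    def __init__(
        self,
        K: int = 6,
        lam: float = 10.0,
        monotone: bool = True,
        monotone_from: int | None = 65,
        robust: bool = False,
        level: float = 0.999,
        detection_K: int = 1,
        population: str | None = None,
    ):
        self.K = K
        self.lam = lam
        self.monotone = monotone
        self.monotone_from = monotone_from
        self.robust = robust
        self.level = level
        self.detection_K = detection_K
        self.population = population

    def _smoothed(self, s):
        if self.lam == 0 and not self.monotone:
            return s.log_rates()
        Y = s.log_rates()
        k = Y.shape[0]
        S = _whittaker_matrix(k, self.lam)
        fitted = S @ Y
        if self.monotone:
            start = 0
            if self.monotone_from is not None:
                start = int(np.searchsorted(s.ages, self.monotone_from))
            iso = IsotonicRegression(increasing=True)
            xs = np.arange(k - start)
            for j in range(fitted.shape[1]):
                fitted[start:, j] = iso.fit_transform(xs, fitted[start:, j])
        return fitted

    def fit(self, surface, y=None):
        s = self._surface_of(surface, self.population)
        Y = self._smoothed(s)
        fit = fit_fpca(Y, self.K)
        flagged = np.zeros(s.n_years, dtype=bool)
        if self.robust:
            if not 0.0 < self.level < 1.0:
                raise MortalityDataError("level must be in (0, 1)")
            flagged = _flag_outlier_years(
                s.log_rates(), self.detection_K, self.level
            )
            if flagged.all():
                raise MortalityDataError(
                    "every year flagged as outlying; raise `level`"
                )
            if flagged.any():
                fit = fit_fpca(Y, self.K, weights=(~flagged).astype(float))
        self.fpca_ = fit
        self.flagged_years_ = s.years[flagged]
        self.ages_, self.years_ = s.ages, s.years
        self.mu_, self.components_, self.scores_ = fit.mu, fit.components, fit.scores
        self.resid_var_ = fit.resid_var
        self.fitted_log_rates_ = fit.reconstruction()
        self.surface_ = s
        return self

    def forecast(self, h: int, level: float = 0.8, n_paths: int = 1000, seed: int = 0):
        self._check_fitted()
        if h < 1:
            raise MortalityDataError("horizon must be >= 1")
        point = np.tile(self.mu_, (h, 1))
        variance = np.tile(self.resid_var_, (h, 1))
        kf = {}
        retained = self.fpca_.weights > 0
        for j in range(self.fpca_.K):
            series = self.scores_[retained, j]
            mean, var = rwd_forecast(series, h)
            point = point + mean[:, None] * self.components_[None, :, j]
            variance = variance + var[:, None] * self.components_[None, :, j] ** 2
            kf[f"score{j + 1}"] = (mean, var)
        lower, upper = gaussian_interval(point, variance, level)
        name = "ROBUST_FDM" if self.robust else "FDM"
        return ForecastResult(
            ages=self.ages_,
            years=self._future_years(h),
            point=point,
            lower=lower,
            upper=upper,
            level=level,
            kappa_forecasts=kf,
            provenance={"model": name, "seed": seed},
        )


def robust_refit(surface: MortalitySurface, K: int = 6, level: float = 0.999, **kw):
    """Fit the robust FDM (outlying years get zero weight)."""
    return FunctionalDataModel(K=K, robust=True, level=level, **kw).fit(surface)


# ---------------------------------------------------------------------------
# multi-population estimators


def _score_forecast(fit: FpcaFit, h):
    """RWD forecasts of every score series; returns (point_add, var_add)."""
    k = fit.mu.size
    point = np.tile(fit.mu, (h, 1))
    variance = np.tile(fit.resid_var, (h, 1))
    retained = fit.weights > 0
    for j in range(fit.K):
        mean, var = rwd_forecast(fit.scores[retained, j], h)
        point = point + mean[:, None] * fit.components[None, :, j]
        variance = variance + var[:, None] * fit.components[None, :, j] ** 2
    return point, variance


class ProductRatioModel(MortalityForecaster):
    """Coherent two-population model of product and ratio functions.

    The square-root product p_t(x) = sqrt(m_M m_F) and square-root ratio
    r_t(x) = sqrt(m_M / m_F) of the (smoothed) rates are modeled by
    independent FDMs on the log scale; forecasts recombine as
    m_M = p * r and m_F = p / r.
    """

    multipopulation = True

    def __init__(self, K: int = 6, lam: float = 10.0, monotone: bool = True):
        self.K = K
        self.lam = lam
        self.monotone = monotone

    def fit(self, popset: PopulationSet, y=None):
        if not isinstance(popset, PopulationSet) or len(popset) != 2:
            raise MortalityDataError("product-ratio model needs exactly two populations")
        labels = popset.labels
        fdm = FunctionalDataModel(K=0, lam=self.lam, monotone=self.monotone)
        logs = {lab: fdm._smoothed(popset[lab]) for lab in labels}
        if any(np.any(~np.isfinite(v)) for v in logs.values()):
            raise MortalityDataError("non-positive rates in product-ratio input")
        lab_a, lab_b = labels
        log_p = 0.5 * (logs[lab_a] + logs[lab_b])
        log_r = 0.5 * (logs[lab_b] - logs[lab_a])  # second pop over first
        self.product_fit_ = fit_fpca(log_p, self.K)
        ratio_K = min(self.K, 3)
        if np.allclose(log_r, log_r.mean()):
            ratio_K = 0
        self.ratio_fit_ = fit_fpca(log_r, ratio_K)
        self.labels_ = labels
        self.ages_ = popset.ages
        self.years_ = popset.years
        self.fitted_log_rates_ = {
            lab_a: self.product_fit_.reconstruction() - self.ratio_fit_.reconstruction(),
            lab_b: self.product_fit_.reconstruction() + self.ratio_fit_.reconstruction(),
        }
        return self

    def forecast(self, h: int, level: float = 0.8, n_paths: int = 1000, seed: int = 0):
        """Forecast both populations; returns {label: ForecastResult}."""
        self._check_fitted()
        p_point, p_var = _score_forecast(self.product_fit_, h)
        r_point, r_var = _score_forecast(self.ratio_fit_, h)
        out = {}
        for lab, sign in ((self.labels_[0], -1.0), (self.labels_[1], 1.0)):
            point = p_point + sign * r_point
            variance = p_var + r_var  # product and ratio treated as independent
            lower, upper = gaussian_interval(point, variance, level)
            out[lab] = ForecastResult(
                ages=self.ages_,
                years=self._future_years(h),
                point=point,
                lower=lower,
                upper=upper,
                level=level,
                provenance={"model": "PRODUCT_RATIO", "population": lab, "seed": seed},
            )
        return out


class MultivariateFdm(MortalityForecaster):
    """Joint FPCA of populations stacked into one long vector per year."""

    multipopulation = True

    def __init__(self, K: int = 6, lam: float = 10.0, monotone: bool = True):
        self.K = K
        self.lam = lam
        self.monotone = monotone

    def fit(self, popset: PopulationSet, y=None):
        if not isinstance(popset, PopulationSet) or len(popset) < 1:
            raise MortalityDataError("multivariate model needs a PopulationSet")
        fdm = FunctionalDataModel(K=0, lam=self.lam, monotone=self.monotone)
        blocks = [fdm._smoothed(popset[lab]) for lab in popset.labels]
        stacked = np.vstack(blocks)
        self.fpca_ = fit_fpca(stacked, self.K)
        self.labels_ = popset.labels
        self.ages_ = popset.ages
        self.years_ = popset.years
        self.block_size_ = len(popset.ages)
        recon = self.fpca_.reconstruction()
        self.fitted_log_rates_ = {
            lab: recon[i * self.block_size_ : (i + 1) * self.block_size_]
            for i, lab in enumerate(self.labels_)
        }
        return self

    def forecast(self, h: int, level: float = 0.8, n_paths: int = 1000, seed: int = 0):
        self._check_fitted()
        point, variance = _score_forecast(self.fpca_, h)
        out = {}
        for i, lab in enumerate(self.labels_):
            sl = slice(i * self.block_size_, (i + 1) * self.block_size_)
            lower, upper = gaussian_interval(point[:, sl], variance[:, sl], level)
            out[lab] = ForecastResult(
                ages=self.ages_,
                years=self._future_years(h),
                point=point[:, sl],
                lower=lower,
                upper=upper,
                level=level,
                provenance={"model": "MULTIVARIATE", "population": lab, "seed": seed},
            )
        return out


class MultilevelFdm(MortalityForecaster):
    """Common trend plus population-specific residual trends.

    Log mortality of population j decomposes as
    mu_j(x) + R_t(x) + U_t^j(x) + e_t^j(x): a population mean curve, a
    common trend shared by all populations (FPCA of the across-population
    average of the centred curves), and a population-specific trend
    (FPCA of what remains).
    """

    multipopulation = True

    def __init__(
        self,
        K_common: int = 3,
        K_specific: int = 3,
        lam: float = 10.0,
        monotone: bool = True,
    ):
        self.K_common = K_common
        self.K_specific = K_specific
        self.lam = lam
        self.monotone = monotone

    def fit(self, popset: PopulationSet, y=None):
        if not isinstance(popset, PopulationSet) or len(popset) < 2:
            raise MortalityDataError("multilevel model needs >= 2 populations")
        n = len(popset.years)
        if self.K_common + self.K_specific >= n:
            raise MortalityDataError("K_common + K_specific must be < number of years")
        fdm = FunctionalDataModel(K=0, lam=self.lam, monotone=self.monotone)
        logs = {lab: fdm._smoothed(popset[lab]) for lab in popset.labels}
        self.mu_ = {lab: logs[lab].mean(axis=1) for lab in popset.labels}
        centred = {lab: logs[lab] - self.mu_[lab][:, None] for lab in popset.labels}
        aggregate = np.mean([centred[lab] for lab in popset.labels], axis=0)
        self.common_fit_ = fit_fpca(aggregate, self.K_common)
        R = self.common_fit_.reconstruction()
        self.specific_fits_ = {}
        self.resid_var_ = {}
        for lab in popset.labels:
            # deviation from the OBSERVED common trend (the average curve),
            # so identical populations have exactly zero specific trend
            deviation = centred[lab] - aggregate
            f = fit_fpca(deviation, self.K_specific)
            self.specific_fits_[lab] = f
            final = centred[lab] - R - f.reconstruction()
            self.resid_var_[lab] = np.mean(final**2, axis=1)
        self.labels_ = popset.labels
        self.ages_ = popset.ages
        self.years_ = popset.years
        self.fitted_log_rates_ = {
            lab: self.mu_[lab][:, None] + R + self.specific_fits_[lab].reconstruction()
            for lab in popset.labels
        }
        return self

    def forecast(self, h: int, level: float = 0.8, n_paths: int = 1000, seed: int = 0):
        self._check_fitted()
        R_point, R_var = _score_forecast(self.common_fit_, h)
        out = {}
        for lab in self.labels_:
            U_point, U_var = _score_forecast(self.specific_fits_[lab], h)
            point = self.mu_[lab][None, :] + R_point + U_point
            variance = R_var + U_var + self.resid_var_[lab][None, :]
            lower, upper = gaussian_interval(point, variance, level)
            out[lab] = ForecastResult(
                ages=self.ages_,
                years=self._future_years(h),
                point=point,
                lower=lower,
                upper=upper,
                level=level,
                provenance={"model": "MULTILEVEL", "population": lab, "seed": seed},
            )
        return out


# ---------------------------------------------------------------------------
# wrappers


def fit_product_ratio(popset: PopulationSet, K: int = 6, **kw) -> ProductRatioModel:
    return ProductRatioModel(K=K, **kw).fit(popset)


def fit_multivariate(popset: PopulationSet, K: int = 6, **kw) -> MultivariateFdm:
    return MultivariateFdm(K=K, **kw).fit(popset)


def fit_multilevel(
    popset: PopulationSet, K_common: int = 3, K_specific: int = 3, **kw
) -> MultilevelFdm:
    return MultilevelFdm(K_common=K_common, K_specific=K_specific, **kw).fit(popset)
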