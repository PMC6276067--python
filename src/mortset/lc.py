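"""Lee-Carter under Gaussian errors with the classic kappa adjustments.

ln m[x, t] = alpha(x) + beta(x) kappa(t) + eps(x, t), with alpha the
per-age mean of the log rates, (beta, kappa) from the leading singular
pair of the centred log-rate matrix, subject to sum(beta) = 1 and
sum(kappa) = 0.  Four variants differ in the second-stage adjustment of
kappa:

* ``none`` — raw SVD scores;
* ``total_deaths`` — per year, kappa re-solved so fitted total deaths
  match observed totals (the original proposal);
* ``e0`` — kappa re-solved so the fitted period life expectancy at the
  youngest age matches the observed lifetable value;
* ``deaths_distribution`` — kappa minimizes the Poisson deviance of the
  year's death counts (fit to the age distribution of deaths).

Forecasts extrapolate kappa by a random walk with drift; the interval
variance is beta(x)^2 * u[n+h|n] + v(x), the sum of score-forecast and
residual variances.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .base import MortalityForecaster
from .data import MortalityDataError, MortalitySurface
from .forecast import ForecastResult, gaussian_interval, rwd_forecast

__all__ = [
    "LeeCarterGaussian",
    "fit_lc_svd",
    "adjust_kappa",
    "period_life_expectancy",
]


def period_life_expectancy(rates, ages=None) -> float:
    """Remaining period life expectancy at the youngest age of the grid.

    Standard period lifetable with a(x) = 0.5 within each single-year
    group; the last (open-ended) group contributes 1 / m_last person
    years per survivor.
    """
    m = np.asarray(rates, dtype=float)
    if np.any(m <= 0) or np.any(~np.isfinite(m)):
        raise MortalityDataError("rates must be positive and finite")
    k = m.size
    q = m[:-1] / (1.0 + 0.5 * m[:-1])  # death probabilities below the open group
    q = np.minimum(q, 1.0)
    l = np.concatenate([[1.0], np.cumprod(1.0 - q)])  # survivors, length k
    d = -np.diff(l)
    L = l[1:] + 0.5 * d  # person-years in closed groups
    L_open = l[-1] / m[-1]
    return float((L.sum() + L_open) / l[0])


class LeeCarterGaussian(MortalityForecaster):
    """SVD Lee-Carter with an optional second-stage kappa adjustment.

    Parameters
    ----------
    adjustment : {"none", "total_deaths", "e0", "deaths_distribution"}
        Second-stage refit of the period index (see module docstring).
    population : str or None
        Which member of a PopulationSet to fit (single-population model).
    """

    def __init__(self, adjustment: str = "none", population: str | None = None):
        self.adjustment = adjustment
        self.population = population

    def fit(self, surface, y=None):
        s = self._surface_of(surface, self.population)
        if s.n_years < 2:
            raise MortalityDataError("need at least 2 years to fit Lee-Carter")
        log_m = s.log_rates()
        alpha = log_m.mean(axis=1)
        centered = log_m - alpha[:, None]
        U, S, Vt = np.linalg.svd(centered, full_matrices=False)
        beta = U[:, 0]
        kappa = S[0] * Vt[0]
        # normalize: sum(beta) = 1
        scale = beta.sum()
        if abs(scale) < 1e-12:
            raise MortalityDataError("degenerate first principal component")
        beta = beta / scale
        kappa = kappa * scale
        kappa = kappa - kappa.mean()
        # sign convention: fitted drift of kappa <= 0 (declining mortality)
        if np.polyfit(np.arange(kappa.size), kappa, 1)[0] > 0:
            beta, kappa = -beta, -kappa

        self.ages_, self.years_ = s.ages, s.years
        self.alpha_, self.beta_, self.kappa_ = alpha, beta, kappa
        self.surface_ = s
        self._finalize(log_m)
        if self.adjustment != "none":
            self.kappa_ = _adjusted_kappa(self, s, self.adjustment)
            self._finalize(log_m)
        return self

    def _finalize(self, log_m):
        fitted = self.alpha_[:, None] + np.outer(self.beta_, self.kappa_)
        self.residuals_ = log_m - fitted
        self.resid_var_ = np.mean(self.residuals_**2, axis=1)
        self.fitted_log_rates_ = fitted

    def forecast(self, h: int, level: float = 0.8, n_paths: int = 1000, seed: int = 0):
        self._check_fitted()
        if h < 1:
            raise MortalityDataError("horizon must be >= 1")
        mean, var = rwd_forecast(self.kappa_, h)
        point = self.alpha_[None, :] + mean[:, None] * self.beta_[None, :]
        variance = (self.beta_[None, :] ** 2) * var[:, None] + self.resid_var_[None, :]
        lower, upper = gaussian_interval(point, variance, level)
        return ForecastResult(
            ages=self.ages_,
            years=self._future_years(h),
            point=point,
            lower=lower,
            upper=upper,
            level=level,
            kappa_forecasts={"kappa": (mean, var)},
            provenance={"model": f"LC[{self.adjustment}]", "seed": seed},
        )


# ---------------------------------------------------------------------------
# kappa adjustments


def _solve_total_deaths(alpha, beta, e_col, d_col, kappa0):
    target = d_col.sum()

    def f(kap):
        return e_col @ np.exp(alpha + beta * kap) - target

    return _bracketed_root(f, kappa0)


def _solve_e0(alpha, beta, observed_e0, kappa0):
    def f(kap):
        return period_life_expectancy(np.exp(alpha + beta * kap)) - observed_e0

    return _bracketed_root(f, kappa0)


def _bracketed_root(f, kappa0, half_width=50.0):
    lo, hi = kappa0 - half_width, kappa0 + half_width
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if np.sign(flo) == np.sign(fhi):
        raise MortalityDataError("kappa adjustment root not bracketed within +/- 50")
    return optimize.brentq(f, lo, hi, xtol=1e-10)


def _solve_deaths_distribution(alpha, beta, e_col, d_col, kappa0):
    def deviance(kap):
        mu = e_col * np.exp(alpha + beta * kap)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(d_col > 0, d_col * np.log(d_col / mu), 0.0)
        return 2.0 * np.sum(term - (d_col - mu))

    res = optimize.minimize_scalar(
        deviance, bounds=(kappa0 - 50.0, kappa0 + 50.0), method="bounded",
        options={"xatol": 1e-10},
    )
    return res.x


def _adjusted_kappa(fit: LeeCarterGaussian, surface: MortalitySurface, method: str):
    alpha, beta = fit.alpha_, fit.beta_
    kappa = fit.kappa_.copy()
    needs_counts = method in ("total_deaths", "deaths_distribution")
    if needs_counts and (surface.deaths is None or surface.exposures is None):
        raise MortalityDataError(f"adjustment {method!r} needs deaths and exposures")
    for j in range(surface.n_years):
        if method == "total_deaths":
            kappa[j] = _solve_total_deaths(
                alpha, beta, surface.exposures[:, j], surface.deaths[:, j], kappa[j]
            )
        elif method == "deaths_distribution":
            kappa[j] = _solve_deaths_distribution(
                alpha, beta, surface.exposures[:, j], surface.deaths[:, j], kappa[j]
            )
        elif method == "e0":
            observed = period_life_expectancy(np.exp(surface.log_rates()[:, j]))
            kappa[j] = _solve_e0(alpha, beta, observed, kappa[j])
        else:
            raise MortalityDataError(f"unknown adjustment {method!r}")
    # the adjusted level is meaningful: no re-centering
    return kappa


# ---------------------------------------------------------------------------
# functional wrappers


def fit_lc_svd(surface: MortalitySurface) -> LeeCarterGaussian:
    """Fit the unadjusted SVD Lee-Carter model."""
    return LeeCarterGaussian(adjustment="none").fit(surface)


def adjust_kappa(fit: LeeCarterGaussian, surface: MortalitySurface, method: str):
    """Return a copy of ``fit`` with kappa re-solved by ``method``."""
    if method == "none":
        return fit
    out = LeeCarterGaussian(adjustment=method, population=fit.population)
    out.ages_, out.years_ = fit.ages_, fit.years_
    out.alpha_, out.beta_ = fit.alpha_.copy(), fit.beta_.copy()
    out.kappa_ = fit.kappa_.copy()
    out.surface_ = surface
    out.kappa_ = _adjusted_kappa(out, surface, method)
    out._finalize(surface.log_rates())
    return out
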