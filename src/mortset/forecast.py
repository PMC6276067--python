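"""Index dynamics and the forecast container.

Period indexes (principal component scores, kappa series) are
extrapolated by a random walk with drift; families with several period
indexes use a multivariate random walk with drift; cohort indexes follow
an ARIMA model selected by AIC.  Point and interval forecasts for every
model are assembled into :class:`ForecastResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ForecastResult",
    "rwd_forecast",
    "mrwd_forecast",
    "cohort_forecast",
]


class ForecastError(ValueError):
    pass


@dataclass
class ForecastResult:
    """Point and symmetric interval forecasts of log mortality rates.

    ``point``, ``lower`` and ``upper`` are (H, k) matrices over horizons
    1..H and the k ages of the fitted surface; ``level`` is the nominal
    coverage 1 - alpha of the central interval.
    """

    ages: np.ndarray
    years: np.ndarray  # forecast calendar years, length H
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    kappa_forecasts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.point = np.asarray(self.point, float)
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        if not (self.point.shape == self.lower.shape == self.upper.shape):
            raise ForecastError("point/lower/upper shapes differ")
        if np.any(self.lower > self.point + 1e-12) or np.any(self.point > self.upper + 1e-12):
            raise ForecastError("interval bounds must bracket the point forecast")

    @property
    def horizons(self) -> np.ndarray:
        return np.arange(1, self.point.shape[0] + 1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format serialization: model,population,year,age,point,lower,upper,level."""
        H, k = self.point.shape
        return pd.DataFrame(
            {
                "model": self.provenance.get("model", ""),
                "population": self.provenance.get("population", ""),
                "year": np.repeat(self.years, k),
                "age": np.tile(self.ages, H),
                "point": self.point.ravel(),
                "lower": self.lower.ravel(),
                "upper": self.upper.ravel(),
                "level": self.level,
            }
        )


# ---------------------------------------------------------------------------
# random walk with drift


def rwd_forecast(series, h: int):
    """Random-walk-with-drift forecast of a scalar index series.

    Returns ``(mean, variance)`` arrays over horizons 1..h, where the
    conditional variance includes the drift-estimation term:
    ``u[h] = sigma^2 * h * (1 + h / (n - 1))`` with ``sigma^2`` the MLE
    of the innovation variance from the n - 1 first differences.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 3:
        raise ForecastError("need at least 3 observations for RWD")
    if h < 1:
        raise ForecastError("horizon must be >= 1")
    diffs = np.diff(series)
    drift = diffs.mean()
    sigma2 = np.mean((diffs - drift) ** 2)
    steps = np.arange(1, h + 1, dtype=float)
    mean = series[-1] + steps * drift
    variance = sigma2 * steps * (1.0 + steps / (n - 1))
    return mean, variance


def mrwd_forecast(series_matrix, h: int, n_paths: int, seed: int):
    """Simulate joint paths of q index series under a multivariate RWD.

    ``series_matrix`` is (q, n).  Returns an array of shape
    ``(n_paths, h, q)`` of simulated future values.
    """
    X = np.atleast_2d(np.asarray(series_matrix, dtype=float))
    q, n = X.shape
    if n < q + 2:
        raise ForecastError(f"need at least {q + 2} time points for a {q}-variate RWD")
    if h < 1:
        raise ForecastError("horizon must be >= 1")
    diffs = np.diff(X, axis=1)  # (q, n-1)
    drift = diffs.mean(axis=1)
    centered = diffs - drift[:, None]
    cov = centered @ centered.T / (n - 1)
    rng = np.random.default_rng(seed)
    # allow singular covariance (e.g. deterministic series)
    try:
        L = np.linalg.cholesky(cov + 1e-14 * np.eye(q) * max(np.trace(cov), 1.0))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n_paths, h, q))
    innov = z @ L.T
    if np.allclose(cov, 0.0):
        innov = np.zeros_like(innov)
    steps = drift[None, None, :] + innov
    return X[:, -1][None, None, :] + np.cumsum(steps, axis=1)


def cohort_forecast(gamma, h_cohorts: int, n_paths: int, seed: int):
    """Simulate future cohort-effect paths with an AIC-selected ARIMA.

    Orders p, q in {0, 1, 2} and d in {0, 1} are scanned; if estimation
    fails for every candidate the forecast falls back to a random walk
    with drift (with a logged warning).  Returns (n_paths, h_cohorts).
    """
    from statsmodels.tsa.arima.model import ARIMA

    gamma = np.asarray(gamma, dtype=float)
    if gamma.size < 10:
        raise ForecastError("need at least 10 cohort observations")
    if h_cohorts < 1:
        raise ForecastError("h_cohorts must be >= 1")
    if np.allclose(gamma, gamma[0]):
        return np.full((n_paths, h_cohorts), gamma[0])
    best = None
    best_aic = np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in (0, 1):
            for p in (0, 1, 2):
                for q in (0, 1, 2):
                    if p == q == 0 and d == 0:
                        continue
                    try:
                        res = ARIMA(
                            gamma, order=(p, d, q), trend="c" if d == 0 else "n"
                        ).fit(method_kwargs={"maxiter": 200})
                        if np.isfinite(res.aic) and res.aic < best_aic:
                            best_aic = res.aic
                            best = res
                    except Exception:
                        continue
    rng = np.random.default_rng(seed)
    if best is None:
        warnings.warn("ARIMA selection failed for cohort index; falling back to RWD")
        mean, var = rwd_forecast(gamma, h_cohorts)
        z = rng.standard_normal((n_paths, h_cohorts))
        return mean[None, :] + np.sqrt(var)[None, :] * z
    sims = best.simulate(
        nsimulations=h_cohorts,
        repetitions=n_paths,
        anchor="end",
        random_state=np.random.RandomState(seed % (2**32 - 1)),
    )
    sims = np.asarray(sims)
    if sims.ndim == 3:  # (h, 1, reps)
        sims = sims[:, 0, :]
    return sims.T  # (n_paths, h)


def cohort_order_selection(gamma):
    """Return the (p, d, q) order the AIC scan selects (for diagnostics)."""
    from statsmodels.tsa.arima.model import ARIMA

    gamma = np.asarray(gamma, dtype=float)
    best_order, best_aic = None, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in (0, 1):
            for p in (0, 1, 2):
                for q in (0, 1, 2):
                    if p == q == 0 and d == 0:
                        continue
                    try:
                        res = ARIMA(
                            gamma, order=(p, d, q), trend="c" if d == 0 else "n"
                        ).fit(method_kwargs={"maxiter": 200})
                        if np.isfinite(res.aic) and res.aic < best_aic:
                            best_aic, best_order = res.aic, (p, d, q)
                    except Exception:
                        continue
    return best_order


def gaussian_interval(point, variance, level: float):
    """Symmetric Gaussian bounds around a point forecast."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(np.maximum(variance, 0.0))
    return point - half, point + half
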