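"""Synthetic mortality surfaces with known ground truth.

The generator follows the log-bilinear structure that the model pool is
built around: an age profile ``alpha(x)`` plus an age loading ``beta(x)``
times a random-walk-with-drift period index ``kappa(t)`` (optionally a
cohort effect), with Poisson death counts given exposures.  Defaults
emulate a retirement-age mortality panel: ages 60..100 (41 groups, the
last open-ended), years 1975..2015, two sexes with correlated declining
trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import MortalityDataError, MortalitySurface, PopulationSet

__all__ = [
    "GroundTruth",
    "simulate_surface",
    "simulate_population_set",
    "inject_outlier_years",
]

DEFAULT_AGES = np.arange(60, 101)
DEFAULT_YEARS = np.arange(1975, 2016)


def _default_alpha(ages):
    # Gompertz-like line on the log scale
    return -9.0 + 0.09 * (np.asarray(ages, dtype=float) - 60.0)


@dataclass
class GroundTruth:
    """Generating parameters for a synthetic mortality surface.

    ``beta`` is normalized to sum to 1; ``kappa`` is a random walk with
    drift ``kappa_drift`` (negative for declining mortality) and
    innovation SD ``kappa_sigma``, centred to sum to zero as in the
    fitted models' identification constraints.
    """

    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    kappa_drift: float = -0.5
    kappa_sigma: float = 0.3
    gamma: np.ndarray | None = None
    exposure_scale: float = 1e5
    sex_gap: float = 0.0
    seed: int = 0

    def resolve(self, ages, rng):
        ages = np.asarray(ages, dtype=int)
        k = len(ages)
        alpha = _default_alpha(ages) if self.alpha is None else np.asarray(self.alpha, float)
        if self.beta is None:
            beta = rng.uniform(0.5, 1.5, size=k)
        else:
            beta = np.asarray(self.beta, float)
        beta = beta / beta.sum()
        if alpha.shape != (k,) or beta.shape != (k,):
            raise MortalityDataError("alpha/beta length must match ages")
        if self.exposure_scale <= 0:
            raise MortalityDataError("exposure_scale must be positive")
        if abs(beta.sum() - 1.0) > 1e-12:
            raise MortalityDataError("beta must be normalizable")
        return alpha, beta


def _kappa_path(n, drift, sigma, rng):
    steps = drift + sigma * rng.standard_normal(n - 1)
    kappa = np.concatenate([[0.0], np.cumsum(steps)])
    return kappa - kappa.mean()


def _log_rates(truth, alpha, beta, kappa, ages, years, offset=0.0):
    log_m = alpha[:, None] + np.outer(beta, kappa) + offset
    if truth.gamma is not None:
        gamma = np.asarray(truth.gamma, float)
        cohorts = years[None, :] - ages[:, None]
        c0 = years[0] - ages[-1]
        n_cohorts = len(ages) + len(years) - 1
        if gamma.shape != (n_cohorts,):
            raise MortalityDataError(f"gamma must have length {n_cohorts}")
        log_m = log_m + gamma[cohorts - c0]
    return log_m


def _observe(log_m, truth, ages, years, label, deterministic, rng):
    ages = np.asarray(ages, int)
    years = np.asarray(years, int)
    m = np.exp(log_m)
    exposures = np.full_like(m, float(truth.exposure_scale))
    if deterministic:
        deaths = exposures * m
        rates = m.copy()
    else:
        deaths = rng.poisson(exposures * m).astype(float)
        rates = deaths / exposures
    return MortalitySurface(
        ages=ages,
        years=years,
        rates=rates,
        deaths=deaths,
        exposures=exposures,
        label=label,
        open_ended=bool(ages[-1] >= 100),
        zero_cells=(deaths == 0),
    )


def simulate_surface(
    truth: GroundTruth,
    ages=DEFAULT_AGES,
    years=DEFAULT_YEARS,
    deterministic: bool = False,
    label: str = "synthetic",
) -> MortalitySurface:
    """Simulate one mortality surface from the ground truth.

    With ``deterministic=True``, Poisson sampling is replaced by the
    expected rates ``exp(alpha + beta kappa (+ gamma))`` exactly,
    enabling exact-recovery tests.
    """
    ages = np.asarray(ages, int)
    years = np.asarray(years, int)
    if len(ages) == 0 or len(years) == 0:
        raise MortalityDataError("empty age or year range")
    rng = np.random.default_rng(truth.seed)
    alpha, beta = truth.resolve(ages, rng)
    kappa = _kappa_path(len(years), truth.kappa_drift, truth.kappa_sigma, rng)
    log_m = _log_rates(truth, alpha, beta, kappa, ages, years)
    surface = _observe(log_m, truth, ages, years, label, deterministic, rng)
    surface.truth_kappa = kappa
    surface.truth_alpha = alpha
    surface.truth_beta = beta
    surface.truth_log_rates = log_m
    return surface


def simulate_population_set(
    truth: GroundTruth,
    n_pops: int = 2,
    cross_corr: float = 0.8,
    ages=DEFAULT_AGES,
    years=DEFAULT_YEARS,
    deterministic: bool = False,
    labels=None,
) -> PopulationSet:
    """Simulate correlated subpopulations sharing a common trend.

    Each population's kappa increments mix a common innovation with an
    idiosyncratic one so that ``corr(d kappa_i, d kappa_j) = cross_corr``.
    The first two populations are offset by ``+/- sex_gap / 2`` on the
    log scale (a male/female-style gap).
    """
    if n_pops < 2:
        raise MortalityDataError("need at least 2 populations")
    if not 0.0 <= cross_corr <= 1.0:
        raise MortalityDataError("cross_corr must be in [0, 1]")
    ages = np.asarray(ages, int)
    years = np.asarray(years, int)
    n = len(years)
    rng = np.random.default_rng(truth.seed)
    alpha, beta = truth.resolve(ages, rng)
    if labels is None:
        labels = ["F", "M"] if n_pops == 2 else [f"pop{i}" for i in range(n_pops)]
    common = rng.standard_normal(n - 1)
    surfaces = {}
    for i, lab in enumerate(labels):
        idio = rng.standard_normal(n - 1)
        z = np.sqrt(cross_corr) * common + np.sqrt(1.0 - cross_corr) * idio
        steps = truth.kappa_drift + truth.kappa_sigma * z
        kappa = np.concatenate([[0.0], np.cumsum(steps)])
        kappa -= kappa.mean()
        offset = 0.0
        if n_pops == 2:
            offset = (-0.5 if i == 0 else 0.5) * truth.sex_gap
        log_m = _log_rates(truth, alpha, beta, kappa, ages, years, offset=offset)
        s = _observe(log_m, truth, ages, years, lab, deterministic, rng)
        s.truth_kappa = kappa
        s.truth_log_rates = log_m
        surfaces[lab] = s
    return PopulationSet(surfaces)


def inject_outlier_years(surface: MortalitySurface, years, shift: float) -> MortalitySurface:
    """Shift the log rates of the listed years by ``shift`` (additively).

    Deaths are rescaled consistently so rates remain deaths/exposures.
    """
    years = list(years)
    rates = surface.rates.copy()
    deaths = None if surface.deaths is None else surface.deaths.copy()
    factor = np.exp(shift)
    for y in years:
        j = surface.year_index(y)  # raises for unknown year
        rates[:, j] *= factor
        if deaths is not None:
            deaths[:, j] *= factor
    out = MortalitySurface(
        ages=surface.ages,
        years=surface.years,
        rates=rates,
        deaths=deaths,
        exposures=None if surface.exposures is None else surface.exposures.copy(),
        label=surface.label,
        open_ended=surface.open_ended,
    )
    return out
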