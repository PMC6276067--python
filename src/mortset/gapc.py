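"""The Poisson generalized age-period-cohort (GAPC) model family.

Predictor structure (log link, deaths ~ Poisson(e * exp(eta))):

    eta[x, t] = alpha(x) + sum_i f_i(x) kappa_i(t) + g(x) gamma(t - x)

where each age-modulating function f_i is either an estimated loading
beta_i(x) or a fixed function of age, and the cohort modulator g is
absent, the constant 1, an estimated loading, or (x_c - x).  The family
covers the Lee-Carter model with Poisson errors, the Renshaw-Haberman
model, the age-period-cohort model, the Cairns-Blake-Dowd model and its
cohort extensions M6/M7/M8, and the Plat model.

Estimation is by alternating one-dimensional Newton updates of each
parameter vector (the standard Poisson log-bilinear scheme), with step
halving whenever a sweep fails to decrease the deviance, followed by
predictor-invariant identifiability transformations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .base import MortalityForecaster
from .data import MortalityDataError, MortalitySurface
from .forecast import ForecastResult, cohort_forecast, mrwd_forecast, rwd_forecast

__all__ = [
    "GapcSpec",
    "GAPC",
    "GAPC_NAMES",
    "fit_gapc",
    "apply_constraints",
    "estimate_xc",
]

GAPC_NAMES = ("LC_POIS", "RH", "APC", "CBD", "M6", "M7", "M8", "PLAT")

_MIN_COHORT_OBS = 3  # cohorts seen fewer times are excluded from the fit


@dataclass
class GapcSpec:
    """Structural description of one GAPC predictor.

    ``period_terms`` lists the age-modulating functions of the period
    indexes: the string ``"est"`` for an estimated loading, otherwise a
    callable of the age vector.  ``cohort_modulator`` is ``None`` (no
    cohort term), ``"one"``, ``"est"``, or ``"xc_minus_x"`` (M8).
    ``gamma_transfer_degree`` is the polynomial degree of the cohort
    constraint set (-1 none, 0: sum gamma = 0, 1: + sum c gamma = 0,
    2: + sum c^2 gamma = 0).
    """

    name: str
    static_age: bool
    period_terms: tuple
    cohort_modulator: str | None
    gamma_transfer_degree: int
    center_kappas: tuple = ()  # indexes of fixed-modulator kappas centred into alpha


def _xbar(ages):
    return float(np.mean(ages))


def _spec(name: str) -> GapcSpec:
    one = lambda x: np.ones_like(x, dtype=float)
    if name == "LC_POIS":
        return GapcSpec(name, True, ("est",), None, -1)
    if name == "RH":
        return GapcSpec(name, True, ("est",), "est", 0)
    if name == "APC":
        return GapcSpec(name, True, (one,), "one", 1, center_kappas=(0,))
    if name == "CBD":
        return GapcSpec(name, False, (one, lambda x: x - _xbar(x)), None, -1)
    if name == "M6":
        return GapcSpec(name, False, (one, lambda x: x - _xbar(x)), "one", 1)
    if name == "M7":

        def quad(x):
            d = x - _xbar(x)
            return d**2 - np.mean(d**2)

        return GapcSpec(name, False, (one, lambda x: x - _xbar(x), quad), "one", 2)
    if name == "M8":
        return GapcSpec(name, False, (one, lambda x: x - _xbar(x)), "xc_minus_x", 0)
    if name == "PLAT":
        return GapcSpec(
            name,
            True,
            (one, lambda x: _xbar(x) - x, lambda x: np.maximum(_xbar(x) - x, 0.0)),
            "one",
            2,
            center_kappas=(0, 1, 2),
        )
    raise MortalityDataError(f"unknown GAPC model {name!r}; choose from {GAPC_NAMES}")


def _poisson_deviance(d, mu, w):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(d / mu), 0.0)
    return float(2.0 * np.sum(w * (term - (d - mu))))


class GAPC(MortalityForecaster):
    """A Poisson GAPC mortality model.

    Parameters
    ----------
    name : str
        One of LC_POIS, RH, APC, CBD, M6, M7, M8, PLAT.
    xc : float or None
        Fixed constant age for the M8 cohort modulator; None triggers
        profile estimation over integer candidates above the age range.
    max_iter, tol : int, float
        Iteration cap and relative-deviance convergence tolerance of the
        alternating Newton scheme.
    population : str or None
        Which member of a PopulationSet to fit.
    """

    def __init__(
        self,
        name: str = "LC_POIS",
        xc: float | None = None,
        max_iter: int = 500,
        tol: float = 1e-6,
        population: str | None = None,
    ):
        self.name = name
        self.xc = xc
        self.max_iter = max_iter
        self.tol = tol
        self.population = population

    # ------------------------------------------------------------------
    def fit(self, surface, y=None):
        s = self._surface_of(surface, self.population)
        if s.deaths is None or s.exposures is None:
            raise MortalityDataError("GAPC models need deaths and exposures")
        if np.isnan(s.deaths).any() or np.isnan(s.exposures).any():
            raise MortalityDataError("NaNs in deaths or exposures")
        spec = _spec(self.name)
        if self.name == "M8" and self.xc is None:
            xc, profile = estimate_xc(s)
            self.xc_ = float(xc)
            self.xc_profile_ = profile
        elif self.name == "M8":
            self.xc_ = float(self.xc)
        self._fit_surface(s, spec, init=None)
        _constrain(self, spec)
        self._refresh_fit(s)
        return self

    # core alternating-Newton fit --------------------------------------
    def _fit_surface(self, s: MortalitySurface, spec: GapcSpec, init):
        ages = s.ages.astype(float)
        years = s.years.astype(float)
        k, n = s.n_ages, s.n_years
        D, E = s.deaths, s.exposures
        W = np.ones((k, n))

        # cohort bookkeeping
        has_cohort = spec.cohort_modulator is not None
        ci = (np.arange(n)[None, :] - np.arange(k)[:, None]) + (k - 1)  # 0..n+k-2
        cohorts = np.arange(int(s.years[0] - s.ages[-1]), int(s.years[-1] - s.ages[0]) + 1)
        n_coh = cohorts.size
        counts = np.bincount(ci.ravel(), minlength=n_coh)
        included = counts >= _MIN_COHORT_OBS
        if has_cohort:
            W = W * included[ci]

        # initial parameters
        if init is None and spec.name == "RH":
            pre = GAPC(name="APC", max_iter=self.max_iter, tol=self.tol)
            pre._fit_surface(s, _spec("APC"), init=None)
            init = {
                "alpha": pre.alpha_.copy(),
                "betas": {0: np.ones(k)},
                "kappas": [pre.kappas_[0].copy()],
                "beta0": np.ones(k),
                "gamma": pre.gamma_.copy(),
            }
        if init is None and spec.name in ("M6", "M7", "M8"):
            pre_name = "CBD" if spec.name in ("M6", "M8") else "M6"
            pre = GAPC(name=pre_name, max_iter=self.max_iter, tol=self.tol)
            pre._fit_surface(s, _spec(pre_name), init=None)
            kaps = [kk.copy() for kk in pre.kappas_]
            while len(kaps) < len(spec.period_terms):
                kaps.append(np.zeros(n))
            init = {
                "alpha": None,
                "betas": {},
                "kappas": kaps,
                "beta0": None,
                "gamma": pre.gamma_.copy() if pre.gamma_ is not None else np.zeros(n_coh),
            }

        log_m = s.log_rates()
        alpha = log_m.mean(axis=1) if spec.static_age else None
        betas = {}
        mods = []
        for i, term in enumerate(spec.period_terms):
            if term == "est":
                betas[i] = np.full(k, 1.0 / k)
                mods.append(None)
            else:
                mods.append(term(ages))
        kappas = [np.zeros(n) for _ in spec.period_terms]
        beta0 = np.full(k, 1.0 / k) if spec.cohort_modulator == "est" else None
        gamma = np.zeros(n_coh) if has_cohort else None
        if spec.cohort_modulator == "one":
            gmod = np.ones(k)
        elif spec.cohort_modulator == "xc_minus_x":
            gmod = self.xc_ - ages
        else:
            gmod = None

        if init is not None:
            if init.get("alpha") is not None:
                alpha = init["alpha"]
            for i, b in init.get("betas", {}).items():
                betas[i] = b
            for i, kk in enumerate(init.get("kappas", [])):
                kappas[i] = kk
            if init.get("beta0") is not None:
                beta0 = init["beta0"]
            if init.get("gamma") is not None and has_cohort:
                gamma = init["gamma"].copy()
                gamma[~included] = 0.0

        state = {"alpha": alpha, "betas": betas, "kappas": kappas, "beta0": beta0, "gamma": gamma}

        def predictor(st):
            eta = np.zeros((k, n))
            if st["alpha"] is not None:
                eta += st["alpha"][:, None]
            for i in range(len(spec.period_terms)):
                B = st["betas"][i] if i in st["betas"] else mods[i]
                eta += np.outer(B, st["kappas"][i])
            if has_cohort:
                G = st["beta0"] if st["beta0"] is not None else gmod
                eta += G[:, None] * st["gamma"][ci]
            return eta

        def sweep(st, damp):
            """One damped Newton pass over all parameter blocks (in place)."""
            eta = predictor(st)
            mu = E * np.exp(eta)
            if st["alpha"] is not None:
                num = np.sum(W * (D - mu), axis=1)
                den = np.sum(W * mu, axis=1)
                st["alpha"] += damp * np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
                mu = E * np.exp(predictor(st))
            for i in range(len(spec.period_terms)):
                B = st["betas"][i] if i in st["betas"] else mods[i]
                num = B @ (W * (D - mu))
                den = (B**2) @ (W * mu)
                st["kappas"][i] += damp * np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
                mu = E * np.exp(predictor(st))
                if i in st["betas"]:
                    kk = st["kappas"][i]
                    num = (W * (D - mu)) @ kk
                    den = (W * mu) @ (kk**2)
                    st["betas"][i] += damp * np.where(
                        den > 0, num / np.maximum(den, 1e-300), 0.0
                    )
                    # predictor-invariant rescale for numerical stability
                    tot = st["betas"][i].sum()
                    if abs(tot) > 1e-8:
                        st["betas"][i] /= tot
                        st["kappas"][i] *= tot
                    mu = E * np.exp(predictor(st))
            if has_cohort:
                G = st["beta0"] if st["beta0"] is not None else gmod
                resid = (G[:, None] * W * (D - mu)).ravel()
                curv = ((G**2)[:, None] * W * mu).ravel()
                num = np.bincount(ci.ravel(), weights=resid, minlength=n_coh)
                den = np.bincount(ci.ravel(), weights=curv, minlength=n_coh)
                delta = np.where((den > 0) & included, num / np.maximum(den, 1e-300), 0.0)
                st["gamma"] += damp * delta
                mu = E * np.exp(predictor(st))
                if st["beta0"] is not None:
                    Gam = st["gamma"][ci]
                    num = np.sum(Gam * W * (D - mu), axis=1)
                    den = np.sum(Gam**2 * W * mu, axis=1)
                    st["beta0"] += damp * np.where(
                        den > 0, num / np.maximum(den, 1e-300), 0.0
                    )

        dev = _poisson_deviance(D, E * np.exp(predictor(state)), W)
        self.deviance_trace_ = [dev]
        converged = False
        for _ in range(self.max_iter):
            accepted = False
            for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
                trial = copy.deepcopy(state)
                sweep(trial, damp)
                new_dev = _poisson_deviance(D, E * np.exp(predictor(trial)), W)
                if new_dev <= dev + 1e-12:
                    state, accepted = trial, True
                    break
            if not accepted:
                break
            self.deviance_trace_.append(new_dev)
            if dev - new_dev < self.tol * max(abs(dev), 1.0):
                dev = new_dev
                converged = True
                break
            dev = new_dev

        self.spec_ = spec
        self.ages_, self.years_ = s.ages, s.years
        self.alpha_ = state["alpha"]
        self.beta_mods_ = mods
        self.betas_ = state["betas"]
        self.kappas_ = state["kappas"]
        self.beta0_ = state["beta0"]
        self.gamma_ = state["gamma"]
        self.gamma_mod_ = gmod
        self.cohorts_ = cohorts
        self.cohort_included_ = included
        self.cohort_index_ = ci
        self.weights_ = W
        self.deviance_ = dev
        self.converged_ = converged
        self.n_iter_ = len(self.deviance_trace_) - 1
        self.surface_ = s
        return self

    # ------------------------------------------------------------------
    def linear_predictor(self) -> np.ndarray:
        """Fitted eta[x, t] on the training grid."""
        k, n = len(self.ages_), len(self.years_)
        eta = np.zeros((k, n))
        if self.alpha_ is not None:
            eta += self.alpha_[:, None]
        for i in range(len(self.kappas_)):
            B = self.betas_[i] if i in self.betas_ else self.beta_mods_[i]
            eta += np.outer(B, self.kappas_[i])
        if self.gamma_ is not None:
            G = self.beta0_ if self.beta0_ is not None else self.gamma_mod_
            eta += G[:, None] * self.gamma_[self.cohort_index_]
        return eta

    def _refresh_fit(self, s):
        eta = self.linear_predictor()
        self.fitted_log_rates_ = eta
        self.fitted_deaths_ = s.exposures * np.exp(eta)

    # ------------------------------------------------------------------
    def forecast(self, h: int, level: float = 0.8, n_paths: int = 1000, seed: int = 0):
        """Simulation-based point and interval forecasts.

        Period indexes follow a joint (multivariate) random walk with
        drift; the cohort index follows an AIC-selected ARIMA.  The
        point forecast is the mean simulated log rate, the bounds are
        the empirical alpha/2 and 1 - alpha/2 quantiles.
        """
        self._check_fitted()
        if h < 1:
            raise MortalityDataError("horizon must be >= 1")
        ss = np.random.SeedSequence(seed)
        s_period, s_cohort = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2)]
        k = len(self.ages_)
        K = np.vstack(self.kappas_)  # (q, n)
        paths = mrwd_forecast(K, h, n_paths, s_period)  # (n_paths, h, q)

        eta = np.zeros((n_paths, h, k))
        if self.alpha_ is not None:
            eta += self.alpha_[None, None, :]
        for i in range(K.shape[0]):
            B = self.betas_[i] if i in self.betas_ else self.beta_mods_[i]
            eta += paths[:, :, i][:, :, None] * B[None, None, :]

        if self.gamma_ is not None:
            G = self.beta0_ if self.beta0_ is not None else self.gamma_mod_
            inc = np.where(self.cohort_included_)[0]
            c_last = int(self.cohorts_[inc[-1]])
            future_years = self._future_years(h)
            max_needed = int(future_years[-1] - self.ages_[0])
            n_future = max_needed - c_last
            gpaths = None
            if n_future > 0:
                gseries = self.gamma_[inc]
                gpaths = cohort_forecast(gseries, n_future, n_paths, s_cohort)
            gmat = np.zeros((n_paths, h, k))
            for j, year in enumerate(future_years):
                c = int(year) - self.ages_.astype(int)  # per age
                for a in range(k):
                    if c[a] <= c_last:
                        idx = c[a] - int(self.cohorts_[0])
                        gmat[:, j, a] = self.gamma_[idx]
                    else:
                        gmat[:, j, a] = gpaths[:, c[a] - c_last - 1]
            eta += gmat * G[None, None, :]

        alpha_tail = 1.0 - level
        point = eta.mean(axis=0)
        lower = np.quantile(eta, alpha_tail / 2.0, axis=0)
        upper = np.quantile(eta, 1.0 - alpha_tail / 2.0, axis=0)
        lower = np.minimum(lower, point)
        upper = np.maximum(upper, point)
        kf = {}
        for i in range(K.shape[0]):
            mean, var = rwd_forecast(K[i], h)
            kf[f"kappa{i + 1}"] = (mean, var)
        return ForecastResult(
            ages=self.ages_,
            years=self._future_years(h),
            point=point,
            lower=lower,
            upper=upper,
            level=level,
            kappa_forecasts=kf,
            provenance={"model": self.name, "seed": seed, "n_paths": n_paths},
        )


# ---------------------------------------------------------------------------
# identifiability constraints


def _poly_transfer(gamma, cohorts, included, degree):
    """Least-squares polynomial of ``degree`` in cohort over included cohorts.

    Returns the raw-coefficient vector phi (length degree + 1) such that
    subtracting phi(c) from gamma makes the residuals orthogonal to
    1, c, ..., c^degree over the included cohorts.
    """
    c = cohorts[included].astype(float)
    g = gamma[included]
    cbar = c.mean()
    V = np.vander(c - cbar, degree + 1, increasing=True)
    phi_c, *_ = np.linalg.lstsq(V, g, rcond=None)
    # convert centred coefficients to raw polynomial coefficients
    phi = np.zeros(3)
    if degree == 0:
        phi[0] = phi_c[0]
    elif degree == 1:
        phi[0] = phi_c[0] - phi_c[1] * cbar
        phi[1] = phi_c[1]
    else:
        phi[0] = phi_c[0] - phi_c[1] * cbar + phi_c[2] * cbar**2
        phi[1] = phi_c[1] - 2.0 * phi_c[2] * cbar
        phi[2] = phi_c[2]
    return phi


def _constrain(fit: GAPC, spec: GapcSpec):
    """Apply the family's identifiability constraints in place.

    All transformations leave the linear predictor unchanged on the
    cells that enter the likelihood.
    """
    ages = fit.ages_.astype(float)
    years = fit.years_.astype(float)
    xbar = float(ages.mean())

    # 1. scale estimated loadings: sum(beta) = 1
    for i, b in list(fit.betas_.items()):
        tot = b.sum()
        if abs(tot) < 1e-12:
            raise MortalityDataError("degenerate age loading (sum beta = 0)")
        fit.betas_[i] = b / tot
        fit.kappas_[i] = fit.kappas_[i] * tot
    if fit.beta0_ is not None:
        tot = fit.beta0_.sum()
        if abs(tot) < 1e-12:
            raise MortalityDataError("degenerate cohort loading (sum beta0 = 0)")
        fit.beta0_ = fit.beta0_ / tot
        fit.gamma_ = fit.gamma_ * tot

    # 2. cohort polynomial transfer
    if fit.gamma_ is not None and spec.gamma_transfer_degree >= 0:
        deg = spec.gamma_transfer_degree
        inc = fit.cohort_included_
        if fit.beta0_ is not None:
            # only the level can be transferred through an estimated loading
            gbar = fit.gamma_[inc].mean()
            fit.gamma_ = np.where(inc, fit.gamma_ - gbar, 0.0)
            fit.alpha_ = fit.alpha_ + fit.beta0_ * gbar
        else:
            phi = _poly_transfer(fit.gamma_, fit.cohorts_, inc, deg)
            p0, p1, p2 = phi
            cvals = fit.cohorts_.astype(float)
            fit.gamma_ = np.where(inc, fit.gamma_ - (p0 + p1 * cvals + p2 * cvals**2), 0.0)
            t = years
            name = spec.name
            if name == "APC":
                fit.kappas_[0] = fit.kappas_[0] + p0 + p1 * t
                fit.alpha_ = fit.alpha_ - p1 * ages
            elif name == "M6":
                fit.kappas_[0] = fit.kappas_[0] + p0 + p1 * (t - xbar)
                fit.kappas_[1] = fit.kappas_[1] - p1
            elif name == "M7":
                sig2 = float(np.mean((ages - xbar) ** 2))
                fit.kappas_[0] = (
                    fit.kappas_[0]
                    + p0
                    + p1 * (t - xbar)
                    + p2 * (t**2 - 2.0 * t * xbar + sig2 + xbar**2)
                )
                fit.kappas_[1] = fit.kappas_[1] - p1 + p2 * (2.0 * xbar - 2.0 * t)
                fit.kappas_[2] = fit.kappas_[2] + p2
            elif name == "M8":
                gbar_terms = p0  # degree 0: phi is just the mean
                fit.kappas_[0] = fit.kappas_[0] + gbar_terms * (fit.xc_ - xbar)
                fit.kappas_[1] = fit.kappas_[1] - gbar_terms
            elif name == "PLAT":
                fit.alpha_ = fit.alpha_ + p0 - p1 * ages + p2 * ages**2
                fit.kappas_[0] = fit.kappas_[0] + p1 * t + p2 * t**2 - 2.0 * p2 * xbar * t
                fit.kappas_[1] = fit.kappas_[1] + 2.0 * p2 * t
            else:  # pragma: no cover
                raise MortalityDataError(f"no transfer rule for {name}")

    # 3. centre kappas
    for i in list(fit.betas_):
        kbar = fit.kappas_[i].mean()
        fit.kappas_[i] = fit.kappas_[i] - kbar
        fit.alpha_ = fit.alpha_ + fit.betas_[i] * kbar
    for i in spec.center_kappas:
        kbar = fit.kappas_[i].mean()
        fit.kappas_[i] = fit.kappas_[i] - kbar
        B = fit.beta_mods_[i]
        fit.alpha_ = fit.alpha_ + B * kbar
    return fit


def apply_constraints(fit: GAPC) -> GAPC:
    """Return a constrained copy of a fitted GAPC model.

    The fitted predictor is unchanged (within round-off) at every cell
    that entered the likelihood; only the parameter representation moves
    to the conventional identified form.
    """
    for name in ("alpha_", "kappas_"):
        arrs = getattr(fit, name)
        vals = arrs if isinstance(arrs, list) else [arrs]
        for v in vals:
            if v is not None and not np.all(np.isfinite(v)):
                raise MortalityDataError("non-finite parameters")
    out = copy.deepcopy(fit)
    _constrain(out, out.spec_)
    out._refresh_fit(out.surface_)
    return out


# ---------------------------------------------------------------------------
# wrappers


def fit_gapc(name: str, surface: MortalitySurface, **kwargs) -> GAPC:
    """Fit a GAPC model by name with identifiability constraints applied."""
    return GAPC(name=name, **kwargs).fit(surface)


def estimate_xc(surface: MortalitySurface, candidates=None):
    """Profile the M8 constant age x_c over a candidate grid.

    Fits M8 at every candidate and returns ``(best, profile)`` where
    ``profile`` is a list of (candidate, deviance); ties break toward
    the smallest candidate.
    """
    if candidates is None:
        top = int(surface.ages[-1])
        candidates = list(range(top, top + 21))
    candidates = list(candidates)
    if not candidates:
        raise MortalityDataError("empty candidate grid for x_c")
    profile = []
    failures = []
    for cand in candidates:
        try:
            m = GAPC(name="M8", xc=float(cand)).fit(surface)
            profile.append((cand, m.deviance_))
        except Exception as exc:  # noqa: BLE001 - reported below
            failures.append((cand, str(exc)))
    if not profile:
        raise MortalityDataError(f"all M8 fits failed: {failures}")
    best = min(profile, key=lambda p: (p[1], p[0]))[0]
    return best, profile
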