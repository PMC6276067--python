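"""Expanding-window forecast evaluation and loss functions.

Models are re-estimated on progressively longer histories; each refit
produces an h-step-ahead forecast curve that is scored against the
holdout year by the root mean squared forecast error (RMSFE, point
accuracy) and the mean interval score (interval accuracy).  Losses are
computed on the log-rate scale, the scale every model in the pool is
built for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .data import MortalityDataError, MortalitySurface, PopulationSet

__all__ = [
    "SplitPlan",
    "LossMatrix",
    "rmsfe",
    "interval_score",
    "expanding_window",
    "build_loss_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """Expanding-window design: train through ``train_end``, validate
    through ``validation_end``, test through ``test_end``, h-step ahead."""

    train_end: int
    validation_end: int
    test_end: int
    horizon: int = 1

    def __post_init__(self):
        if not self.train_end < self.validation_end < self.test_end:
            raise MortalityDataError("need train_end < validation_end < test_end")
        if self.horizon < 1:
            raise MortalityDataError("horizon must be >= 1")

    def origins(self):
        """Fit origins: each model is fitted on years <= origin."""
        return list(range(self.train_end, self.test_end - self.horizon + 1))

    def validation_years(self):
        return [
            o + self.horizon
            for o in self.origins()
            if o + self.horizon <= self.validation_end
        ]

    def test_years(self):
        return [
            o + self.horizon for o in self.origins() if o + self.horizon > self.validation_end
        ]


@dataclass
class LossMatrix:
    """N x m losses: one row per evaluation point, one column per model."""

    models: list
    points: list  # evaluation year labels
    losses: np.ndarray
    loss_type: str = "RMSFE"

    def __post_init__(self):
        self.losses = np.asarray(self.losses, dtype=float)
        N, m = self.losses.shape
        if N < 2:
            raise MortalityDataError("need at least 2 evaluation points")
        if m != len(self.models) or N != len(self.points):
            raise MortalityDataError("loss matrix labels inconsistent with shape")
        if not np.all(np.isfinite(self.losses)):
            raise MortalityDataError("non-finite losses")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.losses, index=self.points, columns=self.models)

    def select(self, models) -> "LossMatrix":
        idx = [self.models.index(m) for m in models]
        return LossMatrix(list(models), self.points, self.losses[:, idx], self.loss_type)


# ---------------------------------------------------------------------------
# losses


def rmsfe(actual, forecast) -> float:
    """Root mean squared error across the ages of one forecast curve."""
    a = np.asarray(actual, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if a.shape != f.shape:
        raise MortalityDataError("actual and forecast lengths differ")
    return float(np.sqrt(np.mean((a - f) ** 2)))


def interval_score(lower, upper, actual, alpha: float = 0.2):
    """Interval score per age and its curve mean.

    S_alpha = (u - l) + (2/alpha)(l - y) 1{y < l} + (2/alpha)(y - u) 1{y > u}.

    Returns ``(scores, mean_score)``.
    """
    l = np.asarray(lower, dtype=float)
    u = np.asarray(upper, dtype=float)
    y = np.asarray(actual, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise MortalityDataError("alpha must be in (0, 1)")
    if np.any(l > u):
        raise MortalityDataError("lower bound exceeds upper bound")
    scores = (u - l) + (2.0 / alpha) * (l - y) * (y < l) + (2.0 / alpha) * (y - u) * (y > u)
    return scores, float(np.mean(scores))


# ---------------------------------------------------------------------------
# expanding window


@dataclass
class WindowResult:
    """Per-model h-step-ahead forecasts over the evaluation years."""

    model: str
    years: list
    point: np.ndarray  # (n_eval, k)
    lower: np.ndarray
    upper: np.ndarray
    level: float
    failures: list = field(default_factory=list)


def expanding_window(
    data,
    models: dict,
    plan: SplitPlan,
    level: float = 0.8,
    n_paths: int = 1000,
    seed: int = 0,
    population: str | None = None,
) -> dict:
    """Refit every model at each origin and collect h-step forecasts.

    ``data`` is a MortalitySurface or PopulationSet; ``models`` maps a
    label to an (unfitted) estimator prototype which is cloned per
    origin.  Multipopulation models are fitted jointly and scored on
    ``population``.  Failures are logged and recorded, never zero-filled.
    """
    is_popset = isinstance(data, PopulationSet)
    if is_popset and population is None:
        population = data.labels[0]
    years = data.years if is_popset else data.years
    plan_years = set(plan.origins())
    if plan.train_end < int(years[0]) + 2 or plan.test_end > int(years[-1]):
        raise MortalityDataError("split plan outside the data range")

    h = plan.horizon
    out = {}
    for label, proto in models.items():
        rows = {}
        failures = []
        for origin in plan.origins():
            subset = data.restrict_years(int(years[0]), origin)
            est = clone(proto)
            origin_seed = int(np.random.SeedSequence([seed, origin]).generate_state(1)[0] % (2**31 - 1))
            try:
                if getattr(est, "multipopulation", False):
                    if not is_popset:
                        raise MortalityDataError(
                            f"model {label} needs a PopulationSet"
                        )
                    est.fit(subset)
                    fc = est.forecast(h, level=level, n_paths=n_paths, seed=origin_seed)[
                        population
                    ]
                else:
                    target = subset[population] if is_popset else subset
                    est.fit(target)
                    fc = est.forecast(h, level=level, n_paths=n_paths, seed=origin_seed)
            except Exception as exc:  # noqa: BLE001 - recorded, not silenced
                logger.warning("model %s failed at origin %s: %s", label, origin, exc)
                failures.append((origin, str(exc)))
                continue
            rows[origin + h] = (fc.point[h - 1], fc.lower[h - 1], fc.upper[h - 1])
        if not rows:
            raise MortalityDataError(f"model {label} failed at every origin")
        eval_years = sorted(rows)
        out[label] = WindowResult(
            model=str(label),
            years=eval_years,
            point=np.array([rows[yy][0] for yy in eval_years]),
            lower=np.array([rows[yy][1] for yy in eval_years]),
            upper=np.array([rows[yy][2] for yy in eval_years]),
            level=level,
            failures=failures,
        )
    return out


def build_loss_matrix(
    results: dict,
    actual: MortalitySurface,
    loss_type: str = "RMSFE",
    years=None,
    alpha: float = 0.2,
) -> LossMatrix:
    """Score each model's forecast curves against the actual log rates.

    One row per evaluation year, one column per model.  ``years``
    restricts to a subset (e.g. the validation period); by default the
    years shared by every model are used.
    """
    labels = list(results)
    if years is None:
        years = sorted(set.intersection(*(set(r.years) for r in results.values())))
    years = list(years)
    log_actual = actual.log_rates()
    losses = np.empty((len(years), len(labels)))
    for j, lab in enumerate(labels):
        r = results[lab]
        for i, yy in enumerate(years):
            if yy not in r.years:
                raise MortalityDataError(f"model {lab} has no forecast for year {yy}")
            idx = r.years.index(yy)
            y_true = log_actual[:, actual.year_index(yy)]
            if loss_type == "RMSFE":
                losses[i, j] = rmsfe(y_true, r.point[idx])
            elif loss_type == "MIS":
                tail = 1.0 - r.level if alpha is None else alpha
                _, losses[i, j] = interval_score(r.lower[idx], r.upper[idx], y_true, tail)
            else:
                raise MortalityDataError(f"unknown loss type {loss_type!r}")
    return LossMatrix(labels, years, losses, loss_type)
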