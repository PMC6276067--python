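"""Forecast combiners.

The headline combiner assigns equal weights to the MCS superior set and
zero weight to the trimmed models.  The baseline assigns every model a
weight proportional to the inverse of its validation-period forecast
error.  Point forecasts and interval bounds are combined by the same
convex average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MortalityDataError
from .forecast import ForecastResult
from .mcs import MCSResult

__all__ = [
    "CombinationWeights",
    "equal_weights",
    "inverse_error_weights",
    "combine_forecasts",
    "combine_window_results",
]


@dataclass
class CombinationWeights:
    """Normalized non-negative model weights."""

    weights: dict
    scheme: str

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise MortalityDataError("weights must sum to 1")
        if any(w < 0 for w in self.weights.values()):
            raise MortalityDataError("weights must be non-negative")

    def support(self):
        return [m for m, w in self.weights.items() if w > 0]


def equal_weights(mcs_result: MCSResult, all_models=None) -> CombinationWeights:
    """1/|superior set| on each superior model, 0 elsewhere."""
    superior = list(mcs_result.superior)
    if not superior:
        raise MortalityDataError("empty superior set")
    w = 1.0 / len(superior)
    weights = {m: w for m in superior}
    if all_models is not None:
        for m in all_models:
            weights.setdefault(m, 0.0)
    return CombinationWeights(weights, "EQUAL_MCS")


def inverse_error_weights(validation_losses: dict) -> CombinationWeights:
    """Weights proportional to 1 / mean validation loss, normalized."""
    if any(loss <= 0 for loss in validation_losses.values()):
        raise MortalityDataError("mean losses must be strictly positive")
    inv = {m: 1.0 / loss for m, loss in validation_losses.items()}
    total = sum(inv.values())
    return CombinationWeights({m: v / total for m, v in inv.items()}, "INVERSE_ERROR")


def combine_forecasts(results: dict, weights: CombinationWeights) -> ForecastResult:
    """Convex combination of member ForecastResults (points and bounds)."""
    support = weights.support()
    if not support:
        raise MortalityDataError("no models with positive weight")
    ref = results[support[0]]
    point = np.zeros_like(ref.point)
    lower = np.zeros_like(ref.lower)
    upper = np.zeros_like(ref.upper)
    for m in support:
        r = results[m]
        if r.point.shape != ref.point.shape or not np.array_equal(r.ages, ref.ages):
            raise MortalityDataError("member forecasts on different grids")
        if r.level != ref.level:
            raise MortalityDataError("member forecasts at different interval levels")
        w = weights.weights[m]
        point += w * r.point
        lower += w * r.lower
        upper += w * r.upper
    return ForecastResult(
        ages=ref.ages,
        years=ref.years,
        point=point,
        lower=lower,
        upper=upper,
        level=ref.level,
        provenance={
            "model": weights.scheme,
            "members": {m: weights.weights[m] for m in support},
        },
    )


def combine_window_results(window_results: dict, weights: CombinationWeights):
    """Combine expanding-window forecast matrices across models.

    Returns a WindowResult-like object with the same evaluation years.
    """
    from .evaluation import WindowResult

    support = weights.support()
    if not support:
        raise MortalityDataError("no models with positive weight")
    ref = window_results[support[0]]
    years = ref.years
    point = np.zeros_like(ref.point)
    lower = np.zeros_like(ref.lower)
    upper = np.zeros_like(ref.upper)
    for m in support:
        r = window_results[m]
        if r.years != years:
            raise MortalityDataError("member forecasts cover different years")
        w = weights.weights[m]
        point += w * r.point
        lower += w * r.lower
        upper += w * r.upper
    return WindowResult(
        model=weights.scheme,
        years=list(years),
        point=point,
        lower=lower,
        upper=upper,
        level=ref.level,
    )
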