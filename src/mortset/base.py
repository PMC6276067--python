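"""Common estimator interface for the mortality model pool.

All models follow the scikit-learn estimator protocol: hyperparameters
are constructor arguments, ``fit`` consumes a :class:`MortalitySurface`
(or :class:`PopulationSet` for the joint models) and stores fitted
attributes with a trailing underscore, and ``forecast`` returns a
:class:`ForecastResult` of log mortality rates.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import MortalitySurface, PopulationSet
from .forecast import ForecastResult

__all__ = ["MortalityForecaster"]


class MortalityForecaster(BaseEstimator):
    """Base class: fit on a mortality surface, forecast log rates."""

    #: set True for models that fit a PopulationSet jointly
    multipopulation = False

    def fit(self, surface, y=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def forecast(self, h: int, level: float = 0.8, n_paths: int = 1000, seed: int = 0):
        raise NotImplementedError

    def predict(self, h: int, **kwargs):
        """Alias for :meth:`forecast` point output (sklearn-style)."""
        return self.forecast(h, **kwargs).point

    def _check_fitted(self):
        if not hasattr(self, "fitted_log_rates_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")

    # helpers shared by subclasses -------------------------------------
    @staticmethod
    def _surface_of(data, population=None):
        if isinstance(data, PopulationSet):
            if population is None:
                population = data.labels[0]
            return data[population]
        if isinstance(data, MortalitySurface):
            return data
        raise TypeError("expected MortalitySurface or PopulationSet")

    def _future_years(self, h):
        return np.arange(self.years_[-1] + 1, self.years_[-1] + 1 + h)
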