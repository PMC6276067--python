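"""Registry of the 17-model pool, keyed by conventional labels 1-17.

1-8   Poisson GAPC family (Lee-Carter Poisson, Renshaw-Haberman, APC,
      CBD, M6, M7, M8, Plat)
9-12  Gaussian Lee-Carter variants (total-deaths adjustment,
      deaths-distribution adjustment, life-expectancy adjustment,
      no adjustment)
13-17 Functional time-series models (FDM, robust FDM, product-ratio,
      multivariate, multilevel)
"""

from __future__ import annotations

from .functional import (
    FunctionalDataModel,
    MultilevelFdm,
    MultivariateFdm,
    ProductRatioModel,
)
from .gapc import GAPC
from .lc import LeeCarterGaussian

__all__ = ["MODEL_REGISTRY", "make_model", "model_name"]

MODEL_REGISTRY = {
    1: ("LC-Poisson", lambda **kw: GAPC(name="LC_POIS", **kw)),
    2: ("Renshaw-Haberman", lambda **kw: GAPC(name="RH", **kw)),
    3: ("APC", lambda **kw: GAPC(name="APC", **kw)),
    4: ("CBD", lambda **kw: GAPC(name="CBD", **kw)),
    5: ("M6", lambda **kw: GAPC(name="M6", **kw)),
    6: ("M7", lambda **kw: GAPC(name="M7", **kw)),
    7: ("M8", lambda **kw: GAPC(name="M8", **kw)),
    8: ("Plat", lambda **kw: GAPC(name="PLAT", **kw)),
    9: ("LC-total-deaths", lambda **kw: LeeCarterGaussian(adjustment="total_deaths", **kw)),
    10: (
        "LC-deaths-distribution",
        lambda **kw: LeeCarterGaussian(adjustment="deaths_distribution", **kw),
    ),
    11: ("LC-e0", lambda **kw: LeeCarterGaussian(adjustment="e0", **kw)),
    12: ("LC-no-adjustment", lambda **kw: LeeCarterGaussian(adjustment="none", **kw)),
    13: ("FDM", lambda **kw: FunctionalDataModel(robust=False, **kw)),
    14: ("Robust-FDM", lambda **kw: FunctionalDataModel(robust=True, **kw)),
    15: ("Product-ratio", lambda **kw: ProductRatioModel(**kw)),
    16: ("Multivariate-FDM", lambda **kw: MultivariateFdm(**kw)),
    17: ("Multilevel-FDM", lambda **kw: MultilevelFdm(**kw)),
}

_NAME_TO_LABEL = {name.lower(): lab for lab, (name, _) in MODEL_REGISTRY.items()}


def model_name(label: int) -> str:
    return MODEL_REGISTRY[int(label)][0]


def make_model(label, **kwargs):
    """Instantiate a pool model by numeric label or name."""
    if isinstance(label, str) and not label.isdigit():
        key = _NAME_TO_LABEL.get(label.lower())
        if key is None:
            raise KeyError(f"unknown model name {label!r}")
        label = key
    label = int(label)
    if label not in MODEL_REGISTRY:
        raise KeyError(f"unknown model label {label}; valid labels are 1-17")
    return MODEL_REGISTRY[label][1](**kwargs)
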