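"""The model confidence set (MCS) procedure.

Given an N x m matrix of per-evaluation-point losses, the equal
predictive ability (EPA) hypothesis — all models have the same expected
loss — is tested with studentized statistics built from pairwise loss
differentials, with variances estimated by a moving-block bootstrap.
The worst model is eliminated and the test repeated until EPA is
accepted; the survivors form the superior set at the chosen confidence
level.

Two statistics are available: T_R = max |t_rho_xi| over model pairs, and
T_max = max t_rho_dot over models, where t_rho_dot studentizes the loss
of model rho relative to the pool average.  Elimination rules pick the
model with the largest standardized relative loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .evaluation import LossMatrix

__all__ = [
    "DifferentialSet",
    "MCSResult",
    "compute_differentials",
    "select_block_length",
    "test_epa",
    "run_mcs",
]


class MCSError(ValueError):
    pass


@dataclass
class DifferentialSet:
    """Sample loss differentials and their bootstrap variances."""

    models: list
    dbar_pair: np.ndarray  # (m, m), antisymmetric
    dbar_dot: np.ndarray  # (m,)
    var_pair: np.ndarray  # (m, m)
    var_dot: np.ndarray  # (m,)
    block_length: int
    B: int
    seed: int
    boot_colmeans: np.ndarray = field(repr=False, default=None)  # (B, m)
    colmeans: np.ndarray = field(repr=False, default=None)  # (m,)


def _block_bootstrap_indices(N: int, block_length: int, B: int, rng) -> np.ndarray:
    """Moving-block bootstrap index matrix of shape (B, N)."""
    bl = max(int(block_length), 1)
    n_blocks = int(np.ceil(N / bl))
    starts = rng.integers(0, N - bl + 1, size=(B, n_blocks))
    idx = (starts[:, :, None] + np.arange(bl)[None, None, :]).reshape(B, -1)
    return idx[:, :N]


def select_block_length(losses: LossMatrix) -> int:
    """Block length = the maximum number of significant AR coefficients.

    For each pairwise differential series an autoregression is fitted
    with the order chosen by AIC (up to floor(N^(1/3)) + 1); the number
    of lag coefficients with |t| > 1.96 is counted and the maximum over
    pairs, floored at 1, is returned.
    """
    from statsmodels.tsa.ar_model import AutoReg, ar_select_order

    L = losses.losses
    N, m = L.shape
    if N < 5:
        return 1
    p_max = int(np.floor(N ** (1.0 / 3.0))) + 1
    best = 0
    for rho in range(m):
        for xi in range(rho + 1, m):
            series = L[:, rho] - L[:, xi]
            if np.allclose(series, series[0]):
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sel = ar_select_order(series, maxlag=p_max, ic="aic", old_names=False)
                    order = len(sel.ar_lags) if sel.ar_lags is not None else 0
                    if order == 0:
                        continue
                    res = AutoReg(series, lags=order, old_names=False).fit()
                tvals = res.tvalues[1:]  # skip the constant
                best = max(best, int(np.sum(np.abs(tvals) > 1.96)))
            except Exception:  # noqa: BLE001 - degenerate series contributes 0
                continue
    return max(best, 1)


def compute_differentials(
    losses: LossMatrix,
    B: int = 5000,
    block_length: int | None = None,
    seed: int = 0,
) -> DifferentialSet:
    """Pairwise/relative mean loss differentials with bootstrap variances.

    The same B moving-block bootstrap replicates are reused later for
    the EPA null distribution, so they are stored on the result.
    """
    L = losses.losses
    N, m = L.shape
    if m < 2:
        raise MCSError("need at least 2 models")
    if block_length is None:
        block_length = select_block_length(losses)
    colmeans = L.mean(axis=0)
    dbar_pair = colmeans[:, None] - colmeans[None, :]
    dbar_dot = dbar_pair.mean(axis=1)

    rng = np.random.default_rng(seed)
    idx = _block_bootstrap_indices(N, block_length, B, rng)
    boot_colmeans = L[idx].mean(axis=1)  # (B, m)

    boot_pair = boot_colmeans[:, :, None] - boot_colmeans[:, None, :]
    var_pair = np.mean((boot_pair - dbar_pair[None]) ** 2, axis=0)
    boot_dot = boot_pair.mean(axis=2)
    var_dot = np.mean((boot_dot - dbar_dot[None]) ** 2, axis=0)

    return DifferentialSet(
        models=list(losses.models),
        dbar_pair=dbar_pair,
        dbar_dot=dbar_dot,
        var_pair=var_pair,
        var_dot=var_dot,
        block_length=int(block_length),
        B=int(B),
        seed=int(seed),
        boot_colmeans=boot_colmeans,
        colmeans=colmeans,
    )


def _studentize(num, var):
    """num / sqrt(var) with the 0/0 convention -> 0, x/0 -> +/- inf."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(var)
    t = np.where((var == 0) & (num == 0), 0.0, t)
    zero_var = (var == 0) & (num != 0)
    if np.any(zero_var):
        t = np.where(zero_var & (num > 0), np.inf, t)
        t = np.where(zero_var & (num < 0), -np.inf, t)
    return t


def test_epa(diff: DifferentialSet, statistic: str = "T_max"):
    """One EPA test: observed statistic, bootstrap p-value, worst model.

    The null distribution uses the stored bootstrap replicates with the
    differentials recentred by their sample means.
    """
    m = len(diff.models)
    if m < 2:
        raise MCSError("need at least 2 models")
    t_pair = _studentize(diff.dbar_pair, diff.var_pair)
    t_dot = _studentize(diff.dbar_dot, diff.var_dot)

    boot_pair = diff.boot_colmeans[:, :, None] - diff.boot_colmeans[:, None, :]
    boot_pair_c = boot_pair - diff.dbar_pair[None]
    boot_dot_c = boot_pair.mean(axis=2) - diff.dbar_dot[None]

    if statistic == "T_R":
        observed = float(np.max(np.abs(t_pair)))
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = boot_pair_c / np.sqrt(diff.var_pair[None])
        tb = np.where(diff.var_pair[None] == 0, 0.0, tb)
        null = np.max(np.abs(tb), axis=(1, 2))
        worst_idx = int(np.argmax(np.max(t_pair, axis=1)))
    elif statistic == "T_max":
        observed = float(np.max(t_dot))
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = boot_dot_c / np.sqrt(diff.var_dot[None])
        tb = np.where(diff.var_dot[None] == 0, 0.0, tb)
        null = np.max(tb, axis=1)
        worst_idx = int(np.argmax(t_dot))
    else:
        raise MCSError(f"unknown statistic {statistic!r}; use 'T_R' or 'T_max'")

    if np.isinf(observed):
        warnings.warn("zero bootstrap variance with nonzero mean differential; p-value 0")
        return observed, 0.0, diff.models[worst_idx]
    if observed == 0.0:
        return 0.0, 1.0, diff.models[worst_idx]
    p_value = float(np.mean(null >= observed))
    return observed, p_value, diff.models[worst_idx]


@dataclass
class MCSResult:
    """Superior set, elimination trace and MCS p-values."""

    superior: list
    eliminated: list  # ordered (label, step p-value, MCS p-value)
    statistic: str
    alpha: float
    B: int
    block_length: int | None
    seed: int

    @property
    def mcs_pvalues(self) -> dict:
        out = {lab: p for lab, _, p in self.eliminated}
        for lab in self.superior:
            out[lab] = 1.0
        return out

    def to_dict(self) -> dict:
        return {
            "superior": list(self.superior),
            "eliminated": [
                {"model": lab, "step_p": sp, "mcs_p": mp} for lab, sp, mp in self.eliminated
            ],
            "statistic": self.statistic,
            "alpha": self.alpha,
            "B": self.B,
            "block_length": self.block_length,
            "seed": self.seed,
        }


def run_mcs(
    losses: LossMatrix,
    alpha: float = 0.10,
    statistic: str = "T_max",
    B: int = 5000,
    block_length: int | None = None,
    seed: int = 0,
) -> MCSResult:
    """Sequential MCS elimination at confidence level 1 - alpha.

    At each round the EPA test is run on the surviving models; if its
    p-value is at least ``alpha`` the survivors are the superior set,
    otherwise the worst model is eliminated, its MCS p-value being the
    running maximum of the step p-values.  Bootstrap replicates are
    redrawn each round with a deterministically advanced seed, so the
    elimination trace depends only on ``seed``, never on ``alpha`` —
    superior sets are nested across confidence levels.
    """
    models = list(losses.models)
    if len(models) == 1:
        return MCSResult(models, [], statistic, alpha, B, block_length, seed)
    current = losses
    eliminated = []
    running_max = 0.0
    used_bl = block_length
    for round_no in range(len(models) - 1):
        round_seed = int(
            np.random.SeedSequence([seed, round_no]).generate_state(1)[0] % (2**31 - 1)
        )
        diff = compute_differentials(
            current, B=B, block_length=block_length, seed=round_seed
        )
        used_bl = diff.block_length
        observed, p_value, worst = test_epa(diff, statistic)
        if p_value >= alpha:
            return MCSResult(
                list(current.models), eliminated, statistic, alpha, B, used_bl, seed
            )
        running_max = max(running_max, p_value)
        eliminated.append((worst, p_value, running_max))
        survivors = [mm for mm in current.models if mm != worst]
        current = current.select(survivors)
    return MCSResult(list(current.models), eliminated, statistic, alpha, B, used_bl, seed)
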