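"""Model-performance metrics and the 70/30 cross-validation protocol.

R^2 and RMSE% are computed against the arithmetic mean of the *observed*
AGB values; the residual fraction is (pred - obs)/pred, so positive values
mean over-prediction.  Cross-validation is a single seeded 70/30 split:
fit on the training 70%, predict each held-out record with the posterior
median, and score the held-out 30%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .records_io import Dataset, DataError, train_test_split
from .bayes_fit import (MCMCConfig, PriorSpec, fit, posterior_predict_records)

logger = logging.getLogger("agbgrowth")


@dataclass(frozen=True)
class PairedPredictions:
    """Observed AGB and posterior-median predictions, aligned elementwise."""

    obs: np.ndarray
    pred: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "obs", np.asarray(self.obs, dtype=float))
        object.__setattr__(self, "pred", np.asarray(self.pred, dtype=float))
        if self.obs.shape != self.pred.shape or self.obs.ndim != 1:
            raise ValueError("obs and pred must be equal-length vectors")
        if self.obs.size < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(self.pred < 0):
            raise ValueError("predictions must be >= 0")


@dataclass
class EvalReport:
    r2: float
    rmse: float
    rmse_percent: float
    mean_residual_fraction: float
    n: int
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


def r_squared(p: PairedPredictions) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (can be negative)."""
    ss_tot = float(np.sum((p.obs - p.obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("R^2 undefined: observed values are all identical")
    ss_res = float(np.sum((p.obs - p.pred) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(p: PairedPredictions) -> float:
    """Root-mean-square error, Mg ha^-1."""
    return float(np.sqrt(np.mean((p.obs - p.pred) ** 2)))


def rmse_percent(p: PairedPredictions) -> float:
    """RMSE as a percentage of the mean observed AGB."""
    ybar = float(p.obs.mean())
    if ybar == 0.0:
        raise DataError("RMSE%% undefined: mean observed AGB is zero")
    return rmse(p) / ybar * 100.0


def residual_fraction(p: PairedPredictions) -> np.ndarray:
    """Elementwise (pred - obs)/pred; entries with pred == 0 are NaN
    (flagged undefined and excluded from the mean by callers)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (p.pred - p.obs) / p.pred
    frac = np.where(p.pred == 0.0, np.nan, frac)
    n_undef = int(np.sum(p.pred == 0.0))
    if n_undef:
        logger.warning("residual_fraction: %d entries with pred == 0 excluded",
                       n_undef)
    return frac


def mean_residual_fraction(p: PairedPredictions) -> float:
    frac = residual_fraction(p)
    return float(np.nanmean(frac))


def evaluate(p: PairedPredictions) -> EvalReport:
    """All four metrics on one set of paired predictions."""
    return EvalReport(r2=r_squared(p), rmse=rmse(p),
                      rmse_percent=rmse_percent(p),
                      mean_residual_fraction=mean_residual_fraction(p),
                      n=p.obs.size)


def cross_validate(data: Dataset, prior: PriorSpec = PriorSpec(),
                   config: MCMCConfig = MCMCConfig(), seed: int = 0,
                   train_fraction: float = 0.7) -> EvalReport:
    """Single 70/30 hold-out evaluation of the fitted growth model.

    The split and the sampler share reproducible seeds; any convergence
    warning from the training fit is propagated into the report rather
    than swallowed.
    """
    if len(data) < 20:
        raise DataError("cross-validation needs >= 20 records")
    train, test = train_test_split(data, train_fraction, seed=seed)
    sample = fit(train, prior, config, check_convergence=False)
    agb, age, z1, z2 = test.arrays()
    pred = posterior_predict_records(sample, age, z1, z2)
    report = evaluate(PairedPredictions(agb, pred))
    report.converged = sample.converged
    if not sample.converged:
        report.warnings.append(
            f"training fit convergence contract not met "
            f"(max R-hat {sample.max_rhat:.4f}, min ESS {sample.min_ess:.0f})")
    return report
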