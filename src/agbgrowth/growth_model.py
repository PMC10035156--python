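"""Monod growth curve, realized accumulation rate, and the heteroscedastic
Gaussian likelihood.

The mean AGB of a stand of age ``a`` follows a Monod (Michaelis-Menten)
saturation curve

    y(a) = mu * a / (a + mu / r),

where ``mu`` is the saturated (asymptotic) AGB in Mg ha^-1 and ``r`` the
initial accumulation rate in Mg ha^-1 yr^-1 (the slope at a = 0).  Both
parameters depend linearly on the normalized climate covariates,

    mu = b_mu0 + b_mu1 * z1 + b_mu2 * z2,
    r  = b_r0  + b_r1  * z1 + b_r2  * z2,

and an observation is Normal(y, (y*sigma)^2): the SD is proportional to the
mean, so large stands are noisier in absolute terms but equally noisy in
relative terms.

The realized accumulation rate is the age-derivative of the curve,

    dy/da = r / (1 + (r/mu) * a)^2,

which equals r at age 0 and decreases strictly with age.  Two PFTs' rate
curves cross at most once for positive age; the crossover age has a closed
form (see :func:`crossover_age`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records_io import Dataset, NormalizedClimate, DataError

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Sentinel log-density meaning "parameter region where the likelihood is
#: undefined" (some record's mean AGB <= 0 makes the proportional SD
#: degenerate).  -inf is never accepted by the sampler and is arithmetic-safe
#: in comparisons.
NEG_INF = -np.inf


@dataclass(frozen=True)
class GrowthParams:
    """The 7 parameters of one PFT's growth model (normalized-covariate scale).

    ``beta_mu`` and ``beta_r`` are (intercept, MAP slope, MAT slope) for the
    saturated AGB and initial rate; ``sigma`` is the proportional-SD
    coefficient (dimensionless, > 0).
    """

    beta_mu: tuple[float, float, float]
    beta_r: tuple[float, float, float]
    sigma: float

    def __post_init__(self) -> None:
        if len(self.beta_mu) != 3 or len(self.beta_r) != 3:
            raise ValueError("beta_mu and beta_r must have length 3")
        vals = (*self.beta_mu, *self.beta_r, self.sigma)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("parameters must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def as_vector(self) -> np.ndarray:
        """(b_mu0, b_mu1, b_mu2, b_r0, b_r1, b_r2, sigma)."""
        return np.array([*self.beta_mu, *self.beta_r, self.sigma], dtype=float)

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "GrowthParams":
        theta = np.asarray(theta, dtype=float)
        return cls(tuple(theta[:3]), tuple(theta[3:6]), float(theta[6]))


PARAM_NAMES = ("beta_mu_0", "beta_mu_1", "beta_mu_2",
               "beta_r_0", "beta_r_1", "beta_r_2", "sigma")


@dataclass(frozen=True)
class CurvePoint:
    age: float
    mean_agb: float
    rate: float


def mu_of(params: GrowthParams, z: NormalizedClimate):
    """Saturated AGB at climate z (may be negative; truncation is the
    prediction step's contract, not this function's)."""
    b = params.beta_mu
    return b[0] + b[1] * np.asarray(z.z1) + b[2] * np.asarray(z.z2)


def r_of(params: GrowthParams, z: NormalizedClimate):
    """Initial accumulation rate at climate z (untruncated)."""
    b = params.beta_r
    return b[0] + b[1] * np.asarray(z.z1) + b[2] * np.asarray(z.z2)


def monod_agb(mu, r, age):
    """Mean AGB y = mu*a/(a + mu/r); 0 when mu <= 0 or r <= 0 (truncated)."""
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(r, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    valid = (mu > 0) & (r > 0)
    mu_s = np.where(valid, mu, 1.0)
    r_s = np.where(valid, r, 1.0)
    y = mu_s * age / (age + mu_s / r_s)
    out = np.where(valid, y, 0.0)
    return float(out) if out.ndim == 0 else out


def accumulation_rate(mu, r, age):
    """Realized rate dy/da = r/(1 + (r/mu)*a)^2; r at age 0; 0 if mu,r <= 0."""
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(r, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    valid = (mu > 0) & (r > 0)
    mu_s = np.where(valid, mu, 1.0)
    r_s = np.where(valid, r, 1.0)
    rate = r_s / (1.0 + (r_s / mu_s) * age) ** 2
    out = np.where(valid, rate, 0.0)
    return float(out) if out.ndim == 0 else out


def curve_points(params: GrowthParams, z: NormalizedClimate,
                 ages) -> list[CurvePoint]:
    """Evaluate mean curve and rate at each age (truncated at prediction)."""
    mu = max(float(mu_of(params, z)), 0.0)
    r = max(float(r_of(params, z)), 0.0)
    return [CurvePoint(float(a), monod_agb(mu, r, a), accumulation_rate(mu, r, a))
            for a in np.asarray(ages, dtype=float)]


def crossover_age(params_a: GrowthParams, params_b: GrowthParams,
                  z: NormalizedClimate) -> float | None:
    """Age at which the two PFTs' realized-rate curves intersect, or None.

    Setting r_A/(1+(r_A/mu_A)a)^2 = r_B/(1+(r_B/mu_B)a)^2 and taking the
    positive square root gives the linear equation

        sqrt(r_A) * (1 + (r_B/mu_B) a) = sqrt(r_B) * (1 + (r_A/mu_A) a)

    whose root is returned when positive; rate curves of two saturating
    growers cross at most once for a > 0.
    """
    mu_a, r_a = float(mu_of(params_a, z)), float(r_of(params_a, z))
    mu_b, r_b = float(mu_of(params_b, z)), float(r_of(params_b, z))
    if mu_a <= 0 or r_a <= 0 or mu_b <= 0 or r_b <= 0:
        raise ValueError("crossover requires positive mu and r for both PFTs")
    sa, sb = np.sqrt(r_a), np.sqrt(r_b)
    denom = sa * r_b / mu_b - sb * r_a / mu_a
    if denom == 0.0:
        return None
    a = (sb - sa) / denom
    return float(a) if a > 0 else None


def log_likelihood(params: GrowthParams, data: Dataset) -> float:
    """Heteroscedastic Gaussian log-likelihood of the dataset.

    Sum over records of log Normal(AGB_i | y_i, (y_i sigma)^2) with y_i the
    Monod mean at the record's age and climate.  Returns -inf when any
    record's y_i <= 0: there the proportional SD degenerates and the stated
    likelihood is undefined, so the sampler must reject.
    """
    agb, age, z1, z2 = data.arrays()
    if agb.size == 0:
        raise DataError("empty dataset")
    return _log_likelihood_arrays(params.as_vector(), agb, age, z1, z2)


def _log_likelihood_arrays(theta: np.ndarray, agb: np.ndarray, age: np.ndarray,
                           z1: np.ndarray, z2: np.ndarray) -> float:
    """Likelihood kernel on raw arrays; theta = 6 betas + sigma.

    Supports a leading batch axis on theta (k, 7) -> (k,) for vectorized
    samplers.
    """
    theta = np.asarray(theta, dtype=float)
    batched = theta.ndim == 2
    th = np.atleast_2d(theta)                      # (k, 7)
    mu = th[:, 0:1] + np.outer(th[:, 1], z1) + np.outer(th[:, 2], z2)
    r = th[:, 3:4] + np.outer(th[:, 4], z1) + np.outer(th[:, 5], z2)
    sigma = th[:, 6]
    ok = (np.all(mu > 0, axis=1) & np.all(r > 0, axis=1) & (sigma > 0))
    mu = np.where(mu > 0, mu, 1.0)
    r = np.where(r > 0, r, 1.0)
    y = mu * age / (age + mu / r)                  # (k, n)
    sd = np.abs(y * sigma[:, None])
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ll = -0.5 * ((agb - y) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI
        total = np.where(ok, ll.sum(axis=1), NEG_INF)
    return total if batched else float(total[0])
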