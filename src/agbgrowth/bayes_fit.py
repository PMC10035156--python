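"""Posterior inference for the growth parameters of one plant functional type.

The target density is ``log_likelihood + log_prior`` with weakly-informative
priors: sigma^2 ~ inv-Gamma(1, 1), intercepts b_mu0 ~ N(200, 1e6) and
b_r0 ~ N(2, 1e6), all climate slopes ~ N(0, 1e6).  Sampling is delegated to
emcee's ensemble sampler (differential-evolution moves): each configured
"chain" is an independent ensemble of 16 walkers started from a jittered
crude least-squares fit.  Split rank-normalized R-hat (arviz) compares the
independent ensembles; bulk ESS treats each walker as an autocorrelated
chain.  The sampler moves in
(betas, log sigma^2) with the Jacobian of the log transform included, since
the inverse-gamma prior is placed on sigma^2 while the reported parameter is
sigma.

A fit is flagged (never silently) when the convergence contract —
R-hat < 1.01 and bulk ESS > 400 for all seven parameters — is not met on the
retained draws.  Identical seed and configuration reproduce the draw matrix
bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

import emcee

from .records_io import Dataset, NormalizedClimate, PFT, DataError, slope_scale
from .growth_model import (GrowthParams, PARAM_NAMES, NEG_INF,
                           _log_likelihood_arrays, monod_agb, accumulation_rate)

_WALKERS_PER_CHAIN = 16  # at least 2x the 7-dim parameter space

#: Map parameter name -> covariate whose normalization scale applies when
#: reporting on original units (per-mm / per-degree effects).
_ORIGINAL_SCALE_COV = {"beta_mu_1": "MAP", "beta_mu_2": "MAT",
                       "beta_r_1": "MAP", "beta_r_2": "MAT"}


class ConvergenceWarning(UserWarning):
    """The MCMC convergence contract (R-hat/ESS) was not met."""


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters; defaults are the model's stated priors."""

    sigma2_shape: float = 1.0
    sigma2_scale: float = 1.0
    beta_mu_0_mean: float = 200.0
    beta_mu_0_var: float = 1e6
    beta_r_0_mean: float = 2.0
    beta_r_0_var: float = 1e6
    slope_mean: float = 0.0
    slope_var: float = 1e6

    def __post_init__(self) -> None:
        if min(self.sigma2_shape, self.sigma2_scale, self.beta_mu_0_var,
               self.beta_r_0_var, self.slope_var) <= 0:
            raise ValueError("prior variances and inverse-gamma parameters must be > 0")


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    iterations: int = 20_000
    warmup_fraction: float = 0.5
    seed: int = 0
    thinning: int = 1

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if not 0 < self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.iterations <= int(self.iterations * self.warmup_fraction):
            raise ValueError("iterations must exceed warmup")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PosteriorSample:
    """Retained MCMC draws, shape (draw, chain, 7), on the GrowthParams scale
    (last column is sigma, not sigma^2).  The chain axis enumerates every
    walker of every independent ensemble (chains x 16 walkers)."""

    draws: np.ndarray
    param_names: tuple[str, ...] = PARAM_NAMES
    config: MCMCConfig | None = None
    pft: PFT | None = None
    n_data: int = 0
    converged: bool = True
    max_rhat: float = np.nan
    min_ess: float = np.nan
    walkers_per_chain: int = 1

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.param_names):
            raise ValueError("draws must have shape (draw, chain, n_params)")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("draws must be finite")
        if np.any(self.draws[..., -1] <= 0):
            raise ValueError("sigma draws must be positive")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """(total draws, 7) matrix pooling all chains."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws (iteration, chain, 7 named columns)."""
        n_it, n_ch, _ = self.draws.shape
        it, ch = np.meshgrid(np.arange(n_it), np.arange(n_ch), indexing="ij")
        df = pd.DataFrame(self.flat(), columns=list(self.param_names))
        df.insert(0, "chain", ch.ravel())
        df.insert(0, "iteration", it.ravel())
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorSample":
        n_it = int(df["iteration"].max()) + 1
        n_ch = int(df["chain"].max()) + 1
        arr = (df.sort_values(["iteration", "chain"])[list(PARAM_NAMES)]
               .to_numpy().reshape(n_it, n_ch, len(PARAM_NAMES)))
        return cls(arr)


@dataclass
class FitResult:
    """Table-style posterior summary: one row per parameter with mean,
    median, 95% credible bounds (normalized and original covariate scales),
    R-hat, bulk ESS, and the credible-interval significance flag."""

    table: pd.DataFrame
    n: int
    pft: PFT | None = None
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Prior density


def log_prior(params: GrowthParams, prior: PriorSpec = PriorSpec()) -> float:
    """Log prior density at ``params``, with the inverse-gamma component
    evaluated on sigma^2.  Returns -inf for sigma <= 0."""
    if params.sigma <= 0:
        return NEG_INF
    theta = params.as_vector()
    return float(_log_prior_batch(theta[None, :6], np.array([params.sigma ** 2]),
                                  prior)[0])


def _norm_logpdf(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def _log_prior_batch(betas: np.ndarray, sigma2: np.ndarray,
                     prior: PriorSpec) -> np.ndarray:
    """Vectorized prior over (k, 6) beta rows and (k,) sigma^2 values.

    Closed-form densities (cheap enough for the sampler's inner loop):
    Normal components for the betas, inv-Gamma(shape, scale) for sigma^2
    with log density a*log(b) - lgamma(a) - (a+1)*log(x) - b/x.
    """
    lp = _norm_logpdf(betas[:, 0], prior.beta_mu_0_mean, prior.beta_mu_0_var)
    lp = lp + _norm_logpdf(betas[:, 3], prior.beta_r_0_mean, prior.beta_r_0_var)
    for j in (1, 2, 4, 5):
        lp = lp + _norm_logpdf(betas[:, j], prior.slope_mean, prior.slope_var)
    a, b = prior.sigma2_shape, prior.sigma2_scale
    with np.errstate(divide="ignore"):
        lp_sig = np.where(
            sigma2 > 0,
            a * np.log(b) - gammaln(a)
            - (a + 1) * np.log(np.where(sigma2 > 0, sigma2, 1.0))
            - b / np.where(sigma2 > 0, sigma2, 1.0),
            -np.inf)
    return lp + lp_sig


# ---------------------------------------------------------------------------
# Fitting


def _initial_point(agb: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Crude climate-free Monod least squares to seed the walkers."""
    mu0 = max(float(np.quantile(agb, 0.9)), 1.0)
    r0 = max(float(np.median(agb / age)), 0.1)

    def resid(p):
        mu, r = np.exp(p)
        y = mu * age / (age + mu / r)
        return (agb - y) / np.maximum(y, 1.0)

    sol = optimize.least_squares(resid, np.log([mu0, r0]), max_nfev=200)
    mu, r = np.exp(sol.x)
    y = mu * age / (age + mu / r)
    sigma = float(np.std((agb - y) / np.maximum(y, 1e-6)))
    sigma = min(max(sigma, 0.05), 2.0)
    return np.array([mu, 0.0, 0.0, r, 0.0, 0.0, np.log(sigma ** 2)])


def _sampling_log_prob(thetas: np.ndarray, agb, age, z1, z2, prior: PriorSpec,
                       prior_only: bool) -> np.ndarray:
    """Log target on the sampling scale (6 betas, u = log sigma^2),
    batched (k, 7) -> (k,).  Includes the d(sigma^2)/du Jacobian."""
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    betas, u = thetas[:, :6], thetas[:, 6]
    u = np.clip(u, -700.0, 700.0)
    sigma2 = np.exp(u)
    lp = _log_prior_batch(betas, sigma2, prior) + u  # + log-Jacobian
    if not prior_only:
        th = np.column_stack([betas, np.sqrt(sigma2)])
        lp = lp + _log_likelihood_arrays(th, agb, age, z1, z2)
    return lp


def fit(data: Dataset, prior: PriorSpec = PriorSpec(),
        config: MCMCConfig = MCMCConfig(), *, prior_only: bool = False,
        check_convergence: bool = True) -> PosteriorSample:
    """Sample the posterior of one PFT's growth parameters.

    Runs ``config.chains`` independent walker ensembles of
    ``config.iterations`` moves each, discards the warmup fraction, and
    returns the retained draws with convergence diagnostics attached.
    """
    pfts = {r.pft for r in data.records}
    if len(pfts) > 1:
        raise DataError("fit requires a single-PFT dataset; split_by_pft first")
    if len(data) < 10 and not prior_only:
        raise DataError(f"need >= 10 records to fit, got {len(data)}")
    agb, age, z1, z2 = data.arrays()

    ndim = 7
    nwalk = _WALKERS_PER_CHAIN
    if prior_only:
        theta0 = np.array([200.0, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0])
        jitter = np.array([500.0, 500.0, 500.0, 500.0, 500.0, 500.0, 1.0])
    else:
        theta0 = _initial_point(agb, age)
        jitter = np.abs(theta0) * 0.05 + np.array([5.0, 2.0, 2.0, 0.3, 0.1, 0.1, 0.05])

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(config.chains)]

    def log_prob(th):
        return _sampling_log_prob(th, agb, age, z1, z2, prior, prior_only)

    warmup = int(config.iterations * config.warmup_fraction)
    per_chain: list[np.ndarray] = []
    for cseed in chain_seeds:
        rs = np.random.RandomState(cseed)
        p0 = np.empty((nwalk, ndim))
        for w in range(nwalk):
            for attempt in range(200):
                cand = theta0 + jitter * rs.randn(ndim) / (1 + attempt // 20)
                if np.isfinite(log_prob(cand[None, :])[0]):
                    p0[w] = cand
                    break
            else:
                raise RuntimeError("could not find a valid starting point")
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(nwalk, ndim, log_prob, vectorize=True,
                                        moves=moves)
        sampler.random_state = np.random.RandomState(cseed)
        sampler.run_mcmc(p0, config.iterations, progress=False)
        chain = sampler.get_chain(discard=warmup, thin=config.thinning)
        per_chain.append(chain)                      # (steps, nwalk, 7)

    raw = np.concatenate(per_chain, axis=1)          # (steps, chains*nwalk, 7)
    draws = raw.copy()
    draws[..., 6] = np.sqrt(np.exp(raw[..., 6]))     # report sigma, not log s2

    rhats, esss = _diagnostics(draws, walkers_per_chain=nwalk)
    max_rhat, min_ess = float(rhats.max()), float(esss.min())
    converged = bool(max_rhat < 1.01 and min_ess > 400)
    sample = PosteriorSample(draws, config=config,
                             pft=next(iter(pfts)) if pfts else None,
                             n_data=len(data), converged=converged,
                             max_rhat=max_rhat, min_ess=min_ess,
                             walkers_per_chain=nwalk)
    if check_convergence and not converged:
        warnings.warn(
            f"convergence contract not met: max R-hat {max_rhat:.4f}, "
            f"min bulk ESS {min_ess:.0f}", ConvergenceWarning, stacklevel=2)
    return sample


def _diagnostics(draws: np.ndarray, walkers_per_chain: int = 1
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Split rank-normalized R-hat and bulk ESS per parameter (arviz).

    R-hat compares the independent ensembles (each ensemble's walkers pooled
    walker-major into one chain) — the between-run mixing check; ESS treats
    every walker as its own autocorrelated chain, which is the correct unit
    for autocorrelation-based effective-sample-size estimation.
    """
    import arviz as az
    n_draw, n_chain_axis, n_par = draws.shape
    walker = np.moveaxis(draws, 0, 1)                # (walkers, draw, 7)
    n_ens = n_chain_axis // walkers_per_chain
    ens = walker.reshape(n_ens, walkers_per_chain * n_draw, n_par)
    rhats, esss = np.empty(n_par), np.empty(n_par)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(n_par):
            rhats[j] = float(az.rhat(
                az.convert_to_dataset({"p": ens[:, :, j]}))["p"].values)
            esss[j] = float(az.ess(
                az.convert_to_dataset({"p": walker[:, :, j]}))["p"].values)
    return rhats, esss


# ---------------------------------------------------------------------------
# Summaries and significance


def summarize(sample: PosteriorSample) -> FitResult:
    """Per-parameter posterior mean/median/95% interval (normalized and
    original covariate scales), diagnostics, and significance flags.

    Quantiles use linear interpolation (numpy default).  Original-scale
    columns divide the MAP slopes by 500 and the MAT slopes by 7 per draw;
    intercepts and sigma are identical on both scales.
    """
    flat = sample.flat()
    rows = []
    for j, name in enumerate(sample.param_names):
        x = flat[:, j]
        q025, med, q975 = np.quantile(x, [0.025, 0.5, 0.975])
        cov = _ORIGINAL_SCALE_COV.get(name)
        scale = 1.0 if cov is None else slope_scale(1.0, cov, "to_original")
        rows.append({
            "parameter": name,
            "mean": x.mean(), "median": med, "q2_5": q025, "q97_5": q975,
            "mean_orig": x.mean() * scale, "median_orig": med * scale,
            "q2_5_orig": q025 * scale, "q97_5_orig": q975 * scale,
            "significant": bool(q025 > 0 or q975 < 0),
        })
    table = pd.DataFrame(rows).set_index("parameter")
    table["rhat"] = np.nan
    table["ess"] = np.nan
    if sample.draws.shape[1] >= 2:
        rhats, esss = _diagnostics(sample.draws, sample.walkers_per_chain)
        table["rhat"] = rhats
        table["ess"] = esss
    notes = [] if sample.converged else [
        f"convergence contract not met (max R-hat {sample.max_rhat:.4f}, "
        f"min ESS {sample.min_ess:.0f})"]
    return FitResult(table=table, n=sample.n_data, pft=sample.pft,
                     converged=sample.converged, warnings=notes)


def is_significant(result: FitResult, parameter: str) -> bool:
    """True iff the parameter's 95% credible interval excludes zero."""
    if parameter not in result.table.index:
        raise ValueError(f"unknown parameter {parameter!r}")
    row = result.table.loc[parameter]
    return bool(row["q2_5"] > 0 or row["q97_5"] < 0)


# ---------------------------------------------------------------------------
# Posterior prediction


@dataclass(frozen=True)
class Prediction:
    """Posterior-median prediction with a central credible interval."""

    agb_median: float
    agb_lower: float
    agb_upper: float
    rate_median: float
    rate_lower: float
    rate_upper: float
    interval: float


def _draw_curves(flat: np.ndarray, age, z: NormalizedClimate):
    """Per-draw truncated (mu, r) and the Monod mean / rate at ``age``."""
    mu = np.maximum(flat[:, 0] + flat[:, 1] * z.z1 + flat[:, 2] * z.z2, 0.0)
    r = np.maximum(flat[:, 3] + flat[:, 4] * z.z1 + flat[:, 5] * z.z2, 0.0)
    return mu, r


def posterior_predict(sample: PosteriorSample, age: float,
                      z: NormalizedClimate, interval: float = 0.95) -> Prediction:
    """Predict mean AGB and accumulation rate at one (age, climate) point.

    Per draw, mu and r are truncated at zero before evaluating the Monod
    curve and its derivative; the returned point estimate is the posterior
    median and the interval is the central credible band of the requested
    mass (0.80 is conventional for rate curves, 0.95 elsewhere).
    """
    if sample.n_draws == 0:
        raise DataError("empty posterior sample")
    if age < 0:
        raise ValueError("age must be >= 0")
    if not 0 < interval < 1:
        raise ValueError("interval must be in (0, 1)")
    mu, r = _draw_curves(sample.flat(), age, z)
    y = monod_agb(mu, r, np.full_like(mu, float(age)))
    rate = accumulation_rate(mu, r, np.full_like(mu, float(age)))
    lo, hi = (1 - interval) / 2, 1 - (1 - interval) / 2
    yq = np.quantile(y, [lo, 0.5, hi])
    rq = np.quantile(rate, [lo, 0.5, hi])
    return Prediction(agb_median=float(yq[1]), agb_lower=float(yq[0]),
                      agb_upper=float(yq[2]), rate_median=float(rq[1]),
                      rate_lower=float(rq[0]), rate_upper=float(rq[2]),
                      interval=interval)


def posterior_predict_records(sample: PosteriorSample, ages: np.ndarray,
                              z1: np.ndarray, z2: np.ndarray,
                              quantile: float = 0.5,
                              block: int = 64) -> np.ndarray:
    """Posterior-quantile AGB prediction for many (age, climate) points.

    Vectorizes over draws in record blocks to bound memory; the default
    quantile 0.5 is the posterior-median predictor.
    """
    flat = sample.flat()
    ages = np.asarray(ages, dtype=float)
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    out = np.empty(ages.shape[0])
    for start in range(0, ages.shape[0], block):
        sl = slice(start, start + block)
        mu = np.maximum(flat[:, [0]] + np.outer(flat[:, 1], z1[sl])
                        + np.outer(flat[:, 2], z2[sl]), 0.0)
        r = np.maximum(flat[:, [3]] + np.outer(flat[:, 4], z1[sl])
                       + np.outer(flat[:, 5], z2[sl]), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.where((mu > 0) & (r > 0),
                         mu * ages[sl] / (ages[sl] + np.where(mu > 0, mu, 1.0)
                                          / np.where(r > 0, r, 1.0)), 0.0)
        out[sl] = np.quantile(y, quantile, axis=0)
    return out
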