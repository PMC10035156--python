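"""Seeded generators reproducing the statistical structure the analysis
assumes, so fitting, evaluation and grid aggregation are testable end to end
without the compiled plot databases.

``default_truth`` returns, per plant functional type, published posterior-mean
growth parameters (converted to the normalized-covariate scale) that serve as
the default generating truth.  ``simulate_records`` draws plot records from
the generative model exactly as the likelihood states it — Monod mean with
climate-linear mu and r, Gaussian noise with SD proportional to the mean —
over an invented but realistic sampling design: ages uniform on 1-150 yr,
MAP ~ Normal(800, 200^2) truncated at 100 mm, MAT ~ Normal(7, 7^2), sample
sizes matching the compiled data set (1623/596/322/3839).  Negative simulated
observations are clamped to zero (real biomass cannot be negative) and the
clamp rate is reported; climates making mu or r nonpositive are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records_io import (AGBRecord, Dataset, PFT, slope_scale,
                         MAP_CENTER_MM, MAP_SCALE_MM, MAT_CENTER_C, MAT_SCALE_C)
from .growth_model import GrowthParams, PARAM_NAMES
from .bayes_fit import MCMCConfig, PriorSpec, fit, summarize
from .global_prediction import AgeClassGrid, GridCell, N_AGE_CLASSES

# Published posterior means, original covariate scales:
# (r0, r_MAP per mm, r_MAT per C, mu0, mu_MAP per mm, mu_MAT per C, sigma)
_TRUTH_ORIGINAL: dict[PFT, tuple[float, ...]] = {
    PFT.BROADLEAF_DECIDUOUS: (5.89, 0.0071, -0.0386, 393.55, -0.2122, 19.0471, 0.52),
    PFT.BROADLEAF_EVERGREEN: (16.37, -0.0032, -0.1429, 373.10, -0.1905, 36.9300, 0.44),
    PFT.NEEDLELEAF_DECIDUOUS: (7.34, 0.0028, 0.2486, 286.30, -0.1964, 8.2000, 0.50),
    PFT.NEEDLELEAF_EVERGREEN: (4.46, -0.0002, 0.2686, 449.56, 0.0874, 22.3700, 0.52),
}

#: Compiled-data sample sizes per PFT.
DEFAULT_N: dict[PFT, int] = {
    PFT.BROADLEAF_DECIDUOUS: 1623,
    PFT.BROADLEAF_EVERGREEN: 596,
    PFT.NEEDLELEAF_DECIDUOUS: 322,
    PFT.NEEDLELEAF_EVERGREEN: 3839,
}


class GenerationError(RuntimeError):
    """The truth specification admits no valid climates."""


def default_truth(pft: PFT) -> GrowthParams:
    """Generating truth for one PFT on the normalized-covariate scale."""
    pft = PFT.parse(pft) if isinstance(pft, str) else pft
    r0, r_map, r_mat, mu0, mu_map, mu_mat, sigma = _TRUTH_ORIGINAL[pft]
    return GrowthParams(
        beta_mu=(mu0, slope_scale(mu_map, "MAP", "to_normalized"),
                 slope_scale(mu_mat, "MAT", "to_normalized")),
        beta_r=(r0, slope_scale(r_map, "MAP", "to_normalized"),
                slope_scale(r_mat, "MAT", "to_normalized")),
        sigma=sigma)


@dataclass(frozen=True)
class TruthSpec:
    """Generating truth and sampling design for synthetic plot records.

    Ages: uniform integers on [age_min, age_max] by default, or a
    right-skewed option (``age_dist='young_skewed'``, Beta(1.2, 3) scaled)
    mimicking chronosequences dominated by young plots.  Climate: MAP in mm
    ~ Normal(map_mean, map_sd^2) truncated at map_min, MAT in C
    ~ Normal(mat_mean, mat_sd^2).  The MAP SD of 200 mm (rather than the
    normalizing 500 mm) keeps mu > 0 regions dominant under the default
    slopes.
    """

    params: dict[PFT, GrowthParams] = field(
        default_factory=lambda: {p: default_truth(p) for p in PFT})
    n: dict[PFT, int] = field(default_factory=lambda: dict(DEFAULT_N))
    seed: int = 0
    age_dist: str = "uniform"
    age_min: int = 1
    age_max: int = 150
    map_mean: float = MAP_CENTER_MM
    map_sd: float = 200.0
    map_min: float = 100.0
    mat_mean: float = MAT_CENTER_C
    mat_sd: float = MAT_SCALE_C

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n.values()):
            raise ValueError("n must be >= 1 per PFT")
        if set(self.n) - set(self.params):
            raise ValueError("every sampled PFT needs generating parameters")
        if self.age_dist not in ("uniform", "young_skewed"):
            raise ValueError(f"unknown age_dist {self.age_dist!r}")

    @classmethod
    def single(cls, pft: PFT | str, n: int, seed: int = 0,
               params: GrowthParams | None = None, **kwargs) -> "TruthSpec":
        """Convenience: a one-PFT specification."""
        pft = PFT.parse(pft) if isinstance(pft, str) else pft
        return cls(params={pft: params or default_truth(pft)},
                   n={pft: n}, seed=seed, **kwargs)


@dataclass
class SimulationReport:
    n_generated: int = 0
    n_climate_redraws: int = 0
    n_clamped: int = 0

    @property
    def clamp_rate(self) -> float:
        return self.n_clamped / self.n_generated if self.n_generated else 0.0


def _draw_ages(spec: TruthSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if spec.age_dist == "uniform":
        return rng.integers(spec.age_min, spec.age_max + 1, size=n).astype(float)
    frac = rng.beta(1.2, 3.0, size=n)
    return np.floor(spec.age_min + frac * (spec.age_max - spec.age_min + 1)).clip(
        spec.age_min, spec.age_max)


def _draw_climate(spec: TruthSpec, rng: np.random.Generator, n: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    map_mm = rng.normal(spec.map_mean, spec.map_sd, size=n)
    for _ in range(1000):
        bad = map_mm < spec.map_min
        if not bad.any():
            break
        map_mm[bad] = rng.normal(spec.map_mean, spec.map_sd, size=int(bad.sum()))
    map_mm = np.clip(map_mm, spec.map_min, None)
    mat_c = rng.normal(spec.mat_mean, spec.mat_sd, size=n)
    return map_mm, mat_c


def simulate_records(spec: TruthSpec) -> Dataset:
    """Draw a synthetic plot dataset from the generative growth model.

    Pure function of the spec (including its seed).  The returned Dataset
    carries a ``sim_report`` attribute counting climate redraws and
    zero-clamped observations.
    """
    root = np.random.SeedSequence(spec.seed)
    children = {pft: np.random.default_rng(child)
                for pft, child in zip(sorted(spec.n, key=lambda p: p.value),
                                      root.spawn(len(spec.n)))}
    report = SimulationReport()
    records: list[AGBRecord] = []
    for pft in sorted(spec.n, key=lambda p: p.value):
        rng = children[pft]
        params = spec.params[pft]
        n = spec.n[pft]
        age = _draw_ages(spec, rng, n)
        map_mm, mat_c = _draw_climate(spec, rng, n)
        bmu, br = np.array(params.beta_mu), np.array(params.beta_r)
        for attempt in range(1000):
            z1 = (map_mm - MAP_CENTER_MM) / MAP_SCALE_MM
            z2 = (mat_c - MAT_CENTER_C) / MAT_SCALE_C
            mu = bmu[0] + bmu[1] * z1 + bmu[2] * z2
            r = br[0] + br[1] * z1 + br[2] * z2
            bad = (mu <= 0) | (r <= 0)
            if not bad.any():
                break
            report.n_climate_redraws += int(bad.sum())
            new_map, new_mat = _draw_climate(spec, rng, int(bad.sum()))
            map_mm[bad], mat_c[bad] = new_map, new_mat
        else:
            raise GenerationError(
                f"{pft.value}: could not find climates with mu, r > 0")
        y = mu * age / (age + mu / r)
        agb = rng.normal(y, y * params.sigma)
        clamped = agb < 0
        report.n_clamped += int(clamped.sum())
        agb = np.maximum(agb, 0.0)
        report.n_generated += n
        records.extend(
            AGBRecord(float(a), float(t), pft, float(m), float(c))
            for a, t, m, c in zip(agb, age, map_mm, mat_c))
    ds = Dataset(records)
    ds.sim_report = report
    return ds


def simulate_grid(n_cells: int, seed: int = 0, spec: TruthSpec | None = None
                  ) -> AgeClassGrid:
    """Random age-class fraction grid with the record generator's climate
    marginals; per cell the total forest fraction is uniform on [0.1, 1],
    partitioned over 4 PFTs x 15 classes by normalized exponential weights."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    spec = spec or TruthSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cells = []
    for i in range(n_cells):
        map_mm, mat_c = _draw_climate(spec, rng, 1)
        lat = float(rng.uniform(-60, 75))
        lon = float(rng.uniform(-180, 180))
        raw = rng.exponential(1.0, size=(len(PFT), N_AGE_CLASSES))
        total = float(rng.uniform(0.1, 1.0))
        w = raw / raw.sum() * total
        fractions = {pft: w[j] for j, pft in enumerate(PFT)}
        cells.append(GridCell(f"cell{i:04d}", lat, lon,
                              float(map_mm[0]), float(mat_c[0]), fractions))
    return AgeClassGrid(cells)


# ---------------------------------------------------------------------------
# Parameter recovery


@dataclass
class RecoveryReport:
    """Per-replicate, per-parameter recovery results and their aggregates."""

    records: pd.DataFrame     # replicate, pft, parameter, truth, est, bias,
                              # rel_error, covered, converged

    @property
    def mean_coverage(self) -> float:
        return float(self.records["covered"].mean())

    def median_rel_error(self, parameter: str) -> float:
        sub = self.records[self.records["parameter"] == parameter]
        return float(sub["rel_error"].median())

    def coverage_by_parameter(self) -> pd.Series:
        return self.records.groupby("parameter")["covered"].mean()


def parameter_recovery_experiment(spec: TruthSpec,
                                  config: MCMCConfig = MCMCConfig(),
                                  n_replicates: int = 10,
                                  seed: int = 0,
                                  prior: PriorSpec = PriorSpec()
                                  ) -> RecoveryReport:
    """Simulate-fit-score loop: for each replicate, draw a dataset from the
    truth, fit each PFT, and record per-parameter bias, relative error
    (|posterior mean - truth| / |truth|) and 95% credible-interval coverage.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(root.spawn(n_replicates)):
        data_seed, fit_seed = (int(s % (2 ** 31))
                               for s in child.generate_state(2))
        rep_spec = replace(spec, seed=data_seed)
        data = simulate_records(rep_spec)
        for pft, subset in data.split_by_pft().items():
            rep_config = replace(config, seed=fit_seed)
            sample = fit(subset, prior, rep_config, check_convergence=False)
            result = summarize(sample)
            truth_vec = spec.params[pft].as_vector()
            for j, name in enumerate(PARAM_NAMES):
                row = result.table.loc[name]
                truth = truth_vec[j]
                est = row["mean"]
                rows.append({
                    "replicate": rep, "pft": pft.value, "parameter": name,
                    "truth": truth, "estimate": est, "bias": est - truth,
                    "rel_error": (abs(est - truth) / abs(truth)
                                  if truth != 0 else np.nan),
                    "covered": bool(row["q2_5"] <= truth <= row["q97_5"]),
                    "converged": sample.converged,
                })
    return RecoveryReport(pd.DataFrame(rows))
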