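# Methods

## Model

Per plant functional type (PFT), observed plot AGB is modelled as
`AGB_i ~ Normal(y_i, (y_i σ)²)` with mean `y_i = μ_i a_i/(a_i + μ_i/r_i)`,
a Monod curve of stand age `a_i`. The proportional-SD form encodes the
empirical pattern that scatter grows with biomass while relative scatter is
roughly constant; it also means the likelihood degenerates when any `y_i ≤ 0`
(zero SD), which shapes two contracts below. `μ` (saturated AGB, Mg ha⁻¹)
and `r` (initial rate, Mg ha⁻¹ yr⁻¹) are linear in the normalized climate
covariates `z₁ = (MAP − 800)/500` and `z₂ = (MAT − 7)/7`. The centering
constants are the compiled data set's climate means, so the four PFTs'
intercepts are comparable at a common reference climate; the scales put the
slopes on similar magnitudes. Slopes are reported on the original per-mm /
per-°C scales at the output boundary by dividing by 500 or 7 — an affine
map, so it commutes with means, medians and quantiles and can be applied to
summaries directly.

The realized accumulation rate is the derivative of the mean curve,
`dy/da = r/(1 + (r/μ)a)²`. (A variant with `μ/r` in the inner ratio
circulates in print; it is not the derivative of the Monod curve above and
admits no positive broadleaf crossover under the default parameter values,
so the algebraically correct form is used throughout.) Two PFTs' rate
curves intersect for `a > 0` where
`√r_A (1 + (r_B/μ_B)a) = √r_B (1 + (r_A/μ_A)a)`, a linear equation solved
in closed form; the solver returns `None` when the root is nonpositive and
is verified against bisection in the tests.

## Priors, likelihood boundaries, and sampling

Priors: `σ² ~ inv-Gamma(1, 1)`, `β_μ,0 ~ N(200, 10⁶)`,
`β_r,0 ~ N(2, 10⁶)`, all slopes `~ N(0, 10⁶)` — weakly informative at the
scale of the data. The prior sits on σ² while the sampler moves in
`u = log σ²` (the Jacobian `+u` is included) and draws are reported as σ.

During fitting, any parameter point that makes some record's mean `y_i ≤ 0`
receives log-density `−∞`: the stated likelihood is undefined there (the SD
would be ≤ 0), and the sentinel guarantees the sampler never accepts such a
point while remaining arithmetic-safe. Truncation of negative `μ` and `r`
to zero is applied only at prediction, where each posterior draw's `μ_l`
and `r_l` are clipped at 0 before evaluating the curve; the reported point
prediction is the posterior median and intervals are central (default mass
0.80 for rate curves, 0.95 elsewhere). Quantiles use linear interpolation
(numpy default) everywhere.

Sampling is delegated to emcee. Each configured "chain" (default 4) is an
independent ensemble of 16 walkers run for the configured number of moves
(default 20 000; the test suite and the recovery experiments use 3 000,
which meets the same convergence contract), initialised in a jittered ball
around a crude climate-free nonlinear least-squares fit and using
differential-evolution moves (80% DE, 20% DE-snooker), which mix several
times faster than the default stretch move on this 7-parameter posterior.
The first 50% of each run is discarded as warmup (no burn-in length is
prescribed by the source analysis; half is a conservative default).
Convergence contract: split rank-normalized R-hat < 1.01 — computed across
the independent ensembles, each ensemble's walkers pooled walker-major into
one chain, which is the honest between-run comparison — and bulk ESS > 400,
computed with each walker as its own autocorrelated sequence. A fit that
misses the contract is returned with a prominent `ConvergenceWarning` and a
flag, never silently. Identical seed and configuration reproduce the draw
matrix bit for bit (per-ensemble seeds derive from a `SeedSequence`).

## Evaluation

`R² = 1 − SS_res/SS_tot` and `RMSE% = RMSE/ȳ × 100` both use the mean of
the *observed* values as `ȳ`. The residual fraction is
`(pred − obs)/pred`, positive when the model over-predicts; elements with
`pred = 0` are undefined and excluded from the mean with a logged count.
Cross-validation is a single seeded 70/30 split (train size round-half-up),
as in the source protocol, with a repeat-over-seeds option; convergence
warnings from the training fit propagate into the report.

## Grid aggregation

A cell carries, per PFT, areal fractions over 15 ten-year age classes
represented by midpoints 5, 15, …, 145 yr. Current AGB is
`Σ_k w_k · y_q(mid_k)` with `y_q` the posterior quantile (median by
default) of the truncated curve — quantile-then-aggregate, matching
class-level median prediction; the alternative ordering is not offered
because the two differ only through the nonlinearity of the quantile, and
the per-class median is the documented estimand. Saturated AGB scales the
posterior quantile of truncated `μ` by the *same* total forest fraction
`Σ_k w_k`, so current and saturated share one areal basis and the potential
(saturated − current) is nonnegative cell-wise by the Monod bound `y ≤ μ`
and the monotonicity of empirical quantiles. Whether published per-PFT
"mean ± SD" potentials are area- or cell-weighted is not stated anywhere
authoritative; the summary here is the unweighted (cell-weighted) mean and
population SD over cells where the PFT is present, and is flagged as such.
Cells without finite climate are skipped with a logged count.

## Synthetic data

The generator draws from exactly the generative model the likelihood
assumes, under a sampling design chosen to resemble compiled chronosequence
collections: ages uniform on 1–150 yr (a right-skewed Beta(1.2, 3) option
mimics young-plot-dominated compilations); MAP ~ Normal(800, 200²) mm
truncated at 100 mm; MAT ~ Normal(7, 7²) °C; default per-PFT sample sizes
1623 / 596 / 322 / 3839 and default parameters equal to the published
posterior means. The MAP SD of 200 mm (not the normalizing 500 mm) keeps
the `μ > 0` region dominant under the default slopes; climates yielding
`μ ≤ 0` or `r ≤ 0` are redrawn with a retry cap and a logged count.
Negative simulated observations are clamped to 0, since real biomass cannot
be negative; the clamp rate equals the censoring probability Φ(−1/σ)
(≈ 2.7% at σ = 0.52) and is reported so its small moment distortion —
the relative-residual SD shrinks by ≈ 2.4% at σ = 0.52 — stays visible.
What the generator does *not* emulate: spatial autocorrelation, repeated
censuses of the same plot, database-specific measurement protocols, or
climate–age sampling covariance; passing recovery tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Problem sizes and numerical choices

The recovery experiment runs 10 replicates of n = 1500 at 4 × 3000
iterations; width-shrinkage and cross-validation tests use shorter chains
(2 × 800–1200) where only relative comparisons matter. The least-squares
initialiser works in log(μ, r) to stay positive and caps σ's starting value
to [0.05, 2]. Ages of exactly 0 are rejected at load because they force a
zero observation SD. Train-size rounding is half-up. AGB = 0 records are
accepted (young stands) but flagged.

## Known limitations

Strictly linear, additive climate effects; no soil, disturbance or
management covariates; climate held fixed over time; single-level pooling
(each PFT fitted separately, no hierarchy); the Monod form cannot represent
late-successional biomass decline. Absolute published fit statistics and
global maps depend on the compiled plot database and the native GFAD
rasters, which are not bundled; the pipeline accepts user-supplied tables
of the documented schema instead.
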