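# Methods

## Population models and standardization

Three confirmatory factor models for 13 memory tasks are built in
`model_zoo`:

* **Model 1 (unitary)** — one factor, all 13 tasks.
* **Model 2 (bi-partite)** — episodic (tasks 1–10) and semantic
  (tasks 11–13) factors with correlation `r`. The exact task allocation
  is an assumption of this package (the split is configurable via
  `build_bipartite(..., allocation=...)`); the default moves task 10 into
  the episodic cluster, which is what makes Models 2 and 3 non-nested.
* **Model 3 (tri-partite)** — pattern separation (tasks 1–6), pattern
  completion (tasks 5–9) and generalization (tasks 10–13), all three
  pairwise factor correlations equal to `r`. Tasks 5 and 6 load on both
  ps and pc.

All generating models are variance-standardized: loadings `a`, residual
variances `1 − a²`, unit factor variances. A task loading on two factors
with correlation `r` would have variance `b²(2 + 2r) + θ`; setting
`b = a/√(2 + 2r)` keeps its total variance at 1 with the same residual as
every other task. Consequently `diag(Σ) = 1` holds to machine precision
for every constructor, which the tests assert across the full `(a, r)`
grid.

Parameters and ranges: `a ∈ (0, 1)` (loading strength; the simulation
grids use 0.5–0.9), `r ∈ (−1, 1]` at construction, with positive-definite
Σ enforced at use (the tri-partite equicorrelation needs `r > −0.5`;
the study grids stay in [0.1, 0.9] since negative correlations among
memory abilities lack any empirical support). Sample sizes are per-group
totals; grids run 50–200 in steps of 5.

## Data generation and seeding

`datagen.generate` draws rows i.i.d. from N(0, Σ) via the Cholesky factor
of Σ, so the population covariance is exact and output is bit-identical
given a seed. Replication streams come from
`SeedSequence(master_seed, spawn_key=(condition_index, replication_index))`;
they depend only on those three integers, never on scheduling, which makes
runs reproducible under any degree of parallelism (including joblib
workers).

The generator emulates the idealized study conditions: multivariate
normal, complete data, exactly equal loadings within a model, exactly
equal factor correlations. Real task batteries have heterogeneous
loadings, floor/ceiling effects, non-normal scores and missingness, so a
passing power estimate here is a best-case figure; the module deliberately
does not model those features (ordinal/non-normal generation and planned
missingness are out of scope).

## Maximum-likelihood estimation

`ml_estimator.fit` minimizes `F_ML(θ) = ln|Σ(θ)| − ln|S| + tr(SΣ(θ)⁻¹) − p`
over the free entries of the candidate pattern, with `S` the divisor-`n`
sample covariance. The gradient is analytic
(`∂F/∂Λ = 2EΛΦ`, `∂F/∂Φ = Λ'EΛ` with off-diagonals doubled,
`∂F/∂θᵢᵢ = Eᵢᵢ`, where `E = Σ⁻¹ − Σ⁻¹SΣ⁻¹`), which makes each of the
~25k fits in a full study a few milliseconds and is exact where numeric
differences would only approximate.

Numerical choices:

* Optimizer: L-BFGS-B on the raw parameters, budget 500 iterations, one
  jittered restart. Residual variances are *not* transformed, so Heywood
  cases stay representable; they are flagged `admissible=False` without
  affecting convergence, mirroring common SEM software defaults.
* Convergence: gradient max-norm ≤ 1e−6 at a point where Σ(θ̂) is
  positive definite. Because L-BFGS-B's relative-f stopping rule can halt
  with the gradient just above that, a short BFGS polish (which stops on
  gradient norm) runs whenever the gradient lands in (1e−6, 1e−3].
  Gradients that stall far above 1e−3 indicate empirically
  under-identified fits — typically a multi-factor candidate on
  effectively one-factor data, where corr(ps, pc) → 1 creates a flat
  valley; those are declared non-converged, and the selection rule scores
  the whole replication as a recovery failure.
* Starting values: loadings 0.5, factor correlations 0, residuals
  `0.5·diag(S)`.
* Outside the positive-definite region the objective returns a large
  constant, which the line search treats as a barrier; `F_ML → ∞` at the
  boundary whenever S is positive definite, so interior solutions are the
  norm.
* Multiplier convention: `T = n·F_ML`, RMSEA uses `n`, log-likelihood
  `ℓ = −(n/2)[p·ln2π + ln|Σ̂| + tr(SΣ̂⁻¹)]` with means saturated and
  therefore constant across candidates. A Wishart `n−1` mode exists for
  sensitivity checks. The baseline (independence) and saturated models are
  closed-form.

Identification defaults to variance-standardized (factor variances fixed
at 1, all loadings free), matching the generating parameterization; a
marker-variable mode exists and the tests verify both reach the same
`F_ML` and the same df.

The estimator is cross-checked three ways: closed-form solutions
(just-identified one-factor models), a stochastic global-minimum oracle
(the optimizer must beat 1000 random admissible parameter draws on random
small instances), and statsmodels' ML factor analysis, which coincides
with the unitary candidate and agrees to ~1e−6.

## Fit indices and the selection rule

`fit_indices` implements the standard normal-theory definitions —
`CFI = 1 − max(T−df,0)/max(T−df, T₀−df₀, 0)`,
`RMSEA = √(max(T−df,0)/(df·n))`, `BIC = −2ℓ + q·ln n` — with the
multiplier convention pinned in the estimator and recorded in results
files. `selection.select` applies the published two-stage rule with
strict inequalities (CFI > .95, RMSEA < .06; boundary values fail), picks
the strictly lowest BIC among passers, scores any non-convergence or an
empty passing set as 0 (no model), and breaks exact BIC ties — a
measure-zero event — toward the model with fewer free parameters so that
replays from stored results are deterministic.

## Simulation engine and problem sizes

`mc_engine.build_design` produces the full `a × r × n` crossing in a fixed
order; `run` executes generate→fit→select per replication and stores all
indices (switchable off); `summarize` reports per-condition correct-selection
and Model-3-selection proportions with binomial standard errors
`√(p̂(1−p̂)/R)`, plus counts by outcome reason. `type_one_mode` is the
same machinery with the generating model restricted to 1 or 2 and the
headline column `prop_model3`.

The study-scale grids (155 = 5×31 and 279 = 9×31 conditions at 1000
replications) are fully runnable through the CLI. The test suite and the
acceptance script work at targeted cells instead: the headline power cell
at 1000 (script) or 500 (tests, with a 2·SE band) replications, and the
type-I grids at 500 replications per cell — sizes chosen so a full check
runs in minutes on a single core while keeping Monte Carlo standard
errors near one percentage point. The r-grid step for the separability
surface defaults to 0.1; it is a config value, not a claim.

## Reliability conversions

`reliability` converts between construct reliability and a common loading
under the equal-loading assumption:
`α = (kλ)²/((kλ)² + k(1−λ²))` and its exact inverse
`λ = √(α/(α + k − αk))`; `loading_from_test_retest` returns `λ = √r`.
The α↔λ pair is implemented as a mutually consistent inverse pair (the
worked case α = 0.7, k = 4 → λ ≈ 0.607 validates it); the roundtrip
identity holds to 1e−12 across the tested grid.

## Known limitations

* Multivariate-normal, complete data only; no ordinal or missing-data
  generation.
* No standard errors of parameter estimates (not needed by the selection
  rule) and no Vuong-type non-nested likelihood-ratio tests.
* Power estimates inherit every assumption of the population models;
  with heterogeneous real-world loadings the printed sample sizes are
  optimistic.
* The Model 2 task allocation is an assumption; type-I results with
  Model 2 generating data are sensitive to it.
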