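# Methods

## Model

Each population j is a stock of biomass density B_j (kg·m⁻³). Producers
grow logistically against a single shared carrying capacity K with all
competition coefficients equal to 1, so the normalized growth model
G_j = 1 − (total producer biomass)/K is identical for every producer and
may be negative during overshoot. Consumers respire at a mass-specific
rate T_j and ingest through a normalized functional response

    F_ij = B_i^(1+q) / [ W^(1+q)·(1 + d·B_j) + Σ_{k∈resources(j)} B_k^(1+q) ],

which is type II at q = 0 and sigmoid (type III, resource switching) for
q > 0. W is the half-saturation biomass: a consumer with a single resource
at B_i = W and no interference feeds at exactly half its maximum rate for
every q. The interference term (1 + d·B_j) multiplies W^(1+q) so that the
half-saturation property is preserved at d = 0. All resources of a
consumer enter the sum with equal weight; there are no preference
coefficients.

Trophic transfer is imperfect twice over: a consumer ingests only the
fraction f_e of the biomass it removes from a resource (the predation loss
is therefore the ingestion divided by f_e), and converts only the
assimilation efficiency e of what it ingests into its own biomass
(e = 0.45 on links from producers, 0.85 on links from animals, following
the conventional values of this model lineage; all overridable).

## Allometric parametrization

Every mass-specific rate scales as M^(−1/4):

- r_j = f_r·a_r·M_j^(−1/4) for producers (zero otherwise),
- T_j = a_T(category)·M_j^(−1/4) for consumers (zero for producers),
- J_ij = f_J(category of j)·a_J(category of j)·M_j^(−1/4), a property of
  the consumer only — every link of a consumer carries the same rate.

The shipped constants file (`allomweb/data/allometric_constants.yaml`)
uses the normalized coefficients of the classic bioenergetic lineage:
producer growth is the reference scale (a_r = 1), respiration is 0.314
(invertebrates) and 0.88 (vertebrate ectotherms) relative to it, and
maximum ingestion is respiration times the empirical maximum-consumption-
to-metabolism ratio (8 and 4 respectively). Because the equations are
integrated in time normalized to the growth rate of the smallest-bodied
producer, only rate ratios matter and the absolute scale of a_r cancels.
The constants live in an editable YAML file rather than code defaults so
that any transcription can be replaced without touching the package.

The seven quantities allometries cannot determine — f_r, f_J
(invertebrate), f_J (vertebrate), d, q, W, K — are the fitted parameters.
Default search box: fractions in [0.01, 1]; d and q in [0, 2]; W in
[10⁻⁸, 10⁻¹] and K in [10⁻⁵, 1] kg·m⁻³, both searched on log₁₀ scale.
The box brackets weak-to-strong interference and switching and plausible
lake biomass densities.

## Simulation to stationarity

Simulations start from the observed biomasses B = N_data·M and run in
normalized time with LSODA (stiff/non-stiff switching; the vector field is
JIT-compiled when numba is available, with an identical pure-numpy
fallback). Integration proceeds in windows; after each window the
trajectory is classified:

- equilibrium, if every species' relative change across the window is
  below `stationarity_tol` (default 10⁻⁶);
- stable oscillation, if the window's time-average agrees with the
  previous window's within `oscillation_tol` (default 10⁻³) while the
  within-window variation exceeds the equilibrium tolerance. Oscillatory
  states are summarized by the window time-average. The oscillation
  tolerance is looser than the equilibrium tolerance because the mean of a
  finite sample of a cycle carries O(period/window) error;
- otherwise the run continues to `t_max` (default 10⁵ normalized units)
  and is reported `not_reached`, returning the last window's state.

Species whose biomass falls below the extinction threshold (default
10⁻³⁰ kg·m⁻³, far below one individual of the smallest species per lake
volume) are set exactly to zero; integration restarts after each
extinction with the reduced system, and zero is absorbing. A separate
`fitting_profile` (t_max 2·10⁴, window 2·10³, tolerance 10⁻⁵, threshold
10⁻¹⁴) is used inside optimization loops, where thousands of simulations
run per campaign; the threshold is still many decades below any plausible
equilibrium biomass but is reached quickly by doomed populations.

## Scoring

score = n_persisting + g(SSE_model), with SSE_model the sum over
persisting species of squared log₁₀ density residuals and g(S) = 1/(1+S).
Any strictly decreasing g with g(0) = 1 and range (0, 1] gives the same
ranking of parameter sets whenever persistence counts are equal; g is
therefore a pluggable argument and the default is a documented choice, not
an empirical claim. A fully extinct simulation scores 0 by convention.
SSE_model is restricted to persisting species because log₁₀ 0 is
undefined; when all species persist it is a plain sum over the community
and directly comparable to SSE_regression, the residual sum of squares of
the OLS regression of log₁₀(N_data) on log₁₀(M).

Pattern summaries: mass–abundance OLS regressions (slope with classical
t-based 95% CI) overall and within metabolic categories having at least 4
species; abundance spectra as total N in equally spaced log₁₀(M) bins
aligned at integer multiples of the bin width (default 1 decade), empty
bins omitted; biomass totals by metabolic category and by prey-averaged
trophic level (basal = 1, otherwise 1 + mean resource level, solved as a
linear system so diet loops and cannibalism are handled) rounded down for
binning.

## Fitting

Start points are a scrambled 7-dimensional Sobol sequence mapped into the
box (log axes in log space), deterministic given (n, seed). Each start is
refined by Nelder–Mead in logit-transformed unit coordinates — a bijection
of the box onto ℝ⁷ — so every trial point is feasible by construction,
which is functionally equivalent to a box-constrained simplex. The
objective is the model score of one simulation (or the mean score across
communities for joint fits); simulation failures score 0 so the simplex
can pass through pathological regions. The best point seen is returned, so
an endpoint never scores below its start. Campaign defaults: 1000 starts
for full-scale studies, 32 for the scaled-down runs used throughout the
tests and the acceptance script (with at most 150 objective evaluations
per start).

## Randomization studies

To test whether quarter-power structure is necessary, one rate's
mass-dependence is destroyed by permuting values within metabolic
categories: r among producers; T among invertebrates and, separately,
vertebrate ectotherms; J at the consumer level within the same two groups
(all links of a consumer move together, since J is a consumer property).
Because the fitted f-factors multiply whole categories uniformly and are
re-fitted after shuffling, the study permutes the allometric kernels
M^(−1/4) and lets the optimizer rescale them — the same family of
randomizations as permuting realized rates. Three independent replicates
per target guard against any single permutation being unrepresentative.
Each replicate repeats the full optimization from the same Sobol starts;
the report compares best scores and the best SSE among full-coexistence
endpoints against the allometric baseline.

## Synthetic communities and the shipped fixture

The generator emulates the statistical skeleton of a north-temperate
pelagic lake community: three metabolic categories in disjoint log-mass
ranges, log-uniform masses, densities from log₁₀(N) = a + b·log₁₀(M) +
Normal(0, σ), size-structured diets (a consumer eats species whose log₁₀
mass ratio falls in a window below zero), link counts pruned to a target
under the constraints that every consumer keeps a resource and every
non-orphan producer keeps a consumer, and a configurable number of
producers that nothing eats. The lake-like default (50 species =
25/22/3 by category, 269 links, 6 orphan producers, masses spanning 14
decades, b = −0.8, σ = 0.6, intercept −2 so that phytoplankton-sized
producers sit near 10⁹ m⁻³ and fish-sized vertebrates near 10⁻¹ m⁻³) is a
structural emulation: it reproduces category counts, link density, size
structure and the power-law abundance baseline, not any real species list.

The shipped 12-species fixture (6 producers, 5 invertebrates, 1 vertebrate
ectotherm, 18 links) narrows the mass ranges to 7 decades so the slowest
consumer is only ~10⁴ times slower than the fastest producer, keeping
single simulations in the 10 ms range. Its observed densities are not raw
line-plus-noise draws: they are the stationary densities of a validated
full-coexistence reference equilibrium (f_r = 0.8, f_J = 0.9/0.85,
d = 0.6, q = 1.1, W = 5·10⁻⁴, K = 4·10⁻³) perturbed by 0.15 dex of
lognormal measurement noise. The reason is statistical: with independent
scatter about a pure power law, the expected model SSE is at least σ²·n
while the regression leaves only σ²·(n−2) — such data contain no trophic
structure a mechanistic model could capture, so "model beats regression"
would be unattainable by construction. Real communities do carry that
structure; conditioning the fixture's densities on model dynamics restores
it, so the fitting pipeline is tested on exactly the task it exists for:
rediscovering mechanistic structure through a 7-parameter search. The
fixture is regenerable from scratch (`make_fixture_community`) and a test
pins the shipped CSVs to the regeneration.

What passing on this fixture does and does not show: it validates the
machinery (rates, dynamics, scoring, search) end to end and the
qualitative orderings (model < regression SSE; randomized < allometric
scores), on a community whose data-generating process is the model itself.
It does not show that the model fits any real lake, nor calibrate
effort for a 50-species, 1000-start campaign, which simply scales the same
pipeline up.

## Numerical choices

- LSODA tolerances: rtol 10⁻⁸ (10⁻⁶ in the fitting profile); atol defaults
  to 10⁻¹² times the smallest positive initial biomass.
- Negative solver excursions are clamped to zero for rate evaluation only.
- Exact half-saturation: W^(1+q) is computed through the same numpy power
  path as the biomass powers, so a single resource at B = W scores exactly
  F = 0.5 in floating point.
- Trophic levels solve (I − A)·TL = 1 directly; a singular matrix (an
  all-cannibal loop with no basal path) is reported as an error.
- Sobol scrambling uses the given seed; with scrambling disabled the
  unscrambled sequence's discrepancy beats uniform sampling (tested).
- Stage seeds in the pipeline derive from the master seed and a CRC32 of
  the stage name, so adding a stage never shifts the seeds of others.
- All floating-point outputs serialize at 17 significant digits; reruns
  with identical config and seed are byte-identical.

## Known limitations

- No temperature dependence, nutrient-explicit producers, size-dependent
  producer competition, external forcing, or stochastic dynamics.
- Extinction times are resolved only to the integration window, not by
  event root-finding.
- The oscillation classifier compares consecutive window means; slow
  quasi-periodic drift below the oscillation tolerance would be classified
  as oscillation rather than transient.
- The score's second term is a documented reconstruction (any strictly
  decreasing map of SSE onto (0, 1] preserves the stated properties); only
  rankings at equal persistence, not absolute score values, should be
  compared across implementations.
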