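# allomweb

Allometrically parametrized bioenergetic food-web dynamics: simulate
multispecies biomass dynamics, score stationary states against observed
species abundances, fit the allometrically undetermined parameters, and
test whether the allometries are necessary.

## The problem

Differential-equation models of whole communities suffer a plague of
parameters: a food web of s species and L links carries hundreds of rate
constants that no snapshot dataset can identify. Physiological allometries
offer a partial cure. Most rates are tied to body mass M by quarter-power
scaling, so for a community with known body masses, metabolic categories
(producer / invertebrate / vertebrate ectotherm) and trophic links, almost
every parameter is pinned down:

    r_j  = f_r  · a_r        · M_j^(-1/4)     producer mass-specific growth
    J_ij = f_J  · a_J(cat j) · M_j^(-1/4)     consumer mass-specific ingestion
    T_j  =        a_T(cat j) · M_j^(-1/4)     consumer mass-specific respiration

The biomass density B_j (kg·m⁻³) of each population then evolves as

    dB_j/dt = r_j G_j(B) B_j − T_j B_j
              + B_j Σ_{i∈res(j)} e_ij J_ij F_ij(B)
              − Σ_{k∈cons(j)} B_k J_jk F_jk(B) / f_e

with a shared logistic growth model G_j = 1 − (Σ producers B_k)/K and a
type II/III functional response with predator interference

    F_ij = B_i^(1+q) / [ W^(1+q) (1 + d B_j) + Σ_{k∈res(j)} B_k^(1+q) ].

Seven quantities remain free: f_r, f_J (invertebrate and vertebrate), the
interference strength d, the response shape q, the half-saturation biomass
W and the global producer carrying capacity K. `allomweb` searches that
7-dimensional box for parameters whose stationary state reproduces the
observed mass–abundance structure, scoring each simulation by

    score = (# species persisting) + 1 / (1 + SSE_model),
    SSE_model = Σ_persisting (log₁₀ N_sim − log₁₀ N_data)²,

directly comparable with SSE_regression, the residual sum of squares of an
OLS regression of log₁₀(N_data) on log₁₀(M). Shuffling one rate's values
within metabolic categories (destroying its mass dependence while keeping
its distribution) and refitting asks whether the allometries are necessary,
not merely convenient.

Who is this for: ecologists confronting bioenergetic community models with
snapshot abundance data, and anyone needing a reproducible test-bed for
consumer–resource dynamics with allometric rate structure.

## Worked example

```python
import allomweb as aw

community = aw.load_fixture_community()        # 12 species, 18 links
fixed     = aw.FixedAllometry.default()        # documented constants file
settings  = aw.SimulationSettings.fitting_profile()

fits = aw.run_fit(community, aw.ParameterSpace.default(),
                  n_starts=32, seed=42, fixed=fixed, settings=settings,
                  max_evaluations=150)
best = aw.best_fit(fits)
sim  = aw.simulate_to_stationary(community, fixed, best.end, settings)
rep  = aw.model_score(sim, community)
print(rep.to_dict())
```

prints (one development run):

```
{'n_persisting': 12, 'sse_model': 0.35664590166778015,
 'second_term': 0.7371120192606333, 'score': 12.737112019260634,
 'sse_regression': 1.5787446985082765}
```

All 12 species persist (so the score exceeds 12), the summed squared
log-density residual of the dynamical model is 0.357, and the purely
phenomenological regression of log abundance on log mass leaves 1.579 —
the mechanistic model explains the abundance pattern better than the
straight line, because the data carry trophic structure that mass alone
cannot.

The same workflow is scriptable from the shell:

```
allomweb synth --seed 3 --out-nodes nodes.csv --out-links links.csv
allomweb validate --nodes nodes.csv --links links.csv
allomweb run --seed 7 --n-starts 32 --randomize-targets J --out-dir results/
```

## Layout

- `allomweb.community` — species/link tables, CSV I/O, validation,
  removal of unconsumed producers
- `allomweb.model` — allometric rates, time normalization, growth model,
  functional response, the biomass vector field
- `allomweb.dynamics` — LSODA integration to equilibrium or stable
  oscillation, extinction handling
- `allomweb.scoring` — model score, SSE comparisons, mass–abundance
  regressions, abundance spectra, prey-averaged trophic levels
- `allomweb.fitting` — Sobol start points, box-constrained Nelder–Mead,
  single and joint objectives, cross-community scoring
- `allomweb.randomize` — within-category rate shuffles and the
  randomization study
- `allomweb.synth` — seeded synthetic communities and the shipped fixture
- `allomweb.pipeline` / `allomweb.cli` — experiment orchestration and the
  `allomweb` command

See `docs/methods.md` for the model assumptions, parameter defaults and
design choices.
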