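"""Model-data agreement scores and community pattern summaries.

The model score for a community of s species is

    score = (number of species persisting) + g(SSE_model),

where SSE_model is the sum over persisting species of squared residuals
(log10 N_sim - log10 N_data)^2 and g is a strictly decreasing map of
[0, inf) onto (0, 1] with g(0) = 1 (default g(S) = 1/(1+S)).  The score
therefore has a maximum of 1 plus the number of persisting species; a
fully extinct simulation scores 0 by convention.  SSE_model is directly
comparable with SSE_regression, the residual sum of squares of an ordinary
least-squares regression of log10(N_data) on log10(M).

Pattern summaries mirror the standard community descriptions: mass-
abundance regressions overall and within metabolic groups, the abundance
(size) spectrum in equally spaced log-mass bins, and biomass totals binned
by floor of prey-averaged trophic level and by metabolic category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .community import Community, INVERTEBRATE, PRODUCER, VERTEBRATE
from .dynamics import SimulationResult


def default_score_transform(sse: float) -> float:
    """g(S) = 1/(1+S): strictly decreasing from g(0)=1 onto (0, 1]."""
    return 1.0 / (1.0 + sse)


@dataclass(frozen=True)
class ScoreReport:
    n_persisting: int
    sse_model: float
    second_term: float
    score: float
    sse_regression: float

    def to_dict(self) -> dict:
        return {
            "n_persisting": int(self.n_persisting),
            "sse_model": float(self.sse_model),
            "second_term": float(self.second_term),
            "score": float(self.score),
            "sse_regression": float(self.sse_regression),
        }


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    n: int


@dataclass(frozen=True)
class CommunityPatterns:
    """Data-side and simulation-side pattern summaries for one community."""

    regressions_data: dict[str, RegressionResult]
    regressions_sim: dict[str, RegressionResult]
    spectrum_data: tuple[np.ndarray, np.ndarray]   # (bin centres, total N)
    spectrum_sim: tuple[np.ndarray, np.ndarray]
    biomass_by_TL_data: dict[int, float]
    biomass_by_TL_sim: dict[int, float]
    biomass_by_category_data: dict[str, float]
    biomass_by_category_sim: dict[str, float]
    residuals: np.ndarray        # log10(N_sim) - log10(N_data), persisting only
    trophic_levels: np.ndarray


def model_score(
    sim: SimulationResult,
    c: Community,
    transform: Callable[[float], float] = default_score_transform,
) -> ScoreReport:
    """Score a stationary state against the observed densities."""
    if sim.B_sim.shape != (c.n_species,):
        raise ValueError(
            f"simulation has {sim.B_sim.shape[0]} species, community has "
            f"{c.n_species}; inputs are misaligned"
        )
    persisting = sim.persisting
    n_persisting = int(persisting.sum())
    try:
        sse_reg = sse_regression(c)
    except ValueError:
        sse_reg = float("nan")
    if n_persisting == 0:
        return ScoreReport(0, float("nan"), 0.0, 0.0, sse_reg)
    resid = (np.log10(sim.N_sim[persisting])
             - np.log10(c.observed_densities[persisting]))
    sse = float(np.sum(resid ** 2))
    second = float(transform(sse))
    return ScoreReport(n_persisting, sse, second, n_persisting + second, sse_reg)


def _ols_log10(M: np.ndarray, N: np.ndarray):
    x = np.log10(np.asarray(M, dtype=float))
    y = np.log10(np.asarray(N, dtype=float))
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("all body masses identical: slope undefined")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    return fit, float(np.sum(resid ** 2)), x.size


def sse_regression(c: Community) -> float:
    """Residual sum of squares of OLS log10(N_data) on log10(M)."""
    _, rss, _ = _ols_log10(c.masses, c.observed_densities)
    return rss


def mass_abundance_regression(M, N, conf: float = 0.95) -> RegressionResult:
    """OLS of log10(N) on log10(M) with a t-interval for the slope."""
    fit, _, n = _ols_log10(np.asarray(M), np.asarray(N))
    half = stats.t.ppf(0.5 + conf / 2, n - 2) * fit.stderr if n > 2 else 0.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci_low=float(fit.slope - half),
        slope_ci_high=float(fit.slope + half),
        n=n,
    )


def abundance_spectrum(
    masses, densities, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Total N in equally spaced log10(M) bins aligned at integer multiples
    of the bin width; empty bins are omitted.  Returns (centres, totals)."""
    if not (bin_width > 0):
        raise ValueError("bin_width must be positive")
    masses = np.asarray(masses, dtype=float)
    densities = np.asarray(densities, dtype=float)
    keep = densities > 0
    idx = np.floor(np.log10(masses[keep]) / bin_width).astype(int)
    order = np.argsort(idx, kind="stable")
    uniq, start = np.unique(idx[order], return_index=True)
    totals = np.add.reduceat(densities[keep][order], start)
    centres = (uniq + 0.5) * bin_width
    return centres, totals


def prey_averaged_trophic_levels(c: Community) -> np.ndarray:
    """Prey-averaged trophic level: 1 for basal species, else 1 plus the
    mean trophic level of the consumer's resources, solved as the linear
    system (I - A) TL = 1 so that diet loops and cannibalism are handled."""
    n = c.n_species
    idx = {sid: i for i, sid in enumerate(c.ids)}
    A = np.zeros((n, n))
    for j, sp in enumerate(c.species):
        res = c.resources_of(sp.id)
        if res:
            w = 1.0 / len(res)
            for rid in res:
                A[j, idx[rid]] += w
    try:
        tl = np.linalg.solve(np.eye(n) - A, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "trophic levels undefined: diet matrix is singular "
            "(a consumer loop with no path to a basal species)"
        ) from exc
    return tl


def summarize_patterns(
    c: Community, sim: SimulationResult, bin_width: float = 1.0
) -> CommunityPatterns:
    """Compute the standard pattern battery on both data and model sides.

    Regressions are fitted overall and within metabolic categories that have
    at least 4 species with distinct masses (small groups such as a handful
    of fish with near-identical masses are skipped).  Simulation-side
    quantities use persisting species only.
    """
    M = c.masses
    N_data = c.observed_densities
    persist = sim.persisting
    N_sim = sim.N_sim
    cats = np.array(c.categories)

    def regressions(N: np.ndarray, mask: np.ndarray) -> dict[str, RegressionResult]:
        out: dict[str, RegressionResult] = {}
        groups = {"all": np.ones(len(M), dtype=bool)}
        for cat in (PRODUCER, INVERTEBRATE, VERTEBRATE):
            groups[cat] = cats == cat
        for name, gmask in groups.items():
            m = gmask & mask
            if name != "all" and m.sum() < 4:
                continue
            try:
                out[name] = mass_abundance_regression(M[m], N[m])
            except ValueError:
                continue
        return out

    tl = prey_averaged_trophic_levels(c)
    floors = np.floor(tl).astype(int)
    B_data = N_data * M
    B_sim = sim.B_sim

    def by_key(keys, values) -> dict:
        out: dict = {}
        for k, v in zip(keys, values):
            out[k] = out.get(k, 0.0) + float(v)
        return out

    return CommunityPatterns(
        regressions_data=regressions(N_data, np.ones(len(M), dtype=bool)),
        regressions_sim=regressions(np.where(persist, N_sim, 1.0), persist),
        spectrum_data=abundance_spectrum(M, N_data, bin_width),
        spectrum_sim=abundance_spectrum(M, N_sim, bin_width),
        biomass_by_TL_data=by_key(floors, B_data),
        biomass_by_TL_sim=by_key(floors, B_sim),
        biomass_by_category_data=by_key(cats, B_data),
        biomass_by_category_sim=by_key(cats, B_sim),
        residuals=np.log10(N_sim[persist]) - np.log10(N_data[persist]),
        trophic_levels=tl,
    )
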