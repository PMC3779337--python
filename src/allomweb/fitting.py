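"""Search of the seven-dimensional free-parameter box for high model scores.

Start points come from a Sobol low-discrepancy sequence mapped into the
box (log-scaled axes are sampled in log space).  Each start is refined by
Nelder-Mead run in a bijective transform of the box onto unbounded
coordinates (a logit per axis after the scale transform), which keeps the
simplex unconstrained while guaranteeing that every evaluated point —
including trial points — is feasible.  The objective of a single-community
fit is the model score of one simulation run to stationarity; joint fits
return the mean score across communities.  The best-seen point is always
returned, so the endpoint never scores worse than the start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .community import Community
from .dynamics import SimulationError, SimulationSettings, simulate_to_stationary
from .model import FREE_PARAMETER_NAMES, FixedAllometry, FreeParameters
from .scoring import model_score

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG10 = "log10"


@dataclass(frozen=True)
class ParameterSpace:
    """Box bounds and sampling scales for the seven free parameters."""

    bounds: dict[str, tuple[float, float]]
    scales: dict[str, str]

    def __post_init__(self) -> None:
        for name in FREE_PARAMETER_NAMES:
            if name not in self.bounds:
                raise ValueError(f"missing bounds for {name}")
            lo, hi = self.bounds[name]
            if not (lo < hi):
                raise ValueError(f"{name}: lower bound must be below upper")
            scale = self.scales.get(name, LINEAR)
            if scale not in (LINEAR, LOG10):
                raise ValueError(f"{name}: unknown scale {scale!r}")
            if scale == LOG10 and not (lo > 0):
                raise ValueError(f"{name}: log10 scale requires positive bounds")

    @classmethod
    def default(cls) -> "ParameterSpace":
        """Fractions bounded by definition; d and q ranges bracketing weak
        through strong interference/switching; W and K bracketing plausible
        lake biomass densities, searched on log scale."""
        return cls(
            bounds={
                "f_r": (0.01, 1.0),
                "f_J_invertebrate": (0.01, 1.0),
                "f_J_vertebrate": (0.01, 1.0),
                "d": (0.0, 2.0),
                "q": (0.0, 2.0),
                "W": (1e-8, 1e-1),
                "K": (1e-5, 1.0),
            },
            scales={
                "f_r": LINEAR,
                "f_J_invertebrate": LINEAR,
                "f_J_vertebrate": LINEAR,
                "d": LINEAR,
                "q": LINEAR,
                "W": LOG10,
                "K": LOG10,
            },
        )

    # -- coordinate transforms --------------------------------------------

    def _scaled_bounds(self, name: str) -> tuple[float, float]:
        lo, hi = self.bounds[name]
        if self.scales.get(name, LINEAR) == LOG10:
            return np.log10(lo), np.log10(hi)
        return lo, hi

    def to_unit(self, p: FreeParameters) -> np.ndarray:
        u = np.empty(len(FREE_PARAMETER_NAMES))
        for i, name in enumerate(FREE_PARAMETER_NAMES):
            lo, hi = self._scaled_bounds(name)
            v = getattr(p, name)
            if self.scales.get(name, LINEAR) == LOG10:
                v = np.log10(v)
            u[i] = (v - lo) / (hi - lo)
        return u

    def from_unit(self, u: np.ndarray) -> FreeParameters:
        vals = {}
        for i, name in enumerate(FREE_PARAMETER_NAMES):
            lo, hi = self._scaled_bounds(name)
            v = lo + float(np.clip(u[i], 0.0, 1.0)) * (hi - lo)
            if self.scales.get(name, LINEAR) == LOG10:
                v = 10.0 ** v
            vals[name] = v
        return FreeParameters(**vals)

    def contains(self, p: FreeParameters, rtol: float = 1e-9) -> bool:
        for name in FREE_PARAMETER_NAMES:
            lo, hi = self.bounds[name]
            v = getattr(p, name)
            span = hi - lo
            if v < lo - rtol * span or v > hi + rtol * span:
                return False
        return True


_LOGIT_EPS = 1e-9


def _to_z(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, _LOGIT_EPS, 1 - _LOGIT_EPS)
    return np.log(u / (1 - u))


def _from_z(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class FitResult:
    start: FreeParameters
    end: FreeParameters
    score_start: float
    score_end: float
    n_evaluations: int
    converged: bool
    per_community_scores: tuple[float, ...] = ()


def sobol_start_points(
    space: ParameterSpace, n: int, seed: int, scramble: bool = True
) -> list[FreeParameters]:
    """n points of a 7-d Sobol sequence mapped into the box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.Sobol(d=len(FREE_PARAMETER_NAMES), scramble=scramble, seed=seed)
    u = sampler.random(n)
    return [space.from_unit(row) for row in u]


def objective_single(
    p: FreeParameters,
    c: Community,
    fixed: FixedAllometry,
    settings: SimulationSettings,
    kernels: dict[str, np.ndarray] | None = None,
) -> float:
    """Model score of one simulation; 0.0 on solver failure (optimizer-safe)."""
    try:
        sim = simulate_to_stationary(c, fixed, p, settings, kernels=kernels)
    except SimulationError as exc:
        logger.debug("simulation failed at %s: %s", p.to_dict(), exc)
        return 0.0
    return model_score(sim, c).score


def objective_joint(
    p: FreeParameters,
    communities: list[Community],
    fixed: FixedAllometry,
    settings: SimulationSettings,
    kernels_by_community: list[dict | None] | None = None,
) -> float:
    """Arithmetic mean of the single-community score across communities."""
    if len(communities) < 2:
        raise ValueError("joint objective needs at least 2 communities")
    kernels_by_community = kernels_by_community or [None] * len(communities)
    return float(np.mean([
        objective_single(p, c, fixed, settings, kernels=k)
        for c, k in zip(communities, kernels_by_community)
    ]))


def optimize_from_start(
    start: FreeParameters,
    objective,
    space: ParameterSpace,
    max_evaluations: int = 400,
    xatol: float = 1e-3,
    fatol: float = 1e-4,
) -> FitResult:
    """Box-constrained Nelder-Mead (maximization) from one start point."""
    if not space.contains(start):
        raise ValueError("start point lies outside the parameter box")
    best = {"score": -np.inf, "p": start, "n": 0, "failures": 0}

    def neg(z: np.ndarray) -> float:
        p = space.from_unit(_from_z(z))
        try:
            s = float(objective(p))
        except Exception:  # pathological regions must not kill the simplex
            best["failures"] += 1
            s = 0.0
        best["n"] += 1
        if s > best["score"]:
            best["score"], best["p"] = s, p
        return -s

    z0 = _to_z(space.to_unit(start))
    score_start = -neg(z0)
    res = optimize.minimize(
        neg, z0, method="Nelder-Mead",
        options={"maxfev": max_evaluations, "xatol": xatol, "fatol": fatol},
    )
    return FitResult(
        start=start,
        end=best["p"],
        score_start=score_start,
        score_end=best["score"],
        n_evaluations=best["n"],
        converged=bool(res.success) and best["failures"] < best["n"],
    )


def run_fit(
    communities: Community | list[Community],
    space: ParameterSpace,
    n_starts: int,
    seed: int,
    fixed: FixedAllometry,
    settings: SimulationSettings,
    kernels=None,
    max_evaluations: int = 400,
    scramble: bool = True,
) -> list[FitResult]:
    """Independent Nelder-Mead runs from Sobol start points (order-stable).

    ``communities`` may be one community (single objective) or a list
    (joint objective, mean score).  ``kernels`` passes shuffled allometric
    kernels through to rate computation for randomization studies.
    """
    if isinstance(communities, Community):
        def objective(p):
            return objective_single(p, communities, fixed, settings, kernels=kernels)
    elif len(communities) == 1:
        c = communities[0]
        def objective(p):
            return objective_single(p, c, fixed, settings, kernels=kernels)
    else:
        def objective(p):
            return objective_joint(p, list(communities), fixed, settings,
                                   kernels_by_community=kernels)
    starts = sobol_start_points(space, n_starts, seed, scramble=scramble)
    results = []
    for i, start in enumerate(starts):
        fit = optimize_from_start(start, objective, space,
                                  max_evaluations=max_evaluations)
        logger.info("run %d/%d: score %.4f -> %.4f (%d evaluations)",
                    i + 1, n_starts, fit.score_start, fit.score_end,
                    fit.n_evaluations)
        results.append(fit)
    return results


def best_fit(results: list[FitResult]) -> FitResult:
    return max(results, key=lambda f: f.score_end)


def cross_community_scores(
    points: list[FreeParameters],
    c1: Community,
    c2: Community,
    fixed: FixedAllometry,
    settings: SimulationSettings,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Evaluate each parameter point on both communities.

    Returns (scores_1, scores_2, Pearson r); used to ask whether parameters
    that suit one community also suit the other.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 parameter points")
    s1 = np.array([objective_single(p, c1, fixed, settings) for p in points])
    s2 = np.array([objective_single(p, c2, fixed, settings) for p in points])
    r = float(stats.pearsonr(s1, s2).statistic)
    return s1, s2, r
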