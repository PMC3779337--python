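"""Within-category rate shuffling: do the dynamics need allometries?

Shuffling a rate's values among the species of a metabolic category
destroys the body-mass dependence of that rate while preserving its
aggregate statistics (the per-category multiset of values is unchanged).
Because the fitted fraction-of-maximum factors (f_r, f_J) multiply whole
categories uniformly and are re-fitted after shuffling, the study shuffles
the allometric kernels M^-0.25 and lets the optimizer rescale them — the
realized rates are the category constant times the kernel, so this is the
same family of randomizations.  Ingestion is shuffled at the consumer
level (every link of a consumer carries that consumer's rate, so all of a
consumer's links move together).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import Community, INVERTEBRATE, PRODUCER, VERTEBRATE
from .dynamics import SimulationSettings, simulate_to_stationary
from .fitting import FitResult, ParameterSpace, best_fit, run_fit
from .model import FixedAllometry, RateSet, allometric_kernels
from .scoring import model_score

TARGETS = ("r", "T", "J")


@dataclass(frozen=True)
class RandomizationPlan:
    target: str                  # which rate to shuffle: r | T | J
    n_replicates: int = 3        # independent shuffles, to avoid relying on one
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _group_masks(c: Community, target: str) -> list[np.ndarray]:
    if target == "r":
        return [c.category_mask(PRODUCER)]
    # T and J both live on consumers, shuffled within each consumer category
    return [c.category_mask(INVERTEBRATE), c.category_mask(VERTEBRATE)]


def category_permutation(c: Community, target: str, rng: np.random.Generator
                         ) -> np.ndarray:
    """A permutation of species indices that mixes only within the shuffled
    groups; identity everywhere else."""
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    perm = np.arange(c.n_species)
    for mask in _group_masks(c, target):
        idx = np.flatnonzero(mask)
        perm[idx] = rng.permutation(idx)
    return perm


def shuffle_rates(rs: RateSet, c: Community, target: str, seed: int) -> RateSet:
    """Permute the target rate's values within metabolic categories.

    Operates on raw (not yet time-normalized) rates; structural zeros never
    cross the producer/consumer divide because groups are category-pure.
    """
    if rs.time_unit != "raw":
        raise ValueError("shuffle raw rates, then re-normalize time")
    rng = np.random.default_rng(seed)
    perm = category_permutation(c, target, rng)
    r, T, J = rs.r.copy(), rs.T.copy(), rs.J.copy()
    if target == "r":
        r = r[perm]
    elif target == "T":
        T = T[perm]
    else:
        _, con_idx = c.link_indices()
        J_species = np.zeros(c.n_species)
        J_species[con_idx] = rs.J          # per-consumer value (constant per j)
        J = J_species[perm][con_idx]
    return RateSet(r=r, T=T, J=J, time_unit="raw")


def shuffled_kernels(
    c: Community, target: str, seed: int, exponent: float = -0.25
) -> dict[str, np.ndarray]:
    """Allometric kernels M^exponent with the target kernel permuted within
    categories; feed to compute_rates/run_fit to fit under shuffled rates."""
    rng = np.random.default_rng(seed)
    perm = category_permutation(c, target, rng)
    kernels = allometric_kernels(c, exponent)
    kernels[target] = kernels[target][perm]
    return kernels


@dataclass(frozen=True)
class RandomizationReport:
    target: str
    baseline_best: FitResult
    baseline_best_sse: float | None
    replicate_fits: tuple[FitResult, ...]        # best fit per replicate
    replicate_best_sse: tuple[float | None, ...]  # SSE at full coexistence, or None
    n_below_baseline: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "which": "allometric",
            "best_score": self.baseline_best.score_end,
            "best_coexistence_sse": self.baseline_best_sse,
        }]
        for i, (fit, sse) in enumerate(
            zip(self.replicate_fits, self.replicate_best_sse)
        ):
            rows.append({
                "which": f"shuffled_{self.target}_{i + 1}",
                "best_score": fit.score_end,
                "best_coexistence_sse": sse,
            })
        return pd.DataFrame(rows)


def _endpoint_sse(
    fits: list[FitResult],
    c: Community,
    fixed: FixedAllometry,
    settings: SimulationSettings,
    kernels=None,
) -> float | None:
    """Minimum SSE_model among endpoints achieving full coexistence."""
    best_sse = None
    for fit in fits:
        sim = simulate_to_stationary(c, fixed, fit.end, settings, kernels=kernels)
        report = model_score(sim, c)
        if report.n_persisting == c.n_species:
            if best_sse is None or report.sse_model < best_sse:
                best_sse = report.sse_model
    return best_sse


def run_randomization_study(
    c: Community,
    plan: RandomizationPlan,
    space: ParameterSpace,
    n_starts: int,
    fixed: FixedAllometry,
    settings: SimulationSettings,
    baseline: list[FitResult] | None = None,
    max_evaluations: int = 400,
) -> RandomizationReport:
    """Fit the free parameters under shuffled kernels and compare with the
    allometric baseline.

    Each replicate draws its own permutation (deterministically from
    plan.seed), refits from the same Sobol starts, and records the best
    score and the best SSE among endpoints with full coexistence.
    """
    if baseline is None:
        baseline = run_fit(c, space, n_starts, plan.seed, fixed, settings,
                           max_evaluations=max_evaluations)
    base_best = best_fit(baseline)
    base_sse = _endpoint_sse(baseline, c, fixed, settings)

    seeds = np.random.SeedSequence(plan.seed).generate_state(plan.n_replicates)
    rep_fits, rep_sses = [], []
    for rep_seed in seeds:
        rep_seed = int(rep_seed % (2 ** 31))
        kernels = shuffled_kernels(c, plan.target, rep_seed,
                                   fixed.allometric_exponent)
        fits = run_fit(c, space, n_starts, plan.seed, fixed, settings,
                       kernels=kernels, max_evaluations=max_evaluations)
        rep_fits.append(best_fit(fits))
        rep_sses.append(_endpoint_sse(fits, c, fixed, settings, kernels=kernels))
    n_below = sum(f.score_end < base_best.score_end for f in rep_fits)
    return RandomizationReport(
        target=plan.target,
        baseline_best=base_best,
        baseline_best_sse=base_sse,
        replicate_fits=tuple(rep_fits),
        replicate_best_sse=tuple(rep_sses),
        n_below_baseline=n_below,
    )
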