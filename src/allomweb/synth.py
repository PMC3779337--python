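"""Seeded synthetic communities with lake-like size structure.

The generator emulates the statistical skeleton the analysis assumes of a
pelagic lake community: three metabolic categories occupying disjoint
log-mass ranges spanning many orders of magnitude (phytoplankton-like
producers, zooplankton-like invertebrates, a few fish-like vertebrate
ectotherms); average densities following a power law
log10(N) = a + b log10(M) with lognormal scatter; size-structured diets
(a consumer eats the species whose log10 mass ratio to itself falls in a
window below zero); and a handful of producers that nothing eats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources

import numpy as np
import yaml

from .community import (
    Community,
    INVERTEBRATE,
    PRODUCER,
    Species,
    VERTEBRATE,
    read_community,
)


class SyntheticSpecError(ValueError):
    """The requested structure cannot be generated; names the constraint."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic community.

    Mass ranges are (low, high) in log10 kg and must be disjoint and ordered
    producer < invertebrate < vertebrate.  The abundance law is
    log10(N) = intercept + slope * log10(M) + Normal(0, scatter).  The diet
    window (lower, upper) is in log10(M_resource / M_consumer); a window
    containing 0 permits cannibalism.
    """

    n_producers: int
    n_invertebrates: int
    n_vertebrates: int
    producer_log10_mass: tuple[float, float]
    invertebrate_log10_mass: tuple[float, float]
    vertebrate_log10_mass: tuple[float, float]
    abundance_intercept: float
    abundance_slope: float
    abundance_scatter: float
    diet_window: tuple[float, float]
    target_links: int
    n_orphan_producers: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_producers < 1:
            raise SyntheticSpecError("need at least one producer")
        if min(self.n_invertebrates, self.n_vertebrates) < 0:
            raise SyntheticSpecError("category counts must be >= 0")
        ranges = [self.producer_log10_mass, self.invertebrate_log10_mass,
                  self.vertebrate_log10_mass]
        for lo, hi in ranges:
            if not (lo < hi):
                raise SyntheticSpecError("mass ranges must satisfy low < high")
        if not (ranges[0][1] <= ranges[1][0] <= ranges[1][1] <= ranges[2][0]):
            raise SyntheticSpecError(
                "mass ranges must be disjoint and ordered "
                "producer < invertebrate < vertebrate"
            )
        if self.abundance_scatter < 0:
            raise SyntheticSpecError("abundance_scatter must be >= 0")
        if not (self.diet_window[0] < self.diet_window[1]):
            raise SyntheticSpecError("diet window lower must be below upper")
        if self.n_orphan_producers < 0 or self.n_orphan_producers > self.n_producers:
            raise SyntheticSpecError("n_orphan_producers out of range")
        if self.target_links < self.n_invertebrates + self.n_vertebrates:
            raise SyntheticSpecError(
                "target_links below one link per consumer is infeasible"
            )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        for key in ("producer_log10_mass", "invertebrate_log10_mass",
                    "vertebrate_log10_mass", "diet_window"):
            payload[key] = tuple(payload[key])
        return cls(**payload)


def default_tuesday_like_spec() -> SyntheticSpec:
    """A 50-species community shaped like a well-studied north-temperate
    lake: 25 producers, 22 invertebrates, 3 fish, 269 links, 6 producers
    with no consumers, masses spanning 14 orders of magnitude."""
    return SyntheticSpec(
        n_producers=25,
        n_invertebrates=22,
        n_vertebrates=3,
        producer_log10_mass=(-15.0, -11.0),
        invertebrate_log10_mass=(-11.0, -6.0),
        vertebrate_log10_mass=(-3.0, -1.0),
        abundance_intercept=-2.0,
        abundance_slope=-0.8,
        abundance_scatter=0.6,
        diet_window=(-8.0, -0.5),
        target_links=269,
        n_orphan_producers=6,
        label="tuesday-like",
    )


def default_small_spec() -> SyntheticSpec:
    """The shipped 12-species test-bed: same architecture at a size where a
    full fit runs in seconds, with mass ranges and scatter narrowed so that
    coexistence is reachable inside the default parameter box."""
    return SyntheticSpec(
        n_producers=6,
        n_invertebrates=5,
        n_vertebrates=1,
        producer_log10_mass=(-13.0, -12.0),
        invertebrate_log10_mass=(-10.0, -8.0),
        vertebrate_log10_mass=(-7.0, -6.0),
        abundance_intercept=-2.0,
        abundance_slope=-0.8,
        abundance_scatter=0.5,
        diet_window=(-6.0, -0.5),
        target_links=18,
        n_orphan_producers=0,
        label="small-12",
    )


def _feasible_pairs(log_m: np.ndarray, is_consumer: np.ndarray,
                    window: tuple[float, float]) -> set[tuple[int, int]]:
    lo, hi = window
    pairs = set()
    for j in np.flatnonzero(is_consumer):
        ratio = log_m - log_m[j]
        for i in np.flatnonzero((ratio >= lo) & (ratio <= hi)):
            pairs.add((int(i), int(j)))
    return pairs


def generate_community(spec: SyntheticSpec, seed: int) -> Community:
    """Draw one community; deterministic given (spec, seed).

    Masses are log-uniform within category ranges; densities follow the
    abundance law; the diet starts from every window-feasible pair and is
    pruned/augmented at random toward target_links under the constraints
    that every consumer keeps at least one resource and every non-orphan
    producer keeps at least one consumer.
    """
    rng = np.random.default_rng(seed)
    counts = {
        PRODUCER: spec.n_producers,
        INVERTEBRATE: spec.n_invertebrates,
        VERTEBRATE: spec.n_vertebrates,
    }
    ranges = {
        PRODUCER: spec.producer_log10_mass,
        INVERTEBRATE: spec.invertebrate_log10_mass,
        VERTEBRATE: spec.vertebrate_log10_mass,
    }
    prefixes = {PRODUCER: "p", INVERTEBRATE: "i", VERTEBRATE: "v"}

    cats, log_m, ids = [], [], []
    for cat in (PRODUCER, INVERTEBRATE, VERTEBRATE):
        lo, hi = ranges[cat]
        draws = np.sort(rng.uniform(lo, hi, size=counts[cat]))
        for k, lm in enumerate(draws):
            cats.append(cat)
            log_m.append(lm)
            ids.append(f"{prefixes[cat]}{k + 1:02d}")
    log_m = np.array(log_m)
    n = len(ids)
    log_n = (spec.abundance_intercept + spec.abundance_slope * log_m
             + rng.normal(0.0, spec.abundance_scatter, size=n))

    is_consumer = np.array([c != PRODUCER for c in cats])
    feasible = _feasible_pairs(log_m, is_consumer, spec.diet_window)
    for j in np.flatnonzero(is_consumer):
        if not any(p[1] == j for p in feasible):
            raise SyntheticSpecError(
                f"consumer {ids[j]} has no feasible resource: the diet "
                f"window {spec.diet_window} excludes every smaller species"
            )

    # choose orphan producers whose removal leaves every consumer fed
    producers = [i for i, c in enumerate(cats) if c == PRODUCER]
    res_count = {int(j): sum(1 for p in feasible if p[1] == j)
                 for j in np.flatnonzero(is_consumer)}
    orphans: set[int] = set()
    for cand in rng.permutation(producers):
        if len(orphans) == spec.n_orphan_producers:
            break
        cand_links = [p for p in feasible if p[0] == cand]
        if all(res_count[j] > 1 for _, j in cand_links):
            orphans.add(int(cand))
            for _, j in cand_links:
                res_count[j] -= 1
            feasible -= set(cand_links)
    if len(orphans) < spec.n_orphan_producers:
        raise SyntheticSpecError(
            "cannot leave that many producers unconsumed without starving a "
            "consumer; reduce n_orphan_producers or widen the diet window"
        )
    for i in producers:
        if i not in orphans and not any(p[0] == i for p in feasible):
            raise SyntheticSpecError(
                f"producer {ids[i]} has no feasible consumer, so exactly "
                f"{spec.n_orphan_producers} orphan producers cannot be "
                "guaranteed; widen the diet window"
            )

    links = set(feasible)
    res_cnt = {j: 0 for j in range(n)}
    cons_cnt = {i: 0 for i in range(n)}
    for i, j in links:
        res_cnt[j] += 1
        cons_cnt[i] += 1

    while len(links) > spec.target_links:
        removable = sorted(
            p for p in links
            if res_cnt[p[1]] > 1
            and (cats[p[0]] != PRODUCER or p[0] in orphans
                 or cons_cnt[p[0]] > 1)
        )
        if not removable:
            raise SyntheticSpecError(
                f"cannot prune to {spec.target_links} links without starving "
                "a consumer or orphaning a producer"
            )
        i, j = removable[int(rng.integers(len(removable)))]
        links.remove((i, j))
        res_cnt[j] -= 1
        cons_cnt[i] -= 1
    if len(links) < spec.target_links:
        raise SyntheticSpecError(
            f"only {len(links)} window-feasible links exist but "
            f"target_links = {spec.target_links}; widen the diet window"
        )

    species = tuple(
        Species(
            id=ids[i],
            name=f"{cats[i]} {ids[i]}",
            body_mass=float(10.0 ** log_m[i]),
            observed_density=float(10.0 ** log_n[i]),
            category=cats[i],
        )
        for i in range(n)
    )
    link_ids = frozenset((ids[i], ids[j]) for i, j in links)
    return Community(label=spec.label, species=species, links=link_ids)


def model_conditioned_densities(
    c: Community,
    fixed,
    free,
    settings=None,
    noise_sigma: float = 0.15,
    seed: int = 0,
) -> Community:
    """Replace observed densities by a reference model equilibrium plus
    lognormal measurement noise.

    Real community data carry trophic structure beyond a pure power law —
    the structure a mechanistic model can capture and a regression cannot.
    Purely line-plus-noise densities lack it, so a test-bed built from them
    cannot reward the model over the regression even in principle.
    Conditioning the densities on a known-good parameter point restores
    that structure while keeping the community synthetic and seeded.  The
    reference point must give coexistence of every species.
    """
    from .dynamics import simulate_to_stationary  # local: avoid import cycle

    sim = simulate_to_stationary(c, fixed, free, settings)
    if not sim.persisting.all():
        raise SyntheticSpecError(
            "reference parameters lose species; densities can only be "
            "conditioned on a full-coexistence equilibrium"
        )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, size=c.n_species)
    species = tuple(
        replace(sp, observed_density=float(sim.N_sim[i] * 10.0 ** noise[i]))
        for i, sp in enumerate(c.species)
    )
    return Community(label=c.label, species=species, links=c.links)


# The shipped 12-species fixture: structure drawn from default_small_spec
# with FIXTURE_SEED, densities conditioned on the reference parameter point
# below (a validated full-coexistence equilibrium) with 0.15 dex of
# lognormal measurement noise.
FIXTURE_SEED = 1
FIXTURE_NOISE_SIGMA = 0.15
FIXTURE_REFERENCE = {
    "f_r": 0.8, "f_J_invertebrate": 0.9, "f_J_vertebrate": 0.85,
    "d": 0.6, "q": 1.1, "W": 5e-4, "K": 4e-3,
}


def make_fixture_community() -> Community:
    """Regenerate the shipped 12-species fixture from scratch."""
    from .dynamics import SimulationSettings
    from .model import FixedAllometry, FreeParameters

    c = generate_community(default_small_spec(), FIXTURE_SEED)
    settings = SimulationSettings(t_max=3e5, window=5000, window_points=60,
                                  stationarity_tol=1e-6, rel_tol=1e-8)
    return model_conditioned_densities(
        c, FixedAllometry.default(), FreeParameters(**FIXTURE_REFERENCE),
        settings, noise_sigma=FIXTURE_NOISE_SIGMA, seed=FIXTURE_SEED,
    )


def load_fixture_community() -> Community:
    """The shipped 12-species community (make_fixture_community stored as
    CSV so external tools can read it; a test pins the equivalence)."""
    base = importlib_resources.files("allomweb").joinpath("fixtures")
    with importlib_resources.as_file(base.joinpath("small12_nodes.csv")) as nodes:
        with importlib_resources.as_file(base.joinpath("small12_links.csv")) as links:
            return read_community(nodes, links, label="small-12")
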