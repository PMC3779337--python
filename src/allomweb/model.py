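"""Allometric rates and the bioenergetic biomass-dynamics vector field.

The model tracks the biomass density B_j (kg m^-3) of each population:

    dB_j/dt = r_j G_j(B) B_j                       (producer growth)
            - T_j B_j                              (respiration)
            + B_j sum_i e_ij J_ij F_ij(B)          (gains over resources i)
            - sum_k B_k J_jk F_jk(B) / f_ejk       (losses to consumers k)

with a shared logistic growth model G_j = 1 - (total producer biomass)/K,
and a type II/III functional response with predator interference

    F_ij = B_i^(1+q) / [ W^(1+q) (1 + d B_j) + sum_{k in resources(j)} B_k^(1+q) ].

All mass-specific rates follow quarter-power allometries: r_j, T_j and J_ij
are a coefficient (by metabolic category) times M^-0.25, times a fitted
fraction-of-maximum factor for growth and ingestion.  The division of the
predation loss by the ingestion efficiency f_e expresses that consumers
remove more biomass from their resources than they actually ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources as importlib_resources
from pathlib import Path

import numpy as np
import yaml

from .community import Community, PRODUCER, INVERTEBRATE, VERTEBRATE

FREE_PARAMETER_NAMES = ("f_r", "f_J_invertebrate", "f_J_vertebrate", "d", "q", "W", "K")


@dataclass(frozen=True)
class FixedAllometry:
    """Allometric coefficients and efficiencies held fixed during fitting.

    Rates are ``a * M**allometric_exponent`` with M in kg; ``a_r`` applies to
    producers, the ``a_J``/``a_T`` pairs to invertebrate and vertebrate
    ectotherm consumers.  ``e_producer_link`` / ``e_animal_link`` are
    assimilation efficiencies by resource type; ``f_e`` is the ingestion
    efficiency (fraction of killed biomass actually ingested).
    """

    a_r: float
    a_J_invertebrate: float
    a_J_vertebrate: float
    a_T_invertebrate: float
    a_T_vertebrate: float
    allometric_exponent: float = -0.25
    e_producer_link: float = 0.45
    e_animal_link: float = 0.85
    f_e: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a_r", "a_J_invertebrate", "a_J_vertebrate",
                     "a_T_invertebrate", "a_T_vertebrate"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        for name in ("e_producer_link", "e_animal_link", "f_e"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "FixedAllometry":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    @classmethod
    def default(cls) -> "FixedAllometry":
        """Coefficients from the shipped, documented constants file."""
        ref = importlib_resources.files("allomweb").joinpath(
            "data/allometric_constants.yaml"
        )
        with importlib_resources.as_file(ref) as path:
            return cls.from_yaml(path)

    def a_J(self, category: str) -> float:
        return {INVERTEBRATE: self.a_J_invertebrate,
                VERTEBRATE: self.a_J_vertebrate}[category]

    def a_T(self, category: str) -> float:
        return {INVERTEBRATE: self.a_T_invertebrate,
                VERTEBRATE: self.a_T_vertebrate}[category]


@dataclass(frozen=True)
class FreeParameters:
    """The seven quantities physiological allometries leave undetermined.

    f_r and the two f_J are fractions of maximum rate realized in context,
    in (0, 1]; d >= 0 is predator-interference strength; q >= 0 shapes the
    functional response (0: type II, >0: type III); W > 0 is the
    half-saturation biomass density (kg m^-3); K > 0 the global producer
    carrying capacity (kg m^-3).
    """

    f_r: float
    f_J_invertebrate: float
    f_J_vertebrate: float
    d: float
    q: float
    W: float
    K: float

    def __post_init__(self) -> None:
        for name in ("f_r", "f_J_invertebrate", "f_J_vertebrate"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if not (self.W > 0):
            raise ValueError("W must be > 0")
        if not (self.K > 0):
            raise ValueError("K must be > 0")

    def f_J(self, category: str) -> float:
        return {INVERTEBRATE: self.f_J_invertebrate,
                VERTEBRATE: self.f_J_vertebrate}[category]

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FREE_PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "FreeParameters":
        return cls(**{name: float(d[name]) for name in FREE_PARAMETER_NAMES})

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FREE_PARAMETER_NAMES])

    @classmethod
    def from_array(cls, x) -> "FreeParameters":
        return cls(**{name: float(v) for name, v in zip(FREE_PARAMETER_NAMES, x)})


@dataclass(frozen=True)
class RateSet:
    """Realized per-species growth (r) and respiration (T) rates and the
    per-link ingestion rates J, aligned with Community.link_indices().

    r is zero exactly on non-producers and T zero exactly on producers.
    J_ij depends only on the consumer j: every link of a consumer carries the
    consumer's ingestion rate.  ``time_unit`` records whether rates are raw
    (1/time in the coefficient units) or normalized to the growth rate of the
    smallest-bodied producer.
    """

    r: np.ndarray
    T: np.ndarray
    J: np.ndarray
    time_unit: str = "raw"  # "raw" | "normalized"
    normalization_constant: float | None = None

    def scaled(self, divisor: float, time_unit: str) -> "RateSet":
        return RateSet(
            r=self.r / divisor,
            T=self.T / divisor,
            J=self.J / divisor,
            time_unit=time_unit,
            normalization_constant=divisor,
        )


# ---------------------------------------------------------------------------
# cached per-community index structure


@dataclass(frozen=True)
class _Structure:
    res_idx: np.ndarray        # per-link resource index
    con_idx: np.ndarray        # per-link consumer index
    producer_mask: np.ndarray
    masses: np.ndarray
    n: int

    def consumer_sums(self, per_link: np.ndarray) -> np.ndarray:
        return np.bincount(self.con_idx, weights=per_link, minlength=self.n)

    def resource_sums(self, per_link: np.ndarray) -> np.ndarray:
        return np.bincount(self.res_idx, weights=per_link, minlength=self.n)


@lru_cache(maxsize=128)
def _structure(c: Community) -> _Structure:
    res_idx, con_idx = c.link_indices()
    return _Structure(
        res_idx=res_idx,
        con_idx=con_idx,
        producer_mask=c.producer_mask,
        masses=c.masses,
        n=c.n_species,
    )


def link_assimilation(c: Community, fixed: FixedAllometry) -> np.ndarray:
    """Per-link assimilation efficiency e_ij, set by the resource's type."""
    s = _structure(c)
    prod = s.producer_mask[s.res_idx]
    return np.where(prod, fixed.e_producer_link, fixed.e_animal_link)


# ---------------------------------------------------------------------------
# operations


def allometric_kernels(c: Community, exponent: float = -0.25) -> dict[str, np.ndarray]:
    """Per-species mass kernels M^exponent for the r, T and J rates.

    Returned separately per rate so that randomization studies can permute
    one rate's kernel within metabolic categories without touching the
    others.
    """
    k = c.masses ** exponent
    return {"r": k.copy(), "T": k.copy(), "J": k.copy()}


def compute_rates(
    c: Community,
    fixed: FixedAllometry,
    free: FreeParameters,
    kernels: dict[str, np.ndarray] | None = None,
) -> RateSet:
    """Realized allometric rates for every species and link (raw time units).

    r_j = f_r a_r M_j^-0.25 on producers (else 0); T_j = a_T(cat) M_j^-0.25
    on consumers (else 0); J_ij = f_J(cat j) a_J(cat j) M_j^-0.25 on every
    link, a function of the consumer only.  ``kernels`` overrides the
    mass-dependent factor per rate (used by within-category shuffling).
    """
    s = _structure(c)
    if kernels is None:
        kernels = allometric_kernels(c, fixed.allometric_exponent)
    cats = np.array(c.categories)

    r = np.where(s.producer_mask, free.f_r * fixed.a_r * kernels["r"], 0.0)

    aT = np.zeros(s.n)
    aJ = np.zeros(s.n)
    fJ = np.zeros(s.n)
    for cat, a_T, a_J, f_J in (
        (INVERTEBRATE, fixed.a_T_invertebrate, fixed.a_J_invertebrate,
         free.f_J_invertebrate),
        (VERTEBRATE, fixed.a_T_vertebrate, fixed.a_J_vertebrate,
         free.f_J_vertebrate),
    ):
        m = cats == cat
        aT[m], aJ[m], fJ[m] = a_T, a_J, f_J
    T = np.where(~s.producer_mask, aT * kernels["T"], 0.0)

    J_species = fJ * aJ * kernels["J"]  # zero on producers (fJ=aJ=0 there)
    J = J_species[s.con_idx]
    if J.size and not np.all(J > 0):
        raise ValueError("every link must carry a positive ingestion rate")
    return RateSet(r=r, T=T, J=J, time_unit="raw")


def normalize_time(rs: RateSet, c: Community) -> RateSet:
    """Rescale every rate by the growth rate of the smallest-bodied producer.

    After normalization that producer's r equals exactly 1 and one model
    time unit is one generation of the fastest producer.
    """
    s = _structure(c)
    if not s.producer_mask.any():
        raise ValueError("cannot normalize time: community has no producers")
    if rs.time_unit != "raw":
        raise ValueError("rates are already normalized")
    prod_idx = np.flatnonzero(s.producer_mask)
    smallest = prod_idx[np.argmin(s.masses[prod_idx])]
    r_star = rs.r[smallest]
    if not (r_star > 0):
        raise ValueError("smallest-bodied producer has zero growth rate")
    return rs.scaled(r_star, "normalized")


def growth_model(B: np.ndarray, c: Community, K: float) -> np.ndarray:
    """Normalized producer growth G_j = 1 - (total producer biomass)/K.

    All competition coefficients equal 1, so producers share one global
    carrying capacity and G is identical across producers.  May be negative
    when total producer biomass overshoots K.
    """
    s = _structure(c)
    B = np.maximum(np.asarray(B, dtype=float), 0.0)
    G = 1.0 - B[s.producer_mask].sum() / K
    return np.full(int(s.producer_mask.sum()), G)


def functional_response(
    B: np.ndarray, c: Community, q: float, W: float, d: float
) -> np.ndarray:
    """Per-link normalized consumption F_ij in [0, 1).

    F_ij = B_i^(1+q) / [W^(1+q) (1 + d B_j) + sum_k B_k^(1+q)], the sum over
    the consumer j's resources.  q = 0 gives a type II response, q > 0 a
    sigmoid type III; a single resource at B_i = W with d B_j = 0 gives
    exactly 0.5 for every q.
    """
    s = _structure(c)
    B = np.maximum(np.asarray(B, dtype=float), 0.0)
    expo = 1.0 + q
    Bpow = B ** expo
    # same numpy power path as Bpow, so B_i == W gives exactly F = 0.5
    Wpow = float(np.asarray(W) ** expo)
    S = s.consumer_sums(Bpow[s.res_idx])
    denom = Wpow * (1.0 + d * B[s.con_idx]) + S[s.con_idx]
    return Bpow[s.res_idx] / denom


def biomass_derivative(
    B: np.ndarray,
    rs: RateSet,
    c: Community,
    fixed: FixedAllometry,
    free: FreeParameters,
) -> np.ndarray:
    """The model vector field dB/dt evaluated at state B.

    Negative entries of B (transient solver excursions) are clamped to zero
    for rate evaluation only; the caller owns the state.
    """
    s = _structure(c)
    B = np.asarray(B, dtype=float)
    if B.shape != (s.n,):
        raise ValueError(f"state has shape {B.shape}, expected ({s.n},)")
    Bc = np.maximum(B, 0.0)

    G = 1.0 - Bc[s.producer_mask].sum() / free.K
    F = functional_response(Bc, c, free.q, free.W, free.d)
    e = link_assimilation(c, fixed)

    JF = rs.J * F
    gain = Bc * s.consumer_sums(e * JF)
    loss = s.resource_sums(Bc[s.con_idx] * JF) / fixed.f_e
    return rs.r * G * Bc - rs.T * Bc + gain - loss
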