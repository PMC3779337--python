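"""Allometric rates, growth model, functional response, vector field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import allomweb as aw
from allomweb.community import Community
from allomweb.model import compute_rates, normalize_time

from conftest import make_species, pair_community, random_web, single_producer_community


# ---------------------------------------------------------------------------
# rates


def test_unit_mass_producer_growth_equals_coefficient(fixed):
    c = single_producer_community(mass=1.0)
    free = aw.FreeParameters(f_r=1.0, f_J_invertebrate=0.5, f_J_vertebrate=0.5,
                             d=0.0, q=0.0, W=1e-3, K=1e-2)
    rs = compute_rates(c, fixed, free)
    assert rs.r[0] == pytest.approx(fixed.a_r)


def test_quarter_power_scaling_is_exact(fixed, reference_parameters):
    c1 = pair_community(m_producer=1e-12, m_consumer=1e-8)
    c2 = pair_community(m_producer=2e-12, m_consumer=2e-8)
    rs1 = compute_rates(c1, fixed, reference_parameters)
    rs2 = compute_rates(c2, fixed, reference_parameters)
    factor = 2.0 ** -0.25
    np.testing.assert_allclose(rs2.r[0], rs1.r[0] * factor, rtol=1e-14)
    np.testing.assert_allclose(rs2.T[1], rs1.T[1] * factor, rtol=1e-14)
    np.testing.assert_allclose(rs2.J, rs1.J * factor, rtol=1e-14)


def test_rate_zero_patterns(fixed, reference_parameters, fixture_community):
    rs = compute_rates(fixture_community, fixed, reference_parameters)
    prod = fixture_community.producer_mask
    assert np.all(rs.r[prod] > 0) and np.all(rs.r[~prod] == 0)
    assert np.all(rs.T[~prod] > 0) and np.all(rs.T[prod] == 0)
    assert np.all(rs.J > 0)


def test_invertebrate_consumer_respiration(fixed, reference_parameters):
    c = pair_community(m_consumer=1e-8)
    rs = compute_rates(c, fixed, reference_parameters)
    assert rs.r[1] == 0.0
    assert rs.T[1] == pytest.approx(fixed.a_T_invertebrate * (1e-8) ** -0.25)


def test_normalize_time_uses_smallest_bodied_producer(fixed, reference_parameters):
    c = Community(
        label="two-producers",
        species=(
            make_species(0, aw.PRODUCER, 1e-12),
            make_species(1, aw.PRODUCER, 1e-14),
            make_species(2, aw.INVERTEBRATE, 1e-9),
        ),
        links=frozenset({("s0", "s2"), ("s1", "s2")}),
    )
    rs = compute_rates(c, fixed, reference_parameters)
    nrs = normalize_time(rs, c)
    assert nrs.normalization_constant == pytest.approx(rs.r[1])
    assert nrs.r[1] == pytest.approx(1.0)
    # shared divisor leaves rate ratios invariant
    np.testing.assert_allclose(nrs.J / nrs.T[2], rs.J / rs.T[2], rtol=1e-14)


def test_normalize_time_requires_producers(fixed, reference_parameters):
    c = pair_community()
    rs = compute_rates(c, fixed, reference_parameters)
    with pytest.raises(ValueError):
        normalize_time(normalize_time(rs, c), c)  # double normalization
    no_prod = Community(
        label="c-only", species=(make_species(0, aw.INVERTEBRATE, 1e-9),),
        links=frozenset())
    rs2 = compute_rates(no_prod, fixed, reference_parameters)
    with pytest.raises(ValueError):
        normalize_time(rs2, no_prod)


# ---------------------------------------------------------------------------
# growth model and functional response


@pytest.mark.parametrize("total_fraction, expected", [
    (0.0, 1.0), (0.5, 0.5), (1.0, 0.0),
])
def test_growth_model_linear_in_producer_biomass(total_fraction, expected):
    c = pair_community()
    K = 1e-2
    B = np.array([total_fraction * K, 5e-3])  # consumer biomass is irrelevant
    G = aw.growth_model(B, c, K)
    assert G.shape == (1,)
    assert G[0] == pytest.approx(expected)


@pytest.mark.parametrize("q", [0.0, 0.34, 1.0, 2.0])
def test_half_saturation_for_every_shape_exponent(q):
    c = pair_community()
    W = 3.7e-4
    B = np.array([W, 0.0])  # consumer biomass zero: no interference term
    F = aw.functional_response(B, c, q=q, W=W, d=5.0)
    assert F[0] == 0.5


def test_functional_response_zero_resource_and_interference_third():
    c = pair_community()
    W = 1e-4
    assert aw.functional_response(np.array([0.0, 1.0]), c, 1.0, W, 0.0)[0] == 0.0
    # d * B_consumer = 1 at q = 0: F = W / (2W + W) = 1/3
    F = aw.functional_response(np.array([W, 2.0]), c, 0.0, W, 0.5)
    assert F[0] == pytest.approx(1.0 / 3.0)


@given(st.integers(0, 2 ** 32 - 1))
@settings(max_examples=25, deadline=None)
def test_type_ii_closed_form_at_q_zero(seed):
    rng = np.random.default_rng(seed)
    c = random_web(rng)
    B = rng.uniform(0, 1e-3, c.n_species)
    W, d = 10.0 ** rng.uniform(-5, -2), rng.uniform(0, 2)
    F = aw.functional_response(B, c, 0.0, W, d)
    res_idx, con_idx = c.link_indices()
    S = np.bincount(con_idx, weights=B[res_idx], minlength=c.n_species)
    expected = B[res_idx] / (W * (1 + d * B[con_idx]) + S[con_idx])
    np.testing.assert_allclose(F, expected, rtol=1e-12)


@given(st.integers(0, 2 ** 32 - 1))
@settings(max_examples=25, deadline=None)
def test_functional_response_bounds_and_monotonicity(seed):
    rng = np.random.default_rng(seed)
    c = random_web(rng)
    B = rng.uniform(1e-6, 1e-3, c.n_species)
    q, W, d = rng.uniform(0, 2), 10.0 ** rng.uniform(-5, -2), rng.uniform(0, 2)
    F = aw.functional_response(B, c, q, W, d)
    assert np.all((F >= 0) & (F < 1))
    res_idx, con_idx = c.link_indices()
    # increasing one resource's biomass raises that link's F
    k = rng.integers(len(res_idx))
    B2 = B.copy()
    B2[res_idx[k]] *= 1.5
    assert aw.functional_response(B2, c, q, W, d)[k] > F[k]
    # stronger interference lowers F on links whose consumer has biomass
    F_d = aw.functional_response(B, c, q, W, d + 0.5)
    assert np.all(F_d[B[con_idx] > 0] < F[B[con_idx] > 0])


# ---------------------------------------------------------------------------
# vector field


def naive_derivative(B, rs, c, fixed, free):
    """Independent double-loop evaluation of the biomass dynamics."""
    ids = list(c.ids)
    idx = {sid: i for i, sid in enumerate(ids)}
    res_idx, con_idx = c.link_indices()
    link_order = {(ids[i], ids[j]): k
                  for k, (i, j) in enumerate(zip(res_idx, con_idx))}
    Bc = np.maximum(np.asarray(B, float), 0.0)
    cats = c.categories
    total_producers = sum(Bc[i] for i in range(c.n_species)
                          if cats[i] == aw.PRODUCER)
    G = 1.0 - total_producers / free.K

    def F(i, j):
        resources = c.resources_of(ids[j])
        S = sum(Bc[idx[r]] ** (1 + free.q) for r in resources)
        return Bc[i] ** (1 + free.q) / (
            free.W ** (1 + free.q) * (1 + free.d * Bc[j]) + S)

    out = np.zeros(c.n_species)
    for j in range(c.n_species):
        out[j] = rs.r[j] * G * Bc[j] - rs.T[j] * Bc[j]
        for rid in c.resources_of(ids[j]):
            i = idx[rid]
            e = (fixed.e_producer_link if cats[i] == aw.PRODUCER
                 else fixed.e_animal_link)
            out[j] += Bc[j] * e * rs.J[link_order[(rid, ids[j])]] * F(i, j)
        for cid in c.consumers_of(ids[j]):
            k = idx[cid]
            out[j] -= (Bc[k] * rs.J[link_order[(ids[j], cid)]] * F(j, k)
                       / fixed.f_e)
    return out


def test_derivative_matches_naive_oracle_on_random_webs(fixed):
    rng = np.random.default_rng(2024)
    space = aw.ParameterSpace.default()
    for _ in range(20):
        c = random_web(rng)
        p = space.from_unit(rng.uniform(0, 1, 7))
        rs = normalize_time(compute_rates(c, fixed, p), c)
        B = rng.uniform(0, 1e-3, c.n_species)
        got = aw.biomass_derivative(B, rs, c, fixed, p)
        want = naive_derivative(B, rs, c, fixed, p)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-300)


def test_single_producer_reduces_to_logistic(fixed):
    c = single_producer_community(mass=1e-12)
    free = aw.FreeParameters(f_r=0.7, f_J_invertebrate=0.5, f_J_vertebrate=0.5,
                             d=0.0, q=0.0, W=1e-3, K=2e-3)
    rs = compute_rates(c, fixed, free)
    for B0 in (1e-4, free.K, 5e-3):
        dB = aw.biomass_derivative(np.array([B0]), rs, c, fixed, free)
        assert dB[0] == pytest.approx(rs.r[0] * B0 * (1 - B0 / free.K))
    assert aw.biomass_derivative(np.array([free.K]), rs, c, fixed, free)[0] == 0.0


def test_starving_consumer_decays_at_respiration_rate(fixed, reference_parameters):
    c = pair_community()
    rs = compute_rates(c, fixed, reference_parameters)
    B = np.array([0.0, 2e-4])
    dB = aw.biomass_derivative(B, rs, c, fixed, reference_parameters)
    assert dB[1] == pytest.approx(-rs.T[1] * B[1])


def test_perfect_efficiency_conserves_trophic_flow(reference_parameters):
    lossless = aw.FixedAllometry(
        a_r=1.0, a_J_invertebrate=2.512, a_J_vertebrate=3.52,
        a_T_invertebrate=0.314, a_T_vertebrate=0.88,
        e_producer_link=1.0, e_animal_link=1.0, f_e=1.0)
    rng = np.random.default_rng(7)
    for _ in range(5):
        c = random_web(rng)
        rs = compute_rates(c, lossless, reference_parameters)
        B = rng.uniform(0, 1e-3, c.n_species)
        dB = aw.biomass_derivative(B, rs, c, lossless, reference_parameters)
        # removing growth and respiration must leave a zero-sum exchange
        Bc = np.maximum(B, 0.0)
        G = aw.growth_model(B, c, reference_parameters.K)
        growth = np.zeros(c.n_species)
        growth[c.producer_mask] = rs.r[c.producer_mask] * G * Bc[c.producer_mask]
        resp = rs.T * Bc
        assert np.sum(dB - growth + resp) == pytest.approx(0.0, abs=1e-12)


def test_normalization_scales_derivative_uniformly(fixed, reference_parameters):
    c = pair_community()
    rs = compute_rates(c, fixed, reference_parameters)
    nrs = normalize_time(rs, c)
    B = np.array([3e-4, 5e-5])
    raw = aw.biomass_derivative(B, rs, c, fixed, reference_parameters)
    norm = aw.biomass_derivative(B, nrs, c, fixed, reference_parameters)
    np.testing.assert_allclose(raw, norm * nrs.normalization_constant, rtol=1e-12)
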