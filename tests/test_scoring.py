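"""Model score, regression SSE, spectra, trophic levels, pattern summaries."""

import numpy as np
import pytest

import allomweb as aw
from allomweb.community import Community
from allomweb.dynamics import SimulationResult
from allomweb.scoring import mass_abundance_regression

from conftest import make_species


def fake_sim(c: Community, N_sim: np.ndarray) -> SimulationResult:
    N_sim = np.asarray(N_sim, float)
    B = N_sim * c.masses
    return SimulationResult(B_sim=B, N_sim=N_sim, persisting=B > 0,
                            stationary_kind="equilibrium",
                            elapsed_model_time=0.0)


def community_on_line(n: int = 10, a: float = -2.0, b: float = -0.8,
                      resid: np.ndarray | None = None) -> Community:
    log_m = np.linspace(-13, -7, n)
    log_n = a + b * log_m + (resid if resid is not None else 0.0)
    species = tuple(
        make_species(i, aw.PRODUCER if i < n // 2 else aw.INVERTEBRATE,
                     10.0 ** log_m[i], 10.0 ** log_n[i])
        for i in range(n)
    )
    links = frozenset((f"s{i}", f"s{j}") for j in range(n // 2, n)
                      for i in range(n // 2))
    return Community(label="line", species=species, links=links)


# ---------------------------------------------------------------------------
# model score


def test_perfect_agreement_scores_species_count_plus_one():
    c = community_on_line(8)
    rep = aw.model_score(fake_sim(c, c.observed_densities), c)
    assert rep.n_persisting == 8
    assert rep.sse_model == 0.0
    assert rep.second_term == 1.0
    assert rep.score == 9.0


def test_total_extinction_scores_zero():
    c = community_on_line(5)
    rep = aw.model_score(fake_sim(c, np.zeros(5)), c)
    assert rep.n_persisting == 0 and rep.score == 0.0


def test_single_tenfold_error_gives_sse_one_score_ten_and_a_half():
    c = community_on_line(10)
    N = c.observed_densities.copy()
    N[3] *= 10.0
    rep = aw.model_score(fake_sim(c, N), c)
    assert rep.sse_model == pytest.approx(1.0)
    assert rep.score == pytest.approx(10.5)


def test_score_strictly_decreases_as_one_density_is_perturbed():
    c = community_on_line(6)
    scores = []
    for factor in (1.0, 1.5, 3.0, 10.0, 100.0):
        N = c.observed_densities.copy()
        N[0] *= factor
        scores.append(aw.model_score(fake_sim(c, N), c).score)
    assert all(a > b for a, b in zip(scores, scores[1:]))


def test_score_increases_with_persistence_count():
    c = community_on_line(6)
    N_all = c.observed_densities.copy()
    N_less = N_all.copy()
    N_less[5] = 0.0
    assert (aw.model_score(fake_sim(c, N_all), c).score
            > aw.model_score(fake_sim(c, N_less), c).score)


def test_sse_matches_naive_summation_oracle():
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = rng.integers(3, 8)
        c = community_on_line(int(n), resid=rng.normal(0, 1, int(n)))
        N_sim = c.observed_densities * 10 ** rng.normal(0, 0.5, int(n))
        rep = aw.model_score(fake_sim(c, N_sim), c)
        naive = sum(
            (np.log10(N_sim[i]) - np.log10(c.observed_densities[i])) ** 2
            for i in range(int(n)))
        assert rep.sse_model == pytest.approx(naive, rel=1e-12)


def test_misaligned_inputs_raise():
    c = community_on_line(5)
    with pytest.raises(ValueError):
        aw.model_score(fake_sim(community_on_line(6),
                                np.ones(6)), c)


# ---------------------------------------------------------------------------
# regressions


def test_sse_regression_zero_on_exact_power_law():
    c = community_on_line(7)
    assert aw.sse_regression(c) == pytest.approx(0.0, abs=1e-20)


def test_sse_regression_matches_hand_computed_ols():
    # 4-point toy table; OLS via explicit normal equations
    M = np.array([1e-12, 1e-10, 1e-8, 1e-6])
    N = np.array([1e8, 1e6, 1e5, 1e2])
    x, y = np.log10(M), np.log10(N)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    inter = y.mean() - slope * x.mean()
    expected = ((y - inter - slope * x) ** 2).sum()
    species = tuple(make_species(i, aw.PRODUCER, M[i], N[i]) for i in range(4))
    c = Community(label="toy", species=species, links=frozenset())
    assert aw.sse_regression(c) == pytest.approx(expected, rel=1e-12)


def test_sse_regression_rejects_identical_masses():
    species = tuple(make_species(i, aw.PRODUCER, 1e-9, 10.0 ** i)
                    for i in range(4))
    c = Community(label="deg", species=species, links=frozenset())
    with pytest.raises(ValueError):
        aw.sse_regression(c)


def test_regression_slope_recovers_exact_exponent_and_scale_invariance():
    M = np.logspace(-12, -6, 9)
    N = 1e-3 * M ** -0.75
    r1 = mass_abundance_regression(M, N)
    assert r1.slope == pytest.approx(-0.75, abs=1e-12)
    r2 = mass_abundance_regression(M, N * 100.0)
    assert r2.slope == pytest.approx(r1.slope, abs=1e-12)
    assert r2.intercept == pytest.approx(r1.intercept + 2.0, abs=1e-10)


def test_regression_ci_matches_textbook_formula():
    from scipy import stats
    M = np.array([1e-12, 1e-11, 1e-10, 1e-9, 1e-8])
    N = np.array([3e7, 5e6, 2e6, 1e5, 8e4])
    x, y = np.log10(M), np.log10(N)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    inter = y.mean() - slope * x.mean()
    s2 = ((y - inter - slope * x) ** 2).sum() / (n - 2)
    half = stats.t.ppf(0.975, n - 2) * np.sqrt(s2 / sxx)
    got = mass_abundance_regression(M, N)
    assert got.slope_ci_low == pytest.approx(slope - half, rel=1e-10)
    assert got.slope_ci_high == pytest.approx(slope + half, rel=1e-10)


# ---------------------------------------------------------------------------
# spectrum


def test_spectrum_single_decade_single_bin():
    M = np.array([2e-10, 5e-10, 9e-10])
    N = np.array([1.0, 2.0, 3.0])
    centres, totals = aw.abundance_spectrum(M, N, 1.0)
    assert len(centres) == 1
    assert totals[0] == pytest.approx(6.0)


def test_spectrum_omits_empty_bins_between_occupied_ones():
    M = np.array([1.5e-12, 1.5e-6])
    N = np.array([10.0, 20.0])
    centres, totals = aw.abundance_spectrum(M, N, 1.0)
    assert len(centres) == 2
    np.testing.assert_allclose(centres, [-11.5, -5.5])


def test_spectrum_total_preserved_under_bin_width_change():
    rng = np.random.default_rng(8)
    M = 10 ** rng.uniform(-13, -5, 30)
    N = 10 ** rng.uniform(0, 8, 30)
    for w in (2.0, 1.0, 0.5, 0.25):
        _, totals = aw.abundance_spectrum(M, N, w)
        assert totals.sum() == pytest.approx(N.sum(), rel=1e-12)


# ---------------------------------------------------------------------------
# trophic levels


def five_species_toy_web() -> Community:
    # producers p0, p1; herbivores h2 (eats p0, p1), h3 (eats p0);
    # omnivore o4 (eats p1 and h2) -> TL = 1 + (1 + 2)/2 = 2.5
    species = (
        make_species(0, aw.PRODUCER, 1e-13),
        make_species(1, aw.PRODUCER, 2e-13),
        make_species(2, aw.INVERTEBRATE, 1e-9),
        make_species(3, aw.INVERTEBRATE, 2e-9),
        make_species(4, aw.INVERTEBRATE, 1e-8),
    )
    links = frozenset({("s0", "s2"), ("s1", "s2"), ("s0", "s3"),
                       ("s1", "s4"), ("s2", "s4")})
    return Community(label="toy5", species=species, links=links)


def test_prey_averaged_trophic_levels_exact_on_toy_web():
    tl = aw.prey_averaged_trophic_levels(five_species_toy_web())
    np.testing.assert_allclose(tl, [1.0, 1.0, 2.0, 2.0, 2.5], atol=1e-10)
    assert list(np.floor(tl).astype(int)) == [1, 1, 2, 2, 2]


def test_trophic_levels_solve_their_defining_equations_with_cannibalism():
    c = five_species_toy_web()
    # add a cannibal loop on the omnivore
    c = Community(label="c", species=c.species,
                  links=c.links | {("s4", "s4")})
    tl = aw.prey_averaged_trophic_levels(c)
    for j, sp in enumerate(c.species):
        res = c.resources_of(sp.id)
        if res:
            want = 1 + np.mean([tl[c.index_of(r)] for r in res])
            assert tl[j] == pytest.approx(want, abs=1e-10)
        else:
            assert tl[j] == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# pattern summaries


def test_patterns_identity_when_simulation_reproduces_data():
    c = community_on_line(12, resid=np.random.default_rng(1).normal(0, 0.3, 12))
    pats = aw.summarize_patterns(c, fake_sim(c, c.observed_densities))
    np.testing.assert_allclose(pats.residuals, 0.0, atol=1e-12)
    for g, rd in pats.regressions_data.items():
        rs = pats.regressions_sim[g]
        assert rs.slope == pytest.approx(rd.slope, rel=1e-12)
    # partitions sum to community totals
    total_B = (c.observed_densities * c.masses).sum()
    assert sum(pats.biomass_by_TL_data.values()) == pytest.approx(total_B)
    assert sum(pats.biomass_by_category_data.values()) == pytest.approx(total_B)


def test_small_vertebrate_group_regression_is_omitted(fixture_community,
                                                      fixed,
                                                      reference_parameters,
                                                      fit_settings):
    sim = aw.simulate_to_stationary(fixture_community, fixed,
                                    reference_parameters, fit_settings)
    pats = aw.summarize_patterns(fixture_community, sim)
    assert aw.VERTEBRATE not in pats.regressions_data  # only 1 fish-like species
    assert "all" in pats.regressions_data


def test_generator_slope_recovered_within_confidence_interval():
    spec = aw.default_tuesday_like_spec()
    c = aw.generate_community(spec, seed=4)
    reg = mass_abundance_regression(c.masses, c.observed_densities)
    assert reg.slope_ci_low <= spec.abundance_slope <= reg.slope_ci_high
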