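"""E-step, M-step, transition-density and initialization unit tests."""

import numpy as np
import pytest
from scipy import optimize

from phasemix import (BiParams, Cohort, EMOptions, LatentState, MonoParams,
                      PatientSeries, PopulationParameters, e_step_z,
                      e_step_zeta, fit_em, grid_search_init, m_step,
                      make_scenario, simulate_cohort, update_pi,
                      update_transition_density)
from phasemix._engine import CohortCache, bic_posterior_z, e_step_group
from phasemix.core import psd_sqrt
from phasemix.em import _series_bi_logliks
from phasemix.params import TransitionDensity

TIMES18 = 21.0 * np.arange(18)


def _flat_series(value=0.0):
    return PatientSeries("flat", TIMES18, np.full(18, value))


def test_zeta_uniform_under_symmetry():
    # a constant trajectory with B = 0 in both phases makes every candidate
    # design equally likely
    series = _flat_series()
    bi = BiParams(np.zeros(4), np.zeros((4, 4)))
    zeta = e_step_zeta(series, bi, 25.0, np.full(17, 1 / 17))
    np.testing.assert_allclose(zeta, 1 / 17, atol=1e-12)
    assert zeta.sum() == pytest.approx(1.0, abs=1e-12)


def test_zeta_zero_prior_weight_stays_zero():
    series = _flat_series()
    bi = BiParams(np.zeros(4), np.zeros((4, 4)))
    pi = np.full(17, 1 / 16)
    pi[3] = 0.0
    zeta = e_step_zeta(series, bi, 25.0, pi)
    assert zeta[3] == 0.0
    assert zeta.sum() == pytest.approx(1.0, abs=1e-12)


def test_zeta_recovers_generating_change_point():
    # zero between-patient covariance, sigma = 5, and a kink sharp enough
    # (slope change 8/day, crossing mid-interval at t* = 94.5) that every
    # visit lies many sigma from the other phase's line: the generating k
    # is the posterior mode for every patient
    bi = BiParams([91.0, -4.0, -665.0, 4.0], np.zeros((4, 4)))
    cfg = make_scenario(1, n_patients=40, seed=9, bi_truth=bi, lam=1.0)
    sim = simulate_cohort(cfg)
    for i in range(40):
        zeta = e_step_zeta(sim.cohort[i], bi, 25.0, np.full(17, 1 / 17))
        assert np.argmax(zeta) + 1 == sim.k[i]


def test_zeta_mode_centered_for_shallow_kink():
    # scenario-1 geometry: the two lines cross at t* = 180 with a slope
    # change of only 0.2/day, so adjacent candidates are nearly
    # equivalent; the mode scatters around the generating k without bias
    cfg = make_scenario(1, n_patients=40, seed=9)
    sim = simulate_cohort(cfg)
    diffs = []
    for i in range(40):
        if sim.eta[i]:
            zeta = e_step_zeta(sim.cohort[i], cfg.bi_truth, 25.0,
                               np.full(17, 1 / 17))
            diffs.append(int(np.argmax(zeta)) + 1 - sim.k[i])
    diffs = np.asarray(diffs)
    assert np.all(np.abs(diffs) <= 5)
    assert abs(diffs.mean()) <= 1.5


def test_z_degenerate_mixing_weight():
    series = _flat_series()
    mono = MonoParams(np.zeros(2), np.zeros((2, 2)))
    bi = BiParams(np.zeros(4), np.zeros((4, 4)))
    pi = np.full(17, 1 / 17)
    assert e_step_z(series, mono, bi, 25.0, 0.0, pi) == 0.0
    assert e_step_z(series, mono, bi, 25.0, 1.0, pi) == 1.0


def test_z_equal_penalized_evidence_returns_lambda():
    for lam in (0.2, 0.5, 0.9):
        z = bic_posterior_z(np.array(-12.3), np.array(-12.3), lam)
        assert z == pytest.approx(lam, abs=1e-12)


def test_bic_penalty_gap():
    # when the mono and bi marginal likelihoods coincide, the class odds
    # are the prior odds divided by M (the extra two parameters cost
    # 2 log M on the 2-log-evidence scale: exp(-2 log 18 / 2) = 1/18)
    series = _flat_series(50.0)
    mono = MonoParams([50.0, 0.0], np.zeros((2, 2)))
    bi = BiParams([50.0, 0.0, 50.0, 0.0], np.zeros((4, 4)))
    pi = np.full(17, 1 / 17)
    lam = 0.6
    z = e_step_z(series, mono, bi, 25.0, lam, pi)
    odds = z / (1 - z)
    assert odds == pytest.approx(lam / (1 - lam) / 18.0, rel=1e-9)
    gap = (-4 + 2) * np.log(18)
    assert gap == pytest.approx(-5.7807, abs=5e-4)


# ---------------------------------------------------------------------------
# M-step


def _estep_instance(n=5, seed=4):
    sim = simulate_cohort(make_scenario(2, n_patients=n, seed=seed))
    cohort = sim.cohort
    cfg = sim.config
    cache = CohortCache(cohort)
    pis = cache.gather_pi(None)
    mono = cfg.mono_truth
    bi = cfg.bi_truth
    es = [e_step_group(g, mono, bi, 25.0, 0.6, pi)
          for g, pi in zip(cache.groups, pis)]
    return cohort, cache, es, pis


def _collect_latent(cache, es_groups):
    z = cache.scatter([e.z for e in es_groups])
    zeta = cache.scatter_pi([e.zeta for e in es_groups])
    from phasemix.params import IndividualEstimate
    s_hat = cache.scatter([e.s_hat for e in es_groups])
    s_cov = cache.scatter([e.s_cov for e in es_groups])
    b_hat = cache.scatter_pi([e.b_hat for e in es_groups])
    b_cov = cache.scatter_pi([e.b_cov for e in es_groups])
    individuals = [IndividualEstimate(s_hat[i], s_cov[i], b_hat[i], b_cov[i])
                   for i in range(len(z))]
    return LatentState(z, zeta), individuals


def test_m_step_lambda_is_mean_z():
    cohort, cache, es, _ = _estep_instance()
    latent, individuals = _collect_latent(cache, es)
    latent.z = np.array([1.0, 0.0, 1.0, 0.0, 0.5])
    out = m_step(cohort, latent, individuals)
    assert out.lam == pytest.approx(0.5)


def _q_function(cohort, latent, individuals, params):
    """Expected complete-data penalized log-posterior at fixed latent
    weights and EB moments (priors (sigma2)^-1 and |Sigma|^-1, whose modes
    give the +2 denominators of the closed-form update)."""
    from phasemix.design import build_biphasic_design, build_mono_design
    s, cov_s = params.mono.mean, params.mono.cov
    b, cov_b = params.bi.mean, params.bi.cov
    s2, lam = params.sigma2, params.lam
    inv_s = np.linalg.inv(cov_s)
    inv_b = np.linalg.inv(cov_b)
    total = -np.log(s2) - np.linalg.slogdet(cov_s)[1] \
        - np.linalg.slogdet(cov_b)[1]
    for i, p in enumerate(cohort):
        z = latent.z[i]
        ind = individuals[i]
        m = p.n_obs
        qs = build_mono_design(p.times)
        rs = p.values - qs @ ind.s_hat
        ds = ind.s_hat - s
        total += (1 - z) * (
            np.log1p(-lam)
            - 0.5 * m * np.log(2 * np.pi * s2)
            - 0.5 * (rs @ rs + np.trace(qs @ ind.s_cov @ qs.T)) / s2
            - 0.5 * np.linalg.slogdet(2 * np.pi * cov_s)[1]
            - 0.5 * (ds @ inv_s @ ds + np.trace(inv_s @ ind.s_cov))
        )
        for j in range(m - 1):
            w = z * latent.zeta[i][j]
            if w == 0:
                continue
            qb = build_biphasic_design(p.times, j + 1)
            rb = p.values - qb @ ind.b_hat[j]
            db = ind.b_hat[j] - b
            total += w * (
                np.log(lam)
                - 0.5 * m * np.log(2 * np.pi * s2)
                - 0.5 * (rb @ rb + np.trace(qb @ ind.b_cov[j] @ qb.T)) / s2
                - 0.5 * np.linalg.slogdet(2 * np.pi * cov_b)[1]
                - 0.5 * (db @ inv_b @ db + np.trace(inv_b @ ind.b_cov[j]))
            )
    return total


def test_m_step_matches_numerical_optimum():
    """Closed-form updates coincide with block-wise numerical maximization
    of the expected complete-data penalized log-posterior (<= 5 patients)."""
    cohort, cache, es, _ = _estep_instance(n=5, seed=4)
    latent, individuals = _collect_latent(cache, es)
    out = m_step(cohort, latent, individuals)

    def q_with(**kw):
        mono = MonoParams(kw.get("s", out.mono.mean),
                          kw.get("cov_s", out.mono.cov))
        bi = BiParams(kw.get("b", out.bi.mean), kw.get("cov_b", out.bi.cov))
        return _q_function(cohort, latent, individuals, PopulationParameters(
            mono, bi, kw.get("sigma2", out.sigma2), kw.get("lam", out.lam)))

    # lambda block (scalar)
    r = optimize.minimize_scalar(lambda x: -q_with(lam=x),
                                 bounds=(1e-4, 1 - 1e-4), method="bounded")
    assert r.x == pytest.approx(out.lam, rel=1e-4)

    # sigma2 block (scalar, log parameterization)
    r = optimize.minimize_scalar(lambda x: -q_with(sigma2=np.exp(x)),
                                 bounds=(np.log(out.sigma2) - 2,
                                         np.log(out.sigma2) + 2),
                                 method="bounded")
    assert np.exp(r.x) == pytest.approx(out.sigma2, rel=1e-4)

    # mean blocks
    r = optimize.minimize(lambda x: -q_with(s=x), out.mono.mean * 1.01,
                          method="Nelder-Mead",
                          options={"xatol": 1e-8, "fatol": 1e-10})
    np.testing.assert_allclose(r.x, out.mono.mean, rtol=1e-4)
    r = optimize.minimize(lambda x: -q_with(b=x), out.bi.mean * 1.01,
                          method="Nelder-Mead",
                          options={"xatol": 1e-8, "fatol": 1e-10,
                                   "maxiter": 4000})
    np.testing.assert_allclose(r.x, out.bi.mean, rtol=1e-4)

    # covariance blocks via Cholesky parameterization
    def unpack(x, d):
        c = np.zeros((d, d))
        c[np.tril_indices(d)] = x
        return c @ c.T

    c0 = np.linalg.cholesky(out.mono.cov)
    x0 = c0[np.tril_indices(2)]
    r = optimize.minimize(lambda x: -q_with(cov_s=unpack(x, 2)), x0 * 1.05,
                          method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12,
                                   "maxiter": 4000})
    np.testing.assert_allclose(unpack(r.x, 2), out.mono.cov, rtol=1e-3,
                               atol=1e-8)


def test_m_step_all_mono_pooled_mean():
    # z = 0 everywhere except a token bi weight: S update is the
    # equal-weight pooled mean of the EB estimates and Sigma_S carries
    # the (N + 2) denominator
    cohort, cache, es, _ = _estep_instance(n=4, seed=8)
    latent, individuals = _collect_latent(cache, es)
    eps = 1e-9
    latent.z = np.full(4, eps)
    out = m_step(cohort, latent, individuals)
    s_hat = np.stack([ind.s_hat for ind in individuals])
    np.testing.assert_allclose(out.mono.mean, s_hat.mean(axis=0), rtol=1e-6)
    scatter = sum(
        individuals[i].s_cov + np.outer(s_hat[i] - out.mono.mean,
                                        s_hat[i] - out.mono.mean)
        for i in range(4))
    np.testing.assert_allclose(out.mono.cov, scatter / (4 + 2 * (1 - eps)),
                               rtol=1e-5)


# ---------------------------------------------------------------------------
# transition density and pi


def test_transition_density_single_interval():
    series = PatientSeries("a", [0.0, 21.0, 42.0], [1.0, 2.0, 3.0])
    cohort = Cohort([series])
    latent = LatentState(np.array([1.0]), [np.array([0.0, 1.0])])
    dens = update_transition_density(cohort, latent)
    mid = 0.5 * (dens.breakpoints[:-1] + dens.breakpoints[1:])
    vals = dens.density
    inside = (mid > 21) & (mid < 42)
    np.testing.assert_allclose(vals[inside], 1 / 21, atol=1e-12)
    np.testing.assert_allclose(vals[~inside], 0, atol=1e-12)


def test_transition_density_integrates_to_one(rng):
    patients, zetas, zs = [], [], []
    for i in range(6):
        times = np.sort(rng.uniform(0, 300, 10))
        patients.append(PatientSeries(i, times, rng.normal(size=10)))
        w = rng.dirichlet(np.ones(9))
        zetas.append(w)
        zs.append(rng.random())
    cohort = Cohort(patients)
    dens = update_transition_density(cohort, LatentState(np.array(zs), zetas))
    total = np.sum(dens.density * np.diff(dens.breakpoints))
    assert total == pytest.approx(1.0, abs=1e-8)


def test_transition_density_duplication_invariance():
    times = 21.0 * np.arange(6)
    zeta = np.array([0.1, 0.4, 0.3, 0.15, 0.05])
    one = Cohort([PatientSeries("a", times, np.zeros(6))])
    two = Cohort([PatientSeries("a", times, np.zeros(6)),
                  PatientSeries("b", times, np.zeros(6))])
    d1 = update_transition_density(one, LatentState(np.ones(1), [zeta]))
    d2 = update_transition_density(two, LatentState(np.ones(2),
                                                    [zeta, zeta]))
    np.testing.assert_allclose(d1.density, d2.density, atol=1e-12)


def test_update_pi_uniform_density_even_visits():
    dens = TransitionDensity([0.0, 357.0], [1 / 357.0])
    series = PatientSeries("a", TIMES18, np.zeros(18))
    pi = update_pi(dens, series)
    np.testing.assert_allclose(pi, 1 / 17, atol=1e-12)


def test_update_pi_point_mass():
    dens = TransitionDensity([0.0, 100.0, 105.0, 357.0],
                             [0.0, 0.2, 0.0])
    series = PatientSeries("a", TIMES18, np.zeros(18))
    pi = update_pi(dens, series)
    j = np.searchsorted(TIMES18, 100.0) - 1
    assert pi[j] == pytest.approx(1.0)


def test_update_pi_matches_quadrature_for_shifted_visit():
    # a patient with one visit a week late gets weights proportional to
    # the actual overlap of their intervals with the density
    from scipy.integrate import quad
    rng = np.random.default_rng(0)
    bp = np.concatenate([[0.0], np.sort(rng.uniform(0, 357, 12)), [357.0]])
    vals = rng.random(len(bp) - 1)
    vals /= np.sum(vals * np.diff(bp))
    dens = TransitionDensity(bp, vals)
    times = TIMES18.copy()
    times[8] += 7.0            # one week later than scheduled
    series = PatientSeries("a", times, np.zeros(18))
    pi = update_pi(dens, series)

    def theta(t):
        j = np.clip(np.searchsorted(bp, t, side="right") - 1, 0,
                    len(vals) - 1)
        return vals[j]

    raw = np.array([quad(theta, times[j], times[j + 1], limit=200)[0]
                    for j in range(17)])
    np.testing.assert_allclose(pi, raw / raw.sum(), atol=1e-7)


# ---------------------------------------------------------------------------
# initialization and full EM


def test_grid_init_scenario1_lambda(small_scenario1):
    init = grid_search_init(small_scenario1.cohort)
    assert abs(init.lam - 0.6) < 0.15


def test_grid_init_identical_lines():
    times = TIMES18
    cohort = Cohort([PatientSeries(i, times, 90 - 0.25 * times)
                     for i in range(10)])
    init = grid_search_init(cohort)
    assert init.lam < 0.05
    np.testing.assert_allclose(init.mono.mean, [90, -0.25], atol=1e-6)


def test_grid_init_passthrough():
    explicit = PopulationParameters(
        MonoParams([1.0, 2.0], np.eye(2)), BiParams(np.arange(4.0),
                                                    np.eye(4)), 1.0, 0.5)
    cohort = Cohort([PatientSeries("a", TIMES18, np.zeros(18))])
    assert grid_search_init(cohort, explicit) is explicit


def test_fit_em_all_mono_reduces_to_linear_mixed_model(mono_cohort):
    res = fit_em(mono_cohort, EMOptions(max_iter=300))
    assert res.params.lam < 0.05
    assert abs(res.params.mono.mean[0] - 90) < 1.5
    assert abs(res.params.mono.mean[1] + 0.25) < 0.02
    assert np.all(np.isfinite(res.trace))


def test_fit_em_invariants_each_patient(small_scenario1_fit):
    res = small_scenario1_fit
    assert np.all((res.latent.z >= 0) & (res.latent.z <= 1))
    for zeta, pi in zip(res.latent.zeta, res.params.pi_weights):
        assert zeta.sum() == pytest.approx(1.0, abs=1e-10)
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(pi >= 0)
    assert np.all(np.isfinite(res.trace))


def test_fit_em_recovers_scenario1_parameters(small_scenario1_fit):
    p = small_scenario1_fit.params
    assert abs(p.mono.mean[0] - 90) < 1.5
    assert abs(p.mono.mean[1] + 0.25) < 0.02
    assert abs(p.bi.mean[0] - 91) < 2.0
    assert abs(p.bi.mean[1] + 0.35) < 0.03
    assert abs(p.sigma - 5.0) < 0.8
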