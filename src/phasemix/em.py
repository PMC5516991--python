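"""EM algorithm for the mono/bi-phasic trajectory mixture.

The E-step computes, per patient, the posterior weights of the candidate
change-point designs (zeta) and the BIC-penalized posterior probability of
the bi-phasic class (z); the M-step applies the closed-form weighted-moment
updates; change-point weights pi are refreshed from the cohort-level phasic
transition density so that patients with misaligned visit times share
change-point information on the time axis rather than by visit index.

Model evidences enter the class posterior through negative BIC:
g_mono = 2 log N(Y | mono marginal) - 2 log M and
g_bi = 2 log(sum_j pi_j N_j) - 4 log M, and
z = lam e^{g_bi/2} / ((1-lam) e^{g_mono/2} + lam e^{g_bi/2}).
The BIC substitution breaks the formal EM ascent guarantee, so the
objective trace is monitored and decreases are reported, not hidden.
"""

from __future__ import annotations

import types
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._engine import (CohortCache, bic_posterior_z, e_step_group,
                      grid_init_stats, m_step_moments, normalize_density,
                      observed_objective, pi_from_density, transition_heights)
from .core import gaussian_evidence, psd_sqrt, suff_stats
from .data import Cohort, PatientSeries
from .design import build_biphasic_design, build_mono_design
from .exceptions import (ComponentCollapseError, FitWarning,
                         InitializationError, NumericalError)
from .params import (BiParams, IndividualEstimate, LatentState, MonoParams,
                     PopulationParameters, TransitionDensity)

__all__ = [
    "EMOptions", "EMResult", "fit_em", "grid_search_init",
    "e_step_zeta", "e_step_z", "m_step",
    "update_transition_density", "update_pi",
]


@dataclass
class EMOptions:
    """EM control knobs: iteration cap, objective tolerance, initializer.

    The BIC-penalized class posterior makes the iteration non-monotone,
    so the stopping rule is patience-based: the fit returns the iterate
    with the best penalized observed-data objective, stopping once no
    improvement larger than ``tol`` has occurred for ``patience``
    consecutive iterations.
    """

    max_iter: int = 500
    tol: float = 1e-6
    patience: int = 25
    init: object = "grid"      # "grid" or an explicit PopulationParameters
    seed: int = 0

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EMResult:
    """Mode estimate, soft latent state, EB moments and diagnostics."""

    params: PopulationParameters
    latent: LatentState
    individuals: list
    trace: np.ndarray
    converged: bool
    n_iter: int
    monotone: bool = True
    objective: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# public single-series operations


def _series_bi_logliks(series: PatientSeries, bi: BiParams, sigma2):
    lb = psd_sqrt(bi.cov)
    out = np.empty(series.n_obs - 1)
    for j, q in enumerate(
            build_biphasic_design(series.times, k)
            for k in range(1, series.n_obs)):
        y2, qty, qtq = suff_stats(series.values, q)
        out[j] = gaussian_evidence(y2, qty, qtq, series.n_obs, bi.mean, lb,
                                   sigma2)
    return out


def e_step_zeta(series: PatientSeries, bi: BiParams, sigma2, pi_i):
    """Posterior weights of the M-1 candidate bi-phasic designs."""
    pi_i = np.asarray(pi_i, dtype=float)
    ll = _series_bi_logliks(series, bi, sigma2)
    with np.errstate(divide="ignore"):
        lw = np.where(pi_i > 0, np.log(np.clip(pi_i, 1e-300, None)), -np.inf)
    lw = lw + ll
    norm = logsumexp(lw)
    if not np.isfinite(norm):
        raise NumericalError(
            f"patient {series.patient_id!r}: no candidate design has "
            "positive posterior weight"
        )
    zeta = np.exp(lw - norm)
    return zeta / zeta.sum()


def e_step_z(series: PatientSeries, mono: MonoParams, bi: BiParams,
             sigma2, lam, pi_i) -> float:
    """BIC-penalized posterior probability that a patient is bi-phasic."""
    pi_i = np.asarray(pi_i, dtype=float)
    q = build_mono_design(series.times)
    y2, qty, qtq = suff_stats(series.values, q)
    ll_s = gaussian_evidence(y2, qty, qtq, series.n_obs, mono.mean,
                             psd_sqrt(mono.cov), sigma2)
    ll_b = _series_bi_logliks(series, bi, sigma2)
    with np.errstate(divide="ignore"):
        lw = np.where(pi_i > 0, np.log(np.clip(pi_i, 1e-300, None)), -np.inf)
    log_mix = logsumexp(lw + ll_b)
    log_m = np.log(series.n_obs)
    g_mono = 2.0 * float(ll_s) - 2.0 * log_m
    g_bi = 2.0 * float(log_mix) - 4.0 * log_m
    return float(bic_posterior_z(g_mono, g_bi, lam))


def m_step(cohort: Cohort, latent: LatentState, individuals) \
        -> PopulationParameters:
    """Closed-form M-step from soft latent weights and EB moments.

    Returns the updated population parameters (pi untouched: refresh it
    separately through the transition density).
    """
    cache = CohortCache(cohort)
    groups = []
    for g in cache.groups:
        es = types.SimpleNamespace(
            z=np.asarray([latent.z[i] for i in g.idx], dtype=float),
            zeta=np.stack([latent.zeta[i] for i in g.idx]),
            s_hat=np.stack([individuals[i].s_hat for i in g.idx]),
            s_cov=np.stack([individuals[i].s_cov for i in g.idx]),
            b_hat=np.stack([individuals[i].b_hat for i in g.idx]),
            b_cov=np.stack([individuals[i].b_cov for i in g.idx]),
        )
        groups.append(es)
    s, cov_s, b, cov_b, sigma2, lam = m_step_moments(cache, groups)
    return PopulationParameters(
        MonoParams(s, _clip_psd(cov_s)), BiParams(b, _clip_psd(cov_b)),
        sigma2, lam)


def _clip_psd(cov):
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    return (v * np.clip(w, 0.0, None)) @ v.T


def update_transition_density(cohort: Cohort, latent: LatentState) \
        -> TransitionDensity:
    """Cohort-level phasic transition density theta(t) on [0, T].

    Piecewise constant on the union of all patients' inter-visit
    intervals; each interval (t_ij, t_{i,j+1}) contributes mass
    z_i * zeta_ij spread uniformly over its length, normalized to
    integrate to one.
    """
    cache = CohortCache(cohort)
    weights = [
        np.asarray([latent.z[i] for i in g.idx])[:, None]
        * np.stack([latent.zeta[i] for i in g.idx])
        for g in cache.groups
    ]
    heights, total = transition_heights(cache, weights)
    density, fallback = normalize_density(cache, heights, total)
    if fallback:
        warnings.warn("no bi-phasic mass: transition density is flat",
                      FitWarning, stacklevel=2)
    return TransitionDensity(cache.breakpoints, density)


def update_pi(density: TransitionDensity, series: PatientSeries):
    """Change-point weights from the transition density.

    pi_ij integrates theta over (t_ij, t_{i,j+1}) and is renormalized over
    the patient's own intervals (mass outside the patient's span is
    redistributed proportionally)."""
    raw = density.integral(series.times[:-1], series.times[1:])
    raw = np.clip(raw, 0.0, None)
    tot = raw.sum()
    if tot <= 0.0:
        return np.full(series.n_obs - 1, 1.0 / (series.n_obs - 1))
    return raw / tot


# ---------------------------------------------------------------------------
# initialization


def grid_search_init(cohort: Cohort, grid_spec=None) -> PopulationParameters:
    """Deterministic starting values from per-patient least squares.

    Each patient gets a single-line fit and a best single-change-point
    two-line fit; patients are clustered by per-patient BIC preference;
    within-cluster pooled coefficients seed (S, B), pooled residual
    variance seeds sigma2, the bi-preferring fraction seeds lam, and the
    histogram of preferred change intervals (through the transition
    density) seeds pi.  Passing an explicit
    :class:`PopulationParameters` as ``grid_spec`` returns it unchanged.
    """
    if isinstance(grid_spec, PopulationParameters):
        return grid_spec
    cache = CohortCache(cohort)
    coef_s, rss_s, coef_b, rss_b, k_best, m_obs = grid_init_stats(cache)
    if not np.all(np.isfinite(coef_s)):
        raise InitializationError("degenerate cohort: least-squares failed")

    # per-patient BIC: the two-line model spends 4 coefficients plus the
    # selected change point (the best-of-M-1 search behaves like an extra
    # parameter, so leaving it unpenalized over-calls bi-phasic starts)
    floor = 1e-9
    bic_s = m_obs * np.log(np.clip(rss_s, floor, None) / m_obs) \
        + 2.0 * np.log(m_obs)
    bic_b = m_obs * np.log(np.clip(rss_b, floor, None) / m_obs) \
        + 5.0 * np.log(m_obs)
    is_bi = bic_b < bic_s
    n = len(cohort)
    lam0 = float(np.clip(is_bi.mean(), 0.02, 0.98))

    if is_bi.all():
        s_mean = coef_s.mean(axis=0)
        cov_s = _init_cov(coef_s)
    else:
        s_mean = coef_s[~is_bi].mean(axis=0)
        cov_s = _init_cov(coef_s[~is_bi])
    if is_bi.any():
        b_mean = coef_b[is_bi].mean(axis=0)
        cov_b = _init_cov(coef_b[is_bi])
    else:
        b_mean = np.concatenate([s_mean, s_mean])
        cov_b = _init_cov(np.concatenate([coef_s, coef_s], axis=1))

    rss_tot = float(np.where(is_bi, rss_b, rss_s).sum())
    dof = float(m_obs.sum())
    sigma2 = max(rss_tot / dof, 1e-6)

    # change-interval histogram -> transition density -> per-patient pi
    zeta = [np.eye(p.n_obs - 1)[k - 1] for p, k in zip(cohort, k_best)]
    latent = LatentState(is_bi.astype(float), zeta)
    if is_bi.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FitWarning)
            density = update_transition_density(cohort, latent)
        pis = [update_pi(density, p) for p in cohort]
    else:
        pis = [np.full(p.n_obs - 1, 1.0 / (p.n_obs - 1)) for p in cohort]

    return PopulationParameters(
        MonoParams(s_mean, cov_s), BiParams(b_mean, cov_b),
        sigma2, lam0, pis)


def _init_cov(coefs):
    d = coefs.shape[1]
    floor = np.diag(np.where(np.arange(d) % 2 == 0, 1e-2, 1e-6))
    if len(coefs) < 2:
        return np.diag(np.where(np.arange(d) % 2 == 0, 1.0, 1e-4))
    return np.cov(coefs, rowvar=False) + floor


# ---------------------------------------------------------------------------
# main loop


def fit_em(cohort: Cohort, options: EMOptions | None = None) -> EMResult:
    """Alternate E- and M-steps, returning the iterate with the best
    penalized observed-data objective and its soft latent state.

    Because the BIC-substituted class posterior is not a proper EM
    E-step, the objective is not guaranteed to ascend; iterating past
    its maximum drifts the covariance estimates toward a degenerate
    zero-covariance spike of the improper posterior.  The fit therefore
    tracks the best objective seen and stops after ``patience``
    iterations without improvement, restoring the best iterate.
    """
    options = options or EMOptions()
    cache = CohortCache(cohort)
    params = grid_search_init(cohort, options.init)
    pis = cache.gather_pi(params.pi_weights)

    mono, bi = params.mono, params.bi
    sigma2, lam = params.sigma2, params.lam
    trace = []
    converged = False
    monotone = True
    best = None
    best_obj = -np.inf
    stall = 0
    for it in range(options.max_iter):
        sqrt_s = psd_sqrt(mono.cov)
        sqrt_b = psd_sqrt(bi.cov)
        estep = [
            e_step_group(g, mono, bi, sigma2, lam, pi, sqrt_s, sqrt_b)
            for g, pi in zip(cache.groups, pis)
        ]
        obj = observed_objective(estep, lam)
        if not np.isfinite(obj):
            raise NumericalError(
                f"non-finite EM objective at iteration {it} "
                f"(lam={lam:.4g}, sigma2={sigma2:.4g})"
            )
        if trace and obj < trace[-1] - 1e-8 * max(1.0, abs(obj)):
            monotone = False
        trace.append(obj)
        if obj > best_obj + options.tol:
            best_obj = obj
            best = (mono, bi, sigma2, lam, pis, estep)
            stall = 0
        else:
            stall += 1
            if stall >= options.patience:
                converged = True
                break

        try:
            s, cov_s, b, cov_b, sigma2, lam = m_step_moments(cache, estep)
        except ComponentCollapseError:
            # one class has (numerically) no members: the mixture has
            # degenerated to a single-class model, which is a legitimate
            # boundary mode (e.g. an all-mono cohort reduces to a linear
            # mixed-effects fit).  Stop here; the best iterate so far is
            # restored below.
            converged = True
            if best is None or obj > best_obj:
                best = (mono, bi, sigma2, lam, pis, estep)
            break
        mono = MonoParams(s, _clip_psd(cov_s))
        bi = BiParams(b, _clip_psd(cov_b))
        weights = [es.z[:, None] * es.zeta for es in estep]
        heights, total = transition_heights(cache, weights)
        density, _ = normalize_density(cache, heights, total)
        pis = pi_from_density(cache, density)

    mono, bi, sigma2, lam, pis, estep = best

    if not monotone:
        warnings.warn(
            "EM objective decreased during fitting (expected occasionally: "
            "the BIC-penalized class posterior is not a proper EM E-step)",
            FitWarning, stacklevel=2)

    z = cache.scatter([es.z for es in estep])
    zeta = cache.scatter_pi([es.zeta for es in estep])
    latent = LatentState(z, zeta)
    s_hat = cache.scatter([es.s_hat for es in estep])
    s_cov = cache.scatter([es.s_cov for es in estep])
    b_hat = cache.scatter_pi([es.b_hat for es in estep])
    b_cov = cache.scatter_pi([es.b_cov for es in estep])
    individuals = [
        IndividualEstimate(s_hat[i], s_cov[i], b_hat[i], b_cov[i])
        for i in range(len(cohort))
    ]
    params = PopulationParameters(mono, bi, sigma2, lam,
                                  cache.scatter_pi(pis))
    return EMResult(params, latent, individuals, np.asarray(trace),
                    converged, len(trace), monotone,
                    float(max(best_obj, np.max(trace))))
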