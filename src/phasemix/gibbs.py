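"""Heuristic Gibbs sampler and simultaneous credible regions.

The sampler follows the eleven-step sweep of the model's full conditionals:
hard design-matrix draws (multinomial over the zeta weights), hard
phasicity draws (Bernoulli over the BIC-penalized class posterior),
Dirichlet change-point weights from the transition density, Beta mixing
weight, normal draws of individual and population coefficients,
inverse-Wishart covariance draws and a scaled inverse-chi-square residual
variance.  No pseudoprior is used for the between-model move (the
Carlin–Chib caveat applies); the sampler is deliberately left in that
heuristic form.

Degrees of freedom for the inverse-Wishart conditionals are
(#mono - 1) and (#bi - 3); when class occupancy drops below the matrix
dimension the step raises instead of clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import invwishart

from ._engine import CohortCache, bic_posterior_z
from .core import gaussian_evidence, psd_sqrt, residual_sumsq
from .data import Cohort
from .exceptions import OccupancyError
from .params import (BiParams, MonoParams, PopulationParameters)

__all__ = [
    "GibbsOptions", "PosteriorDraw", "ChainSummary", "CredibleRegion",
    "gibbs_step", "run_chain", "simultaneous_credible_region",
    "draw_lambda", "draw_sigma2", "draw_cov",
]


@dataclass
class GibbsOptions:
    """Chain length controls and the (typically EM-mode) starting values."""

    n_iter: int = 30_000
    burn_in: int = 3_000
    thin: int = 1
    seed: int = 0
    init: PopulationParameters | None = None

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraw:
    """One sweep's population snapshot and hard latent state."""

    population: PopulationParameters
    eta: np.ndarray            # (N,) 0/1 phasicity indicators
    k: np.ndarray              # (N,) selected first-phase counts
    s_i: np.ndarray            # (N, 2) sampled mono coefficients
    b_i: np.ndarray            # (N, 4) sampled bi coefficients


@dataclass
class ChainSummary:
    """Kept draws flattened to the documented scalar-parameter order."""

    table: np.ndarray          # (n_kept, 21)
    names: tuple
    z_mean: np.ndarray         # (N,) posterior mean of eta over kept draws
    last: PosteriorDraw
    n_iter: int
    burn_in: int
    thin: int
    guard_hits: int = 0

    @property
    def n_kept(self) -> int:
        return self.table.shape[0]

    def params_8(self) -> np.ndarray:
        """Draws of the 8 scenario-1-style parameters."""
        return self.table[:, :8]


@dataclass
class CredibleRegion:
    """Hyperrectangle of per-parameter bounds with joint coverage."""

    level: float
    lower: np.ndarray
    upper: np.ndarray
    pointwise_level: float = field(default=np.nan)
    names: tuple = ()

    def contains(self, x) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower) & np.all(x <= self.upper))


# ---------------------------------------------------------------------------
# conjugate conditional draws (unit-testable against closed forms)


def draw_lambda(eta, rng) -> float:
    """lambda | eta ~ Beta(sum eta + 1, sum(1 - eta) + 1)."""
    eta = np.asarray(eta)
    return float(rng.beta(eta.sum() + 1.0, (1 - eta).sum() + 1.0))


def draw_sigma2(nu, pooled_ss, rng) -> float:
    """Scaled inverse-chi-square draw: nu * s2 / chi2_nu with
    s2 = pooled_ss / nu."""
    return float(pooled_ss / rng.chisquare(nu))


def draw_cov(df, scale, dim, label, rng) -> np.ndarray:
    """Inverse-Wishart draw with the occupancy guard."""
    if df < dim:
        raise OccupancyError(
            f"{label}: inverse-Wishart degrees of freedom {df} below "
            f"dimension {dim}; too few subjects in the class"
        )
    return invwishart.rvs(df=df, scale=scale, random_state=rng)


def _draw_dirichlet_rows(alpha, rng) -> np.ndarray:
    g = rng.gamma(alpha)
    tot = g.sum(axis=-1, keepdims=True)
    tot = np.where(tot > 0, tot, 1.0)
    out = g / tot
    flat = out.sum(axis=-1) <= 0
    if np.any(flat):
        out[flat] = 1.0 / alpha.shape[-1]
    return out


def _sample_mvn(mean, cov, rng):
    cov = np.asarray(cov)
    d = cov.shape[-1]
    jitter = 1e-12 * np.eye(d)
    chol = np.linalg.cholesky(cov + jitter)
    x = rng.standard_normal(mean.shape)
    return mean + np.einsum("...ab,...b->...a", chol, x)


# ---------------------------------------------------------------------------
# one sweep

# raw state threaded through the hot loop: avoids re-validating parameter
# dataclasses 30k times per chain
_IU2 = np.triu_indices(2)
_IU4 = np.triu_indices(4)


def _flatten_raw(state) -> np.ndarray:
    s_mean, cov_s, b_mean, cov_b, sigma2, lam = state
    return np.concatenate([
        s_mean, b_mean, [np.sqrt(sigma2), lam],
        cov_s[_IU2], cov_b[_IU4],
    ])


def _raw_from_params(pop: PopulationParameters):
    return (pop.mono.mean, pop.mono.cov, pop.bi.mean, pop.bi.cov,
            pop.sigma2, pop.lam)


def _params_from_raw(state) -> PopulationParameters:
    s_mean, cov_s, b_mean, cov_b, sigma2, lam = state
    return PopulationParameters(
        MonoParams(s_mean, 0.5 * (cov_s + cov_s.T)),
        BiParams(b_mean, 0.5 * (cov_b + cov_b.T)),
        sigma2, min(max(lam, 0.0), 1.0))


def _sweep(cache: CohortCache, state, pis, rng):
    """One full Gibbs sweep; returns (new raw state, per-group pis,
    eta, sel, s_i, b_i in cohort order)."""
    s_mean, cov_s, b_mean, cov_b, sigma2, lam = state
    sqrt_s = psd_sqrt(cov_s)
    sqrt_b = psd_sqrt(cov_b)

    etas, sels = [], []
    for g, pi in zip(cache.groups, pis):
        ll_s = gaussian_evidence(g.y2, g.qty_s, g.qtq_s, g.m, s_mean,
                                 sqrt_s, sigma2)
        ll_b = gaussian_evidence(g.y2[:, None], g.qty_b, g.qtq_b, g.m,
                                 b_mean, sqrt_b, sigma2)
        with np.errstate(divide="ignore"):
            lw = np.where(pi > 0, np.log(np.clip(pi, 1e-300, None)),
                          -np.inf) + ll_b
        lw -= lw.max(axis=1, keepdims=True)
        zeta = np.exp(lw)
        zeta /= zeta.sum(axis=1, keepdims=True)
        # step 2: multinomial design draw
        u = rng.random(g.n)
        sel = np.minimum((np.cumsum(zeta, axis=1) < u[:, None]).sum(axis=1),
                         g.k - 1)
        rows = np.arange(g.n)
        # step 3: class posterior given the selected design
        log_m = np.log(g.m)
        g_mono = 2.0 * ll_s - 2.0 * log_m
        g_bi = 2.0 * ll_b[rows, sel] - 4.0 * log_m
        z = bic_posterior_z(g_mono, g_bi, lam)
        eta = (rng.random(g.n) < z).astype(float)
        etas.append(eta)
        sels.append(sel)

    # step 5: transition density from the hard draws
    h = np.zeros(cache.n_seg + 1)
    for g, eta, sel in zip(cache.groups, etas, sels):
        rows = np.arange(g.n)
        li = g.left_idx[rows, sel]
        ri = g.right_idx[rows, sel]
        h[: cache.n_seg] += (
            np.bincount(li, eta, minlength=cache.n_seg + 1)
            - np.bincount(ri, eta, minlength=cache.n_seg + 1)
        )[: cache.n_seg]
    heights = np.clip(np.cumsum(h[: cache.n_seg]), 0.0, None)
    total = float(heights @ cache.seg_lengths)
    if total > 0:
        density = heights / total
    else:
        span = cache.breakpoints[-1] - cache.breakpoints[0]
        density = np.full(cache.n_seg, 1.0 / span)
    cum = np.concatenate([[0.0], np.cumsum(density * cache.seg_lengths)])

    # step 6: Dirichlet change-point weights per patient.  The
    # concentration adds, on top of the uniform +1 prior, the expected
    # number of cohort transitions in each of the patient's intervals
    # (bi-phasic count times the normalized-density integral): the
    # conjugate count for a Dirichlet is on the scale of observations,
    # and using the bare normalized integral (at most one in total)
    # would let the prior swamp the shared change-point signal entirely.
    eta_all = np.concatenate(etas)
    n_bi = float(eta_all.sum())
    new_pis = []
    for g in cache.groups:
        ints = n_bi * (cum[g.right_idx] - cum[g.left_idx])
        new_pis.append(_draw_dirichlet_rows(np.clip(ints, 0, None) + 1.0,
                                            rng))

    # step 7: mixing weight
    n_mono = float(len(eta_all) - n_bi)
    lam_new = draw_lambda(eta_all, rng)

    # occupancy guards (steps 9-10 divide by class counts)
    if n_mono - 1.0 < 2.0:
        raise OccupancyError(
            f"only {n_mono:.0f} mono-phasic subjects this sweep; "
            "Sigma_S conditional is improper")
    if n_bi - 3.0 < 4.0:
        raise OccupancyError(
            f"only {n_bi:.0f} bi-phasic subjects this sweep; "
            "Sigma_B conditional is improper")

    # step 8: individual coefficients from their EB conditionals
    s_all, b_all, rss = [], [], 0.0
    for g, eta, sel in zip(cache.groups, etas, sels):
        rows = np.arange(g.n)
        _, s_hat, s_cov = gaussian_evidence(
            g.y2, g.qty_s, g.qtq_s, g.m, s_mean, sqrt_s, sigma2,
            want_posterior=True)
        _, b_hat, b_cov = gaussian_evidence(
            g.y2, g.qty_b[rows, sel],
            g.qtq_b[rows, sel], g.m, b_mean, sqrt_b, sigma2,
            want_posterior=True)
        s_i = _sample_mvn(s_hat, s_cov, rng)
        b_i = _sample_mvn(b_hat, b_cov, rng)
        s_all.append(s_i)
        b_all.append(b_i)
        rss_s = residual_sumsq(g.y2, g.qty_s, g.qtq_s, s_i)
        rss_b = residual_sumsq(g.y2, g.qty_b[rows, sel],
                               g.qtq_b[rows, sel], b_i)
        rss += float((1.0 - eta) @ rss_s + eta @ rss_b)

    # step 9: population means
    w_mono = [1.0 - e for e in etas]
    s_bar = sum(w @ s for w, s in zip(w_mono, s_all)) / n_mono
    b_bar = sum(e @ b for e, b in zip(etas, b_all)) / n_bi
    s_new = _sample_mvn(s_bar, cov_s / n_mono, rng)
    b_new = _sample_mvn(b_bar, cov_b / n_bi, rng)

    # step 10: covariances around the sampled means
    scat_s = np.zeros((2, 2))
    scat_b = np.zeros((4, 4))
    for w, e, s_i, b_i in zip(w_mono, etas, s_all, b_all):
        ds = s_i - s_new
        db = b_i - b_new
        scat_s += (w[:, None] * ds).T @ ds
        scat_b += (e[:, None] * db).T @ db
    cov_s_new = draw_cov(n_mono - 1.0, scat_s, 2, "Sigma_S", rng)
    cov_b_new = draw_cov(n_bi - 3.0, scat_b, 4, "Sigma_B", rng)

    # step 11: residual variance
    nu = cache.n_obs_total
    sigma2_new = draw_sigma2(nu, rss, rng)

    state_new = (s_new, cov_s_new, b_new, cov_b_new, sigma2_new, lam_new)
    return (state_new, new_pis, cache.scatter(etas), cache.scatter(sels),
            cache.scatter(s_all), cache.scatter(b_all))


def gibbs_step(state: PosteriorDraw, cohort: Cohort, rng) -> PosteriorDraw:
    """One sweep of the sampler from an explicit state (convenience
    entry point; :func:`run_chain` drives the cached fast path)."""
    cache = CohortCache(cohort)
    pis = cache.gather_pi(state.population.pi_weights)
    raw, pis, eta, sel, s_i, b_i = _sweep(
        cache, _raw_from_params(state.population), pis, rng)
    pop = _params_from_raw(raw)
    pop.pi_weights = cache.scatter_pi(pis)
    return PosteriorDraw(pop, eta.astype(int), sel + 1, s_i, b_i)


def run_chain(cohort: Cohort, options: GibbsOptions) -> ChainSummary:
    """Run the sampler; apply burn-in and thinning; record the flattened
    scalar parameters of every kept draw.  Reproducible given the seed."""
    if options.init is None:
        raise ValueError("GibbsOptions.init must provide starting values "
                         "(typically the EM mode)")
    cache = CohortCache(cohort)
    rng = np.random.default_rng(options.seed)
    state = _raw_from_params(options.init)
    pis = cache.gather_pi(options.init.pi_weights)

    kept = []
    eta_accum = np.zeros(cache.n_patients)
    n_eta = 0
    guard_hits = 0
    last = None
    for it in range(options.n_iter):
        for attempt in range(20):
            try:
                out = _sweep(cache, state, pis, rng)
                break
            except OccupancyError:
                guard_hits += 1
                if guard_hits > 0.5 * max(it, 1) + 10:
                    raise OccupancyError(
                        f"component collapse in more than half of "
                        f"{it + 1} iterations; chain aborted"
                    )
        else:
            raise OccupancyError("could not complete a sweep in 20 attempts")
        state, pis, eta, sel, s_i, b_i = out
        if it >= options.burn_in and (it - options.burn_in) % options.thin == 0:
            kept.append(_flatten_raw(state))
            eta_accum += eta
            n_eta += 1
            last = (state, eta, sel, s_i, b_i)
    state, eta, sel, s_i, b_i = last
    last_draw = PosteriorDraw(_params_from_raw(state), eta.astype(int),
                              sel + 1, s_i, b_i)
    names = PopulationParameters.flat_names(include_cov=True)
    return ChainSummary(np.asarray(kept), names, eta_accum / max(n_eta, 1),
                        last_draw, options.n_iter, options.burn_in,
                        options.thin, guard_hits)


# ---------------------------------------------------------------------------
# simultaneous rectangular credible regions


def simultaneous_credible_region(chain, level: float = 0.95,
                                 names=()) -> CredibleRegion:
    """Smallest per-parameter quantile hyperrectangle with joint coverage.

    Bisection over the pointwise coverage level q: for each q the region is
    the componentwise equal-tailed [(1-q)/2, (1+q)/2] quantile box; the
    returned region uses the smallest q whose box contains at least
    ``level`` of the joint draws.
    """
    draws = chain.table if isinstance(chain, ChainSummary) else \
        np.asarray(chain, dtype=float)
    if draws.ndim == 1:
        draws = draws[:, None]
    n = draws.shape[0]
    if n < 100:
        raise ValueError(f"need at least 100 draws, got {n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")

    def box(q):
        lo = np.quantile(draws, (1.0 - q) / 2.0, axis=0)
        hi = np.quantile(draws, (1.0 + q) / 2.0, axis=0)
        return lo, hi

    def coverage(q):
        lo, hi = box(q)
        inside = np.all((draws >= lo) & (draws <= hi), axis=1)
        return inside.mean(), lo, hi

    lo_q, hi_q = level, 1.0
    cov, lo, hi = coverage(hi_q)
    for _ in range(40):
        mid = 0.5 * (lo_q + hi_q)
        c, ml, mh = coverage(mid)
        if c >= level:
            hi_q, cov, lo, hi = mid, c, ml, mh
        else:
            lo_q = mid
    if isinstance(chain, ChainSummary) and not names:
        names = chain.names
    return CredibleRegion(level, lo, hi, hi_q, tuple(names))
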