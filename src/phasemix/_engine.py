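"""Vectorized fitting engine.

Patients are grouped by their number of observations M so that every E-step
quantity is computed with batched d x d linear algebra over (patients,
candidate designs).  Only sufficient statistics (Y'Y, Q'Y, Q'Q) and the
interval bookkeeping for the transition density are precomputed; no
M-dimensional array is touched inside an iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .core import gaussian_evidence, psd_sqrt, residual_sumsq
from .data import Cohort
from .design import build_biphasic_design, build_mono_design
from .exceptions import ComponentCollapseError, NumericalError

_NEG_INF = -np.inf


class _Group:
    """Patients sharing the same observation count M."""

    __slots__ = ("idx", "m", "k", "times", "y", "y2", "qty_s", "qtq_s",
                 "qty_b", "qtq_b", "left", "right", "left_idx", "right_idx")

    def __init__(self, idx, patients):
        self.idx = np.asarray(idx, dtype=int)
        m = patients[0].n_obs
        self.m = m
        self.k = m - 1
        self.times = np.stack([p.times for p in patients])
        self.y = np.stack([p.values for p in patients])
        self.y2 = np.einsum("nm,nm->n", self.y, self.y)
        qs = np.stack([build_mono_design(p.times) for p in patients])
        self.qty_s = np.einsum("nmd,nm->nd", qs, self.y)
        self.qtq_s = np.einsum("nmd,nme->nde", qs, qs)
        qb = np.stack([
            np.stack([build_biphasic_design(p.times, k)
                      for k in range(1, m)])
            for p in patients
        ])  # (n, K, M, 4)
        self.qty_b = np.einsum("nkmd,nm->nkd", qb, self.y)
        self.qtq_b = np.einsum("nkmd,nkme->nkde", qb, qb)
        # change-point intervals (t_j, t_{j+1}) for j = 1..M-1
        self.left = self.times[:, :-1]
        self.right = self.times[:, 1:]
        self.left_idx = None
        self.right_idx = None

    @property
    def n(self):
        return len(self.idx)


class CohortCache:
    """Precomputed per-cohort sufficient statistics and interval grid."""

    def __init__(self, cohort: Cohort):
        self.cohort = cohort
        self.n_patients = len(cohort)
        self.n_obs_total = cohort.n_obs_total
        by_m: dict[int, list] = {}
        for i, p in enumerate(cohort):
            by_m.setdefault(p.n_obs, []).append(i)
        self.groups = [
            _Group(idx, [cohort[i] for i in idx])
            for m, idx in sorted(by_m.items())
        ]
        t0 = min(float(p.times[0]) for p in cohort)
        t_lo = min(0.0, t0)
        all_times = np.concatenate(
            [[t_lo], *[p.times for p in cohort], [cohort.t_max]]
        )
        self.breakpoints = np.unique(all_times)
        self.seg_lengths = np.diff(self.breakpoints)
        self.n_seg = len(self.seg_lengths)
        for g in self.groups:
            g.left_idx = np.searchsorted(self.breakpoints, g.left)
            g.right_idx = np.searchsorted(self.breakpoints, g.right)

    def scatter(self, per_group_values):
        """Reassemble per-patient values (cohort order) from group arrays."""
        n = self.n_patients
        first = per_group_values[0]
        out = np.empty((n,) + first.shape[1:], dtype=first.dtype)
        for g, v in zip(self.groups, per_group_values):
            out[g.idx] = v
        return out

    def gather_pi(self, pi_weights):
        """Per-group (n, K) arrays from a per-patient list (or None)."""
        out = []
        for g in self.groups:
            if pi_weights is None:
                out.append(np.full((g.n, g.k), 1.0 / g.k))
            else:
                out.append(np.stack([
                    np.asarray(pi_weights[i], dtype=float) for i in g.idx
                ]))
        return out

    def scatter_pi(self, pis):
        """Per-patient list (cohort order) from per-group arrays."""
        out = [None] * self.n_patients
        for g, pi in zip(self.groups, pis):
            for row, i in enumerate(g.idx):
                out[i] = pi[row].copy()
        return out


@dataclass
class EStepGroup:
    """E-step output for one group (soft posteriors and EB moments)."""

    ll_s: np.ndarray          # (n,) mono marginal log-likelihood
    ll_b: np.ndarray          # (n, K) bi marginal log-likelihoods
    log_mix_b: np.ndarray     # (n,) log sum_j pi_ij N_j
    zeta: np.ndarray          # (n, K)
    z: np.ndarray             # (n,)
    g_mono: np.ndarray        # (n,) BIC-penalized mono evidence (2 log scale)
    g_bi: np.ndarray          # (n,)
    s_hat: np.ndarray         # (n, 2)
    s_cov: np.ndarray         # (n, 2, 2)
    b_hat: np.ndarray         # (n, K, 4)
    b_cov: np.ndarray         # (n, K, 4, 4)


def bic_posterior_z(g_mono, g_bi, lam):
    """P(bi-phasic | data) from BIC-penalized evidences (2 log scale).

    z = lam exp(g_bi/2) / ((1-lam) exp(g_mono/2) + lam exp(g_bi/2)),
    evaluated through the log-odds for stability.
    """
    if lam <= 0.0:
        return np.zeros(np.shape(g_mono))
    if lam >= 1.0:
        return np.ones(np.shape(g_mono))
    logit = np.log(lam) - np.log1p(-lam) + 0.5 * (g_bi - g_mono)
    return expit(logit)


def e_step_group(g: _Group, mono, bi, sigma2, lam, pi,
                 sqrt_s=None, sqrt_b=None, want_posterior=True) -> EStepGroup:
    """Full soft E-step for one group under the current parameters."""
    ls = psd_sqrt(mono.cov) if sqrt_s is None else sqrt_s
    lb = psd_sqrt(bi.cov) if sqrt_b is None else sqrt_b
    res_s = gaussian_evidence(g.y2, g.qty_s, g.qtq_s, g.m, mono.mean, ls,
                              sigma2, want_posterior=want_posterior)
    res_b = gaussian_evidence(g.y2[:, None], g.qty_b, g.qtq_b, g.m, bi.mean,
                              lb, sigma2, want_posterior=want_posterior)
    if want_posterior:
        ll_s, s_hat, s_cov = res_s
        ll_b, b_hat, b_cov = res_b
    else:
        ll_s, s_hat, s_cov = res_s, None, None
        ll_b, b_hat, b_cov = res_b, None, None

    with np.errstate(divide="ignore"):
        log_pi = np.where(pi > 0.0, np.log(np.clip(pi, 1e-300, None)),
                          _NEG_INF)
    lw = log_pi + ll_b
    log_mix = logsumexp(lw, axis=1)
    if np.any(~np.isfinite(log_mix)):
        bad = g.idx[~np.isfinite(log_mix)]
        raise NumericalError(
            f"all candidate designs have zero posterior weight for "
            f"patient index/indices {bad.tolist()}"
        )
    zeta = np.exp(lw - log_mix[:, None])
    zeta /= zeta.sum(axis=1, keepdims=True)

    log_m = np.log(g.m)
    g_mono = 2.0 * ll_s - 2.0 * log_m
    g_bi = 2.0 * log_mix - 4.0 * log_m
    z = bic_posterior_z(g_mono, g_bi, lam)
    return EStepGroup(ll_s, ll_b, log_mix, zeta, z, g_mono, g_bi,
                      s_hat, s_cov, b_hat, b_cov)


def observed_objective(estep_groups, lam) -> float:
    """BIC-penalized observed-data log-likelihood of the mixture."""
    total = 0.0
    for es in estep_groups:
        if lam <= 0.0:
            total += float(np.sum(0.5 * es.g_mono))
        elif lam >= 1.0:
            total += float(np.sum(0.5 * es.g_bi))
        else:
            total += float(np.sum(np.logaddexp(
                np.log1p(-lam) + 0.5 * es.g_mono,
                np.log(lam) + 0.5 * es.g_bi,
            )))
    return total


def m_step_moments(cache: CohortCache, estep_groups):
    """Closed-form weighted-moment updates (everything except pi).

    Returns (S, cov_S, B, cov_B, sigma2, lam) from the soft latent weights
    and empirical-Bayes moments of the E-step.  Covariance denominators
    carry the +2 of the improper-prior mode; sigma2 pools the expected
    residual sum of squares over all observations (denominator
    total observations + 2).
    """
    sum_z = 0.0
    sum_1mz = 0.0
    s1 = np.zeros(2)
    s2 = np.zeros((2, 2))
    b1 = np.zeros(4)
    b2 = np.zeros((4, 4))
    rss = 0.0
    for g, es in zip(cache.groups, estep_groups):
        w_mono = 1.0 - es.z
        w_bi = es.z
        sum_z += float(w_bi.sum())
        sum_1mz += float(w_mono.sum())
        s1 += w_mono @ es.s_hat
        s2 += np.einsum("n,nab->ab", w_mono,
                        es.s_cov + np.einsum("na,nb->nab", es.s_hat, es.s_hat))
        wz = w_bi[:, None] * es.zeta               # (n, K)
        b1 += np.einsum("nk,nka->a", wz, es.b_hat)
        b2 += np.einsum("nk,nkab->ab", wz,
                        es.b_cov + np.einsum("nka,nkb->nkab",
                                             es.b_hat, es.b_hat))
        rss_s = residual_sumsq(g.y2, g.qty_s, g.qtq_s, es.s_hat)
        tr_s = np.einsum("nab,nab->n", g.qtq_s, es.s_cov)
        rss += float(w_mono @ (rss_s + tr_s))
        rss_b = residual_sumsq(g.y2[:, None], g.qty_b, g.qtq_b, es.b_hat)
        tr_b = np.einsum("nkab,nkab->nk", g.qtq_b, es.b_cov)
        rss += float(np.sum(wz * (rss_b + tr_b)))

    n = cache.n_patients
    eps = 1e-10 * n
    if sum_1mz <= eps or sum_z <= eps:
        raise ComponentCollapseError(
            f"a mixture component collapsed (sum(1-z)={sum_1mz:.3g}, "
            f"sum(z)={sum_z:.3g}); re-initialize lambda away from 0/1"
        )
    s_mean = s1 / sum_1mz
    cov_s = (s2 - sum_1mz * np.outer(s_mean, s_mean)) / (sum_1mz + 2.0)
    b_mean = b1 / sum_z
    cov_b = (b2 - sum_z * np.outer(b_mean, b_mean)) / (sum_z + 2.0)
    cov_s = 0.5 * (cov_s + cov_s.T)
    cov_b = 0.5 * (cov_b + cov_b.T)
    sigma2 = rss / (cache.n_obs_total + 2.0)
    lam = sum_z / n
    return s_mean, cov_s, b_mean, cov_b, sigma2, lam


def transition_heights(cache: CohortCache, weights):
    """Unnormalized piecewise-constant transition intensity per segment.

    ``weights`` is a per-group list of (n, K) arrays holding w_i * zeta_ij
    (soft: z_i zeta_ij; hard: eta_i xi_ij).  Returns (heights, total mass).
    """
    h = np.zeros(cache.n_seg + 1)
    for g, w in zip(cache.groups, weights):
        wf = np.asarray(w, dtype=float).ravel()
        h[: cache.n_seg] += (
            np.bincount(g.left_idx.ravel(), wf, minlength=cache.n_seg + 1)
            - np.bincount(g.right_idx.ravel(), wf, minlength=cache.n_seg + 1)
        )[: cache.n_seg]
    heights = np.cumsum(h[: cache.n_seg])
    heights = np.clip(heights, 0.0, None)
    total = float(heights @ cache.seg_lengths)
    return heights, total


def normalize_density(cache: CohortCache, heights, total):
    """Normalize to a density on the breakpoint grid; flat fallback when
    there is no bi-phasic mass."""
    if total <= 0.0:
        span = cache.breakpoints[-1] - cache.breakpoints[0]
        return np.full(cache.n_seg, 1.0 / span), True
    return heights / total, False


def pi_from_density(cache: CohortCache, density):
    """Per-group change-point weights: integrate the density over each
    patient interval, then renormalize within each patient."""
    cum = np.concatenate([[0.0], np.cumsum(density * cache.seg_lengths)])
    out = []
    for g in cache.groups:
        raw = cum[g.right_idx] - cum[g.left_idx]
        tot = raw.sum(axis=1, keepdims=True)
        pi = np.where(tot > 0.0, raw / np.where(tot > 0, tot, 1.0),
                      1.0 / g.k)
        out.append(pi)
    return out


def grid_init_stats(cache: CohortCache):
    """Per-patient single-line and best two-line least-squares fits.

    Returns cohort-ordered arrays: mono coefficients (N, 2), mono RSS,
    best bi coefficients (N, 4), best bi RSS, best first-phase count k,
    and the per-patient observation counts.
    """
    coef_s, rss_s, coef_b, rss_b, k_best, m_obs = [], [], [], [], [], []
    for g in cache.groups:
        bs = np.linalg.solve(g.qtq_s, g.qty_s[..., None])[..., 0]
        rs = residual_sumsq(g.y2, g.qty_s, g.qtq_s, bs)
        pinv = np.linalg.pinv(g.qtq_b, hermitian=True)
        bb = np.einsum("nkab,nkb->nka", pinv, g.qty_b)
        rb = residual_sumsq(g.y2[:, None], g.qty_b, g.qtq_b, bb)
        kb = np.argmin(rb, axis=1)
        rows = np.arange(g.n)
        coef_s.append(bs)
        rss_s.append(np.clip(rs, 0.0, None))
        coef_b.append(bb[rows, kb])
        rss_b.append(np.clip(rb[rows, kb], 0.0, None))
        k_best.append(kb + 1)
        m_obs.append(np.full(g.n, g.m))
    return (cache.scatter(coef_s), cache.scatter(rss_s),
            cache.scatter(coef_b), cache.scatter(rss_b),
            cache.scatter(k_best), cache.scatter(m_obs))
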