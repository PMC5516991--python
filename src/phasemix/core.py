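"""Marginal Gaussian evidence and empirical-Bayes estimators.

For a patient with values Y, design Q (M x d), population mean m, random-
effect covariance Sigma and residual variance sigma2, the marginal law of Y
is N(Q m, Q Sigma Q' + sigma2 I).  Everything here is evaluated through the
d x d (d <= 4) matrix

    A = sigma2 I_d + L' Q'Q L,        Sigma = L L'   (PSD square root),

using the determinant lemma and Woodbury identity:

    log|Q Sigma Q' + sigma2 I| = (M - d) log sigma2 + log|A|
    r' C^{-1} r = (r'r - g' A^{-1} g) / sigma2,      g = L' Q' r
    posterior mean  = m + L A^{-1} g
    posterior cov   = sigma2 L A^{-1} L'

These forms are exact for singular Sigma (including Sigma = 0), which the
zero-between-patient-variability scenario requires, and they only touch the
sufficient statistics (Y'Y, Q'Y, Q'Q), so no M-dimensional array appears in
the fitting hot loops.
"""

from __future__ import annotations

import numpy as np

from ._kernels import HAVE_NUMBA, _evidence_batch
from .exceptions import NumericalError

__all__ = [
    "psd_sqrt",
    "gaussian_evidence",
    "log_marginal_gaussian",
    "empirical_bayes",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def psd_sqrt(sigma: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition (negative
    eigenvalues from roundoff are clipped to zero)."""
    sigma = np.asarray(sigma, dtype=float)
    sym = 0.5 * (sigma + sigma.T)
    w, v = np.linalg.eigh(sym)
    if w[-1] > 0 and w[0] < -1e-8 * w[-1]:
        raise NumericalError("covariance has a significantly negative eigenvalue")
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def suff_stats(y: np.ndarray, q: np.ndarray):
    """(Y'Y, Q'Y, Q'Q) sufficient statistics for one series/design."""
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(y @ y), q.T @ y, q.T @ q


def residual_sumsq(y2, qty, qtq, beta):
    """||Y - Q beta||^2 from sufficient statistics (batched)."""
    lin = (qty * beta).sum(-1)
    quad = (beta * (qtq @ beta[..., None])[..., 0]).sum(-1)
    return y2 - 2.0 * lin + quad


def gaussian_evidence(y2, qty, qtq, m_obs, mean, sqrt_sigma, sigma2,
                      want_posterior=False):
    """Log marginal density and (optionally) empirical-Bayes moments.

    Batched over the leading dimensions of ``y2`` (...,), ``qty`` (..., d)
    and ``qtq`` (..., d, d); ``mean`` and ``sqrt_sigma`` are (d,)/(d, d).

    Returns ``loglik`` or ``(loglik, post_mean, post_cov)``.
    """
    y2 = np.asarray(y2, dtype=float)
    qty = np.asarray(qty, dtype=float)
    qtq = np.asarray(qtq, dtype=float)
    mean = np.asarray(mean, dtype=float)
    ell = np.asarray(sqrt_sigma, dtype=float)
    d = mean.shape[-1]
    if sigma2 <= 0:
        raise NumericalError("sigma2 must be positive")

    if HAVE_NUMBA:
        batch_shape = qty.shape[:-1]
        y2_f = np.ascontiguousarray(
            np.broadcast_to(y2, batch_shape), dtype=float).reshape(-1)
        qty_f = np.ascontiguousarray(qty, dtype=float).reshape(-1, d)
        qtq_f = np.ascontiguousarray(qtq, dtype=float).reshape(-1, d, d)
        ll, pm, pc, ok = _evidence_batch(
            y2_f, qty_f, qtq_f, float(m_obs),
            np.ascontiguousarray(mean, dtype=float),
            np.ascontiguousarray(ell, dtype=float),
            float(sigma2), bool(want_posterior))
        if not ok:
            raise NumericalError(
                "marginal covariance is not positive definite")
        ll = ll.reshape(batch_shape) if batch_shape else float(ll[0])
        if not want_posterior:
            return ll
        pm = pm.reshape(batch_shape + (d,))
        pc = pc.reshape(batch_shape + (d, d))
        if not batch_shape:
            pm, pc = pm[()], pc[()]
        return ll, pm, pc

    # residual projections: Q'r = Q'Y - Q'Q m ;  r'r via residual_sumsq
    qtr = qty - (qtq @ mean[..., None])[..., 0]
    rr = residual_sumsq(y2, qty, qtq, mean)
    g = qtr @ ell                       # (...,d) row form of L' Q'r
    a = (ell.T @ qtq) @ ell
    a = a + sigma2 * np.eye(d)
    try:
        ca = np.linalg.cholesky(a)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(
            "marginal covariance is not positive definite"
        ) from exc
    logdet_a = 2.0 * np.sum(
        np.log(np.diagonal(ca, axis1=-2, axis2=-1)), axis=-1
    )
    ainv_g = np.linalg.solve(a, g[..., None])[..., 0]
    quad = (rr - (g * ainv_g).sum(-1)) / sigma2
    loglik = -0.5 * (
        m_obs * _LOG_2PI + (m_obs - d) * np.log(sigma2) + logdet_a + quad
    )
    if not want_posterior:
        return loglik
    post_mean = mean + ainv_g @ ell.T
    ainv = np.linalg.inv(a)
    post_cov = sigma2 * ((ell @ ainv) @ ell.T)
    post_cov = 0.5 * (post_cov + np.swapaxes(post_cov, -1, -2))
    return loglik, post_mean, post_cov


def log_marginal_gaussian(y, q, mean_params, sigma, sigma2) -> float:
    """log N(Y | Q m, Q Sigma Q' + sigma2 I) for one series and design."""
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    if q.shape[0] != y.shape[0]:
        raise NumericalError("Y and Q have incompatible shapes")
    y2, qty, qtq = suff_stats(y, q)
    return float(gaussian_evidence(y2, qty, qtq, q.shape[0], mean_params,
                                   psd_sqrt(sigma), sigma2))


def empirical_bayes(series, q, mean_params, sigma, sigma2):
    """Empirical-Bayes posterior mean and covariance of one patient's
    individual regression coefficients.

    Equivalent to m + (Sigma^{-1} + Q'Q/sigma2)^{-1} Q'(Y - Q m)/sigma2 and
    (Sigma^{-1} + Q'Q/sigma2)^{-1}, but evaluated in the shrinkage form that
    is exact for singular Sigma.
    """
    y = np.asarray(getattr(series, "values", series), dtype=float)
    q = np.asarray(q, dtype=float)
    y2, qty, qtq = suff_stats(y, q)
    try:
        _, mean, cov = gaussian_evidence(
            y2, qty, qtq, q.shape[0], mean_params, psd_sqrt(sigma), sigma2,
            want_posterior=True)
    except NumericalError as exc:
        pid = getattr(series, "patient_id", None)
        raise NumericalError(
            f"empirical-Bayes precision is singular for patient {pid!r}"
        ) from exc
    return mean, cov
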