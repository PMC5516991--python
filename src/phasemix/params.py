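"""Population-parameter and latent-state containers.

Parameter layout follows the two-class hierarchy: mono-phasic subjects draw
an (intercept, slope) pair s_i ~ N(S, Sigma_S); bi-phasic subjects draw
(first intercept, first slope, second intercept, second slope)
b_i ~ N(B, Sigma_B).  Residuals are iid N(0, sigma2); lam is the marginal
probability of the bi-phasic class; pi_weights holds each patient's
change-point (design-matrix) probabilities over k = 1..M_i-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError

__all__ = [
    "MonoParams",
    "BiParams",
    "PopulationParameters",
    "LatentState",
    "IndividualEstimate",
    "TransitionDensity",
    "PARAM_NAMES_8",
]

#: Flattening order of the scalar parameters reported in summaries and
#: coverage experiments (means, sigma, lambda first; covariances appended).
PARAM_NAMES_8 = ("S0", "S1", "B0", "B1", "B0p", "B1p", "sigma", "lam")


def _check_cov(sigma, d, name):
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (d, d):
        raise ConfigError(f"{name} must be {d}x{d}")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise ConfigError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(0.5 * (sigma + sigma.T))[0] < -1e-8:
        raise ConfigError(f"{name} must be positive semi-definite")
    return 0.5 * (sigma + sigma.T)


@dataclass(frozen=True)
class MonoParams:
    """Mono-phasic population mean (S0, S1) and covariance Sigma_S."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        if mean.shape != (2,):
            raise ConfigError("mono mean must have length 2")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", _check_cov(self.cov, 2, "Sigma_S"))


@dataclass(frozen=True)
class BiParams:
    """Bi-phasic population mean (B0, B1, B0', B1') and covariance Sigma_B."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        if mean.shape != (4,):
            raise ConfigError("bi mean must have length 4")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", _check_cov(self.cov, 4, "Sigma_B"))


@dataclass
class PopulationParameters:
    """Full population-level parameter state.

    pi_weights is a list with one probability vector per patient (length
    M_i - 1, summing to one); ``None`` means uniform weights everywhere.
    """

    mono: MonoParams
    bi: BiParams
    sigma2: float
    lam: float
    pi_weights: list | None = None

    def __post_init__(self):
        if not self.sigma2 > 0:
            raise ConfigError("sigma2 must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigError("lam must lie in [0, 1]")
        if self.pi_weights is not None:
            checked = []
            for i, pi in enumerate(self.pi_weights):
                pi = np.asarray(pi, dtype=float)
                if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-8:
                    raise ConfigError(
                        f"pi_weights[{i}] must be a probability vector"
                    )
                checked.append(np.clip(pi, 0.0, None) / pi.sum())
            self.pi_weights = checked

    @property
    def sigma(self) -> float:
        """Residual standard deviation."""
        return float(np.sqrt(self.sigma2))

    def flatten(self, include_cov: bool = False) -> np.ndarray:
        """Scalar parameter vector in the documented order.

        The first 8 entries are (S0, S1, B0, B1, B0', B1', sigma, lam).
        With ``include_cov`` the 3 upper-triangular entries of Sigma_S and
        the 10 of Sigma_B are appended (21 parameters in total).
        """
        out = [*self.mono.mean, *self.bi.mean, self.sigma, self.lam]
        if include_cov:
            iu2 = np.triu_indices(2)
            iu4 = np.triu_indices(4)
            out.extend(self.mono.cov[iu2])
            out.extend(self.bi.cov[iu4])
        return np.asarray(out, dtype=float)

    @staticmethod
    def flat_names(include_cov: bool = False) -> tuple:
        names = list(PARAM_NAMES_8)
        if include_cov:
            names += [f"covS_{i}{j}" for i, j in zip(*np.triu_indices(2))]
            names += [f"covB_{i}{j}" for i, j in zip(*np.triu_indices(4))]
        return tuple(names)


@dataclass
class LatentState:
    """Per-patient phasicity and change-point posteriors.

    ``z`` holds expected bi-phasic probabilities (or 0/1 indicators in
    Gibbs mode); ``zeta`` one normalized vector per patient over candidate
    designs (or one-hot in Gibbs mode); ``k`` the argmax first-phase count.
    """

    z: np.ndarray
    zeta: list
    k: np.ndarray = field(default=None)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if np.any(self.z < -1e-12) or np.any(self.z > 1 + 1e-12):
            raise ConfigError("z must lie in [0, 1]")
        self.zeta = [np.asarray(zt, dtype=float) for zt in self.zeta]
        for i, zt in enumerate(self.zeta):
            if abs(zt.sum() - 1.0) > 1e-10:
                raise ConfigError(f"zeta[{i}] must sum to 1")
        if self.k is None:
            self.k = np.asarray(
                [int(np.argmax(zt)) + 1 for zt in self.zeta], dtype=int
            )


@dataclass
class IndividualEstimate:
    """Empirical-Bayes moments for one patient.

    ``b_hat``/``b_cov`` are stacked over the M_i-1 candidate designs.
    """

    s_hat: np.ndarray
    s_cov: np.ndarray
    b_hat: np.ndarray
    b_cov: np.ndarray


@dataclass
class TransitionDensity:
    """Piecewise-constant phasic-transition density on [0, T].

    ``breakpoints`` (length n+1) partition the support; ``density`` (length
    n) gives the constant value on each segment; integrates to one.
    """

    breakpoints: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.breakpoints) != len(self.density) + 1:
            raise ConfigError("breakpoints must be one longer than density")
        if np.any(self.density < -1e-12):
            raise ConfigError("density must be nonnegative")
        total = float(np.sum(self.density * np.diff(self.breakpoints)))
        if abs(total - 1.0) > 1e-8:
            raise ConfigError("density must integrate to 1")

    def cumulative(self, t) -> np.ndarray:
        """Integral of the density from the left endpoint up to t."""
        bp = self.breakpoints
        cum = np.concatenate([[0.0], np.cumsum(self.density * np.diff(bp))])
        return np.interp(t, bp, cum)

    def integral(self, a, b) -> np.ndarray:
        """Integral over [a, b] (vectorized)."""
        return self.cumulative(b) - self.cumulative(a)
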