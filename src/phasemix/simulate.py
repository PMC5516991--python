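"""Synthetic-cohort generator.

Generates two-class longitudinal cohorts: each patient is bi-phasic with
probability lam; individual regression coefficients are drawn from
multivariate normals around the class means; visits follow a fixed schedule
(default: baseline day 0 plus 17 follow-ups every 21 days, last at day 357)
with independent uniform per-visit time jitter (default +/- 5 days, baseline
anchored at 0); observations add iid N(0, sigma^2) noise.  A bi-phasic
patient's change point is the intersection time of the two lines,
t* = (b0 - b0') / (b1' - b1), which under normal coefficient draws follows a
heavy-tailed Gaussian-ratio law — some bi-phasic patients therefore switch
outside the observation window and look mono-phasic.  Such patients are
kept and keep their generating-class label; this is deliberate and is the
source of the documented downward bias of the fitted mixing weight.

The three stock scenarios share the population means
S = (90, -0.25), B = (91, -0.35, 55, -0.15), sigma = 5, lam = 0.6, N = 100
and differ only in between-patient covariance: scenario 1 has none;
scenario 2 has independent variation (variance 4 on intercepts, 0.0009 on
slopes); scenario 3 adds correlation 0.5 between the two bi-phasic slopes
(covariance 0.00045).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import Cohort, PatientSeries
from .exceptions import ConfigError
from .params import BiParams, MonoParams

__all__ = [
    "ScenarioConfig", "SimulatedCohort", "make_scenario",
    "transition_time", "simulate_cohort", "make_sensitivity_grid",
]

_S_TRUE = (90.0, -0.25)
_B_TRUE = (91.0, -0.35, 55.0, -0.15)


@dataclass
class ScenarioConfig:
    """Generative truth for one simulated cohort."""

    mono_truth: MonoParams
    bi_truth: BiParams
    sigma: float = 5.0
    lam: float = 0.6
    n_patients: int = 100
    baseline_day: float = 0.0
    visit_spacing: float = 21.0
    n_followups: int = 17
    jitter: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigError("lam must lie in [0, 1]")
        if self.sigma < 0:
            raise ConfigError("sigma must be nonnegative")
        if self.n_patients < 1 or self.n_followups < 1:
            raise ConfigError("need at least 1 patient and 1 follow-up")
        if self.jitter < 0 or 2 * self.jitter >= self.visit_spacing:
            raise ConfigError("jitter must satisfy 0 <= 2*jitter < spacing")

    @property
    def schedule(self) -> np.ndarray:
        """Scheduled visit days (baseline plus equally spaced follow-ups)."""
        return self.baseline_day + self.visit_spacing * np.arange(
            self.n_followups + 1)


@dataclass
class SimulatedCohort:
    """A cohort plus its generating truth, aligned by patient order."""

    cohort: Cohort
    eta: np.ndarray          # true class indicator (1 = bi-phasic)
    coefficients: list       # per patient: (2,) mono or (4,) bi true coefs
    t_star: np.ndarray       # transition time (nan for mono patients)
    k: np.ndarray            # visits at or before t_star (0..M; nan->-1 mono)
    config: ScenarioConfig = field(repr=False, default=None)


def make_scenario(which: int, **overrides) -> ScenarioConfig:
    """Stock scenario configurations (1, 2, 3)."""
    if which not in (1, 2, 3):
        raise ConfigError("scenario must be 1, 2 or 3")
    if which == 1:
        cov_s = np.zeros((2, 2))
        cov_b = np.zeros((4, 4))
    else:
        cov_s = np.diag([4.0, 0.0009])
        cov_b = np.diag([4.0, 0.0009, 4.0, 0.0009])
        if which == 3:
            cov_b[1, 3] = cov_b[3, 1] = 0.5 * 0.03 * 0.03  # 0.00045
    mono = overrides.pop("mono_truth", MonoParams(_S_TRUE, cov_s))
    bi = overrides.pop("bi_truth", BiParams(_B_TRUE, cov_b))
    return ScenarioConfig(mono_truth=mono, bi_truth=bi, **overrides)


def transition_time(b) -> float:
    """Intersection time (b0 - b0') / (b1' - b1) of the two lines."""
    b = np.asarray(b, dtype=float)
    denom = b[3] - b[1]
    if denom == 0.0:
        raise ConfigError("parallel phases: transition time undefined")
    return float((b[0] - b[2]) / denom)


def _jittered_times(config: ScenarioConfig, rng) -> np.ndarray:
    sched = config.schedule
    for _ in range(100):
        jit = rng.uniform(-config.jitter, config.jitter,
                          size=config.n_followups)
        times = sched.copy()
        times[1:] += jit          # baseline visit stays anchored
        if np.all(np.diff(times) > 0):
            return times
    raise ConfigError("could not draw a strictly increasing visit schedule")


def simulate_cohort(config: ScenarioConfig) -> SimulatedCohort:
    """Draw one cohort from the generative process."""
    rng = np.random.default_rng(config.seed)
    eta = (rng.random(config.n_patients) < config.lam).astype(int)
    patients, coefs, t_stars, ks = [], [], [], []
    for i in range(config.n_patients):
        times = _jittered_times(config, rng)
        if eta[i]:
            b = rng.multivariate_normal(config.bi_truth.mean,
                                        config.bi_truth.cov,
                                        method="eigh")
            t_star = transition_time(b)
            first = times <= t_star      # phase 1 closed on the left
            mean = np.where(first, b[0] + b[1] * times, b[2] + b[3] * times)
            coefs.append(b)
            t_stars.append(t_star)
            ks.append(int(first.sum()))
        else:
            s = rng.multivariate_normal(config.mono_truth.mean,
                                        config.mono_truth.cov,
                                        method="eigh")
            mean = s[0] + s[1] * times
            coefs.append(s)
            t_stars.append(np.nan)
            ks.append(-1)
        y = mean + rng.normal(0.0, config.sigma, size=len(times))
        patients.append(PatientSeries(f"p{i:04d}", times, y))
    return SimulatedCohort(Cohort(patients), eta, coefs,
                           np.asarray(t_stars), np.asarray(ks, dtype=int),
                           config)


def make_sensitivity_grid(kind: str, base: ScenarioConfig,
                          n_points: int = 5,
                          obs_grid=(6, 9, 12, 18),
                          n_grid=(20, 50, 100, 200)) -> list[ScenarioConfig]:
    """Configuration grids for the sensitivity analyses.

    ``kind="slopes"``: vary the bi-phasic first slope over [-0.45, -0.26]
    and the second slope over [-0.24, -0.05], setting the second intercept
    so that the population-level transition stays at 178 days (the middle
    of the 357-day trial).  ``kind="design_size"``: vary observations per
    patient (evenly spaced over day 0..357) and cohort size N.
    """
    if kind == "slopes":
        b0 = base.bi_truth.mean[0]
        out = []
        for b1 in np.linspace(-0.45, -0.26, n_points):
            for b1p in np.linspace(-0.24, -0.05, n_points):
                b0p = b0 + 178.0 * (b1 - b1p)
                bi = BiParams((b0, b1, b0p, b1p), base.bi_truth.cov)
                out.append(replace(base, bi_truth=bi))
        return out
    if kind == "design_size":
        out = []
        span = base.visit_spacing * base.n_followups
        for m in obs_grid:
            out.append(replace(base, n_followups=m - 1,
                               visit_spacing=span / (m - 1)))
        for n in n_grid:
            out.append(replace(base, n_patients=n))
        return out
    raise ConfigError("kind must be 'slopes' or 'design_size'")
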