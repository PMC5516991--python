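"""Classification metrics and replication experiments.

Convention for the confusion summary (mirroring the simulation-study
tables): *sensitivity* is the fraction of true mono-phasic patients
classified mono-phasic, *specificity* the fraction of true bi-phasic
patients classified bi-phasic.  Raw counts are always reported so the
opposite convention can be recomputed.

Truth labels are generating-class labels: a bi-phasic patient whose
transition falls outside the observation window still counts as bi-phasic,
so part of the reported "misclassification" reflects genuinely
indistinguishable trajectories (this is what drives the mixing-weight
bias in the scenarios with between-patient variability).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .em import EMOptions, fit_em
from .exceptions import PhasemixError
from .gibbs import GibbsOptions, run_chain, simultaneous_credible_region
from .params import PopulationParameters, LatentState
from .simulate import make_scenario, simulate_cohort

__all__ = [
    "ClassificationReport", "RecoverySummary", "CoverageSummary",
    "classify", "confusion_metrics",
    "run_recovery_experiment", "run_coverage_experiment",
    "run_sensitivity_grid",
]

PARAM_COLUMNS = ("S0", "S1", "B0", "B1", "B0p", "B1p", "sigma", "lam")


@dataclass
class ClassificationReport:
    """Confusion counts and the table's sensitivity/specificity."""

    n_mono_true: int
    n_bi_true: int
    n_mono_correct: int
    n_bi_correct: int
    predicted: np.ndarray
    z: np.ndarray | None = None

    @property
    def sensitivity(self) -> float:
        """P(classified mono | truly mono); nan if no true mono patients."""
        if self.n_mono_true == 0:
            return float("nan")
        return self.n_mono_correct / self.n_mono_true

    @property
    def specificity(self) -> float:
        """P(classified bi | truly bi); nan if no true bi patients."""
        if self.n_bi_true == 0:
            return float("nan")
        return self.n_bi_correct / self.n_bi_true

    @property
    def accuracy(self) -> float:
        return (self.n_mono_correct + self.n_bi_correct) / \
            (self.n_mono_true + self.n_bi_true)


@dataclass
class RecoverySummary:
    """Replicate means/SDs of the EM point estimates against truth."""

    estimates: pd.DataFrame      # one row per successful replicate
    truth: pd.Series
    n_replicates: int
    n_failed: int
    sensitivity: np.ndarray      # per-replicate rates (nan when undefined)
    specificity: np.ndarray

    @property
    def mean(self) -> pd.Series:
        return self.estimates.mean()

    @property
    def sd(self) -> pd.Series:
        return self.estimates.std(ddof=1)

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.specificity))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"truth": self.truth, "mean": self.mean, "sd": self.sd})


@dataclass
class CoverageSummary:
    """Joint coverage of simultaneous credible regions across replicates."""

    level: float
    n_replicates: int
    n_failed: int
    joint_coverage: float
    per_parameter: pd.Series
    detection: float = float("nan")   # scenario-3 slope-correlation detection


def classify(latent, cutoff: float = 0.5) -> np.ndarray:
    """Hard class labels: bi-phasic iff z strictly exceeds the cutoff."""
    z = latent.z if isinstance(latent, LatentState) else np.asarray(latent)
    return (z > cutoff).astype(int)


def confusion_metrics(truth, predicted, z=None) -> ClassificationReport:
    """Confusion counts for true vs predicted phasicity (1 = bi)."""
    truth = np.asarray(truth).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    return ClassificationReport(
        n_mono_true=int((truth == 0).sum()),
        n_bi_true=int((truth == 1).sum()),
        n_mono_correct=int(((truth == 0) & (predicted == 0)).sum()),
        n_bi_correct=int(((truth == 1) & (predicted == 1)).sum()),
        predicted=predicted, z=None if z is None else np.asarray(z))


def _replicate_seeds(seed, n):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


def run_recovery_experiment(which_scenario: int, n_replicates: int,
                            seed: int = 0, em_options: EMOptions | None = None,
                            config_overrides: dict | None = None,
                            cutoff: float = 0.5) -> RecoverySummary:
    """Simulate-fit-classify replicates of one scenario and aggregate.

    Per replicate: draw a cohort, fit the mixture by EM, record the 8
    scalar point estimates and the confusion of the 0.5-cutoff classifier
    against the generating labels.  Replicate seeds are derived
    deterministically from the root seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    overrides = dict(config_overrides or {})
    seeds = _replicate_seeds(seed, n_replicates)
    rows, sens, spec = [], [], []
    n_failed = 0
    truth_cfg = make_scenario(which_scenario, **overrides)
    for rep in range(n_replicates):
        config = make_scenario(which_scenario, seed=int(seeds[rep]),
                               **overrides)
        sim = simulate_cohort(config)
        try:
            fit = fit_em(sim.cohort, em_options)
        except PhasemixError:
            n_failed += 1
            continue
        rows.append(fit.params.flatten())
        report = confusion_metrics(sim.eta, classify(fit.latent, cutoff))
        sens.append(report.sensitivity)
        spec.append(report.specificity)
    if not rows:
        raise RuntimeError("every replicate failed to fit")
    truth = pd.Series(
        PopulationParameters(truth_cfg.mono_truth, truth_cfg.bi_truth,
                             truth_cfg.sigma**2, truth_cfg.lam).flatten(),
        index=PARAM_COLUMNS)
    return RecoverySummary(
        pd.DataFrame(rows, columns=PARAM_COLUMNS), truth,
        n_replicates, n_failed, np.asarray(sens), np.asarray(spec))


def run_sensitivity_grid(configs, n_replicates: int, seed: int = 0,
                         em_options: EMOptions | None = None,
                         cutoff: float = 0.5) -> pd.DataFrame:
    """Average classification rates over a grid of generative configs.

    Returns a long-format table with one row per configuration
    (bi-phasic slopes, observations per patient, cohort size, mean
    sensitivity and specificity) suitable for contour plotting.
    """
    rows = []
    seeds = _replicate_seeds(seed, len(configs) * n_replicates)
    idx = 0
    for config in configs:
        sens, spec = [], []
        for _ in range(n_replicates):
            sim = simulate_cohort(dc_replace(config, seed=int(seeds[idx])))
            idx += 1
            try:
                fit = fit_em(sim.cohort, em_options)
            except PhasemixError:
                continue
            rep = confusion_metrics(sim.eta, classify(fit.latent, cutoff))
            sens.append(rep.sensitivity)
            spec.append(rep.specificity)
        rows.append({
            "B1": config.bi_truth.mean[1], "B1p": config.bi_truth.mean[3],
            "n_obs": config.n_followups + 1,
            "n_patients": config.n_patients,
            "sensitivity": float(np.nanmean(sens)) if sens else np.nan,
            "specificity": float(np.nanmean(spec)) if spec else np.nan,
        })
    return pd.DataFrame(rows)


def run_coverage_experiment(which_scenario: int, n_replicates: int,
                            gibbs_options: GibbsOptions,
                            seed: int = 0,
                            em_options: EMOptions | None = None,
                            config_overrides: dict | None = None,
                            level: float = 0.95) -> CoverageSummary:
    """Simultaneous-credible-region coverage across replicates.

    Scenario 1 checks the 8 scalar parameters; scenarios 2 and 3 all 21
    (including the covariance entries).  Scenario 3 additionally records
    how often zero is excluded from the credible interval of the
    first/second-slope covariance.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    include_cov = which_scenario != 1
    overrides = dict(config_overrides or {})
    seeds = _replicate_seeds(seed, n_replicates)
    truth_cfg = make_scenario(which_scenario, **overrides)
    truth = PopulationParameters(
        truth_cfg.mono_truth, truth_cfg.bi_truth,
        truth_cfg.sigma**2, truth_cfg.lam).flatten(include_cov=include_cov)
    names = PopulationParameters.flat_names(include_cov=include_cov)
    n_par = len(truth)

    covered = []
    per_par = np.zeros(n_par)
    detect = []
    n_failed = 0
    for rep in range(n_replicates):
        config = make_scenario(which_scenario, seed=int(seeds[rep]),
                               **overrides)
        sim = simulate_cohort(config)
        try:
            fit = fit_em(sim.cohort, em_options)
            opts = dc_replace(gibbs_options, seed=int(seeds[rep]) + 1,
                              init=fit.params)
            chain = run_chain(sim.cohort, opts)
        except PhasemixError:
            n_failed += 1
            continue
        draws = chain.table[:, :n_par] if not include_cov else chain.table
        region = simultaneous_credible_region(draws, level, names=names)
        covered.append(region.contains(truth))
        per_par += (truth >= region.lower) & (truth <= region.upper)
        if which_scenario == 3:
            # slope-correlation detection focuses on this one parameter,
            # so it uses the marginal equal-tailed interval, not the
            # (much wider) simultaneous region
            j = names.index("covB_13")
            lo, hi = np.quantile(draws[:, j], [(1 - level) / 2,
                                               (1 + level) / 2])
            detect.append(not lo <= 0.0 <= hi)
    n_ok = len(covered)
    if n_ok == 0:
        raise RuntimeError("every replicate failed")
    return CoverageSummary(
        level, n_replicates, n_failed,
        joint_coverage=float(np.mean(covered)),
        per_parameter=pd.Series(per_par / n_ok, index=names),
        detection=float(np.mean(detect)) if detect else float("nan"))
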