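"""Model/Results front end.

`BiphasicMixture` is the user-facing entry point: build it from a cohort or
a long-format DataFrame, call :meth:`fit` to run the EM algorithm, then
optionally :meth:`BiphasicMixtureResults.sample_posterior` to continue into
the Gibbs sampler from the EM mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import Cohort, cohort_from_frame
from .em import EMOptions, EMResult, fit_em
from .evaluate import classify, confusion_metrics
from .gibbs import (ChainSummary, GibbsOptions, run_chain,
                    simultaneous_credible_region)
from .params import PopulationParameters

__all__ = ["BiphasicMixture", "BiphasicMixtureResults", "PosteriorResults"]


class BiphasicMixture:
    """Two-class (mono/bi-phasic) piecewise-linear trajectory mixture.

    Each subject's biomarker series either follows one line with
    subject-level coefficients s_i ~ N(S, Sigma_S), or two lines joined at
    a latent change point with coefficients b_i ~ N(B, Sigma_B); residuals
    are iid N(0, sigma^2) and a subject is bi-phasic with probability
    lambda.  Fitting estimates the population parameters, each subject's
    class probability and change-point distribution.

    Examples
    --------
    >>> from phasemix import BiphasicMixture, make_scenario, simulate_cohort
    >>> sim = simulate_cohort(make_scenario(1, n_patients=40, seed=3))
    >>> res = BiphasicMixture(sim.cohort).fit()
    >>> res.params.round(2)  # doctest: +SKIP
    """

    def __init__(self, cohort: Cohort):
        self.cohort = cohort

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, patient_col="patient_id",
                       time_col="time", value_col="value"):
        """Build from a long-format table (one row per observation)."""
        return cls(cohort_from_frame(df, patient_col, time_col, value_col))

    def fit(self, max_iter: int = 500, tol: float = 1e-6,
            init="grid", seed: int = 0) -> "BiphasicMixtureResults":
        """Run the EM algorithm and return a results object."""
        res = fit_em(self.cohort,
                     EMOptions(max_iter=max_iter, tol=tol, init=init,
                               seed=seed))
        return BiphasicMixtureResults(self, res)


class BiphasicMixtureResults:
    """EM mode estimate with latent state, diagnostics and summaries."""

    def __init__(self, model: BiphasicMixture, result: EMResult):
        self.model = model
        self._result = result
        self.population: PopulationParameters = result.params
        self.latent = result.latent
        self.individuals = result.individuals
        self.converged = result.converged
        self.n_iter = result.n_iter
        self.objective_trace = result.trace

    @property
    def params(self) -> pd.Series:
        """(S0, S1, B0, B1, B0', B1', sigma, lambda) point estimates."""
        return pd.Series(self.population.flatten(),
                         index=PopulationParameters.flat_names())

    def classify(self, cutoff: float = 0.5) -> np.ndarray:
        """Hard labels: 1 (bi-phasic) iff z_i > cutoff."""
        return classify(self.latent, cutoff)

    def classification_report(self, truth, cutoff: float = 0.5):
        return confusion_metrics(truth, self.classify(cutoff),
                                 z=self.latent.z)

    def patient_table(self) -> pd.DataFrame:
        """Per-patient posterior class probability, modal change point and
        empirical-Bayes coefficients."""
        rows = []
        for p, z, zeta, ind in zip(self.model.cohort, self.latent.z,
                                   self.latent.zeta, self.individuals):
            k = int(np.argmax(zeta)) + 1
            rows.append({
                "patient_id": p.patient_id, "n_obs": p.n_obs,
                "z_biphasic": z, "k_mode": k,
                "s0": ind.s_hat[0], "s1": ind.s_hat[1],
                "b0": ind.b_hat[k - 1][0], "b1": ind.b_hat[k - 1][1],
                "b0p": ind.b_hat[k - 1][2], "b1p": ind.b_hat[k - 1][3],
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        p = self.params
        lines = [
            "Mixture piecewise-linear trajectory model (EM)",
            "=" * 54,
            f"patients: {len(self.model.cohort):>6d}    "
            f"observations: {self.model.cohort.n_obs_total}",
            f"iterations: {self.n_iter:>4d}    converged: {self.converged}",
            f"objective: {self._result.objective:.4f}",
            "-" * 54,
            f"{'parameter':<12}{'estimate':>12}",
        ]
        for name, val in p.items():
            lines.append(f"{name:<12}{val:>12.4f}")
        n_bi = int(self.classify().sum())
        lines.append("-" * 54)
        lines.append(f"classified bi-phasic at 0.5 cutoff: {n_bi} / "
                     f"{len(self.model.cohort)}")
        return "\n".join(lines)

    def sample_posterior(self, n_iter: int = 30_000, burn_in: int = 3_000,
                         thin: int = 1, seed: int = 0) -> "PosteriorResults":
        """Run the Gibbs sampler from this EM mode."""
        opts = GibbsOptions(n_iter=n_iter, burn_in=burn_in, thin=thin,
                            seed=seed, init=self.population)
        chain = run_chain(self.model.cohort, opts)
        return PosteriorResults(self, chain)


class PosteriorResults:
    """Posterior draws (Gibbs) started from an EM mode."""

    def __init__(self, em_results: BiphasicMixtureResults,
                 chain: ChainSummary):
        self.em_results = em_results
        self.chain = chain

    def to_frame(self) -> pd.DataFrame:
        """One row per kept draw, one column per scalar parameter."""
        return pd.DataFrame(self.chain.table, columns=self.chain.names)

    @property
    def posterior_mean(self) -> pd.Series:
        return self.to_frame().mean()

    def credible_region(self, level: float = 0.95, include_cov=True):
        """Simultaneous rectangular credible region for all parameters."""
        draws = self.chain.table if include_cov else self.chain.params_8()
        names = self.chain.names if include_cov else self.chain.names[:8]
        return simultaneous_credible_region(draws, level, names=names)

    def summary(self, level: float = 0.95) -> str:
        df = self.to_frame()
        region = self.credible_region(level)
        lines = [
            "Posterior draws (Gibbs sampler from EM mode)",
            "=" * 62,
            f"kept draws: {self.chain.n_kept}   "
            f"(n_iter={self.chain.n_iter}, burn_in={self.chain.burn_in}, "
            f"thin={self.chain.thin})",
            "-" * 62,
            f"{'parameter':<10}{'mean':>12}{'sd':>12}"
            f"{'lower':>13}{'upper':>13}",
        ]
        for j, name in enumerate(self.chain.names):
            lines.append(
                f"{name:<10}{df[name].mean():>12.4f}{df[name].std():>12.4f}"
                f"{region.lower[j]:>13.4f}{region.upper[j]:>13.4f}")
        lines.append("-" * 62)
        lines.append(f"{level:.0%} simultaneous rectangular credible region "
                     f"(pointwise level {region.pointwise_level:.4f})")
        return "\n".join(lines)
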