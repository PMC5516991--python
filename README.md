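# phasemix

Mixture piecewise-linear Bayesian hierarchical modelling of longitudinal
biomarker trajectories.

## The problem

Longitudinal biomarker series from clinical cohorts — serum M-protein in
multiple myeloma, viral load under antiretroviral therapy, BCR-ABL
transcripts in CML — are often neither homogeneous across patients nor
linear in time.  Some patients decline along a single line; others show a
*bi-phasic* pattern: a steep initial response followed by a slower second
phase, with the switch happening at an unknown, patient-specific time.
`phasemix` jointly (i) classifies each subject as mono- or bi-phasic,
(ii) locates each bi-phasic subject's change point, and (iii) estimates
population and subject-level regression parameters with full posterior
uncertainty.

## The model

For subject *i* with observations *y<sub>ij</sub>* at times
*t<sub>ij</sub>* (*j = 1..M<sub>i</sub>*), a latent indicator
η<sub>i</sub> ~ Bernoulli(λ) selects the class:

* mono-phasic (η<sub>i</sub> = 0):
  *y<sub>ij</sub>* = s<sub>0i</sub> + s<sub>1i</sub> t<sub>ij</sub> + ε<sub>ij</sub>,
  with **s**<sub>i</sub> ~ N(**S**, Σ<sub>S</sub>);
* bi-phasic (η<sub>i</sub> = 1): two lines joined after the
  k<sub>i</sub>-th observation,
  *y<sub>ij</sub>* = b<sub>0i</sub> + b<sub>1i</sub> t<sub>ij</sub> (first
  phase) or b′<sub>0i</sub> + b′<sub>1i</sub> t<sub>ij</sub> (second
  phase), with **b**<sub>i</sub> ~ N(**B**, Σ<sub>B</sub>);

and ε<sub>ij</sub> ~ N(0, σ²).  The admissible change points are the
M<sub>i</sub> − 1 gaps between consecutive observations; each gets a
per-subject probability π<sub>ij</sub> (uniform Dirichlet prior), and a
latent one-hot ξ<sub>i</sub> picks the realized bi-phasic design matrix.

Fitting proceeds in two stages:

1. **EM** to the posterior mode.  The E-step computes change-point
   posteriors ζ<sub>ij</sub> and class posteriors z<sub>i</sub>, where the
   mono/bi evidences are penalized by their negative BIC
   (−2 log M<sub>i</sub> vs −4 log M<sub>i</sub>) to correct for the
   bi-phasic model's extra flexibility; the M-step has closed-form
   weighted-moment updates, and π is refreshed through a cohort-level
   *phasic transition density* θ(t) so subjects with jittered visit times
   share change-point information on the time axis.
2. **Gibbs sampling** from the EM mode, drawing in turn
   ξ, η, θ, π (Dirichlet), λ (Beta), individual and population
   coefficients (normal), Σ<sub>S</sub>, Σ<sub>B</sub> (inverse-Wishart)
   and σ² (scaled inverse-χ²).  Simultaneous rectangular credible regions
   are built from the joint draws by bisection on the pointwise level.

A subject is called bi-phasic when its posterior probability z<sub>i</sub>
exceeds 0.5.

## Worked example

```python
from phasemix import BiphasicMixture, make_scenario, simulate_cohort

sim = simulate_cohort(make_scenario(1, n_patients=100, seed=1))
res = BiphasicMixture(sim.cohort).fit()
print(res.summary())
```

```
Mixture piecewise-linear trajectory model (EM)
======================================================
patients:    100    observations: 1800
iterations:   90    converged: True
objective: -5994.9398
------------------------------------------------------
parameter       estimate
S0               90.1811
S1               -0.2503
B0               90.7585
B1               -0.3473
B0p              55.3180
B1p              -0.1524
sigma             5.0092
lam               0.5700
------------------------------------------------------
classified bi-phasic at 0.5 cutoff: 57 / 100
```

The cohort was generated with S = (90, −0.25), B = (91, −0.35, 55, −0.15),
σ = 5 and λ = 0.6; 57 of the 100 simulated patients happened to be
bi-phasic, and the fit recovers both the class split (λ̂ = 0.57, all 57
correctly flagged at the 0.5 cutoff) and the regression parameters to
within a few percent.  Posterior uncertainty then comes from the sampler:

```python
post = res.sample_posterior(n_iter=5000, burn_in=1000, seed=2)
region = post.credible_region(0.95)   # simultaneous rectangular region
```

The same pipeline is available from the shell:

```bash
phasemix simulate --scenario 2 --seed 7 --out-dir sim
phasemix fit-em    --input sim/cohort.csv --out-dir fit
phasemix fit-gibbs --input sim/cohort.csv --out-dir post
phasemix evaluate  --experiment table3 --scenario 2 --scale reduced
```

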