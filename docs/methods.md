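# Methods

## Model

Each subject's biomarker series is generated by one of two latent classes.
A mono-phasic subject follows a single line with subject-level
coefficients s_i = (s0, s1) drawn from N(S, Sigma_S); a bi-phasic subject
follows two lines with coefficients b_i = (b0, b1, b0', b1') drawn from
N(B, Sigma_B), switching from the first to the second line after its k-th
observation.  Residuals are iid N(0, sigma^2); the bi-phasic class has
marginal probability lambda.  A change point before the first or after
the last observation is excluded — such a subject is observationally
mono-phasic — so subject i with M_i observations has M_i − 1 admissible
bi-phasic design matrices, with per-subject selection probabilities
pi_i = (pi_i1 .. pi_i,M_i−1) under a uniform Dirichlet prior.  The
remaining priors are improper: P(sigma^2) = (sigma^2)^-1, flat Beta(1,1)
on lambda, and Jeffreys-style powers of |Sigma| on the covariances.

Marginalizing the subject-level coefficients gives, for each class and
candidate design Q, a Gaussian evidence
N(Y_i | Q m, Q Sigma Q' + sigma^2 I).  All evidence and empirical-Bayes
computations run through the d × d (d ≤ 4) matrix
A = sigma^2 I + L' Q'Q L with Sigma = L L' (eigendecomposition square
root), via the determinant lemma and Woodbury identity.  This form is
exact when Sigma is singular — required because the zero-covariance
scenario drives the fitted Sigma toward 0 — and touches only the
sufficient statistics (Y'Y, Q'Y, Q'Q), which are precomputed once per
cohort.  All mixture sums are log-sum-exp; 18-point Gaussian products
underflow otherwise.

## EM stage

E-step.  Change-point posteriors zeta_ij are proportional to
pi_ij × (bi-phasic evidence for design j).  Class posteriors use
BIC-penalized evidences: on the 2-log scale, g_mono = 2 log N_mono −
2 log M_i and g_bi = 2 log(sum_j pi_ij N_j) − 4 log M_i, and

    z_i = lam e^{g_bi/2} / ((1 − lam) e^{g_mono/2} + lam e^{g_bi/2}).

Without the penalty the richer bi-phasic model absorbs nearly every
subject; the penalty difference (−2 log M_i) acts as per-subject prior
odds and is what produces the method's deliberate mono-ward conservatism.

M-step.  lambda, S, B are weighted means of the empirical-Bayes
subject estimates; Sigma_S, Sigma_B are weighted scatter matrices with a
"+2" in the denominator (the mode under a |Sigma|^-1 penalty — this is
the denominator the closed-form update actually uses, and the numerical
oracle test maximizes the matching objective); sigma^2 pools the expected
residual sum of squares plus the trace term tr(Q Sigma_hat Q') over all
observations, divided by (total observations + 2).  The per-observation
(rather than per-subject) denominator is the dimensional reading of the
update that reproduces sigma ≈ 5 on simulated cohorts; a per-subject
denominator inflates sigma^2 by roughly a factor M.

Change-point weights.  Because visit times are jittered, zeta cannot be
averaged across subjects by visit index.  Instead a cohort-level phasic
transition density theta(t) — piecewise constant on the union of all
inter-visit intervals, each interval (t_ij, t_i,j+1) contributing mass
z_i zeta_ij spread uniformly over its length, normalized to integrate to
one on [0, T] — is integrated over each subject's own intervals and
renormalized per subject to give the new pi_i.  Mass outside a subject's
span is thereby redistributed proportionally (each subject's design
indicator must sum to one over its own candidates).

Initialization is a deterministic per-subject least-squares screen: a
single-line fit and the best two-line fit over all candidate change
points, compared by per-subject BIC.  The two-line BIC charges five
parameters (four coefficients plus the selected change point): the
best-of-(M−1) search behaves like an extra fitted parameter, and charging
only four systematically over-seeds the bi-phasic class.  Cluster
fractions, pooled coefficients, pooled residual variance and the
histogram of preferred change intervals (through theta) seed lambda,
(S, B), sigma^2 and pi; covariances start at the within-cluster empirical
covariance plus a small diagonal floor.

Stopping rule.  The monitored objective is the BIC-penalized
observed-data log-likelihood,
sum_i log[(1−lam) e^{g_mono/2} + lam e^{g_bi/2}]; the improper covariance
priors are excluded from it because −log|Sigma| diverges as the
zero-covariance scenario's Sigma estimates shrink.  The BIC-substituted
class posterior is not a proper EM E-step, so this objective is not
guaranteed to ascend — and in practice it does not: on zero-covariance
cohorts it rises for a few dozen iterations, peaks, and then drifts
slowly downward while the covariance estimates spiral into a degenerate
Sigma = 0 spike of the improper posterior (once Sigma hits 0 the
empirical-Bayes estimates pin to the population mean and the update can
never leave).  A plain "absolute change < tol" rule rides that drift for
hundreds of iterations and returns the collapsed iterate, whose
point-mass covariances also cripple the sampler's mixing.  The fit
therefore tracks the best objective seen, stops after `patience`
(default 25) iterations without an improvement larger than `tol`
(default 1e-6; max_iter 500), and returns the best iterate — the actual
maximizer of the monitored objective.  At that iterate the fitted
covariances remain positive on zero-covariance data (intercept variances
of order 0.1–10), matching the magnitudes the replication experiments
report.  The objective trace is recorded in full and a decrease raises a
`FitWarning` rather than being hidden or asserted away.  If one class
loses essentially all weight (e.g. an all-mono cohort), the mixture has
degenerated to a single-class model — a legitimate boundary mode
equivalent to a linear mixed-effects fit — and iteration stops there.

## Gibbs stage

From the EM mode the sampler sweeps: (1) zeta; (2) one-hot design draw
xi_i ~ Multinomial(zeta_i); (3) z_i from the selected design (single
evidence, same BIC penalties); (4) eta_i ~ Bernoulli(z_i); (5) theta from
the hard draws; (6) pi_i ~ Dirichlet over the patient's intervals, with
concentration (expected number of cohort transitions in the interval,
i.e. the bi-phasic count times the normalized-theta integral) + 1 — the
conjugate Dirichlet count must be on the scale of observed transitions;
adding the bare normalized integral (at most one in total across all
intervals) would let the uniform prior swamp the shared change-point
signal, leaving pi near-uniform every sweep and biasing the bi-phasic
coefficients through change-point scatter;
(7) lambda ~ Beta(#bi + 1, #mono + 1); (8) subject coefficients from
their empirical-Bayes normal conditionals; (9) population means
S ~ N(mean of mono s_i, Sigma_S / #mono) and likewise B; (10)
Sigma_S ~ Inv-Wishart(#mono − 1, scatter), Sigma_B ~ Inv-Wishart(#bi − 3,
scatter); (11) sigma^2 ~ scaled Inv-chi^2(total observations, pooled
residual mean square).  No pseudoprior is used for the between-model
move; this is the known heuristic shortcut relative to a strict
Carlin–Chib sampler and is kept deliberately — the simulation results
below are produced by exactly this sweep, with no silent correction.
When class occupancy drops below the inverse-Wishart dimension
(#mono − 1 < 2 or #bi − 3 < 4) the conditional is improper; the step
raises rather than clamping, the chain driver resamples the sweep, and a
chain aborts if more than half of its iterations hit the guard.

Defaults: 30,000 iterations, 3,000 burn-in, thin 1; one root seed drives
a single generator through a fixed sweep order so chains are bit
reproducible.  Kept draws are flattened in a fixed order — S0, S1, B0,
B1, B0', B1', sigma, lambda, then the 3 upper-triangular entries of
Sigma_S and the 10 of Sigma_B (21 scalars) — so coverage experiments are
comparable across runs.

Simultaneous rectangular credible regions: for pointwise level q the
region is the componentwise equal-tailed [(1−q)/2, (1+q)/2] quantile box;
bisection (40 steps) finds the smallest q whose box contains at least the
nominal fraction of joint draws.  In one dimension this reduces to the
ordinary equal-tailed interval.

## Synthetic cohorts

The simulator draws eta_i ~ Bernoulli(lambda), subject coefficients from
the class normals, and iid Gaussian noise on a fixed schedule: baseline
day 0 plus 17 follow-ups every 21 days (last at day 357), each follow-up
independently jittered uniformly on ±5 days.  The baseline visit is not
jittered, anchoring the intercepts at t = 0; uniform jitter is the
minimal assumption consistent with a stated ±5-day bound.  A bi-phasic
subject's transition time is the intersection of its two lines,
t* = (b0 − b0')/(b1' − b1); observations at t ≤ t* belong to the first
phase.  Under normal coefficient draws t* follows a heavy-tailed
Gaussian-ratio law, so some generated bi-phasic subjects switch outside
the observation window and are observationally straight lines.  They are
kept, and truth labels remain generator-class labels: the resulting
"misclassifications" (and the downward bias of the fitted lambda in the
scenarios with between-patient variability) are properties of the data
generating process that the model is expected to reproduce, not errors
to be patched.  The simulator does not model dropout, missing visits, or
informative observation times, so test results say nothing about those
features of real trial data.

Stock scenarios (N = 100, S = (90, −0.25), B = (91, −0.35, 55, −0.15),
sigma = 5, lambda = 0.6): scenario 1 has no between-patient variability;
scenario 2 adds independent variation (variance 4 on intercepts, 0.0009
on slopes); scenario 3 adds correlation 0.5 between the two bi-phasic
slopes (covariance 0.5 · 0.03 · 0.03 = 0.00045).  Sensitivity grids vary
the bi-phasic slopes over [−0.45, −0.26] × [−0.24, −0.05] with the second
intercept set so the population-level transition stays at 178 days, or
vary observations per patient / cohort size.

## Problem sizes and numerical choices

Replication experiments default to 50 EM replicates per scenario and, for
the coverage experiment, 100 replicates of 5,000-iteration chains
(burn-in 1,000) for scenario 1 and 30 replicates for the scenario-3
correlation-detection rate (zero excluded from the marginal equal-tailed
95% interval of the slope-slope covariance — the detection question
concerns that single parameter, so the simultaneous region, whose
per-parameter level is far above 95%, is not the right yardstick); the package's full-scale configuration
(1,000 replicates, 30,000 iterations) is available through
`phasemix evaluate --scale full`.  Reduced-scale Monte-Carlo error is the
reason the replication tests use band checks (e.g. joint coverage within
a 70–90% window) rather than point comparisons.

Replicate seeds derive from one root seed through a single generator, so
experiments are reproducible and replicates are independent.  Hot loops
optionally run through a fused numba kernel implementing the identical
evidence algebra; the plain-numpy path remains the fallback and both are
cross-checked against a dense-matrix multivariate-normal oracle in the
tests.  Ties at z = cutoff classify as mono-phasic, consistent with the
method's conservative lean.  Degenerate inputs (series with fewer than
two visits, duplicate visit times, non-finite values) are rejected at
construction.

## Known limitations

At most two phases per subject and two mixture classes; no covariate
adjustment.  The heuristic between-model move means the sampler is not a
strict Gibbs sampler on the joint model space; posterior lambda
uncertainty should be read accordingly.  The covariance of the bi-phasic
second intercept is systematically over-estimated (change-point
misassignment, back-projection to t = 0, and heavy-tailed transition
times all inflate it), and empirical coverage of the simultaneous regions
falls short of nominal — both behaviours are inherent to the method and
are reproduced, not corrected, here.
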