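# Methods

`cogvar` quantifies interindividual differences in *intraindividual*
cognitive variability from trial-level response times, and analyses how
those differences relate across tasks and to mean performance.  This note
documents the models, the synthetic data they are validated on, the
numerical choices, and the limits of what the validation shows.

## The within-task model

For each task separately, the log response time of person *i* at trial *t*
follows a two-level AR(1) location-scale model:

    y_it = mu_i + beta_i * x(t) + w_it
    w_it = phi_i * w_i,t-1 + eps_it,      eps_it ~ N(0, exp(omega_i))
    (mu_i, beta_i, phi_i, omega_i)' ~ N(gamma, Sigma)

- **mu_i** — person mean log RT (location).
- **beta_i** — linear practice/improvement trend.  The time covariate
  x(t) is the trial index centered at the person's midpoint and divided
  by 100, which keeps beta numerically comparable to mu; the scaling is a
  package convention (any affine recoding of t is absorbed by mu and
  beta).
- **phi_i** — inertia: the lag-1 carryover of a deviation to the next
  trial, constrained to (-1, 1).
- **omega_i** — log residual variance, the **cognitive variability**
  score.  The log link keeps the variance positive while letting omega
  itself go negative; exp(omega) is the trial-to-trial innovation
  variance on the log-ms scale.

The initial state is stationary, w_i1 ~ N(0, exp(omega_i)/(1 - phi_i²)),
which avoids an arbitrary warm-up convention and makes the AR variance
identity Var(w) = exp(omega)/(1 - phi²) exact.

### Estimation

Metropolis-within-Gibbs, vectorized across persons:

- (mu_i, beta_i): conjugate normal updates after prewhitening the series
  by the current phi_i (the first observation is scaled by
  sqrt(1 - phi²), later ones are quasi-differenced).
- (phi_i, omega_i): joint random-walk Metropolis with per-person step
  sizes adapted toward a ~30% acceptance rate during burn-in and frozen
  afterwards; phi proposals reflect at ±1.
- (gamma, Sigma): semi-conjugate normal and inverse-Wishart updates.
  Priors: gamma ~ N(0, 100² I); Sigma ~ IW(dim + 2, 0.1·I).  The 0.1
  scale is weakly informative on the scale the parameters actually live
  on (between-person variances of order 1e-4 to 0.25 on log-ms); a unit
  scale would overwhelm them at realistic sample sizes, and a much
  smaller one over-shrinks the person effects and blunts the DIC
  comparison below.  The scale is a constructor argument.
- Missing trials (Tukey-masked outliers) are imputed as latent states by
  single-site Gibbs updates in a checkerboard (even/odd positions)
  schedule, preserving the AR chain across gaps.

Defaults: 20,000 iterations per chain with the first half as burn-in,
two chains, PSRF (split R-hat) reported per top-level quantity with a
1.1 convergence threshold.  Subjects with fewer than 10 observed trials
(configurable) are dropped: below that, omega_i is essentially
unidentified.

### DIC and the random-variability test

Whether variability *differs between people* is tested by refitting with
omega_i constrained to its population value (the row and column of Sigma
for omega removed) and comparing DIC = D̄ + pD, pD = D̄ − D(θ̂), where
the deviance conditions on the person-level effects — the standard
convention for this model class.  Missing trials are marginalized
analytically in the deviance using the Markov property of the AR(1)
process (after a gap of g trials the deviation is
N(phi^g w_prev, sigma² (1−phi^{2g})/(1−phi²))), so the DIC is a
deterministic function of the stored draws and the observed data.

ΔDIC between two MCMC runs carries Monte-Carlo noise of a few units at
desk scales, while the systematic penalty for a spurious random effect
grows with persons × per-person information.  The shipped simulation
check therefore uses 60 persons × 100 trials and 1,500 iterations per
chain, where the separation is comfortably larger than the noise; at
much smaller scales the null-case comparison approaches a coin flip.

### Reliability of the variability score

No closed form is attempted.  Reliability is estimated by simulation:
replicate persons are drawn from the fitted (gamma, Sigma), observed for
n occasions with added white measurement noise of variance
(1 − rho)/rho × the median within-person variance (rho the assumed scale
reliability, .5/.7/.9), omega is re-estimated per replicate by a
method-of-moments AR(1)-with-trend fit, and reliability is the squared
correlation with the generating omega.  It is monotone in both n and rho
and approaches the determinacy ceiling at study-scale trial counts.

## Preprocessing

Fixed order: guided (instruction) trials dropped → incorrect trials
dropped → RT divided by the presented item count on span tasks (all
working-memory tasks and tangram, where more items mechanically mean
longer responses) → natural log → Tukey masking.  Fences are
Q1 − 1.5·IQR and Q3 + 1.5·IQR with linearly interpolated quartiles,
computed per task on the pooled distribution across subjects; flagged
values become missing without shortening the series.  Whether fences are
computed on logged (default) or raw per-item RTs is a config switch —
on strictly positive data the two differ only through the skew of the
raw scale.  Under a Gaussian log-RT model the fences flag ~0.7% of
trials; heavier-tailed real RT data flag more.

## Cross-task structure

Person-level omega scores (and mean-performance scores: mean difficulty
level over correct trials) form subjects × tasks matrices.  Pearson
correlations use pairwise-complete cases (≥ 3 required), two-sided
p values, and Holm's step-down adjustment over the unique pairs.
Williams's t (pooled-correlation variant, r̄ = (r12+r13)/2, with the
correlation-matrix determinant, df = n − 3) compares dependent
correlations sharing one variable.  The median-RT control analysis
correlates the vectorized lower triangle of the |median RT difference|
matrix with the matching variability correlations; a near-zero value
says RT-scale differences between tasks do not drive the correlation
structure.  Signed (not absolute) correlations are averaged when a mean
off-diagonal r is reported.

## Confirmatory factor models

Covariance-structure-only ML: F_ML = ln|Σ(θ)| + tr(SΣ⁻¹) − ln|S| − p,
minimized by L-BFGS-B from standardized starts with a Nelder-Mead
polish; χ² = (n−1)F.  Marker identification (first loading per latent
fixed to 1) gives the shipped specs their analytic degrees of freedom:
unidimensional over 11 tasks df = 44, general factor with a WM
subdomain df = 43, three-subdomain hierarchical df = 40.  Variance
estimates are deliberately unbounded so improper solutions surface as
Heywood flags instead of silently hitting a bound.  RMSEA uses
sqrt(max(χ²−df,0)/(df(n−1))) with a 90% CI from inverting the
noncentral χ²; CFI compares against the independence baseline.  Plain
normal-theory ML is used throughout — the standard formulas, not
kurtosis-robust corrections, which require raw-data moments outside
this package's scope.  Incomplete matrices are handled by casewise
(full-information) ML under MAR, with the saturated model estimated by
EM for the likelihood-ratio χ².

In the three-subdomain spec, the backwards digit span task cross-loads
on mathematics and working memory; nonverbal reasoning is placed on the
general factor directly.  That placement is a configuration choice, not
a task-battery fact, and alternative placements can be expressed in the
one-line-per-latent model text format.

## Exploratory factor analysis

Minres extraction: uniquenesses optimized (L-BFGS-B, SMC starts) to
minimize squared off-diagonal residuals; an infinitesimal (1e-6)
parsimony term breaks the tie on exactly diagonal inputs toward null
loadings.  Rotation is oblimin with γ = 0 (direct quartimin) via
gradient projection; factors are ordered by explained variance
(diag(Λ'ΛΦ)/p) with positive column sums.  Factor counts come from
Horn's parallel analysis; the default compares empirical eigenvalues to
the *mean* reference eigenvalues of size-matched random normal data —
the classical rule, which is intentionally liberal: on pure-noise data
the top empirical eigenvalue exceeds the reference mean about half the
time, so a spurious factor or two can be suggested, and decisions near
a boundary are unstable across seeds (the motivation for looping the
analysis over many seeds and tallying).  A `quantile=` argument (e.g.
0.95) gives the stricter rule whose null false-positive rate is about
1 − quantile.  Factor scores are Thurstone regression scores
Z R⁻¹ (ΛΦ), standardized; their correlation with a true factor is
bounded by the factor determinacy, ≈ 0.92 for four indicators loading
0.8 — recovery checks are calibrated against that ceiling, not against
1.

## The synthetic battery

The generator emulates the study design the models assume: 11 tasks
(six working-memory span tasks, two mathematics tasks, nonverbal
reasoning, rotation, tangram), per-task trial counts matching the
study's median trials per child, person effects N(gamma, Sigma) with
defaults gamma = (8.9, 0, 0.3, −3.2) and
Sigma = diag(0.04, 0.0001, 0.02, 0.25) on the log-ms scale, omega
linked across tasks by a configurable loading matrix (default: a WM
factor, a mathematical-reasoning factor, and a tangram factor), and
phi redrawn (not clipped) into (−1, 1).  Difficulty follows a one-up /
one-down staircase with a logistic accuracy model in
(ability − level); ability is tied to −mu by a configurable
coefficient, so slower people sit at lower levels and, when Sigma or
the accuracy coupling says so, are also more variable — reproducing the
sign of the variability–performance association.  Span tasks record
per-item RT × item count, so the preprocessing division exactly
recovers the modelled series.  Guided trials are emitted flagged, so
their removal is exercised rather than assumed.

What the generator does **not** emulate: a one-up/one-down staircase
equilibrates near 50–60% accuracy, far below the high correct rates of
real adaptive training data, so roughly half of generated trials are
discarded by the correct-only filter — reduced-scale runs must budget
trials accordingly; there are no session boundaries, no day-level
variability timescale, no heavy-tailed RT contamination beyond the
log-normal model, and no item content.  Passing recovery tests
therefore show that the estimators invert the model they assume, not
that real data obey that model.

## Problem sizes in the shipped checks

Chosen as the package's validation design: person-effect recovery at
150 × 150 with 2,000 post-burn-in draws; DIC selection at 60 × 100,
20 replications per truth condition; Williams/Holm error control at
10,000 Monte-Carlo replications (n = 2,608 per replication for
Williams); parallel analysis looped over 100 seeds on 800 × 11 scores;
CFA self-consistency at n = 2,000 over 20 seeds per spec.

## Known limitations

- The sampler is exact-model Bayesian but single-task; no cross-task
  joint model (scores are correlated post hoc, as in the analysis it
  reproduces).
- DIC uses the conditional deviance; marginal-likelihood criteria would
  penalize differently.
- FIML assumes MAR; Tukey masking inside the DSEM is MNAR in principle
  (values are masked *because* they are extreme), handled instead by
  latent-state imputation under the model.
- Robust (sandwich/kurtosis-corrected) SEM statistics are out of scope;
  fit indices assume normality.
- Reliability is simulation-defined, not a closed-form coefficient;
  different method-of-moments estimators would shift its absolute level
  (its monotone behavior is what the package relies on).
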