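# cogvar

Cognitive performance fluctuates from trial to trial, and people differ
reliably in *how much* they fluctuate.  `cogvar` is a Python toolkit for
treating that intraindividual variability as a phenotype in its own
right: it estimates a person-level variability score per task from dense
trial-by-trial response-time data, tests whether variability genuinely
differs between people, and analyses how variability — in contrast to
mean performance — is structured across a battery of tasks.  It is aimed
at researchers in developmental and cognitive psychology or
psychiatry/education research who have intensive longitudinal task data
(training apps, e-learning platforms, repeated testing) and want more
than a mean and an SD per person.

## The model

For each task, log response times of person *i* follow a two-level AR(1)
location-scale model:

```
y_it = μ_i + β_i·x(t) + w_it
w_it = φ_i·w_i,t−1 + ε_it,      ε_it ~ N(0, exp(ω_i))
(μ_i, β_i, φ_i, ω_i)′ ~ N(γ, Σ)
```

μ_i is the person's mean log RT, β_i a practice trend, φ_i the inertia
(lag-1 carryover) and ω_i the log residual variance — the **cognitive
variability** score.  The model is estimated by Metropolis-within-Gibbs
MCMC (conjugate location updates, reflected random-walk steps for φ and
ω, normal/inverse-Wishart updates for γ and Σ, latent imputation of
outlier-masked trials).  A Deviance Information Criterion comparison
against a model with ω_i fixed across people tests whether variability
differences are real; extracted ω̂_i scores then feed cross-task
correlation (with Holm correction and Williams's tests), confirmatory
factor models (ML with RMSEA/CFI and Heywood detection), and exploratory
factor analysis (minres + oblimin, factor counts by looped parallel
analysis).

A synthetic-data module generates full task batteries with known ground
truth — adaptive difficulty staircases, span-task per-item RTs, guided
trials, and a configurable cross-task factor structure for ω — so every
estimator is validated by parameter recovery.  See `docs/methods.md` for
assumptions, priors, numerical choices and limitations.

## Worked example

```python
import numpy as np
from cogvar import (default_battery, generate_population, preprocess_trials,
                    fit_dsem, extract_factor_scores)
from cogvar.synthetic import SPAN_TASKS

gen = default_battery(n_subjects=40, seed=7, trial_scale=0.5)
trials, truth = generate_population(gen)
series, report = preprocess_trials(trials, span_task_ids=SPAN_TASKS)
print(f"{len(trials)} trials generated; "
      f"{report['tasks']['grid']['masked_fraction']:.2%} masked in 'grid'")

sub = series[series.task == "grid"]
fit = fit_dsem(sub, n_iterations=2000, n_chains=2, random_state=7)
print(f"gamma: mu={fit.gamma_['mu']:.2f} beta={fit.gamma_['beta']:.3f} "
      f"phi={fit.gamma_['phi']:.2f} omega={fit.gamma_['omega']:.2f}")
print(f"tau2_omega = {fit.tau2_omega_:.3f}   DIC = {fit.dic_:.1f}   "
      f"max PSRF = {fit.psrf_['max']:.3f}")

scores = extract_factor_scores(fit)
truth_grid = truth[truth.task == "grid"].set_index("subject")
r = np.corrcoef(scores.set_index("subject")["omega"],
                truth_grid.loc[scores["subject"], "omega"])[0, 1]
print(f"corr(omega_hat, omega_true) = {r:.2f}")
```

Output:

```
55200 trials generated; 1.72% masked in 'grid'
gamma: mu=8.90 beta=-0.032 phi=0.17 omega=-3.43
tau2_omega = 0.117   DIC = -864.9   max PSRF = 1.016
corr(omega_hat, omega_true) = 0.77
```

Reading it: the pooled Tukey fences masked 1.7% of the task's correct
trials as outliers; the population mean log RT (8.90 ≈ 7.3 s) and log
residual variance (−3.43) are recovered; τ²_ω = 0.117 > 0 says people
genuinely differ in variability in this small sample; and the extracted
per-person variability scores correlate 0.77 with the generating truth —
at 40 subjects and ~40 observed trials each.  Larger designs push that
recovery correlation toward 0.98 (see the acceptance script below).

The same pipeline runs from the shell:

```
cogvar generate --subjects 100 --trial-scale 0.5 --seed 7 --out data/
cogvar run-all --out results/ --seed 7
```

with subcommands `preprocess`, `fit-dsem`, `scores`, `crosstask`, `cfa`
and `efa` for the individual stages.

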