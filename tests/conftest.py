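import numpy as np
import pandas as pd
import pytest

from cogvar.synthetic import TaskConfig, draw_person_effects, simulate_task_series

GAMMA = np.array([8.9, 0.0, 0.3, -3.2])
SIGMA = np.diag([0.04, 0.0001, 0.02, 0.25])


def make_ar1_panel(n_subjects, n_trials, tau2_omega=0.25, seed=0, gamma=None):
    """Subjects x trials log-RT matrix from the generative model, plus truth."""
    gamma = GAMMA if gamma is None else gamma
    Sigma = np.diag([0.04, 0.0001, 0.02, tau2_omega])
    effects = draw_person_effects(n_subjects, gamma, Sigma, seed)
    task = TaskConfig("t", n_trials=n_trials)
    rng = np.random.default_rng(seed + 10_000)
    y = np.empty((n_subjects, n_trials))
    for i in range(n_subjects):
        rec = simulate_task_series(effects.iloc[i], task, rng)
        y[i] = np.log(rec["rt_ms"].to_numpy())
    return y, effects


def make_factor_scores(n, loadings, seed=0):
    """Score matrix with a known factor structure (unit-variance columns)."""
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    p, k = loadings.shape
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, k))
    uniq = np.sqrt(np.clip(1.0 - np.sum(loadings**2, axis=1), 1e-6, None))
    X = f @ loadings.T + rng.standard_normal((n, p)) * uniq
    return pd.DataFrame(X, columns=[f"t{j}" for j in range(p)]), f


@pytest.fixture(scope="session")
def small_recovery_fit():
    """One moderately sized DSEM fit shared across tests (expensive)."""
    from cogvar.dsem import AR1LocationScaleDSEM

    y, effects = make_ar1_panel(60, 80, seed=1)
    fit = AR1LocationScaleDSEM(
        n_iterations=800, burn_in=300, n_chains=2, random_state=3
    ).fit(y)
    return fit, y, effects
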