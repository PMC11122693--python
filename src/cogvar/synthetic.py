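"""Synthetic trial-level data with known ground truth.

Generates multi-task batteries of response-time series with the statistical
structure the multilevel AR(1) location-scale model assumes: each person i
has a latent 4-vector of effects (mu, beta, phi, omega) — mean log RT, linear
trend, inertia (lag-1 autoregression) and log residual variance — drawn from
a multivariate normal between-person distribution N(gamma, Sigma).  Within a
task, trial t of person i follows

    y_it = mu_i + beta_i * x(t) + w_it,
    w_it = phi_i * w_i,t-1 + eps_it,     eps_it ~ N(0, exp(omega_i)),

with a stationary initial state.  Across tasks, the log residual variances
omega follow a configurable factor model (loadings * common factors + unique
noise), so the cross-task correlation structure of "cognitive variability"
is known exactly and can be used for recovery testing.

Difficulty is adaptive: a one-up / one-down staircase on an integer level,
with correctness drawn from a logistic model in (ability - level).  Span
tasks (working-memory style) present `level` items per trial, and the raw
recorded RT is the per-item RT times the number of items, so that the
preprocessing division by item count recovers the modelled series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "GeneratorConfig",
    "draw_person_effects",
    "simulate_task_series",
    "generate_population",
    "default_battery",
]

#: column order of the person-effect vector everywhere in the package
EFFECT_NAMES = ("mu", "beta", "phi", "omega")


@dataclass
class TaskConfig:
    """Configuration of one adaptive task.

    Parameters
    ----------
    task_id : str
        Task label.
    n_trials : int
        Trials per subject (including guided trials).
    is_span_task : bool
        If True, each trial presents ``level`` items and the recorded RT is
        the per-item RT multiplied by the item count (working-memory span
        tasks and the tangram task behave this way).
    max_level : int
        Ceiling of the difficulty staircase.
    accuracy_intercept, accuracy_slope : float
        Logistic accuracy model: P(correct) = sigmoid(intercept +
        slope * (ability - level)).
    ability_coef, ability_offset : float
        Person ability is ``ability_coef * (ability_offset - mu_i)``: slower
        people (larger mean log RT) are less able, which couples variability
        to mean performance when Sigma correlates mu and omega.
    guided_trials : int
        Number of initial trials flagged as guided (instruction) trials.
    """

    task_id: str
    n_trials: int = 100
    is_span_task: bool = False
    max_level: int = 12
    accuracy_intercept: float = 3.0
    accuracy_slope: float = 0.7
    ability_coef: float = 5.0
    ability_offset: float = 9.0
    guided_trials: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.max_level < 1:
            raise ValueError(f"max_level must be >= 1, got {self.max_level}")
        if self.guided_trials < 0 or self.guided_trials > self.n_trials:
            raise ValueError("guided_trials must be in [0, n_trials]")


@dataclass
class GeneratorConfig:
    """Population-level configuration of a multi-task battery.

    ``gamma`` and ``Sigma`` are the between-person mean vector and covariance
    of (mu, beta, phi, omega) on the log-ms scale, applied within every task.
    ``omega_loadings`` (tasks x factors) and ``omega_unique`` (per-task)
    define the cross-task factor structure of omega: rows are standardized so
    that loadings @ loadings.T + diag(unique) is a correlation matrix, then
    scaled by sqrt(Sigma[3, 3]).
    """

    n_subjects: int
    tasks: list[TaskConfig]
    gamma: np.ndarray = field(
        default_factory=lambda: np.array([8.9, 0.0, 0.3, -3.2])
    )
    Sigma: np.ndarray = field(
        default_factory=lambda: np.diag([0.04, 0.0001, 0.02, 0.25])
    )
    omega_loadings: np.ndarray | None = None
    omega_unique: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.gamma.shape != (4,):
            raise ValueError("gamma must be a length-4 vector")
        _check_psd(self.Sigma, 4)
        if self.omega_loadings is not None:
            self.omega_loadings = np.atleast_2d(
                np.asarray(self.omega_loadings, dtype=float)
            )
            if self.omega_loadings.shape[0] != len(self.tasks):
                raise ValueError(
                    f"omega_loadings has {self.omega_loadings.shape[0]} rows "
                    f"but there are {len(self.tasks)} tasks"
                )
            if self.omega_unique is None:
                comm = np.sum(self.omega_loadings**2, axis=1)
                self.omega_unique = np.maximum(1.0 - comm, 1e-6)
            self.omega_unique = np.asarray(self.omega_unique, dtype=float)
            if self.omega_unique.shape != (len(self.tasks),):
                raise ValueError("omega_unique must have one entry per task")
            if np.any(self.omega_unique < 0):
                raise ValueError("omega_unique entries must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        tasks = [TaskConfig(**t) for t in raw.pop("tasks")]
        for key in ("gamma", "Sigma", "omega_loadings", "omega_unique"):
            if key in raw and raw[key] is not None:
                raw[key] = np.asarray(raw[key], dtype=float)
        return cls(tasks=tasks, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["tasks"] = [dataclasses.asdict(t) for t in self.tasks]
        for key in ("gamma", "Sigma", "omega_loadings", "omega_unique"):
            if raw[key] is not None:
                raw[key] = np.asarray(raw[key]).tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _check_psd(Sigma: np.ndarray, dim: int) -> None:
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape != (dim, dim):
        raise ValueError(f"covariance must be {dim}x{dim}, got {Sigma.shape}")
    if not np.allclose(Sigma, Sigma.T, atol=1e-10):
        raise ValueError("covariance matrix is not symmetric")
    eigvals = np.linalg.eigvalsh(Sigma)
    tol = -1e-10 * max(1.0, eigvals.max(initial=0.0))
    if eigvals.min() < tol:
        raise ValueError(
            f"covariance matrix is not positive semidefinite: "
            f"smallest eigenvalue {eigvals.min():.6g} < 0"
        )


def _mvn_factor(Sigma: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD matrix (eigen-based, rank-deficient safe)."""
    vals, vecs = np.linalg.eigh(Sigma)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def draw_person_effects(
    n: int,
    gamma: np.ndarray,
    Sigma: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw n person-effect vectors (mu, beta, phi, omega) ~ N(gamma, Sigma).

    Rows whose implied inertia phi falls outside (-1, 1) are redrawn (not
    clipped), preserving the distributional shape near the boundary.
    Deterministic given the seed.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (4,):
        raise ValueError("gamma must be a length-4 vector")
    _check_psd(Sigma, 4)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    A = _mvn_factor(np.asarray(Sigma, dtype=float))
    out = np.empty((n, 4))
    todo = np.arange(n)
    for _ in range(1000):
        z = rng.standard_normal((todo.size, 4))
        out[todo] = gamma + z @ A.T
        bad = np.abs(out[todo, 2]) >= 1.0
        todo = todo[bad]
        if todo.size == 0:
            break
    else:  # pragma: no cover - only reachable with pathological configs
        raise RuntimeError("could not draw |phi| < 1 after 1000 rounds")
    df = pd.DataFrame(out, columns=list(EFFECT_NAMES))
    df.insert(0, "subject", np.arange(n))
    return df


def _staircase_series(
    rng: np.random.Generator,
    effects,
    task: TaskConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (log_rt, correct, level, n_items) for one person."""
    n = task.n_trials
    mu, beta, phi, omega = (
        float(effects["mu"]),
        float(effects["beta"]),
        float(effects["phi"]),
        float(effects["omega"]),
    )
    if not abs(phi) < 1:
        raise ValueError(f"|phi| must be < 1, got {phi}")
    sigma = np.sqrt(np.exp(omega))
    # stationary AR(1) deviations
    w = np.empty(n)
    eps = rng.standard_normal(n)
    w[0] = eps[0] * sigma / np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        w[t] = phi * w[t - 1] + sigma * eps[t]
    t_idx = np.arange(1, n + 1)
    x = (t_idx - (n + 1) / 2.0) / 100.0
    log_rt = mu + beta * x + w

    ability = task.ability_coef * (task.ability_offset - mu)
    level = np.empty(n, dtype=int)
    correct = np.empty(n, dtype=bool)
    u = rng.random(n)
    lev = 1
    for t in range(n):
        level[t] = lev
        p = 1.0 / (1.0 + np.exp(-(task.accuracy_intercept
                                  + task.accuracy_slope * (ability - lev))))
        correct[t] = u[t] < p
        lev = min(lev + 1, task.max_level) if correct[t] else max(lev - 1, 1)
    n_items = level if task.is_span_task else np.ones(n, dtype=int)
    return log_rt, correct, level, n_items


def simulate_task_series(
    effects,
    task: TaskConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one subject's trial records for one task.

    ``effects`` is a mapping (or DataFrame row) with keys mu, beta, phi,
    omega.  Returns a TrialRecord frame: subject, task, trial_index, rt_ms,
    correct, level, n_items, guided.  For span tasks the recorded rt_ms is
    the modelled per-item RT times the current item count.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log_rt, correct, level, n_items = _staircase_series(rng, effects, task)
    rt_ms = np.exp(log_rt) * n_items
    n = task.n_trials
    return pd.DataFrame(
        {
            "subject": np.full(n, effects.get("subject", 0) if hasattr(effects, "get") else 0),
            "task": task.task_id,
            "trial_index": np.arange(1, n + 1),
            "rt_ms": rt_ms,
            "correct": correct,
            "level": level,
            "n_items": n_items,
            "guided": np.arange(n) < task.guided_trials,
        }
    )


def _draw_omega_matrix(
    rng: np.random.Generator,
    n_subjects: int,
    gamma_omega: float,
    tau2_omega: float,
    loadings: np.ndarray,
    unique: np.ndarray,
) -> np.ndarray:
    """Draw the subjects x tasks matrix of omega from the factor model.

    Rows of (loadings | sqrt(unique)) are standardized to unit length, so the
    implied cross-task correlation matrix is the standardized
    loadings @ loadings.T + diag(unique); each column is marginally
    N(gamma_omega, tau2_omega).
    """
    comm = np.sum(loadings**2, axis=1) + unique
    scale = np.sqrt(np.where(comm > 0, comm, 1.0))
    lam = loadings / scale[:, None]
    psi = unique / np.where(comm > 0, comm, 1.0)
    n_factors = loadings.shape[1]
    f = rng.standard_normal((n_subjects, n_factors))
    u = rng.standard_normal((n_subjects, loadings.shape[0]))
    z = f @ lam.T + u * np.sqrt(psi)
    return gamma_omega + np.sqrt(tau2_omega) * z


def generate_population(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate trial records for a full battery plus the ground truth.

    Returns ``(trials, truth)``: ``trials`` is a long TrialRecord frame over
    all subjects and tasks; ``truth`` holds the generating person effects
    (subject, task, mu, beta, phi, omega).

    When ``omega_loadings`` is set, omega is drawn across tasks from the
    factor model and (mu, beta, phi) per task from their conditional
    distribution given omega under N(gamma, Sigma) — so each task marginally
    obeys the stated between-person model while the cross-task correlation
    of omega follows the standardized loading structure.
    """
    rng = np.random.default_rng(config.seed)
    n, tasks = config.n_subjects, config.tasks
    gamma, Sigma = config.gamma, config.Sigma

    if config.omega_loadings is None:
        effects_by_task = {
            t.task_id: draw_person_effects(n, gamma, Sigma, rng) for t in tasks
        }
    else:
        tau2 = Sigma[3, 3]
        omega_mat = _draw_omega_matrix(
            rng, n, gamma[3], tau2, config.omega_loadings, config.omega_unique
        )
        # conditional N(gamma_abc + S_ao/tau2*(omega-gamma_o), Schur complement)
        S_ao = Sigma[:3, 3]
        if tau2 > 0:
            cond_cov = Sigma[:3, :3] - np.outer(S_ao, S_ao) / tau2
            slope = S_ao / tau2
        else:
            cond_cov = Sigma[:3, :3]
            slope = np.zeros(3)
        A = _mvn_factor(cond_cov)
        effects_by_task = {}
        for k, t in enumerate(tasks):
            om = omega_mat[:, k]
            cond_mean = gamma[:3] + np.outer(om - gamma[3], slope)
            cand = np.empty((n, 3))
            todo = np.arange(n)
            for _ in range(1000):
                z = rng.standard_normal((todo.size, 3))
                cand[todo] = cond_mean[todo] + z @ A.T
                todo = todo[np.abs(cand[todo, 2]) >= 1.0]
                if todo.size == 0:
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not draw |phi| < 1 after 1000 rounds")
            df = pd.DataFrame(
                np.column_stack([cand, om]), columns=list(EFFECT_NAMES)
            )
            df.insert(0, "subject", np.arange(n))
            effects_by_task[t.task_id] = df

    trial_frames, truth_frames = [], []
    for t in tasks:
        eff = effects_by_task[t.task_id]
        truth = eff.copy()
        truth.insert(1, "task", t.task_id)
        truth_frames.append(truth)
        for i in range(n):
            rec = simulate_task_series(eff.iloc[i], t, rng)
            rec["subject"] = eff["subject"].iloc[i]
            trial_frames.append(rec)
    trials = pd.concat(trial_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return trials, truth


# Default 11-task battery mirroring the study design: six working-memory
# span tasks, two mathematics tasks, nonverbal reasoning, mental rotation
# and tangram.  Trials per subject follow the study's median trial counts;
# span treatment applies to all WM tasks and tangram.
_BATTERY = [
    # (task_id, n_trials, is_span)
    ("grid3d", 78, True),
    ("circle", 60, True),
    ("crush", 93, True),
    ("grid", 165, True),
    ("move", 33, True),
    ("num", 38, True),
    ("npals", 920, False),
    ("nline", 703, False),
    ("nvr", 210, False),
    ("rot", 396, False),
    ("tan", 66, True),
]

WM_TASKS = ("grid3d", "circle", "crush", "grid", "move", "num")
SPAN_TASKS = WM_TASKS + ("tan",)

# Cross-task factor structure of omega emulating the study's qualitative
# pattern: a WM variability factor, a mathematical-reasoning factor, and a
# tangram factor, with rotation loading modestly on all three.
_DEFAULT_OMEGA_LOADINGS = {
    "grid3d": (0.70, 0.00, 0.00),
    "circle": (0.70, 0.00, 0.00),
    "crush": (0.70, 0.00, 0.00),
    "grid": (0.70, 0.00, 0.00),
    "move": (0.65, 0.00, 0.00),
    "num": (0.55, 0.20, 0.00),
    "npals": (0.00, 0.55, 0.00),
    "nline": (0.00, 0.55, 0.00),
    "nvr": (0.00, 0.50, 0.00),
    "rot": (0.25, 0.35, 0.30),
    "tan": (0.00, 0.00, 0.63),
}


def default_battery(
    n_subjects: int = 2608,
    seed: int = 0,
    trial_scale: float = 1.0,
    guided_trials: int = 2,
) -> GeneratorConfig:
    """Study-scale generator configuration for the 11-task battery.

    ``trial_scale`` multiplies every task's trial count (floor 10), for
    reduced-scale runs; all other settings are the study conditions.
    """
    tasks = [
        TaskConfig(
            task_id=tid,
            n_trials=max(10, int(round(nt * trial_scale))),
            is_span_task=span,
            guided_trials=guided_trials,
        )
        for tid, nt, span in _BATTERY
    ]
    loadings = np.array([_DEFAULT_OMEGA_LOADINGS[t.task_id] for t in tasks])
    return GeneratorConfig(
        n_subjects=n_subjects,
        tasks=tasks,
        omega_loadings=loadings,
        seed=seed,
    )
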