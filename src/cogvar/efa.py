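"""Exploratory factor analysis: minres extraction, oblimin rotation,
Horn's parallel analysis and regression factor scores.

Extraction is minimum-residual (minres): uniquenesses are chosen so that
the rank-k eigen-approximation of the reduced correlation matrix minimizes
the sum of squared off-diagonal residuals.  Rotation is oblimin with
gamma = 0 (direct quartimin), the common default for oblique solutions;
factors are re-ordered by explained variance with signs chosen so each
column's loading sum is positive.  Factor counts come from parallel
analysis — empirical eigenvalues compared with the mean eigenvalues of
size-matched random normal data — optionally looped over many seeds to
expose boundary instability.  Factor scores are Thurstone regression
scores through the inverse correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "EfaResult",
    "ParallelResult",
    "extract_factors",
    "oblimin_rotate",
    "parallel_analysis",
    "loop_parallel",
    "factor_scores",
    "ExploratoryFactorAnalysis",
    "tucker_congruence",
]


@dataclass
class EfaResult:
    """Rotated factor solution on a correlation matrix."""

    loadings: np.ndarray          # pattern matrix, tasks x k
    Phi: np.ndarray               # factor correlations, k x k
    uniquenesses: np.ndarray
    variance_shares: np.ndarray
    criterion: float
    converged: bool
    variables: list = field(default_factory=list)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"F{j + 1}" for j in range(self.loadings.shape[1])]
        idx = self.variables or list(range(self.loadings.shape[0]))
        return pd.DataFrame(self.loadings, index=idx, columns=cols)


@dataclass
class ParallelResult:
    """Parallel-analysis eigenvalues and the suggested factor count."""

    empirical: np.ndarray
    reference: np.ndarray         # mean eigenvalues of the random replicates
    suggested: int
    n_replicates: int
    seed: int


def _prepare_R(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be a symmetric correlation matrix")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("R must have a unit diagonal")
    vals = np.linalg.eigvalsh(R)
    if vals.min() < -1e-8:
        warnings.warn(
            f"correlation matrix not PSD (min eigenvalue {vals.min():.3g}); "
            "repairing by eigenvalue clipping",
            stacklevel=3,
        )
        w, V = np.linalg.eigh(R)
        R = V @ np.diag(np.clip(w, 1e-6, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return 0.5 * (R + R.T)


def _loadings_from_psi(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    w, V = np.linalg.eigh(R - np.diag(psi))
    order = np.argsort(w)[::-1][:k]
    return V[:, order] * np.sqrt(np.clip(w[order], 0.0, None))


def extract_factors(R, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-residual extraction of k unrotated factors.

    Returns (loadings, uniquenesses).  The uniqueness vector is optimized
    (L-BFGS-B from squared-multiple-correlation starts) to minimize the sum
    of squared off-diagonal residuals of R - Lambda Lambda'.  Deterministic
    given R and k.
    """
    R = _prepare_R(R)
    p = R.shape[0]
    if not 1 <= k < p:
        raise ValueError(f"k must be in [1, {p - 1}], got {k}")
    offdiag = ~np.eye(p, dtype=bool)

    def objective(psi):
        lam = _loadings_from_psi(R, psi, k)
        resid = R - lam @ lam.T
        # the 1e-6 term breaks the tie on exactly diagonal R (where the
        # off-diagonal residual is flat in psi) toward null loadings
        return float(np.sum(resid[offdiag] ** 2) + 1e-6 * np.sum(1.0 - psi))

    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:  # singular R
        smc = np.full(p, 0.5)
    x0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        bounds=[(1e-3, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
    )
    lam = _loadings_from_psi(R, res.x, k)
    # column sign convention: positive loading sums
    sign = np.where(lam.sum(axis=0) < 0, -1.0, 1.0)
    lam = lam * sign
    uniq = np.clip(1.0 - np.sum(lam**2, axis=1), 0.0, 1.0)
    return lam, uniq


def _order_factors(L: np.ndarray, Phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ss = np.diag(L.T @ L @ Phi).copy()
    order = np.argsort(ss)[::-1]
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    sign = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * sign
    Phi = Phi * np.outer(sign, sign)
    return L, Phi


def _quartimin_value(L: np.ndarray) -> float:
    L2 = L**2
    G = L2 @ (np.ones((L.shape[1], L.shape[1])) - np.eye(L.shape[1]))
    return float(np.sum(L2 * G) / 4.0)


def oblimin_rotate(loadings: np.ndarray, variables=None) -> EfaResult:
    """Oblique oblimin (gamma = 0, direct quartimin) rotation.

    With a single factor the rotation is the identity.  The model-implied
    matrix Lambda Phi Lambda' is exactly preserved by rotation.
    """
    A = np.asarray(loadings, dtype=float)
    if A.ndim != 2:
        raise ValueError("loadings must be 2-D")
    comm = np.sum(A**2, axis=1)
    if A.shape[1] == 1:
        L, Phi, crit, conv = A.copy(), np.eye(1), _quartimin_value(A), True
    else:
        try:
            L, T = rotate_factors(A, "quartimin")
            Phi = T.T @ T
            crit = _quartimin_value(L)
            conv = True
        except Exception as exc:  # pragma: no cover - GPA non-convergence
            warnings.warn(f"rotation did not converge: {exc}", stacklevel=2)
            L, Phi, crit, conv = A.copy(), np.eye(A.shape[1]), np.inf, False
        L, Phi = _order_factors(L, Phi)
    p = A.shape[0]
    shares = np.diag(L.T @ L @ Phi) / p
    return EfaResult(
        loadings=L,
        Phi=Phi,
        uniquenesses=np.clip(1.0 - comm, 0.0, 1.0),
        variance_shares=np.asarray(shares),
        criterion=crit,
        converged=conv,
        variables=list(variables) if variables is not None else [],
    )


def parallel_analysis(
    scores, n_replicates: int = 50, seed: int = 0,
    quantile: float | None = None,
) -> ParallelResult:
    """Horn's parallel analysis on a subjects x tasks score matrix.

    The suggested factor count is the number of leading empirical
    eigenvalues of the task correlation matrix that exceed the reference
    eigenvalues of ``n_replicates`` random standard-normal datasets of the
    same shape.  The reference is the replicate mean by default; passing
    ``quantile`` (e.g. 0.95) compares against that replicate quantile
    instead, a stricter rule whose false-positive rate on pure-noise data
    is about ``1 - quantile``.
    """
    X = pd.DataFrame(scores)
    n, p = X.shape
    if p < 2 or n < 10:
        raise ValueError("need at least 2 tasks and 10 subjects")
    R = X.corr(min_periods=3).to_numpy()
    emp = np.sort(np.linalg.eigvalsh(R))[::-1]
    rng = np.random.default_rng(seed)
    ref = np.empty((n_replicates, p))
    for b in range(n_replicates):
        Z = rng.standard_normal((n, p))
        ref[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    if quantile is None:
        ref_mean = ref.mean(axis=0)
    else:
        ref_mean = np.quantile(ref, quantile, axis=0)
    exceeds = emp > ref_mean
    suggested = 0
    for flag in exceeds:
        if flag:
            suggested += 1
        else:
            break
    return ParallelResult(
        empirical=emp,
        reference=ref_mean,
        suggested=suggested,
        n_replicates=n_replicates,
        seed=seed,
    )


def loop_parallel(
    scores, seeds, n_replicates: int = 50, quantile: float | None = None
) -> dict:
    """Run parallel analysis once per seed; tally the suggested counts.

    Returns {"tally": {k: count}, "proportions": {k: share}, "runs": [...]}.
    """
    seeds = list(seeds)
    runs = [
        parallel_analysis(
            scores, n_replicates=n_replicates, seed=s, quantile=quantile
        )
        for s in seeds
    ]
    tally: dict[int, int] = {}
    for r in runs:
        tally[r.suggested] = tally.get(r.suggested, 0) + 1
    props = {k: v / len(seeds) for k, v in sorted(tally.items())}
    return {"tally": dict(sorted(tally.items())), "proportions": props,
            "n_seeds": len(seeds), "runs": runs}


def factor_scores(scores, result: EfaResult) -> pd.DataFrame:
    """Thurstone regression factor scores, standardized per factor.

    W = R^-1 (Lambda Phi); scores are standardized observed variables times
    W.  Missing entries are mean-imputed (at 0 after standardization) for
    the weighting step.  A near-singular correlation matrix is ridge-
    regularized with a warning.
    """
    X = pd.DataFrame(scores)
    if result.variables:
        X = X[list(result.variables)]
    Z = (X - X.mean()) / X.std(ddof=1)
    R = X.corr(min_periods=3).to_numpy()
    if np.linalg.cond(R) > 1e10:
        warnings.warn(
            "correlation matrix is near-singular; ridge-regularizing",
            stacklevel=2,
        )
        R = R + 1e-6 * np.eye(R.shape[0])
    structure = result.loadings @ result.Phi
    W = np.linalg.solve(R, structure)
    S = Z.fillna(0.0).to_numpy() @ W
    S = (S - S.mean(axis=0)) / S.std(axis=0, ddof=1)
    out = pd.DataFrame(
        S, index=X.index, columns=[f"F{j + 1}" for j in range(S.shape[1])]
    )
    return out


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Tucker congruence coefficients between columns of A and B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    num = A.T @ B
    den = np.sqrt(np.outer(np.sum(A**2, axis=0), np.sum(B**2, axis=0)))
    return num / den


class ExploratoryFactorAnalysis:
    """Estimator: minres extraction + oblimin rotation on a score matrix.

    Parameters
    ----------
    n_factors : int, default 3
    rotation : 'oblimin' or None
    Attributes: ``loadings_`` (pattern), ``Phi_``, ``uniquenesses_``,
    ``variance_shares_``, ``result_``.  ``transform`` returns regression
    factor scores.
    """

    def __init__(self, n_factors: int = 3, rotation: str | None = "oblimin"):
        self.n_factors = n_factors
        self.rotation = rotation

    def get_params(self, deep: bool = True) -> dict:
        return {"n_factors": self.n_factors, "rotation": self.rotation}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("n_factors", "rotation"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        R = X.corr(min_periods=3).to_numpy()
        lam, uniq = extract_factors(R, self.n_factors)
        if self.rotation == "oblimin":
            res = oblimin_rotate(lam, variables=list(X.columns))
        elif self.rotation is None:
            p = R.shape[0]
            res = EfaResult(
                loadings=lam, Phi=np.eye(self.n_factors), uniquenesses=uniq,
                variance_shares=np.sum(lam**2, axis=0) / p,
                criterion=_quartimin_value(lam), converged=True,
                variables=list(X.columns),
            )
        else:
            raise ValueError(f"unknown rotation {self.rotation!r}")
        res.uniquenesses = uniq
        self.result_ = res
        self.loadings_ = res.loadings
        self.Phi_ = res.Phi
        self.uniquenesses_ = res.uniquenesses
        self.variance_shares_ = res.variance_shares
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise RuntimeError("fit must be called before transform")
        return factor_scores(X, self.result_)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
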