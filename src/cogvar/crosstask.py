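"""Cross-task structure of variability and mean-performance scores.

Operates on subjects x tasks score matrices (person-level variability
scores omega from the DSEM fits, or mean-performance scores).  Provides
pairwise-complete Pearson correlation matrices with Holm-adjusted p values,
Williams's test for two dependent correlations sharing one variable, the
median-RT dissimilarity control analysis, and the first-factor variance
share used to contrast the strength of the positive manifold between mean
performance and variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrResult",
    "mean_performance",
    "correlation_matrix",
    "williams_test",
    "rt_dissimilarity_test",
    "first_factor_share",
]


@dataclass
class CorrResult:
    """Pairwise correlation structure with multiplicity control."""

    r: pd.DataFrame
    p: pd.DataFrame
    p_holm: pd.DataFrame
    significant: pd.DataFrame
    n: pd.DataFrame
    mean_offdiag_r: float
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)

    @property
    def tasks(self) -> list:
        return list(self.r.columns)


def mean_performance(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean correct difficulty level per subject x task.

    The mean-performance score is the mean of the difficulty level over a
    subject's correct trials in a task; subjects without any correct trial
    in a task get a missing score.
    """
    if "level" not in trials.columns:
        raise KeyError("trials must have a 'level' column")
    correct = trials.loc[trials["correct"].astype(bool)]
    scores = (
        correct.groupby(["subject", "task"], sort=False)["level"]
        .mean()
        .unstack("task")
    )
    all_subjects = pd.unique(trials["subject"])
    all_tasks = pd.unique(trials["task"])
    scores = scores.reindex(index=all_subjects, columns=all_tasks)
    if scores.isna().any().any():
        n_missing = int(scores.isna().sum().sum())
        warnings.warn(
            f"{n_missing} subject-task cell(s) have no correct trials; "
            "scores set to missing",
            stacklevel=2,
        )
    return scores


def correlation_matrix(scores: pd.DataFrame, alpha: float = 0.05) -> CorrResult:
    """Pearson correlations between task scores, Holm-adjusted.

    Pairwise-complete observations are used per task pair (at least 3
    required).  The Holm step-down adjustment runs over the unique
    off-diagonal pairs.  Zero-variance columns are dropped with a warning.
    """
    scores = pd.DataFrame(scores)
    keep = []
    for c in scores.columns:
        v = scores[c].dropna()
        if len(v) >= 2 and np.nanstd(v.to_numpy(dtype=float)) > 0:
            keep.append(c)
        else:
            warnings.warn(
                f"column {c!r} has zero variance or too few values; dropped",
                stacklevel=2,
            )
    scores = scores[keep]
    tasks = list(scores.columns)
    p_ = len(tasks)
    r = np.eye(p_)
    pval = np.zeros((p_, p_))
    nmat = np.zeros((p_, p_), dtype=int)
    np.fill_diagonal(nmat, scores.notna().sum().to_numpy())
    pairs = [(i, j) for i in range(p_) for j in range(i + 1, p_)]
    raw_p = []
    for i, j in pairs:
        xy = scores[[tasks[i], tasks[j]]].dropna().to_numpy(dtype=float)
        if xy.shape[0] < 3:
            raise ValueError(
                f"fewer than 3 complete pairs for tasks "
                f"{tasks[i]!r} and {tasks[j]!r}"
            )
        rr, pp = stats.pearsonr(xy[:, 0], xy[:, 1])
        r[i, j] = r[j, i] = rr
        pval[i, j] = pval[j, i] = pp
        nmat[i, j] = nmat[j, i] = xy.shape[0]
        raw_p.append(pp)
    if pairs:
        _, p_adj, _, _ = multipletests(raw_p, alpha=alpha, method="holm")
    else:
        p_adj = []
    ph = np.zeros((p_, p_))
    for (i, j), a in zip(pairs, p_adj):
        ph[i, j] = ph[j, i] = a
    sig = (ph < alpha) & ~np.eye(p_, dtype=bool)
    offdiag = np.array([r[i, j] for i, j in pairs]) if pairs else np.array([])
    mk = lambda m: pd.DataFrame(m, index=tasks, columns=tasks)  # noqa: E731
    return CorrResult(
        r=mk(r),
        p=mk(pval),
        p_holm=mk(ph),
        significant=mk(sig),
        n=mk(nmat),
        mean_offdiag_r=float(offdiag.mean()) if offdiag.size else np.nan,
        alpha=alpha,
        meta={"n_pairs": len(pairs), "adjustment": "holm"},
    )


def williams_test(r12, r13, r23, n: int):
    """Williams's t for two dependent correlations sharing one variable.

    Tests r12 = r13 where variable 1 is shared, using the pooled-correlation
    variant with rbar = (r12 + r13) / 2 and the determinant
    |R| = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23, on n - 3 degrees of
    freedom.  Accepts scalars or equally shaped arrays of correlation
    triples; returns (t, two-sided p) with the input shape.
    """
    scalar = np.isscalar(r12) and np.isscalar(r13) and np.isscalar(r23)
    r12 = np.asarray(r12, dtype=float)
    r13 = np.asarray(r13, dtype=float)
    r23 = np.asarray(r23, dtype=float)
    for name, v in (("r12", r12), ("r13", r13), ("r23", r23)):
        if np.any(np.abs(v) > 1.0):
            raise ValueError(f"{name} must be in [-1, 1]")
    if n <= 3:
        raise ValueError("n must exceed 3")
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if np.any(detR < -1e-12):
        bad = float(np.min(detR))
        raise ValueError(
            "the correlation triple does not form a positive semidefinite "
            f"matrix (|R| = {bad:.6g} < 0)"
        )
    detR = np.maximum(detR, 0.0)
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * detR * (n - 1) / (n - 3) + rbar**2 * (1.0 - r23) ** 3
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            denom > 0,
            (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / np.maximum(denom, 1e-300)),
            0.0,
        )
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 3)
    if scalar:
        return float(t), float(p)
    return t, p


def rt_dissimilarity_test(
    median_rts: pd.Series, var_corr: CorrResult
) -> tuple[float, float]:
    """Correlate median-RT dissimilarity with variability correlations.

    Pairwise dissimilarity is the absolute difference between task median
    RTs; the vectorized lower triangle of the dissimilarity matrix is
    Pearson-correlated with the matching variability correlations.  A value
    near zero says that differences in response-time scale between tasks do
    not drive the between-task variability correlations.
    """
    median_rts = pd.Series(median_rts)
    tasks = var_corr.tasks
    missing = [t for t in tasks if t not in median_rts.index]
    if missing:
        raise ValueError(f"median RTs missing for tasks {missing}")
    m = median_rts.loc[tasks].to_numpy(dtype=float)
    il, jl = np.tril_indices(len(tasks), k=-1)
    d = np.abs(m[il] - m[jl])
    rv = var_corr.r.to_numpy()[il, jl]
    if np.allclose(d, d[0]):
        raise ValueError(
            "all pairwise dissimilarities are equal; the correlation with "
            "variability correlations is undefined"
        )
    r, p = stats.pearsonr(d, rv)
    return float(r), float(p)


def first_factor_share(scores, from_corr: bool = False) -> float:
    """Proportion of variance explained by a single common factor.

    A one-factor minimum-residual extraction is run on the task correlation
    matrix; the share is the sum of squared loadings divided by the number
    of tasks.
    """
    from .efa import extract_factors

    if from_corr:
        R = np.asarray(scores, dtype=float)
    else:
        scores = pd.DataFrame(scores)
        if scores.shape[1] < 2:
            raise ValueError("at least 2 tasks are required")
        R = scores.corr(min_periods=3).to_numpy()
    loadings, _ = extract_factors(R, 1)
    return float(np.sum(loadings**2) / R.shape[0])
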