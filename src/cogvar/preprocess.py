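"""Raw trial records -> per-person log-RT series ready for modelling.

The pipeline order is fixed: guided-trial removal, correct-trial filtering,
per-item RT division (span tasks only), log transform, Tukey outlier
masking.  The per-item division precedes the log transform and the outlier
treatment.  Outlier fences are computed per task on the pooled distribution
across all subjects (not per subject); flagged values are recoded as
missing, never deleted, so series length is unchanged by masking.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "remove_guided",
    "filter_correct",
    "per_item_adjust",
    "tukey_mask",
    "preprocess_trials",
    "TrialPreprocessor",
]


def remove_guided(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop rows flagged as guided (instruction) trials."""
    if "guided" not in trials.columns:
        raise KeyError("trials must have a 'guided' column")
    out = trials.loc[~trials["guided"].astype(bool)].reset_index(drop=True)
    if len(out) == 0 and len(trials) > 0:
        warnings.warn("all trials were guided; nothing remains", stacklevel=2)
    return out


def filter_correct(trials: pd.DataFrame) -> pd.DataFrame:
    """Retain only correct trials, preserving chronological order."""
    if "correct" not in trials.columns:
        raise KeyError("trials must have a 'correct' column")
    out = trials.loc[trials["correct"].astype(bool)].reset_index(drop=True)
    if len(out) == 0 and len(trials) > 0:
        warnings.warn("no correct trials remain", stacklevel=2)
    return out


def per_item_adjust(trials: pd.DataFrame, span_task_ids) -> pd.DataFrame:
    """Divide rt_ms by the presented item count, on span-task rows only."""
    span_task_ids = set(span_task_ids)
    out = trials.copy()
    is_span = out["task"].isin(span_task_ids)
    if is_span.any():
        items = out.loc[is_span, "n_items"]
        bad = items.isna() | (items < 1)
        if bad.any():
            rows = out.index[is_span][np.asarray(bad)].tolist()
            raise ValueError(
                f"span-task rows with missing/invalid n_items at index {rows[:10]}"
            )
        out.loc[is_span, "rt_ms"] = out.loc[is_span, "rt_ms"] / items
    return out


def tukey_mask(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics on the
    pooled finite values.  With fewer than 4 finite values no masking is
    done (a warning is issued).
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        warnings.warn("fewer than 4 finite values; no outlier masking", stacklevel=2)
        return np.zeros(values.shape, dtype=bool)
    q1, q3 = np.percentile(values[finite], [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    mask = np.zeros(values.shape, dtype=bool)
    mask[finite] = (values[finite] < lo) | (values[finite] > hi)
    return mask


def preprocess_trials(
    trials: pd.DataFrame,
    span_task_ids=(),
    fences_on: str = "log",
    fence_k: float = 1.5,
) -> tuple[pd.DataFrame, dict]:
    """Run the full preprocessing pipeline on a long TrialRecord frame.

    Returns ``(series, report)``.  ``series`` is long format with columns
    subject, task, position (1-based within subject x task after filtering),
    log_rt (NaN where Tukey-masked).  ``report`` counts removals per task at
    each stage.

    ``fences_on`` selects whether Tukey fences are computed on logged
    (default) or raw per-item-adjusted RTs; the flagged set feeds the same
    masking either way.
    """
    if fences_on not in ("log", "raw"):
        raise ValueError("fences_on must be 'log' or 'raw'")
    report: dict = {"tasks": {}, "fences_on": fences_on}
    n0 = len(trials)
    kept = remove_guided(trials)
    n_guided = n0 - len(kept)
    kept = filter_correct(kept)
    kept = per_item_adjust(kept, span_task_ids)
    if (kept["rt_ms"] <= 0).any():
        raise ValueError("nonpositive rt_ms after per-item adjustment")
    kept = kept.copy()
    kept["log_rt"] = np.log(kept["rt_ms"].to_numpy(dtype=float))

    frames = []
    for task, grp in kept.groupby("task", sort=True):
        basis = grp["log_rt"] if fences_on == "log" else grp["rt_ms"]
        mask = tukey_mask(basis.to_numpy(dtype=float), k=fence_k)
        vals = grp["log_rt"].to_numpy(dtype=float).copy()
        vals[mask] = np.nan
        sub = pd.DataFrame(
            {
                "subject": grp["subject"].to_numpy(),
                "task": task,
                "trial_index": grp["trial_index"].to_numpy(),
                "log_rt": vals,
            }
        )
        sub = sub.sort_values(["subject", "trial_index"], kind="stable")
        sub["position"] = sub.groupby("subject").cumcount() + 1
        frames.append(sub)
        report["tasks"][str(task)] = {
            "n_input": int((trials["task"] == task).sum()),
            "n_after_filters": int(len(grp)),
            "n_masked": int(mask.sum()),
            "n_observed": int(np.isfinite(vals).sum()),
            "masked_fraction": float(mask.mean()) if len(grp) else 0.0,
        }
    report["n_guided_removed"] = int(n_guided)
    series = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["subject", "task", "trial_index", "log_rt", "position"])
    )
    return series[["subject", "task", "position", "trial_index", "log_rt"]], report


class TrialPreprocessor:
    """Transformer wrapping :func:`preprocess_trials`.

    Parameters
    ----------
    span_task_ids : sequence of task labels whose RTs are divided by item
        count before the log transform.
    fences_on : 'log' (default) or 'raw' — scale on which Tukey fences are
        computed.
    fence_k : fence multiplier (1.5 = standard boxplot whiskers).
    """

    def __init__(self, span_task_ids=(), fences_on: str = "log", fence_k: float = 1.5):
        self.span_task_ids = span_task_ids
        self.fences_on = fences_on
        self.fence_k = fence_k

    def get_params(self, deep: bool = True) -> dict:
        return {
            "span_task_ids": self.span_task_ids,
            "fences_on": self.fences_on,
            "fence_k": self.fence_k,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        series, report = preprocess_trials(
            X, self.span_task_ids, self.fences_on, self.fence_k
        )
        self.report_ = report
        return series

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
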