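"""End-to-end orchestration: generate/ingest -> preprocess -> per-task DSEM
-> score matrices -> cross-task statistics -> CFA -> EFA -> report.

Intermediates are plain CSV/JSON files in the output directory, keyed by a
hash of the configuration and seed so reruns with the same settings resume
from stored stage outputs instead of recomputing them.  No stage mutates
its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cfa as cfa_mod
from . import crosstask, efa
from .dsem import extract_factor_scores, fit_dsem, test_random_variability
from .preprocess import preprocess_trials
from .synthetic import SPAN_TASKS, GeneratorConfig, default_battery, generate_population

log = logging.getLogger("cogvar")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "read_trials",
    "write_trials",
    "write_scores",
    "read_scores",
]

TRIAL_COLUMNS = [
    "subject", "task", "trial_index", "rt_ms", "correct", "level",
    "n_items", "guided",
]


@dataclass
class PipelineConfig:
    """Settings for one full analysis run."""

    output_dir: str
    trials_csv: str | None = None          # ingest path; None -> synthetic
    generator: GeneratorConfig | None = None
    span_tasks: tuple = SPAN_TASKS
    seed: int = 0
    n_iterations: int = 2000
    burn_in: int | None = None
    n_chains: int = 2
    min_trials: int = 10
    run_dic_test: bool = False
    n_efa_factors: int = 3
    parallel_seeds: int = 20
    fences_on: str = "log"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        gen = raw.pop("generator", None)
        if gen is not None:
            from .synthetic import TaskConfig

            tasks = [TaskConfig(**t) for t in gen.pop("tasks")]
            for key in ("gamma", "Sigma", "omega_loadings", "omega_unique"):
                if key in gen and gen[key] is not None:
                    gen[key] = np.asarray(gen[key], dtype=float)
            gen = GeneratorConfig(tasks=tasks, **gen)
        if "span_tasks" in raw and raw["span_tasks"] is not None:
            raw["span_tasks"] = tuple(raw["span_tasks"])
        return cls(generator=gen, **raw)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_trials(path) -> pd.DataFrame:
    """Read a TrialRecord CSV, rejecting malformed rows with line numbers."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path} contains no trial rows", stacklevel=2)
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required column(s) {missing}")
    bad = ~(pd.to_numeric(df["rt_ms"], errors="coerce") > 0)
    if bad.any():
        # +2: one for the header line, one for 0- vs 1-based indexing
        lines = (df.index[bad] + 2).tolist()
        warnings.warn(
            f"rejected {int(bad.sum())} row(s) with nonpositive or "
            f"non-numeric rt_ms at line(s) {lines[:10]}",
            stacklevel=2,
        )
        df = df[~bad]
    df = df.copy()
    for col, typ in (("trial_index", int), ("level", int), ("n_items", int)):
        df[col] = df[col].astype(typ)
    for col in ("correct", "guided"):
        df[col] = df[col].astype(bool)
    df["rt_ms"] = df["rt_ms"].astype(float)
    return df.reset_index(drop=True)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a subjects x tasks score matrix (empty field = missing)."""
    scores.to_csv(path, index=True, index_label="subject", na_rep="")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject")


def _stage_path(outdir: Path, name: str, tag: str) -> Path:
    return outdir / f"{name}.{tag}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report: dict = {"seed": config.seed, "config_hash": chash, "stages": {}}

    manifest_path = outdir / "manifest.json"
    prior = {}
    if manifest_path.exists():
        try:
            prior = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            prior = {}
    resume = prior.get("config_hash") == chash

    def fresh(path: Path) -> bool:
        return not (resume and path.exists())

    # --- stage 1: data
    trials_path = outdir / "trials.csv"
    truth_path = outdir / "truth.csv"
    if config.trials_csv is not None:
        trials = read_trials(config.trials_csv)
        truth = None
    else:
        gen = config.generator or default_battery(
            n_subjects=100, seed=config.seed, trial_scale=0.3
        )
        if fresh(trials_path):
            log.info("generating synthetic battery (%d subjects)", gen.n_subjects)
            trials, truth = generate_population(gen)
            write_trials(trials, trials_path)
            truth.to_csv(truth_path, index=False)
        else:
            trials = read_trials(trials_path)
            truth = pd.read_csv(truth_path) if truth_path.exists() else None
    if trials.empty:
        raise ValueError("no trial data to analyse")
    data_tasks = set(trials["task"].unique())
    wanted = set(config.span_tasks) & data_tasks
    absent = [t for t in config.span_tasks if t not in data_tasks]
    report["stages"]["data"] = {
        "n_trials": int(len(trials)),
        "n_subjects": int(trials["subject"].nunique()),
        "tasks": sorted(map(str, data_tasks)),
    }
    if config.generator is not None:
        declared = {t.task_id for t in config.generator.tasks}
        missing_declared = declared - data_tasks
        if missing_declared:
            raise ValueError(
                f"configured task(s) {sorted(missing_declared)} absent from data"
            )
    if absent:
        log.info("span task(s) %s not present in data; ignored", absent)

    # --- stage 2: preprocessing
    series_path = outdir / "series.csv"
    if fresh(series_path):
        series, prep_report = preprocess_trials(
            trials, span_task_ids=wanted, fences_on=config.fences_on
        )
        series.to_csv(series_path, index=False)
        (outdir / "preprocess_report.json").write_text(
            json.dumps(prep_report, indent=2)
        )
    else:
        series = pd.read_csv(series_path)
        prep_report = json.loads((outdir / "preprocess_report.json").read_text())
    report["stages"]["preprocess"] = prep_report

    # --- stage 3: per-task DSEM
    scores_path = outdir / "variability_scores.csv"
    gamma_path = outdir / "dsem_summary.json"
    tasks = sorted(map(str, data_tasks))
    if fresh(scores_path):
        omega_cols = {}
        dsem_summary = {}
        for task in tasks:
            sub = series[series["task"] == task]
            log.info("fitting DSEM for task %s", task)
            try:
                fit = fit_dsem(
                    sub,
                    n_iterations=config.n_iterations,
                    burn_in=config.burn_in,
                    n_chains=config.n_chains,
                    min_trials=config.min_trials,
                    random_state=config.seed,
                )
            except ValueError as exc:
                log.warning("task %s not fitted: %s", task, exc)
                dsem_summary[task] = {"error": str(exc)}
                continue
            sc = extract_factor_scores(fit).set_index("subject")
            omega_cols[task] = sc["omega"]
            sc.to_csv(outdir / f"dsem_scores_{task}.csv")
            entry = {
                "gamma": fit.gamma_.to_dict(),
                "tau2_omega": fit.tau2_omega_,
                "dic": fit.dic_,
                "pd": fit.dic_components_["pd"],
                "psrf_max": fit.psrf_.get("max"),
                "converged": fit.converged_,
            }
            if config.run_dic_test:
                comp = test_random_variability(
                    sub,
                    random_state=config.seed,
                    n_iterations=config.n_iterations,
                    burn_in=config.burn_in,
                    n_chains=config.n_chains,
                    min_trials=config.min_trials,
                )
                entry["dic_constrained"] = comp["dic_constrained"]
                entry["delta_dic"] = comp["delta_dic"]
                entry["preferred"] = comp["preferred"]
            dsem_summary[task] = entry
        variability = pd.DataFrame(omega_cols)
        write_scores(variability, scores_path)
        gamma_path.write_text(json.dumps(dsem_summary, indent=2, default=float))
    else:
        variability = read_scores(scores_path)
        dsem_summary = json.loads(gamma_path.read_text())
    report["stages"]["dsem"] = dsem_summary

    # --- stage 4: mean performance + cross-task statistics
    perf_path = outdir / "mean_performance.csv"
    if fresh(perf_path):
        post_guided = trials[~trials["guided"].astype(bool)]
        performance = crosstask.mean_performance(post_guided)
        write_scores(performance, perf_path)
    else:
        performance = read_scores(perf_path)

    var_corr = crosstask.correlation_matrix(variability)
    perf_corr = crosstask.correlation_matrix(performance)
    var_corr.r.to_csv(outdir / "variability_corr.csv")
    var_corr.p_holm.to_csv(outdir / "variability_corr_p_holm.csv")
    perf_corr.r.to_csv(outdir / "performance_corr.csv")
    post_guided = trials[~trials["guided"].astype(bool)]
    median_rts = post_guided.groupby("task")["rt_ms"].median()
    try:
        rt_dis = crosstask.rt_dissimilarity_test(median_rts, var_corr)
    except ValueError:
        rt_dis = (float("nan"), float("nan"))
    report["stages"]["crosstask"] = {
        "mean_r_variability": var_corr.mean_offdiag_r,
        "mean_r_performance": perf_corr.mean_offdiag_r,
        "n_significant_variability": int(var_corr.significant.to_numpy().sum() // 2),
        "rt_dissimilarity_r": rt_dis[0],
        "rt_dissimilarity_p": rt_dis[1],
        "first_factor_share_variability": crosstask.first_factor_share(variability),
        "first_factor_share_performance": crosstask.first_factor_share(performance),
    }

    # --- stage 5: CFA (on whichever shipped specs the task set supports)
    cfa_results = {}
    task_set = set(tasks)
    specs = {}
    specs["unidimensional"] = cfa_mod.unidimensional_spec(tuple(tasks))
    if set(cfa_mod.BATTERY_TASKS) <= task_set:
        specs["wm_hierarchical"] = cfa_mod.wm_hierarchical_spec()
        specs["three_subdomain"] = cfa_mod.three_subdomain_spec()
    for name, spec in specs.items():
        for label, scores in (("variability", variability), ("performance", performance)):
            model = cfa_mod.ConfirmatoryFactorModel(spec)
            try:
                model.fit(scores)
            except Exception as exc:
                cfa_results[f"{name}/{label}"] = {"error": str(exc)}
                continue
            cfa_results[f"{name}/{label}"] = {
                "chi2": model.chi2_,
                "df": model.df_,
                "rmsea": model.rmsea_,
                "rmsea_ci": list(model.rmsea_ci_),
                "cfi": model.cfi_,
                "heywood": model.heywood_,
                "converged": model.converged_,
            }
    report["stages"]["cfa"] = cfa_results

    # --- stage 6: EFA with looped parallel analysis
    tally = efa.loop_parallel(
        variability, seeds=range(config.seed, config.seed + config.parallel_seeds)
    )
    model = efa.ExploratoryFactorAnalysis(n_factors=config.n_efa_factors)
    model.fit(variability)
    model.result_.loadings_frame().to_csv(outdir / "efa_loadings.csv")
    var_scores = model.transform(variability)
    perf_efa = efa.ExploratoryFactorAnalysis(n_factors=1).fit(performance)
    perf_scores = perf_efa.transform(performance)
    fs = var_scores.join(perf_scores.rename(columns={"F1": "performance_g"}))
    fs.to_csv(outdir / "factor_scores.csv")
    cors = {
        col: float(fs[col].corr(fs["performance_g"]))
        for col in var_scores.columns
    }
    report["stages"]["efa"] = {
        "parallel_tally": {str(k): v for k, v in tally["tally"].items()},
        "variance_shares": model.variance_shares_.tolist(),
        "factor_correlations": model.Phi_.tolist(),
        "variability_vs_performance_r": cors,
    }

    report_path = outdir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float))
    manifest_path.write_text(json.dumps(
        {"config_hash": chash, "seed": config.seed}, indent=2
    ))
    return report
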