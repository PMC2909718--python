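"""Repetition loop, prediction error and bootstrap summaries.

One repetition realises the gene-level parameters of a scenario, draws
a training dataset, pools its biological values at pool size ``m_p``
(``m_p = 1`` is the single-sample design), trains a method on the
pooled measured matrix, and evaluates it on an independent test set of
single samples drawn under the same realised parameters.  Test samples
are classified on their biological values — technical noise enters
through the training arrays only (the ``test_noise`` config flag adds
measurement noise to the test set as well).  The prediction error is
the relative frequency of wrongly classified test samples.

The experiment grid crosses scenarios x noise levels x methods x pool
sizes.  Within a repetition all methods and pool sizes share the same
training and test data (paired comparison); pool membership is
re-randomised every repetition.  Summaries report per-cell mean errors
with percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .config import METHODS, SCENARIOS, ClassifierConfig, RunConfig, SimulationConfig
from .classifiers import TrainedModel, predict, train_classifier
from .pooling import make_pooled_training_set
from .simulate import ROLE_BACKGROUND, draw_scenario_params, sample_dataset

RECORD_COLUMNS = [
    "scenario", "noise_sd", "method", "m_p", "rep", "error", "n_test", "tuning",
]


def prediction_error(predicted, truth) -> float:
    """Fraction of wrongly classified samples."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and true labels must have equal length")
    if predicted.size == 0:
        raise ValueError("need at least one test sample")
    return float(np.mean(predicted != truth))


def bootstrap_ci(
    errors, level: float = 0.95, n_boot: int = 1000, rng=None
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``errors``."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("need at least one error value")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, errors.size, size=(n_boot, errors.size))
    means = errors[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _tuning_summary(model: TrainedModel, truth: pd.DataFrame | None) -> str:
    t = dict(model.tuning)
    t.pop("gamma_grid", None)
    t.pop("pvalues", None)
    if "powers" in t:
        t["powers"] = [round(float(p), 3) for p in t["powers"]]
    selected = t.pop("selected_features", None)
    if selected is not None and truth is not None:
        informative = set(np.flatnonzero(truth["role"].to_numpy() != ROLE_BACKGROUND))
        t["n_selected_informative"] = len(informative & set(selected))
    return json.dumps(t)


def run_single_repetition(
    cfg: SimulationConfig,
    m_p: int,
    method: str,
    rep_seed,
    clf_cfg: ClassifierConfig | None = None,
) -> dict:
    """One repetition: simulate, pool the training set, train, test.

    Fully reproducible from ``rep_seed``; the test set consists of
    single samples drawn under the same realised gene-level parameters
    as the training set.
    """
    rng = np.random.default_rng(rep_seed)
    params = draw_scenario_params(cfg, rng)
    train_ds = sample_dataset(cfg, params, rng)
    pooled_y, pool_labels, _ = make_pooled_training_set(train_ds, m_p, cfg.noise_sd, rng)
    model = train_classifier(method, pooled_y, pool_labels, clf_cfg, rng)
    test_ds = sample_dataset(cfg, params, rng)
    test_y = test_ds.Y if cfg.test_noise else test_ds.X
    err = prediction_error(predict(model, test_y), test_ds.labels)
    return {
        "scenario": cfg.scenario,
        "noise_sd": cfg.noise_sd,
        "method": method,
        "m_p": m_p,
        "error": err,
        "n_test": len(test_ds.labels),
        "tuning": _tuning_summary(model, train_ds.truth),
    }


def _paired_repetition(
    cfg: SimulationConfig,
    methods,
    pool_sizes,
    clf_cfg: ClassifierConfig,
    base_seed: int,
    cell_key: tuple[int, int],
    rep: int,
) -> list[dict]:
    """One repetition evaluating all methods and pool sizes on shared data."""
    si, ni = cell_key
    rng_data = np.random.default_rng(np.random.SeedSequence([base_seed, si, ni, rep]))
    params = draw_scenario_params(cfg, rng_data)
    train_ds = sample_dataset(cfg, params, rng_data)
    test_ds = sample_dataset(cfg, params, rng_data)
    test_y = test_ds.Y if cfg.test_noise else test_ds.X
    out = []
    for m_p in pool_sizes:
        rng_pool = np.random.default_rng(
            np.random.SeedSequence([base_seed, si, ni, rep, 100 + m_p])
        )
        pooled_y, pool_labels, _ = make_pooled_training_set(
            train_ds, m_p, cfg.noise_sd, rng_pool
        )
        for mi, method in enumerate(methods):
            rng_model = np.random.default_rng(
                np.random.SeedSequence([base_seed, si, ni, rep, 100 + m_p, mi])
            )
            model = train_classifier(method, pooled_y, pool_labels, clf_cfg, rng_model)
            err = prediction_error(predict(model, test_y), test_ds.labels)
            out.append({
                "scenario": cfg.scenario,
                "noise_sd": cfg.noise_sd,
                "method": method,
                "m_p": m_p,
                "rep": rep,
                "error": err,
                "n_test": len(test_ds.labels),
                "tuning": _tuning_summary(model, train_ds.truth),
            })
    return out


@dataclass
class ExperimentResult:
    """Long-format error records plus per-cell summaries."""

    records: pd.DataFrame
    summary: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out_dir / "records.csv", index=False)
        self.summary.to_csv(out_dir / "summary.csv", index=False)


def _run_cell(
    run_cfg: RunConfig, si: int, scenario: str, ni: int, noise_sd: float
) -> pd.DataFrame:
    """All repetitions for one (scenario, noise) combination."""
    cfg = run_cfg.simulation.with_(scenario=scenario, noise_sd=noise_sd)
    if run_cfg.paired:
        reps = Parallel(n_jobs=run_cfg.n_jobs)(
            delayed(_paired_repetition)(
                cfg, run_cfg.methods, run_cfg.pool_sizes, run_cfg.classifier,
                run_cfg.base_seed, (si, ni), rep,
            )
            for rep in range(run_cfg.n_reps)
        )
        rows = [r for rep_rows in reps for r in rep_rows]
    else:
        rows = []
        for m_p in run_cfg.pool_sizes:
            for mi, method in enumerate(run_cfg.methods):
                for rep in range(run_cfg.n_reps):
                    seed = np.random.SeedSequence(
                        [run_cfg.base_seed, si, ni, 100 + m_p, mi, rep]
                    )
                    rec = run_single_repetition(
                        cfg, m_p, method, seed, run_cfg.classifier
                    )
                    rec["rep"] = rep
                    rows.append(rec)
    return pd.DataFrame(rows)[RECORD_COLUMNS]


def run_experiment(run_cfg: RunConfig, progress: bool = False) -> ExperimentResult:
    """Execute the full grid of ``run_cfg`` and summarise.

    Cells — one (scenario, noise) combination each — are executed in
    order; with ``out_dir`` set, records are flushed to
    ``records.csv`` after every cell and cells already complete in that
    file are skipped on rerun.
    """
    out_dir = Path(run_cfg.out_dir) if run_cfg.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    records_path = out_dir / "records.csv" if out_dir else None
    existing = None
    if records_path is not None and records_path.exists():
        existing = pd.read_csv(records_path)
    frames: list[pd.DataFrame] = []
    expected_per_cell = run_cfg.n_reps * len(run_cfg.methods) * len(run_cfg.pool_sizes)
    # repeated fits raise identical warnings (e.g. near-singular LDA at
    # m_p = 5); collect them and re-emit each kind once per run
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for si, scenario in enumerate(run_cfg.scenarios):
            for ni, noise_sd in enumerate(run_cfg.noise_sds):
                if existing is not None:
                    done = existing[
                        (existing["scenario"] == scenario)
                        & (existing["noise_sd"] == noise_sd)
                    ]
                    if len(done) >= expected_per_cell:
                        frames.append(done)
                        continue
                cell = _run_cell(run_cfg, si, scenario, ni, noise_sd)
                frames.append(cell)
                if records_path is not None:
                    pd.concat(frames, ignore_index=True).to_csv(
                        records_path, index=False
                    )
                if progress:
                    print(f"cell scenario={scenario} noise_sd={noise_sd}: "
                          f"{len(cell)} records")
    seen = set()
    for w in caught:
        key = (w.category, str(w.message))
        if key not in seen:
            seen.add(key)
            warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    records = pd.concat(frames, ignore_index=True)
    summary = summarize(
        records,
        level=run_cfg.bootstrap_level,
        n_boot=run_cfg.n_boot,
        seed=run_cfg.base_seed,
    )
    result = ExperimentResult(records=records, summary=summary)
    if out_dir is not None:
        result.write(out_dir)
    return result


def summarize(
    records: pd.DataFrame,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell mean errors with bootstrap CIs and pooling degradation.

    One row per (scenario, noise_sd, method, m_p), deterministically
    ordered, with the mean prediction error, the percentile-bootstrap
    interval for the mean, the repetition count, and — where both
    designs are present — the ratio of the cell's mean error to the
    single-sample (m_p = 1) mean and the m_p = 5 / m_p = 1 ratio.
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")
    records = records.copy()
    records["_s"] = pd.Categorical(
        records["scenario"], categories=list(SCENARIOS), ordered=True
    )
    records["_m"] = pd.Categorical(
        records["method"], categories=list(METHODS), ordered=True
    )
    rows = []
    grouped = records.groupby(["_s", "noise_sd", "_m", "m_p"], observed=True, sort=True)
    for gi, ((scen, noise, method, m_p), grp) in enumerate(grouped):
        errs = grp["error"].to_numpy(dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 777, gi]))
        lo, hi = bootstrap_ci(errs, level=level, n_boot=n_boot, rng=rng)
        rows.append({
            "scenario": str(scen),
            "noise_sd": noise,
            "method": str(method),
            "m_p": m_p,
            "mean_error": errs.mean(),
            "ci_lower": lo,
            "ci_upper": hi,
            "n_reps": len(errs),
        })
    summary = pd.DataFrame(rows)
    base = summary[summary["m_p"] == 1].set_index(["scenario", "noise_sd", "method"])[
        "mean_error"
    ]

    def _ratio(row, target_mp):
        key = (row["scenario"], row["noise_sd"], row["method"])
        if key not in base.index or base.loc[key] == 0:
            return np.nan
        if target_mp is not None and row["m_p"] != target_mp:
            return np.nan
        return row["mean_error"] / base.loc[key]

    summary["error_ratio_vs_single"] = summary.apply(_ratio, axis=1, target_mp=None)
    ratio5 = summary.apply(_ratio, axis=1, target_mp=5)
    key = summary.set_index(["scenario", "noise_sd", "method"]).index
    ratio5_by_key = pd.Series(ratio5.to_numpy(), index=key).groupby(level=[0, 1, 2]).max()
    summary["ratio_mp5_vs_mp1"] = [ratio5_by_key.get(k, np.nan) for k in key]
    return summary


def plot_summary(summary: pd.DataFrame, scenario: str, noise_sd: float, ax=None):
    """Bar chart of mean errors (methods x pool sizes) with CI whiskers."""
    import matplotlib.pyplot as plt

    sub = summary[(summary["scenario"] == scenario) & (summary["noise_sd"] == noise_sd)]
    if len(sub) == 0:
        raise ValueError(f"no summary rows for {scenario} at noise_sd={noise_sd}")
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    methods = [m for m in METHODS if m in set(sub["method"])]
    pool_sizes = sorted(sub["m_p"].unique())
    width = 0.8 / len(pool_sizes)
    for k, m_p in enumerate(pool_sizes):
        vals, errs_lo, errs_hi, xs = [], [], [], []
        for j, method in enumerate(methods):
            row = sub[(sub["method"] == method) & (sub["m_p"] == m_p)]
            if len(row) == 0:
                continue
            row = row.iloc[0]
            xs.append(j + (k - (len(pool_sizes) - 1) / 2) * width)
            vals.append(row["mean_error"])
            errs_lo.append(row["mean_error"] - row["ci_lower"])
            errs_hi.append(row["ci_upper"] - row["mean_error"])
        ax.bar(xs, vals, width=width * 0.9, label=f"m_p={m_p}",
               yerr=[errs_lo, errs_hi], capsize=2)
    ax.set_xticks(range(len(methods)))
    ax.set_xticklabels([m.upper() for m in methods])
    ax.set_ylabel("prediction error")
    ax.set_title(f"scenario={scenario}, noise sd={noise_sd}")
    ax.legend(title="pool size")
    return ax
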