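"""End-to-end study orchestration.

One config drives the full analysis: simulate (or ingest) a cohort,
compute eyeblink rates from pupil streams, fit logistic psychometric
functions per participant and task, apply the goodness-of-fit and
missing-EBR exclusions, and emit the full battery of rank-based
correlational analyses with bootstrap CIs and default Bayes factors,
plus EBR-tercile response summaries.

Reproducibility: a single master seed derives per-stage seeds through a
fixed spawn order (population, trials, streams, pdev, bootstrap), so
stages are independently re-runnable and the whole report is
byte-identical across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .bayes_inference import (
    DEFAULT_CAUCHY_SCALE,
    DEFAULT_KAPPA,
    bf_from_spearman,
    bf_ttest_from_t,
)
from .correlation_stats import (
    bca_ci,
    compare_dependent_correlations,
    paired_ttest,
    partial_spearman,
    remove_bivariate_outliers,
    spearman,
)
from .eyeblink import ebr_from_stream, read_pupil_stream
from .psychometrics import (
    ResponseSummary,
    apply_exclusions,
    fit_pf_mle,
    goodness_of_fit_pdev,
)
from .synthetic_data import (
    PopulationSpec,
    build_design,
    observer_from_row,
    read_trial_table,
    sample_population,
    simulate_observer_responses,
    simulate_pupil_stream,
)

_STAGES = ("population", "trials", "streams", "pdev", "bootstrap")
TASKS = ("time", "color")


@dataclass
class StudyConfig:
    """All knobs of one study run (defaults mirror the study protocol)."""

    mode: str = "simulate"                      # simulate | files
    trials_path: Optional[str] = None
    streams_dir: Optional[str] = None
    ebr_path: Optional[str] = None              # event/rate table alternative to streams
    n_participants: int = 75
    target_rho: float = 0.28
    lapse_rate: float = 0.0
    n_missing_ebr: int = 0
    master_seed: int = 1
    n_boot: int = 10000
    n_sim_pdev: int = 1000
    pdev_threshold: float = 0.05
    outlier_removal: str = "both"               # none | both (pre and post reported)
    kappa: float = DEFAULT_KAPPA
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE
    include_reminders: bool = False
    include_training: bool = False
    keep_trials: Optional[bool] = None          # default: only for cohorts <= 200

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be simulate|files")
        if not 0 < self.pdev_threshold < 1:
            raise ValueError("pdev_threshold must be in (0, 1)")
        if self.outlier_removal not in ("none", "both"):
            raise ValueError("outlier_removal must be none|both")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyReport:
    participants: pd.DataFrame
    analyses: pd.DataFrame
    exclusions: pd.DataFrame
    terciles: pd.DataFrame
    provenance: dict
    summaries: dict = field(default_factory=dict)   # (pid, task) -> ResponseSummary
    trials: Optional[pd.DataFrame] = None
    truth: Optional[pd.DataFrame] = None            # simulate mode only


# ---------------------------------------------------------------------------
# data acquisition stages
# ---------------------------------------------------------------------------

def _simulate_cohort(config: StudyConfig, seeds: dict) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    spec = PopulationSpec(
        n_participants=config.n_participants,
        target_spearman_rho_ebr_wf=config.target_rho,
        lapse_rate=config.lapse_rate,
    )
    truth = sample_population(spec, rng=np.random.default_rng(seeds["population"]))

    trial_seeds = seeds["trials"].spawn(len(truth))
    stream_seeds = seeds["streams"].spawn(len(truth) + 1)
    missing_rng = np.random.default_rng(stream_seeds[-1])
    missing = set(
        missing_rng.choice(truth["participant_id"], size=config.n_missing_ebr, replace=False)
    ) if config.n_missing_ebr else set()

    frames, ebr_rows, summaries = [], [], {}
    for i, row in truth.iterrows():
        pid = row["participant_id"]
        rng_t = np.random.default_rng(trial_seeds[i])
        for task in TASKS:
            design = build_design(task)
            obs = observer_from_row(row, task)
            tr = simulate_observer_responses(
                design, obs, rng=rng_t, participant_id=pid,
                include_training=True,
            )
            summaries[(pid, task)] = ResponseSummary.from_trials(
                tr, include_reminders=config.include_reminders,
                include_training=config.include_training,
            )
            frames.append(tr)
        if pid in missing:
            ebr_rows.append((pid, np.nan, np.nan))
        else:
            stream, _ = simulate_pupil_stream(
                blink_rate_per_min=float(row["ebr_true"]),
                rng=np.random.default_rng(stream_seeds[i]),
            )
            res = ebr_from_stream(stream)
            ebr_rows.append((pid, res.ebr, res.n_blinks_in_window))

    keep = config.keep_trials if config.keep_trials is not None else len(truth) <= 200
    trials = pd.concat(frames, ignore_index=True) if keep else None
    ebr = pd.DataFrame(ebr_rows, columns=["participant_id", "ebr", "n_blinks"])
    return ebr, truth, {"summaries": summaries, "trials": trials}


def read_inputs(
    trials_path, streams_dir=None, ebr_path=None,
    include_reminders: bool = False, include_training: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Ingest the delimited trial/stream formats into typed tables.

    Returns (ebr table, participant index, {'summaries': ..., 'trials': ...}).
    EBR comes from per-participant `<pid>.csv` streams in ``streams_dir``
    or from a precomputed ``participant_id,ebr`` table; participants
    without either are carried with EBR = NaN (flagged, excluded only
    from correlational rows).
    """
    trials = read_trial_table(trials_path)
    pids = sorted(trials["participant_id"].unique())
    summaries = {}
    for (pid, task), grp in trials.groupby(["participant_id", "task"]):
        summaries[(pid, task)] = ResponseSummary.from_trials(
            grp, include_reminders=include_reminders, include_training=include_training
        )
    ebr_rows = []
    if ebr_path is not None:
        tab = pd.read_csv(ebr_path)
        if not {"participant_id", "ebr"}.issubset(tab.columns):
            raise ValueError(f"{ebr_path}: expected columns participant_id,ebr")
        if tab["participant_id"].duplicated().any():
            dup = tab[tab["participant_id"].duplicated()]["participant_id"].iloc[0]
            raise ValueError(f"{ebr_path}: duplicated participant row {dup!r}")
        known = tab.set_index("participant_id")["ebr"]
        for pid in pids:
            ebr_rows.append((pid, float(known.get(pid, np.nan)), np.nan))
    elif streams_dir is not None:
        for pid in pids:
            f = Path(streams_dir) / f"{pid}.csv"
            if f.exists():
                res = ebr_from_stream(read_pupil_stream(f))
                ebr_rows.append((pid, res.ebr, res.n_blinks_in_window))
            else:
                ebr_rows.append((pid, np.nan, np.nan))
    else:
        ebr_rows = [(pid, np.nan, np.nan) for pid in pids]
    ebr = pd.DataFrame(ebr_rows, columns=["participant_id", "ebr", "n_blinks"])
    truth = pd.DataFrame({"participant_id": pids})
    return ebr, truth, {"summaries": summaries, "trials": trials}


# ---------------------------------------------------------------------------
# fitting stage
# ---------------------------------------------------------------------------

def fit_cohort(summaries: dict, config: StudyConfig, pdev_seed) -> pd.DataFrame:
    """Fit every (participant, task) summary and compute pDev."""
    pids = sorted({pid for pid, _ in summaries})
    pdev_seeds = pdev_seed.spawn(len(pids))
    rows = []
    for i, pid in enumerate(pids):
        rng = np.random.default_rng(pdev_seeds[i])
        for task in TASKS:
            if (pid, task) not in summaries:
                continue
            summ = summaries[(pid, task)]
            fit = fit_pf_mle(summ)
            if fit.converged:
                pdev = goodness_of_fit_pdev(fit, summ, n_sim=config.n_sim_pdev, rng=rng)
                bp, dl, wf = fit.bp, fit.dl, fit.wf
            else:
                pdev, bp, dl, wf = np.nan, np.nan, np.nan, np.nan
            rows.append(
                dict(participant_id=pid, task=task, alpha=fit.alpha, beta=fit.beta,
                     bp=bp, dl=dl, wf=wf, deviance=fit.deviance, pdev=pdev,
                     converged=fit.converged)
            )
    return pd.DataFrame(rows)


def merge_participant_table(fits: pd.DataFrame, ebr: pd.DataFrame) -> pd.DataFrame:
    """Wide per-participant table: EBR plus per-task fit columns."""
    wide = fits.pivot(index="participant_id", columns="task")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    merged = ebr.merge(wide.reset_index(), on="participant_id", how="outer")
    return merged.sort_values("participant_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# analysis battery
# ---------------------------------------------------------------------------

def _row(name, stat, estimate, n, p=np.nan, ci=(np.nan, np.nan), bf_label="", bf=np.nan, notes=""):
    return dict(analysis=name, stat=stat, estimate=float(estimate), n=int(n),
                p_value=float(p), ci_low=float(ci[0]), ci_high=float(ci[1]),
                bf_label=bf_label, bf=float(bf), notes=notes)


def analyze_merged(merged: pd.DataFrame, config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Run the full correlational battery on the merged participant table.

    ``merged`` must carry ``ebr``, per-task ``wf_*``, ``bp_*``,
    ``pdev_*`` and ``converged_*`` columns.  Every row records the exact
    N it used (complete cases for its own variable set).
    """
    thr = config.pdev_threshold
    ok = {}
    for task in TASKS:
        ok[task] = (
            merged[f"converged_{task}"].fillna(False).astype(bool)
            & (merged[f"pdev_{task}"] >= thr)
        )
    has_ebr = merged["ebr"].notna()

    def corr_block(name, xcol, ycol, mask, side) -> list[dict]:
        sub = merged[mask]
        x, y = sub[xcol].to_numpy(), sub[ycol].to_numpy()
        res = spearman(x, y)
        res.ci_low, res.ci_high = bca_ci(x, y, n_boot=config.n_boot, rng=rng)
        bf = bf_from_spearman(res.rho, res.n, kappa=config.kappa, side=side)
        rows = [_row(name, "spearman_rho", res.rho, res.n, res.p_value,
                     (res.ci_low, res.ci_high), f"BF_{side}", bf.by_side(side))]
        if config.outlier_removal == "both" and res.n >= 10:
            out = remove_bivariate_outliers(x, y)
            if out.any():
                res2 = spearman(x[~out], y[~out])
                res2.ci_low, res2.ci_high = bca_ci(x[~out], y[~out], n_boot=config.n_boot, rng=rng)
                bf2 = bf_from_spearman(res2.rho, res2.n, kappa=config.kappa, side=side)
                rows.append(_row(f"{name}__outliers_removed", "spearman_rho", res2.rho,
                                 res2.n, res2.p_value, (res2.ci_low, res2.ci_high),
                                 f"BF_{side}", bf2.by_side(side),
                                 notes=f"removed={int(out.sum())}"))
            else:
                rows.append(_row(f"{name}__outliers_removed", "spearman_rho", res.rho,
                                 res.n, res.p_value, (res.ci_low, res.ci_high),
                                 f"BF_{side}", bf.by_side(side), notes="removed=0"))
        return rows

    def semipartial_row(name, xcol, ycol, zcol, mask, side) -> dict:
        sub = merged[mask]
        res = partial_spearman(sub[xcol], sub[ycol], sub[zcol], semi_on="y")
        bf = bf_from_spearman(res.rho, res.n, kappa=config.kappa, side=side)
        return _row(name, "semipartial_spearman_rho", res.rho, res.n, res.p_value,
                    bf_label=f"BF_{side}", bf=bf.by_side(side), notes=res.method)

    def diff_row(name, xcol, acol, bcol, mask) -> dict:
        sub = merged[mask]
        d = compare_dependent_correlations(
            sub[xcol].to_numpy(), sub[acol].to_numpy(), sub[bcol].to_numpy(),
            n_boot=config.n_boot, rng=rng,
        )
        return _row(name, "rho_difference", d.diff, d.n,
                    ci=(d.diff_ci_low, d.diff_ci_high),
                    notes=f"t({d.df})={d.t_stat:.3f}; d_z={d.d_z:.3f}; z_diff={d.z_diff:.3f}; "
                          f"significant={d.significant}; {d.method}")

    rows: list[dict] = []
    m_time = has_ebr & ok["time"]
    m_color = has_ebr & ok["color"]
    m_tasks = ok["time"] & ok["color"]
    m_all = has_ebr & ok["time"] & ok["color"]

    rows += corr_block("ebr_x_wf_time", "ebr", "wf_time", m_time, "plus")
    rows += corr_block("ebr_x_wf_color", "ebr", "wf_color", m_color, "plus")
    rows.append(diff_row("wf_ebr_correlation_difference", "ebr", "wf_time", "wf_color", m_all))
    rows += corr_block("wf_time_x_wf_color", "wf_time", "wf_color", m_tasks, "plus")
    rows.append(semipartial_row("ebr_x_wf_time_ctrl_wf_color", "ebr", "wf_time", "wf_color", m_all, "plus"))
    rows.append(semipartial_row("ebr_x_wf_color_ctrl_wf_time", "ebr", "wf_color", "wf_time", m_all, "plus"))
    rows += corr_block("ebr_x_bp_time", "ebr", "bp_time", m_time, "minus")
    rows += corr_block("ebr_x_bp_color", "ebr", "bp_color", m_color, "minus")
    rows.append(diff_row("bp_ebr_correlation_difference", "ebr", "bp_time", "bp_color", m_all))
    rows += corr_block("bp_time_x_bp_color", "bp_time", "bp_color", m_tasks, "two")
    rows.append(semipartial_row("ebr_x_bp_time_ctrl_bp_color", "ebr", "bp_time", "bp_color", m_all, "minus"))
    rows.append(semipartial_row("ebr_x_bp_color_ctrl_bp_time", "ebr", "bp_color", "bp_time", m_all, "minus"))

    # task-difficulty check: paired t on WFs over everyone with converged
    # fits in both tasks (no pDev or EBR requirement)
    m_fit = (merged["converged_time"].fillna(False).astype(bool)
             & merged["converged_color"].fillna(False).astype(bool))
    sub = merged[m_fit]
    tt = paired_ttest(sub["wf_time"].to_numpy(), sub["wf_color"].to_numpy())
    bf_t = bf_ttest_from_t(tt.t_stat, tt.n, cauchy_scale=config.cauchy_scale)
    rows.append(_row("wf_time_vs_wf_color_paired_t", "t", tt.t_stat, tt.n, tt.p_value,
                     bf_label="BF_10", bf=bf_t.bf10,
                     notes=f"df={tt.df}; d_z={tt.d_z:.3f}"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# terciles
# ---------------------------------------------------------------------------

def tercile_summary(merged: pd.DataFrame, summaries: dict, config: StudyConfig) -> pd.DataFrame:
    """Mean positive-response proportion per level for EBR terciles.

    Computed after exclusions, task-wise; ties at tercile boundaries are
    broken by participant id order.
    """
    thr = config.pdev_threshold
    rows = []
    for task in TASKS:
        ok = (
            merged[f"converged_{task}"].fillna(False).astype(bool)
            & (merged[f"pdev_{task}"] >= thr)
            & merged["ebr"].notna()
        )
        sub = merged[ok].sort_values(["ebr", "participant_id"], kind="stable")
        if len(sub) < 3:
            continue
        parts = np.array_split(sub["participant_id"].to_numpy(), 3)
        for label, pids in zip(("low", "medium", "high"), parts):
            props = np.array([summaries[(pid, task)].proportions for pid in pids])
            levels = summaries[(pids[0], task)].levels
            for lev, mp_ in zip(levels, props.mean(axis=0)):
                rows.append(dict(task=task, tercile=label, level=float(lev),
                                 mean_p_positive=float(mp_), n_participants=len(pids)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig) -> StudyReport:
    """Execute every stage in fixed order with seeds derived from the master.

    Stage failures raise with a stage-tagged message; the per-analysis N
    accounting follows complete cases per variable set (so temporal and
    color Ns may differ).
    """
    ss = np.random.SeedSequence(config.master_seed)
    seeds = dict(zip(_STAGES, ss.spawn(len(_STAGES))))

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as e:
            raise RuntimeError(f"stage '{name}' failed: {e}") from e

    if config.mode == "simulate":
        ebr, truth, data = stage("simulate", _simulate_cohort, config, seeds)
    else:
        if config.trials_path is None:
            raise ValueError("files mode requires trials_path")
        ebr, truth, data = stage(
            "ingest", read_inputs, config.trials_path, config.streams_dir,
            config.ebr_path, config.include_reminders, config.include_training,
        )

    fits = stage("fit", fit_cohort, data["summaries"], config, seeds["pdev"])
    retained, excl_log = stage("exclusions", apply_exclusions, fits, ebr, config.pdev_threshold)
    merged = merge_participant_table(fits, ebr)

    boot_rng = np.random.default_rng(seeds["bootstrap"])
    analyses = stage("analyze", analyze_merged, merged, config, boot_rng)
    terciles = stage("terciles", tercile_summary, merged, data["summaries"], config)

    n_by_analysis = dict(zip(analyses["analysis"], analyses["n"]))
    provenance = {
        "package": f"bisectlab {_version}",
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "stage_order": list(_STAGES),
        "n_participants": int(len(merged)),
        "n_missing_ebr": int(merged["ebr"].isna().sum()),
        "n_excluded": {
            task: int(((merged[f"pdev_{task}"] < config.pdev_threshold)
                       | ~merged[f"converged_{task}"].fillna(False).astype(bool)).sum())
            for task in TASKS
        },
        "analysis_n": {k: int(v) for k, v in n_by_analysis.items()},
    }
    return StudyReport(
        participants=merged, analyses=analyses, exclusions=excl_log,
        terciles=terciles, provenance=provenance,
        summaries=data["summaries"], trials=data.get("trials"),
        truth=truth if config.mode == "simulate" else None,
    )


def write_report(report: StudyReport, outdir) -> None:
    """Serialize the report as delimited text plus a plain-text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.participants.to_csv(outdir / "participants.csv", index=False)
    report.analyses.to_csv(outdir / "analyses.csv", index=False)
    report.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    report.terciles.to_csv(outdir / "terciles.csv", index=False)
    (outdir / "provenance.yaml").write_text(yaml.safe_dump(report.provenance, sort_keys=True))
    lines = ["bisectlab study report", "======================", ""]
    for _, r in report.analyses.iterrows():
        ci = ""
        if np.isfinite(r["ci_low"]):
            ci = f" [95% CI {r['ci_low']:.3f}, {r['ci_high']:.3f}]"
        p = f", p = {r['p_value']:.4f}" if np.isfinite(r["p_value"]) else ""
        bf = f", {r['bf_label']} = {r['bf']:.3f}" if np.isfinite(r["bf"]) else ""
        lines.append(f"{r['analysis']}: {r['stat']} = {r['estimate']:.3f}{ci}{p} "
                     f"(N = {r['n']}){bf}")
        if r["notes"]:
            lines.append(f"    {r['notes']}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    if report.trials is not None:
        report.trials.to_csv(outdir / "trials.csv", index=False)
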