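"""Synthetic cohorts for the bisection/eyeblink analysis pipeline.

Emulates the statistical structure the analysis assumes, so that every
downstream stage (blink detection, psychometric fitting, rank-based
inference) can be exercised without any recorded data:

* task designs — temporal bisection over 300..967 ms and a color
  bisection control over 22..78 %-blue, each with 3 blocks of 76 trials
  (4 anchor reminders at block start, then 16 repetitions of each of the
  four middle levels and 4 of each anchor), preceded by a 20-trial
  anchor training phase with an 80%-accuracy extension rule;
* logistic observers responding "long"/"red" with probability
  ``(1 - 2*lapse) * psi(x; alpha, beta) + lapse`` (the positive response
  label follows the upper anchor by coding convention — in the color
  task the probability is parameterized as increasing along the
  percent-blue axis);
* a population in which spontaneous eyeblink rate (EBR) and the *true*
  temporal Weber fraction are coupled through a Gaussian copula at a
  configurable Spearman rho, while color-task parameters are drawn
  independently of EBR;
* resting-state pupil streams: 8 min at 500 Hz with Poisson-arriving
  blinks (refractory-thinned) written as runs of missing samples.

Coupling is applied to the true WF, not the fitted one, so attenuation
by estimation noise is itself measurable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .eyeblink import MIN_BLINK_SAMPLES, BlinkEvent, PupilStream
from .psychometrics import LN3, psi_logistic

TIME_LEVELS = (300.0, 433.0, 567.0, 700.0, 833.0, 967.0)      # ms
COLOR_LEVELS = (22.0, 34.0, 45.0, 55.0, 66.0, 78.0)           # % blue

TRIAL_COLUMNS = ["participant_id", "task", "phase", "block", "stimulus", "response", "rt_s"]

#: nominal seconds per trial, used to cap the adaptive training phase
#: (stimulus + jittered ISIs + response) at the 6-minute limit.
_TRAINING_SECONDS_PER_TRIAL = 4.0


# ---------------------------------------------------------------------------
# designs and observers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusDesign:
    task_kind: str
    levels: tuple
    n_blocks: int = 3
    trials_per_block: int = 76
    reminders_per_anchor_per_block: int = 2
    middle_reps_per_block: int = 16
    anchor_reps_per_block: int = 4
    training_block_size: int = 20
    training_accuracy_target: float = 0.80
    training_max_minutes: float = 6.0

    def __post_init__(self) -> None:
        if len(self.levels) != 6:
            raise ValueError("exactly 6 stimulus levels expected")
        if not all(a < b for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")
        total = (
            2 * self.reminders_per_anchor_per_block
            + 4 * self.middle_reps_per_block
            + 2 * self.anchor_reps_per_block
        )
        if total != self.trials_per_block:
            raise ValueError("per-block trial accounting does not add up")

    @property
    def anchors(self) -> tuple:
        return self.levels[0], self.levels[-1]

    @property
    def middle_levels(self) -> tuple:
        return self.levels[1:-1]


def build_design(task_kind: str) -> StimulusDesign:
    """Return the fixed design constants for one task."""
    if task_kind == "time":
        return StimulusDesign("time", TIME_LEVELS)
    if task_kind == "color":
        return StimulusDesign("color", COLOR_LEVELS)
    raise ValueError(f"unknown task_kind: {task_kind!r}")


@dataclass(frozen=True)
class ObserverParams:
    """True logistic-observer parameters for one participant and task."""

    alpha: float
    beta: float
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")

    @property
    def wf(self) -> float:
        return LN3 / (self.alpha * self.beta)

    def p_positive(self, x) -> np.ndarray:
        lam = self.lapse_rate
        return (1 - 2 * lam) * np.asarray(psi_logistic(x, self.alpha, self.beta)) + lam


_POSITIVE = {"time": "long", "color": "red"}
_NEGATIVE = {"time": "short", "color": "blue"}


def simulate_observer_responses(
    design: StimulusDesign,
    observer: ObserverParams,
    seed=None,
    *,
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "p001",
    include_training: bool = True,
    with_rt: bool = True,
) -> pd.DataFrame:
    """One simulated session of one task: training, reminders and test trials.

    Returns a trial table with columns
    ``participant_id,task,phase,block,stimulus,response,rt_s``.  Response
    draws are Bernoulli with ``P(positive) = (1-2*lapse)*psi + lapse``;
    per-level test counts match the design exactly.  Response times are
    shifted-lognormal plumbing only.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    pos, neg = _POSITIVE[design.task_kind], _NEGATIVE[design.task_kind]
    lo, hi = design.anchors
    rows_stim, rows_phase, rows_block = [], [], []

    if include_training:
        max_trials = int(design.training_max_minutes * 60 / _TRAINING_SECONDS_PER_TRIAL)
        half = design.training_block_size // 2
        stims = list(rng.permutation([lo] * half + [hi] * half))
        correct = []
        while True:
            # responses drawn lazily so extensions reuse the same machinery
            while len(correct) < len(stims):
                x = stims[len(correct)]
                r = rng.random() < observer.p_positive(x)
                correct.append(r == (x == hi))
            window = correct[-design.training_block_size:]
            if (
                np.mean(window) >= design.training_accuracy_target
                and len(stims) >= design.training_block_size
            ):
                break
            if len(stims) >= max_trials:
                break
            stims.append(lo if rng.random() < 0.5 else hi)
        resp_train = [
            (x == hi) == c for x, c in zip(stims, correct)
        ]  # recover the drawn response from correctness
        for x, r in zip(stims, resp_train):
            rows_stim.append((x, pos if r else neg))
            rows_phase.append("training")
            rows_block.append(0)

    for block in range(1, design.n_blocks + 1):
        reminders = [lo, hi] * design.reminders_per_anchor_per_block
        test = (
            list(np.repeat(design.middle_levels, design.middle_reps_per_block))
            + [lo, hi] * design.anchor_reps_per_block
        )
        test = list(rng.permutation(test))
        for x in reminders:
            r = rng.random() < observer.p_positive(x)
            rows_stim.append((x, pos if r else neg))
            rows_phase.append("reminder")
            rows_block.append(block)
        for x in test:
            r = rng.random() < observer.p_positive(x)
            rows_stim.append((x, pos if r else neg))
            rows_phase.append("test")
            rows_block.append(block)

    n_rows = len(rows_stim)
    rt = 0.25 + rng.lognormal(-0.7, 0.4, size=n_rows) if with_rt else np.full(n_rows, np.nan)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "task": design.task_kind,
            "phase": rows_phase,
            "block": rows_block,
            "stimulus": [s for s, _ in rows_stim],
            "response": [r for _, r in rows_stim],
            "rt_s": np.round(rt, 4),
        },
        columns=TRIAL_COLUMNS,
    )


# ---------------------------------------------------------------------------
# population with EBR-WF copula coupling
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Population distributions for the simulated cohort.

    Marginals (configurable; defaults resemble typical bisection / EBR
    literature values): BP ``alpha ~ Normal(633, 60)`` ms truncated to
    the level range; true WF lognormal with median 0.15 (log-sd 0.35);
    EBR ``~ Gamma`` with mean 15 and sd 8 blinks/min.  The slope is
    derived as ``beta = ln(3) / (alpha * wf)``.  EBR and temporal true
    WF share a Gaussian copula with latent Pearson
    ``r = 2 sin(pi * rho_s / 6)`` so their population Spearman rho hits
    the target; color-task parameters are independent of EBR.
    """

    n_participants: int = 75
    alpha_dist: tuple = (633.0, 60.0)            # ms, truncated to level range
    wf_dist: tuple = (float(np.log(0.15)), 0.35)  # log-mean, log-sd of true WF
    ebr_dist: tuple = (15.0, 8.0)                 # mean, sd blinks/min
    alpha_color_dist: tuple = (50.0, 5.0)         # % blue, truncated to level range
    wf_color_dist: tuple = (float(np.log(0.15)), 0.35)
    target_spearman_rho_ebr_wf: float = 0.28
    lapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_spearman_rho_ebr_wf <= 1.0:
            raise ValueError("|target rho| must be <= 1")
        for _, sd in (self.alpha_dist, self.ebr_dist, self.alpha_color_dist):
            if sd < 0:
                raise ValueError("sds must be >= 0")


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def sample_population(spec: PopulationSpec, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw a cohort of observers with EBR coupled to temporal true WF.

    Returns one row per participant with true EBR (blinks/min), and per
    task the true (alpha, beta, wf).  With ``|target rho| = 1`` the
    latent correlation is exactly +/-1, giving comonotone (antimonotone)
    EBR/WF ranks.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_participants
    rho_s = spec.target_spearman_rho_ebr_wf
    r_latent = 2.0 * np.sin(np.pi * rho_s / 6.0)

    z1 = rng.standard_normal(n)
    z2 = r_latent * z1 + np.sqrt(max(0.0, 1.0 - r_latent**2)) * rng.standard_normal(n)
    u_ebr, u_wf = stats.norm.cdf(z1), stats.norm.cdf(z2)

    ebr_mean, ebr_sd = spec.ebr_dist
    shape = (ebr_mean / ebr_sd) ** 2
    scale = ebr_sd**2 / ebr_mean
    ebr = stats.gamma.ppf(u_ebr, shape, scale=scale)

    wf_time = stats.lognorm.ppf(u_wf, s=spec.wf_dist[1], scale=np.exp(spec.wf_dist[0]))
    alpha_time = _truncnorm(rng, *spec.alpha_dist, TIME_LEVELS[0], TIME_LEVELS[-1], n)
    beta_time = LN3 / (alpha_time * wf_time)

    alpha_color = _truncnorm(rng, *spec.alpha_color_dist, COLOR_LEVELS[0], COLOR_LEVELS[-1], n)
    wf_color = rng.lognormal(spec.wf_color_dist[0], spec.wf_color_dist[1], size=n)
    beta_color = LN3 / (alpha_color * wf_color)

    return pd.DataFrame(
        {
            "participant_id": [f"p{i + 1:03d}" for i in range(n)],
            "ebr_true": ebr,
            "alpha_time": alpha_time,
            "beta_time": beta_time,
            "wf_time_true": wf_time,
            "alpha_color": alpha_color,
            "beta_color": beta_color,
            "wf_color_true": wf_color,
            "lapse_rate": spec.lapse_rate,
        }
    )


def observer_from_row(row: pd.Series, task_kind: str) -> ObserverParams:
    return ObserverParams(
        alpha=float(row[f"alpha_{task_kind}"]),
        beta=float(row[f"beta_{task_kind}"]),
        lapse_rate=float(row.get("lapse_rate", 0.0)),
    )


# ---------------------------------------------------------------------------
# pupil streams
# ---------------------------------------------------------------------------

def simulate_pupil_stream(
    duration_min: float = 8.0,
    rate_hz: float = 500.0,
    blink_rate_per_min: float = 15.0,
    blink_duration_ms: tuple = (100.0, 300.0),
    refractory_ms: float = 100.0,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PupilStream, list[BlinkEvent]]:
    """Binary pupil stream with Poisson-arriving blinks and ground truth.

    Candidate onsets form a Poisson process at ``blink_rate_per_min``;
    a candidate is kept only if it starts at least ``refractory_ms``
    (and one detected sample) after the previous blink's offset.  Blink
    durations are uniform on ``blink_duration_ms`` (the lower bound must
    be >= 3 samples, the detection threshold).  Blinks truncated by the
    stream end to < 3 samples are dropped.  Returns the stream and the
    ground-truth blink list.
    """
    if blink_rate_per_min < 0:
        raise ValueError("blink rate must be >= 0")
    d_lo, d_hi = blink_duration_ms
    min_ms = MIN_BLINK_SAMPLES * 1000.0 / rate_hz
    if d_lo < min_ms:
        raise ValueError(f"blink duration below {min_ms:g} ms is undetectable at {rate_hz:g} Hz")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_samples = int(round(duration_min * 60.0 * rate_hz))
    flags = np.ones(n_samples, dtype=np.uint8)
    blinks: list[BlinkEvent] = []
    if blink_rate_per_min > 0:
        rate_s = blink_rate_per_min / 60.0
        t, guard = 0.0, -np.inf  # guard: earliest admissible onset (s)
        while True:
            t += rng.exponential(1.0 / rate_s)
            if t >= duration_min * 60.0:
                break
            if t < guard:
                continue  # thinned by the refractory period
            onset = int(t * rate_hz)
            dur_ms = rng.uniform(d_lo, d_hi)
            offset = min(onset + max(int(round(dur_ms * rate_hz / 1000.0)), MIN_BLINK_SAMPLES), n_samples)
            if offset - onset < MIN_BLINK_SAMPLES:
                break  # truncated tail blink, undetectable
            flags[onset:offset] = 0
            blinks.append(BlinkEvent(onset, offset, rate_hz))
            guard = offset / rate_hz + refractory_ms / 1000.0 + 1.5 / rate_hz
    return PupilStream(flags, rate_hz=rate_hz), blinks


# ---------------------------------------------------------------------------
# trial-table I/O
# ---------------------------------------------------------------------------

_VALID_RESPONSES = {"time": {"long", "short"}, "color": {"red", "blue"}}


def write_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(Path(path), index=False, columns=TRIAL_COLUMNS)


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate the delimited trial format (errors carry row numbers)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        task = row["task"]
        if task not in _VALID_RESPONSES:
            raise ValueError(f"{path} line {line}: unknown task {task!r}")
        if row["response"] not in _VALID_RESPONSES[task]:
            raise ValueError(f"{path} line {line}: malformed response {row['response']!r}")
        if row["phase"] not in ("training", "reminder", "test"):
            raise ValueError(f"{path} line {line}: unknown phase {row['phase']!r}")
        levels = build_design(task).levels
        if row["phase"] != "training" and float(row["stimulus"]) not in levels:
            raise ValueError(f"{path} line {line}: stimulus {row['stimulus']} not a design level")
    return df
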