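"""Trial cleaning, task metrics, score filtering, screening and ICC.

The cleaning/scoring pipeline runs in a fixed order mirroring the study
narrative: (1) remove anticipatory responses (RT < 200 ms); (2) remove trials
beyond 3 individual SDs of the individual mean RT, per participant x task;
(3) compute task metrics; (4) drop a participant's task score when any
condition retains fewer than 5 trials or overall accuracy falls below chance
for the task's option count; (5) drop score outliers beyond +/-3 median
absolute deviations of the task median.  Every removal is attributed to
exactly one stage and tallies are conserved.

Task metrics: rate correct score (RCS, correct responses per second of
response time), mean correct RT (ms), and object span.  RT-based metrics are
oriented by the ``-x / 100`` transform so higher is better; all task scores
are residualised on the hand-appropriate basic response time mean before the
network/factor analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .battery import TaskSpec, span_score
from .engine import NO_RESPONSE, TrialRecord

__all__ = [
    "CleaningConfig",
    "ScoreTable",
    "ICCResult",
    "records_to_frame",
    "clean_trials",
    "score_task",
    "validity_filter",
    "mad_outlier_filter",
    "residualize",
    "transform_rt_metric",
    "screen_participants",
    "icc",
    "build_score_table",
    "basic_rt_covariates",
    "prepare_scores",
]

TRIAL_COLUMNS = (
    "participant_id", "session", "task", "condition", "trial", "stimulus",
    "answer", "response", "rt_ms", "window_ms", "feedback",
)


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds of the cleaning/filtering pipeline (all positive)."""

    anticipatory_cutoff_ms: float = 200.0
    individual_sd_k: float = 3.0
    min_trials_per_condition: int = 5
    mad_k: float = 3.0
    mad_scale_constant: float = 1.4826  # normal-consistent MAD; 1.0 = raw MAD
    rcs_literal_product: bool = False   # divide by n_trials * total RT instead

    def __post_init__(self) -> None:
        for name in ("anticipatory_cutoff_ms", "individual_sd_k",
                     "min_trials_per_condition", "mad_k", "mad_scale_constant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ScoreTable:
    """Participant x task-metric score matrix with removal provenance.

    ``data`` rows are participants, columns task ids; missing entries are
    NaN.  ``units`` records the metric unit per column; ``removals`` is a
    tidy frame with one row per removal event (stage, participant, task,
    count).
    """

    data: pd.DataFrame
    units: Dict[str, str]
    removals: pd.DataFrame

    def removal_tally(self) -> Dict[str, int]:
        if self.removals.empty:
            return {}
        return self.removals.groupby("stage")["count"].sum().to_dict()


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation between two assessment sessions."""

    icc: float
    model: str
    f_stat: float
    df1: int
    df2: int
    p_value: float

    @property
    def quality(self) -> str:
        """Qualitative class: excellent (>0.75) / good (0.60-0.74) /
        fair (0.40-0.59) / poor (<0.40)."""
        if self.icc > 0.75:
            return "excellent"
        if self.icc >= 0.60:
            return "good"
        if self.icc >= 0.40:
            return "fair"
        return "poor"


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Convert trial records to the pinned trial-log frame."""
    rows = [
        (r.participant_id, r.session, r.task, r.condition, r.trial, r.stimulus,
         r.answer, r.response, r.rt_ms, r.window_ms, str(r.feedback))
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


# ---------------------------------------------------------------------------
# Trial-level cleaning
# ---------------------------------------------------------------------------


def clean_trials(
    trials: pd.DataFrame,
    cfg: CleaningConfig = CleaningConfig(),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage trial cleaning; returns (kept trials, removal tally).

    Stage ``anticipatory`` removes responded trials with RT below the cutoff;
    stage ``sd_trim`` then removes trials whose RT lies beyond ``k``
    individual SDs of the individual (participant x task) mean RT, computed
    on post-stage-1 data.  Omitted responses carry no RT and pass through
    both stages.  With fewer than two responded trials, or zero SD, the SD
    stage removes nothing.
    """
    rt = trials["rt_ms"]
    responded = rt.notna()
    anticipatory = responded & (rt < cfg.anticipatory_cutoff_ms)
    stage1 = trials.loc[~anticipatory]

    grp = stage1.groupby(["participant_id", "task"])["rt_ms"]
    mean = grp.transform("mean")
    sd = grp.transform("std")
    dev_ok = (stage1["rt_ms"] - mean).abs() <= cfg.individual_sd_k * sd
    # NaN rt (omissions), NaN sd (single trial) and zero sd all pass
    keep2 = dev_ok | stage1["rt_ms"].isna() | sd.isna() | (sd == 0)
    stage2 = stage1.loc[keep2]

    tally = _tally_removals(
        [("anticipatory", trials.loc[anticipatory]),
         ("sd_trim", stage1.loc[~keep2])]
    )
    return stage2.reset_index(drop=True), tally


def _tally_removals(stages: List[Tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    rows = []
    for stage, removed in stages:
        if removed.empty:
            continue
        counts = removed.groupby(["participant_id", "task"]).size()
        for (pid, task), n in counts.items():
            rows.append({"stage": stage, "participant_id": pid,
                         "task": task, "count": int(n)})
    return pd.DataFrame(rows, columns=["stage", "participant_id", "task", "count"])


# ---------------------------------------------------------------------------
# Task metrics
# ---------------------------------------------------------------------------


def _is_correct(trials: pd.DataFrame) -> pd.Series:
    return trials["response"] == trials["answer"]


def score_task(
    trials: pd.DataFrame,
    metric_id: str,
    cfg: CleaningConfig = CleaningConfig(),
) -> float:
    """Compute one task metric from (cleaned) trials of one participant.

    * ``rcs``: number of correct responses divided by the total response
      time in seconds over responded trials — the average number of correct
      responses per second.  Correct-but-late responses count as correct
      (the metric has no timeliness qualifier); omitted responses contribute
      neither to the numerator nor the denominator (no RT exists).  With
      ``cfg.rcs_literal_product`` the denominator is instead the literal
      product of trial count and total response time.
    * ``mean_correct_rt``: mean RT over correctly answered responded trials.
    * ``object_span``: longest sequence length attempted twice in a row.

    Returns NaN when no scorable trial exists.
    """
    if trials.empty:
        return float("nan")
    if metric_id == "object_span":
        lengths = trials["condition"].str.removeprefix("len").astype(int)
        history = list(zip(lengths, _is_correct(trials)))
        return float(span_score(history))
    responded = trials["rt_ms"].notna()
    correct = _is_correct(trials) & responded
    if metric_id == "rcs":
        total_rt_s = trials.loc[responded, "rt_ms"].sum() / 1000.0
        if total_rt_s <= 0:
            return float("nan")
        denom = total_rt_s
        if cfg.rcs_literal_product:
            denom *= int(responded.sum())
        return float(correct.sum() / denom)
    if metric_id == "mean_correct_rt":
        if correct.sum() == 0:
            return float("nan")
        return float(trials.loc[correct, "rt_ms"].mean())
    raise ValueError(f"unknown metric_id {metric_id!r}")


def _task_accuracy(trials: pd.DataFrame, spec: TaskSpec) -> float:
    """Overall accuracy (fraction of trials answered correctly; omissions on
    response-required trials count as errors, correct rejections on no-go
    trials count as correct)."""
    correct = _is_correct(trials)
    return float(correct.mean()) if len(trials) else float("nan")


def _chance_level(trials: pd.DataFrame, spec: TaskSpec) -> float:
    """Chance accuracy for the strictly-less-than filter.

    Forced-choice tasks: 1 / option count.  Go/no-go tasks have no symmetric
    option count, so chance is the accuracy of the better of the blind
    always-respond / never-respond strategies (max of the target and
    non-target trial shares), equivalent to requiring d' > 0.  Span and
    single-option speeded tasks are not accuracy-filtered.
    """
    if spec.is_span or spec.n_options <= 1:
        return 0.0
    if spec.go_nogo:
        p_target = float((trials["condition"] == "target").mean())
        return max(p_target, 1.0 - p_target)
    return 1.0 / spec.n_options


# ---------------------------------------------------------------------------
# Score-level filters
# ---------------------------------------------------------------------------


def validity_filter(
    scores: pd.Series,
    condition_counts: Dict[str, Dict[str, int]],
    accuracies: Dict[str, float],
    chance: Dict[str, float],
    cfg: CleaningConfig = CleaningConfig(),
) -> Tuple[pd.Series, List[str]]:
    """Drop scores failing the min-trials or chance-accuracy rules.

    ``scores`` is one task's score per participant; ``condition_counts``
    maps participant -> condition -> retained trial count.  A score is
    dropped when any condition retains fewer than ``min_trials_per_condition``
    trials or accuracy is strictly below chance (exactly-at-chance scores are
    retained).  Returns the filtered series and the dropped participant ids.
    """
    dropped = []
    out = scores.copy()
    for pid in scores.index:
        if pd.isna(scores[pid]):
            continue
        counts = condition_counts.get(pid, {})
        too_few = any(n < cfg.min_trials_per_condition for n in counts.values()) \
            or not counts
        below_chance = accuracies.get(pid, 1.0) < chance.get(pid, 0.0)
        if too_few or below_chance:
            out[pid] = np.nan
            dropped.append(pid)
    return out, dropped


def mad_outlier_filter(
    scores: pd.Series,
    cfg: CleaningConfig = CleaningConfig(),
) -> pd.Series:
    """Keep mask for the +/- k MAD score-outlier rule.

    Drops x with ``|x - median| > mad_k * MAD * scale_constant``; missing
    values are kept (they carry no evidence).  A zero MAD removes nothing.
    """
    x = scores.astype(float)
    obs = x.dropna()
    if len(obs) < 3:
        return pd.Series(True, index=scores.index)
    med = float(obs.median())
    mad = float((obs - med).abs().median())
    if mad == 0:
        return pd.Series(True, index=scores.index)
    thresh = cfg.mad_k * mad * cfg.mad_scale_constant
    keep = (x - med).abs() <= thresh
    return keep | x.isna()


def residualize(
    scores: pd.Series,
    covariate: pd.Series,
) -> pd.Series:
    """Residuals of a least-squares simple regression of score on covariate.

    Computed on pairwise-complete rows; residuals have zero sample
    correlation with the covariate by the normal equations.  A constant
    covariate yields centred scores.
    """
    joined = pd.concat([scores.rename("y"), covariate.rename("x")], axis=1)
    ok = joined.notna().all(axis=1)
    out = pd.Series(np.nan, index=scores.index, dtype=float)
    if ok.sum() < 2:
        return out
    y = joined.loc[ok, "y"].to_numpy(float)
    x = joined.loc[ok, "x"].to_numpy(float)
    if np.ptp(x) == 0:
        out[ok] = y - y.mean()
        return out
    slope, intercept = np.polyfit(x, y, 1)
    out[ok] = y - (slope * x + intercept)
    return out


def transform_rt_metric(x):
    """Orient a mean-RT metric: multiply by -1 and divide by 100.

    Faster (smaller RT) maps to a higher score; the division tempers the
    variance of millisecond-scale metrics relative to the unit-scale ones.
    """
    return -np.asarray(x, dtype=float) / 100.0


def screen_participants(
    metadata: pd.DataFrame,
    high_risk_cols: Optional[Sequence[str]] = None,
    moderate_risk_cols: Optional[Sequence[str]] = None,
    moderate_threshold: int = 4,
) -> pd.DataFrame:
    """Bad-actor screening from boolean risk-indicator flags.

    A participant is excluded when any high-risk indicator is present, or
    when the count of moderate-risk indicators reaches ``moderate_threshold``
    (default >= 4).  Flag columns default to those prefixed ``high_risk``
    and ``moderate_risk``.  Returns a frame with ``keep`` and ``reason``.
    """
    if high_risk_cols is None:
        high_risk_cols = [c for c in metadata.columns if c.startswith("high_risk")]
    if moderate_risk_cols is None:
        moderate_risk_cols = [c for c in metadata.columns
                              if c.startswith("moderate_risk")]
    high = metadata[list(high_risk_cols)].fillna(False).astype(bool) \
        if high_risk_cols else pd.DataFrame(index=metadata.index)
    mod = metadata[list(moderate_risk_cols)].fillna(False).astype(bool) \
        if moderate_risk_cols else pd.DataFrame(index=metadata.index)
    any_high = high.any(axis=1) if not high.empty else pd.Series(False, index=metadata.index)
    n_mod = mod.sum(axis=1) if not mod.empty else pd.Series(0, index=metadata.index)
    keep = ~(any_high | (n_mod >= moderate_threshold))
    reason = np.where(
        any_high, "high_risk_indicator",
        np.where(n_mod >= moderate_threshold,
                 f">={moderate_threshold}_moderate_risk_indicators", ""),
    )
    return pd.DataFrame({"keep": keep, "reason": reason}, index=metadata.index)


# ---------------------------------------------------------------------------
# Test-retest reliability
# ---------------------------------------------------------------------------


def icc(session1: pd.Series, session2: pd.Series) -> ICCResult:
    """ICC between two assessment sessions of the same participants.

    Two-way random effects, absolute agreement, single measures — ICC(2,1)
    in the Shrout–Fleiss taxonomy, ICC(A,1) in McGraw–Wong — computed from
    the two-way ANOVA mean squares on complete pairs:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with k = 2 sessions.  The p-value tests ICC = 0 via F = MSR / MSE on
    (n-1, (n-1)(k-1)) degrees of freedom.
    """
    pair = pd.concat([pd.Series(session1).rename("s1"),
                      pd.Series(session2).rename("s2")], axis=1).dropna()
    n = len(pair)
    if n < 3:
        raise ValueError("ICC requires at least 3 complete pairs")
    x = pair.to_numpy(float)
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    est = (msr - mse) / denom if denom > 0 else float("nan")
    f = msr / mse if mse > 0 else float("inf")
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(stats.f.sf(f, df1, df2))
    return ICCResult(icc=float(est), model="ICC(2,1) absolute agreement",
                     f_stat=float(f), df1=df1, df2=df2, p_value=p)


# ---------------------------------------------------------------------------
# Pipeline: trials -> score table
# ---------------------------------------------------------------------------

_METRIC_UNITS = {"rcs": "correct/s", "mean_correct_rt": "ms", "object_span": "items"}


def build_score_table(
    trials: pd.DataFrame,
    battery: Dict[str, TaskSpec],
    cfg: CleaningConfig = CleaningConfig(),
    session: Optional[int] = None,
) -> ScoreTable:
    """Run the full cleaning/scoring pipeline for one session of trials.

    Stage order: anticipatory trim -> individual-SD trim -> task metrics ->
    min-trials / chance-accuracy filter -> +/- k MAD score outliers.
    """
    if session is not None:
        trials = trials.loc[trials["session"] == session]
    cleaned, tally = clean_trials(trials, cfg)
    participants = sorted(trials["participant_id"].unique())
    data: Dict[str, pd.Series] = {}
    removal_rows = [] if tally.empty else tally.to_dict("records")
    for task_id, spec in battery.items():
        sub = cleaned.loc[cleaned["task"] == task_id]
        scores = {}
        counts: Dict[str, Dict[str, int]] = {}
        accs: Dict[str, float] = {}
        chance: Dict[str, float] = {}
        for pid, tsub in sub.groupby("participant_id"):
            scores[pid] = score_task(tsub, spec.metric_id, cfg)
            counts[pid] = tsub.groupby("condition").size().to_dict()
            accs[pid] = _task_accuracy(tsub, spec)
            chance[pid] = _chance_level(tsub, spec)
        col = pd.Series(scores, dtype=float).reindex(participants)
        if not spec.is_span:
            col, dropped = validity_filter(col, counts, accs, chance, cfg)
            removal_rows += [
                {"stage": "validity", "participant_id": pid, "task": task_id,
                 "count": 1} for pid in dropped
            ]
        keep = mad_outlier_filter(col, cfg)
        removal_rows += [
            {"stage": "mad_outlier", "participant_id": pid, "task": task_id,
             "count": 1} for pid in col.index[~keep]
        ]
        col = col.where(keep)
        data[task_id] = col
    table = pd.DataFrame(data, index=participants)
    units = {t: _METRIC_UNITS[battery[t].metric_id] for t in battery}
    removals = pd.DataFrame(
        removal_rows, columns=["stage", "participant_id", "task", "count"]
    )
    return ScoreTable(data=table, units=units, removals=removals)


def basic_rt_covariates(
    trials: pd.DataFrame,
    metadata: Optional[pd.DataFrame] = None,
    cfg: CleaningConfig = CleaningConfig(),
) -> pd.DataFrame:
    """Per-participant basic-RT means used as processing-speed covariates.

    ``two_hand`` is the mean correct RT across both hand blocks; ``dominant``
    is the mean for the dominant hand (from metadata; right assumed when
    unknown).  Computed on cleaned basic-RT trials.
    """
    cleaned, _ = clean_trials(trials.loc[trials["task"] == "basic_rt"], cfg)
    correct = cleaned.loc[(cleaned["response"] == cleaned["answer"])
                          & cleaned["rt_ms"].notna()]
    rows = {}
    for pid, sub in correct.groupby("participant_id"):
        hand = "right"
        if metadata is not None and pid in metadata.index and \
                "dominant_hand" in metadata.columns:
            hand = str(metadata.loc[pid, "dominant_hand"])
        dom = sub.loc[sub["condition"] == hand, "rt_ms"]
        rows[pid] = {
            "two_hand": float(sub["rt_ms"].mean()),
            "dominant": float(dom.mean()) if len(dom) else float(sub["rt_ms"].mean()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def prepare_scores(
    table: ScoreTable,
    battery: Dict[str, TaskSpec],
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Analysis-ready score matrix: orient RT metrics, then residualise.

    Mean-correct-RT metrics are first transformed by ``-x/100`` so higher is
    better; every task score is then residualised on the hand-appropriate
    basic-RT mean (two-hand vs dominant, per the task's response mode).
    The basic-RT column itself is dropped — it is the covariate.
    """
    out = {}
    for task_id, spec in battery.items():
        if task_id == "basic_rt" or task_id not in table.data.columns:
            continue
        col = table.data[task_id].astype(float)
        if spec.metric_id == "mean_correct_rt":
            col = pd.Series(transform_rt_metric(col), index=col.index)
        cov_col = "two_hand" if spec.rt_control == "two_hand" else "dominant"
        cov = covariates[cov_col].reindex(col.index) if cov_col in covariates.columns \
            else pd.Series(np.nan, index=col.index)
        out[task_id] = residualize(col, cov)
    return pd.DataFrame(out, index=table.data.index)
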