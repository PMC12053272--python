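"""Trial-schedule generation and task controllers for the eleven paradigms.

The battery comprises one processing-speed task (``basic_rt``), two spatial
span tasks (``span_fwd``, ``span_bwd``), six inhibitory-control tasks
(``flanker``, ``cpt_impulsive``, ``cpt_sustained``, ``stroop``, ``boxed``,
``compass``) and two cognitive-flexibility tasks (``taskswitch``,
``tap_trace``).  Stimulus content is represented by opaque tokens — only
condition labels and correctness matter downstream.

Schedules are lists of :class:`TrialTemplate`; condition proportions within a
block are honoured *exactly* via largest-remainder rounding, and block orders
are fixed (Boxed: feature-4, feature-12, conjunction-4, conjunction-12;
Tap & Trace: tap then dual; Basic RT: right hand then left hand).

Span tasks are driven by a length staircase instead of a schedule: sequence
length starts at 3 and advances by 1 after two successful recalls in a row
(capped at 9); three consecutive failures terminate the task.  A variant
advancement rule ("three correct, allow one miss") is selectable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engine import (
    NO_RESPONSE,
    Feedback,
    ResponseWindowState,
    TrialRecord,
    classify_response,
    update_window,
)

__all__ = [
    "Block",
    "TaskSpec",
    "TrialTemplate",
    "SpanState",
    "TASK_IDS",
    "default_battery",
    "make_schedule",
    "span_next",
    "span_score",
    "administer_task",
]

TASK_IDS = (
    "basic_rt",
    "span_fwd",
    "span_bwd",
    "flanker",
    "cpt_impulsive",
    "cpt_sustained",
    "stroop",
    "boxed",
    "compass",
    "taskswitch",
    "tap_trace",
)


@dataclass(frozen=True)
class Block:
    """One block of trials with fixed condition proportions."""

    label: str
    n_trials: int
    proportions: Dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"block '{self.label}': condition proportions sum to {total}, not 1"
            )
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")


@dataclass(frozen=True)
class TaskSpec:
    """Static description of one task paradigm.

    ``metric_id`` selects the scored outcome: ``rcs`` (rate correct score,
    correct responses per second), ``mean_correct_rt`` (ms) or
    ``object_span``.  ``rt_control`` names the processing-speed covariate
    used at residualisation (two-hand vs dominant-hand basic RT mean).
    ``go_nogo`` tasks require a response only on target trials; for adaptive
    go/no-go tasks the window updates on target trials only.
    """

    task_id: str
    metric_id: str
    blocks: Tuple[Block, ...]
    adaptive: bool = True
    n_options: int = 2
    go_nogo: bool = False
    rt_control: str = "two_hand"  # or "dominant_hand"
    is_span: bool = False
    advancement_rule: str = "two_in_a_row"
    max_sequences: int = 40

    def __post_init__(self) -> None:
        if self.task_id in ("cpt_impulsive", "cpt_sustained") and self.adaptive:
            raise ValueError("continuous-performance tasks are non-adaptive")
        if self.metric_id not in ("rcs", "mean_correct_rt", "object_span"):
            raise ValueError(f"unknown metric_id {self.metric_id!r}")

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)


@dataclass(frozen=True)
class TrialTemplate:
    """One planned trial: condition label plus opaque stimulus/answer tokens."""

    task_id: str
    trial_index: int
    block: str
    condition: str
    stimulus: str
    answer: str
    options: Tuple[str, ...]
    is_target: bool = True
    span_length: Optional[int] = None


def default_battery(
    overrides: Optional[Dict[str, dict]] = None,
    advancement_rule: str = "two_in_a_row",
) -> Dict[str, TaskSpec]:
    """The default eleven-task battery.

    Per-block trial counts are package defaults sized for 5–10 minute tasks;
    every count and proportion can be overridden per task via ``overrides``
    (a mapping task_id -> field overrides, as produced by the battery config
    reader in :mod:`efbattery.workbench`).
    """
    b = Block
    specs = {
        "basic_rt": TaskSpec(
            "basic_rt", "mean_correct_rt",
            (b("right", 20, {"right": 1.0}), b("left", 20, {"left": 1.0})),
            adaptive=True, n_options=1, rt_control="dominant_hand",
        ),
        "span_fwd": TaskSpec(
            "span_fwd", "object_span", (), adaptive=False, n_options=2,
            rt_control="dominant_hand", is_span=True,
            advancement_rule=advancement_rule,
        ),
        "span_bwd": TaskSpec(
            "span_bwd", "object_span", (), adaptive=False, n_options=2,
            rt_control="dominant_hand", is_span=True,
            advancement_rule=advancement_rule,
        ),
        "flanker": TaskSpec(
            "flanker", "rcs",
            (b("main", 40, {"congruent": 0.5, "incongruent": 0.5}),),
            n_options=2,
        ),
        "cpt_impulsive": TaskSpec(
            "cpt_impulsive", "mean_correct_rt",
            (b("main", 50, {"target": 0.8, "distractor": 0.2}),),
            adaptive=False, n_options=2, go_nogo=True,
            rt_control="dominant_hand",
        ),
        "cpt_sustained": TaskSpec(
            "cpt_sustained", "mean_correct_rt",
            (b("main", 50, {"target": 0.2, "distractor": 0.8}),),
            adaptive=False, n_options=2, go_nogo=True,
            rt_control="dominant_hand",
        ),
        "stroop": TaskSpec(
            "stroop", "rcs",
            (b("main", 48, {"congruent": 0.5, "incongruent": 0.5}),),
            n_options=4,
        ),
        "boxed": TaskSpec(
            "boxed", "rcs",
            (
                b("feature_4", 16, {"feature_4": 1.0}),
                b("feature_12", 16, {"feature_12": 1.0}),
                b("conjunction_4", 16, {"conjunction_4": 1.0}),
                b("conjunction_12", 16, {"conjunction_12": 1.0}),
            ),
            n_options=2,
        ),
        "compass": TaskSpec(
            "compass", "rcs",
            (b("main", 48, {"neutral": 1 / 3, "congruent": 1 / 3,
                            "incongruent": 1 / 3}),),
            n_options=2,
        ),
        "taskswitch": TaskSpec(
            "taskswitch", "rcs",
            (b("main", 48, {"stay": 0.5, "switch": 0.5}),),
            n_options=2,
        ),
        "tap_trace": TaskSpec(
            "tap_trace", "mean_correct_rt",
            (
                b("tap", 30, {"target": 0.8, "distractor": 0.2}),
                b("dual", 30, {"target": 0.8, "distractor": 0.2}),
            ),
            go_nogo=True, rt_control="dominant_hand",
        ),
    }
    if overrides:
        for task_id, kv in overrides.items():
            if task_id not in specs:
                raise KeyError(f"unknown task_id {task_id!r}")
            spec = specs[task_id]
            if "blocks" in kv:
                kv = dict(kv)
                kv["blocks"] = tuple(
                    Block(bl["label"], int(bl["n_trials"]),
                          dict(bl["proportions"]))
                    for bl in kv["blocks"]
                )
            specs[task_id] = dataclasses.replace(spec, **kv)
    return specs


def _largest_remainder_counts(proportions: Dict[str, float], n: int) -> Dict[str, int]:
    labels = list(proportions)
    exact = {c: proportions[c] * n for c in labels}
    counts = {c: math.floor(exact[c]) for c in labels}
    short = n - sum(counts.values())
    # distribute the remainder by descending fractional part, stable in
    # declaration order on ties
    order = sorted(labels, key=lambda c: -(exact[c] - counts[c]))
    for c in order[:short]:
        counts[c] += 1
    return counts


def make_schedule(spec: TaskSpec, rng: np.random.Generator) -> List[TrialTemplate]:
    """Generate the ordered trial templates for a (non-span) task.

    Within each block the realised condition counts match the declared
    proportions exactly (largest-remainder rounding); trial order within a
    block is a seeded permutation.  Span tasks have no fixed schedule — their
    trials are generated adaptively by :func:`administer_task` — so an empty
    list is returned.
    """
    if spec.is_span:
        return []
    templates: List[TrialTemplate] = []
    idx = 0
    for block in spec.blocks:
        counts = _largest_remainder_counts(block.proportions, block.n_trials)
        conditions: List[str] = []
        for label, k in counts.items():
            conditions.extend([label] * k)
        conditions = [conditions[i] for i in rng.permutation(len(conditions))]
        for cond in conditions:
            if spec.go_nogo:
                is_target = cond == "target"
                # on no-go trials the correct "response" is withholding
                answer = "press" if is_target else NO_RESPONSE
                options = ("press", "none")
            else:
                is_target = True
                k = int(rng.integers(spec.n_options))
                options = tuple(f"opt{j}" for j in range(spec.n_options))
                answer = options[k]
            templates.append(
                TrialTemplate(
                    task_id=spec.task_id,
                    trial_index=idx,
                    block=block.label,
                    condition=cond,
                    stimulus=f"{block.label}:{cond}:{idx}",
                    answer=answer,
                    options=options,
                    is_target=is_target,
                )
            )
            idx += 1
    return templates


# ---------------------------------------------------------------------------
# Span-task length staircase
# ---------------------------------------------------------------------------

SPAN_MIN, SPAN_MAX = 3, 9


@dataclass(frozen=True)
class SpanState:
    """State of the sequence-length staircase for the span tasks."""

    current_length: int = SPAN_MIN
    consecutive_successes: int = 0
    consecutive_failures: int = 0
    successes_at_length: int = 0
    failures_at_length: int = 0
    history: Tuple[Tuple[int, bool], ...] = ()
    terminated: bool = False
    advancement_rule: str = "two_in_a_row"

    def __post_init__(self) -> None:
        if not SPAN_MIN <= self.current_length <= SPAN_MAX:
            raise ValueError("sequence length must stay within 3..9")
        if self.advancement_rule not in ("two_in_a_row", "three_correct_allow_one_miss"):
            raise ValueError(f"unknown advancement_rule {self.advancement_rule!r}")


def span_next(state: SpanState, trial_success: bool) -> SpanState:
    """Advance the span staircase by one attempted sequence.

    Under ``two_in_a_row``, two consecutive successes at a length raise the
    length by one (capped at 9, where the task simply continues); under
    ``three_correct_allow_one_miss`` the length is raised once three recalls
    at the current length succeed with at most one interleaved miss.  Either
    way, three consecutive failed recalls terminate the task.
    """
    if state.terminated:
        raise ValueError("span task already terminated")
    history = state.history + ((state.current_length, trial_success),)
    if not trial_success:
        cf = state.consecutive_failures + 1
        return dataclasses.replace(
            state,
            history=history,
            consecutive_successes=0,
            consecutive_failures=cf,
            failures_at_length=state.failures_at_length + 1,
            terminated=cf >= 3,
        )
    cs = state.consecutive_successes + 1
    sal = state.successes_at_length + 1
    if state.advancement_rule == "two_in_a_row":
        advance = cs >= 2
    else:
        advance = sal >= 3 and state.failures_at_length <= 1
    if advance:
        return dataclasses.replace(
            state,
            history=history,
            current_length=min(state.current_length + 1, SPAN_MAX),
            consecutive_successes=0,
            consecutive_failures=0,
            successes_at_length=0,
            failures_at_length=0,
        )
    return dataclasses.replace(
        state,
        history=history,
        consecutive_successes=cs,
        consecutive_failures=0,
        successes_at_length=sal,
    )


def span_score(history: Sequence[Tuple[int, bool]]) -> int:
    """Object span: longest length attempted on two consecutive trials."""
    if not history:
        raise ValueError("empty span history")
    best = 0
    for (l1, _), (l2, _) in zip(history, history[1:]):
        if l1 == l2:
            best = max(best, l1)
    if best == 0:
        # a single attempt at each length: fall back to the shortest length,
        # which is always attempted at least twice in practice (the staircase
        # repeats a length until advancement or termination)
        best = min(l for l, _ in history)
    return best


# ---------------------------------------------------------------------------
# Task administration
# ---------------------------------------------------------------------------

Responder = Callable[[TrialTemplate, float, np.random.Generator],
                     Tuple[str, Optional[float]]]


def administer_task(
    spec: TaskSpec,
    responder: Responder,
    rng: np.random.Generator,
    *,
    participant_id: str = "p0",
    session: int = 1,
    init_window: Optional[ResponseWindowState] = None,
) -> List[TrialRecord]:
    """Administer one task to one respondent, returning its trial records.

    ``responder(template, window_ms, rng)`` returns ``(response_token,
    rt_ms)`` with ``rt_ms is None`` iff the response is omitted.  Adaptive
    tasks thread the response-window staircase through
    :func:`efbattery.engine.update_window`; for adaptive go/no-go tasks only
    target trials update the window.  Non-adaptive tasks record
    ``Feedback.NOT_APPLICABLE`` and a constant window.
    """
    if spec.is_span:
        return _administer_span(spec, responder, rng,
                                participant_id=participant_id, session=session)
    state = init_window or ResponseWindowState(window_ms=1500.0)
    records: List[TrialRecord] = []
    for tpl in make_schedule(spec, rng):
        response, rt = responder(tpl, state.window_ms, rng)
        if spec.go_nogo and not tpl.is_target:
            # no-go trial: correct rejection has no RT and no colour feedback
            fb = Feedback.NOT_APPLICABLE if response == NO_RESPONSE else Feedback.RED
            if not spec.adaptive:
                fb = Feedback.NOT_APPLICABLE
        elif not spec.adaptive:
            fb = Feedback.NOT_APPLICABLE
        else:
            fb = classify_response(response, tpl.answer, rt, state.window_ms)
        records.append(
            TrialRecord(
                participant_id=participant_id,
                session=session,
                task=spec.task_id,
                condition=tpl.condition,
                trial=tpl.trial_index,
                stimulus=tpl.stimulus,
                answer=tpl.answer,
                response=response,
                rt_ms=rt,
                window_ms=state.window_ms,
                feedback=fb,
            )
        )
        if spec.adaptive and fb is not Feedback.NOT_APPLICABLE and (
            not spec.go_nogo or tpl.is_target
        ):
            state = update_window(state, fb)
    return records


def _administer_span(
    spec: TaskSpec,
    responder: Responder,
    rng: np.random.Generator,
    *,
    participant_id: str,
    session: int,
) -> List[TrialRecord]:
    state = SpanState(advancement_rule=spec.advancement_rule)
    records: List[TrialRecord] = []
    idx = 0
    while not state.terminated and idx < spec.max_sequences:
        tpl = TrialTemplate(
            task_id=spec.task_id,
            trial_index=idx,
            block="main",
            condition=f"len{state.current_length}",
            stimulus=f"seq:{state.current_length}:{idx}",
            answer="correct",
            options=("correct", "incorrect"),
            span_length=state.current_length,
        )
        response, rt = responder(tpl, float("inf"), rng)
        success = response == "correct"
        records.append(
            TrialRecord(
                participant_id=participant_id,
                session=session,
                task=spec.task_id,
                condition=tpl.condition,
                trial=idx,
                stimulus=tpl.stimulus,
                answer=tpl.answer,
                response=response,
                rt_ms=rt,
                window_ms=0.0,
                feedback=Feedback.NOT_APPLICABLE,
            )
        )
        state = span_next(state, success)
        idx += 1
    return records
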