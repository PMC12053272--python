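"""Closed-loop adaptive response-window staircase.

Most tasks in the battery share one adaptive mechanism: each trial must be
answered both correctly and within a response window (a per-trial deadline).
After every trial the window shrinks or grows:

* correct and on time  -> window decreases by ``step_down * 2**c`` ms, where
  ``c`` is the number of *previous* consecutive correct-and-on-time trials;
* incorrect or late    -> window increases by ``step_up * 2**l`` ms, where
  ``l`` is the number of *previous* consecutive incorrect-or-late trials.

With the default 10 ms down / 40 ms up asymmetry and streak scaling disabled,
the window drifts to the point where the probability of a correct-and-on-time
response balances the two step sizes, i.e. the long-run on-time rate converges
to ``step_up / (step_up + step_down)`` = 0.8.

Trial feedback is tri-colour: GREEN (correct, on time), YELLOW (correct but
late), RED (incorrect).  Late responses feed the lapse streak because the
increment rule groups "incorrect or late".
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np

__all__ = [
    "Feedback",
    "NO_RESPONSE",
    "ResponseWindowState",
    "TrialRecord",
    "classify_response",
    "update_window",
    "run_staircase",
    "equilibrium_rate",
]

#: Sentinel token for an omitted response.
NO_RESPONSE = "NO_RESPONSE"


class Feedback(str, enum.Enum):
    """Tri-colour per-trial feedback class."""

    GREEN = "green"    #: correct and on time
    YELLOW = "yellow"  #: correct but late
    RED = "red"        #: incorrect (or omitted on a response-required trial)
    NOT_APPLICABLE = "na"  #: task has no adaptive window (e.g. go/no-go)

    def __str__(self) -> str:  # CSV-friendly
        return self.value


@dataclass(frozen=True)
class ResponseWindowState:
    """State of the adaptive response window between trials.

    Parameters
    ----------
    window_ms : float
        Current response window in milliseconds.
    step_down_ms, step_up_ms : float
        Base decrement (default 10) and increment (default 40) in ms.
    consec_correct, consec_lapse : int
        Streak counters of *previous* consecutive green / non-green trials.
        At most one of them is nonzero; both are zero only at initialisation.
    min_ms, max_ms : float
        Clamp bounds of the window; clamping never resets streaks.
    streak_scaling : bool
        When False the exponent is fixed at zero (constant step sizes).
    exponent_cap : int
        Upper bound on the streak exponent so a single streak cannot jump
        past the clamp range by more than one clamped step (numeric sanity;
        behaviourally invisible given the clamps).
    """

    window_ms: float
    step_down_ms: float = 10.0
    step_up_ms: float = 40.0
    consec_correct: int = 0
    consec_lapse: int = 0
    min_ms: float = 200.0
    max_ms: float = 5000.0
    streak_scaling: bool = True
    exponent_cap: int = 6

    def __post_init__(self) -> None:
        if not (self.min_ms <= self.window_ms <= self.max_ms):
            raise ValueError(
                f"window_ms={self.window_ms} outside clamp bounds "
                f"[{self.min_ms}, {self.max_ms}]"
            )
        if self.step_down_ms <= 0 or self.step_up_ms <= 0:
            raise ValueError("step sizes must be positive")
        if self.consec_correct < 0 or self.consec_lapse < 0:
            raise ValueError("streak counters must be non-negative")
        if self.consec_correct and self.consec_lapse:
            raise ValueError("at most one streak counter may be nonzero")


@dataclass(frozen=True)
class TrialRecord:
    """One administered trial of any task.

    ``rt_ms`` is ``None`` exactly when ``response`` is :data:`NO_RESPONSE`;
    ``feedback`` is :attr:`Feedback.NOT_APPLICABLE` for tasks without an
    adaptive response window.
    """

    participant_id: str
    session: int          # 1-based session index
    task: str
    condition: str
    trial: int            # 0-based within task
    stimulus: str         # opaque token
    answer: str           # correct-answer token
    response: str         # response token or NO_RESPONSE
    rt_ms: Optional[float]
    window_ms: float      # window at presentation
    feedback: Feedback

    def __post_init__(self) -> None:
        if (self.response == NO_RESPONSE) != (self.rt_ms is None):
            raise ValueError("rt_ms must be absent iff response is omitted")


def classify_response(
    response: str,
    correct_answer: str,
    rt_ms: Optional[float],
    window_ms: float,
) -> Feedback:
    """Classify a response as GREEN / YELLOW / RED.

    GREEN iff the response matches the correct answer and lands inside the
    window; YELLOW iff correct but late; RED iff incorrect.  An omitted
    response (``NO_RESPONSE`` / ``rt_ms is None``) on a response-required
    trial is RED: no separate omission class exists for adaptive tasks.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if response == NO_RESPONSE or rt_ms is None:
        return Feedback.RED
    if rt_ms <= 0:
        raise ValueError("rt_ms must be positive")
    if response != correct_answer:
        return Feedback.RED
    return Feedback.GREEN if rt_ms <= window_ms else Feedback.YELLOW


def update_window(state: ResponseWindowState, feedback: Feedback) -> ResponseWindowState:
    """Advance the staircase one trial.

    GREEN shrinks the window by ``step_down * 2**consec_correct`` and extends
    the correct streak; YELLOW and RED both grow it by
    ``step_up * 2**consec_lapse`` and extend the lapse streak (the increment
    rule groups "incorrect or late").  The result is clamped to
    ``[min_ms, max_ms]``; clamping does not reset streaks.  With
    ``streak_scaling`` off the exponents are fixed at zero.
    """
    if feedback is Feedback.NOT_APPLICABLE:
        return state
    if feedback is Feedback.GREEN:
        exp = min(state.consec_correct, state.exponent_cap) if state.streak_scaling else 0
        new_window = state.window_ms - state.step_down_ms * (2.0 ** exp)
        return dataclasses.replace(
            state,
            window_ms=float(np.clip(new_window, state.min_ms, state.max_ms)),
            consec_correct=state.consec_correct + 1,
            consec_lapse=0,
        )
    exp = min(state.consec_lapse, state.exponent_cap) if state.streak_scaling else 0
    new_window = state.window_ms + state.step_up_ms * (2.0 ** exp)
    return dataclasses.replace(
        state,
        window_ms=float(np.clip(new_window, state.min_ms, state.max_ms)),
        consec_lapse=state.consec_lapse + 1,
        consec_correct=0,
    )


def run_staircase(
    rt_sampler: Callable[[np.random.Generator], tuple],
    n_trials: int,
    init: ResponseWindowState,
    rng: np.random.Generator,
) -> list:
    """Run the staircase against a stochastic respondent.

    ``rt_sampler(rng)`` must return ``(rt_ms, is_correct)`` for one trial.
    Returns the length-``n_trials`` trajectory of
    ``(window_ms_at_presentation, Feedback)`` tuples; bit-reproducible for a
    fixed ``rng`` state.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    state = init
    trajectory = []
    for _ in range(n_trials):
        rt, is_correct = rt_sampler(rng)
        if rt is not None and rt <= 0:
            raise ValueError("rt_sampler yielded a non-positive RT")
        if rt is None or not is_correct:
            fb = Feedback.RED
        elif rt <= state.window_ms:
            fb = Feedback.GREEN
        else:
            fb = Feedback.YELLOW
        trajectory.append((state.window_ms, fb))
        state = update_window(state, fb)
    return trajectory


def equilibrium_rate(step_down: float, step_up: float) -> float:
    """Stationary GREEN rate of the staircase with streak scaling off.

    At equilibrium the expected window drift is zero:
    ``p * step_down = (1 - p) * step_up``, hence
    ``p = step_up / (step_down + step_up)``.
    """
    if step_down <= 0 or step_up <= 0:
        raise ValueError("step sizes must be positive")
    return step_up / (step_down + step_up)
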