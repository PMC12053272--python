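"""Shared fixtures and independent reference implementations.

The reference implementations here are deliberately naive (brute force,
spreadsheet-style arithmetic) and independent of the package's code paths;
they serve as oracles for the fast implementations under test.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import pytest

from efbattery.cohort import default_cohort_model


@pytest.fixture(scope="session")
def cohort_model():
    return default_cohort_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Exact-moment data: sample mean and (ML) covariance match targets exactly
# ---------------------------------------------------------------------------


def exact_moment_data(mu: np.ndarray, sigma: np.ndarray, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Data whose sample mean/ML-covariance equal (mu, sigma) to rounding."""
    p = len(mu)
    z = rng.standard_normal((n, p))
    z -= z.mean(axis=0)
    s = z.T @ z / n
    w = np.linalg.cholesky(s)
    white = np.linalg.solve(w, z.T).T          # exact identity covariance
    return white @ np.linalg.cholesky(sigma).T + mu


# ---------------------------------------------------------------------------
# Brute-force span-task reference simulator
# ---------------------------------------------------------------------------


def reference_span_run(outcomes: Sequence[bool], rule: str
                       ) -> Tuple[List[Tuple[int, bool]], bool]:
    """Replay a success/failure string through a naive span controller.

    Returns the (length, success) history actually consumed and whether the
    task terminated within the string.  Literal transcription of the rules:
    start at 3; `two_in_a_row`: two consecutive successes raise the length
    (cap 9); `three_correct_allow_one_miss`: advance once three recalls at
    the length succeed with at most one miss so far at that length; three
    consecutive failures terminate.
    """
    length = 3
    consec_s = consec_f = 0
    s_at = f_at = 0
    history: List[Tuple[int, bool]] = []
    for ok in outcomes:
        history.append((length, ok))
        if ok:
            consec_s += 1
            consec_f = 0
            s_at += 1
            if rule == "two_in_a_row":
                advance = consec_s >= 2
            else:
                advance = s_at >= 3 and f_at <= 1
            if advance:
                length = min(length + 1, 9)
                consec_s = consec_f = 0
                s_at = f_at = 0
        else:
            consec_f += 1
            consec_s = 0
            f_at += 1
            if consec_f >= 3:
                return history, True
    return history, False


def reference_object_span(history: Sequence[Tuple[int, bool]]) -> int:
    """Brute-force scan over all consecutive pairs of attempts."""
    best = 0
    for a, b in zip(history, history[1:]):
        if a[0] == b[0]:
            best = max(best, a[0])
    if best == 0:
        best = min(l for l, _ in history)
    return best


# ---------------------------------------------------------------------------
# Spreadsheet-style scoring oracle
# ---------------------------------------------------------------------------


def reference_rcs(rows: Sequence[Tuple[str, str, float]]) -> float:
    """(answer, response, rt_ms) triples -> correct responses per second."""
    n_correct = sum(1 for ans, resp, rt in rows
                    if rt is not None and resp == ans)
    total_s = sum(rt for _, _, rt in rows if rt is not None) / 1000.0
    return n_correct / total_s


def make_trials(rows, task="flanker", participant="p0", session=1):
    """Build a minimal trial frame from (answer, response, rt_ms[, condition])."""
    recs = []
    for i, row in enumerate(rows):
        ans, resp, rt = row[:3]
        cond = row[3] if len(row) > 3 else "main"
        recs.append({
            "participant_id": participant, "session": session, "task": task,
            "condition": cond, "trial": i, "stimulus": f"s{i}",
            "answer": ans, "response": resp, "rt_ms": rt,
            "window_ms": 1000.0, "feedback": "na",
        })
    return pd.DataFrame(recs)
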