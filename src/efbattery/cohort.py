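"""Generative virtual-respondent model and cohort sampler.

Validation analyses downstream (network estimation, community detection,
factor models, invariance, test-retest reliability) assume data with a known
statistical structure.  This module plants that structure:

* ten scored task metrics share a sparse latent precision matrix ``K`` whose
  partial correlations form three communities (set reconfiguration,
  attentional control, interference resolution) plus a handful of bridge
  edges — seventeen nonzero edges in the default model;
* two age groups (younger / older adults) differ in latent means and scales
  while their edges are identical, giving the invariance pipeline a planted
  true-positive/true-negative pair;
* abilities are stable across sessions with correlation ``r_tt``;
* a comparator battery measures the same abilities attenuated by
  ``lambda_cv``, so the true concurrent correlation is known by construction;
* trial-level behaviour is lognormal RTs with anticipations and lapses, and
  a logistic span-capacity model, calibrated (``data/calibration.yaml``) so
  summary metrics land in published ranges for comparable tasks.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .battery import TaskSpec, TrialTemplate, administer_task, default_battery
from .engine import NO_RESPONSE, TrialRecord

__all__ = [
    "METRICS",
    "DEFAULT_COMMUNITIES",
    "DEFAULT_BRIDGES",
    "CohortModel",
    "RespondentProfile",
    "load_calibration",
    "planted_precision",
    "default_cohort_model",
    "sample_cohort",
    "sample_scores",
    "respond",
    "make_responder",
    "simulate_sessions",
    "session_score_pairs",
    "comparator_battery",
]

#: The ten scored task metrics.  Basic response time is a covariate, not a
#: network variable, so it does not appear here.
METRICS = (
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

DEFAULT_COMMUNITIES: Dict[str, Tuple[str, ...]] = {
    "set_reconfiguration": ("span_fwd", "span_bwd", "taskswitch"),
    "attentional_control": ("cpt_impulsive", "cpt_sustained"),
    "interference_resolution": ("flanker", "stroop", "boxed", "compass", "tap_trace"),
}

#: Bridge edges crossing community boundaries (eight of them, so the default
#: network carries 9 within-community + 8 bridge = 17 nonzero edges).
DEFAULT_BRIDGES: Tuple[Tuple[str, str], ...] = (
    ("taskswitch", "cpt_impulsive"),
    ("taskswitch", "flanker"),
    ("taskswitch", "tap_trace"),
    ("tap_trace", "cpt_sustained"),
    ("boxed", "span_bwd"),
    ("boxed", "cpt_sustained"),
    ("compass", "cpt_impulsive"),
    ("stroop", "span_fwd"),
)


def load_calibration(path: Optional[str] = None) -> dict:
    """Load the trait-to-metric calibration constants (YAML)."""
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    ref = importlib.resources.files("efbattery") / "data" / "calibration.yaml"
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


@dataclass(frozen=True)
class CohortModel:
    """Population model for a simulated cohort.

    ``K`` is the latent precision matrix over the ten task metrics; partial
    correlations are ``-K_ij / sqrt(K_ii K_jj)``.  ``group_params`` maps a
    group label to ``(mean_shift, scale)`` applied to every latent ability;
    edges are identical across groups by construction.
    """

    variables: Tuple[str, ...]
    K: pd.DataFrame
    communities: Dict[str, Tuple[str, ...]]
    group_params: Dict[str, Tuple[float, float]]
    r_tt: float = 0.70
    lambda_cv: float = 0.45
    calibration: dict = field(default_factory=load_calibration, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_tt <= 1.0:
            raise ValueError("r_tt must lie in [0, 1]")
        if not 0.0 <= self.lambda_cv <= 1.0:
            raise ValueError("lambda_cv must lie in [0, 1]")
        for _, scale in self.group_params.values():
            if scale <= 0:
                raise ValueError("group scales must be positive")

    def partial_correlations(self) -> pd.DataFrame:
        K = self.K.to_numpy()
        d = np.sqrt(np.diag(K))
        omega = -K / np.outer(d, d)
        np.fill_diagonal(omega, 0.0)
        return pd.DataFrame(omega, index=self.variables, columns=self.variables)

    def latent_covariance(self, group: str) -> np.ndarray:
        _, scale = self.group_params[group]
        sigma = np.linalg.inv(self.K.to_numpy())
        return (scale ** 2) * sigma


@dataclass
class RespondentProfile:
    """One virtual respondent: latent abilities plus nuisance parameters."""

    participant_id: str
    group: str
    age: float
    eta: Dict[str, float]          # per-metric latent ability (z scale)
    t0_ms: float                   # non-decision RT floor
    sigma: float                   # lognormal RT spread
    lapse: float                   # probability of an attention lapse
    anticipatory: float            # probability of an anticipatory response
    span_capacity: Dict[str, float]
    dominant_hand: str = "right"


def planted_precision(
    variables: Sequence[str],
    communities: Dict[str, Sequence[str]],
    within_pc: float,
    between_pc: float,
    bridge_edges: Sequence[Tuple[str, str]],
) -> pd.DataFrame:
    """Build a precision matrix with planted partial correlations.

    Within each community the variables are joined on a ring (a 2-variable
    community gets its single edge) at partial correlation ``within_pc``;
    listed bridge edges get ``between_pc``; all other partial correlations
    are exactly zero.  With unit diagonal, ``K = I - Omega`` reproduces the
    target partial correlations exactly; positive definiteness is checked
    and a violation reported with the offending eigenvalue.
    """
    variables = list(variables)
    seen: set = set()
    for name, members in communities.items():
        for m in members:
            if m not in variables:
                raise ValueError(f"community {name!r} member {m!r} not a variable")
            if m in seen:
                raise ValueError(f"variable {m!r} assigned to two communities")
            seen.add(m)
    if seen != set(variables):
        raise ValueError("communities must partition the variable list")

    idx = {v: i for i, v in enumerate(variables)}
    p = len(variables)
    omega = np.zeros((p, p))

    def set_edge(a: str, b: str, w: float) -> None:
        i, j = idx[a], idx[b]
        if i == j:
            raise ValueError("self edges are not allowed")
        omega[i, j] = omega[j, i] = w

    for members in communities.values():
        members = list(members)
        if len(members) == 2:
            set_edge(members[0], members[1], within_pc)
        elif len(members) > 2:
            for a, b in zip(members, members[1:] + members[:1]):
                set_edge(a, b, within_pc)
    for a, b in bridge_edges:
        set_edge(a, b, between_pc)

    K = np.eye(p) - omega
    eigmin = float(np.linalg.eigvalsh(K).min())
    if eigmin <= 1e-10:
        raise ValueError(
            f"planted structure is not positive definite "
            f"(smallest eigenvalue {eigmin:.3e}); reduce the partial correlations"
        )
    return pd.DataFrame(K, index=variables, columns=variables)


def default_cohort_model(
    within_pc: float = 0.30,
    between_pc: float = 0.10,
    calibration: Optional[dict] = None,
) -> CohortModel:
    """The default planted-3-community cohort model (17 nonzero edges)."""
    cal = calibration or load_calibration()
    K = planted_precision(METRICS, DEFAULT_COMMUNITIES, within_pc, between_pc,
                          DEFAULT_BRIDGES)
    groups = {
        name: (float(g["mean_shift"]), float(g["scale"]))
        for name, g in cal["groups"].items()
    }
    return CohortModel(
        variables=tuple(METRICS),
        K=K,
        communities={k: tuple(v) for k, v in DEFAULT_COMMUNITIES.items()},
        group_params=groups,
        r_tt=float(cal["test_retest_r"]),
        lambda_cv=float(cal["concurrent_r"]),
        calibration=cal,
    )


def _uniform(rng: np.random.Generator, lo_hi: Sequence[float]) -> float:
    return float(rng.uniform(lo_hi[0], lo_hi[1]))


def sample_cohort(
    model: CohortModel,
    n: int,
    rng: np.random.Generator,
    group_split: float = 0.5,
) -> List[RespondentProfile]:
    """Sample ``n`` respondents; ``group_split`` is the younger-group share."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cal = model.calibration
    groups = list(model.group_params)
    n_first = int(round(group_split * n))
    labels = [groups[0]] * n_first + [groups[1 % len(groups)]] * (n - n_first)
    chol = {g: np.linalg.cholesky(model.latent_covariance(g)) for g in groups}
    ranges = cal["nuisance_ranges"]
    kbase = cal["span_capacity_base"]
    kslope = float(cal["span_capacity_per_sd"])
    profiles: List[RespondentProfile] = []
    for i, group in enumerate(labels):
        shift, _ = model.group_params[group]
        z = rng.standard_normal(len(model.variables))
        eta_vec = shift + chol[group] @ z
        eta = dict(zip(model.variables, map(float, eta_vec)))
        age_lo, age_hi = cal["groups"][group]["age_range"]
        profiles.append(
            RespondentProfile(
                participant_id=f"p{i:05d}",
                group=group,
                age=float(rng.uniform(age_lo, age_hi)),
                eta=eta,
                t0_ms=_uniform(rng, ranges["t0_ms"]),
                sigma=_uniform(rng, ranges["sigma"]),
                lapse=_uniform(rng, ranges["lapse"]),
                anticipatory=_uniform(rng, ranges["anticipatory"]),
                span_capacity={
                    t: float(kbase[t]) + kslope * eta[t]
                    for t in ("span_fwd", "span_bwd")
                },
                dominant_hand="right" if rng.uniform() < 0.9 else "left",
            )
        )
    return profiles


def sample_scores(
    model: CohortModel,
    n: int,
    rng: np.random.Generator,
    group_split: float = 0.5,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Sample latent ability scores directly (no trial noise).

    Returns the n x 10 score table and the group label per row.  This is the
    analysis-level shortcut used by structure-recovery and calibration
    simulations; the trial-level route goes through :func:`sample_cohort` +
    :func:`make_responder`.
    """
    profiles = sample_cohort(model, n, rng, group_split)
    data = pd.DataFrame(
        [[p.eta[v] for v in model.variables] for p in profiles],
        columns=list(model.variables),
        index=[p.participant_id for p in profiles],
    )
    groups = pd.Series([p.group for p in profiles], index=data.index, name="group")
    return data, groups


# ---------------------------------------------------------------------------
# Trial-level response model
# ---------------------------------------------------------------------------


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _task_cal(cal: dict, task_id: str) -> dict:
    return cal["tasks"][task_id]


def _draw_rt(profile: RespondentProfile, tcal: dict, condition: str,
             eta: float, cal: dict, rng: np.random.Generator) -> float:
    cost = float(tcal.get("condition_costs", {}).get(condition, 0.0))
    mu = float(tcal["rt_logmedian"]) + cost - float(cal["rt_ability_slope"]) * eta
    return profile.t0_ms + float(np.exp(rng.normal(mu, profile.sigma)))


def respond(
    profile: RespondentProfile,
    template: TrialTemplate,
    window_ms: float,
    rng: np.random.Generator,
    calibration: Optional[dict] = None,
) -> Tuple[str, Optional[float]]:
    """Generate one response ``(token, rt_ms)`` for a trial template.

    With probability ``anticipatory`` the response is a guess with an RT
    uniform on the anticipatory range (below the 200 ms cleaning cutoff).
    Otherwise RT is ``t0 + LogNormal(median + condition_cost - slope*eta,
    sigma)`` and accuracy is ``(1 - lapse) * logistic(slope*eta + logit)``.
    Span trials succeed with probability
    ``logistic(span_slope * (capacity - length))``.
    """
    cal = calibration or load_calibration()
    task = template.task_id
    tcal = _task_cal(cal, task)
    eta = profile.eta.get(task, 0.0)

    if template.span_length is not None:
        p_ok = _logistic(float(cal["span_slope"])
                         * (profile.span_capacity[task] - template.span_length))
        ok = rng.uniform() < p_ok
        rt = max(1.0, template.span_length * 350.0 + float(rng.normal(0.0, 80.0)))
        return ("correct" if ok else "incorrect", rt)

    if rng.uniform() < profile.anticipatory:
        rt = _uniform(rng, cal["anticipatory_rt_range"])
        if template.options == ("press", "none"):
            return "press", rt
        return str(template.options[rng.integers(len(template.options))]), rt

    if template.options == ("press", "none"):  # go/no-go
        if template.is_target:
            p_hit = (1.0 - profile.lapse) * _logistic(
                float(cal["accuracy_slope"]) * eta + float(tcal["accuracy_logit"])
            )
            if rng.uniform() < p_hit:
                return "press", _draw_rt(profile, tcal, template.condition, eta, cal, rng)
            return NO_RESPONSE, None
        p_cr = (1.0 - profile.lapse) * _logistic(
            float(cal["accuracy_slope"]) * eta + float(tcal.get("nogo_logit", 1.5))
        )
        if rng.uniform() < p_cr:
            return NO_RESPONSE, None
        return "press", _draw_rt(profile, tcal, template.condition, eta, cal, rng)

    # forced-choice tasks (including basic_rt with a single option)
    logit = float(tcal["accuracy_logit"]) + float(
        tcal.get("condition_logits", {}).get(template.condition, 0.0)
    )
    p_correct = (1.0 - profile.lapse) * _logistic(
        float(cal["accuracy_slope"]) * eta + logit
    )
    rt = _draw_rt(profile, tcal, template.condition, eta, cal, rng)
    if len(template.options) == 1 or rng.uniform() < p_correct:
        return template.answer, rt
    wrong = [o for o in template.options if o != template.answer]
    return str(wrong[rng.integers(len(wrong))]), rt


def make_responder(profile: RespondentProfile, calibration: Optional[dict] = None):
    """Bind a profile (and calibration) into a battery responder callable."""
    cal = calibration or load_calibration()

    def responder(template: TrialTemplate, window_ms: float,
                  rng: np.random.Generator) -> Tuple[str, Optional[float]]:
        return respond(profile, template, window_ms, rng, cal)

    return responder


def simulate_sessions(
    profile: RespondentProfile,
    battery: Dict[str, TaskSpec],
    k_sessions: int,
    r_tt: float,
    rng: np.random.Generator,
    calibration: Optional[dict] = None,
) -> Dict[int, List[TrialRecord]]:
    """Administer the battery over ``k_sessions`` repeated sessions.

    Session ``s > 1`` abilities are ``r_tt * eta_1 + sqrt(1 - r_tt^2) * z``
    with fresh standard-normal ``z``, so the induced score-level test-retest
    correlation approaches ``r_tt`` as trial noise vanishes.
    """
    if not 0.0 <= r_tt <= 1.0:
        raise ValueError("r_tt must lie in [0, 1]")
    if k_sessions < 1:
        raise ValueError("k_sessions must be >= 1")
    cal = calibration or load_calibration()
    kbase = cal["span_capacity_base"]
    kslope = float(cal["span_capacity_per_sd"])
    sessions: Dict[int, List[TrialRecord]] = {}
    for s in range(1, k_sessions + 1):
        if s == 1:
            prof_s = profile
        else:
            eta_s = {
                t: r_tt * v + float(np.sqrt(1.0 - r_tt ** 2)) * float(rng.standard_normal())
                for t, v in profile.eta.items()
            }
            prof_s = dataclasses.replace(
                profile,
                eta=eta_s,
                span_capacity={
                    t: float(kbase[t]) + kslope * eta_s[t]
                    for t in ("span_fwd", "span_bwd")
                },
            )
        responder = make_responder(prof_s, cal)
        records: List[TrialRecord] = []
        for task_id in TASK_ORDER:
            if task_id not in battery:
                continue
            records.extend(
                administer_task(
                    battery[task_id], responder, rng,
                    participant_id=profile.participant_id, session=s,
                )
            )
        sessions[s] = records
    return sessions


TASK_ORDER = (
    "basic_rt", "span_fwd", "span_bwd", "flanker", "cpt_impulsive",
    "cpt_sustained", "stroop", "boxed", "compass", "taskswitch", "tap_trace",
)


def session_score_pairs(
    n: int,
    r_tt: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Score-level test-retest pairs for reliability simulations.

    Session-1 scores are standard normal abilities plus measurement noise of
    standard deviation ``noise_sd``; session-2 abilities are the stability-
    attenuated abilities plus independent noise.  The population ICC is
    ``r_tt / (1 + noise_sd^2)``.
    """
    if not 0.0 <= r_tt <= 1.0:
        raise ValueError("r_tt must lie in [0, 1]")
    eta1 = rng.standard_normal(n)
    eta2 = r_tt * eta1 + np.sqrt(1.0 - r_tt ** 2) * rng.standard_normal(n)
    s1 = eta1 + noise_sd * rng.standard_normal(n)
    s2 = eta2 + noise_sd * rng.standard_normal(n)
    return s1, s2


def comparator_battery(
    profile: RespondentProfile,
    rng: np.random.Generator,
    lambda_cv: float = 0.45,
) -> Dict[str, float]:
    """Comparator-suite scores measuring the same latent abilities.

    Score for metric ``j`` is ``lambda_cv * eta_j + sqrt(1 - lambda_cv^2) *
    noise`` so the population concurrent correlation equals ``lambda_cv`` by
    construction.
    """
    if not 0.0 <= lambda_cv <= 1.0:
        raise ValueError("lambda_cv must lie in [0, 1]")
    noise_scale = float(np.sqrt(1.0 - lambda_cv ** 2))
    return {
        t: lambda_cv * v + noise_scale * float(rng.standard_normal())
        for t, v in profile.eta.items()
    }
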