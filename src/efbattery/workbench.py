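"""Configuration, I/O and end-to-end study orchestration.

Runs the full "validation study at desk scale": simulate a cohort, administer
the battery, clean and score, residualise and transform, screen participants,
then (per analysis toggles) the test-retest ICC table, the pruned network
with communities / bootstrap / centrality, the factor-model comparison, the
multigroup invariance ladder and the concurrent-validity correlations.
Everything is driven by one integer seed fanned out deterministically to
per-stage child seeds, and the emitted bundle (CSV + JSON with a manifest)
is byte-identical across runs with the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .battery import TaskSpec, default_battery
from .cfa import FactorModel, compare_models, default_pattern
from .cohort import (
    CohortModel,
    comparator_battery,
    default_cohort_model,
    load_calibration,
    make_responder,
    sample_cohort,
    simulate_sessions,
)
from .engine import NO_RESPONSE
from .network import (
    GaussianGraphicalModel,
    bootstrap_edges,
    centrality,
    concurrent_correlations,
    invariance_ladder,
    spinglass_communities,
)
from .scoring import (
    TRIAL_COLUMNS,
    CleaningConfig,
    ScoreTable,
    basic_rt_covariates,
    build_score_table,
    icc,
    prepare_scores,
    records_to_frame,
    screen_participants,
)

__all__ = [
    "RunConfig",
    "read_config",
    "read_trials",
    "write_trials",
    "read_scores",
    "write_scores",
    "simulate_study_data",
    "run_validation_study",
]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """One study run: sizes, cohort parameters, cleaning rules, toggles."""

    seed: int = 0
    n_validation: int = 240
    n_retest: int = 60
    n_concurrent: int = 80
    group_split: float = 0.5
    within_pc: float = 0.30
    between_pc: float = 0.10
    r_tt: float = 0.70
    lambda_cv: float = 0.45
    prune_alpha: float = 0.05
    n_boot: int = 200
    spinglass_reps: int = 250
    advancement_rule: str = "two_in_a_row"
    battery_overrides: Dict[str, dict] = field(default_factory=dict)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    analyses: Dict[str, bool] = field(default_factory=lambda: {
        "icc": True, "network": True, "communities": True, "bootstrap": True,
        "cfa": True, "invariance": True, "concurrent": True,
    })

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the global seed."""
        order = ("cohort", "administration", "retest", "comparator",
                 "bootstrap", "spinglass", "cfa", "flags")
        if stage not in order:
            raise KeyError(f"unknown stage {stage!r}")
        child = np.random.SeedSequence(self.seed).spawn(len(order))
        return np.random.default_rng(child[order.index(stage)])


def read_config(path: str) -> RunConfig:
    """Read a YAML run configuration (unknown keys rejected)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    raw.pop("schema_version", None)
    cleaning = raw.pop("cleaning", None)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if cleaning:
        cfg.cleaning = CleaningConfig(**cleaning)
    return cfg


# ---------------------------------------------------------------------------
# Pinned CSV formats
# ---------------------------------------------------------------------------


def write_trials(trials: pd.DataFrame, path: str) -> None:
    """Write the trial log (UTF-8, header row, empty field = missing)."""
    out = trials.copy()
    out["response"] = out["response"].replace(NO_RESPONSE, "")
    out.to_csv(path, index=False, na_rep="", encoding="utf-8",
               lineterminator="\n")


def read_trials(path: str) -> pd.DataFrame:
    """Read a trial log, validating columns and numeric fields.

    Missing required columns and malformed numeric rows are rejected with
    the column name / 1-based line number; parsing is locale-independent
    (plain ``float()`` on the pinned decimal-point format).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing required column(s): {missing}")
    df = df[list(TRIAL_COLUMNS)]
    for col, kind in (("session", int), ("trial", int),
                      ("rt_ms", float), ("window_ms", float)):
        vals = []
        for i, raw in enumerate(df[col]):
            raw = raw.strip()
            if raw == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(kind(float(raw)) if kind is int else float(raw))
            except ValueError as exc:
                raise ValueError(
                    f"malformed value {raw!r} in column {col!r} at line {i + 2}"
                ) from exc
        df[col] = vals
    df["response"] = df["response"].replace("", NO_RESPONSE)
    df["session"] = df["session"].astype(int)
    df["trial"] = df["trial"].astype(int)
    return df


def write_scores(table: pd.DataFrame, path: str) -> None:
    """Write a participant x metric score matrix (wide CSV)."""
    table.sort_index().to_csv(path, index=True, index_label="participant_id",
                              na_rep="", encoding="utf-8", lineterminator="\n")


def read_scores(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    if "participant_id" not in df.columns:
        raise ValueError("scores file missing required column 'participant_id'")
    return df.set_index("participant_id")


def _write_json(obj, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Simulation stages
# ---------------------------------------------------------------------------


def _risk_flags(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic bad-actor indicator flags for the screening stage."""
    return pd.DataFrame({
        "high_risk_location": rng.uniform(size=n) < 0.02,
        "high_risk_shared_ip": rng.uniform(size=n) < 0.01,
        "high_risk_disposable_email": rng.uniform(size=n) < 0.01,
        **{f"moderate_risk_{k}": rng.uniform(size=n) < 0.05
           for k in ("age_mismatch", "zip_mismatch", "speeding",
                     "straightlining", "duplicate_device")},
    })


def simulate_study_data(
    config: RunConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, CohortModel, Dict[str, TaskSpec]]:
    """Simulate the validation-arm cohort: trials + participant metadata."""
    model = default_cohort_model(config.within_pc, config.between_pc)
    model = dataclasses.replace(model, r_tt=config.r_tt,
                                lambda_cv=config.lambda_cv)
    battery = default_battery(config.battery_overrides,
                              advancement_rule=config.advancement_rule)
    rng_cohort = config.stage_rng("cohort")
    profiles = sample_cohort(model, config.n_validation, rng_cohort,
                             config.group_split)
    flags = _risk_flags(config.n_validation, config.stage_rng("flags"))
    meta = pd.DataFrame({
        "participant_id": [p.participant_id for p in profiles],
        "group": [p.group for p in profiles],
        "age": [round(p.age, 1) for p in profiles],
        "dominant_hand": [p.dominant_hand for p in profiles],
    }).set_index("participant_id")
    meta = pd.concat([meta, flags.set_index(meta.index)], axis=1)

    rng_admin = config.stage_rng("administration")
    cal = model.calibration
    frames = []
    for profile in profiles:
        responder = make_responder(profile, cal)
        from .cohort import TASK_ORDER
        records = []
        for task_id in TASK_ORDER:
            from .battery import administer_task
            records.extend(administer_task(
                battery[task_id], responder, rng_admin,
                participant_id=profile.participant_id, session=1))
        frames.append(records_to_frame(records))
    trials = pd.concat(frames, ignore_index=True)
    return trials, meta, model, battery


# ---------------------------------------------------------------------------
# End-to-end study
# ---------------------------------------------------------------------------


def run_validation_study(config: RunConfig, outdir: str) -> Dict[str, str]:
    """Run the full simulated validation study and write the report bundle.

    Returns a manifest mapping artifact names to file paths.  Stage
    failures are caught; the bundle is written with whatever completed plus
    a failure manifest.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: Dict[str, str] = {}
    failures: Dict[str, str] = {}

    def emit_csv(name: str, df: pd.DataFrame, **kw) -> None:
        path = os.path.join(outdir, f"{name}.csv")
        df.to_csv(path, na_rep="", encoding="utf-8", lineterminator="\n", **kw)
        paths[name] = path

    # --- simulate, clean, score -----------------------------------------
    trials, meta, model, battery = simulate_study_data(config)
    write_trials(trials, os.path.join(outdir, "trials.csv"))
    paths["trials"] = os.path.join(outdir, "trials.csv")
    emit_csv("participants", meta.sort_index(), index=True,
             index_label="participant_id")

    screened = screen_participants(meta)
    emit_csv("screening", screened.sort_index(), index=True,
             index_label="participant_id")
    kept = screened.index[screened["keep"]]
    trials_kept = trials.loc[trials["participant_id"].isin(kept)]

    table = build_score_table(trials_kept, battery, config.cleaning)
    covs = basic_rt_covariates(trials_kept, meta, config.cleaning)
    prepared = prepare_scores(table, battery, covs)
    write_scores(table.data, os.path.join(outdir, "scores_raw.csv"))
    paths["scores_raw"] = os.path.join(outdir, "scores_raw.csv")
    write_scores(prepared, os.path.join(outdir, "scores_prepared.csv"))
    paths["scores_prepared"] = os.path.join(outdir, "scores_prepared.csv")
    emit_csv("removals", table.removals, index=False)

    groups = meta.loc[prepared.index, "group"]
    analyses = config.analyses

    # --- test-retest arm --------------------------------------------------
    if analyses.get("icc", True):
        try:
            rng = config.stage_rng("retest")
            cohort_rng = np.random.default_rng(rng.integers(2 ** 31))
            retest_profiles = sample_cohort(model, config.n_retest, cohort_rng,
                                            config.group_split)
            frames = []
            for prof in retest_profiles:
                sessions = simulate_sessions(prof, battery, 2, config.r_tt,
                                             rng, model.calibration)
                for recs in sessions.values():
                    frames.append(records_to_frame(recs))
            retest_trials = pd.concat(frames, ignore_index=True)
            t1 = build_score_table(retest_trials, battery, config.cleaning, session=1)
            t2 = build_score_table(retest_trials, battery, config.cleaning, session=2)
            rows = []
            for task in battery:
                try:
                    res = icc(t1.data[task], t2.data[task])
                    rows.append({"task": task, "icc": res.icc,
                                 "p_value": res.p_value, "quality": res.quality})
                except ValueError:
                    rows.append({"task": task, "icc": np.nan,
                                 "p_value": np.nan, "quality": ""})
            emit_csv("icc_table", pd.DataFrame(rows), index=False)
        except Exception as exc:  # pragma: no cover - failure manifest path
            failures["icc"] = repr(exc)

    # --- network arm ------------------------------------------------------
    pruned = None
    if analyses.get("network", True):
        try:
            ggm = GaussianGraphicalModel(prepared)
            pruned = ggm.fit().prune_and_refit(alpha=config.prune_alpha)
            emit_csv("network_edges", pruned.edge_list(), index=False)
            emit_csv("network_adjacency",
                     (pruned.omega() * pruned.mask).round(10), index=True)
            _write_json(pruned.fit_indices().as_dict(),
                        os.path.join(outdir, "network_fit.json"))
            paths["network_fit"] = os.path.join(outdir, "network_fit.json")
            emit_csv("centrality", centrality(pruned).round(10), index=True)
        except Exception as exc:
            failures["network"] = repr(exc)

    if pruned is not None and analyses.get("communities", True):
        try:
            part = spinglass_communities(pruned, n_reps=config.spinglass_reps,
                                         rng=config.stage_rng("spinglass"))
            emit_csv("communities", pd.DataFrame({
                "task": list(part.labels),
                "community": list(part.labels.values()),
            }), index=False)
            _write_json({"selection_frequency": part.frequency,
                         "n_reps": part.n_reps},
                        os.path.join(outdir, "communities_meta.json"))
            paths["communities_meta"] = os.path.join(outdir, "communities_meta.json")
        except Exception as exc:
            failures["communities"] = repr(exc)

    if analyses.get("bootstrap", True):
        try:
            boot = bootstrap_edges(prepared.dropna(), n_boot=config.n_boot,
                                   alpha=config.prune_alpha,
                                   rng=config.stage_rng("bootstrap"))
            emit_csv("bootstrap_edges", boot.round(10), index=False)
        except Exception as exc:
            failures["bootstrap"] = repr(exc)

    # --- factor-model comparison -----------------------------------------
    if analyses.get("cfa", True):
        try:
            complete = prepared.dropna()
            fits = {}
            if pruned is not None:
                ggm_c = GaussianGraphicalModel(complete)
                fits["network"] = ggm_c.fit().prune_and_refit(config.prune_alpha)
            cfa3 = FactorModel(complete, default_pattern(), kind="correlated").fit()
            bif = FactorModel(complete, default_pattern(), kind="bifactor").fit()
            fits["correlated_3factor"] = cfa3
            fits["bifactor"] = bif
            emit_csv("model_comparison", compare_models(fits).round(6), index=True)
            emit_csv("factor_loadings", pd.concat(
                {"correlated_3factor": cfa3.loadings,
                 "bifactor": bif.loadings}, axis=1).round(6), index=True)
            _write_json({"bifactor_warnings": bif.warnings,
                         "correlated_warnings": cfa3.warnings},
                        os.path.join(outdir, "cfa_warnings.json"))
            paths["cfa_warnings"] = os.path.join(outdir, "cfa_warnings.json")
        except Exception as exc:
            failures["cfa"] = repr(exc)

    # --- invariance -------------------------------------------------------
    if analyses.get("invariance", True):
        try:
            inv = invariance_ladder(prepared, groups, alpha=config.prune_alpha)
            emit_csv("invariance", inv.table.round(6), index=True)
            _write_json({"preferred_by_lrt": inv.preferred_by_lrt,
                         "preferred_by_aic": inv.preferred_by_aic,
                         "preferred_by_bic": inv.preferred_by_bic,
                         "full_constraint_lrt": inv.full_constraint_lrt},
                        os.path.join(outdir, "invariance_verdict.json"))
            paths["invariance_verdict"] = os.path.join(outdir,
                                                       "invariance_verdict.json")
        except Exception as exc:
            failures["invariance"] = repr(exc)

    # --- concurrent validity ----------------------------------------------
    if analyses.get("concurrent", True):
        try:
            rng = config.stage_rng("comparator")
            sub_model = model
            profiles = sample_cohort(sub_model, config.n_concurrent, rng,
                                     config.group_split)
            own = pd.DataFrame(
                [[p.eta[v] for v in sub_model.variables] for p in profiles],
                columns=list(sub_model.variables),
                index=[p.participant_id for p in profiles])
            comp = pd.DataFrame(
                [comparator_battery(p, rng, config.lambda_cv) for p in profiles],
                index=own.index)
            emit_csv("concurrent", concurrent_correlations(own, comp).round(6),
                     index=False)
        except Exception as exc:
            failures["concurrent"] = repr(exc)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "cleaning"},
        "cleaning": dataclasses.asdict(config.cleaning),
        "artifacts": sorted(os.path.basename(p) for p in paths.values()),
        "failures": failures,
    }
    _write_json(manifest, os.path.join(outdir, "manifest.json"))
    paths["manifest"] = os.path.join(outdir, "manifest.json")
    return paths
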