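"""Cohort simulation, analysis, and calibration orchestration.

``simulate_cohort`` composes the schedule builder, stimulus generator,
agent model and participant model into a tidy trial log;
``analyze`` computes every behavioral index and statistical contrast
from such a log; ``calibrate`` searches generative parameters so the
synthetic cohort hits printed target statistics.  Everything is a pure
function of the run configuration: per-participant random substreams are
spawned from the master seed, so cohort-size changes never perturb
earlier participants' data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agent as agent_mod
from . import metrics
from . import participant as part_mod
from . import stats as stats_mod
from .config import RunConfig
from .design import (
    Condition,
    ConditionOrder,
    Group,
    SessionSchedule,
    TaskKind,
    TurnKind,
    build_session,
)
from .stimuli import generate_stimuli

logger = logging.getLogger(__name__)

__all__ = ["TrialLog", "simulate_cohort", "simulate_participant", "analyze", "calibrate"]

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "condition_order",
    "task",
    "block",
    "condition",
    "turn_kind",
    "trial_index",
    "s",
    "first_disk_offset",
    "participant_estimate",
    "agent_estimate",
    "agent_resampled",
    "influence",
    "interval_index",
    "final_decision",
    "decider",
    "is_final_block",
]

RATING_COLUMNS = [
    "participant_id",
    "group",
    "task",
    "condition",
    "trial_index",
    "self_rating",
    "other_rating",
    "partner_mean_influence",
]


@dataclass
class TrialLog:
    """Cohort trial table plus the ratings table."""

    trials: pd.DataFrame
    ratings: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RATING_COLUMNS))

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.ratings.to_csv(out / "ratings.csv", index=False)

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrialLog":
        out = Path(out_dir)
        trials = pd.read_csv(out / "trials.csv")
        ratings_path = out / "ratings.csv"
        ratings = (
            pd.read_csv(ratings_path)
            if ratings_path.exists()
            else pd.DataFrame(columns=RATING_COLUMNS)
        )
        return cls(trials=trials, ratings=ratings)


def _participant_rng(seed: int, group: Group, index: int) -> np.random.Generator:
    group_key = 0 if group is Group.COMPUTER else 1
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1, group_key, index))
    )


def _cohort_orders(n: int) -> list[ConditionOrder]:
    orders = [ConditionOrder.SUSCEPTIBLE_FIRST, ConditionOrder.UNSUSCEPTIBLE_FIRST]
    return [orders[i % 2] for i in range(n)]


def simulate_participant(
    schedule: SessionSchedule,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one full session (all three tasks) for one participant."""
    agent_params = config.agent.to_params()
    observer = part_mod.Observer(params=config.observer.to_params())
    policy = config.policy.to_params()
    rating_model = config.ratings.to_params()
    # Stable per-participant dispositions in self/other ratings.
    if rating_model.between_subject_sd > 0:
        rating_model.self_rating_base = float(
            np.clip(
                rating_model.self_rating_base
                + rng.normal(0.0, rating_model.between_subject_sd),
                1.0,
                10.0,
            )
        )
        rating_model.other_rating_base = float(
            np.clip(
                rating_model.other_rating_base
                + rng.normal(0.0, rating_model.between_subject_sd),
                1.0,
                10.0,
            )
        )
    base_weber = observer.params.weber_fraction
    group = schedule.group

    direction = (
        "S_TO_U" if schedule.condition_order is ConditionOrder.SUSCEPTIBLE_FIRST else "U_TO_S"
    )
    transition_intervals = agent_mod.transition_schedule(direction)
    transition_cursor = 0
    last_main = schedule.last_main_condition

    # Fresh balanced stimulus sequences per task.
    stim_by_task = {
        TaskKind.PERCEPTUAL_INFERENCE: generate_stimuli(66, rng),
        TaskKind.SOCIAL_INFLUENCE: generate_stimuli(66, rng),
        TaskKind.RECIPROCAL: generate_stimuli(176, rng),
    }

    # Running record of agent influence draws for rating prompts.
    observed_agent_influence: list[float] = []

    trial_rows: list[dict] = []
    rating_rows: list[dict] = []

    for slot in schedule:
        stim = stim_by_task[slot.task][slot.trial_index]
        condition = slot.condition

        # Condition-dependent perceptual-noise modifier (learning effects).
        mod_condition = condition
        if condition in (Condition.TRANSITION, Condition.FINAL):
            mod_condition = last_main if condition is Condition.FINAL else None
        observer.params.weber_fraction = base_weber * config.observer.modifier(
            group, mod_condition
        )

        p_est = part_mod.perceive_and_estimate(stim.s, observer, rng)

        row = {
            "participant_id": schedule.participant_id,
            "group": group.value,
            "condition_order": schedule.condition_order.value,
            "task": slot.task.value,
            "block": slot.block_index,
            "condition": condition.value if condition else "",
            "turn_kind": slot.turn_kind.value,
            "trial_index": slot.trial_index,
            "s": stim.s,
            "first_disk_offset": stim.first_disk_offset,
            "participant_estimate": p_est,
            "agent_estimate": np.nan,
            "agent_resampled": False,
            "influence": np.nan,
            "interval_index": -1,
            "final_decision": np.nan,
            "decider": "participant",
            "is_final_block": condition is Condition.FINAL,
        }

        if slot.turn_kind is not TurnKind.SOLO:
            a_est = agent_mod.agent_estimate(stim.s, p_est, agent_params, rng)
            row["agent_estimate"] = a_est.value
            row["agent_resampled"] = a_est.resampled

            if slot.turn_kind is TurnKind.DECISION:
                nd = metrics.normalized_response_distance(p_est, a_est.value, stim.s)
                policy_condition = condition if condition is not None else Condition.BASELINE
                if condition is Condition.FINAL:
                    policy_condition = last_main
                i = part_mod.decide_influence(
                    nd,
                    group,
                    policy_condition,
                    is_final_block=condition is Condition.FINAL,
                    policy=policy,
                    rng=rng,
                )
                row["influence"] = i
                row["final_decision"] = part_mod.participant_final_decision(
                    p_est, a_est.value, i
                )
            else:  # OBSERVATION: the agent decides.
                if condition is Condition.TRANSITION:
                    lo, hi = transition_intervals[transition_cursor]
                    transition_cursor += 1
                    i = float(rng.uniform(lo, hi))
                    interval_index = transition_cursor - 1
                else:
                    draw = agent_mod.sample_influence(
                        condition, agent_params, rng, last_condition=last_main
                    )
                    i, interval_index = draw.i, draw.interval_index
                row["influence"] = i
                row["interval_index"] = interval_index
                row["final_decision"] = agent_mod.agent_final_decision(
                    a_est.value, p_est, i
                )
                row["decider"] = "agent"
                observed_agent_influence.append(i)

        trial_rows.append(row)

        if slot.rating_prompt:
            if slot.task is TaskKind.PERCEPTUAL_INFERENCE:
                self_r, _ = part_mod.emit_ratings(0.0, rating_model, rng)
                observed, other_r = np.nan, np.nan
            elif slot.task is TaskKind.SOCIAL_INFLUENCE:
                observed = 0.0
                self_r, other_r = part_mod.emit_ratings(observed, rating_model, rng)
            else:
                # Mean agent influence observed since the previous prompt.
                recent = observed_agent_influence[-22:]
                observed = float(np.mean(recent)) if recent else 0.0
                self_r, other_r = part_mod.emit_ratings(observed, rating_model, rng)
            rating_rows.append(
                {
                    "participant_id": schedule.participant_id,
                    "group": group.value,
                    "task": slot.task.value,
                    "condition": condition.value if condition else "",
                    "trial_index": slot.trial_index,
                    "self_rating": self_r,
                    "other_rating": other_r,
                    "partner_mean_influence": observed,
                }
            )

    observer.params.weber_fraction = base_weber
    return pd.DataFrame(trial_rows), pd.DataFrame(rating_rows)


def simulate_cohort(config: RunConfig) -> TrialLog:
    """Simulate the full two-group cohort described by ``config``.

    Condition order alternates within each group (exactly
    counterbalanced for even group sizes; off by one participant for odd
    sizes, matching a 25-per-group design).
    """
    all_trials: list[pd.DataFrame] = []
    all_ratings: list[pd.DataFrame] = []
    for group in (Group.COMPUTER, Group.ROBOT):
        orders = _cohort_orders(config.n_per_group)
        for i, order in enumerate(orders):
            pid = f"{group.value}_{i:03d}"
            schedule = build_session(group, order, pid)
            rng = _participant_rng(config.seed, group, i)
            trials, ratings = simulate_participant(schedule, config, rng)
            all_trials.append(trials)
            all_ratings.append(ratings)
    trials = pd.concat(all_trials, ignore_index=True)[TRIAL_COLUMNS]
    ratings = pd.concat(all_ratings, ignore_index=True)
    if not ratings.empty:
        ratings = ratings[RATING_COLUMNS]
    logger.info(
        "simulated cohort: %d participants, %d trials", 2 * config.n_per_group, len(trials)
    )
    return TrialLog(trials=trials, ratings=ratings)


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

MAIN_CONDITIONS = ("baseline", "susceptible", "unsusceptible")


def participant_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per participant x task x condition with every aggregate index."""
    required = {"participant_id", "group", "task", "condition", "turn_kind", "s",
                "participant_estimate", "agent_estimate", "final_decision", "decider"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    rows = []
    for (pid, group, task, condition), grp in trials.groupby(
        ["participant_id", "group", "task", "condition"], dropna=False
    ):
        err = metrics.estimation_error(
            grp["participant_estimate"].to_numpy(), grp["s"].to_numpy()
        ).mean()
        entry = {
            "participant_id": pid,
            "group": group,
            "task": task,
            "condition": condition if isinstance(condition, str) else "",
            "mean_estimation_error": float(err),
            "n_trials": len(grp),
        }
        if task == TaskKind.PERCEPTUAL_INFERENCE.value:
            entry["regression_index"] = metrics.regression_index(
                grp["s"], grp["participant_estimate"]
            )
            entry["underestimation"] = metrics.underestimation(grp["participant_estimate"])
        decisions = grp[(grp["decider"] == "participant") & grp["final_decision"].notna()]
        if len(decisions):
            infl = [
                metrics.influence_index(r.participant_estimate, r.agent_estimate, r.final_decision)
                for r in decisions.itertuples()
            ]
            valid = [rec.i for rec in infl if rec.valid]
            entry["mean_influence"] = float(np.mean(valid)) if valid else np.nan
            entry["n_valid_influence"] = len(valid)
            nd = metrics.normalized_response_distance(
                decisions["participant_estimate"].to_numpy(),
                decisions["agent_estimate"].to_numpy(),
                decisions["s"].to_numpy(),
            )
            entry["mean_normalized_distance"] = float(np.mean(nd))
        rows.append(entry)
    return pd.DataFrame(rows)


def trial_level_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial-level derived indices for model fitting (participant decisions
    and estimates only)."""
    df = trials.copy()
    df["estimation_error"] = metrics.estimation_error(
        df["participant_estimate"].to_numpy(), df["s"].to_numpy()
    )
    has_agent = df["agent_estimate"].notna()
    df.loc[has_agent, "normalized_distance"] = metrics.normalized_response_distance(
        df.loc[has_agent, "participant_estimate"].to_numpy(),
        df.loc[has_agent, "agent_estimate"].to_numpy(),
        df.loc[has_agent, "s"].to_numpy(),
    )
    decision = (df["decider"] == "participant") & df["final_decision"].notna()
    infl = np.full(len(df), np.nan)
    for idx in np.flatnonzero(decision.to_numpy()):
        rec = metrics.influence_index(
            df["participant_estimate"].iat[idx],
            df["agent_estimate"].iat[idx],
            df["final_decision"].iat[idx],
        )
        infl[idx] = rec.i if rec.valid else np.nan
    df["influence_index"] = infl
    return df


def _relabel(results, mapping):
    out = []
    for res in results:
        term = res.name.split(":", 1)[1]
        if term in mapping:
            res.name = res.name.split(":", 1)[0] + ":" + mapping[term]
            out.append(res)
    return out


def _fit_group_condition_model(
    model_id: int, df: pd.DataFrame, response: str
) -> list[stats_mod.StatResult]:
    """Group x condition random-intercept model reported with per-group
    condition contrasts plus their group interactions (models 3-5)."""
    results: list[stats_mod.StatResult] = []
    base = (
        f"{response} ~ C(group, Treatment('{{g}}'))"
        f" * C(condition, Treatment('{{c}}'))"
    )
    # Reference computer/baseline: computer contrasts + interactions.
    spec = stats_mod.ModelSpec(
        model_id=model_id,
        response=response,
        formula=base.format(g="computer", c="baseline"),
    )
    res_c = stats_mod.fit_random_intercept_model(df, spec)
    mapping_c = {
        "Intercept": "Intercept[Computer,Baseline]",
        "C(condition, Treatment('baseline'))[T.susceptible]": "Susceptible-Baseline[Computer]",
        "C(condition, Treatment('baseline'))[T.unsusceptible]": "Unsusceptible-Baseline[Computer]",
        "C(group, Treatment('computer'))[T.robot]:C(condition, Treatment('baseline'))[T.susceptible]": "Susceptible-Baseline,Robot-Computer",
        "C(group, Treatment('computer'))[T.robot]:C(condition, Treatment('baseline'))[T.unsusceptible]": "Unsusceptible-Baseline,Robot-Computer",
    }
    results += _relabel(res_c, mapping_c)
    # Reference robot/baseline: robot condition contrasts.
    spec = stats_mod.ModelSpec(
        model_id=model_id,
        response=response,
        formula=base.format(g="robot", c="baseline"),
    )
    res_r = stats_mod.fit_random_intercept_model(df, spec)
    mapping_r = {
        "C(condition, Treatment('baseline'))[T.susceptible]": "Susceptible-Baseline[Robot]",
        "C(condition, Treatment('baseline'))[T.unsusceptible]": "Unsusceptible-Baseline[Robot]",
    }
    results += _relabel(res_r, mapping_r)
    return results


def _fit_model5_extra(df: pd.DataFrame) -> list[stats_mod.StatResult]:
    """Susceptible - Unsusceptible contrasts of model 5."""
    results: list[stats_mod.StatResult] = []
    base = (
        "influence_index ~ C(group, Treatment('{g}'))"
        " * C(condition, Treatment('unsusceptible'))"
    )
    for g, label in (("computer", "Computer"), ("robot", "Robot")):
        spec = stats_mod.ModelSpec(model_id=5, response="influence_index", formula=base.format(g=g))
        res = stats_mod.fit_random_intercept_model(df, spec)
        mapping = {
            "C(condition, Treatment('unsusceptible'))[T.susceptible]": f"Susceptible-Unsusceptible[{label}]"
        }
        if g == "computer":
            mapping[
                "C(group, Treatment('computer'))[T.robot]:C(condition, Treatment('unsusceptible'))[T.susceptible]"
            ] = "Susceptible-Unsusceptible,Robot-Computer"
        results += _relabel(res, mapping)
    return results


def run_models(df: pd.DataFrame, ratings: pd.DataFrame | None = None) -> list[stats_mod.StatResult]:
    """Fit analysis models 1-6 on a trial-level table."""
    results: list[stats_mod.StatResult] = []

    # Model 1: influence vs group x distance, joint-task trials.
    social = df[(df["task"] == "social_influence") & df["influence_index"].notna()].copy()
    for g, label in (("computer", "Computer"), ("robot", "Robot")):
        spec = stats_mod.ModelSpec(
            model_id=1,
            response="influence_index",
            formula=f"influence_index ~ C(group, Treatment('{g}')) * normalized_distance",
        )
        res = stats_mod.fit_random_intercept_model(social, spec)
        if g == "computer":
            mapping = {
                "Intercept": "Intercept[Computer]",
                "C(group, Treatment('computer'))[T.robot]": "Robot-Computer",
                "normalized_distance": "distance[Computer]",
                "C(group, Treatment('computer'))[T.robot]:normalized_distance": "distance:Robot-Computer",
            }
        else:
            mapping = {"normalized_distance": "distance[Robot]"}
        results += _relabel(res, mapping)

    # Model 2: rating gap (self - other) vs partner influence, reciprocal prompts.
    if ratings is not None and len(ratings):
        rec = ratings[
            (ratings["task"] == "reciprocal") & ratings["other_rating"].notna()
        ].copy()
        if len(rec) and rec["participant_id"].nunique() >= 2:
            rec["rating_gap"] = rec["self_rating"] - rec["other_rating"]
            rec["partner_influence"] = rec["partner_mean_influence"]
            spec = stats_mod.ModelSpec(
                model_id=2,
                response="rating_gap",
                formula="rating_gap ~ partner_influence",
            )
            res = stats_mod.fit_random_intercept_model(rec, spec)
            results += _relabel(
                res, {"Intercept": "Intercept", "partner_influence": "partner_influence"}
            )

    # Models 3-5: group x condition on error, distance, influence.
    main = df[df["condition"].isin(MAIN_CONDITIONS)].copy()
    results += _fit_group_condition_model(3, main, "estimation_error")
    dist = main[main["normalized_distance"].notna()]
    results += _fit_group_condition_model(4, dist, "normalized_distance")
    infl = main[main["influence_index"].notna()]
    results += _fit_group_condition_model(5, infl, "influence_index")
    results += _fit_model5_extra(infl)

    # Model 6: final block vs the preceding main block, participant decisions.
    recip = df[(df["task"] == "reciprocal") & df["influence_index"].notna()].copy()
    m6 = recip[recip["block"].isin([2, 3])].copy()
    m6["block_kind"] = np.where(m6["block"] == 3, "final", "preceding")
    for g, label in (("computer", "Computer"), ("robot", "Robot")):
        spec = stats_mod.ModelSpec(
            model_id=6,
            response="influence_index",
            formula=(
                f"influence_index ~ C(group, Treatment('{g}'))"
                " * C(block_kind, Treatment('preceding'))"
            ),
        )
        res = stats_mod.fit_random_intercept_model(m6, spec)
        mapping = {
            "C(block_kind, Treatment('preceding'))[T.final]": f"Final-Preceding[{label}]"
        }
        if g == "computer":
            mapping[
                "C(group, Treatment('computer'))[T.robot]:C(block_kind, Treatment('preceding'))[T.final]"
            ] = "Final-Preceding,Robot-Computer"
        results += _relabel(res, mapping)
    return results


def run_nonparametric(summary: pd.DataFrame, ratings: pd.DataFrame) -> list[stats_mod.StatResult]:
    """The direct participant-level contrasts: signed-rank, rank-sum."""
    results: list[stats_mod.StatResult] = []
    perc = summary[summary["task"] == "perceptual_inference"]
    soc = summary[summary["task"] == "social_influence"]

    comp_err = perc[perc["group"] == "computer"]["mean_estimation_error"]
    rob_err = perc[perc["group"] == "robot"]["mean_estimation_error"]
    results.append(
        stats_mod.wilcoxon_rank_sum(rob_err, comp_err, name="error:Robot-Computer(perceptual)")
    )

    for g, label in (("computer", "Computer"), ("robot", "Robot")):
        vals = soc[soc["group"] == g]["mean_influence"].dropna()
        res = stats_mod.wilcoxon_signed_rank(
            vals, mu=0.5, name=f"influence-vs-0.5[{label}]"
        )
        results.append(res)

    comp_inf = soc[soc["group"] == "computer"]["mean_influence"].dropna()
    rob_inf = soc[soc["group"] == "robot"]["mean_influence"].dropna()
    results.append(
        stats_mod.wilcoxon_rank_sum(rob_inf, comp_inf, name="influence:Robot-Computer(social)")
    )
    return results


def analyze(log: TrialLog, run_models_flag: bool = True, run_nonparametric_flag: bool = True) -> dict:
    """Full report bundle: aggregates, bin table, tests, models."""
    df = trial_level_table(log.trials)
    summary = participant_summary(log.trials)

    social = df[(df["task"] == "social_influence") & df["influence_index"].notna()]
    bin_tables = {}
    for g in ("computer", "robot"):
        sub = social[social["group"] == g][
            ["participant_id", "s", "participant_estimate", "agent_estimate", "influence_index"]
        ].rename(columns={"influence_index": "influence"})
        if len(sub):
            bin_tables[g] = metrics.binned_standardized_influence(sub)

    stat_results: list[stats_mod.StatResult] = []
    if run_nonparametric_flag:
        stat_results += run_nonparametric(summary, log.ratings)
    if run_models_flag:
        stat_results += run_models(df, log.ratings)

    spearman_results = {}
    soc_sum = summary[summary["task"] == "social_influence"]
    ratings = log.ratings
    soc_ratings = ratings[ratings["task"] == "social_influence"] if len(ratings) else ratings
    if len(soc_ratings):
        merged = soc_sum.merge(soc_ratings, on=["participant_id", "group"])
        merged["rating_gap"] = merged["self_rating"] - merged["other_rating"]
        for g in ("computer", "robot"):
            sub = merged[merged["group"] == g].dropna(subset=["mean_influence", "rating_gap"])
            if len(sub) >= 4 and sub["rating_gap"].nunique() > 1 and sub["mean_influence"].nunique() > 1:
                rho, p = stats_mod.spearman(sub["rating_gap"], sub["mean_influence"])
                spearman_results[g] = {"rho": rho, "p": p, "n": len(sub)}

    return {
        "trials": df,
        "summary": summary,
        "bin_tables": bin_tables,
        "stat_results": stat_results,
        "spearman": spearman_results,
    }


def save_report(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["summary"].to_csv(out / "participant_summary.csv", index=False)
    for g, table in report["bin_tables"].items():
        table.to_csv(out / f"distance_bins_{g}.csv", index=False)
    stats_frame = pd.DataFrame([r.to_dict() for r in report["stat_results"]])
    stats_frame.to_csv(out / "stat_results.csv", index=False)
    payload = {
        "stat_results": [r.to_dict() for r in report["stat_results"]],
        "spearman": report["spearman"],
    }
    with open(out / "stat_results.json", "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

SUPPORTED_TARGETS = {
    "mean_estimation_error",
    "mean_influence_computer",
    "mean_influence_robot",
    "regression_index",
}

DEFAULT_TARGETS = {
    "mean_estimation_error": (0.20, 0.05),
    "regression_index": (0.46, 0.10),
    "mean_influence_computer": (0.26, 0.13),
    "mean_influence_robot": (0.35, 0.16),
}


def _perceptual_stats(config: RunConfig) -> tuple[float, float]:
    log = simulate_cohort(config)
    perc = participant_summary(
        log.trials[log.trials["task"] == "perceptual_inference"]
    )
    perc = perc[perc["group"] == "computer"]
    return (
        float(perc["mean_estimation_error"].mean()),
        float(perc["regression_index"].mean()),
    )


def _influence_stats(config: RunConfig) -> dict[str, float]:
    log = simulate_cohort(config)
    soc = participant_summary(log.trials[log.trials["task"] == "social_influence"])
    return {
        g: float(soc[soc["group"] == g]["mean_influence"].mean())
        for g in ("computer", "robot")
    }


def calibrate(
    targets: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_per_group: int = 12,
    weber_grid=None,
    prior_sd_grid=None,
    baseline_grid=None,
    base_config: RunConfig | None = None,
) -> tuple[RunConfig, dict[str, float]]:
    """Grid search minimizing squared standardized distance to targets.

    Stage 1 tunes the observer (weber_fraction, prior_sd) against the
    estimation-error and regression-index targets; stage 2 tunes the
    group baselines of the influence policy.  Returns the winning config
    and the achieved statistics.
    """
    targets = dict(DEFAULT_TARGETS if targets is None else targets)
    unknown = set(targets) - SUPPORTED_TARGETS
    if unknown:
        raise ValueError(f"unsupported calibration targets: {sorted(unknown)}")
    config = (base_config or RunConfig()).model_copy(deep=True)
    config.seed = seed
    config.n_per_group = n_per_group

    weber_grid = weber_grid if weber_grid is not None else np.arange(0.16, 0.33, 0.02)
    prior_sd_grid = prior_sd_grid if prior_sd_grid is not None else np.arange(1.8, 4.3, 0.4)
    baseline_grid = baseline_grid if baseline_grid is not None else np.arange(-1.4, 0.41, 0.1)

    achieved: dict[str, float] = {}

    if {"mean_estimation_error", "regression_index"} & set(targets):
        best = (np.inf, None, None)
        for w in weber_grid:
            for psd in prior_sd_grid:
                trial = config.model_copy(deep=True)
                trial.observer.weber_fraction = float(w)
                trial.observer.prior_sd = float(psd)
                err, reg = _perceptual_stats(trial)
                loss = 0.0
                if "mean_estimation_error" in targets:
                    t, sd = targets["mean_estimation_error"]
                    loss += ((err - t) / sd) ** 2
                if "regression_index" in targets:
                    t, sd = targets["regression_index"]
                    loss += ((reg - t) / sd) ** 2
                if loss < best[0]:
                    best = (loss, float(w), float(psd))
        _, w, psd = best
        config.observer.weber_fraction = w
        config.observer.prior_sd = psd
        err, reg = _perceptual_stats(config)
        achieved["mean_estimation_error"] = err
        achieved["regression_index"] = reg

    influence_targets = {
        "computer": targets.get("mean_influence_computer"),
        "robot": targets.get("mean_influence_robot"),
    }
    for g, target in influence_targets.items():
        if target is None:
            continue
        t, sd = target
        best = (np.inf, config.policy.baseline_influence[g])
        for b in baseline_grid:
            trial = config.model_copy(deep=True)
            trial.policy.baseline_influence[g] = float(b)
            got = _influence_stats(trial)[g]
            loss = ((got - t) / sd) ** 2
            if loss < best[0]:
                best = (loss, float(b))
        config.policy.baseline_influence[g] = best[1]
    got = _influence_stats(config)
    for g in ("computer", "robot"):
        if influence_targets[g] is not None:
            achieved[f"mean_influence_{g}"] = got[g]

    return config, achieved
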