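"""Interim-analysis state machine and domain lifecycle.

Each open domain is reviewed approximately every 26 weeks.  The review
follows a gated sequence:

1. *Success* — once at least 100 intervention participants (and 100
   concurrently randomized controls) have completed the 108-week follow-up,
   the intervention stops for success when P(slope contrast > 0) exceeds the
   success threshold (default 0.985).
2. *Futility* — once 100/arm have completed 24 weeks, the UACR surrogate
   gate stops the intervention when P(UACR reduction >= 25%) falls below the
   futility cutoff; once 100/arm have completed 52 weeks, the eGFR gate
   additionally stops it when P(slope > 0.8 mL/min/1.73 m^2 per year) falls
   below the cutoff.
3. Otherwise the domain continues to the next review.

Success is evaluated before futility, so a treatment crossing both
thresholds at the same look is declared successful.  The slope endpoint is
estimated on the week 4-52 window while follow-up is immature and switches
to the full 4-104 chronic window once 100/arm have completed week 104.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, DomainConfig, PlatformConfig
from .cohort import (
    ARM_INTERVENTION,
    ARM_PLACEBO,
    TruthParams,
    simulate_cohort,
)
from .inference import (
    GatedDataError,
    PosteriorSummary,
    fit_slope_posterior,
    fit_uacr_posterior,
    nearest_visit_week,
    prob_exceeds,
    uacr_reduction_probability,
)

DECISION_CONTINUE = "continue"
DECISION_FUTILITY = "stop_futility"
DECISION_SUCCESS = "stop_success"

_ARMS = (ARM_PLACEBO, ARM_INTERVENTION)


@dataclass(frozen=True)
class EligibilityFlags:
    """Gate eligibility at one interim, from completer counts per arm."""

    uacr_futility_eligible: bool
    egfr_futility_eligible: bool
    success_eligible: bool
    completers_24w: dict[str, int] = field(default_factory=dict)
    completers_52w: dict[str, int] = field(default_factory=dict)
    completers_108w: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class InterimRecord:
    interim_index: int
    calendar_week: float
    flags: EligibilityFlags
    uacr_summary: PosteriorSummary | None
    slope_summary: PosteriorSummary | None
    decision: str
    probabilities: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class TrialResult:
    final_decision: str  # success | futility | completed_max_followup
    decision_week: float
    n_randomized: int
    n_intervention: int
    interims: list[InterimRecord]


def count_completers(
    observations: pd.DataFrame,
    calendar_week: float,
    visit_week: float,
    arms: tuple[str, str] = _ARMS,
) -> dict[str, int]:
    """Participants per arm whose week-``visit_week`` visit has occurred.

    A participant completes the visit when the visit survived dropout (a row
    exists) and ``enroll_week + visit_week <= calendar_week``.
    """
    at_visit = observations[
        (observations["week"] == visit_week)
        & (observations["enroll_week"] + visit_week <= calendar_week)
    ]
    return {arm: int((at_visit["arm"] == arm).sum()) for arm in arms}


def _gate_holds(counts: dict[str, int], gate: int) -> bool:
    return bool(counts) and min(counts.values()) >= gate


def compute_flags(
    observations: pd.DataFrame,
    calendar_week: float,
    config: PlatformConfig,
    schedule,
    arms: tuple[str, str] = _ARMS,
) -> EligibilityFlags:
    """Evaluate the three completer gates at a calendar week.

    The nominal 24-week completion maps to the nearest scheduled visit
    within +-4 weeks (week 26 on the default schedule); 52 and 108 map to
    themselves.
    """
    gate = config.completers_gate
    v24 = nearest_visit_week(schedule, 24.0)
    c24 = count_completers(observations, calendar_week, v24, arms)
    c52 = count_completers(observations, calendar_week, 52.0, arms)
    c108 = count_completers(
        observations, calendar_week, float(config.final_visit_week), arms
    )
    return EligibilityFlags(
        uacr_futility_eligible=_gate_holds(c24, gate),
        egfr_futility_eligible=_gate_holds(c52, gate),
        success_eligible=_gate_holds(c108, gate),
        completers_24w=c24,
        completers_52w=c52,
        completers_108w=c108,
    )


def interim_calendar(
    accrual_times,
    schedule,
    config: PlatformConfig,
    n_arms_total: int = 2,
) -> list[float]:
    """Review weeks: every ``interim_interval_weeks`` from first possible gate.

    The first interim is the earliest multiple of the cadence at which any
    eligibility gate *can* hold — i.e. enough participants have been enrolled
    long enough that the earliest completer gate (the 24-week UACR gate)
    could be met.  Reviews continue until the last enrollee reaches the
    final visit; the maximum-follow-up analysis itself is handled by the
    caller.
    """
    times = np.asarray(accrual_times, dtype=float)
    if times.size == 0:
        return []
    v24 = nearest_visit_week(schedule, 24.0)
    needed = config.completers_gate * n_arms_total
    max_followup = float(times.max()) + config.final_visit_week
    step = config.interim_interval_weeks
    cals = np.arange(step, max_followup + step, step, dtype=float)
    cals = cals[cals < max_followup]
    enrolled_by = np.searchsorted(np.sort(times), cals - v24, side="right")
    eligible = enrolled_by >= needed
    if not eligible.any():
        return []
    first = int(np.argmax(eligible))
    return [float(c) for c in cals[first:]]


def interim_decision(
    flags: EligibilityFlags,
    uacr_summary: PosteriorSummary | None,
    slope_summary: PosteriorSummary | None,
    config: PlatformConfig,
    interim_index: int = 0,
    calendar_week: float = 0.0,
    futility_active: bool = True,
) -> InterimRecord:
    """Apply the success-then-futility rule to one interim's posteriors.

    ``futility_active=False`` evaluates the success rule only (used when
    calibrating the success threshold against repeated testing alone).
    """
    if flags.uacr_futility_eligible and uacr_summary is None:
        raise ConfigError("UACR gate eligible but no UACR posterior supplied")
    if (flags.egfr_futility_eligible or flags.success_eligible) and slope_summary is None:
        raise ConfigError("eGFR gate eligible but no slope posterior supplied")

    probabilities: dict[str, float] = {}
    if slope_summary is not None:
        probabilities["p_slope_gt0"] = prob_exceeds(slope_summary, 0.0)
        probabilities["p_slope_gt_margin"] = prob_exceeds(
            slope_summary, config.slope_margin
        )
    if uacr_summary is not None:
        probabilities["p_uacr_reduction_ge_margin"] = uacr_reduction_probability(
            uacr_summary, config.uacr_margin
        )

    decision = DECISION_CONTINUE
    if (
        flags.success_eligible
        and probabilities["p_slope_gt0"] > config.success_threshold
    ):
        decision = DECISION_SUCCESS
    elif futility_active and (
        (
            flags.uacr_futility_eligible
            and probabilities["p_uacr_reduction_ge_margin"]
            < config.futility_prob_cutoff
        )
        or (
            flags.egfr_futility_eligible
            and probabilities["p_slope_gt_margin"] < config.futility_prob_cutoff
        )
    ):
        decision = DECISION_FUTILITY

    return InterimRecord(
        interim_index=interim_index,
        calendar_week=calendar_week,
        flags=flags,
        uacr_summary=uacr_summary,
        slope_summary=slope_summary,
        decision=decision,
        probabilities=probabilities,
    )


def _analysis_at(
    obs: pd.DataFrame,
    calendar_week: float,
    platform: PlatformConfig,
    schedule,
    interim_index: int,
    method: str,
    futility_active: bool = True,
) -> InterimRecord:
    cut = obs[obs["enroll_week"] + obs["week"] <= calendar_week]
    flags = compute_flags(cut, calendar_week, platform, schedule)
    c104 = count_completers(cut, calendar_week, float(platform.treatment_end_week))
    full_window = _gate_holds(c104, platform.completers_gate)
    window = (
        (float(platform.chronic_window_start_week), float(platform.treatment_end_week))
        if full_window
        else (float(platform.chronic_window_start_week), 52.0)
    )
    uacr_summary = None
    if flags.uacr_futility_eligible:
        uacr_summary = fit_uacr_posterior(cut)
    slope_summary = None
    if flags.egfr_futility_eligible or flags.success_eligible:
        slope_summary = fit_slope_posterior(cut, window=window, method=method)
    return interim_decision(
        flags,
        uacr_summary,
        slope_summary,
        platform,
        interim_index,
        calendar_week,
        futility_active=futility_active,
    )


def run_trial(
    domain_config: DomainConfig,
    platform_config: PlatformConfig,
    truth: TruthParams,
    seed,
    method: str = "two_stage",
    disable_interims: bool = False,
    futility_active: bool = True,
    block_size: int | None = None,
) -> TrialResult:
    """Simulate one complete domain: cohort, interim reviews, final analysis.

    ``method`` selects the slope backend passed to the inference layer; the
    analytic two-stage estimator is the default for simulation-scale runs.
    ``disable_interims`` runs a fixed (single final analysis) version of the
    same design, used for calibration references and adaptive-vs-fixed
    comparisons.  Decisions are deterministic given the generated dataset.
    """
    domain_config.validate(platform_config)
    participants, obs = simulate_cohort(
        domain_config, platform_config, truth, seed, block_size=block_size
    )
    if len(participants) == 0:
        raise ConfigError("no participants accrued; cannot run a trial")
    schedule = domain_config.schedule(platform_config)
    enroll = participants["enroll_week"].to_numpy()
    max_followup = float(enroll.max()) + platform_config.final_visit_week

    records: list[InterimRecord] = []
    if not disable_interims:
        for idx, cal in enumerate(
            interim_calendar(enroll, schedule, platform_config), start=1
        ):
            try:
                rec = _analysis_at(
                    obs,
                    cal,
                    platform_config,
                    schedule,
                    idx,
                    method,
                    futility_active=futility_active,
                )
            except GatedDataError:
                continue  # gates held on paper but paired data not yet analyzable
            records.append(rec)
            if rec.decision != DECISION_CONTINUE:
                n_rand = int((enroll <= cal).sum())
                n_int = int(
                    ((enroll <= cal) & (participants["arm"] == ARM_INTERVENTION)).sum()
                )
                return TrialResult(
                    final_decision=(
                        "success" if rec.decision == DECISION_SUCCESS else "futility"
                    ),
                    decision_week=cal,
                    n_randomized=n_rand,
                    n_intervention=n_int,
                    interims=records,
                )

    final = _analysis_at(
        obs,
        max_followup,
        platform_config,
        schedule,
        len(records) + 1,
        method,
        futility_active=futility_active,
    )
    records.append(final)
    n_int = int((participants["arm"] == ARM_INTERVENTION).sum())
    final_map = {
        DECISION_SUCCESS: "success",
        DECISION_FUTILITY: "futility",
        DECISION_CONTINUE: "completed_max_followup",
    }
    return TrialResult(
        final_decision=final_map[final.decision],
        decision_week=max_followup,
        n_randomized=len(participants),
        n_intervention=n_int,
        interims=records,
    )
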