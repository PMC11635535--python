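"""Design constants of the platform master protocol.

The platform evaluates interventions that slow chronic kidney disease (CKD)
progression against placebo under a single master protocol.  Everything the
decision machinery needs to know about the *design* — posterior-probability
thresholds, futility margins, completer gates, visit schedule, interim
cadence — lives in :class:`PlatformConfig` and :class:`DomainConfig`.
Alongside those sit the two clinical primitives used at screening and at
every visit: the 2021 CKD-EPI creatinine equation for the estimated
glomerular filtration rate (eGFR), and the core eligibility screen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

#: Weeks per year used everywhere a week index is annualized.
WEEKS_PER_YEAR = 52.18

#: Two-sided 95% normal quantile used for all credible intervals.
Z_95 = 1.959964


class ConfigError(ValueError):
    """A configuration violated a design invariant or contained unknown keys."""


@dataclass(frozen=True)
class PlatformConfig:
    """Design constants shared by every domain of the platform.

    Parameters
    ----------
    success_threshold:
        Posterior probability of superiority, P(slope contrast > 0), required
        to stop an intervention for success.  The default 0.985 is calibrated
        so that repeated interim testing keeps the one-sided type I error
        below ``alpha_one_sided``.
    futility_prob_cutoff:
        An eligible futility gate stops the intervention when the posterior
        probability of a clinically meaningful benefit falls below this value.
        This is a free design parameter (not derivable from the decision
        thresholds); the default 0.10 stops when a meaningful benefit has
        less than a 10% posterior probability.
    uacr_margin:
        Fractional urinary albumin-to-creatinine ratio (UACR) reduction
        regarded as clinically meaningful (0.25 = 25%).
    slope_margin:
        Chronic eGFR slope improvement, mL/min/1.73 m^2 per year, regarded as
        clinically meaningful.
    completers_gate:
        Participants per arm who must complete the relevant follow-up before
        a gate (futility or success) becomes eligible.
    """

    success_threshold: float = 0.985
    futility_prob_cutoff: float = 0.10
    uacr_margin: float = 0.25
    slope_margin: float = 0.8
    completers_gate: int = 100
    interim_interval_weeks: int = 26
    alpha_one_sided: float = 0.025
    washout_weeks: int = 4
    treatment_end_week: int = 104
    final_visit_week: int = 108
    chronic_window_start_week: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.success_threshold < 1.0:
            raise ConfigError(
                f"success_threshold must lie in (0, 1); got {self.success_threshold}"
            )
        if not 0.0 < self.futility_prob_cutoff < self.success_threshold:
            raise ConfigError(
                "futility_prob_cutoff must lie in (0, success_threshold); "
                f"got {self.futility_prob_cutoff}"
            )
        if not 0.0 < self.uacr_margin < 1.0:
            raise ConfigError(f"uacr_margin must lie in (0, 1); got {self.uacr_margin}")
        if self.slope_margin <= 0:
            raise ConfigError(f"slope_margin must be positive; got {self.slope_margin}")
        if self.completers_gate < 1:
            raise ConfigError("completers_gate must be at least 1")
        if self.interim_interval_weeks < 1:
            raise ConfigError("interim_interval_weeks must be at least 1")
        if not 0.0 < self.alpha_one_sided < 0.5:
            raise ConfigError("alpha_one_sided must lie in (0, 0.5)")
        if not (
            self.chronic_window_start_week
            < self.treatment_end_week
            < self.final_visit_week
        ):
            raise ConfigError(
                "need chronic_window_start_week < treatment_end_week < final_visit_week"
            )
        if self.final_visit_week - self.treatment_end_week != self.washout_weeks:
            raise ConfigError(
                "final_visit_week - treatment_end_week must equal washout_weeks"
            )


@dataclass(frozen=True)
class DomainConfig:
    """One domain: a set of mutually exclusive interventions plus placebo.

    ``n_arms`` counts *intervention* arms; the placebo arm is implicit, so a
    default two-arm domain has ``n_arms = 1``.  ``visit_weeks`` of ``None``
    means "use :func:`default_visit_schedule`".
    """

    name: str = "domain"
    n_arms: int = 1
    max_per_arm: int = 500
    min_egfr: float = 25.0
    accrual_rate: float = 9.6
    visit_weeks: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ConfigError("a domain needs at least one intervention arm")
        if self.max_per_arm < 1:
            raise ConfigError("max_per_arm must be at least 1")
        if self.min_egfr <= 0:
            raise ConfigError("min_egfr must be positive")
        if self.accrual_rate <= 0:
            raise ConfigError("accrual_rate must be positive")

    def schedule(self, platform: PlatformConfig) -> list[int]:
        weeks = (
            list(self.visit_weeks)
            if self.visit_weeks is not None
            else default_visit_schedule(platform)
        )
        validate_schedule(weeks, platform)
        return weeks

    def validate(self, platform: PlatformConfig) -> None:
        if self.max_per_arm < platform.completers_gate:
            raise ConfigError(
                f"max_per_arm ({self.max_per_arm}) must be at least the "
                f"completers gate ({platform.completers_gate})"
            )
        self.schedule(platform)


@dataclass(frozen=True)
class EligibilityCriteria:
    """Core-protocol screening record: eGFR floor plus exclusion flags."""

    min_egfr: float = 25.0
    maintenance_dialysis: bool = False
    transplant_planned: bool = False
    limited_life_expectancy: bool = False

    def __post_init__(self) -> None:
        if self.min_egfr <= 0:
            raise ConfigError("min_egfr must be positive")
        for flag in (
            "maintenance_dialysis",
            "transplant_planned",
            "limited_life_expectancy",
        ):
            if not isinstance(getattr(self, flag), (bool, np.bool_)):
                raise ConfigError(f"exclusion flag {flag!r} must be boolean")


def default_visit_schedule(config: PlatformConfig | None = None) -> list[int]:
    """In-person visit weeks: baseline, post-acute week, then quarterly.

    The protocol anchors weeks 0, 4 (end of the acute-effect window), 24/26
    (the 6-month surrogate assessment), 52, 104 (end of treatment) and 108
    (end of washout); between weeks 4 and 104 the default is a quarterly
    (13-week) cadence so that per-participant slopes are estimable.
    """
    config = config or PlatformConfig()
    weeks = [0, config.chronic_window_start_week]
    w = 13
    while w < config.treatment_end_week:
        weeks.append(w)
        w += 13
    weeks.append(config.treatment_end_week)
    weeks.append(config.final_visit_week)
    validate_schedule(weeks, config)
    return weeks


def validate_schedule(weeks: list[int], config: PlatformConfig) -> None:
    if len(weeks) < 2 or weeks[0] != 0:
        raise ConfigError("visit schedule must start at week 0")
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ConfigError("visit schedule must be strictly increasing")
    for anchor in (
        config.chronic_window_start_week,
        config.treatment_end_week,
        config.final_visit_week,
    ):
        if anchor not in weeks:
            raise ConfigError(f"visit schedule must include week {anchor}")


def egfr_ckd_epi_2021(serum_creatinine, age, sex):
    """Estimated GFR (mL/min/1.73 m^2) from the 2021 CKD-EPI creatinine equation.

    eGFR = 142 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.200 * 0.9938^age
           * (1.012 if female), with k = 0.7 (female) / 0.9 (male) and
    a = -0.241 (female) / -0.302 (male).  The race-free 2021 refit.

    Accepts scalars or arrays (broadcast together).  Raises
    :class:`ConfigError` for non-positive creatinine, age below 18, or an
    unrecognized sex label.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    sex_arr = np.asarray(sex)
    if np.any(scr <= 0):
        raise ConfigError("serum creatinine must be positive (mg/dL)")
    if np.any(age_arr < 18):
        raise ConfigError("age must be at least 18 years")
    valid = np.isin(sex_arr, ("female", "male"))
    if not np.all(valid):
        raise ConfigError("sex must be 'female' or 'male'")
    female = sex_arr == "female"
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    ratio = scr / kappa
    egfr = (
        142.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.200
        * 0.9938**age_arr
        * np.where(female, 1.012, 1.0)
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def screen_eligibility(baseline_egfr: float, criteria: EligibilityCriteria) -> bool:
    """Core-protocol screen: eGFR at or above the floor and no exclusion flag."""
    if baseline_egfr <= 0:
        raise ConfigError("baseline eGFR must be positive")
    return bool(
        baseline_egfr >= criteria.min_egfr
        and not criteria.maintenance_dialysis
        and not criteria.transplant_planned
        and not criteria.limited_life_expectancy
    )


def _from_mapping(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    if cls is DomainConfig and "visit_weeks" in data and data["visit_weeks"] is not None:
        data = dict(data, visit_weeks=tuple(data["visit_weeks"]))
    return cls(**data)


def load_config(path) -> tuple[PlatformConfig, DomainConfig]:
    """Read a YAML or JSON design file with top-level ``platform`` / ``domain``.

    Field names mirror the dataclasses exactly; unknown keys (at any level)
    are an error rather than silently ignored.  Missing sections fall back to
    the defaults.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(raw) - {"platform", "domain"}
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
    platform = _from_mapping(PlatformConfig, raw.get("platform", {}) or {}, "platform")
    domain = _from_mapping(DomainConfig, raw.get("domain", {}) or {}, "domain")
    domain.validate(platform)
    return platform, domain
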