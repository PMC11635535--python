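"""Bayesian posterior summaries the interim decisions act on.

The design decides on three treatment contrasts, all summarized as normal
posteriors under a flat prior:

* the chronic eGFR slope contrast (mL/min/1.73 m^2 per year) over a visit
  window that excludes the acute-effect period,
* the week-24 change from baseline in ln(UACR) between arms (a log ratio;
  ``1 - exp(mean)`` is the proportional reduction), and
* the change in eGFR from randomization to the end of washout.

The reference slope backend is a mixed model for repeated measures (MMRM):
a linear mixed model with a random intercept and random slope per
participant and a fixed arm-by-time contrast, fit by REML through
statsmodels.  A precision-weighted two-stage estimator (per-participant OLS
slopes combined with inverse-variance weights) is provided as a fast
analytic backend; on balanced complete data the two contrasts coincide
exactly, which is exercised as an invariant test.  Normal posteriors can
also be reconstructed from a published point estimate and 95% CI, which is
how the printed interim analyses of the reference design are replayed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import WEEKS_PER_YEAR, Z_95, ConfigError, PlatformConfig
from .cohort import ARM_INTERVENTION, ARM_PLACEBO


class GatedDataError(ValueError):
    """Raised when an endpoint has too little data to analyze.

    The decision engine treats this as "gate not eligible" rather than a
    hard failure.
    """


class InvalidInputError(ValueError):
    """Raised for arguments that violate an operation's contract."""


@dataclass(frozen=True)
class PosteriorSummary:
    """Normal posterior of a treatment contrast.

    ``ci95`` is always ``mean -/+ 1.959964 * sd``; it is stored (rather than
    recomputed) so summaries reconstructed from printed intervals round-trip.
    """

    metric: str  # slope_contrast | uacr_log_ratio | washout_change
    mean: float
    sd: float
    ci95: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    n_per_arm: dict[str, int] | None = None
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise InvalidInputError("posterior sd must be positive")
        if self.ci95 is None:
            object.__setattr__(
                self,
                "ci95",
                (self.mean - Z_95 * self.sd, self.mean + Z_95 * self.sd),
            )
        if self.ci95[0] >= self.ci95[1]:
            raise InvalidInputError("ci95 must be ordered (low, high)")


@dataclass(frozen=True)
class ClinicalEvent:
    participant_id: object
    type: str  # decline40 | kidney_failure
    week: float


def prob_exceeds(summary: PosteriorSummary, threshold: float) -> float:
    """P(contrast > threshold) under the normal posterior."""
    return float(norm.sf(threshold, loc=summary.mean, scale=summary.sd))


def posterior_from_ci(
    point: float,
    ci_low: float,
    ci_high: float,
    metric: str = "slope_contrast",
    **kwargs,
) -> PosteriorSummary:
    """Reconstruct a normal posterior from a point estimate and 95% CI."""
    if not ci_low < point < ci_high:
        raise InvalidInputError(
            f"need ci_low < point < ci_high; got {ci_low}, {point}, {ci_high}"
        )
    sd = (ci_high - ci_low) / (2.0 * Z_95)
    return PosteriorSummary(metric=metric, mean=point, sd=sd, ci95=(ci_low, ci_high), **kwargs)


def uacr_summary_from_pct(
    reduction_pct: float, ci_low_pct: float, ci_high_pct: float, **kwargs
) -> PosteriorSummary:
    """Log-ratio posterior from a printed percent reduction with 95% CI.

    A *larger* reduction is a *smaller* (more negative) log ratio, so the
    upper percent CI end maps to the lower log end.
    """
    if not 0.0 < ci_low_pct < reduction_pct < ci_high_pct < 100.0:
        raise InvalidInputError(
            "need 0 < ci_low_pct < reduction_pct < ci_high_pct < 100"
        )
    point = math.log(1.0 - reduction_pct / 100.0)
    log_low = math.log(1.0 - ci_high_pct / 100.0)
    log_high = math.log(1.0 - ci_low_pct / 100.0)
    sd = (log_high - log_low) / (2.0 * Z_95)
    return PosteriorSummary(
        metric="uacr_log_ratio", mean=point, sd=sd, ci95=(log_low, log_high), **kwargs
    )


def uacr_reduction_probability(
    summary: PosteriorSummary, margin: float = 0.25
) -> float:
    """P(UACR reduction >= margin) = P(log ratio <= ln(1 - margin))."""
    return float(norm.cdf(math.log(1.0 - margin), loc=summary.mean, scale=summary.sd))


def uacr_reduction_prob(
    reduction_pct: float,
    ci_low_pct: float,
    ci_high_pct: float,
    margin: float = 0.25,
) -> float:
    """Probability of at least a ``margin`` UACR reduction from printed values."""
    summary = uacr_summary_from_pct(reduction_pct, ci_low_pct, ci_high_pct)
    return uacr_reduction_probability(summary, margin)


def percent_reduction(summary: PosteriorSummary) -> float:
    """Point estimate of the proportional UACR reduction, in percent."""
    return 100.0 * (1.0 - math.exp(summary.mean))


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------


def _check_arms(data: pd.DataFrame, arms: tuple[str, str]) -> None:
    present = set(data["arm"].unique())
    missing = set(arms) - present
    if missing:
        raise GatedDataError(f"no observations for arm(s): {sorted(missing)}")


def _two_stage_slope(
    d: pd.DataFrame, arms: tuple[str, str]
) -> tuple[float, float, dict[str, int]]:
    """Precision-weighted two-stage estimator of the slope contrast.

    Stage 1 fits per-participant OLS slopes on annualized time; stage 2
    combines them with inverse-variance weights 1 / (sigma^2 / Sxx_i + tau^2),
    where sigma^2 pools the stage-1 residual variance and tau^2 is a
    method-of-moments estimate of the between-participant slope variance.
    With a common visit set the weights are equal and the contrast reduces
    to the difference of mean per-participant slopes.
    """
    d = d.copy()
    d["t"] = d["week"] / WEEKS_PER_YEAR
    d["ty"] = d["t"] * d["egfr"]
    d["tt"] = d["t"] * d["t"]
    d["yy"] = d["egfr"] * d["egfr"]
    g = d.groupby("participant_id", sort=False)
    s = g[["t", "egfr", "ty", "tt", "yy"]].sum()
    s["n"] = g.size()
    s["arm"] = g["arm"].first()
    s = s[s["n"] >= 2]
    sxx = s["tt"] - s["t"] ** 2 / s["n"]
    s = s[sxx > 0]
    sxx = sxx[s.index]
    sxy = s["ty"] - s["t"] * s["egfr"] / s["n"]
    syy = s["yy"] - s["egfr"] ** 2 / s["n"]
    slope = sxy / sxx
    rss = np.maximum(syy - sxy**2 / sxx, 0.0)

    counts = {arm: int((s["arm"] == arm).sum()) for arm in arms}
    if min(counts.values()) < 2:
        raise GatedDataError(
            f"need at least 2 participants per arm with 2+ window visits; got {counts}"
        )

    df_resid = (s["n"] - 2).sum()
    sigma2 = float(rss.sum() / df_resid) if df_resid > 0 else 0.0
    v_i = sigma2 / sxx  # stage-1 sampling variance of each slope
    # Method-of-moments between-participant slope variance, pooled within arms.
    dev2 = 0.0
    for arm in arms:
        b = slope[s["arm"] == arm]
        dev2 += float(((b - b.mean()) ** 2).sum())
    s2_b = dev2 / max(len(s) - 2, 1)
    tau2 = max(s2_b - float(v_i.mean()), 0.0)

    total_var = v_i + tau2
    if float(total_var.max()) <= 0.0:  # degenerate noise-free cohort
        w = pd.Series(1.0, index=s.index)
        contrast_var = 1e-24
    else:
        w = 1.0 / total_var
        contrast_var = sum(
            1.0 / float(w[s["arm"] == arm].sum()) for arm in arms
        )
    means = {
        arm: float((w[s["arm"] == arm] * slope[s["arm"] == arm]).sum()
                   / w[s["arm"] == arm].sum())
        for arm in arms
    }
    contrast = means[arms[1]] - means[arms[0]]
    return contrast, math.sqrt(contrast_var), counts


def _mmrm_slope(
    d: pd.DataFrame, arms: tuple[str, str]
) -> tuple[float, float, dict[str, int]]:
    import statsmodels.formula.api as smf

    d = d.copy()
    d["t"] = d["week"] / WEEKS_PER_YEAR
    d["active"] = (d["arm"] == arms[1]).astype(float)
    counts = {
        arm: int(d.loc[d["arm"] == arm, "participant_id"].nunique()) for arm in arms
    }
    if min(counts.values()) < 2:
        raise GatedDataError(f"need at least 2 participants per arm; got {counts}")
    model = smf.mixedlm(
        "egfr ~ active + t + active:t",
        d,
        groups=d["participant_id"],
        re_formula="~t",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, maxiter=200)
    contrast = float(fit.params["active:t"])
    se = float(fit.bse["active:t"])
    if not (fit.converged and np.isfinite(contrast) and np.isfinite(se) and se > 0):
        raise np.linalg.LinAlgError("MMRM did not converge")
    return contrast, se, counts


def fit_slope_posterior(
    observations: pd.DataFrame,
    window: tuple[float, float] = (4, 104),
    arms: tuple[str, str] = (ARM_PLACEBO, ARM_INTERVENTION),
    method: str = "mmrm",
) -> PosteriorSummary:
    """Posterior for the chronic eGFR slope contrast (intervention - placebo).

    Restricts to visits with ``window[0] <= week <= window[1]`` (the chronic
    window, excluding the acute-effect period), fits the requested backend,
    and returns the flat-prior normal posterior: mean = contrast point
    estimate, sd = its standard error, in mL/min/1.73 m^2 per year.

    ``method`` is ``"mmrm"`` (REML linear mixed model, the reference
    backend) or ``"two_stage"`` (the analytic estimator used for large
    Monte-Carlo runs).  A non-converged or singular MMRM falls back to the
    two-stage estimator with a warning.
    """
    lo, hi = window
    if lo >= hi:
        raise InvalidInputError("window must be (start, end) with start < end")
    d = observations[(observations["week"] >= lo) & (observations["week"] <= hi)]
    d = d[d["arm"].isin(arms)]
    if d.empty:
        raise GatedDataError("no observations inside the analysis window")
    _check_arms(d, arms)
    if method == "two_stage":
        contrast, se, counts = _two_stage_slope(d, arms)
    elif method == "mmrm":
        try:
            contrast, se, counts = _mmrm_slope(d, arms)
        except GatedDataError:
            raise
        except Exception:
            warnings.warn(
                "MMRM fit failed to converge; falling back to the two-stage "
                "slope estimator",
                stacklevel=2,
            )
            contrast, se, counts = _two_stage_slope(d, arms)
    else:
        raise InvalidInputError(f"unknown slope method {method!r}")
    return PosteriorSummary(
        metric="slope_contrast",
        mean=contrast,
        sd=max(se, 1e-12),
        n_per_arm=counts,
        window=(float(lo), float(hi)),
    )


def _paired_change(
    observations: pd.DataFrame,
    value_col: str,
    week_from: float,
    week_to: float,
    log_scale: bool,
) -> pd.DataFrame:
    base = observations[observations["week"] == week_from]
    post = observations[observations["week"] == week_to]
    merged = base[["participant_id", "arm", value_col]].merge(
        post[["participant_id", value_col]],
        on="participant_id",
        suffixes=("_0", "_1"),
    )
    a, b = f"{value_col}_0", f"{value_col}_1"
    if log_scale:
        merged["change"] = np.log(merged[b]) - np.log(merged[a])
    else:
        merged["change"] = merged[b] - merged[a]
    return merged


def _change_contrast(
    merged: pd.DataFrame, arms: tuple[str, str], metric: str, window
) -> PosteriorSummary:
    counts = {arm: int((merged["arm"] == arm).sum()) for arm in arms}
    if min(counts.values()) < 2:
        raise GatedDataError(
            f"need at least 2 participants per arm with paired visits; got {counts}"
        )
    stats_ = merged.groupby("arm")["change"].agg(["mean", "var", "count"])
    mean = float(stats_.loc[arms[1], "mean"] - stats_.loc[arms[0], "mean"])
    var = float(
        stats_.loc[arms[1], "var"] / stats_.loc[arms[1], "count"]
        + stats_.loc[arms[0], "var"] / stats_.loc[arms[0], "count"]
    )
    return PosteriorSummary(
        metric=metric,
        mean=mean,
        sd=max(math.sqrt(var), 1e-12),
        n_per_arm=counts,
        window=window,
    )


def nearest_visit_week(
    weeks, nominal: float, tolerance: float = 4.0
) -> float:
    """Scheduled visit closest to a nominal analysis week, within a tolerance."""
    weeks = np.asarray(sorted(set(np.asarray(weeks, dtype=float))))
    diffs = np.abs(weeks - nominal)
    i = int(np.argmin(diffs))
    if diffs[i] > tolerance:
        raise GatedDataError(
            f"no visit within {tolerance} weeks of nominal week {nominal}"
        )
    return float(weeks[i])


def fit_uacr_posterior(
    observations: pd.DataFrame,
    nominal_week: float = 24,
    arms: tuple[str, str] = (ARM_PLACEBO, ARM_INTERVENTION),
    tolerance_weeks: float = 4.0,
) -> PosteriorSummary:
    """Posterior for the week-24 change from baseline in ln(UACR), by arm.

    Uses the scheduled visit nearest the nominal week (within a +-4-week
    window; the default schedule maps week 24 to the week-26 visit).  The
    posterior mean is a log ratio; ``percent_reduction`` converts it to the
    percent scale.
    """
    week = nearest_visit_week(
        observations["week"].unique()[observations["week"].unique() > 0],
        nominal_week,
        tolerance_weeks,
    )
    merged = _paired_change(observations, "uacr", 0.0, week, log_scale=True)
    return _change_contrast(merged, arms, "uacr_log_ratio", (0.0, week))


def washout_change_posterior(
    observations: pd.DataFrame,
    config: PlatformConfig | None = None,
    arms: tuple[str, str] = (ARM_PLACEBO, ARM_INTERVENTION),
) -> PosteriorSummary:
    """Posterior for the arm contrast of eGFR change, baseline to end of washout.

    For a fully reversible acute effect this off-treatment change, annualized,
    estimates the same quantity as the chronic slope contrast — the property
    that lets immature interims lean on the on-treatment chronic change.
    """
    config = config or PlatformConfig()
    final = float(config.final_visit_week)
    if not (observations["week"] == final).any():
        raise GatedDataError(f"no end-of-washout (week {final:g}) visits present")
    merged = _paired_change(observations, "egfr", 0.0, final, log_scale=False)
    return _change_contrast(merged, arms, "washout_change", (0.0, final))


def derive_clinical_events(
    observations: pd.DataFrame,
    baselines: pd.Series | None = None,
    kidney_failure_egfr: float = 15.0,
) -> list[ClinicalEvent]:
    """First 40%-decline and kidney-failure events per participant.

    ``decline40`` fires at the first post-baseline visit with
    eGFR <= 0.6 * baseline; ``kidney_failure`` at the first visit with
    eGFR < 15 mL/min/1.73 m^2.  Baselines default to each participant's
    week-0 eGFR.  At most one event of each type per participant.
    """
    obs = observations.sort_values(["participant_id", "week"])
    if baselines is None:
        base = obs[obs["week"] == 0].set_index("participant_id")["egfr"]
    else:
        base = baselines
    obs = obs[obs["week"] > 0].copy()
    obs["baseline"] = base.reindex(obs["participant_id"]).to_numpy()
    obs = obs[obs["baseline"].notna()]
    events: list[ClinicalEvent] = []
    decline = obs[obs["egfr"] <= 0.6 * obs["baseline"]]
    for pid, week in decline.groupby("participant_id", sort=True)["week"].first().items():
        events.append(ClinicalEvent(pid, "decline40", float(week)))
    failure = obs[obs["egfr"] < kidney_failure_egfr]
    for pid, week in failure.groupby("participant_id", sort=True)["week"].first().items():
        events.append(ClinicalEvent(pid, "kidney_failure", float(week)))
    return sorted(events, key=lambda e: (str(e.participant_id), e.type))
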