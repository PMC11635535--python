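"""Dataset I/O, run manifests, and caption-style interim reports."""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .config import Z_95
from .decisions import InterimRecord


class CohortSchemaError(ValueError):
    """A cohort CSV violated the interchange schema (message names row/column)."""


def write_cohort_csv(path, observations: pd.DataFrame) -> None:
    """Write a long-format cohort table with the canonical column order."""
    missing = [c for c in COHORT_COLUMNS if c not in observations.columns]
    if missing:
        raise CohortSchemaError(f"missing column(s): {missing}")
    observations[COHORT_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a long-format cohort table.

    The header must match the schema exactly; rows violating an observation
    invariant (non-positive eGFR or UACR, negative week) raise an error
    naming the offending line (1-based, counting the header) and column.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if list(df.columns) != COHORT_COLUMNS:
        raise CohortSchemaError(
            f"header must be exactly {COHORT_COLUMNS}; got {list(df.columns)}"
        )
    checks = [
        ("egfr", df["egfr"] <= 0, "egfr must be positive"),
        ("uacr", df["uacr"] <= 0, "uacr must be positive"),
        ("week", df["week"] < 0, "week must be non-negative"),
        ("enroll_week", df["enroll_week"] < 0, "enroll_week must be non-negative"),
    ]
    for col, bad, msg in checks:
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise CohortSchemaError(f"line {line}, column '{col}': {msg}")
    df["on_treatment"] = df["on_treatment"].astype(bool)
    return df


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every CLI output."""

    config_path: str | None
    seed: int | None
    command: str
    version: str
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    output_paths: list[str] = field(default_factory=list)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and math.isinf(obj):
        return None
    return obj


def to_json(obj, path=None, indent: int = 2) -> str:
    """Serialize a result dataclass (or mapping) to JSON text, optionally to disk."""
    text = json.dumps(_jsonable(obj), indent=indent)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def render_interim_caption(record: InterimRecord) -> str:
    """Human-readable interim report shaped like a figure caption.

    Deterministic: identical records render identical text.  Percent
    reductions are shown to 1 decimal, probabilities to 3 decimals.
    """
    lines = [
        f"Interim analysis {record.interim_index} (calendar week "
        f"{record.calendar_week:g})."
    ]
    if record.uacr_summary is not None:
        s = record.uacr_summary
        pct = 100.0 * (1.0 - math.exp(s.mean))
        lo = 100.0 * (1.0 - math.exp(s.ci95[1]))
        hi = 100.0 * (1.0 - math.exp(s.ci95[0]))
        line = (
            f"The treatment effect is estimated to reduce UACR by {pct:.1f}% "
            f"(95% CI, {lo:.1f}%-{hi:.1f}%)"
        )
        p = record.probabilities.get("p_uacr_reduction_ge_margin")
        if p is not None:
            line += (
                "; the probability of providing a clinically important "
                f"reduction is {p:.3f}"
            )
        lines.append(line + ".")
    if record.slope_summary is not None:
        s = record.slope_summary
        lines.append(
            f"The difference in eGFR slope is {s.mean:.2f} (95% CI, "
            f"{s.ci95[0]:.2f} to {s.ci95[1]:.2f}) mL/min/1.73 m^2 per year."
        )
        p0 = record.probabilities.get("p_slope_gt0")
        pm = record.probabilities.get("p_slope_gt_margin")
        if p0 is not None:
            lines.append(f"Probability of a slope effect greater than 0: {p0:.3f}.")
        if pm is not None:
            lines.append(
                "Probability of a clinically important slope effect: " f"{pm:.3f}."
            )
    gates = []
    f = record.flags
    gates.append(f"UACR futility gate {'open' if f.uacr_futility_eligible else 'closed'}")
    gates.append(f"eGFR futility gate {'open' if f.egfr_futility_eligible else 'closed'}")
    gates.append(f"success gate {'open' if f.success_eligible else 'closed'}")
    lines.append("Eligibility: " + "; ".join(gates) + ".")
    lines.append(f"Decision: {record.decision}.")
    return "\n".join(lines)
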