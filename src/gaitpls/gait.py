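"""Dual-task cost on gait speed and its exercise-induced improvement.

Dual-task cost (DTC) is the percent change in gait speed when a cognitive
task is added to walking: DTC = (dual - single) / single x 100, negative
when dual-task walking is slower. In the cross-over design, the
exercise-induced improvement is the DTC delta over each arm's exercise
period: midpoint - baseline for the exercise-first arm, final - midpoint
for the exercise-second arm. Positive delta = improvement (DTC less
negative after exercise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "CONDITIONS",
    "GROUPS",
    "ARMS",
    "MissingDataError",
    "SubjectRecord",
    "compute_dtc",
    "compute_improvement",
    "required_timepoints",
    "filter_complete",
    "summarize_by_group",
]

TIMEPOINTS = ("baseline", "midpoint", "final")
CONDITIONS = ("single", "dual")
GROUPS = ("freezer", "nonfreezer")
ARMS = ("exercise_first", "exercise_second")


class MissingDataError(ValueError):
    """A required measurement is absent; never silently treated as zero."""


def compute_dtc(single_speed: float, dual_speed: float) -> float:
    """Dual-task cost on gait speed, percent.

    ``(dual - single) / single x 100``; negative when dual-task walking is
    slower than single-task walking.
    """
    if not single_speed > 0:
        raise ValueError(f"single-task speed must be > 0 m/s, got {single_speed}")
    return (dual_speed - single_speed) / single_speed * 100.0


def required_timepoints(arm: str) -> tuple[str, str]:
    """The (pre, post) timepoints whose DTC delta defines the improvement."""
    if arm == "exercise_first":
        return ("baseline", "midpoint")
    if arm == "exercise_second":
        return ("midpoint", "final")
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


@dataclass
class SubjectRecord:
    """One participant: group, arm, covariates, and gait speeds (m/s).

    ``speeds`` maps ``(timepoint, condition)`` -> speed in m/s; absent
    entries are simply missing. Freezing status follows the NFoGQ rule:
    freezers score > 0 on the New Freezing of Gait Questionnaire,
    nonfreezers have no NFoGQ score.
    """

    id: str
    group: str
    arm: str
    speeds: dict[tuple[str, str], float] = field(default_factory=dict)
    updrs_iii: float | None = None
    pigd: float | None = None
    disease_duration: float | None = None
    gender: str | None = None
    moca: float | None = None
    nfogq: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        for (tp, cond), v in self.speeds.items():
            if tp not in TIMEPOINTS or cond not in CONDITIONS:
                raise ValueError(f"unknown speed key {(tp, cond)!r}")
            if not v > 0:
                raise ValueError(
                    f"subject {self.id!r}: speed at {(tp, cond)} must be > 0, got {v}"
                )
        if self.nfogq is not None:
            is_freezer = self.group == "freezer"
            if is_freezer != (self.nfogq > 0):
                raise ValueError(
                    f"subject {self.id!r}: group {self.group!r} inconsistent with "
                    f"NFoGQ={self.nfogq} (freezer iff NFoGQ > 0)"
                )

    def dtc(self, timepoint: str) -> float | None:
        """DTC (percent) at ``timepoint``, or None if either speed is absent."""
        single = self.speeds.get((timepoint, "single"))
        dual = self.speeds.get((timepoint, "dual"))
        if single is None or dual is None:
            return None
        return compute_dtc(single, dual)

    @property
    def improvement(self) -> float | None:
        try:
            return compute_improvement(self)
        except MissingDataError:
            return None


def compute_improvement(record: SubjectRecord) -> float:
    """Exercise-induced DTC improvement (percent) under the cross-over rule.

    exercise_first -> DTC(midpoint) - DTC(baseline);
    exercise_second -> DTC(final) - DTC(midpoint).
    """
    pre, post = required_timepoints(record.arm)
    dtc_pre, dtc_post = record.dtc(pre), record.dtc(post)
    missing = [tp for tp, v in ((pre, dtc_pre), (post, dtc_post)) if v is None]
    if missing:
        raise MissingDataError(
            f"subject {record.id!r} ({record.arm}): DTC unavailable at {missing}"
        )
    return dtc_post - dtc_pre


def filter_complete(cohort: list[SubjectRecord]) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Split a cohort into (kept, excluded) by improvement computability.

    A subject is kept when both timepoints their arm requires have DTC
    values — subjects with only two of three assessments are kept as long
    as the pair covers their arm's exercise period. This is a cohort-level
    filter, not a per-record error.
    """
    kept, excluded = [], []
    for rec in cohort:
        (kept if rec.improvement is not None else excluded).append(rec)
    return kept, excluded


_SUMMARY_VARIABLES = (
    "dtc_baseline",
    "improvement",
    "updrs_iii",
    "pigd",
    "disease_duration",
    "moca",
    "nfogq",
)


def _extract(record: SubjectRecord, variable: str) -> float | None:
    if variable == "dtc_baseline":
        return record.dtc("baseline")
    if variable == "improvement":
        return record.improvement
    return getattr(record, variable)


def summarize_by_group(
    cohort: list[SubjectRecord],
    variables: tuple[str, ...] = _SUMMARY_VARIABLES,
) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1) and n for each variable.

    Missing values are excluded pairwise; n counts the non-missing values.
    With a single observation the SD is reported as NaN.
    """
    groups = sorted({r.group for r in cohort})
    if not groups:
        raise ValueError("empty cohort")
    for g in GROUPS:
        if g in groups and not any(r.group == g for r in cohort):
            raise ValueError(f"empty group {g!r}")
    rows = []
    for g in groups:
        members = [r for r in cohort if r.group == g]
        for var in variables:
            vals = np.array(
                [v for r in members if (v := _extract(r, var)) is not None
                 and not (isinstance(v, float) and math.isnan(v))],
                dtype=float,
            )
            n = len(vals)
            rows.append(
                {
                    "group": g,
                    "variable": var,
                    "n": n,
                    "mean": float(vals.mean()) if n else math.nan,
                    "sd": float(vals.std(ddof=1)) if n > 1 else math.nan,
                }
            )
    return pd.DataFrame(rows)
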