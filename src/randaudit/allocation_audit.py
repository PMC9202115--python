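"""Allocation-balance audit for stratified permuted-block randomization.

Three checks on the realized allocation sequence:

* per-stratum treatment/control counts with the imbalance Δ = |nT - nC|
  and, when the maximum block size is known, whether Δ exceeds the largest
  mid-block imbalance a 1:1 permuted block permits (floor(max_block / 2));
* the per-center protocol restriction that enrollment counts in the two
  time strata must differ by fewer than a threshold (3 in the audited
  trial), checked on final counts or replayed sequentially;
* an exact binomial test on the direction split of allocation cross-overs
  (participants who received the arm the schedule did not assign them),
  under the null that each cross-over is equally likely in either
  direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import pandas as pd
from scipy import stats

from .trial_model import Arm, ParticipantRecord, StratumKey, TimeStratum, _as_frame

__all__ = [
    "StratumAllocation",
    "AllocationTable",
    "RestrictionViolation",
    "CrossoverTestResult",
    "allocation_counts",
    "flag_allocation_deviations",
    "check_time_strata_restriction",
    "crossover_direction_test",
    "crossover_counts",
]


@dataclass
class StratumAllocation:
    """Arm counts in one stratum (or one time-stratum margin)."""

    stratum: StratumKey | TimeStratum
    n_treatment: int
    n_control: int
    exceeds_block_bound: bool | None = None

    @property
    def delta(self) -> int:
        return abs(self.n_treatment - self.n_control)

    @property
    def favored_arm(self) -> Arm | None:
        if self.n_treatment > self.n_control:
            return Arm.TREATMENT
        if self.n_control > self.n_treatment:
            return Arm.CONTROL
        return None

    def to_json(self) -> dict[str, Any]:
        stratum = (
            {"clinical_center": self.stratum.clinical_center, "time_stratum": self.stratum.time_stratum.value}
            if isinstance(self.stratum, StratumKey)
            else {"time_stratum": self.stratum.value}
        )
        return {
            "stratum": stratum,
            "n_treatment": self.n_treatment,
            "n_control": self.n_control,
            "delta": self.delta,
            "favored_arm": self.favored_arm.value if self.favored_arm else None,
            "exceeds_block_bound": self.exceeds_block_bound,
        }


@dataclass
class AllocationTable:
    """Per-stratum allocation counts plus the two time-stratum margins."""

    strata: list[StratumAllocation] = field(default_factory=list)
    time_margins: dict[TimeStratum, StratumAllocation] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(row.n_treatment + row.n_control for row in self.strata)

    def margin(self, time_stratum: TimeStratum | str) -> StratumAllocation:
        return self.time_margins[TimeStratum(time_stratum)]


@dataclass
class RestrictionViolation:
    """A center whose time-strata enrollment counts differ by >= threshold."""

    clinical_center: str
    n_early: int
    n_late: int
    threshold: int
    running_violation_index: int | None = None

    @property
    def diff(self) -> int:
        return abs(self.n_early - self.n_late)


@dataclass
class CrossoverTestResult:
    """Exact binomial test of the cross-over direction split.

    ``point_probability`` is the binomial point mass of exactly
    ``n_in_direction`` of ``n_crossovers`` falling in the observed
    direction; ``tail_probability`` is the one-sided upper tail (at least
    that many).  Both are reported because reanalyses sometimes print the
    point mass where a tail would be conventional.
    """

    n_crossovers: int
    n_in_direction: int
    null_prob: float
    point_probability: float
    tail_probability: float


# ---------------------------------------------------------------------------


def allocation_counts(records: Sequence[ParticipantRecord] | pd.DataFrame) -> AllocationTable:
    """Count treatment/control allocations per unique stratum and per
    time-stratum margin.  Deterministic; empty input yields an empty table."""
    frame = _as_frame(records)
    table = AllocationTable()
    if len(frame) == 0:
        return table
    grouped = frame.groupby(["clinical_center", "time_stratum"], sort=True, observed=True)["arm"]
    for (center, ts), arms in grouped:
        table.strata.append(
            StratumAllocation(
                stratum=StratumKey(str(center), TimeStratum(ts)),
                n_treatment=int((arms == Arm.TREATMENT.value).sum()),
                n_control=int((arms == Arm.CONTROL.value).sum()),
            )
        )
    for ts, arms in frame.groupby("time_stratum", sort=True, observed=True)["arm"]:
        table.time_margins[TimeStratum(ts)] = StratumAllocation(
            stratum=TimeStratum(ts),
            n_treatment=int((arms == Arm.TREATMENT.value).sum()),
            n_control=int((arms == Arm.CONTROL.value).sum()),
        )
    return table


def flag_allocation_deviations(
    alloc: AllocationTable,
    max_block_size: int | None = None,
    *,
    threshold: int = 1,
) -> list[StratumAllocation]:
    """Flag strata deviating from 1:1 allocation (Δ >= ``threshold``).

    With ``max_block_size`` given, each stratum is annotated with whether
    its Δ exceeds floor(max_block / 2) — the largest imbalance attainable
    mid-block under 1:1 permuted blocks, hence impossible without a
    randomization error even if the last block was left incomplete.
    """
    if max_block_size is not None and (max_block_size < 2 or max_block_size % 2 != 0):
        raise ValueError(f"max_block_size must be an even integer >= 2 for 1:1 allocation, got {max_block_size}")
    if threshold < 1:
        raise ValueError("deviation threshold must be >= 1")
    flagged = []
    for row in alloc.strata:
        if max_block_size is not None:
            row.exceeds_block_bound = row.delta > max_block_size // 2
        if row.delta >= threshold:
            flagged.append(row)
    return flagged


def check_time_strata_restriction(
    records: Sequence[ParticipantRecord] | pd.DataFrame,
    threshold: int = 3,
    mode: str = "final",
) -> list[RestrictionViolation]:
    """Check the per-center restriction on time-strata enrollment counts.

    ``mode="final"`` (the default, and what a reanalysis of closed trial
    data can always do) compares end-of-trial counts: a center violates when
    |n_early - n_late| >= threshold.  ``mode="sequential"`` replays the
    enrollment order — the protocol rule is intrinsically sequential — and
    reports the first enrollment position at which a center's running
    difference reached the threshold; it requires ``enrollment_index``.
    """
    if mode not in ("final", "sequential"):
        raise ValueError(f"mode must be 'final' or 'sequential', got {mode!r}")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    frame = _as_frame(records)
    violations: list[RestrictionViolation] = []
    if len(frame) == 0:
        return violations
    if mode == "sequential" and frame["enrollment_index"].isna().any():
        raise ValueError("sequential restriction check requires enrollment_index on every record")

    for center, sub in frame.groupby("clinical_center", sort=True, observed=True):
        n_early = int((sub["time_stratum"] == TimeStratum.EARLY.value).sum())
        n_late = int((sub["time_stratum"] == TimeStratum.LATE.value).sum())
        if mode == "final":
            if abs(n_early - n_late) >= threshold:
                violations.append(RestrictionViolation(str(center), n_early, n_late, threshold))
            continue
        running = 0
        first_hit: int | None = None
        ordered = sub.sort_values("enrollment_index")
        for idx, ts in zip(ordered["enrollment_index"], ordered["time_stratum"]):
            running += 1 if ts == TimeStratum.EARLY.value else -1
            if abs(running) >= threshold:
                first_hit = int(idx)
                break
        if first_hit is not None:
            violations.append(
                RestrictionViolation(str(center), n_early, n_late, threshold, running_violation_index=first_hit)
            )
    return violations


def crossover_counts(records: Sequence[ParticipantRecord] | pd.DataFrame) -> tuple[int, int]:
    """(total cross-overs, cross-overs in the treatment->control direction).

    A cross-over who *received* control was scheduled for treatment, the
    direction the audited trial saw in 21 of its 22 cross-overs.
    """
    frame = _as_frame(records)
    if len(frame) == 0:
        return 0, 0
    cross = frame[frame["crossover"].fillna(False).astype(bool)]
    n = len(cross)
    to_control = int((cross["arm"] == Arm.CONTROL.value).sum())
    return n, to_control


def crossover_direction_test(
    n_crossovers: int,
    n_in_direction: int,
    null_prob: float = 0.5,
) -> CrossoverTestResult:
    """Exact binomial probabilities for the observed cross-over direction
    split under per-cross-over direction probability ``null_prob``.

    In the audited trial 21 of 22 cross-overs moved participants scheduled
    for treatment onto placebo; at null_prob 0.5 the point mass is
    C(22,21)/2**22 ≈ 5.2e-6 and the upper tail 23/2**22 ≈ 5.5e-6.
    """
    if not 0 <= n_in_direction <= n_crossovers:
        raise ValueError("need 0 <= n_in_direction <= n_crossovers")
    if not 0 < null_prob < 1:
        raise ValueError(f"null_prob must lie strictly inside (0, 1), got {null_prob}")
    point = float(stats.binom.pmf(n_in_direction, n_crossovers, null_prob))
    tail = float(stats.binom.sf(n_in_direction - 1, n_crossovers, null_prob))
    tail = max(tail, point)  # guards a one-ulp inversion when k = n
    return CrossoverTestResult(
        n_crossovers=n_crossovers,
        n_in_direction=n_in_direction,
        null_prob=null_prob,
        point_probability=point,
        tail_probability=min(tail, 1.0),
    )
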