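"""Baseline-imbalance scans between allocation arms.

Two scans mirror the sensitivity analyses of the audit: CT-derived
covariates compared between arms inside each unique randomization stratum,
and all baseline covariates compared between arms inside each time-stratum
margin.  Continuous covariates use a two-sided t-test (Welch by default),
categorical covariates a chi-square test with Yates continuity correction.
Significance is alpha = 0.05 inclusive, with no multiple-testing
correction — matching the audited reanalysis; the scan reports how many
tests it ran so readers can judge the multiplicity themselves.

A flagged imbalance is annotated with which arm it prognostically favors,
using a per-covariate direction map (e.g. a lower mean baseline NIHSS is
better, prior aspirin use is a favorable marker).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_model import (
    Arm,
    BASELINE_COVARIATES,
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    CT_COVARIATES,
    ParticipantRecord,
    StratumKey,
    TimeStratum,
    _as_frame,
)

__all__ = [
    "Direction",
    "PrognosisMap",
    "DEFAULT_PROGNOSIS",
    "TestResult",
    "ImbalanceResult",
    "ScanReport",
    "welch_t_test",
    "welch_t_from_stats",
    "chisq_yates",
    "scan_covariates",
    "scan_ct_by_unique_stratum",
]


class Direction(str, enum.Enum):
    HIGHER_IS_WORSE = "higher_is_worse"
    HIGHER_IS_BETTER = "higher_is_better"
    PRESENCE_IS_WORSE = "presence_is_worse"
    PRESENCE_IS_BETTER = "presence_is_better"
    UNKNOWN = "unknown"


#: Covariate -> prognostic direction.  Unlisted covariates are UNKNOWN and
#: never receive a "favors" annotation.
PrognosisMap = Mapping[str, Direction]

DEFAULT_PROGNOSIS: dict[str, Direction] = {
    "nihss_baseline": Direction.HIGHER_IS_WORSE,
    "aspirin_pre": Direction.PRESENCE_IS_BETTER,
    "hyperintense_artery": Direction.PRESENCE_IS_WORSE,
    "abnormal_ct": Direction.PRESENCE_IS_WORSE,
    "loss_grey_white": Direction.PRESENCE_IS_WORSE,
    "small_vessel_subtype": Direction.PRESENCE_IS_BETTER,
    "old_lesion_volume": Direction.HIGHER_IS_WORSE,
}


@dataclass
class TestResult:
    statistic: float
    p_value: float
    warning: str | None = None

    def __iter__(self):
        return iter((self.statistic, self.p_value))


@dataclass
class ImbalanceResult:
    """One covariate comparison between arms within one scope."""

    stratum: StratumKey | TimeStratum
    covariate: str
    test: str  # "welch_t" | "pooled_t" | "chisq_yates"
    statistic: float
    p_value: float
    group_summaries: dict[str, dict[str, float]]
    alpha: float
    favors: Arm | None = None
    warning: str | None = None

    @property
    def flagged(self) -> bool:
        return self.p_value <= self.alpha

    def to_json(self) -> dict[str, Any]:
        stratum = (
            {"clinical_center": self.stratum.clinical_center, "time_stratum": self.stratum.time_stratum.value}
            if isinstance(self.stratum, StratumKey)
            else {"time_stratum": self.stratum.value}
        )
        return {
            "stratum": stratum,
            "covariate": self.covariate,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_summaries": self.group_summaries,
            "flagged": self.flagged,
            "favors": self.favors.value if self.favors else None,
            "warning": self.warning,
        }


@dataclass
class ScanReport:
    """All comparisons performed plus per-covariate diagnostics for
    comparisons that could not be run (absent covariate, degenerate data,
    empty arm)."""

    results: list[ImbalanceResult] = field(default_factory=list)
    diagnostics: list[dict[str, Any]] = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return len(self.results)

    @property
    def flagged(self) -> list[ImbalanceResult]:
        return [r for r in self.results if r.flagged]


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------


def welch_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    *,
    pooled: bool = False,
) -> TestResult:
    """Two-sided two-sample t-test (Welch-Satterthwaite df by default,
    pooled-variance with ``pooled=True``).  Symmetric under group exchange:
    the statistic flips sign, the p-value is unchanged."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return TestResult(float(res.statistic), float(res.pvalue))


def welch_t_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> TestResult:
    """Welch t-test from summary statistics, so published mean ± sd tables
    are checkable without the raw data."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a <= 0 and sd_b <= 0:
        raise ValueError("degenerate variance in both groups")
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue))


def chisq_yates(a: int, b: int, c: int, d: int) -> TestResult:
    """Chi-square test with Yates continuity correction on the 2x2 table
    [[a, b], [c, d]].

    Statistic N(|ad - bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)], truncated to 0
    when |ad - bc| <= N/2; p from chi-square with 1 df.  A zero margin is an
    error; an expected cell below 5 attaches a warning to the result.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square test undefined with a zero margin")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    warning = None
    if (expected < 5).any():
        warning = f"expected cell count below 5 (min {expected.min():.2f})"
    statistic, p, _, _ = stats.chi2_contingency(table, correction=True)
    return TestResult(float(statistic), float(p), warning)


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------


def _favored_arm(
    covariate: str,
    direction: Direction,
    summary_t: dict[str, float],
    summary_c: dict[str, float],
) -> Arm | None:
    """Which arm a flagged imbalance prognostically favors."""
    key = "mean" if "mean" in summary_t else "proportion"
    vt, vc = summary_t[key], summary_c[key]
    if vt == vc or direction is Direction.UNKNOWN:
        return None
    higher = Arm.TREATMENT if vt > vc else Arm.CONTROL
    if direction in (Direction.HIGHER_IS_WORSE, Direction.PRESENCE_IS_WORSE):
        return higher.other()
    return higher


def _scan_one(
    sub: pd.DataFrame,
    scope: StratumKey | TimeStratum,
    covariate: str,
    alpha: float,
    prognosis: PrognosisMap,
    pooled: bool,
) -> tuple[ImbalanceResult | None, dict[str, Any] | None]:
    if covariate not in sub.columns:
        return None, {"scope": str(scope), "covariate": covariate, "reason": "covariate absent from records"}
    data = sub[["arm", covariate]].dropna()
    grp_t = data.loc[data["arm"] == Arm.TREATMENT.value, covariate]
    grp_c = data.loc[data["arm"] == Arm.CONTROL.value, covariate]
    if len(grp_t) < 2 or len(grp_c) < 2:
        return None, {"scope": str(scope), "covariate": covariate, "reason": "fewer than 2 complete cases in an arm"}

    direction = prognosis.get(covariate, Direction.UNKNOWN)
    if covariate in CONTINUOUS_COVARIATES or (
        covariate not in BINARY_COVARIATES and data[covariate].dtype.kind in "fi"
        and data[covariate].nunique() > 2
    ):
        t = np.asarray(grp_t, dtype=float)
        c = np.asarray(grp_c, dtype=float)
        if t.std(ddof=1) == 0 and c.std(ddof=1) == 0:
            return None, {"scope": str(scope), "covariate": covariate, "reason": "degenerate (constant) values"}
        test = welch_t_test(t, c, pooled=pooled)
        summaries = {
            "treatment": {"mean": float(t.mean()), "sd": float(t.std(ddof=1)), "n": len(t)},
            "control": {"mean": float(c.mean()), "sd": float(c.std(ddof=1)), "n": len(c)},
        }
        test_name = "pooled_t" if pooled else "welch_t"
    else:
        t = np.asarray(grp_t, dtype=bool)
        c = np.asarray(grp_c, dtype=bool)
        a, b = int(t.sum()), int((~t).sum())
        cc, d = int(c.sum()), int((~c).sum())
        if (a + cc) == 0 or (b + d) == 0:
            return None, {"scope": str(scope), "covariate": covariate, "reason": "degenerate (constant) values"}
        test = chisq_yates(a, b, cc, d)
        summaries = {
            "treatment": {"proportion": a / len(t), "n": len(t)},
            "control": {"proportion": cc / len(c), "n": len(c)},
        }
        test_name = "chisq_yates"

    result = ImbalanceResult(
        stratum=scope,
        covariate=covariate,
        test=test_name,
        statistic=test.statistic,
        p_value=test.p_value,
        group_summaries=summaries,
        alpha=alpha,
        warning=test.warning,
    )
    if result.flagged:
        result.favors = _favored_arm(covariate, direction, summaries["treatment"], summaries["control"])
    return result, None


def scan_covariates(
    records: Sequence[ParticipantRecord] | pd.DataFrame,
    scope: StratumKey | TimeStratum | str | None = None,
    covariates: Sequence[str] = BASELINE_COVARIATES,
    alpha: float = 0.05,
    prognosis: PrognosisMap = DEFAULT_PROGNOSIS,
    *,
    pooled_t: bool = False,
) -> ScanReport:
    """Compare baseline covariates between arms within a scope.

    ``scope`` selects a unique stratum (:class:`StratumKey`), a time-stratum
    margin (:class:`TimeStratum`), or the whole table (``None``).  Each
    covariate yields one :class:`ImbalanceResult` — Welch t for continuous,
    Yates chi-square for binary — flagged when p <= alpha; covariates that
    cannot be tested produce diagnostics and the scan continues.
    """
    frame = _as_frame(records)
    if isinstance(scope, str):
        scope = TimeStratum(scope)
    if isinstance(scope, StratumKey):
        sub = frame[
            (frame["clinical_center"] == scope.clinical_center)
            & (frame["time_stratum"] == scope.time_stratum.value)
        ]
    elif isinstance(scope, TimeStratum):
        sub = frame[frame["time_stratum"] == scope.value]
    else:
        sub = frame
        scope = scope or "all"

    report = ScanReport()
    for covariate in covariates:
        result, diag = _scan_one(sub, scope, covariate, alpha, prognosis, pooled_t)
        if result is not None:
            report.results.append(result)
        if diag is not None:
            report.diagnostics.append(diag)
    return report


def scan_ct_by_unique_stratum(
    records: Sequence[ParticipantRecord] | pd.DataFrame,
    ct_covariates: Sequence[str] = CT_COVARIATES,
    alpha: float = 0.05,
    prognosis: PrognosisMap = DEFAULT_PROGNOSIS,
) -> ScanReport:
    """Scan CT-derived covariates between arms inside every unique stratum.

    Strata where an arm has fewer than 2 complete cases are skipped with a
    diagnostic (their test would be meaningless), as are degenerate
    all-identical covariates.
    """
    frame = _as_frame(records)
    report = ScanReport()
    if len(frame) == 0:
        return report
    for (center, ts), _ in frame.groupby(["clinical_center", "time_stratum"], sort=True, observed=True):
        key = StratumKey(str(center), TimeStratum(ts))
        sub_report = scan_covariates(frame, key, ct_covariates, alpha, prognosis)
        report.results.extend(sub_report.results)
        report.diagnostics.extend(sub_report.diagnostics)
    return report
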