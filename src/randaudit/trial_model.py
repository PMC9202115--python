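"""Participant-level domain model for a stratified two-arm trial.

The audit operates on participant-level data from a randomized controlled
trial that stratified its permuted-block randomization by clinical center
and by time from symptom onset to treatment (0-90 min vs 91-180 min), with
1:1 allocation to active treatment (alteplase) or placebo.  This module
defines the normalized record schema, a tabular reader/writer driven by a
user-supplied data dictionary, stratification, and the dichotomization
rules for the four 90-day outcomes:

* modified Rankin Scale (mRS): favorable iff score 0-1,
* Barthel Index (BI): favorable iff 95 or 100,
* NIH Stroke Scale (NIHSS): favorable iff <= 1,
* Glasgow Outcome Scale (GOS): favorable iff 1.

Internally arms are normalized to ``treatment``/``control`` and time strata
to ``early`` (0-90 min) / ``late`` (91-180 min); trial-specific labels such
as alteplase/placebo live only in the :class:`DataDictionary`.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arm",
    "TimeStratum",
    "Endpoint",
    "StratumKey",
    "ParticipantRecord",
    "DataDictionary",
    "LoadResult",
    "MissingColumnError",
    "load_trial_table",
    "write_trial_table",
    "write_diagnostics",
    "records_to_frame",
    "frame_to_records",
    "dichotomize_endpoint",
    "dichotomize_frame",
    "stratify",
    "BASELINE_COVARIATES",
    "BINARY_COVARIATES",
    "CONTINUOUS_COVARIATES",
    "CT_COVARIATES",
    "DEFAULT_NINDS_DICTIONARY",
    "FIXTURE_DICTIONARY",
]


class Arm(str, enum.Enum):
    """Allocation arm, normalized away from drug names."""

    TREATMENT = "treatment"
    CONTROL = "control"

    def other(self) -> "Arm":
        return Arm.CONTROL if self is Arm.TREATMENT else Arm.TREATMENT


class TimeStratum(str, enum.Enum):
    """Time-from-onset stratum: EARLY = 0-90 min, LATE = 91-180 min."""

    EARLY = "early"
    LATE = "late"


class Endpoint(str, enum.Enum):
    """The four dichotomized 90-day outcomes."""

    MRS = "mrs"
    BARTHEL = "barthel"
    NIHSS = "nihss"
    GOS = "gos"


class StratumKey(NamedTuple):
    """One of the unique randomization strata (center x time window)."""

    clinical_center: str
    time_stratum: TimeStratum


#: Baseline covariates the audit scans, in a stable order.
BASELINE_COVARIATES: tuple[str, ...] = (
    "nihss_baseline",
    "aspirin_pre",
    "hyperintense_artery",
    "small_vessel_subtype",
    "abnormal_ct",
    "loss_grey_white",
    "old_lesion_volume",
)

BINARY_COVARIATES: frozenset[str] = frozenset(
    {"aspirin_pre", "hyperintense_artery", "small_vessel_subtype", "abnormal_ct", "loss_grey_white"}
)
CONTINUOUS_COVARIATES: frozenset[str] = frozenset({"nihss_baseline", "old_lesion_volume"})

#: Covariates derived from the baseline CT scan.
CT_COVARIATES: tuple[str, ...] = (
    "hyperintense_artery",
    "abnormal_ct",
    "loss_grey_white",
    "old_lesion_volume",
)

_OUTCOME_FIELDS = ("mrs_90d", "barthel_90d", "nihss_90d", "gos_90d")

# (low, high) inclusive bounds for bounded scores.
_RANGES: dict[str, tuple[float, float]] = {
    "nihss_baseline": (0, 42),
    "mrs_90d": (0, 6),
    "barthel_90d": (0, 100),
    "nihss_90d": (0, 42),
    "gos_90d": (1, 5),
    "old_lesion_volume": (0, float("inf")),
}


@dataclass
class ParticipantRecord:
    """One enrolled participant.

    ``time_stratum`` and ``arm`` are always populated: a participant counts
    as randomized only once study drug started infusing, so every record in
    an audit has an allocation.  Outcome scores and baseline covariates may
    be missing (``None``); bounded scores outside their stated ranges are
    rejected at load time.
    """

    participant_id: str
    clinical_center: str
    time_stratum: TimeStratum
    arm: Arm
    enrollment_index: int | None = None
    nihss_baseline: int | None = None
    aspirin_pre: bool | None = None
    hyperintense_artery: bool | None = None
    small_vessel_subtype: bool | None = None
    abnormal_ct: bool | None = None
    loss_grey_white: bool | None = None
    old_lesion_volume: float | None = None
    mrs_90d: int | None = None
    barthel_90d: int | None = None
    nihss_90d: int | None = None
    gos_90d: int | None = None
    crossover: bool = False
    unblinded: bool = False

    def stratum(self) -> StratumKey:
        return StratumKey(self.clinical_center, self.time_stratum)

    def validate(self) -> list[str]:
        """Return invariant violations (empty list means the record is valid)."""
        problems: list[str] = []
        for name, (lo, hi) in _RANGES.items():
            value = getattr(self, name)
            if value is None:
                continue
            if not (lo <= value <= hi):
                problems.append(f"{name}={value!r} outside [{lo}, {hi}]")
        bi = self.barthel_90d
        if bi is not None and bi % 5 != 0:
            problems.append(f"barthel_90d={bi!r} not a multiple of 5")
        if self.enrollment_index is not None and self.enrollment_index < 1:
            problems.append(f"enrollment_index={self.enrollment_index!r} not positive")
        return problems


# ---------------------------------------------------------------------------
# Data dictionary & loading
# ---------------------------------------------------------------------------

_TRUE_CODES = {"1", "true", "t", "yes", "y"}
_FALSE_CODES = {"0", "false", "f", "no", "n"}

_MANDATORY_FIELDS = ("arm", "clinical_center", "time_stratum")

_INT_FIELDS = {"enrollment_index", "nihss_baseline", "mrs_90d", "barthel_90d", "nihss_90d", "gos_90d"}
_FLOAT_FIELDS = {"old_lesion_volume"}
_BOOL_FIELDS = BINARY_COVARIATES | {"crossover", "unblinded"}


class MissingColumnError(KeyError):
    """A column required by the data dictionary is absent from the table."""


class DecodeError(ValueError):
    """A cell value cannot be decoded to its target field."""


@dataclass
class DataDictionary:
    """Mapping from external column names to normalized record fields.

    ``columns`` maps an external header name to a :class:`ParticipantRecord`
    field; unmapped columns are retained in the raw table but ignored by the
    audit.  ``levels`` gives per-field decodings of categorical labels (for
    example ``{"arm": {"rt-PA": "treatment", "Placebo": "control"}}``);
    level matching is case-insensitive.  ``missing_codes`` are cell values
    treated as missing for any field.

    The time stratum is decoded either from a pre-coded label via ``levels``
    or, when the cell is numeric, from onset-to-treatment minutes using the
    closed intervals [0, 90] -> early and [91, 180] -> late.
    """

    columns: Mapping[str, str]
    levels: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    missing_codes: frozenset[str] = frozenset({"", "na", "nan", "null", ".", "unknown"})

    def __post_init__(self) -> None:
        valid = {f.name for f in dataclasses.fields(ParticipantRecord)}
        seen: dict[str, str] = {}
        for col, target in self.columns.items():
            if target not in valid:
                raise ValueError(f"dictionary maps {col!r} to unknown field {target!r}")
            if target in seen.values() and target != "participant_id":
                raise ValueError(f"field {target!r} mapped by more than one column")
            seen[col] = target

    def field_for(self, column: str) -> str | None:
        return self.columns.get(column)

    def decode(self, fieldname: str, raw: Any) -> Any:
        """Decode one cell to its normalized field value (``None`` = missing)."""
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return None
        text = str(raw).strip()
        if text.lower() in self.missing_codes:
            return None
        levels = {k.lower(): v for k, v in self.levels.get(fieldname, {}).items()}
        if text.lower() in levels:
            text = levels[text.lower()]
        if fieldname == "arm":
            try:
                return Arm(text.lower())
            except ValueError:
                raise DecodeError(f"undecodable arm label {raw!r}")
        if fieldname == "time_stratum":
            try:
                return TimeStratum(text.lower())
            except ValueError:
                pass
            try:
                minutes = float(text)
            except ValueError:
                raise DecodeError(f"undecodable time stratum {raw!r}")
            if 0 <= minutes <= 90:
                return TimeStratum.EARLY
            if 90 < minutes <= 180:
                return TimeStratum.LATE
            raise DecodeError(f"onset-to-treatment minutes {minutes} outside [0, 180]")
        if fieldname in _BOOL_FIELDS:
            low = text.lower()
            if low in _TRUE_CODES:
                return True
            if low in _FALSE_CODES:
                return False
            raise DecodeError(f"undecodable boolean {raw!r} for {fieldname}")
        if fieldname in _INT_FIELDS:
            try:
                value = float(text)
            except ValueError:
                raise DecodeError(f"undecodable integer {raw!r} for {fieldname}")
            if value != int(value):
                raise DecodeError(f"non-integer value {raw!r} for {fieldname}")
            return int(value)
        if fieldname in _FLOAT_FIELDS:
            try:
                return float(text)
            except ValueError:
                raise DecodeError(f"undecodable number {raw!r} for {fieldname}")
        return text


#: Identity dialect used by the synthetic generator and by test fixtures:
#: headers are the normalized field names themselves.
FIXTURE_DICTIONARY = DataDictionary(
    columns={f.name: f.name for f in dataclasses.fields(ParticipantRecord)},
)

#: Default dictionary for a public-archive export of the stroke trial.  The
#: archive's header names are not standardized across distributions, so this
#: is configuration, not fact: edit ``columns`` to match the export in hand.
DEFAULT_NINDS_DICTIONARY = DataDictionary(
    columns={
        "record_id": "participant_id",
        "ninds_center": "clinical_center",
        "onset_to_treatment_min": "time_stratum",
        "treatment_group": "arm",
        "nihss_baseline": "nihss_baseline",
        "aspirin_pretreatment": "aspirin_pre",
        "hyperdense_artery_ct": "hyperintense_artery",
        "small_vessel_occlusive": "small_vessel_subtype",
        "abnormal_baseline_ct": "abnormal_ct",
        "loss_grey_white_ct": "loss_grey_white",
        "old_lesion_volume": "old_lesion_volume",
        "rankin_90": "mrs_90d",
        "barthel_90": "barthel_90d",
        "nihss_90": "nihss_90d",
        "glasgow_90": "gos_90d",
        "crossover": "crossover",
        "unblinded": "unblinded",
    },
    levels={"arm": {"rt-PA": "treatment", "Alteplase": "treatment", "Placebo": "control"}},
)


@dataclass
class LoadResult:
    """Outcome of loading a trial table: records, a normalized frame and
    per-row diagnostics for rows that failed decoding or range invariants."""

    records: list[ParticipantRecord]
    diagnostics: list[dict[str, Any]]

    @property
    def n_loaded(self) -> int:
        return len(self.records)

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def load_trial_table(
    path: str | Path,
    dictionary: DataDictionary = FIXTURE_DICTIONARY,
    *,
    delimiter: str | None = None,
) -> LoadResult:
    """Load a delimited participant table into normalized records.

    The delimiter is autodetected (comma or tab) unless given.  A mandatory
    mapped column (arm, clinical_center, time_stratum) missing from the
    header is a hard :class:`MissingColumnError`; an undecodable cell or a
    range-invariant violation drops that row into ``diagnostics`` and the
    load continues.
    """
    path = Path(path)
    if delimiter is None:
        frame = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    mapped = {col: fld for col, fld in dictionary.columns.items() if col in frame.columns}
    present_fields = set(mapped.values())
    for mandatory in _MANDATORY_FIELDS:
        if mandatory not in present_fields:
            missing_cols = [c for c, f in dictionary.columns.items() if f == mandatory]
            raise MissingColumnError(
                f"mandatory column for field {mandatory!r} missing from table "
                f"(dictionary expects one of {missing_cols})"
            )

    records: list[ParticipantRecord] = []
    diagnostics: list[dict[str, Any]] = []
    for row_no, row in enumerate(frame.to_dict(orient="records"), start=2):  # header = line 1
        values: dict[str, Any] = {}
        errors: list[str] = []
        for col, fld in mapped.items():
            raw = row[col]
            try:
                values[fld] = dictionary.decode(fld, raw)
            except DecodeError as exc:
                errors.append(str(exc))
        if not errors:
            for mandatory in _MANDATORY_FIELDS:
                if values.get(mandatory) is None:
                    errors.append(f"mandatory field {mandatory!r} missing in row")
        if not errors:
            if values.get("participant_id") is None:
                values["participant_id"] = f"row{row_no}"
            values["crossover"] = bool(values.get("crossover") or False)
            values["unblinded"] = bool(values.get("unblinded") or False)
            record = ParticipantRecord(**values)
            errors.extend(record.validate())
            if not errors:
                records.append(record)
                continue
        diagnostics.append({"line": row_no, "errors": errors})
    return LoadResult(records=records, diagnostics=diagnostics)


def write_trial_table(
    records: Sequence[ParticipantRecord] | pd.DataFrame,
    path: str | Path,
    *,
    delimiter: str = ",",
) -> Path:
    """Write records as a normalized delimited table (round-trips through
    :func:`load_trial_table` with the fixture dialect)."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype == object or str(out[col].dtype) == "boolean":
            out[col] = out[col].map(
                lambda v: "" if v is None or v is pd.NA else (str(int(v)) if isinstance(v, (bool, np.bool_)) else str(v))
            )
    path = Path(path)
    out.to_csv(path, sep=delimiter, index=False)
    return path


def write_diagnostics(diagnostics: Iterable[Mapping[str, Any]], path: str | Path) -> Path:
    """Write diagnostics as line-oriented JSON."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for item in diagnostics:
            fh.write(json.dumps(dict(item), sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# Frame conversion
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Normalized DataFrame view (one row per participant, enum values as
    their string codes, missing values as ``pd.NA``)."""
    names = [f.name for f in dataclasses.fields(ParticipantRecord)]
    rows = []
    for rec in records:
        row = {}
        for name in names:
            value = getattr(rec, name)
            if isinstance(value, enum.Enum):
                value = value.value
            row[name] = pd.NA if value is None else value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=names)
    if len(frame) == 0:
        return frame
    for name in _INT_FIELDS:
        frame[name] = frame[name].astype("Int64")
    for name in _BOOL_FIELDS:
        frame[name] = frame[name].astype("boolean")
    frame["old_lesion_volume"] = pd.to_numeric(frame["old_lesion_volume"], errors="coerce")
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for _, row in frame.iterrows():
        values: dict[str, Any] = {}
        for f in dataclasses.fields(ParticipantRecord):
            value = row.get(f.name, None)
            if value is pd.NA or value is None or (isinstance(value, float) and np.isnan(value)):
                value = None
            elif f.name == "arm":
                value = Arm(value)
            elif f.name == "time_stratum":
                value = TimeStratum(value)
            elif f.name in _INT_FIELDS:
                value = int(value)
            elif f.name in _BOOL_FIELDS:
                value = bool(value)
            values[f.name] = value
        values["crossover"] = bool(values.get("crossover") or False)
        values["unblinded"] = bool(values.get("unblinded") or False)
        records.append(ParticipantRecord(**values))
    return records


def _as_frame(records: Sequence[ParticipantRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


# ---------------------------------------------------------------------------
# Endpoints & stratification
# ---------------------------------------------------------------------------

_ENDPOINT_FIELD = {
    Endpoint.MRS: "mrs_90d",
    Endpoint.BARTHEL: "barthel_90d",
    Endpoint.NIHSS: "nihss_90d",
    Endpoint.GOS: "gos_90d",
}


def dichotomize_endpoint(record: ParticipantRecord, endpoint: Endpoint | str) -> bool | None:
    """Favorable-outcome indicator for one participant.

    Rules: mRS favorable iff <= 1; BI favorable iff in {95, 100}; NIHSS
    favorable iff <= 1; GOS favorable iff == 1.  A missing raw score returns
    ``None`` (explicitly missing, never silently unfavorable).
    """
    endpoint = Endpoint(endpoint)
    score = getattr(record, _ENDPOINT_FIELD[endpoint])
    if score is None:
        return None
    if endpoint is Endpoint.MRS:
        return score <= 1
    if endpoint is Endpoint.BARTHEL:
        return score in (95, 100)
    if endpoint is Endpoint.NIHSS:
        return score <= 1
    return score == 1


def dichotomize_frame(frame: pd.DataFrame, endpoint: Endpoint | str) -> pd.Series:
    """Vectorized favorable indicator (nullable boolean series)."""
    endpoint = Endpoint(endpoint)
    score = frame[_ENDPOINT_FIELD[endpoint]]
    if endpoint is Endpoint.MRS:
        out = score <= 1
    elif endpoint is Endpoint.BARTHEL:
        out = score.isin([95, 100]) & score.notna()
    elif endpoint is Endpoint.NIHSS:
        out = score <= 1
    else:
        out = score == 1
    out = out.astype("boolean")
    out[score.isna()] = pd.NA
    return out


def stratify(records: Sequence[ParticipantRecord] | pd.DataFrame) -> dict[StratumKey, pd.DataFrame]:
    """Partition records into the unique randomization strata.

    The sub-frames are disjoint and exhaustive; empty strata are omitted
    (the mapping only contains observed center x time combinations).
    """
    frame = _as_frame(records)
    if len(frame) == 0:
        return {}
    out: dict[StratumKey, pd.DataFrame] = {}
    for (center, ts), sub in frame.groupby(["clinical_center", "time_stratum"], sort=True, observed=True):
        out[StratumKey(str(center), TimeStratum(ts))] = sub
    return out
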