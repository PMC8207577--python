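"""Patient-level cohort I/O, mortality outcome derivation, and the exclusion cascade.

Records are plain frozen dataclasses with closed categorical vocabularies.
CSV round-tripping uses a documented column set; an optional schema mapping
renames columns on the way in.  Exclusions are tallied under exactly one
reason each, in a fixed precedence order, so reports partition the input.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import numbers
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Optional, Sequence

log = logging.getLogger(__name__)

SEXES = frozenset({"male", "female"})
CAUSES = frozenset({"disease", "non_disease"})
AVPU_LEVELS = frozenset({"A", "V", "P", "U"})
ED_RESULTS = frozenset({"discharged", "admitted", "died", "transferred", "hopeless_discharge"})
HOSPITAL_RESULTS = frozenset({"discharged", "died", "hopeless_discharge", "not_admitted"})

#: results counted as death, in the ED or after admission
DEATH_RESULTS = frozenset({"died", "hopeless_discharge"})

#: canonical CSV column order
CSV_COLUMNS = (
    "id", "age", "sex", "cause", "avpu",
    "sbp", "dbp", "hr", "rr", "bt", "spo2",
    "arrival_arrest", "transferred_out", "ed_result", "hospital_result",
)

#: columns that must be present (possibly via schema mapping); vital-sign
#: columns may be absent entirely, in which case the field is absent
MANDATORY_COLUMNS = (
    "id", "age", "sex", "cause", "avpu",
    "arrival_arrest", "transferred_out", "ed_result", "hospital_result",
)

VITAL_FIELDS = ("sbp", "dbp", "hr", "rr", "bt", "spo2")

#: exclusion reasons in precedence order; a record failing several rules is
#: tallied under the first one only
EXCLUSION_REASONS = (
    "under_15", "transfer_out", "arrival_arrest", "missing_variable", "implausible_value",
)

#: fields whose absence triggers the missing_variable exclusion (dbp and bt
#: are carried but not required: the prediction model does not use them)
REQUIRED_FOR_SCORING = ("sex", "cause", "avpu", "sbp", "hr", "rr", "spo2")

MAX_PLAUSIBLE_BP = 300.0
MAX_PLAUSIBLE_SPO2 = 100.0


class CohortError(ValueError):
    """Base class for cohort-level input errors."""


class SchemaError(CohortError):
    """A mandatory column is missing from the CSV header."""


class EmptyInputError(CohortError):
    """The CSV contains a header but no data rows."""


class RecordValidationError(CohortError):
    """A field value is outside its closed vocabulary or invariant."""


@dataclass(frozen=True)
class PatientRecord:
    """One ED visit: demographics, consciousness, vitals and outcomes.

    Vital signs are optional floats; ``None`` means not recorded.  The pair
    (``ed_result``, ``hospital_result``) satisfies: ``hospital_result`` is
    ``not_admitted`` if and only if ``ed_result`` is not ``admitted``.
    """

    id: str
    age: int
    sex: str
    cause: str
    avpu: str
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    hr: Optional[float] = None
    rr: Optional[float] = None
    bt: Optional[float] = None
    spo2: Optional[float] = None
    arrival_arrest: bool = False
    transferred_out: bool = False
    ed_result: str = "discharged"
    hospital_result: str = "not_admitted"

    def __post_init__(self) -> None:
        if not isinstance(self.age, numbers.Integral) or self.age < 0:
            raise RecordValidationError(f"record {self.id!r}: age must be a non-negative integer, got {self.age!r}")
        _check_enum(self.id, "sex", self.sex, SEXES)
        _check_enum(self.id, "cause", self.cause, CAUSES)
        _check_enum(self.id, "avpu", self.avpu, AVPU_LEVELS)
        _check_enum(self.id, "ed_result", self.ed_result, ED_RESULTS)
        _check_enum(self.id, "hospital_result", self.hospital_result, HOSPITAL_RESULTS)
        for name in VITAL_FIELDS:
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise RecordValidationError(
                    f"record {self.id!r}: {name} must be a finite non-negative number, got {value!r}"
                )
        not_admitted = self.hospital_result == "not_admitted"
        if not_admitted != (self.ed_result != "admitted"):
            raise RecordValidationError(
                f"record {self.id!r}: hospital_result must be 'not_admitted' exactly when "
                f"ed_result is not 'admitted' (got {self.ed_result!r}/{self.hospital_result!r})"
            )


def _check_enum(rid: str, name: str, value: str, allowed: frozenset) -> None:
    if value not in allowed:
        raise RecordValidationError(
            f"record {rid!r}: invalid {name} {value!r} (allowed: {sorted(allowed)})"
        )


@dataclass
class ExclusionReport:
    """Audit of the exclusion cascade: each input record is either retained
    or counted under exactly one exclusion reason."""

    n_input: int
    n_retained: int
    counts_by_reason: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for reason in EXCLUSION_REASONS:
            self.counts_by_reason.setdefault(reason, 0)
        if self.n_input != self.n_retained + sum(self.counts_by_reason.values()):
            raise ValueError("exclusion report does not partition the input")

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "counts_by_reason": dict(self.counts_by_reason),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def log_lines(self) -> list[str]:
        lines = [f"exclusions: {self.n_input} in, {self.n_retained} retained, {self.n_excluded} excluded"]
        for reason in EXCLUSION_REASONS:
            n = self.counts_by_reason[reason]
            if n:
                lines.append(f"  {reason}: {n}")
        return lines


def derive_outcome(record: PatientRecord) -> str:
    """Binary outcome for a visit: ``"died"`` or ``"survived"``.

    Death covers death in the ED, death in hospital after admission, and
    discharge with no realistic chance of recovery (either setting).
    """
    if record.ed_result in DEATH_RESULTS or record.hospital_result in DEATH_RESULTS:
        return "died"
    return "survived"


def exclusion_reason(record: PatientRecord) -> Optional[str]:
    """First exclusion rule the record fails, or ``None`` if retained."""
    if record.age < 15:
        return "under_15"
    if record.transferred_out or record.ed_result == "transferred":
        return "transfer_out"
    if record.arrival_arrest:
        return "arrival_arrest"
    for name in REQUIRED_FOR_SCORING:
        if getattr(record, name) is None:
            return "missing_variable"
    if record.sbp is not None and record.sbp > MAX_PLAUSIBLE_BP:
        return "implausible_value"
    if record.dbp is not None and record.dbp > MAX_PLAUSIBLE_BP:
        return "implausible_value"
    if record.spo2 is not None and record.spo2 > MAX_PLAUSIBLE_SPO2:
        return "implausible_value"
    return None


def apply_exclusions(cohort: Sequence[PatientRecord]) -> tuple[list[PatientRecord], ExclusionReport]:
    """Apply the exclusion cascade; returns retained records and an audit report."""
    retained: list[PatientRecord] = []
    counts = {reason: 0 for reason in EXCLUSION_REASONS}
    for record in cohort:
        reason = exclusion_reason(record)
        if reason is None:
            retained.append(record)
        else:
            counts[reason] += 1
    report = ExclusionReport(n_input=len(cohort), n_retained=len(retained), counts_by_reason=counts)
    for line in report.log_lines():
        log.info(line)
    return retained, report


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def _parse_bool(rid: str, name: str, cell: str) -> bool:
    lowered = cell.strip().lower()
    if lowered in _TRUE:
        return True
    if lowered in _FALSE:
        return False
    raise RecordValidationError(f"record {rid!r}: cannot parse boolean {name} from {cell!r}")


def read_cohort(
    path,
    schema: Optional[Mapping[str, str]] = None,
) -> list[PatientRecord]:
    """Read patient records from a CSV file.

    Parameters
    ----------
    path : str or Path
        UTF-8, comma-separated, header row required.
    schema : mapping, optional
        Maps record field names to CSV column names; unmapped fields use
        their own name as column name.

    Unparseable or negative vital-sign cells become absent values with a
    logged warning; categorical fields are validated strictly and raise
    :class:`RecordValidationError` naming the row and field.
    """
    colmap = {name: name for name in CSV_COLUMNS}
    if schema:
        unknown = set(schema) - set(CSV_COLUMNS)
        if unknown:
            raise SchemaError(f"schema maps unknown fields: {sorted(unknown)}")
        colmap.update(schema)

    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path}: file is empty")
        header = set(reader.fieldnames)
        for fld in MANDATORY_COLUMNS:
            if colmap[fld] not in header:
                raise SchemaError(f"{path}: missing mandatory column {colmap[fld]!r} (field {fld!r})")
        if schema:
            for fld, col in schema.items():
                if col not in header:
                    raise SchemaError(f"{path}: schema maps {fld!r} to missing column {col!r}")
        missing_vital_cols = [v for v in VITAL_FIELDS if colmap[v] not in header]
        if missing_vital_cols:
            log.warning("columns absent, fields left unrecorded: %s", missing_vital_cols)

        records: list[PatientRecord] = []
        bad_vitals: dict[str, int] = {}
        for row_number, row in enumerate(reader, start=2):
            rid = (row.get(colmap["id"]) or "").strip() or f"row{row_number}"
            try:
                age_cell = row[colmap["age"]].strip()
                age_float = float(age_cell)
                if not age_float.is_integer() or age_float < 0:
                    raise ValueError
                age = int(age_float)
            except (ValueError, AttributeError):
                raise RecordValidationError(
                    f"{path} row {row_number}: cannot parse age from {row.get(colmap['age'])!r}"
                ) from None

            vitals: dict[str, Optional[float]] = {}
            for name in VITAL_FIELDS:
                col = colmap[name]
                cell = (row.get(col) or "").strip()
                if cell == "" or col not in header:
                    vitals[name] = None
                    continue
                try:
                    value = float(cell)
                    if not math.isfinite(value) or value < 0:
                        raise ValueError
                    vitals[name] = value
                except ValueError:
                    vitals[name] = None
                    bad_vitals[name] = bad_vitals.get(name, 0) + 1

            try:
                record = PatientRecord(
                    id=rid,
                    age=age,
                    sex=(row.get(colmap["sex"]) or "").strip(),
                    cause=(row.get(colmap["cause"]) or "").strip(),
                    avpu=(row.get(colmap["avpu"]) or "").strip(),
                    arrival_arrest=_parse_bool(rid, "arrival_arrest", row.get(colmap["arrival_arrest"]) or ""),
                    transferred_out=_parse_bool(rid, "transferred_out", row.get(colmap["transferred_out"]) or ""),
                    ed_result=(row.get(colmap["ed_result"]) or "").strip(),
                    hospital_result=(row.get(colmap["hospital_result"]) or "").strip(),
                    **vitals,
                )
            except RecordValidationError as exc:
                raise RecordValidationError(f"{path} row {row_number}: {exc}") from None
            records.append(record)

    if not records:
        raise EmptyInputError(f"{path}: no data rows")
    for name, count in bad_vitals.items():
        log.warning("%s: %d unparseable %s value(s) treated as unrecorded", path, count, name)
    return records


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write records as CSV using the canonical column set (round-trips with
    :func:`read_cohort`)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for record in records:
            row = []
            for name in CSV_COLUMNS:
                value = getattr(record, name)
                if value is None:
                    row.append("")
                elif isinstance(value, bool):
                    row.append("true" if value else "false")
                else:
                    row.append(value)
            writer.writerow(row)
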