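"""Within-record checks: univariate range/format validation and the
multivariate consistency rules (topography x morphology, age x tumour type,
TNM x stage, basis of diagnosis x morphology, date coherence).

Every check is a pure function of ``(record, tables)`` returning zero or
more :class:`CheckMessage`; the engine concatenates the messages of all
checks. A field that fails format or range validation is excluded from the
multivariate checks that use it, so a single typo produces one message
instead of a cascade.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .protocols import (
    ProtocolDef,
    ReferenceTables,
    VariableDef,
    canonical_topography,
)

#: Message codes emitted anywhere in the package, with report-legend text.
CODE_LEGEND: dict[str, str] = {
    "E-MISS": "Value missing",
    "E-FORM": "Format error",
    "E-OUTR": "Value out of range",
    "E-DATE": "Incoherent date order",
    "E-DUPL": "Perfect duplicate record (same patient and tumour IDs)",
    "W-MOTO": "Morphology + Topography not valid",
    "W-AGMT": "Unlikely Age + tumour type",
    "W-TNMS": "Inconsistency between TNM and stage",
    "W-BDMO": "Morphology too specific for the basis of diagnosis",
    "W-MULP": "Multiple records of the same primary tumour",
    "C-EMPT": "Dataset empty or below the minimum number of records",
    "C-HEAD": "File header does not match the protocol",
    "C-NCOL": "Row with wrong number of columns",
    "C-CAP": "Message cap exceeded; validation aborted",
}


def severity_for(code: str) -> str:
    if code.startswith("W-"):
        return "warning"
    if code.startswith("E-"):
        return "error"
    return "critical"


@dataclass(frozen=True)
class CheckMessage:
    """One error/warning/critical finding."""

    code: str
    variables: tuple[str, ...]
    values: tuple[str, ...]
    line_no: int
    detail: str
    severity: str = ""
    #: report context: Pat, Tum, BoD, Topo, Morpho, Beh, Sex, DoI, DoB
    context: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        expected = severity_for(self.code)
        if self.severity == "":
            object.__setattr__(self, "severity", expected)
        elif self.severity != expected:
            raise ValueError(
                f"severity {self.severity!r} inconsistent with code "
                f"{self.code!r}")


# sentinel stored in ParsedRecord.parsed for unparseable fields
class _ParseFailed:
    def __repr__(self):  # pragma: no cover
        return "<parse-failed>"


PARSE_FAILED = _ParseFailed()

# per-variable status values
OK = "ok"
EMPTY = "empty"
CODED_MISSING = "coded_missing"
FORMAT_ERROR = "format_error"
OUT_OF_RANGE = "out_of_range"


@dataclass
class ParsedRecord:
    line_no: int
    values: dict[str, str]          # raw strings, keyed by variable name
    parsed: dict[str, object]       # typed values or PARSE_FAILED
    status: dict[str, str]
    pat_id: str = ""
    tum_id: str = ""

    def usable(self, name: str) -> bool:
        """True when the field is present, parseable and in range."""
        return self.status.get(name) == OK


_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def _parse_value(raw: str, var: VariableDef):
    """Typed value for a nonempty raw string, or PARSE_FAILED."""
    if var.datatype == "date":
        if not _DATE_RE.match(raw):
            return PARSE_FAILED
        try:
            return _dt.date.fromisoformat(raw)
        except ValueError:
            return PARSE_FAILED
    if var.datatype in ("integer-code", "count"):
        try:
            return int(raw)
        except ValueError:
            return PARSE_FAILED
    if var.datatype == "probability":
        try:
            return float(raw)
        except ValueError:
            return PARSE_FAILED
    # text-code: canonicalise topography-shaped values for table lookups
    if var.allowed is not None and var.allowed.kind == "table" \
            and var.allowed.table == "topo":
        return canonical_topography(raw)
    return raw


def _in_range(raw: str, parsed, var: VariableDef,
              tables: Optional[ReferenceTables]) -> bool:
    spec = var.allowed
    if spec is None:
        return True
    if spec.kind == "set":
        return raw in spec.values
    if spec.kind == "range":
        return spec.lo <= parsed <= spec.hi
    if spec.kind == "pattern":
        return re.fullmatch(spec.pattern, raw) is not None
    # table-backed domains
    if tables is None:
        return True
    if spec.table == "topo":
        return parsed in tables.topo_valid
    if spec.table == "morpho":
        return raw in tables.morpho_valid
    if spec.table.startswith("tnm_"):
        axis = spec.table.split("_", 1)[1]
        return raw in tables.tnm_values.get(axis, frozenset())
    return True


def parse_record(fields: Sequence[str], protocol: ProtocolDef,
                 tables: Optional[ReferenceTables], line_no: int
                 ) -> ParsedRecord:
    """Map one raw row (already split into fields) to a ParsedRecord."""
    if len(fields) != len(protocol.variables):
        raise ValueError(
            f"row {line_no}: {len(fields)} fields for a "
            f"{len(protocol.variables)}-variable protocol")
    values: dict[str, str] = {}
    parsed: dict[str, object] = {}
    status: dict[str, str] = {}
    for var, raw in zip(protocol.variables, fields):
        raw = raw.strip()
        values[var.name] = raw
        if raw == "":
            parsed[var.name] = None
            status[var.name] = EMPTY
            continue
        value = _parse_value(raw, var)
        parsed[var.name] = value
        if value is PARSE_FAILED:
            status[var.name] = FORMAT_ERROR
        elif raw in var.missing_codes:
            status[var.name] = CODED_MISSING
        elif not _in_range(raw, value, var, tables):
            status[var.name] = OUT_OF_RANGE
        else:
            status[var.name] = OK
    return ParsedRecord(
        line_no=line_no, values=values, parsed=parsed, status=status,
        pat_id=values.get("Pat", ""), tum_id=values.get("Tum", ""),
    )


CONTEXT_VARS = ("Pat", "Tum", "BoD", "Topo", "Morpho", "Beh", "Sex",
                "DoI", "DoB")


def record_context(record: ParsedRecord) -> tuple[tuple[str, str], ...]:
    return tuple((v, record.values[v]) for v in CONTEXT_VARS
                 if v in record.values)


def _msg(record: ParsedRecord, code: str, variables: Sequence[str],
         detail: str) -> CheckMessage:
    return CheckMessage(
        code=code,
        variables=tuple(variables),
        values=tuple(record.values.get(v, "") for v in variables),
        line_no=record.line_no,
        detail=detail,
        context=record_context(record),
    )


# ---------------------------------------------------------------------------
# Univariate checks
# ---------------------------------------------------------------------------

def check_missing(record: ParsedRecord, var: VariableDef) -> list[CheckMessage]:
    """E-MISS when a required field is empty; coded unknowns are not missing."""
    if var.required and record.status.get(var.name) == EMPTY:
        return [_msg(record, "E-MISS", [var.name],
                     f"required variable {var.name} has no value")]
    return []


def check_format(record: ParsedRecord, var: VariableDef) -> list[CheckMessage]:
    if record.status.get(var.name) == FORMAT_ERROR:
        return [_msg(record, "E-FORM", [var.name],
                     f"value does not parse as {var.datatype}")]
    return []


def check_range(record: ParsedRecord, var: VariableDef,
                tables: Optional[ReferenceTables] = None) -> list[CheckMessage]:
    if record.status.get(var.name) == OUT_OF_RANGE:
        return [_msg(record, "E-OUTR", [var.name],
                     f"value outside the allowed range for {var.name}")]
    return []


def run_univariate(record: ParsedRecord, protocol: ProtocolDef,
                   tables: Optional[ReferenceTables] = None
                   ) -> list[CheckMessage]:
    out: list[CheckMessage] = []
    for var in protocol.variables:
        out += check_missing(record, var)
        out += check_format(record, var)
        out += check_range(record, var, tables)
    return out


# ---------------------------------------------------------------------------
# Multivariate checks (one record)
# ---------------------------------------------------------------------------

def check_topo_morpho(record: ParsedRecord,
                      tables: ReferenceTables) -> list[CheckMessage]:
    """W-MOTO when (topography, morphology) is absent from the allowed table."""
    if not (record.usable("Topo") and record.usable("Morpho")):
        return []
    topo = record.parsed["Topo"]
    morpho = record.values["Morpho"]
    if (topo, morpho) in tables.topo_morpho:
        return []
    return [_msg(record, "W-MOTO", ["Topo", "Morpho"],
                 f"combination {topo} + {morpho} not in the allowed "
                 f"topography/morphology table")]


def age_at_diagnosis(record: ParsedRecord) -> Optional[int]:
    """Completed years between birth and diagnosis.

    Prefers the DoB/DoI date pair; falls back to an explicit Age variable
    when one of the dates is unusable.
    """
    if record.usable("DoB") and record.usable("DoI"):
        dob = record.parsed["DoB"]
        doi = record.parsed["DoI"]
        age = doi.year - dob.year - (
            (doi.month, doi.day) < (dob.month, dob.day))
        return age if age >= 0 else None
    if record.usable("Age"):
        return record.parsed["Age"]
    return None


def check_age_topo_morpho(record: ParsedRecord,
                          tables: ReferenceTables) -> list[CheckMessage]:
    """W-AGMT when age/topography/morphology matches an unlikely combination."""
    if not (record.usable("Topo") and record.usable("Morpho")):
        return []
    age = age_at_diagnosis(record)
    if age is None:
        return []
    topo = record.parsed["Topo"]
    morpho = record.values["Morpho"]
    for entry in tables.age_topo_morpho_unlikely:
        if not entry.age_min <= age <= entry.age_max:
            continue
        if morpho not in entry.morpho_codes:
            continue
        if any(topo.startswith(p) for p in entry.topo_prefixes):
            return [_msg(
                record, "W-AGMT", ["Topo", "Morpho"],
                f"morphology {morpho} at site {topo} is unlikely at age "
                f"{age}")]
    return []


def normalize_tnm_category(value: str) -> str:
    """Reduce a T/N/M value to its main category (``1biv`` -> ``1``)."""
    v = value.strip()
    if v[:2].lower() == "is":
        return "is"
    if v and v[0].isdigit():
        return v[0]
    return "X"


_STAGE_ROMAN_RE = re.compile(r"^(IV|III|II|I|0)")


def stage_group_of(stage: str) -> Optional[str]:
    m = _STAGE_ROMAN_RE.match(stage.strip().upper())
    return m.group(1) if m else None


def _check_tnm_triple(record: ParsedRecord, tables: ReferenceTables,
                      prefix: str) -> tuple[list[CheckMessage], bool]:
    """Messages and a not-evaluable flag for one complete c- or p- triple."""
    names = [f"{prefix}T", f"{prefix}N", f"{prefix}M"]
    if not all(record.usable(n) for n in names):
        return [], False
    if not record.usable("Stage"):
        return [], False
    t, n, m = (normalize_tnm_category(record.values[x]) for x in names)
    if m == "X":
        return [], False
    recorded = stage_group_of(record.values["Stage"])
    if recorded is None:
        return [], False

    edition = record.values.get("TNMEdition", "").strip() or "7"
    group = None
    if record.usable("Topo"):
        group = tables.topo_groups.get(record.parsed["Topo"][:3])
    expected = None
    if group is not None:
        expected = tables.stage_for(edition, group, t, n, m)
    if expected is None:
        if m == "1":
            expected = "IV"  # any M1 is stage IV, whatever the site
        else:
            return [], True  # site/edition not covered: not evaluable
    if stage_group_of(expected) != recorded:
        return [_msg(
            record, "W-TNMS", names + ["Stage"],
            f"{prefix}T{record.values[names[0]]} "
            f"{prefix}N{record.values[names[1]]} "
            f"{prefix}M{record.values[names[2]]} implies stage "
            f"{expected}, record says {record.values['Stage']}")], False
    return [], False


def check_tnm_stage(record: ParsedRecord,
                    tables: ReferenceTables) -> list[CheckMessage]:
    """W-TNMS when a complete TNM triple contradicts the recorded stage.

    Clinical and pathological triples are checked independently; an M1
    triple with a stage other than IV always warns.
    """
    msgs, _ = check_tnm_stage_ex(record, tables)
    return msgs


def check_tnm_stage_ex(record: ParsedRecord, tables: ReferenceTables
                       ) -> tuple[list[CheckMessage], int]:
    """As :func:`check_tnm_stage`, also counting not-evaluable triples."""
    messages: list[CheckMessage] = []
    not_evaluable = 0
    for prefix in ("c", "p"):
        if not all(record.values.get(f"{prefix}{axis}") is not None
                   for axis in "TNM"):
            continue
        msgs, ne = _check_tnm_triple(record, tables, prefix)
        messages += msgs
        not_evaluable += int(ne)
    return messages, not_evaluable


def check_bod_morpho(record: ParsedRecord,
                     tables: ReferenceTables) -> list[CheckMessage]:
    """W-BDMO: specific morphology without microscopic verification."""
    if not (record.usable("BoD") and record.usable("Morpho")):
        return []
    bod = record.values["BoD"]
    morpho = record.values["Morpho"]
    if bod in tables.non_microscopic_bod and morpho in tables.bod_specificity:
        return [_msg(record, "W-BDMO", ["BoD", "Morpho"],
                     f"morphology {morpho} is too specific for "
                     f"non-microscopic basis of diagnosis {bod}")]
    return []


def check_date_order(record: ParsedRecord) -> list[CheckMessage]:
    """E-DATE: diagnosis before birth, or follow-up before diagnosis."""
    out: list[CheckMessage] = []
    if record.usable("DoB") and record.usable("DoI"):
        if record.parsed["DoI"] < record.parsed["DoB"]:
            out.append(_msg(record, "E-DATE", ["DoB", "DoI"],
                            "date of incidence precedes date of birth"))
    if record.usable("DoI") and record.usable("DoF"):
        if record.parsed["DoF"] < record.parsed["DoI"]:
            out.append(_msg(record, "E-DATE", ["DoI", "DoF"],
                            "follow-up date precedes date of incidence"))
    return out


def run_record_checks(record: ParsedRecord, protocol: ProtocolDef,
                      tables: ReferenceTables
                      ) -> tuple[list[CheckMessage], int]:
    """All checks for one record: (messages, not-evaluable TNM count)."""
    messages = run_univariate(record, protocol, tables)
    not_evaluable = 0
    if protocol.file_kind == "incidence":
        messages += check_topo_morpho(record, tables)
        messages += check_age_topo_morpho(record, tables)
        tnm_msgs, ne = check_tnm_stage_ex(record, tables)
        messages += tnm_msgs
        not_evaluable += ne
        messages += check_bod_morpho(record, tables)
        messages += check_date_order(record)
    return messages, not_evaluable
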