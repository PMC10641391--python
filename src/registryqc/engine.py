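"""Validation engine: pre-record structure checks and duplicate scan,
streaming record cycle, external sort of per-rule temp files, and the
post-record cycle for cross-record rules.

The engine never holds the dataset in memory: the record cycle keeps one
record at a time, the external sort keeps at most ``chunk_size`` records,
and the post-record cycle one patient batch. Cross-record rules receive
their input through per-rule temporary files of *acceptable* records
(``qcs_acceptable_by_rule_<id>.csv``), sorted by the rule's key
(``...-by-PAT.csv`` for the patient ID).
"""

from __future__ import annotations

import csv
import datetime as _dt
import heapq
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from . import mpt as _mpt
from . import reporting as _reporting
from .protocols import (
    ProtocolDef,
    ReferenceTables,
    load_protocol,
    load_reference_tables,
)
from .rules_core import (
    CheckMessage,
    ParsedRecord,
    parse_record,
    record_context,
    run_record_checks,
)

DEFAULT_CHUNK_SIZE = 50_000
DEFAULT_MESSAGE_CAP = 10_000_000

LOG_FILENAME = "qcs_rule_output.csv"


@dataclass(frozen=True)
class RuleAcceptance:
    """Per-record decision whether a cross-record rule may use the record."""

    rule_id: str
    accepted: bool
    blocking_messages: tuple[tuple[str, str], ...] = ()  # (variable, code)


@dataclass
class RunResult:
    total_records: int
    messages_by_code: dict[str, int]
    blocking_failure: Optional[str] = None
    output_paths: dict[str, Path] = field(default_factory=dict)
    messages: list[CheckMessage] = field(default_factory=list)
    tnm_not_evaluable: int = 0
    mpt_clusters: int = 0

    @property
    def total_messages(self) -> int:
        return sum(self.messages_by_code.values())


def _critical(code: str, detail: str, line_no: int = 0,
              variables: tuple[str, ...] = ()) -> CheckMessage:
    return CheckMessage(code=code, variables=variables, values=(),
                        line_no=line_no, detail=detail)


def _iter_rows(path: Path, delimiter: str) -> Iterator[tuple[int, list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for line_no, row in enumerate(reader, start=1):
            yield line_no, row


# ---------------------------------------------------------------------------
# Pre-record cycle
# ---------------------------------------------------------------------------

def validate_file_structure(path: Path, protocol: ProtocolDef,
                            *, delimiter: Optional[str] = None,
                            min_records: int = 1) -> list[CheckMessage]:
    """Structural (critical) findings: emptiness, header, column counts."""
    path = Path(path)
    if not path.is_file():
        raise OSError(f"input file not found: {path}")
    delim = delimiter or protocol.delimiter
    n_vars = len(protocol.variables)
    messages: list[CheckMessage] = []
    data_rows = 0
    for line_no, row in _iter_rows(path, delim):
        if protocol.has_header and line_no == 1:
            if [c.strip() for c in row] != list(protocol.variable_names):
                messages.append(_critical(
                    "C-HEAD",
                    f"header does not match protocol {protocol.id} "
                    f"({len(row)} columns, expected {n_vars})", line_no=1))
            continue
        if len(row) != n_vars:
            messages.append(_critical(
                "C-NCOL", f"{len(row)} columns, expected {n_vars}",
                line_no=line_no))
            continue
        data_rows += 1
    if data_rows < min_records:
        messages.insert(0, _critical(
            "C-EMPT",
            f"dataset holds {data_rows} record(s); minimum is {min_records}"))
    return messages


def detect_perfect_duplicates(
        record_stream: Iterable[ParsedRecord]) -> list[CheckMessage]:
    """One E-DUPL per record whose (patient, tumour) key was already seen.

    Memory grows with the number of distinct keys only; the first
    occurrence of a key is never flagged.
    """
    seen: set[tuple[str, str]] = set()
    messages = []
    for record in record_stream:
        key = (record.pat_id, record.tum_id)
        if key in seen:
            messages.append(CheckMessage(
                code="E-DUPL", variables=("Pat", "Tum"),
                values=key, line_no=record.line_no,
                detail=(f"same patient and tumour IDs as an earlier record "
                        f"(Pat={record.pat_id}, Tum={record.tum_id})"),
                context=record_context(record)))
        else:
            seen.add(key)
    return messages


# ---------------------------------------------------------------------------
# Record cycle
# ---------------------------------------------------------------------------

def decide_acceptance(rule_id: str, protocol: ProtocolDef,
                      messages: Sequence[CheckMessage]) -> RuleAcceptance:
    """A record is acceptable for a rule unless one of its messages hits the
    rule's critical (variable, code) pairs."""
    criteria = protocol.acceptance_criteria.get(rule_id, frozenset())
    blocking = tuple(
        (var, msg.code)
        for msg in messages
        for var in msg.variables
        if (var, msg.code) in criteria)
    return RuleAcceptance(rule_id=rule_id, accepted=not blocking,
                          blocking_messages=blocking)


def acceptable_temp_path(workdir: Path, rule_id: str) -> Path:
    return Path(workdir) / f"qcs_acceptable_by_rule_{rule_id}.csv"


@dataclass
class RecordCycleResult:
    messages: list[CheckMessage]
    temp_files: dict[str, Path]
    total_records: int = 0
    tnm_not_evaluable: int = 0
    capped: bool = False


def run_record_cycle(record_stream: Iterable[ParsedRecord],
                     protocol: ProtocolDef, tables: ReferenceTables,
                     workdir: Path, *,
                     message_cap: int = DEFAULT_MESSAGE_CAP
                     ) -> RecordCycleResult:
    """Apply all within-record checks one record at a time.

    Acceptable records are appended to one temp file per cross-record rule
    as delimited lines ``line_no;field1;...;fieldN``, so the post-record
    cycle can re-anchor its messages to the original dataset order.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    result = RecordCycleResult(messages=[], temp_files={})
    writers = {}
    handles = []
    try:
        for rule_id in protocol.rules:
            temp = acceptable_temp_path(workdir, rule_id)
            fh = open(temp, "w", newline="", encoding="utf-8")
            handles.append(fh)
            writers[rule_id] = csv.writer(fh, delimiter=";")
            result.temp_files[rule_id] = temp
        for record in record_stream:
            result.total_records += 1
            messages, not_evaluable = run_record_checks(
                record, protocol, tables)
            result.tnm_not_evaluable += not_evaluable
            result.messages.extend(messages)
            if len(result.messages) > message_cap:
                result.messages.append(_critical(
                    "C-CAP", f"more than {message_cap} messages produced",
                    line_no=record.line_no))
                result.capped = True
                break
            for rule_id in protocol.rules:
                acceptance = decide_acceptance(rule_id, protocol, messages)
                if acceptance.accepted:
                    writers[rule_id].writerow(
                        [record.line_no]
                        + [record.values[v] for v in protocol.variable_names])
    finally:
        for fh in handles:
            fh.close()
    return result


# ---------------------------------------------------------------------------
# Sorting of temporary files
# ---------------------------------------------------------------------------

def external_sort(temp_file: Path, key: str, protocol: ProtocolDef,
                  chunk_size: int = DEFAULT_CHUNK_SIZE) -> Path:
    """Stable external merge sort of a temp file by one variable.

    Peak memory is bounded by ``chunk_size`` records; ties are broken by
    the original line number, so batch order within a key is reproducible.
    The output file carries a ``-by-<KEY>`` suffix (``-by-PAT`` for the
    patient ID).
    """
    temp_file = Path(temp_file)
    key_idx = protocol.by_name[key].position  # row[0] is the line number
    sort_key = lambda row: (row[key_idx], int(row[0]))
    out_path = temp_file.with_name(
        f"{temp_file.stem}-by-{key[:3].upper()}{temp_file.suffix}")

    runs: list[Path] = []
    with tempfile.TemporaryDirectory(dir=temp_file.parent) as rundir:
        with open(temp_file, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter=";")
            chunk: list[list[str]] = []
            for row in reader:
                chunk.append(row)
                if len(chunk) >= chunk_size:
                    runs.append(_write_run(rundir, len(runs),
                                           sorted(chunk, key=sort_key)))
                    chunk = []
            if chunk:
                runs.append(_write_run(rundir, len(runs),
                                       sorted(chunk, key=sort_key)))

        def read_run(p: Path) -> Iterator[list[str]]:
            with open(p, newline="", encoding="utf-8") as fh:
                yield from csv.reader(fh, delimiter=";")

        with open(out_path, "w", newline="", encoding="utf-8") as out:
            writer = csv.writer(out, delimiter=";")
            for row in heapq.merge(*(read_run(p) for p in runs),
                                   key=sort_key):
                writer.writerow(row)
    return out_path


def _write_run(rundir, index: int, rows: list[list[str]]) -> Path:
    path = Path(rundir) / f"run_{index:06d}.csv"
    with open(path, "w", newline="", encoding="utf-8") as fh:
        csv.writer(fh, delimiter=";").writerows(rows)
    return path


# ---------------------------------------------------------------------------
# Post-record cycle
# ---------------------------------------------------------------------------

def _iter_patient_batches(sorted_file: Path, protocol: ProtocolDef,
                          tables: ReferenceTables
                          ) -> Iterator[list[ParsedRecord]]:
    """Batches of consecutive records sharing the patient ID.

    Raises on a decreasing key: the input must be sorted.
    """
    pat_idx = protocol.by_name["Pat"].position
    batch: list[ParsedRecord] = []
    current: Optional[str] = None
    last_key: Optional[str] = None
    with open(sorted_file, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter=";"):
            key = row[pat_idx]
            if last_key is not None and key < last_key:
                raise RuntimeError(
                    f"{sorted_file} is not sorted by Pat "
                    f"({key!r} after {last_key!r})")
            last_key = key
            record = parse_record(row[1:], protocol, tables, int(row[0]))
            if key != current and batch:
                yield batch
                batch = []
            current = key
            batch.append(record)
    if batch:
        yield batch


@dataclass
class PostRecordResult:
    messages: list[CheckMessage]
    mpt_clusters: int = 0


def run_post_record_cycle(sorted_files: Mapping[str, Path],
                          protocol: ProtocolDef, tables: ReferenceTables,
                          *, behaviour_floor: int =
                          _mpt.DEFAULT_BEHAVIOUR_FLOOR) -> PostRecordResult:
    """Apply each cross-record rule per patient batch; at most one patient's
    records are resident at a time."""
    result = PostRecordResult(messages=[])
    accepted = RuleAcceptance(rule_id="MPT", accepted=True)
    for rule_id, sorted_file in sorted_files.items():
        if rule_id != "MPT":
            raise RuntimeError(f"no post-record procedure for rule {rule_id}")
        for batch in _iter_patient_batches(sorted_file, protocol, tables):
            refs = [
                _mpt.tumour_ref(rec) for rec in batch
                if _mpt.filter_mpt_eligible(rec, accepted, tables,
                                            behaviour_floor)
            ]
            result.messages.extend(
                _mpt.evaluate_patient_batch(refs, tables))
            result.mpt_clusters += len(
                _mpt.same_primary_clusters(refs, tables))
    return result


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _write_log(messages: Sequence[CheckMessage], workdir: Path) -> Path:
    log_path = Path(workdir) / LOG_FILENAME
    with open(log_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=";")
        writer.writerow(["Line", "Error_Code", "Severity", "Var_Name",
                         "Var_Value", "Detail"])
        for msg in messages:
            writer.writerow([msg.line_no, msg.code, msg.severity,
                             ",".join(msg.variables), ",".join(msg.values),
                             msg.detail])
    return log_path


def run_validation(path: Path, protocol_id: str, *,
                   config_root: Optional[Path] = None,
                   workdir: Optional[Path] = None,
                   output_dir: Optional[Path] = None,
                   delimiter: Optional[str] = None,
                   chunk_size: int = DEFAULT_CHUNK_SIZE,
                   on_structural_error: str = "abort",
                   message_cap: int = DEFAULT_MESSAGE_CAP,
                   min_records: int = 1,
                   behaviour_floor: int = _mpt.DEFAULT_BEHAVIOUR_FLOOR,
                   timestamp: Optional[_dt.datetime] = None) -> RunResult:
    """Validate one file end to end: structure, duplicates, record cycle,
    sort, post-record cycle, reports."""
    path = Path(path)
    protocol = load_protocol(config_root, protocol_id)
    tables = load_reference_tables(config_root)
    delim = delimiter or protocol.delimiter
    output_dir = Path(output_dir) if output_dir else path.parent / "output"
    workdir = Path(workdir) if workdir else output_dir / "tmp"
    output_dir.mkdir(parents=True, exist_ok=True)
    workdir.mkdir(parents=True, exist_ok=True)
    n_vars = len(protocol.variables)

    structure = validate_file_structure(
        path, protocol, delimiter=delim, min_records=min_records)
    blocking = any(m.code in ("C-EMPT", "C-HEAD") for m in structure) or (
        on_structural_error == "abort" and bool(structure))
    bad_lines = {m.line_no for m in structure if m.code == "C-NCOL"}

    def records(with_tables: Optional[ReferenceTables]
                ) -> Iterator[ParsedRecord]:
        for line_no, row in _iter_rows(path, delim):
            if protocol.has_header and line_no == 1:
                continue
            if line_no in bad_lines or len(row) != n_vars:
                continue
            yield parse_record(row, protocol, with_tables, line_no)

    messages: list[CheckMessage] = list(structure)
    if blocking:
        log_path = _write_log(messages, workdir)
        return RunResult(
            total_records=0,
            messages_by_code=_count_by_code(messages),
            blocking_failure=structure[0].detail if structure else None,
            output_paths={"log": log_path},
            messages=messages)

    # pre-record: perfect duplicates (incidence layouts carry Pat and Tum)
    if protocol.has_variable("Pat") and protocol.has_variable("Tum"):
        messages += detect_perfect_duplicates(records(None))

    cycle = run_record_cycle(records(tables), protocol, tables, workdir,
                             message_cap=message_cap)
    messages += cycle.messages

    mpt_clusters = 0
    if not cycle.capped:
        sorted_files = {
            rule_id: external_sort(temp, "Pat", protocol, chunk_size)
            for rule_id, temp in cycle.temp_files.items()
        }
        post = run_post_record_cycle(sorted_files, protocol, tables,
                                     behaviour_floor=behaviour_floor)
        messages += post.messages
        mpt_clusters = post.mpt_clusters

    log_path = _write_log(messages, workdir)
    report = _reporting.build_report(
        messages, input_name=path.name, total_records=cycle.total_records,
        timestamp=timestamp)
    output_paths = _reporting.write_reports(report, output_dir)
    output_paths["log"] = log_path

    return RunResult(
        total_records=cycle.total_records,
        messages_by_code=_count_by_code(messages),
        blocking_failure="message cap exceeded" if cycle.capped else None,
        output_paths=output_paths,
        messages=messages,
        tnm_not_evaluable=cycle.tnm_not_evaluable,
        mpt_clusters=mpt_clusters)


def _count_by_code(messages: Iterable[CheckMessage]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for msg in messages:
        counts[msg.code] = counts.get(msg.code, 0) + 1
    return dict(sorted(counts.items()))
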