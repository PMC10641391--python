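"""Report assembly: restore original dataset order, summarise, and write
the CSV and TXT report files.

The CSV report holds every message (one per row, semicolon-delimited, with
header) in original dataset order, for machine consumption. The TXT report
carries a header block (run metadata, critical messages, code legend and
the summary table of record counts per code) followed by the same detail
rows in the same order. Critical messages are run-level and appear in the
TXT header block rather than in the per-record detail.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .rules_core import CODE_LEGEND, CheckMessage

#: Column order of the CSV report (bit-exact contract).
CSV_COLUMNS = ["Line", "Pat", "Tum", "BoD", "Topo", "Morpho", "Beh", "Sex",
               "DoI", "DoB", "Var_Name", "Var_Value", "Error_Code",
               "Severity", "Detail"]

# joins multi-variable names/values inside one CSV cell; "|" never occurs in
# registry codes, so the CSV report round-trips exactly
_LIST_JOINER = "|"


@dataclass
class RunReport:
    header: dict                      # timestamp, input name, row count, totals
    detail: list[CheckMessage]        # non-critical, original dataset order
    criticals: list[CheckMessage]
    summary: dict[str, int]           # code -> number of distinct records

    @property
    def all_messages(self) -> list[CheckMessage]:
        return self.criticals + self.detail


def restore_original_order(log: Iterable[CheckMessage]) -> list[CheckMessage]:
    """Stable ascending sort by original line number."""
    messages = list(log)
    for msg in messages:
        if msg.line_no is None:
            raise RuntimeError(f"message without a record locator: {msg}")
    return sorted(messages, key=lambda m: m.line_no)


def summarize(messages: Iterable[CheckMessage]) -> dict[str, int]:
    """Per code, the number of distinct records carrying that code."""
    records: dict[str, set[int]] = {}
    for msg in messages:
        records.setdefault(msg.code, set()).add(msg.line_no)
    return {code: len(lines) for code, lines in sorted(records.items())}


def severity_totals(messages: Iterable[CheckMessage]) -> dict[str, int]:
    totals = {"warning": 0, "error": 0, "critical": 0}
    for msg in messages:
        totals[msg.severity] += 1
    return totals


def build_report(messages: Sequence[CheckMessage], *, input_name: str,
                 total_records: int,
                 timestamp: Optional[_dt.datetime] = None) -> RunReport:
    ordered = restore_original_order(messages)
    detail = sorted((m for m in ordered if m.severity != "critical"),
                    key=lambda m: (m.line_no, m.code))
    criticals = [m for m in ordered if m.severity == "critical"]
    header = {
        "timestamp": timestamp or _dt.datetime.now(),
        "input_name": input_name,
        "total_records": total_records,
        "totals": severity_totals(ordered),
    }
    return RunReport(header=header, detail=detail, criticals=criticals,
                     summary=summarize(ordered))


def _context_value(msg: CheckMessage, name: str) -> str:
    for key, value in msg.context:
        if key == name:
            return value
    return ""


def _csv_row(msg: CheckMessage) -> list[str]:
    return [
        str(msg.line_no),
        _context_value(msg, "Pat"), _context_value(msg, "Tum"),
        _context_value(msg, "BoD"), _context_value(msg, "Topo"),
        _context_value(msg, "Morpho"), _context_value(msg, "Beh"),
        _context_value(msg, "Sex"), _context_value(msg, "DoI"),
        _context_value(msg, "DoB"),
        _LIST_JOINER.join(msg.variables),
        _LIST_JOINER.join(msg.values),
        msg.code, msg.severity, msg.detail,
    ]


def write_csv_report(report: RunReport, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=";")
        writer.writerow(CSV_COLUMNS)
        for msg in report.criticals:
            writer.writerow(_csv_row(msg))
        for msg in report.detail:
            writer.writerow(_csv_row(msg))


def read_csv_report(path: Path) -> list[CheckMessage]:
    """Parse a CSV report back into messages (round-trip of write_csv_report)."""
    messages = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=";")
        for row in reader:
            context = tuple(
                (name, row[name]) for name in
                ("Pat", "Tum", "BoD", "Topo", "Morpho", "Beh", "Sex",
                 "DoI", "DoB")
                if row[name] != "")
            messages.append(CheckMessage(
                code=row["Error_Code"],
                variables=tuple(v for v in
                                row["Var_Name"].split(_LIST_JOINER) if v),
                values=tuple(row["Var_Value"].split(_LIST_JOINER))
                if row["Var_Name"] else (),
                line_no=int(row["Line"]),
                detail=row["Detail"],
                severity=row["Severity"],
                context=context,
            ))
    return messages


def write_txt_report(report: RunReport, path: Path) -> None:
    h = report.header
    lines = [
        "JRC-style registry quality check report",
        "=" * 54,
        f"Run date and time : {h['timestamp']:%Y-%m-%d %H:%M:%S}",
        f"Processed file    : {h['input_name']}",
        f"Number of rows    : {h['total_records']}",
        f"Total errors      : {h['totals']['error']}",
        f"Total warnings    : {h['totals']['warning']}",
        f"Total criticals   : {h['totals']['critical']}",
        "",
    ]
    if report.criticals:
        lines.append("Critical (run-level) messages:")
        for msg in report.criticals:
            lines.append(f"  {msg.code}  {msg.detail}")
        lines.append("")
    lines.append("Message codes:")
    for code, text in CODE_LEGEND.items():
        lines.append(f"  {code:7s} {text}")
    lines.append("")
    lines.append("Summary (number of records per code):")
    if report.summary:
        for code, count in report.summary.items():
            lines.append(f"  {code:7s} {count:8d}")
    else:
        lines.append("  (no findings)")
    lines.append("")
    lines.append("Detail (original dataset order):")
    lines.append("Line;Pat;Tum;Var_Name;Var_Value;Error_Code;Detail")
    for msg in report.detail:
        lines.append(";".join([
            str(msg.line_no), _context_value(msg, "Pat"),
            _context_value(msg, "Tum"),
            _LIST_JOINER.join(msg.variables),
            _LIST_JOINER.join(msg.values),
            msg.code, msg.detail,
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_reports(report: RunReport, output_dir: Path,
                  *, basename: str = "qcs_report") -> dict[str, Path]:
    """Write the CSV and TXT artefacts; returns their paths."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    csv_path = output_dir / f"{basename}.csv"
    txt_path = output_dir / f"{basename}.txt"
    write_csv_report(report, csv_path)
    write_txt_report(report, txt_path)
    return {"csv": csv_path, "txt": txt_path}
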