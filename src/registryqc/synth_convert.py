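"""Layout conversion and synthetic registry data generation.

The converter turns near-miss registry extracts (shuffled columns, local
value codings, 3-character topography codes) into protocol-compliant files.
The generator is the package's test instrument: it produces files that are
valid under a protocol except for an exactly controlled error-injection
profile, and records the ground truth in a ledger so engine output can be
compared against it. It targets check coverage, not epidemiological
realism: sites, morphologies and ages are drawn from the reference tables,
not from incidence distributions.
"""

from __future__ import annotations

import csv
import datetime as _dt
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .protocols import (
    ProtocolDef,
    ReferenceTables,
    canonical_topography,
)


class ConversionError(Exception):
    pass


class GenerationError(Exception):
    pass


# ---------------------------------------------------------------------------
# CSV data layout converter
# ---------------------------------------------------------------------------

@dataclass
class LayoutMapping:
    """How a source extract maps onto a protocol layout.

    ``column_map``: source column name -> protocol variable name.
    ``value_maps``: per protocol variable, source code -> protocol code
    (e.g. ``{"Sex": {"M": "1", "F": "2"}}``).
    ``fixups``: normalisation rules applied after recoding; currently
    ``normalize_topography``.
    """

    column_map: dict[str, str]
    value_maps: dict[str, dict[str, str]] = field(default_factory=dict)
    delimiter_in: str = ";"
    fixups: list[str] = field(default_factory=list)


def identity_mapping(protocol: ProtocolDef,
                     delimiter_in: Optional[str] = None) -> LayoutMapping:
    return LayoutMapping(
        column_map={name: name for name in protocol.variable_names},
        delimiter_in=delimiter_in or protocol.delimiter)


def load_mapping(path: Path) -> LayoutMapping:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return LayoutMapping(
        column_map={str(k): str(v) for k, v in data["column_map"].items()},
        value_maps={str(var): {str(k): str(v) for k, v in table.items()}
                    for var, table in (data.get("value_maps") or {}).items()},
        delimiter_in=str(data.get("delimiter_in", ";")),
        fixups=[str(f) for f in data.get("fixups", [])],
    )


_TOPO_SHAPE = re.compile(r"^C\d{2}(\.?\d)?$", re.IGNORECASE)


def normalize_topography(value: str) -> tuple[str, bool]:
    """Canonicalise a topography code; 3-character codes gain the ``.9``
    unspecified-subsite digit (``C61`` -> ``C619``).

    Returns ``(canonical value, fixup applied?)``; values that are not
    C-code shaped (or empty) pass through unchanged.
    """
    raw = value.strip()
    if raw == "" or not _TOPO_SHAPE.match(raw):
        return value, False
    canon = canonical_topography(raw)
    if len(canon) == 3:
        canon += "9"  # unspecified subsite
    return canon, canon != value


_FIXUPS = {"normalize_topography": normalize_topography}
_FIXUP_TARGETS = {"normalize_topography": "Topo"}


@dataclass
class ConversionReport:
    rows: int = 0
    fixups_applied: int = 0
    #: (line_no, variable, value) cells a value map could not recode
    unconvertible: list[tuple[int, str, str]] = field(default_factory=list)


def convert_layout(input_path: Path, mapping: LayoutMapping,
                   protocol: ProtocolDef, output_path: Path
                   ) -> ConversionReport:
    """Rewrite a source extract in protocol column order and coding.

    Unconvertible cells are passed through verbatim (and listed in the
    report) rather than dropped, so the validator can flag them; the output
    always has the protocol's column count.
    """
    for fixup in mapping.fixups:
        if fixup not in _FIXUPS:
            raise ConversionError(f"unknown fixup {fixup!r}")
    report = ConversionReport()
    with open(input_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=mapping.delimiter_in)
        try:
            source_header = [c.strip() for c in next(reader)]
        except StopIteration:
            raise ConversionError("source file is empty")
        var_to_col: dict[str, int] = {}
        for i, col in enumerate(source_header):
            if col in mapping.column_map:
                var_to_col[mapping.column_map[col]] = i
        required = [v.name for v in protocol.variables if v.required]
        missing = [name for name in required if name not in var_to_col]
        if missing:
            raise ConversionError(
                "source lacks columns for required variables: "
                + ", ".join(missing))

        with open(output_path, "w", newline="", encoding="utf-8") as out:
            writer = csv.writer(out, delimiter=protocol.delimiter)
            writer.writerow(protocol.variable_names)
            for line_no, row in enumerate(reader, start=2):
                out_row = []
                for var in protocol.variables:
                    idx = var_to_col.get(var.name)
                    raw = row[idx].strip() if idx is not None and \
                        idx < len(row) else ""
                    vmap = mapping.value_maps.get(var.name)
                    if vmap is not None and raw != "":
                        if raw in vmap:
                            raw = vmap[raw]
                        else:
                            report.unconvertible.append(
                                (line_no, var.name, raw))
                    for fixup in mapping.fixups:
                        if _FIXUP_TARGETS[fixup] == var.name and raw != "":
                            raw, applied = _FIXUPS[fixup](raw)
                            report.fixups_applied += int(applied)
                    out_row.append(raw)
                writer.writerow(out_row)
                report.rows += 1
    return report


# ---------------------------------------------------------------------------
# Synthetic incidence generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LedgerEntry:
    code: str
    line_no: int
    variable: str


@dataclass
class InjectionLedger:
    """Ground truth of an error-injected synthetic file."""

    seed: int
    entries: list[LedgerEntry] = field(default_factory=list)

    @property
    def expected_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.code] = counts.get(e.code, 0) + 1
        return dict(sorted(counts.items()))

    def write(self, path: Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=";")
            writer.writerow(["code", "line_no", "variable"])
            for e in self.entries:
                writer.writerow([e.code, e.line_no, e.variable])

    @classmethod
    def read(cls, path: Path, seed: int = -1) -> "InjectionLedger":
        ledger = cls(seed=seed)
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter=";")
            for row in reader:
                ledger.entries.append(LedgerEntry(
                    row["code"], int(row["line_no"]), row["variable"]))
        return ledger


#: sites coded essentially in one sex only (kept coherent, not checked)
_SEX_SITES = {"C50": "2", "C53": "2", "C56": "2", "C61": "1", "C62": "1"}

_STAGE_TRIPLES = [("1", "0", "0"), ("2", "0", "0"), ("2", "1", "0"),
                  ("3", "1", "0"), ("3", "2", "0"), ("1", "0", "1")]

INJECTABLE_CODES = ("E-MISS", "E-FORM", "E-OUTR", "E-DATE", "W-MOTO",
                    "W-AGMT", "W-TNMS", "W-BDMO", "E-DUPL", "W-MULP")


def _is_unlikely(tables: ReferenceTables, age: int, topo: str,
                 morpho: str) -> bool:
    for entry in tables.age_topo_morpho_unlikely:
        if entry.age_min <= age <= entry.age_max \
                and morpho in entry.morpho_codes \
                and any(topo.startswith(p) for p in entry.topo_prefixes):
            return True
    return False


class _IncidenceSampler:
    """Clean-record sampler over the reference tables."""

    def __init__(self, protocol: ProtocolDef, tables: ReferenceTables,
                 rng: random.Random):
        self.protocol = protocol
        self.tables = tables
        self.rng = rng
        # joint (topo, morpho) draws come from the allowed table so clean
        # records never produce topography/morphology warnings
        self.pairs = sorted(
            (t, m) for t, m in tables.topo_morpho
            if "3" in tables.morpho_valid[m])

    def sample_pair(self, sex: Optional[str] = None) -> tuple[str, str]:
        while True:
            topo, morpho = self.rng.choice(self.pairs)
            site_sex = _SEX_SITES.get(topo[:3])
            if sex is not None and site_sex is not None and site_sex != sex:
                continue
            return topo, morpho

    def sample_age(self, topo: str, morpho: str) -> int:
        for _ in range(200):
            age = self.rng.randint(0, 84)
            if not _is_unlikely(self.tables, age, topo, morpho):
                return age
        raise GenerationError(
            f"no plausible age for {topo}/{morpho} in the unlikely table")

    def tnm_and_stage(self, topo: str) -> dict[str, str]:
        group = self.tables.topo_groups.get(topo[:3])
        t, n, m = self.rng.choice(_STAGE_TRIPLES)
        stage = None
        if group is not None:
            stage = self.tables.stage_for("7", group, t, n, m)
        if stage is None:
            return {"pT": "", "pN": "", "pM": "", "Stage": "X",
                    "TNMEdition": ""}
        return {"pT": t, "pN": n, "pM": m, "Stage": stage, "TNMEdition": "7"}

    def record(self, pat: str, tum: str, *, sex: Optional[str] = None,
               dob: Optional[_dt.date] = None,
               min_doi: Optional[_dt.date] = None,
               pair: Optional[tuple[str, str]] = None) -> dict[str, str]:
        rng = self.rng
        if pair is None:
            pair = self.sample_pair(sex)
        topo, morpho = pair
        if sex is None:
            sex = _SEX_SITES.get(topo[:3]) or rng.choice(["1", "2"])
        doi = _dt.date(rng.randint(2016, 2019), rng.randint(1, 12),
                       rng.randint(1, 28))
        if min_doi is not None and doi < min_doi:
            doi = min_doi
        if dob is None:
            age = self.sample_age(topo, morpho)
            dob = doi.replace(year=doi.year - age)
        else:
            age = doi.year - dob.year - (
                (doi.month, doi.day) < (dob.month, dob.day))
            if age < 0 or _is_unlikely(self.tables, age, topo, morpho):
                raise GenerationError("incompatible birth date for pair")
        bod = rng.choice(["5", "6", "7"]) \
            if morpho in self.tables.bod_specificity \
            else rng.choice(["1", "5", "6", "7"])
        row = {name: "" for name in self.protocol.variable_names}
        row.update({
            "Pat": pat, "Tum": tum, "Sex": sex,
            "DoB": dob.isoformat(), "DoI": doi.isoformat(),
            "YoI": str(doi.year), "Age": str(age),
            "BoD": bod, "Topo": topo, "Morpho": morpho, "Beh": "3",
            "Grade": rng.choice(["1", "2", "3", "9"]),
            "VitalStatus": rng.choice(["1", "2"]),
            "DoF": (doi + _dt.timedelta(days=rng.randint(30, 1200)))
            .isoformat(),
        })
        row.update(self.tnm_and_stage(topo))
        return row


def _recompute_age(row: dict[str, str], age: int) -> None:
    doi = _dt.date.fromisoformat(row["DoI"])
    row["DoB"] = doi.replace(year=doi.year - age).isoformat()
    row["Age"] = str(age)


def _inject_in_place(code: str, row: dict[str, str],
                     sampler: _IncidenceSampler) -> str:
    """Mutate one clean singleton row to trigger exactly one message of
    ``code``; returns the ledger variable name."""
    if code == "E-MISS":
        row["Stage"] = ""
        return "Stage"
    if code == "E-FORM":
        row["Sex"] = "xx"
        return "Sex"
    if code == "E-OUTR":
        row["Sex"] = "5"
        return "Sex"
    if code == "E-DATE":
        doi = _dt.date.fromisoformat(row["DoI"])
        row["DoF"] = (doi - _dt.timedelta(days=10)).isoformat()
        return "DoF"
    if code == "W-MOTO":
        # refused pair straight from the worked example: lymph node +
        # squamous carcinoma (probably a metastasis)
        row.update({"Topo": "C779", "Morpho": "8070", "Beh": "3", "BoD": "7",
                    "pT": "", "pN": "", "pM": "", "Stage": "X",
                    "TNMEdition": ""})
        return "Topo"
    if code == "W-AGMT":
        row.update({"Topo": "C692", "Morpho": "9510", "Beh": "3", "BoD": "7",
                    "pT": "", "pN": "", "pM": "", "Stage": "X",
                    "TNMEdition": ""})
        _recompute_age(row, 75)  # retinoblastoma in an adult
        return "Morpho"
    if code == "W-TNMS":
        row.update({"Topo": "C509", "Morpho": "8500", "Beh": "3", "BoD": "7",
                    "Sex": "2", "pT": "3", "pN": "1", "pM": "1",
                    "Stage": "IIIA", "TNMEdition": "7"})
        _recompute_age(row, 60)
        return "Stage"
    if code == "W-BDMO":
        row.update({"Topo": "C329", "Morpho": "8070", "Beh": "3", "BoD": "1",
                    "pT": "", "pN": "", "pM": "", "Stage": "X",
                    "TNMEdition": ""})
        _recompute_age(row, 60)
        return "BoD"
    raise GenerationError(f"cannot inject code {code!r}")


def _mpt_partner(row: dict[str, str], tum: str,
                 sampler: _IncidenceSampler) -> dict[str, str]:
    """A second tumour of the same patient judged the same primary."""
    tables = sampler.tables
    group = tables.topo_groups[row["Topo"][:3]]
    family = tables.morpho_families[row["Morpho"]]
    age = int(row["Age"])
    candidates = [
        (t, m) for t, m in sampler.pairs
        if tables.topo_groups[t[:3]] == group
        and tables.morpho_families[m] == family
        and not _is_unlikely(tables, age, t, m)
    ]
    if not candidates:
        raise GenerationError(
            f"no same-primary partner available for "
            f"{row['Topo']}/{row['Morpho']}")
    pair = sampler.rng.choice(candidates)
    partner = sampler.record(
        row["Pat"], tum, sex=row["Sex"],
        dob=_dt.date.fromisoformat(row["DoB"]),
        min_doi=_dt.date.fromisoformat(row["DoI"]),
        pair=pair)
    partner["BoD"] = "7"
    return partner


def generate_incidence(n: int, protocol: ProtocolDef,
                       tables: ReferenceTables,
                       error_profile: Optional[Mapping[str, int]] = None,
                       seed: int = 0, *, out_dir: Path,
                       multi_tumour_fraction: float = 0.10,
                       basename: str = "incidence"
                       ) -> tuple[Path, InjectionLedger]:
    """Write a synthetic incidence file of ``n`` base records plus the rows
    appended for duplicate/MPT injections, together with its ledger.

    The file is protocol-valid except for the injected defects: validating
    it must yield exactly the ledger's message counts. Deterministic given
    ``seed``.
    """
    profile = {k: int(v) for k, v in (error_profile or {}).items() if v}
    unknown = set(profile) - set(INJECTABLE_CODES)
    if unknown:
        raise GenerationError(f"cannot inject codes: {sorted(unknown)}")
    if protocol.file_kind != "incidence":
        raise GenerationError("generate_incidence needs an incidence protocol")

    rng = random.Random(seed)
    sampler = _IncidenceSampler(protocol, tables, rng)

    n_multi = int(n * multi_tumour_fraction) // 2
    if 2 * n_multi > n:
        raise GenerationError("multi_tumour_fraction too large for n")
    rows: list[dict[str, str]] = []
    singleton_idx: list[int] = []
    pat_serial = 0
    # independent two-tumour patients: different site group and family,
    # so clean files carry multi-tumour structure without MPT findings
    for _ in range(n_multi):
        pat_serial += 1
        pat = f"P{pat_serial:06d}"
        first = sampler.record(pat, "T01")
        g1 = tables.topo_groups[first["Topo"][:3]]
        f1 = tables.morpho_families[first["Morpho"]]
        for _ in range(500):
            second = sampler.record(
                pat, "T02", sex=first["Sex"],
                dob=None, min_doi=_dt.date.fromisoformat(first["DoI"]))
            g2 = tables.topo_groups[second["Topo"][:3]]
            f2 = tables.morpho_families[second["Morpho"]]
            if g1 != g2 and f1 != f2:
                break
        else:  # pragma: no cover
            raise GenerationError("could not sample an independent pair")
        rows.append(first)
        rows.append(second)
    while len(rows) < n:
        pat_serial += 1
        singleton_idx.append(len(rows))
        rows.append(sampler.record(f"P{pat_serial:06d}", "T01"))

    first_data_line = 2 if protocol.has_header else 1

    def line_of(idx: int) -> int:
        return idx + first_data_line

    ledger = InjectionLedger(seed=seed)
    pool = list(singleton_idx)
    rng.shuffle(pool)

    def take() -> int:
        if not pool:
            raise GenerationError(
                "error profile needs more singleton records than available; "
                "increase n or lower the profile")
        return pool.pop()

    appended: list[dict[str, str]] = []
    for code in INJECTABLE_CODES:
        for _ in range(profile.get(code, 0)):
            idx = take()
            if code == "E-DUPL":
                appended.append(dict(rows[idx]))
                ledger.entries.append(LedgerEntry(
                    code, len(rows) + len(appended) - 1 + first_data_line,
                    "Pat"))
            elif code == "W-MULP":
                appended.append(_mpt_partner(rows[idx], "T90", sampler))
                ledger.entries.append(LedgerEntry(
                    code, len(rows) + len(appended) - 1 + first_data_line,
                    "Tum"))
            else:
                variable = _inject_in_place(code, rows[idx], sampler)
                ledger.entries.append(LedgerEntry(
                    code, line_of(idx), variable))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_path = out_dir / f"{basename}.csv"
    with open(data_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=protocol.delimiter)
        if protocol.has_header:
            writer.writerow(protocol.variable_names)
        for row in rows + appended:
            writer.writerow([row[name] for name in protocol.variable_names])
    ledger.entries.sort(key=lambda e: (e.line_no, e.code))
    ledger.write(out_dir / f"{basename}.ledger.csv")
    return data_path, ledger


# ---------------------------------------------------------------------------
# Aggregate files (mortality / population / life table)
# ---------------------------------------------------------------------------

DEFAULT_RANGES = {
    "years": (2017, 2019),
    "age_step": 5,
    "age_max": 99,
    "geo": [("AREA01", "Registry area 1")],
}


def generate_aggregate(file_kind: str, protocol: ProtocolDef,
                       ranges: Optional[Mapping] = None, seed: int = 0, *,
                       out_path: Path) -> Path:
    """Synthetic mortality/population/life-table file over a year x sex x
    age (x geography) grid, consistent with a paired incidence file when the
    same ``ranges`` are used."""
    if protocol.file_kind != file_kind:
        raise GenerationError(
            f"protocol {protocol.id} is a {protocol.file_kind} layout, "
            f"not {file_kind}")
    r = dict(DEFAULT_RANGES)
    r.update(ranges or {})
    rng = random.Random(seed)
    y0, y1 = r["years"]
    ages = list(range(0, r["age_max"] + 1, r["age_step"]))

    def cell(name: str, year: int, sex: int, age: int,
             geo: tuple[str, str]) -> str:
        if name == "Year":
            return str(year)
        if name == "Sex":
            return str(sex)
        if name == "Age":
            return str(age)
        if name == "AgeGroup":
            top = min(age + r["age_step"] - 1, r["age_max"])
            return f"{age}-{top}"
        if name == "CauseOfDeath":
            return "C00-C97"
        if name == "Deaths":
            return str(rng.randint(0, 500))
        if name == "Residents":
            return str(rng.randint(500, 100_000))
        if name == "GeoCode":
            return geo[0]
        if name == "GeoLabel":
            return geo[1]
        if name == "DeathProb":
            return f"{rng.uniform(0.0, 0.2):.6f}"
        raise GenerationError(f"no generator for variable {name!r}")

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=protocol.delimiter)
        if protocol.has_header:
            writer.writerow(protocol.variable_names)
        for year in range(y0, y1 + 1):
            for sex in (1, 2):
                for age in ages:
                    for geo in r["geo"]:
                        writer.writerow([
                            cell(name, year, sex, age, geo)
                            for name in protocol.variable_names])
    return out_path
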