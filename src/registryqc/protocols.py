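"""Validation protocols: file layouts, variable definitions and reference tables.

A *protocol* describes one of the ten supported registry file modalities
(incidence, mortality, population and life-table layouts in their 2014 and
2020 versions): the ordered variable list, the field delimiter, the
cross-record rules that apply and, per rule, the acceptance criteria that
decide which records the rule may use.

Everything is loaded from plain-text configuration files (YAML for
protocols, delimited text with a header row for reference tables) so the
logic of most checks can be changed without touching code: users point the
engine at an alternative config root or override individual tables.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

#: Cross-record rules implemented by the engine; protocol configs may only
#: bind rules from this set (a dangling binding is a configuration error).
KNOWN_RULES = frozenset({"MPT"})

DATATYPES = frozenset(
    {"integer-code", "text-code", "date", "count", "probability"}
)


class ConfigError(Exception):
    """A configuration file is missing, malformed or violates an invariant."""

    def __init__(self, message: str, *, path: Optional[Path] = None,
                 line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# Variable and protocol definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AllowedSpec:
    """Allowed-value specification for one variable.

    Exactly one of the four forms is active:

    - ``set``: explicit value set (canonical strings)
    - ``range``: inclusive numeric ``(lo, hi)`` bounds
    - ``pattern``: anchored regular expression on the raw string
    - ``table``: name of a reference-table domain (``topo``, ``morpho``,
      ``tnm_T``, ``tnm_N``, ``tnm_M``)
    """

    kind: str
    values: frozenset[str] = frozenset()
    lo: float = 0.0
    hi: float = 0.0
    pattern: str = ""
    table: str = ""

    def __post_init__(self):
        if self.kind not in {"set", "range", "pattern", "table"}:
            raise ConfigError(f"unknown allowed-spec kind {self.kind!r}")


@dataclass(frozen=True)
class VariableDef:
    name: str
    position: int  # 1-based column index
    datatype: str
    allowed: Optional[AllowedSpec] = None
    missing_codes: frozenset[str] = frozenset()
    required: bool = False

    def __post_init__(self):
        if self.datatype not in DATATYPES:
            raise ConfigError(
                f"variable {self.name!r}: unknown datatype {self.datatype!r}")
        if self.datatype in ("integer-code", "text-code"):
            if self.allowed is None:
                raise ConfigError(
                    f"variable {self.name!r}: coded datatype requires an "
                    f"allowed-value specification")
        if self.allowed is not None and self.allowed.kind == "set":
            extra = self.missing_codes - self.allowed.values
            if extra:
                raise ConfigError(
                    f"variable {self.name!r}: missing codes {sorted(extra)} "
                    f"not contained in the allowed set")


@dataclass(frozen=True)
class ProtocolDef:
    id: str
    file_kind: str  # incidence | mortality | population | lifetable
    version: int    # 2014 | 2020
    delimiter: str
    variables: tuple[VariableDef, ...]
    rules: tuple[str, ...] = ()
    #: rule id -> set of (variable name, message code) pairs deemed critical
    acceptance_criteria: Mapping[str, frozenset[tuple[str, str]]] = \
        field(default_factory=dict)
    has_header: bool = True

    def __post_init__(self):
        positions = [v.position for v in self.variables]
        if sorted(positions) != list(range(1, len(positions) + 1)):
            raise ConfigError(
                f"protocol {self.id!r}: variable positions must form "
                f"1..{len(positions)} without gaps or duplicates")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ConfigError(f"protocol {self.id!r}: duplicate variable names")
        for rule in self.rules:
            if rule not in KNOWN_RULES:
                raise ConfigError(
                    f"protocol {self.id!r}: rule {rule!r} is not implemented")

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def by_name(self) -> dict[str, VariableDef]:
        return {v.name: v for v in self.variables}

    def has_variable(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeTopoMorphoEntry:
    """One unlikely age/topography/morphology combination.

    ``topo_prefixes`` are 3-character site prefixes (e.g. ``C56``);
    ``morpho_codes`` explicit morphology codes. A record matches when its
    age at diagnosis falls in ``[age_min, age_max]`` and both codes match.
    """

    age_min: int
    age_max: int
    topo_prefixes: frozenset[str]
    morpho_codes: frozenset[str]


@dataclass(frozen=True)
class StageRow:
    """One row of a stage-grouping table.

    T and N may be ``*`` (any category); M is always explicit (``0``/``1``)
    so the "any M1 is stage IV" convention can be enforced.
    """

    edition: str
    site_group: str
    t: str
    n: str
    m: str
    stage: str


@dataclass(frozen=True)
class ReferenceTables:
    topo_valid: frozenset[str]                       # canonical, undotted
    morpho_valid: Mapping[str, frozenset[str]]       # code -> behaviours
    topo_morpho: frozenset[tuple[str, str]]          # allowed pairs
    age_topo_morpho_unlikely: tuple[AgeTopoMorphoEntry, ...]
    tnm_values: Mapping[str, frozenset[str]]         # axis (T/N/M) -> values
    stage_grouping: tuple[StageRow, ...]
    bod_specificity: frozenset[str]                  # "too specific" morphos
    morpho_families: Mapping[str, str]
    topo_groups: Mapping[str, str]                   # 3-char code -> group
    non_microscopic_bod: frozenset[str] = frozenset()

    def __post_init__(self):
        morpho_codes = set(self.morpho_valid)
        for topo, morpho in self.topo_morpho:
            if topo not in self.topo_valid:
                raise ConfigError(
                    f"topo_morpho row ({topo};{morpho}): topography not in "
                    f"the valid-topography table")
            if morpho not in morpho_codes:
                raise ConfigError(
                    f"topo_morpho row ({topo};{morpho}): morphology not in "
                    f"the valid-morphology table")
        for row in self.stage_grouping:
            if row.m not in ("0", "1"):
                raise ConfigError(
                    f"stage_grouping row for {row.site_group}: M must be an "
                    f"explicit 0 or 1, got {row.m!r}")
            if row.m == "1" and row.stage != "IV":
                raise ConfigError(
                    f"stage_grouping row for {row.site_group} "
                    f"(T={row.t},N={row.n},M=1): M=1 must map to stage IV, "
                    f"got {row.stage!r}")
        for code in morpho_codes:
            if code not in self.morpho_families:
                raise ConfigError(
                    f"morpho_families is not total: morphology {code} "
                    f"has no family")
        for topo in self.topo_valid:
            if topo[:3] not in self.topo_groups:
                raise ConfigError(
                    f"topo_groups is not total: topography {topo} "
                    f"has no site group")

    def stage_for(self, edition: str, site_group: str,
                  t: str, n: str, m: str) -> Optional[str]:
        """First-match stage lookup on normalised T/N/M categories."""
        for row in self.stage_grouping:
            if row.edition != edition or row.site_group != site_group:
                continue
            if row.t not in ("*", t):
                continue
            if row.n not in ("*", n):
                continue
            if row.m != m:
                continue
            return row.stage
        return None


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def default_config_root() -> Path:
    """Directory of the configuration set bundled with the package."""
    return Path(__file__).resolve().parent / "configs"


def _read_yaml(path: Path) -> dict:
    try:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError("configuration file not found", path=path)
    except yaml.YAMLError as exc:
        line = getattr(getattr(exc, "problem_mark", None), "line", None)
        raise ConfigError(f"broken configuration: {exc}", path=path,
                          line=None if line is None else line + 1)
    if not isinstance(data, dict):
        raise ConfigError("configuration file must hold a mapping", path=path)
    return data


def _parse_allowed(raw, *, path: Path, varname: str) -> Optional[AllowedSpec]:
    if raw is None:
        return None
    if not isinstance(raw, dict) or len(raw) != 1:
        raise ConfigError(
            f"variable {varname!r}: 'allowed' must be a one-key mapping",
            path=path)
    (kind, value), = raw.items()
    if kind == "set":
        return AllowedSpec("set", values=frozenset(str(v) for v in value))
    if kind == "range":
        lo, hi = value
        return AllowedSpec("range", lo=float(lo), hi=float(hi))
    if kind == "pattern":
        try:
            re.compile(value)
        except re.error as exc:
            raise ConfigError(
                f"variable {varname!r}: bad pattern ({exc})", path=path)
        return AllowedSpec("pattern", pattern=str(value))
    if kind == "table":
        return AllowedSpec("table", table=str(value))
    raise ConfigError(
        f"variable {varname!r}: unknown allowed kind {kind!r}", path=path)


def list_protocols(config_root: Optional[Path] = None) -> list[str]:
    """Identifiers of all protocols loadable from ``config_root``, sorted."""
    root = Path(config_root) if config_root else default_config_root()
    proto_dir = root / "protocols"
    if not proto_dir.is_dir():
        if not root.is_dir():
            raise OSError(f"config root {root} is not a readable directory")
        return []
    ids = []
    for path in sorted(proto_dir.glob("*.yaml")):
        data = _read_yaml(path)
        pid = data.get("id")
        if not pid:
            raise ConfigError("protocol file lacks an 'id'", path=path)
        ids.append(str(pid))
    return sorted(ids)


def load_protocol(config_root: Optional[Path], protocol_id: str) -> ProtocolDef:
    """Load and fully validate one protocol definition."""
    root = Path(config_root) if config_root else default_config_root()
    path = root / "protocols" / f"{protocol_id}.yaml"
    if not path.is_file():
        raise ConfigError(
            f"unknown protocol {protocol_id!r}; available: "
            f"{', '.join(list_protocols(root)) or '(none)'}", path=path)
    data = _read_yaml(path)
    if str(data.get("id")) != protocol_id:
        raise ConfigError(
            f"protocol file id {data.get('id')!r} does not match requested "
            f"{protocol_id!r}", path=path)
    try:
        variables = []
        for raw in data.get("variables", []):
            variables.append(VariableDef(
                name=str(raw["name"]),
                position=int(raw["position"]),
                datatype=str(raw["datatype"]),
                allowed=_parse_allowed(raw.get("allowed"), path=path,
                                       varname=str(raw["name"])),
                missing_codes=frozenset(
                    str(v) for v in raw.get("missing", [])),
                required=bool(raw.get("required", False)),
            ))
        criteria = {}
        for rule, pairs in (data.get("acceptance_criteria") or {}).items():
            criteria[str(rule)] = frozenset(
                (str(var), str(code)) for var, code in pairs)
        return ProtocolDef(
            id=protocol_id,
            file_kind=str(data["file_kind"]),
            version=int(data["version"]),
            delimiter=str(data.get("delimiter", ";")),
            variables=tuple(sorted(variables, key=lambda v: v.position)),
            rules=tuple(str(r) for r in data.get("rules", [])),
            acceptance_criteria=criteria,
            has_header=bool(data.get("has_header", True)),
        )
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"broken protocol definition: {exc!r}", path=path)


def _read_table(path: Path, columns: Sequence[str]) -> list[dict[str, str]]:
    if not path.is_file():
        raise ConfigError("reference table not found", path=path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=";")
        if reader.fieldnames is None or [c.strip() for c in
                                         reader.fieldnames] != list(columns):
            raise ConfigError(
                f"expected header {';'.join(columns)!r}, got "
                f"{reader.fieldnames}", path=path, line=1)
        rows = []
        for i, row in enumerate(reader, start=2):
            if any(row[c] is None for c in columns):
                raise ConfigError("short row", path=path, line=i)
            rows.append({c: row[c].strip() for c in columns})
        return rows


def canonical_topography(value: str) -> str:
    """Canonical undotted uppercase form of a topography code (C61.9 -> C619)."""
    return value.strip().upper().replace(".", "")


def load_reference_tables(
    config_root: Optional[Path] = None,
    table_overrides: Optional[Mapping[str, Path]] = None,
) -> ReferenceTables:
    """Load the lookup tables, replacing bundled tables wholesale per override.

    Override keys are table basenames: ``topography``, ``morphology``,
    ``topo_morpho``, ``age_topo_morpho``, ``tnm_values``, ``stage_grouping``,
    ``bod_specificity``, ``morpho_families``, ``topo_groups``, ``checks``.
    """
    root = Path(config_root) if config_root else default_config_root()
    overrides = dict(table_overrides or {})

    def table_path(name: str, ext: str = "csv") -> Path:
        if name in overrides:
            return Path(overrides[name])
        return root / "tables" / f"{name}.{ext}"

    topo_rows = _read_table(table_path("topography"), ["code", "label"])
    topo_valid = frozenset(canonical_topography(r["code"]) for r in topo_rows)

    morpho_rows = _read_table(table_path("morphology"),
                              ["code", "behaviours", "label"])
    morpho_valid = {
        r["code"]: frozenset(r["behaviours"].split(","))
        for r in morpho_rows
    }

    tm_rows = _read_table(table_path("topo_morpho"), ["topo", "morpho"])
    topo_morpho = frozenset(
        (canonical_topography(r["topo"]), r["morpho"]) for r in tm_rows)

    atm_rows = _read_table(
        table_path("age_topo_morpho"),
        ["age_min", "age_max", "topo_prefixes", "morpho_codes"])
    unlikely = tuple(
        AgeTopoMorphoEntry(
            age_min=int(r["age_min"]),
            age_max=int(r["age_max"]),
            topo_prefixes=frozenset(
                canonical_topography(p) for p in r["topo_prefixes"].split(",")),
            morpho_codes=frozenset(r["morpho_codes"].split(",")),
        )
        for r in atm_rows)

    tnm_rows = _read_table(table_path("tnm_values"), ["axis", "value"])
    tnm_values: dict[str, set[str]] = {}
    for r in tnm_rows:
        tnm_values.setdefault(r["axis"], set()).add(r["value"])

    stage_rows = _read_table(
        table_path("stage_grouping"),
        ["edition", "site_group", "T", "N", "M", "stage"])
    stage_grouping = tuple(
        StageRow(r["edition"], r["site_group"], r["T"], r["N"], r["M"],
                 r["stage"])
        for r in stage_rows)

    bod_rows = _read_table(table_path("bod_specificity"), ["morpho"])
    bod_specificity = frozenset(r["morpho"] for r in bod_rows)

    fam_rows = _read_table(table_path("morpho_families"),
                           ["code", "family_id"])
    morpho_families = {r["code"]: r["family_id"] for r in fam_rows}

    grp_rows = _read_table(table_path("topo_groups"), ["code", "group_id"])
    topo_groups = {canonical_topography(r["code"]): r["group_id"]
                   for r in grp_rows}

    checks_path = table_path("checks", ext="yaml")
    checks = _read_yaml(checks_path) if checks_path.is_file() else {}
    non_micro = frozenset(
        str(v) for v in checks.get("non_microscopic_bod", []))

    return ReferenceTables(
        topo_valid=topo_valid,
        morpho_valid=morpho_valid,
        topo_morpho=topo_morpho,
        age_topo_morpho_unlikely=unlikely,
        tnm_values={k: frozenset(v) for k, v in tnm_values.items()},
        stage_grouping=stage_grouping,
        bod_specificity=bod_specificity,
        morpho_families=morpho_families,
        topo_groups=topo_groups,
        non_microscopic_bod=non_micro,
    )
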