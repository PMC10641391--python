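"""Multiple-primary-tumour (MPT) rule: cross-record logic per patient.

Two tumour records of one patient are flagged as the *same primary* when
their topography codes fall in the same site group and their morphology
codes in the same family; otherwise they count as independent primaries.
Records whose codes are absent from the grouping tables are not evaluable.
Only records that passed the rule's acceptance criteria and whose behaviour
digit reaches the configured floor (default 3, malignant) take part.
"""

from __future__ import annotations

import datetime as _dt
import itertools
from dataclasses import dataclass
from typing import Optional, Sequence, TYPE_CHECKING

from .protocols import ReferenceTables
from .rules_core import CheckMessage, ParsedRecord, record_context

if TYPE_CHECKING:  # pragma: no cover
    from .engine import RuleAcceptance

#: Warning code for two records describing one primary tumour.
MPT_WARNING_CODE = "W-MULP"

DEFAULT_BEHAVIOUR_FLOOR = 3

SAME_PRIMARY = "same_primary"
INDEPENDENT = "independent"
NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class TumourRef:
    """The MPT-relevant slice of one accepted incidence record."""

    pat_id: str
    tum_id: str
    topo: str                      # canonical undotted topography
    morpho: str
    beh: int
    doi: Optional[_dt.date]        # reporting only; never affects verdicts
    line_no: int
    context: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class MPTVerdict:
    pair: tuple[TumourRef, TumourRef]
    verdict: str
    criteria_fired: tuple[str, ...] = ()


def tumour_ref(record: ParsedRecord) -> TumourRef:
    doi = record.parsed.get("DoI")
    return TumourRef(
        pat_id=record.pat_id,
        tum_id=record.tum_id,
        topo=record.parsed.get("Topo") or "",
        morpho=record.values.get("Morpho", ""),
        beh=int(record.values.get("Beh") or -1),
        doi=doi if isinstance(doi, _dt.date) else None,
        line_no=record.line_no,
        context=record_context(record),
    )


def filter_mpt_eligible(record: ParsedRecord,
                        acceptance: "RuleAcceptance",
                        tables: ReferenceTables,
                        behaviour_floor: int = DEFAULT_BEHAVIOUR_FLOOR
                        ) -> bool:
    """True when the record may enter MPT evaluation.

    Requires acceptance by the MPT rule (no critical errors on core
    variables) and a behaviour digit at or above the floor: a benign
    (behaviour 0) breast record is ignored, a malignant (behaviour 3) one
    is processed.
    """
    if not acceptance.accepted:
        return False
    if not record.usable("Beh"):
        return False
    return record.parsed["Beh"] >= behaviour_floor


def same_primary(a: TumourRef, b: TumourRef,
                 tables: ReferenceTables) -> MPTVerdict:
    """Pairwise verdict: same primary, independent, or not evaluable."""
    if a.pat_id != b.pat_id:
        raise ValueError("same_primary compares tumours of one patient only")
    group_a = tables.topo_groups.get(a.topo[:3])
    group_b = tables.topo_groups.get(b.topo[:3])
    fam_a = tables.morpho_families.get(a.morpho)
    fam_b = tables.morpho_families.get(b.morpho)
    if None in (group_a, group_b, fam_a, fam_b):
        return MPTVerdict(pair=(a, b), verdict=NOT_EVALUABLE)
    fired = []
    if group_a == group_b:
        fired.append("topo-group match")
    if fam_a == fam_b:
        fired.append("morpho-family match")
    verdict = SAME_PRIMARY if len(fired) == 2 else INDEPENDENT
    return MPTVerdict(pair=(a, b), verdict=verdict,
                      criteria_fired=tuple(fired))


def _pair_message(a: TumourRef, b: TumourRef) -> CheckMessage:
    first, second = sorted((a, b), key=lambda t: t.line_no)
    return CheckMessage(
        code=MPT_WARNING_CODE,
        variables=("Tum", "Topo", "Morpho"),
        values=(f"{first.tum_id},{second.tum_id}",
                f"{first.topo},{second.topo}",
                f"{first.morpho},{second.morpho}"),
        line_no=second.line_no,
        detail=(f"tumours {first.tum_id} (line {first.line_no}) and "
                f"{second.tum_id} (line {second.line_no}) of patient "
                f"{first.pat_id} appear to be the same primary tumour"),
        context=second.context,
    )


def evaluate_patient_batch(batch: Sequence[TumourRef],
                           tables: ReferenceTables) -> list[CheckMessage]:
    """One warning per unordered same-primary pair within a patient batch.

    Pairs sharing the tumour ID are skipped (those are perfect duplicates,
    handled in the pre-record cycle).
    """
    pats = {t.pat_id for t in batch}
    if len(pats) > 1:
        raise ValueError(f"batch spans several patients: {sorted(pats)}")
    messages = []
    for a, b in itertools.combinations(sorted(batch, key=lambda t: t.line_no),
                                       2):
        if a.tum_id == b.tum_id:
            continue
        if same_primary(a, b, tables).verdict == SAME_PRIMARY:
            messages.append(_pair_message(a, b))
    return messages


def same_primary_clusters(batch: Sequence[TumourRef],
                          tables: ReferenceTables) -> list[list[TumourRef]]:
    """Transitive closure of pairwise same-primary verdicts.

    Returns only clusters of two or more records ("twice or more"); used
    for the run summary, not for message emission.
    """
    items = sorted(batch, key=lambda t: t.line_no)
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(items)), 2):
        if items[i].tum_id == items[j].tum_id:
            continue
        if same_primary(items[i], items[j], tables).verdict == SAME_PRIMARY:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[TumourRef]] = {}
    for i, item in enumerate(items):
        clusters.setdefault(find(i), []).append(item)
    return [c for c in clusters.values() if len(c) > 1]
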