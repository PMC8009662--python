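"""Lineage-tracing records for the stomatal lineage and their tissue summaries.

State machine: a protodermal precursor can enter the lineage by an entry
asymmetric division (ACD) producing a meristemoid and an SLGC, or
differentiate into a pavement cell.  A meristemoid self-renews by amplifying
ACDs or commits to a guard mother cell (GMC); the GMC divides symmetrically
(SCD) into a pair of guard cells (one stoma).  An SLGC can re-enter by a
spacing ACD or differentiate into a pavement cell.

A :class:`LineageRecord` stores each cell's per-timepoint state (and cortical
polarity call), parent links and division events; the summaries derived from
it are division-type counts and fractions, the per-meristemoid amplifying
histogram, the stomatal index and the cell-number trajectory.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

PROTODERMAL = "protodermal"
MERISTEMOID = "meristemoid"
SLGC = "slgc"
GMC = "gmc"
GUARD = "guard_cell"
PAVEMENT = "pavement"
STATES = (PROTODERMAL, MERISTEMOID, SLGC, GMC, GUARD, PAVEMENT)

POLARIZED = "polarized"
DEPOLARIZED = "depolarized"
ABSENT = "absent"
POLARITY_CALLS = (POLARIZED, DEPOLARIZED, ABSENT)

ENTRY = "entry"
AMPLIFYING = "amplifying"
SPACING = "spacing"
GMC_SCD = "gmc_scd"
DIVISION_TYPES = (ENTRY, AMPLIFYING, SPACING, GMC_SCD)

# same-cell state changes allowed between consecutive timepoints
_ALLOWED_TRANSITIONS = {
    PROTODERMAL: {PROTODERMAL, PAVEMENT},
    MERISTEMOID: {MERISTEMOID, GMC},
    SLGC: {SLGC, PAVEMENT},
    GMC: {GMC},
    GUARD: {GUARD},
    PAVEMENT: {PAVEMENT},
}

# division type -> (parent state, sorted daughter states)
_DIVISION_RULES = {
    ENTRY: (PROTODERMAL, (MERISTEMOID, SLGC)),
    AMPLIFYING: (MERISTEMOID, (MERISTEMOID, SLGC)),
    SPACING: (SLGC, (MERISTEMOID, SLGC)),
    GMC_SCD: (GMC, (GUARD, GUARD)),
}


@dataclass
class CellHistory:
    """One cell's timeline: states and polarity calls keyed by timepoint."""

    cell_id: int
    parent_id: Optional[int] = None
    states: dict = field(default_factory=dict)      # timepoint -> state
    polarity: dict = field(default_factory=dict)    # timepoint -> polarity call

    def first_timepoint(self, order: list):
        for tp in order:
            if tp in self.states:
                return tp
        return None

    def last_timepoint(self, order: list):
        for tp in reversed(order):
            if tp in self.states:
                return tp
        return None


@dataclass
class Division:
    parent_id: int
    daughter_ids: tuple[int, int]
    timepoint: object
    division_type: Optional[str] = None  # None = unlabeled


@dataclass
class LineageRecord:
    """Cells, parent links and division events over a tracing window."""

    timepoints: list
    cells: dict = field(default_factory=dict)       # cell_id -> CellHistory
    divisions: list = field(default_factory=list)   # list[Division]

    def founders(self) -> list[int]:
        t0 = self.timepoints[0]
        return [c.cell_id for c in self.cells.values()
                if c.parent_id is None and t0 in c.states]

    def living_at(self, timepoint) -> list[int]:
        return [c.cell_id for c in self.cells.values() if timepoint in c.states]

    def final_composition(self) -> Counter:
        """State counts at the last timepoint (guard cells counted singly)."""
        tp = self.timepoints[-1]
        return Counter(c.states[tp] for c in self.cells.values() if tp in c.states)


@dataclass
class DivisionCall:
    division_type: Optional[str]
    reason: Optional[str] = None


@dataclass
class DivisionSummary:
    counts: dict
    fractions: dict
    total_divisions: int
    n_unlabeled: int
    meristemoid_histogram: dict  # amplifying-round bin -> count of meristemoid lines
    stomatal_index: Optional[float]
    cell_counts: list  # per timepoint


# ---------------------------------------------------------------------------
# validation

def validate_lineage(record: LineageRecord) -> list[str]:
    """Check a record against the lineage state machine; [] means valid."""
    issues: list[str] = []
    order = record.timepoints
    tp_index = {tp: i for i, tp in enumerate(order)}

    daughters_seen: Counter = Counter()
    for div in record.divisions:
        if len(div.daughter_ids) != 2:
            issues.append(f"division of {div.parent_id} has {len(div.daughter_ids)} daughters")
            continue
        if div.timepoint not in tp_index:
            issues.append(f"division of {div.parent_id} at unknown timepoint {div.timepoint!r}")
            continue
        t = tp_index[div.timepoint]
        parent = record.cells.get(div.parent_id)
        if parent is None:
            issues.append(f"division parent {div.parent_id} missing")
            continue
        for d in div.daughter_ids:
            daughters_seen[d] += 1
            cell = record.cells.get(d)
            if cell is None:
                issues.append(f"daughter {d} missing")
                continue
            if cell.parent_id != div.parent_id:
                issues.append(f"daughter {d} parent link {cell.parent_id} != {div.parent_id}")
            ft = cell.first_timepoint(order)
            if ft is None or tp_index[ft] != t:
                issues.append(f"daughter {d} does not first appear at division timepoint")
        lt = parent.last_timepoint(order)
        if lt is not None and tp_index[lt] >= t:
            issues.append(f"parent {div.parent_id} still present at/after its division")
        # state legality of the labeled type
        if div.division_type is not None:
            if div.division_type not in _DIVISION_RULES:
                issues.append(f"unknown division type {div.division_type!r}")
            else:
                want_parent, want_daughters = _DIVISION_RULES[div.division_type]
                if lt is not None and parent.states[lt] != want_parent:
                    issues.append(
                        f"{div.division_type} division from parent state {parent.states[lt]}")
                got = tuple(sorted(
                    record.cells[d].states.get(div.timepoint, "?")
                    for d in div.daughter_ids if d in record.cells))
                if len(got) == 2 and got != want_daughters:
                    issues.append(f"{div.division_type} division produced daughters {got}")

    for cid, count in daughters_seen.items():
        if count > 1:
            issues.append(f"cell {cid} is daughter of {count} divisions")
    for cell in record.cells.values():
        if cell.parent_id is not None and daughters_seen.get(cell.cell_id, 0) == 0:
            issues.append(f"cell {cell.cell_id} has parent {cell.parent_id} but no division event")
        # contiguity + legal transitions
        present = [tp for tp in order if tp in cell.states]
        if not present:
            issues.append(f"cell {cell.cell_id} has no timepoints")
            continue
        idxs = [tp_index[tp] for tp in present]
        if idxs != list(range(idxs[0], idxs[-1] + 1)):
            issues.append(f"cell {cell.cell_id} has gaps in its timeline")
        for a, b in zip(present[:-1], present[1:]):
            s0, s1 = cell.states[a], cell.states[b]
            if s0 not in _ALLOWED_TRANSITIONS or s1 not in _ALLOWED_TRANSITIONS.get(s0, ()):
                issues.append(f"cell {cell.cell_id}: illegal transition {s0} -> {s1}")

    # guard cells must arise as sibling pairs of a GMC division
    guard_from_div = set()
    for div in record.divisions:
        states = [record.cells[d].states.get(div.timepoint) for d in div.daughter_ids
                  if d in record.cells]
        if states.count(GUARD) == 1:
            issues.append(f"division of {div.parent_id} produced a lone guard cell")
        if states.count(GUARD) == 2:
            guard_from_div.update(div.daughter_ids)
    for cell in record.cells.values():
        if GUARD in cell.states.values() and cell.cell_id not in guard_from_div:
            issues.append(f"guard cell {cell.cell_id} not produced by a division pair")
    return issues


# ---------------------------------------------------------------------------
# classification

def classify_division(
    parent_state: str,
    daughter_states: tuple[str, str],
    parent_polarity: str = ABSENT,
    daughter_sizes: Optional[tuple[float, float]] = None,
) -> DivisionCall:
    """Infer the division type from parent state, daughter fates and polarity.

    GMC divisions are symmetric and depolarized; ACDs are polarized and
    subtyped by the parent: protodermal -> entry, meristemoid -> amplifying,
    SLGC -> spacing.  Contradictory evidence yields an unlabeled call with a
    reason.  ``daughter_sizes`` is accepted for annotation provenance but is
    not used by the rule.
    """
    daughters = tuple(sorted(daughter_states))
    guard_daughters = daughters == (GUARD, GUARD)
    if guard_daughters and parent_polarity == POLARIZED:
        return DivisionCall(None, "polarized parent but guard-cell daughters")
    if parent_state == GMC or (parent_polarity == DEPOLARIZED and guard_daughters):
        if parent_state not in (GMC, MERISTEMOID):
            return DivisionCall(None, f"guard daughters from {parent_state} parent")
        return DivisionCall(GMC_SCD)
    if guard_daughters:
        return DivisionCall(None, "guard-cell daughters without depolarized/GMC evidence")
    if parent_polarity == DEPOLARIZED:
        return DivisionCall(None, "depolarized parent but non-guard daughters")
    subtype = {PROTODERMAL: ENTRY, MERISTEMOID: AMPLIFYING, SLGC: SPACING}.get(parent_state)
    if subtype is None:
        return DivisionCall(None, f"parent state {parent_state} cannot divide asymmetrically")
    if daughters != (MERISTEMOID, SLGC):
        return DivisionCall(None, f"ACD with daughters {daughters}")
    return DivisionCall(subtype)


def _division_context(record: LineageRecord, div: Division):
    order = record.timepoints
    parent = record.cells[div.parent_id]
    lt = parent.last_timepoint(order)
    parent_state = parent.states[lt] if lt is not None else "?"
    parent_pol = parent.polarity.get(lt, ABSENT) if lt is not None else ABSENT
    d_states = tuple(record.cells[d].states.get(div.timepoint, "?") for d in div.daughter_ids)
    return parent_state, d_states, parent_pol


def label_divisions(record: LineageRecord) -> list[DivisionCall]:
    """Classify every division in the record from its recorded evidence."""
    return [classify_division(*_division_context(record, d)) for d in record.divisions]


# ---------------------------------------------------------------------------
# summaries

def _meristemoid_lines(record: LineageRecord) -> list[int]:
    """Amplifying-round count per founder-derived meristemoid line.

    A line starts at a meristemoid created by an entry division (or already a
    meristemoid at the first timepoint) and follows the meristemoid daughter
    through successive amplifying divisions.
    """
    order = record.timepoints
    div_by_parent = {d.parent_id: d for d in record.divisions}

    def line_start_ids():
        t0 = order[0]
        for c in record.cells.values():
            if c.parent_id is None and c.states.get(t0) == MERISTEMOID:
                yield c.cell_id
        for d in record.divisions:
            ps, dstates, _ = _division_context(record, d)
            if ps == PROTODERMAL:
                for did, st in zip(d.daughter_ids, dstates):
                    if st == MERISTEMOID:
                        yield did

    counts = []
    for start in line_start_ids():
        rounds = 0
        cid = start
        while True:
            div = div_by_parent.get(cid)
            if div is None:
                break
            dstates = [record.cells[d].states.get(div.timepoint) for d in div.daughter_ids]
            if MERISTEMOID in dstates:  # amplifying: follow the meristemoid daughter
                rounds += 1
                cid = div.daughter_ids[dstates.index(MERISTEMOID)]
            else:
                break
        counts.append(rounds)
    return counts


def summarize_divisions(record: LineageRecord, histogram_cap: int = 3) -> DivisionSummary:
    """Division counts/fractions, meristemoid histogram, SI and cell counts.

    Divisions carry their stored labels where present; otherwise they are
    classified from the recorded states and polarity calls.  Unlabeled
    divisions are counted separately and excluded from the fractions.
    Histogram bins are 0, 1, ..., histogram_cap-1 and ``{cap}+``.
    """
    counts = Counter()
    n_unlabeled = 0
    for div in record.divisions:
        dtype = div.division_type
        if dtype is None:
            dtype = classify_division(*_division_context(record, div)).division_type
        if dtype is None:
            n_unlabeled += 1
        else:
            counts[dtype] += 1
    total = sum(counts.values())
    fractions = {t: counts[t] / total for t in counts} if total else {}

    hist = Counter()
    for rounds in _meristemoid_lines(record):
        key = str(rounds) if rounds < histogram_cap else f"{histogram_cap}+"
        hist[key] += 1

    try:
        si = stomatal_index(record)
    except ValueError:
        si = None
    return DivisionSummary(
        counts=dict(counts),
        fractions=fractions,
        total_divisions=total + n_unlabeled,
        n_unlabeled=n_unlabeled,
        meristemoid_histogram=dict(hist),
        stomatal_index=si,
        cell_counts=cell_count_trajectory(record),
    )


def stomatal_index(record_or_composition) -> float:
    """SI = stomata / all epidermal cells, with a guard-cell pair counted as
    one stoma and one unit.

    Meristemoids and GMCs (still undifferentiated at the window end) are
    excluded; accepts a LineageRecord (final timepoint) or a state-count
    mapping.
    """
    comp = (record_or_composition.final_composition()
            if isinstance(record_or_composition, LineageRecord)
            else Counter(record_or_composition))
    n_guard = comp.get(GUARD, 0)
    if n_guard % 2:
        raise ValueError("odd number of guard cells")
    n_stomata = n_guard // 2
    n_other = comp.get(PAVEMENT, 0) + comp.get(PROTODERMAL, 0) + comp.get(SLGC, 0)
    denom = n_stomata + n_other
    if denom == 0:
        raise ValueError("no differentiated epidermal cells; SI undefined")
    return n_stomata / denom


def cell_count_trajectory(record: LineageRecord) -> list[int]:
    """Number of living cells at each timepoint (guard pair = 2 cells)."""
    return [len(record.living_at(tp)) for tp in record.timepoints]


# ---------------------------------------------------------------------------
# CSV round trip (long format)

_COLUMNS = ["cell_id", "timepoint", "state", "polarity_call", "parent_id", "division_type"]


def to_frame(record: LineageRecord) -> pd.DataFrame:
    """Long-format table: one row per (cell, timepoint).

    ``division_type`` is carried on each daughter's first row (the division
    that created it); founders leave ``parent_id`` empty.
    """
    div_by_daughter = {}
    for d in record.divisions:
        for did in d.daughter_ids:
            div_by_daughter[did] = d
    rows = []
    for cell in sorted(record.cells.values(), key=lambda c: c.cell_id):
        first = cell.first_timepoint(record.timepoints)
        for tp in record.timepoints:
            if tp not in cell.states:
                continue
            div = div_by_daughter.get(cell.cell_id)
            rows.append({
                "cell_id": cell.cell_id,
                "timepoint": tp,
                "state": cell.states[tp],
                "polarity_call": cell.polarity.get(tp, ABSENT),
                "parent_id": cell.parent_id,
                "division_type": (div.division_type
                                  if div is not None and tp == first else None),
            })
    return pd.DataFrame(rows, columns=_COLUMNS)


def from_frame(df: pd.DataFrame) -> LineageRecord:
    """Rebuild a LineageRecord from the long-format table."""
    missing = [c for c in _COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"lineage table missing columns: {missing}")
    timepoints = list(pd.unique(df["timepoint"]))
    cells: dict[int, CellHistory] = {}
    first_tp: dict[int, object] = {}
    dtype_at_birth: dict[int, Optional[str]] = {}
    for row in df.itertuples(index=False):
        cid = int(row.cell_id)
        parent = None if pd.isna(row.parent_id) else int(row.parent_id)
        cell = cells.get(cid)
        if cell is None:
            cell = cells[cid] = CellHistory(cell_id=cid, parent_id=parent)
            first_tp[cid] = row.timepoint
            dt = getattr(row, "division_type", None)
            dtype_at_birth[cid] = None if (dt is None or pd.isna(dt)) else str(dt)
        if row.state not in STATES:
            raise ValueError(f"unknown state {row.state!r}")
        cell.states[row.timepoint] = row.state
        if row.polarity_call is not None and not pd.isna(row.polarity_call):
            if row.polarity_call not in POLARITY_CALLS:
                raise ValueError(f"unknown polarity call {row.polarity_call!r}")
            cell.polarity[row.timepoint] = row.polarity_call

    divisions = []
    by_parent: dict[int, list[int]] = {}
    for cell in cells.values():
        if cell.parent_id is not None:
            by_parent.setdefault(cell.parent_id, []).append(cell.cell_id)
    for parent_id, daughters in sorted(by_parent.items()):
        daughters = sorted(daughters)
        dtypes = {dtype_at_birth[d] for d in daughters} - {None}
        divisions.append(Division(
            parent_id=parent_id,
            daughter_ids=tuple(daughters),
            timepoint=first_tp[daughters[0]],
            division_type=dtypes.pop() if dtypes else None,
        ))
    return LineageRecord(timepoints=timepoints, cells=cells, divisions=divisions)
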