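"""Stochastic branching model of stomatal-lineage progression.

Each founder is a protodermal cell that either differentiates into a
pavement cell or performs an entry ACD (probability ``p_entry``) producing a
meristemoid and an SLGC.  Per round, a meristemoid self-renews by an
amplifying ACD with probability ``p_amp`` (up to ``max_rounds`` amplifying
rounds per line, after which it differentiates), otherwise it becomes a GMC
and divides symmetrically into a guard-cell pair (one stoma) on the next
round.  An SLGC re-enters by a spacing ACD with probability ``p_spacing``
(same per-line cap) or differentiates into a pavement cell.  Decisions are
i.i.d. Bernoulli; time is counted in discrete division rounds.

The tissue-level consequence: raising ``p_amp`` (more stem-cell-like ACDs
per stoma formed) lowers the stomatal index SI and raises the epidermal
cell number; in the no-spacing regime the stationary value is
SI = 1 / (E[n] + 2) with n the (truncated-)geometric number of amplifying
rounds — computed exactly by :func:`expected_si`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import lineage as L


@dataclass
class SimParams:
    """Transition probabilities and run size of the lineage simulator."""

    n_founders: int = 100
    p_entry: float = 1.0
    p_amp: float = 0.5      # per-round meristemoid self-renewal probability
    p_spacing: float = 0.0  # per-round SLGC re-entry probability
    max_rounds: int = 5     # cap on amplifying (and spacing) rounds per line
    seed: int = 0

    def __post_init__(self):
        for name in ("p_entry", "p_amp", "p_spacing"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class SimResult:
    """End-state tissue composition and division tallies of one run."""

    n_founders: int
    n_stomata: int
    n_pavement: int
    n_undifferentiated: int
    divisions_by_type: dict
    stomatal_index: float
    total_cells: int
    amp_rounds_per_founder: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def total_divisions(self) -> int:
        return sum(self.divisions_by_type.values())


def simulate(params: SimParams, record: bool = True) -> tuple[SimResult, Optional[L.LineageRecord]]:
    """Run the branching model to absorption; deterministic given the seed.

    With ``record=True`` a full :class:`~stomapolar.lineage.LineageRecord`
    (with true division-type labels and polarity calls) is emitted alongside
    the summary; the random decision sequence is identical either way.
    """
    rng = np.random.default_rng(params.seed)
    p_entry, p_amp, p_spacing = params.p_entry, params.p_amp, params.p_spacing
    cap = params.max_rounds

    div_counts = Counter()
    comp = Counter()
    amp_per_founder = np.zeros(params.n_founders, dtype=np.int64)

    cells: dict[int, L.CellHistory] = {}
    divisions: list[L.Division] = []
    births: dict[int, tuple[int, str]] = {}   # cell_id -> (birth round, state)
    changes: list[tuple[int, int, str]] = []  # (cell_id, round, new state)
    deaths: dict[int, int] = {}               # cell_id -> division round
    pol_marks: dict[int, tuple[int, str]] = {}  # cell_id -> (round, polarity call)
    next_id = 0
    t_final = 0

    def new_cell(state: str, t: int, parent: Optional[int]) -> int:
        nonlocal next_id
        cid = next_id
        next_id += 1
        if record:
            cells[cid] = L.CellHistory(cell_id=cid, parent_id=parent)
            births[cid] = (t, state)
        return cid

    def divide(parent: int, t: int, dtype: str, d_states: tuple[str, str]) -> tuple[int, int]:
        div_counts[dtype] += 1
        d0 = new_cell(d_states[0], t, parent)
        d1 = new_cell(d_states[1], t, parent)
        if record:
            deaths[parent] = t
            divisions.append(L.Division(parent, (d0, d1), t, dtype))
            pol_marks[parent] = (t - 1, L.DEPOLARIZED if dtype == L.GMC_SCD else L.POLARIZED)
        return d0, d1

    for f in range(params.n_founders):
        founder = new_cell(L.PROTODERMAL, 0, None)
        # active: (cell_id, state, amplifying rounds used in this meristemoid
        # line, spacing re-entry depth, primary-line flag).  Depth increments
        # at every spacing division and is inherited by all offspring, so
        # re-entry cannot branch indefinitely (the tree is finite for any
        # probabilities once depth reaches the cap).
        active = [(founder, L.PROTODERMAL, 0, 0, True)]
        t = 0
        while active:
            t += 1
            nxt = []
            for cid, state, used, depth, primary in active:
                if state == L.PROTODERMAL:
                    if rng.random() < p_entry:
                        m, s = divide(cid, t, L.ENTRY, (L.MERISTEMOID, L.SLGC))
                        nxt.append((m, L.MERISTEMOID, 0, depth, primary))
                        nxt.append((s, L.SLGC, 0, depth, primary))
                    else:
                        comp[L.PAVEMENT] += 1
                        if record:
                            changes.append((cid, t, L.PAVEMENT))
                elif state == L.MERISTEMOID:
                    if used < cap and rng.random() < p_amp:
                        if primary:
                            amp_per_founder[f] += 1
                        m, s = divide(cid, t, L.AMPLIFYING, (L.MERISTEMOID, L.SLGC))
                        nxt.append((m, L.MERISTEMOID, used + 1, depth, primary))
                        nxt.append((s, L.SLGC, 0, depth, False))
                    else:
                        if record:
                            changes.append((cid, t, L.GMC))
                        nxt.append((cid, L.GMC, used, depth, primary))
                elif state == L.GMC:
                    divide(cid, t, L.GMC_SCD, (L.GUARD, L.GUARD))
                    comp[L.GUARD] += 2
                elif state == L.SLGC:
                    if depth < cap and rng.random() < p_spacing:
                        m, s = divide(cid, t, L.SPACING, (L.MERISTEMOID, L.SLGC))
                        nxt.append((m, L.MERISTEMOID, 0, depth + 1, False))
                        nxt.append((s, L.SLGC, 0, depth + 1, False))
                    else:
                        comp[L.PAVEMENT] += 1
                        if record:
                            changes.append((cid, t, L.PAVEMENT))
            active = nxt
        t_final = max(t_final, t)

    n_stomata = comp[L.GUARD] // 2
    n_pavement = comp[L.PAVEMENT]
    undiff = 0  # all lineages run to absorption under the round cap
    total_cells = comp[L.GUARD] + n_pavement
    si = n_stomata / (n_stomata + n_pavement) if (n_stomata + n_pavement) else 0.0
    result = SimResult(
        n_founders=params.n_founders,
        n_stomata=n_stomata,
        n_pavement=n_pavement,
        n_undifferentiated=undiff,
        divisions_by_type=dict(div_counts),
        stomatal_index=si,
        total_cells=total_cells,
        amp_rounds_per_founder=amp_per_founder,
    )
    if not record:
        return result, None

    # materialise the per-timepoint record
    timepoints = list(range(t_final + 1))
    state_changes: dict[int, list[tuple[int, str]]] = {}
    for cid, t, st in changes:
        state_changes.setdefault(cid, []).append((t, st))
    for cid, cell in cells.items():
        t0, state = births[cid]
        end = deaths.get(cid, t_final + 1)
        marks = sorted(state_changes.get(cid, []))
        for t in range(t0, min(end, t_final + 1)):
            while marks and marks[0][0] <= t:
                state = marks.pop(0)[1]
            cell.states[t] = state
        if cid in pol_marks:
            t, call = pol_marks[cid]
            if t in cell.states:
                cell.polarity[t] = call
    rec = L.LineageRecord(timepoints=timepoints, cells=cells, divisions=divisions)
    return result, rec


def expected_si(p_amp: float, max_rounds: Optional[int] = None) -> float:
    """Analytic stomatal index in the no-spacing regime, SI = 1/(E[n] + 2).

    n, the number of amplifying rounds of one meristemoid line, is geometric
    with continuation probability ``p_amp``, truncated at ``max_rounds``
    (``None`` = unbounded, requires ``p_amp`` < 1): each founder ends as one
    stoma plus n + 1 pavement-fated SLGCs.
    """
    if not 0.0 <= p_amp <= 1.0:
        raise ValueError("p_amp must be in [0, 1]")
    if max_rounds is None:
        if p_amp >= 1.0:
            raise ValueError("p_amp = 1 requires a finite max_rounds")
        e_n = p_amp / (1.0 - p_amp)
    else:
        ks = np.arange(max_rounds)
        e_n = float(np.sum(ks * p_amp ** ks * (1.0 - p_amp)) + max_rounds * p_amp ** max_rounds)
    return 1.0 / (e_n + 2.0)


def sweep(
    p_amp_values,
    p_spacing_values=(0.0,),
    n_founders: int = 10000,
    max_rounds: int = 5,
    p_entry: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid of simulator runs; one row of (SI, cell number, ...) per point.

    Each grid point gets its own deterministic child seed derived from
    ``seed`` so points are independent but the sweep is reproducible.
    """
    seed_rng = np.random.default_rng(seed)
    rows = []
    for p_amp in p_amp_values:
        for p_spacing in p_spacing_values:
            child = int(seed_rng.integers(2 ** 31))
            res, _ = simulate(SimParams(
                n_founders=n_founders, p_entry=p_entry, p_amp=float(p_amp),
                p_spacing=float(p_spacing), max_rounds=max_rounds, seed=child,
            ), record=False)
            rows.append({
                "p_amp": float(p_amp),
                "p_spacing": float(p_spacing),
                "stomatal_index": res.stomatal_index,
                "total_cells": res.total_cells,
                "n_stomata": res.n_stomata,
                "n_pavement": res.n_pavement,
                "total_divisions": res.total_divisions,
                "expected_si_no_spacing": expected_si(float(p_amp), max_rounds),
                "seed": child,
            })
    return pd.DataFrame(rows)


#: illustrative scenario presets: qualitative orderings only — ethylene
#: suppresses amplifying ACDs (higher SI, fewer cells), glucose promotes them
SCENARIOS = {
    "wild-type": SimParams(n_founders=1000, p_entry=0.8, p_amp=0.5, p_spacing=0.15),
    "high-ethylene": SimParams(n_founders=1000, p_entry=0.8, p_amp=0.25, p_spacing=0.15),
    "high-glucose": SimParams(n_founders=1000, p_entry=0.8, p_amp=0.7, p_spacing=0.15),
}
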