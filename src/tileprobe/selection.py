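"""Two-stage probe selection: fixed windows, then largest-gap filling.

Stage one tiles each strand of each molecule with windows of ``WS`` bases
and picks at most one probe per window; stage two repeatedly inserts the
best remaining candidate into the largest start-to-start gap between
already-selected probes until exactly the requested number of probes is
reached.  A minimum start-to-start distance is enforced per strand against
*every* occurrence of every selected probe, so repeated sequences (one
array feature, several loci) block their whole neighborhood.

The default window size is ``floor(2*GS / MS)`` (GS = combined genome
length, doubled for the two strands; MS = probe spots).  If a sequential
pass ever selects more than MS probes the pass is repeated with a window
one base larger.  The default minimum distance is ``ceil(WS / 4)``.

Two comparators are used, deliberately different:

* within a window or gap (best probe of the region): restrict to the best
  cross-hybridization level present, then (Tm deviation asc, self-annealing
  MFE desc, identity stretch asc, percent identity asc, length desc,
  position asc);
* across gaps (which gap to fill next): gap size desc, then the winning
  probe's (identity stretch asc, percent identity asc, Tm deviation asc,
  MFE desc, length desc, position asc).
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass

from .enumeration import ProbeCandidate
from .genome import GenomeMolecule

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass
class DesignPlan:
    gs: int             # combined genome length (bases)
    ms: int             # total probe spots requested
    window_size: int
    min_distance: int

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not 1 <= self.min_distance <= self.window_size:
            raise ValueError("min_distance must be in [1, window_size]")


def default_min_distance(ws: int) -> int:
    """Smallest allowed start-to-start spacing derived from the window size."""
    if ws < 1:
        raise ValueError("window size must be >= 1")
    return math.ceil(ws / 4)


def plan_window_size(
    gs: int, ms: int, user_ws: int | None = None, user_min_distance: int | None = None
) -> DesignPlan:
    """Initial design plan: WS = floor(2*GS/MS) unless user-supplied."""
    if gs < 1 or ms < 1:
        raise ValueError("genome size and probe count must be positive")
    if user_ws is not None:
        ws = user_ws
    else:
        ws = (2 * gs) // ms
        if ws == 0:
            raise ValueError(
                f"requested probe count {ms} exceeds twice the genome size {gs}"
            )
    md = user_min_distance if user_min_distance is not None else default_min_distance(ws)
    return DesignPlan(gs=gs, ms=ms, window_size=ws, min_distance=md)


def window_key(cand: ProbeCandidate, traversal_start: int):
    """Within-window/within-gap comparator (smaller is better)."""
    return (
        cand.xhyb_level,
        cand.tm_dev,
        -cand.mfe,       # less negative MFE = less self-annealing = better
        cand.is_pct,
        cand.pi,
        -cand.length,
        traversal_start,
    )


def gap_key(cand: ProbeCandidate, position: tuple):
    """Across-gap comparator applied after gap size (smaller is better)."""
    return (cand.is_pct, cand.pi, cand.tm_dev, -cand.mfe, -cand.length, position)


def rank_in_window(items: list[tuple[ProbeCandidate, int]]) -> ProbeCandidate | None:
    """Best probe among (candidate, traversal start) pairs, or None."""
    if not items:
        return None
    return min(items, key=lambda it: window_key(it[0], it[1]))[0]


def rank_in_gap(items: list[tuple[ProbeCandidate, int]]) -> ProbeCandidate | None:
    """Within a gap the window-stage comparator applies unchanged."""
    return rank_in_window(items)


class SelectionState:
    """Selected probes plus per-(molecule, strand) occupied start positions."""

    def __init__(self, candidates: list[ProbeCandidate], molecules: list[GenomeMolecule]):
        self.candidates = candidates
        self.molecules = molecules
        self.mol_rank = {m.id: i for i, m in enumerate(molecules)}
        self.mol_len = {m.id: m.length for m in molecules}
        self.mol_circ = {m.id: m.is_circular for m in molecules}
        # occurrence table per (molecule, strand), sorted by start
        self.occ: dict[tuple[str, str], list[tuple[int, int]]] = {
            (m.id, s): [] for m in molecules for s in STRANDS
        }
        for ci, cand in enumerate(candidates):
            if cand.rejected:
                continue
            for p in cand.positions:
                self.occ[(p.molecule_id, p.strand)].append((p.start, ci))
        for lst in self.occ.values():
            lst.sort()
        self.occ_starts = {k: [s for s, _ in v] for k, v in self.occ.items()}
        self.reset()

    def reset(self) -> None:
        self.selected: list[int] = []
        self.selected_set: set[int] = set()
        self.occupied: dict[tuple[str, str], list[int]] = {
            k: [] for k in self.occ
        }

    # -- distance bookkeeping -------------------------------------------------

    def _dist_ok(self, mol_id: str, strand: str, start: int, min_distance: int) -> bool:
        occ = self.occupied[(mol_id, strand)]
        if not occ:
            return True
        L = self.mol_len[mol_id]
        circ = self.mol_circ[mol_id]
        i = bisect_left(occ, start)
        neighbors = []
        if i < len(occ):
            neighbors.append(occ[i])
        if i > 0:
            neighbors.append(occ[i - 1])
        if circ:
            neighbors.append(occ[0])
            neighbors.append(occ[-1])
        for nb in neighbors:
            d = abs(start - nb)
            if circ:
                d = min(d, L - d)
            if d < min_distance:
                return False
        return True

    def candidate_ok(self, ci: int, min_distance: int) -> bool:
        cand = self.candidates[ci]
        if cand.rejected or ci in self.selected_set:
            return False
        return all(
            self._dist_ok(p.molecule_id, p.strand, p.start, min_distance)
            for p in cand.positions
        )

    def occupy(self, ci: int) -> None:
        cand = self.candidates[ci]
        self.selected.append(ci)
        self.selected_set.add(ci)
        for p in cand.positions:
            insort(self.occupied[(p.molecule_id, p.strand)], p.start)

    # -- queries --------------------------------------------------------------

    def occ_in_range(self, mol_id: str, strand: str, lo: int, hi: int):
        """Occurrences with lo <= start <= hi (non-modular)."""
        starts = self.occ_starts[(mol_id, strand)]
        occ = self.occ[(mol_id, strand)]
        return occ[bisect_left(starts, lo) : bisect_right(starts, hi)]

    def occupied_in_open_range(self, mol_id: str, strand: str, lo: int, hi: int) -> list[int]:
        """Occupied starts strictly inside (lo, hi), modular if hi > L."""
        occ = self.occupied[(mol_id, strand)]
        L = self.mol_len[mol_id]
        if hi <= L:
            return occ[bisect_right(occ, lo) : bisect_left(occ, hi)]
        out = occ[bisect_right(occ, lo) :]
        out += [s + L for s in occ[: bisect_left(occ, hi - L)]]
        return out


def select_sequential(state: SelectionState, plan: DesignPlan) -> int:
    """One sequential pass: one probe at most per window, per strand.

    Windows are processed molecule by molecule in input order, forward
    strand then reverse.  A window already containing an occurrence of a
    selected probe (a repeat picked earlier) is skipped; otherwise the best
    admissible candidate starting in the window is selected and all its
    occurrences become occupied.  Returns the number of probes selected.
    """
    ws = plan.window_size
    for mol in state.molecules:
        for strand in STRANDS:
            for wstart in range(1, mol.length + 1, ws):
                wend = min(wstart + ws - 1, mol.length)
                occs = state.occ_in_range(mol.id, strand, wstart, wend)
                if not occs:
                    continue
                if any(ci in state.selected_set for _, ci in occs):
                    continue  # repeat already represents this window
                items: list[tuple[ProbeCandidate, int]] = []
                seen: set[int] = set()
                for s, ci in occs:
                    if ci in seen:
                        continue
                    seen.add(ci)
                    if state.candidate_ok(ci, plan.min_distance):
                        items.append((state.candidates[ci], s))
                if not items:
                    continue
                best = min(items, key=lambda it: window_key(it[0], it[1]))[0]
                for s, cj in occs:
                    if state.candidates[cj] is best:
                        state.occupy(cj)
                        break
    return len(state.selected)


def run_sequential(
    state: SelectionState,
    gs: int,
    ms: int,
    user_ws: int | None = None,
    user_min_distance: int | None = None,
) -> DesignPlan:
    """Sequential stage with the window-size retry rule.

    Starts from the floor-derived (or user) window size; while a pass
    selects more than MS probes, the window is widened by one base and the
    pass repeats.  The minimum distance is re-derived from the window size
    on each retry unless user-supplied.
    """
    plan = plan_window_size(gs, ms, user_ws, user_min_distance)
    while True:
        state.reset()
        n = select_sequential(state, plan)
        if n <= ms:
            logger.info(
                "sequential stage: %d probes at window size %d (min distance %d)",
                n, plan.window_size, plan.min_distance,
            )
            return plan
        logger.info(
            "sequential pass selected %d > %d probes; widening window to %d",
            n, ms, plan.window_size + 1,
        )
        if plan.window_size > 2 * gs:
            raise ValueError(
                "cannot reduce the sequential selection to the requested probe count"
            )
        md = user_min_distance
        plan = DesignPlan(
            gs=gs, ms=ms, window_size=plan.window_size + 1,
            min_distance=md if md is not None else default_min_distance(plan.window_size + 1),
        )


@dataclass
class Gap:
    """Start-to-start interval between adjacent selected probes on a strand.

    ``right`` may exceed the molecule length for the circular wrap-around
    gap; ``left`` 0 / ``right`` L+1 stand for the open ends of a linear
    molecule (usable for filling, excluded from gap statistics).
    """

    molecule_id: str
    strand: str
    left: int
    right: int

    @property
    def size(self) -> int:
        return self.right - self.left


def _best_in_gap(state: SelectionState, gap: Gap, min_distance: int):
    """Best admissible (cand index, start) strictly inside the gap, or None."""
    L = state.mol_len[gap.molecule_id]
    if gap.right <= L:
        occs = state.occ_in_range(gap.molecule_id, gap.strand, gap.left + 1, gap.right - 1)
    else:  # wrap gap: (left, L] then [1, right - L)
        occs = state.occ_in_range(gap.molecule_id, gap.strand, gap.left + 1, L)
        occs = occs + state.occ_in_range(gap.molecule_id, gap.strand, 1, gap.right - L - 1)
    best = None
    best_k = None
    seen: set[int] = set()
    for s, ci in occs:
        if ci in seen:
            continue
        seen.add(ci)
        if not state.candidate_ok(ci, min_distance):
            continue
        k = window_key(state.candidates[ci], s if s > gap.left else s + L)
        if best_k is None or k < best_k:
            best, best_k = (ci, s), k
    return best


def _gap_priority(state: SelectionState, gap: Gap, ci: int, start: int):
    cand = state.candidates[ci]
    pos = (state.mol_rank[gap.molecule_id], start, 0 if gap.strand == "+" else 1)
    return (-gap.size, *gap_key(cand, pos))


def initial_gaps(state: SelectionState) -> list[Gap]:
    """Start-to-start gaps per strand after the sequential stage.

    Circular strands get the wrap-around gap; linear strands additionally
    get the two open end intervals so the ends remain fillable.
    """
    gaps: list[Gap] = []
    for mol in state.molecules:
        L = mol.length
        for strand in STRANDS:
            occ = state.occupied[(mol.id, strand)]
            if not occ:
                if state.occ[(mol.id, strand)]:
                    gaps.append(Gap(mol.id, strand, 0, L + 1))
                continue
            for a, b in itertools.pairwise(occ):
                gaps.append(Gap(mol.id, strand, a, b))
            if mol.is_circular:
                gaps.append(Gap(mol.id, strand, occ[-1], occ[0] + L))
            else:
                if occ[0] > 1:
                    gaps.append(Gap(mol.id, strand, 0, occ[0]))
                if occ[-1] < L:
                    gaps.append(Gap(mol.id, strand, occ[-1], L + 1))
    return gaps


def gap_fill(state: SelectionState, plan: DesignPlan, target_count: int) -> bool:
    """Fill the largest gaps until exactly ``target_count`` probes are selected.

    Returns True on success, False on shortfall (every gap exhausted first).
    Gap entries are revalidated lazily on pop: a gap invalidated by a repeat
    occurrence landing inside it is split, and a stale best-probe entry is
    re-queued with its fresh priority before it can win.
    """
    if len(state.selected) > target_count:
        raise RuntimeError("sequential stage selected more probes than requested")
    counter = itertools.count()
    heap: list = []

    def push(gap: Gap) -> None:
        L = state.mol_len[gap.molecule_id]
        if gap.left > L:  # canonicalize wrap-region children
            gap = Gap(gap.molecule_id, gap.strand, gap.left - L, gap.right - L)
        found = _best_in_gap(state, gap, plan.min_distance)
        if found is None:
            return
        ci, s = found
        heapq.heappush(heap, (_gap_priority(state, gap, ci, s), next(counter), gap, ci, s))

    for gap in initial_gaps(state):
        push(gap)

    while len(state.selected) < target_count and heap:
        prio, _, gap, ci, s = heapq.heappop(heap)
        inner = state.occupied_in_open_range(gap.molecule_id, gap.strand, gap.left, gap.right)
        if inner:  # another selection landed inside: split and retry
            bounds = [gap.left] + inner + [gap.right]
            for a, b in itertools.pairwise(bounds):
                push(Gap(gap.molecule_id, gap.strand, a, b))
            continue
        found = _best_in_gap(state, gap, plan.min_distance)
        if found is None:
            continue
        ci2, s2 = found
        fresh = _gap_priority(state, gap, ci2, s2)
        if fresh != prio:
            heapq.heappush(heap, (fresh, next(counter), gap, ci2, s2))
            continue
        state.occupy(ci2)
        L = state.mol_len[gap.molecule_id]
        s_virtual = s2 if s2 > gap.left else s2 + L
        push(Gap(gap.molecule_id, gap.strand, gap.left, s_virtual))
        push(Gap(gap.molecule_id, gap.strand, s_virtual, gap.right))

    if len(state.selected) < target_count:
        logger.warning(
            "shortfall: only %d of %d requested probes could be placed",
            len(state.selected), target_count,
        )
        return False
    return True
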