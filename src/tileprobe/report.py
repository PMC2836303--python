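"""Final probe-set output and design summary statistics.

Emits the selected probe set as TSV (one row per non-redundant probe),
BED6 (one line per genomic occurrence, wrap-aware), FASTA, and a YAML
summary holding the per-strand start totals and the start-to-start gap-size
histogram — the quantities a designer checks first: how many spots were
used, how evenly the genome is covered, and that no spacing dips below the
minimum distance.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .enumeration import ProbeCandidate
from .genome import GenomicPosition
from .selection import DesignPlan, SelectionState


@dataclass
class DesignSummary:
    total_probes: int
    window_size: int
    min_distance: int
    forward_starts: int
    reverse_starts: int
    gap_histogram: dict[int, int] = field(default_factory=dict)


_COLUMNS = [
    "probe_id", "sequence", "length", "tm", "tm_dev", "cycles",
    "xhyb_level", "pi", "is_pct", "mfe", "n_positions", "positions",
]


def _sorted_selected(state: SelectionState) -> list[ProbeCandidate]:
    cands = [state.candidates[i] for i in state.selected]
    rank = state.mol_rank

    def key(c: ProbeCandidate):
        p = c.positions[0]
        return (rank[p.molecule_id], p.start, 0 if p.strand == "+" else 1)

    return sorted(cands, key=key)


def probe_ids(selected: list[ProbeCandidate]) -> list[str]:
    return [f"P{i + 1:07d}" for i in range(len(selected))]


def write_probe_table(state: SelectionState, path: str | Path) -> list[ProbeCandidate]:
    """TSV of the selection, sorted by (molecule, start, strand)."""
    selected = _sorted_selected(state)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for pid, c in zip(probe_ids(selected), selected):
            pos = ";".join(f"{p.molecule_id}:{p.start}:{p.strand}" for p in c.positions)
            w.writerow([
                pid, c.sequence, c.length, f"{c.tm:.4f}", f"{c.tm_dev:.4f}",
                c.cycles, c.xhyb_level, f"{c.pi:.4f}", f"{c.is_pct:.4f}",
                f"{c.mfe:.4f}", len(c.positions), pos,
            ])
    return selected


def read_probe_table(path: str | Path) -> list[ProbeCandidate]:
    """Inverse of :func:`write_probe_table` (round-trip safe)."""
    out: list[ProbeCandidate] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            positions = []
            for tok in row["positions"].split(";"):
                mol, start, strand = tok.rsplit(":", 2)
                positions.append(GenomicPosition(mol, int(start), strand))
            out.append(ProbeCandidate(
                sequence=row["sequence"], positions=positions, offsets=[],
                cycles=int(row["cycles"]), tm=float(row["tm"]),
                tm_dev=float(row["tm_dev"]), xhyb_level=int(row["xhyb_level"]),
                pi=float(row["pi"]), is_pct=float(row["is_pct"]),
                mfe=float(row["mfe"]),
            ))
    return out


def write_bed(state: SelectionState, path: str | Path) -> None:
    """BED6, 0-based half-open; occurrences wrapping a circular origin are
    split into two lines at the origin."""
    selected = _sorted_selected(state)
    with open(path, "w") as fh:
        for pid, c in zip(probe_ids(selected), selected):
            for p in c.positions:
                L = state.mol_len[p.molecule_id]
                b0 = p.start - 1
                end = b0 + c.length
                score = c.xhyb_level
                if end <= L:
                    fh.write(f"{p.molecule_id}\t{b0}\t{end}\t{pid}\t{score}\t{p.strand}\n")
                else:  # circular wrap: split at the origin
                    fh.write(f"{p.molecule_id}\t{b0}\t{L}\t{pid}\t{score}\t{p.strand}\n")
                    fh.write(f"{p.molecule_id}\t0\t{end - L}\t{pid}\t{score}\t{p.strand}\n")


def write_fasta(state: SelectionState, path: str | Path) -> None:
    selected = _sorted_selected(state)
    with open(path, "w") as fh:
        for pid, c in zip(probe_ids(selected), selected):
            fh.write(f">{pid}\n{c.sequence}\n")


def summarize(state: SelectionState, plan: DesignPlan) -> DesignSummary:
    """Per-strand start totals and start-to-start gap histogram.

    Gaps are differences of adjacent occupied starts on one strand over all
    occurrences; circular strands include the wrap-around gap, so their gap
    count equals their start count.
    """
    hist: Counter[int] = Counter()
    fwd = rev = 0
    for mol in state.molecules:
        L = mol.length
        for strand in ("+", "-"):
            occ = state.occupied[(mol.id, strand)]
            if strand == "+":
                fwd += len(occ)
            else:
                rev += len(occ)
            if len(occ) >= 2:
                for a, b in zip(occ, occ[1:]):
                    hist[b - a] += 1
            if mol.is_circular and occ:
                hist[(occ[0] + L) - occ[-1]] += 1
    return DesignSummary(
        total_probes=len(state.selected),
        window_size=plan.window_size,
        min_distance=plan.min_distance,
        forward_starts=fwd,
        reverse_starts=rev,
        gap_histogram=dict(sorted(hist.items())),
    )


def write_summary(summary: DesignSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "total_probes": summary.total_probes,
                "window_size": summary.window_size,
                "min_distance": summary.min_distance,
                "forward_starts": summary.forward_starts,
                "reverse_starts": summary.reverse_starts,
                "gap_histogram": summary.gap_histogram,
            },
            fh,
            sort_keys=False,
        )
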