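"""Exhaustive probe enumeration and merging into non-redundant candidates.

Every valid start offset of the pseudo-molecule yields two raw probes of the
maximum length: the forward-strand window itself and its reverse complement
(the '-'-strand probe at the same forward-axis start).  Windows containing
any non-ACGT character are skipped entirely, which transparently handles
both spacers and ambiguity codes.  After length adjustment, identical final
sequences are merged into one candidate carrying every genomic occurrence —
a repeated sequence occupies a single array feature but many loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .genome import GenomicPosition, PseudoMolecule, reverse_complement


class RawProbe(NamedTuple):
    """A not-yet-adjusted probe of maximum length at one locus."""

    raw: str          # probe sequence (already reverse-complemented for '-')
    offset: int       # 0-based pseudo offset of the forward-axis window start
    strand: str       # '+' or '-'


class FinalOccurrence(NamedTuple):
    """One genomic occurrence of a final (length-adjusted) probe sequence."""

    sequence: str
    position: GenomicPosition
    offset: int       # adjusted 0-based pseudo offset of the final footprint
    strand: str


@dataclass
class ProbeCandidate:
    """A non-redundant probe: one distinct sequence, all its loci, metrics."""

    sequence: str
    positions: list[GenomicPosition]
    offsets: list[tuple[int, str]]  # (pseudo offset, strand) per occurrence
    cycles: int = 0
    tm: float = 0.0
    tm_dev: float = 0.0
    xhyb_level: int = 1
    pi: float = 0.0
    is_pct: float = 0.0
    mfe: float = 0.0
    rejected: bool = False  # synthesis-cycle limit unmeetable even at min length

    @property
    def length(self) -> int:
        return len(self.sequence)


def _valid_start_mask(seq_bytes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over offsets 0..len-k: window [o, o+k) is all-ACGT."""
    ok = (
        (seq_bytes == ord("A")) | (seq_bytes == ord("C"))
        | (seq_bytes == ord("G")) | (seq_bytes == ord("T"))
    ).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(ok)))
    n = len(seq_bytes)
    if n < k:
        return np.zeros(0, dtype=bool)
    return (cum[k:] - cum[:-k]) == k


def enumerate_probes(pseudo: PseudoMolecule, k_max: int | None = None) -> Iterator[RawProbe]:
    """Stream every raw probe of length ``k_max`` from both strands.

    Start-offset ranges per segment: a circular molecule of length L has L
    valid forward-axis starts (wrap handled by its extension); a linear one
    has L - k_max + 1.
    """
    k = k_max if k_max is not None else pseudo.k_max
    if k != pseudo.k_max:
        raise ValueError("pseudo-molecule was built for a different k_max")
    seq = pseudo.sequence
    sb = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = _valid_start_mask(sb, k)
    for seg in pseudo.segments:
        last = seg.offset + seg.length - 1 if seg.extension else seg.offset + seg.length - k
        for o in range(seg.offset, last + 1):
            if not valid[o]:
                continue
            window = seq[o : o + k]
            yield RawProbe(window, o, "+")
            yield RawProbe(reverse_complement(window), o, "-")


def finalize_occurrence(
    pseudo: PseudoMolecule, raw: RawProbe, final_len: int
) -> FinalOccurrence:
    """Genomic coordinates of a raw probe after 3'-truncation to ``final_len``.

    A forward probe keeps its start; truncating a '-'-strand probe removes
    bases from the *left* of the forward-axis window, so its recorded start
    shifts right by the number of bases removed.
    """
    k = pseudo.k_max
    if raw.strand == "+":
        off = raw.offset
        seq = raw.raw[:final_len]
    else:
        off = raw.offset + (k - final_len)
        seq = raw.raw[:final_len]
    pos = pseudo.map_position(off, raw.strand, final_len)
    return FinalOccurrence(seq, pos, off, raw.strand)


def deduplicate(
    occurrences: Iterable[FinalOccurrence], molecule_order: list[str]
) -> list[ProbeCandidate]:
    """Merge identical final sequences into candidates with sorted positions.

    Positions are ordered by (molecule file order, start, '+' before '-');
    candidates are returned in order of their first-sorted position.
    """
    mol_rank = {m: i for i, m in enumerate(molecule_order)}
    by_seq: dict[str, ProbeCandidate] = {}
    for occ in occurrences:
        cand = by_seq.get(occ.sequence)
        if cand is None:
            cand = ProbeCandidate(occ.sequence, [], [])
            by_seq[occ.sequence] = cand
        cand.positions.append(occ.position)
        cand.offsets.append((occ.offset, occ.strand))

    def pos_key(p: GenomicPosition) -> tuple:
        return (mol_rank[p.molecule_id], p.start, 0 if p.strand == "+" else 1)

    for cand in by_seq.values():
        order = sorted(range(len(cand.positions)), key=lambda i: pos_key(cand.positions[i]))
        cand.positions = [cand.positions[i] for i in order]
        cand.offsets = [cand.offsets[i] for i in order]
    return sorted(by_seq.values(), key=lambda c: pos_key(c.positions[0]))
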