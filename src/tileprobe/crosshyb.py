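"""Cross-hybridization scoring against the pseudo-molecule.

Each probe is compared with every similar locus in the genome (both
strands).  Specificity is summarized by two probe-length-relative measures
over the best non-self hits: percent identity (PI, matched bases of a hit
as % of probe length) and identity stretch (IS, longest contiguous match
run as % of probe length).  Probes are then binned into four
cross-hybridization levels (1 = most specific):

    level 1  PI < 50
    level 2  50 <= PI < 75  and IS < 30
    level 3  75 <= PI < 90  and 30 <= IS < 40
    level 4  PI >= 90 and IS >= 40

extended to a total, monotone mapping by taking the worse of the PI band
and the IS band, so every (PI, IS) combination gets a deterministic level.

The search is seed-and-extend: exact ``word_size`` seeds gate which
diagonals are examined; PI and IS are then computed over the full
probe/subject overlap of each seeded diagonal, which makes the builtin
search exactly equivalent to an exhaustive all-offsets ungapped comparison
restricted to diagonals with a match run of at least ``word_size``.

Self-hits are discarded in genomic coordinates: a diagonal is self when it
matches exactly over the whole available overlap and corresponds to a
recorded occurrence of the probe (including the duplicated images of a
locus created by a circular molecule's origin extension).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from numba import njit

from .genome import PseudoMolecule

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


class HitSummary(NamedTuple):
    pi: float
    is_pct: float
    n_hits: int


@dataclass(frozen=True)
class LevelLimits:
    """User-adjustable PI/IS band boundaries (percent)."""

    pi_bounds: tuple[float, float, float] = (50.0, 75.0, 90.0)
    is_bounds: tuple[float, float] = (30.0, 40.0)

    def __post_init__(self) -> None:
        if not (0 < self.pi_bounds[0] < self.pi_bounds[1] < self.pi_bounds[2] < 100):
            raise ValueError("pi_bounds must be strictly increasing within (0, 100)")
        if not (0 < self.is_bounds[0] < self.is_bounds[1] < 100):
            raise ValueError("is_bounds must be strictly increasing within (0, 100)")


def assign_level(pi: float, is_pct: float, limits: LevelLimits = LevelLimits()) -> int:
    """Cross-hybridization level 1-4 (worse of the PI band and the IS band)."""
    p1, p2, p3 = limits.pi_bounds
    i1, i2 = limits.is_bounds
    pi_band = 1 if pi < p1 else 2 if pi < p2 else 3 if pi < p3 else 4
    is_band = 1 if is_pct < i1 else 3 if is_pct < i2 else 4
    return max(pi_band, is_band)


def encode(sequence: str) -> np.ndarray:
    return _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _word_values(enc, w):
    n = enc.size
    out = np.full(max(0, n - w + 1), -1, dtype=np.int64)
    for o in range(n - w + 1):
        v = 0
        ok = True
        for t in range(w):
            b = enc[o + t]
            if b > 3:
                ok = False
                break
            v = v * 4 + b
        if ok:
            out[o] = v
    return out


@njit(cache=True)
def _scan_orientation(penc, senc, pwords, csr_starts, csr_pos):
    """Unique seeded diagonals with full-overlap match count and longest run."""
    # count seed hits
    total = 0
    for q in range(pwords.size):
        v = pwords[q]
        if v >= 0:
            total += csr_starts[v + 1] - csr_starts[v]
    diags = np.empty(total, dtype=np.int64)
    t = 0
    for q in range(pwords.size):
        v = pwords[q]
        if v < 0:
            continue
        for idx in range(csr_starts[v], csr_starts[v + 1]):
            diags[t] = csr_pos[idx] - q
            t += 1
    diags = np.sort(diags)
    plen, slen = penc.size, senc.size
    out_d = np.empty(total, dtype=np.int64)
    out_m = np.empty(total, dtype=np.int64)
    out_r = np.empty(total, dtype=np.int64)
    k = 0
    for idx in range(total):
        d = diags[idx]
        if idx > 0 and d == diags[idx - 1]:
            continue
        i0 = 0 if d >= 0 else -d
        i1 = plen if d + plen <= slen else slen - d
        if i1 <= i0:
            continue
        matches = 0
        run = 0
        cur = 0
        for i in range(i0, i1):
            if penc[i] == senc[d + i]:
                matches += 1
                cur += 1
                if cur > run:
                    run = cur
            else:
                cur = 0
        out_d[k], out_m[k], out_r[k] = d, matches, run
        k += 1
    return out_d[:k], out_m[:k], out_r[:k]


def self_diagonals(
    pseudo: PseudoMolecule, offsets: Iterable[tuple[int, str]]
) -> set[tuple[int, int]]:
    """Pseudo-space diagonals holding exact images of the probe's own loci.

    A circular molecule's origin region exists twice in the pseudo-molecule
    (body and extension), so each occurrence contributes its own offset
    plus, on circular segments, the +-L shifted images.
    """
    out: set[tuple[int, int]] = set()
    for off, strand in offsets:
        orient = 0 if strand == "+" else 1
        seg = pseudo.segment_of(off)
        out.add((orient, off))
        if seg.extension:
            out.add((orient, off + seg.length))
            out.add((orient, off - seg.length))
    return out


class PseudoIndex:
    """Word index of the pseudo-molecule's forward strand."""

    def __init__(self, pseudo: PseudoMolecule, word_size: int = 7):
        if word_size < 4:
            raise ValueError("word_size must be >= 4")
        self.pseudo = pseudo
        self.word_size = word_size
        self.senc = encode(pseudo.sequence)
        words = _word_values(self.senc, word_size)
        valid = words >= 0
        nwords = 4**word_size
        counts = np.bincount(words[valid], minlength=nwords)
        self.csr_starts = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        order = np.argsort(words[valid], kind="stable")
        self.csr_pos = np.flatnonzero(valid)[order].astype(np.int64)

    def summarize(self, probe_sequence: str, offsets: Iterable[tuple[int, str]]) -> HitSummary:
        penc = encode(probe_sequence)
        rc = penc[::-1].copy()
        rc[rc < 4] = 3 - rc[rc < 4]
        selfd = self_diagonals(self.pseudo, offsets)
        plen = len(probe_sequence)
        best_m = 0
        best_r = 0
        n_hits = 0
        for orient, enc_p in ((0, penc), (1, rc)):
            pwords = _word_values(enc_p, self.word_size)
            ds, ms, rs = _scan_orientation(
                enc_p, self.senc, pwords, self.csr_starts, self.csr_pos
            )
            for d, m, r in zip(ds, ms, rs):
                d = int(d)
                i0 = max(0, -d)
                i1 = min(plen, self.senc.size - d)
                if m == i1 - i0 and (orient, d) in selfd:
                    continue  # exact image of the probe's own locus
                n_hits += 1
                if m > best_m:
                    best_m = int(m)
                if r > best_r:
                    best_r = int(r)
        return HitSummary(100.0 * best_m / plen, 100.0 * best_r / plen, n_hits)


def search_hits(
    probe_sequence: str,
    offsets: Iterable[tuple[int, str]],
    pseudo: PseudoMolecule | PseudoIndex,
    word_size: int = 7,
) -> HitSummary:
    """PI/IS maxima of a probe's non-self hits (builds an index if needed)."""
    index = pseudo if isinstance(pseudo, PseudoIndex) else PseudoIndex(pseudo, word_size)
    return index.summarize(probe_sequence, offsets)


def exhaustive_hits(
    probe_sequence: str,
    offsets: Iterable[tuple[int, str]],
    pseudo: PseudoMolecule,
    word_size: int = 7,
) -> HitSummary:
    """All-offsets ungapped oracle: every diagonal with a run >= word_size.

    Independent of the seeded search path; intended for small genomes.
    """
    senc = encode(pseudo.sequence)
    penc = encode(probe_sequence)
    rc = penc[::-1].copy()
    rc[rc < 4] = 3 - rc[rc < 4]
    selfd = self_diagonals(pseudo, offsets)
    plen, slen = penc.size, senc.size
    best_m = best_r = 0
    n_hits = 0
    for orient, enc_p in ((0, penc), (1, rc)):
        for d in range(-(plen - 1), slen):
            i0 = max(0, -d)
            i1 = min(plen, slen - d)
            if i1 <= i0:
                continue
            eq = enc_p[i0:i1] == senc[d + i0 : d + i1]
            matches = int(eq.sum())
            run = 0
            cur = 0
            for v in eq:
                cur = cur + 1 if v else 0
                run = max(run, cur)
            if run < word_size:
                continue
            if matches == i1 - i0 and (orient, d) in selfd:
                continue
            n_hits += 1
            best_m = max(best_m, matches)
            best_r = max(best_r, run)
    return HitSummary(100.0 * best_m / plen, 100.0 * best_r / plen, n_hits)
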