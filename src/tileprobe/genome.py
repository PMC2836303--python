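"""Genome input and pseudo-molecule construction.

A tiling design treats all replicons of a genome (chromosomes and plasmids,
circular or linear) as a single search and enumeration substrate: the
*pseudo-molecule*.  Each circular replicon contributes its sequence plus its
first ``k_max - 1`` bases appended at the 3' end, so probes crossing the
origin are enumerable; replicons are separated by runs of ``N`` spacer
characters long enough that no all-ACGT window can span two replicons.

Coordinates are 1-based and inclusive on the forward genomic axis.  A
'-'-strand probe with start ``s`` and length ``k`` covers forward positions
``s .. s+k-1`` and its sequence is the reverse complement of that slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO

CIRCULAR = "circular"
LINEAR = "linear"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeMolecule:
    """One input replicon."""

    id: str
    sequence: str  # uppercase DNA, may contain IUPAC ambiguity codes
    topology: str = CIRCULAR

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"molecule {self.id!r} has empty sequence")
        if self.topology not in (CIRCULAR, LINEAR):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR


@dataclass(frozen=True)
class GenomicPosition:
    """1-based forward-axis start of a probe occurrence."""

    molecule_id: str
    start: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class Segment:
    """One replicon's slice of the pseudo-molecule (0-based offsets)."""

    molecule_id: str
    offset: int       # pseudo offset of molecule position 1
    length: int       # original replicon length L
    extension: int    # circular extension length (k_max - 1, or 0 if linear)

    @property
    def end(self) -> int:
        """One past the last pseudo offset belonging to this segment."""
        return self.offset + self.length + self.extension


@dataclass
class PseudoMolecule:
    sequence: str
    segments: list[Segment]
    k_max: int
    spacer_char: str = "N"
    spacer_len: int = 0
    molecules: dict[str, GenomeMolecule] = field(default_factory=dict)

    def segment_of(self, pseudo_offset: int) -> Segment:
        for seg in self.segments:
            if seg.offset <= pseudo_offset < seg.end:
                return seg
        raise ValueError(
            f"pseudo offset {pseudo_offset} falls in spacer or outside sequence"
        )

    def map_position(self, pseudo_offset: int, strand: str, probe_len: int) -> GenomicPosition:
        """Map a 0-based pseudo offset to a 1-based genomic start.

        Offsets inside a circular extension wrap back to positions
        ``1 .. k_max-1`` of their molecule.
        """
        seg = self.segment_of(pseudo_offset)
        local = pseudo_offset - seg.offset  # 0-based within segment
        start = (local % seg.length) + 1
        mol = self.molecules[seg.molecule_id]
        if not mol.is_circular and start > mol.length - probe_len + 1:
            raise ValueError(
                f"start {start} too close to the end of linear molecule {mol.id!r}"
            )
        return GenomicPosition(seg.molecule_id, start, strand)


def load_genome(
    fasta_source, topology_map: Mapping[str, str] | None = None,
    default_topology: str = CIRCULAR,
) -> list[GenomeMolecule]:
    """Read a (multi-)FASTA into :class:`GenomeMolecule` records.

    ``topology_map`` assigns ``circular``/``linear`` per record id; records
    not listed default to ``default_topology`` (circular, the common case for
    microbial replicons).  Sequences are uppercased and U is converted to T.
    """
    topology_map = topology_map or {}
    molecules: list[GenomeMolecule] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(fasta_source, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"record {rec.id!r} has zero-length sequence")
        topo = topology_map.get(rec.id, default_topology)
        molecules.append(GenomeMolecule(rec.id, seq, topo))
    if not molecules:
        raise ValueError("no FASTA records found")
    return molecules


def build_pseudomolecule(
    molecules: Iterable[GenomeMolecule], k_max: int,
    spacer_char: str = "N", spacer_len: int | None = None,
) -> PseudoMolecule:
    """Concatenate replicons with spacers and circular extensions.

    Each circular molecule contributes its sequence plus its first
    ``k_max - 1`` bases.  The spacer is ``k_max`` copies of a non-ACGT
    character by default, so no enumerable (all-ACGT) window spans two
    molecules.  Requires every molecule length >= k_max so a wrapped start in
    the extension region cannot duplicate an already-enumerated start.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if spacer_len is None:
        spacer_len = k_max
    molecules = list(molecules)
    if not molecules:
        raise ValueError("no molecules given")
    parts: list[str] = []
    segments: list[Segment] = []
    offset = 0
    for i, mol in enumerate(molecules):
        if mol.length < k_max:
            raise ValueError(
                f"molecule {mol.id!r} shorter than max probe length "
                f"({mol.length} < {k_max})"
            )
        if i > 0:
            parts.append(spacer_char * spacer_len)
            offset += spacer_len
        ext = k_max - 1 if mol.is_circular else 0
        parts.append(mol.sequence + mol.sequence[:ext])
        segments.append(Segment(mol.id, offset, mol.length, ext))
        offset += mol.length + ext
    return PseudoMolecule(
        sequence="".join(parts),
        segments=segments,
        k_max=k_max,
        spacer_char=spacer_char,
        spacer_len=spacer_len,
        molecules={m.id: m for m in molecules},
    )


def extract(mol: GenomeMolecule, start: int, length: int, strand: str) -> str:
    """Sequence of a probe occurrence from genomic coordinates (wrap-aware)."""
    if mol.is_circular:
        doubled = mol.sequence + mol.sequence[: length - 1]
        s = doubled[start - 1 : start - 1 + length]
    else:
        s = mol.sequence[start - 1 : start - 1 + length]
    if len(s) != length:
        raise ValueError("occurrence extends past the end of a linear molecule")
    return reverse_complement(s) if strand == "-" else s
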