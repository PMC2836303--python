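"""Seeded synthetic microbial genomes for exercising every pipeline stage.

The generator emulates the genome features the probe designer must handle:
i.i.d. background sequence at a chosen GC fraction (Tm spread), planted
exact or mutated repeats (multi-locus probes, window skipping, graded
PI/IS), low-complexity tracts, ambiguity sites (window omission) and
circular topology (origin-wrapping probes).  Output is deterministic for a
fixed seed; a YAML manifest records the ground truth (repeat coordinates
and copies) so tests can assert multi-position candidates directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genome import CIRCULAR, GenomeMolecule, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepeatSpec:
    unit_length: int
    copies: int
    strands: str = ""        # e.g. "++-"; defaults to all '+'
    mutation_rate: float = 0.0
    molecule: int = 0

    def strand_pattern(self) -> str:
        return self.strands or "+" * self.copies


@dataclass(frozen=True)
class LowComplexitySpec:
    period: int
    span: int
    molecule: int = 0


@dataclass
class SynthSpec:
    lengths: list[int]
    topologies: list[str] = field(default_factory=list)   # default all circular
    gc: list[float] = field(default_factory=list)         # default all 0.5
    repeats: list[RepeatSpec] = field(default_factory=list)
    low_complexity: list[LowComplexitySpec] = field(default_factory=list)
    ambiguity_sites: list[tuple[int, int]] = field(default_factory=list)  # (mol, 1-based pos)
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.lengths)
        if not self.topologies:
            self.topologies = [CIRCULAR] * n
        if not self.gc:
            self.gc = [0.5] * n
        if not (len(self.topologies) == len(self.gc) == n):
            raise ValueError("lengths, topologies and gc must align")
        for r in self.repeats:
            if r.unit_length * r.copies > self.lengths[r.molecule]:
                raise ValueError("repeat copies do not fit inside their molecule")
            if len(r.strand_pattern()) != r.copies:
                raise ValueError("strand pattern length must equal copy number")


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at, gcw = (1.0 - gc) / 2.0, gc / 2.0
    idx = rng.choice(4, size=length, p=[at, gcw, gcw, at])
    return _BASES[idx]


def _place(rng, length: int, span: int, taken: list[tuple[int, int]]) -> int:
    """Deterministic rejection sampling of a non-overlapping 0-based start."""
    for _ in range(10_000):
        s = int(rng.integers(0, length - span + 1))
        if all(s + span <= a or s >= b for a, b in taken):
            taken.append((s, s + span))
            return s
    raise ValueError("could not place feature without overlap (spec too dense)")


def generate(
    spec: SynthSpec,
    fasta_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
) -> tuple[list[GenomeMolecule], dict]:
    """Build the genome set; optionally write FASTA and the YAML manifest."""
    rng = np.random.default_rng(spec.seed)
    arrays = [
        _background(rng, L, gc) for L, gc in zip(spec.lengths, spec.gc)
    ]
    taken: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(arrays))}
    manifest: dict = {
        "seed": spec.seed,
        "molecules": [
            {"id": f"mol{i + 1}", "length": L, "topology": t, "gc": g}
            for i, (L, t, g) in enumerate(zip(spec.lengths, spec.topologies, spec.gc))
        ],
        "repeats": [],
        "low_complexity": [],
        "ambiguity_sites": [[m, p] for m, p in spec.ambiguity_sites],
    }
    for r in spec.repeats:
        arr = arrays[r.molecule]
        unit = _background(rng, r.unit_length, spec.gc[r.molecule])
        entry = {"molecule": r.molecule, "unit_length": r.unit_length, "copies": []}
        for strand in r.strand_pattern():
            s = _place(rng, len(arr), r.unit_length, taken[r.molecule])
            copy = unit.copy()
            if strand == "-":
                copy = np.array(list(reverse_complement("".join(unit))))
            if r.mutation_rate > 0:
                hits = rng.random(r.unit_length) < r.mutation_rate
                for i in np.flatnonzero(hits):
                    copy[i] = rng.choice([b for b in "ACGT" if b != copy[i]])
            arr[s : s + r.unit_length] = copy
            entry["copies"].append({"start": s + 1, "strand": strand})
        manifest["repeats"].append(entry)
    for lc in spec.low_complexity:
        arr = arrays[lc.molecule]
        unit = _background(rng, lc.period, spec.gc[lc.molecule])
        tract = np.tile(unit, lc.span // lc.period + 1)[: lc.span]
        s = _place(rng, len(arr), lc.span, taken[lc.molecule])
        arr[s : s + lc.span] = tract
        manifest["low_complexity"].append(
            {"molecule": lc.molecule, "start": s + 1, "period": lc.period, "span": lc.span}
        )
    for m, pos in spec.ambiguity_sites:
        arrays[m][pos - 1] = "N"

    molecules = [
        GenomeMolecule(f"mol{i + 1}", "".join(arr), topo)
        for i, (arr, topo) in enumerate(zip(arrays, spec.topologies))
    ]
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for mol in molecules:
                fh.write(f">{mol.id}\n")
                for i in range(0, mol.length, 70):
                    fh.write(mol.sequence[i : i + 70] + "\n")
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return molecules, manifest
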