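# tileprobe

Design **exact-count genomic tiling probe sets** for microbial genomes on
maskless in-situ synthesized microarrays.

Given one or more replicons (circular chromosomes, plasmids, or linear
contigs) and a target probe count, `tileprobe` returns exactly that many
oligonucleotide probes, tiled across both strands with bounded spacing, each
annotated with melting temperature, synthesis cost, cross-hybridization
level, and self-annealing energy.

## The design problem

Tiling arrays interrogate a genome with probes laid out at (roughly) regular
intervals rather than one probe per gene. On maskless synthesis platforms
the array capacity is a hard number of features, so the design task is to
pick **exactly MS probes** for a genome of **GS bases** while keeping the
probes well behaved:

1. **Pseudo-molecule.** All replicons are concatenated into one working
   sequence. Circular replicons are extended with a copy of their first
   `max_len − 1` bases so origin-spanning windows exist; replicons are
   separated by `N` spacers so no window straddles two molecules.
2. **Enumeration and isothermal trimming.** Every `max_len`-mer on both
   strands is enumerated (windows containing non-ACGT bases are skipped).
   Each probe is first trimmed from the 3' end until it fits the synthesis
   cycle budget (cycle count is simulated against the instrument's cyclic
   flow order), then further 3'-trimmed, down to `min_len`, to the length
   whose salt-adjusted melting temperature is closest to the genome-wide
   median Tm — an approximately isothermal probe set. Identical final
   sequences are merged into one candidate carrying all of its genomic
   positions.
3. **Cross-hybridization screen.** Each candidate is aligned against the
   whole pseudo-molecule (both orientations) with a seeded word search that
   provably reproduces an exhaustive per-diagonal scan. The best non-self
   alignment is summarized as percent identity (PI) and longest identical
   stretch (IS, as % of probe length) and mapped to four risk levels:
   level 1 (PI < 50, IS < 30) through level 4 (PI ≥ 90 or IS ≥ 40).
4. **Self-annealing screen.** A nearest-neighbor minimum-free-energy fold
   (hairpins, bulges, internal loops, multiloops) ranks each probe's
   tendency to fold on itself.
5. **Sequential selection.** A window size `WS = floor(2·GS/MS)` tiles each
   strand; the best probe per window is chosen by (cross-hyb level, |Tm −
   median|, MFE, IS, PI, length, position). Windows containing an already
   selected repeat occurrence are skipped; every selection occupies *all*
   its genomic positions and enforces a minimum probe-to-probe distance of
   `ceil(WS/4)`. If a pass overshoots MS, WS is increased by one and the
   pass repeats.
6. **Gap filling.** Remaining capacity is spent on the largest start-to-start
   gaps (largest first, ties broken by probe quality) until the selection
   holds exactly MS probes.

The default probe geometry is 45–50 nt with a 180-cycle synthesis budget and
Tm computed at 1 M Na⁺.

## Worked example

Generate a deterministic 20 kb circular test genome with planted repeats
(three exact 1.2 kb copies, two 300 bp copies at 2% divergence), then design
exactly 2000 probes:

```
$ tileprobe synth --length 20000 --repeat 1200x3 --repeat 300x2@0.02 \
      --seed 42 --out genome.fasta --manifest genome.manifest.yaml
wrote genome.fasta and genome.manifest.yaml

$ tileprobe design --fasta genome.fasta --probes 2000 --out-prefix design/mygenome
designed 2000 probes (window 20, min distance 5; starts +:1160 -:1147)

$ tileprobe summarize design/mygenome.summary.yaml | head -8
2000 probes, window 20, min distance 5
starts  +:1160  -:1147
gap size histogram:
       5  166
       6  73
       7  89
       8  81
       9  67
```

Note the start counts: 1160 + 1147 = 2307 strand starts for 2000 probes —
the planted repeats yield multi-position probes, so fewer synthesized
features cover more genomic loci. The smallest start-to-start gap equals the
enforced minimum distance (`ceil(20/4) = 5`).

Four files are written:

```
$ head -3 design/mygenome.probes.tsv | cut -c1-160
probe_id  sequence  length  tm  tm_dev  cycles  xhyb_level  pi  is_pct  mfe  n_positions  positions
P0000001  CCTGTCAGATGTCTTTACGTAAGCGGTACTCGAACCGGTTAATCCAGCAG  50  88.5000  0.0000  130  4  74.0000  66.0000  -1.4500  1  mol1:10:+
P0000002  CTGCTGGATTAACCGGTTCGAGTACCGCTTACGTAAAGACATCTGACAGG  50  88.5000  0.0000  130  4  74.0000  66.0000  -1.4500  1  mol1:10:-

$ head -4 design/mygenome.probes.bed
mol1	9	59	P0000001	4	+
mol1	9	59	P0000002	4	-
mol1	26	71	P0000003	2	+
mol1	2072	2117	P0000003	2	+
```

`*.probes.tsv` is the full annotated probe table (1-based genomic starts,
`;`-separated for multi-locus probes), `*.probes.bed` gives 0-based
half-open coordinates with the cross-hyb level in the score column
(origin-wrapping occurrences are split into two BED lines), `*.probes.fasta`
holds the sequences, and `*.summary.yaml` the design summary.

The same pipeline is available as a library:

```python
from tileprobe import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(probes=2000, fasta="genome.fasta"))
print(result.plan.window_size, len(result.state.selected))
```

## Reproduction

Everything is deterministic: the synthetic-genome generator is seeded and
the design pipeline contains no randomness, so repeated runs are
byte-identical.

```
pip install --no-build-isolation -e .[test]
pytest                                   # full unit + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script prints the package-computed default minimum probe
distances at the three reference window sizes:

```
{"t3": {"value": 3, "n": 12}, "t4": {"value": 4, "n": 16}, "t5": {"value": 2, "n": 5}}
```

## Layout

| Module | Role |
| --- | --- |
| `tileprobe.genome` | FASTA input, pseudo-molecule construction, coordinate mapping |
| `tileprobe.enumeration` | both-strand window enumeration, final-coordinate bookkeeping, deduplication |
| `tileprobe.thermo` | synthesis-cycle simulation, salt-adjusted Tm, isothermal length adjustment |
| `tileprobe.crosshyb` | seeded whole-genome similarity search, PI/IS, four-level classification |
| `tileprobe.folding` | nearest-neighbor MFE folding (with an exhaustive oracle for testing) |
| `tileprobe.selection` | window planning, sequential selection, largest-gap filling |
| `tileprobe.report` | probe table / BED / FASTA / summary writers |
| `tileprobe.synth` | seeded synthetic genomes with ground-truth manifests |
| `tileprobe.cli` | `tileprobe design / synth / summarize` |

See `docs/methods.md` for the precise formulas, tie-breaking rules, and the
self-hit definition used by the cross-hybridization screen.
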