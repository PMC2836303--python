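# Methods

Precise definitions for every quantity the pipeline computes. Coordinates
are 1-based on the forward strand of each input replicon unless stated
otherwise; a probe's *start* is the smallest forward-strand coordinate it
covers, for both `+` and `-` strand probes.

## 1. Pseudo-molecule

Replicons are concatenated in input order into a single working string.

- A **circular** replicon of length `L` contributes its sequence followed by
  a copy of its first `k_max − 1` bases (`k_max` = maximum probe length), so
  every origin-spanning window of length ≤ `k_max` appears literally.
- Consecutive replicons are separated by a spacer of `k_max` `N` characters,
  which no valid window can span.
- Local pseudo-molecule offsets map back to `(molecule, start, strand)`;
  positions inside the circular extension wrap modulo `L`.

Input sequences are uppercased and `U` is normalized to `T`. A replicon
shorter than `k_max` is an error.

## 2. Enumeration and length adjustment

For every segment, each window of length `k_max` whose bases are all in
`{A,C,G,T}` yields two raw probes: the window itself (`+`) and its reverse
complement (`-`), both anchored at the same start. A circular replicon has
exactly `L` starts per strand; a linear one `L − k_max + 1`.

Each distinct raw sequence is then trimmed from the 3' end, twice:

1. **Cycle budget.** Synthesis is simulated base by base against the cyclic
   flow order (default `ACGT`). The deposition order is the reverse of the
   probe sequence (3'→5' synthesis). Each deposited base consumes flows
   until its own flow comes up; the cycle count is the total number of
   flows. Bases are removed from the probe 3' end until the count is ≤
   `max_cycles` (default 180) or the probe reaches `min_len`; if the budget
   still cannot be met the probe is flagged rejected and excluded from
   selection.
2. **Isothermal trimming.** The genome-wide **median Tm** is computed over
   all enumerated occurrences (each raw sequence weighted by its occurrence
   count) after cycle trimming. Each probe is then truncated to the length
   `ℓ ∈ [min_len, len]` whose Tm is closest to the median; ties prefer the
   longer probe.

Melting temperature (salt-adjusted, GC-based):

```
Tm = 81.5 + 16.6·log10[Na+] + 0.41·GC%          − 13.5        if N ≤ 50
Tm = 81.5 + 16.6·log10[Na+] + 0.41·GC% − 0.65·F − 675/N       if N > 50
```

with `N` the probe length, `GC%` in percent, `F` the formamide percentage,
and the constant `−13.5 = −675/50` making the two branches continuous at
`N = 50`. Defaults: `[Na+] = 1.0 M`, `F = 0`. All coefficients are
configurable in `ThermoParams`. Probes shorter than 8 nt are rejected.

Because trimming is 3'-only, a `-` strand probe's final start shifts to
`start + (k_max − ℓ)`; a `+` probe keeps its start. Probes with identical
**final** sequences are merged into one candidate listing every position.

## 3. Cross-hybridization

Each candidate is compared against the entire pseudo-molecule in both
orientations (probe vs. forward text, and probe vs. reverse-complemented
text).

- A word index (default word size `w = 7`) over the pseudo-molecule supplies
  the set of diagonals on which at least one exact `w`-mer of the probe
  matches. Seeding only *gates* diagonals: on each seeded diagonal the full
  probe/text overlap is scored, so the result equals an exhaustive
  per-diagonal scan restricted to diagonals that contain at least one
  `w`-mer match (diagonals without one cannot contain an identical stretch
  ≥ `w` and score PI below any actionable threshold).
- For each diagonal: **PI** = matches / probe length × 100, **IS** = longest
  run of consecutive matches / probe length × 100. The reported summary is
  the maximum over all non-self diagonals (PI and IS maximized jointly via
  level ordering, then PI, then IS).
- **Self hits.** A diagonal is *self* iff it aligns the probe exactly
  (full-overlap identity) **and** its (orientation, offset) corresponds to
  one of the candidate's own recorded genomic occurrences, including the
  `±L` images created by the circular-extension copy of each occurrence.
  An exact alignment elsewhere (an unrecorded repeat copy) therefore counts
  as cross-hybridization at PI = 100.

Levels combine a PI band and an IS band, worst wins:

| band | PI | IS |
| --- | --- | --- |
| 1 | < 50 | < 30 |
| 2 | 50–74.99 | — |
| 3 | 75–89.99 | 30–39.99 |
| 4 | ≥ 90 | ≥ 40 |

i.e. `level = max(level_PI, level_IS)` with `level_IS ∈ {1, 3, 4}`. Bounds
are configurable (`LevelLimits`).

## 4. Self-annealing (folding)

Minimum free energy of intramolecular folding at 37 °C, used **only to rank
probes** (less negative = better):

- Watson–Crick pairs only; unified DNA nearest-neighbor stack energies
  (16-entry table read off top-strand dinucleotide steps).
- Tabulated hairpin (≥ 3 unpaired), bulge, and internal-loop penalties with
  Jacobson–Stockmayer extrapolation (`ΔG(n) = ΔG(n₀) + 1.75·R·T·ln(n/n₀)`)
  beyond the table; loops larger than 30 are capped at the extrapolated
  value of 30.
- Single-base bulges retain the closing stack term.
- Affine multiloop model `a + b·(branches incl. closing) + c·unpaired` with
  `a = 3.4, b = 0.4, c = 0` kcal/mol.
- Standard O(n³) Zuker-style recursions (`V`, `WM`, exterior `W`), exterior
  energy capped at 0 (the unfolded state).

An independent oracle (exhaustive structure enumeration + loop-decomposition
scoring over the same tables) verifies the DP exactly for sequences ≤ 16 nt.

## 5. Sequential window selection

- Window size `WS = floor(2·GS / MS)` (`GS` = total genome length, `MS` =
  requested probe count; both strands are tiled, hence the factor 2). An
  error is raised if `MS > 2·GS`.
- Minimum probe-to-probe distance (per molecule and strand, start-to-start,
  circular-aware): `ceil(WS/4)` unless overridden.
- Each strand of each molecule is scanned in windows `[1, WS], [WS+1, 2·WS],
  …`. A window containing an occurrence of an already selected probe is
  skipped. Otherwise the best admissible candidate *starting* in the window
  is selected and **all** of its occurrences become occupied.
- Within-window comparator (lexicographic, smaller wins): cross-hyb level,
  `|Tm − median|`, `−MFE`, IS, PI, `−length`, traversal position.
- If the pass selects more than `MS` probes, `WS` is increased by one and
  the pass restarts from scratch, repeating until the count fits.

## 6. Gap filling

After the sequential pass, the selection is completed to exactly `MS`:

- Gaps are start-to-start intervals per (molecule, strand), including the
  circular wrap gap; linear molecule ends are treated as open intervals so
  they remain fillable.
- A priority queue orders gaps by size (largest first), then by the quality
  of the gap's best admissible probe (IS, PI, `|Tm − median|`, `−MFE`,
  `−length`, position).
- Popped entries are revalidated: if another selection landed inside the
  gap (a repeat occurrence), the gap is split and re-queued; stale
  best-probe entries are re-queued at their fresh priority before they can
  win. Filling preserves the minimum-distance constraint.
- If every gap is exhausted before reaching `MS`, the run reports a
  shortfall (exit failure under `--strict`).

## 7. Reporting

- Probe IDs `P0000001…` are assigned in genomic order of each probe's first
  occurrence (molecule input order, start, `+` before `-`).
- The summary's gap histogram counts start-to-start distances per strand;
  on a circular strand with `k` starts there are exactly `k` gaps
  (including the wrap gap). Open linear end intervals are not gaps.
- BED output is 0-based half-open; origin-wrapping occurrences are split at
  the origin into two lines sharing the probe ID.

## 8. Determinism

The design pipeline contains no random choices; all ties are broken by
explicit lexicographic keys ending in genomic position. The synthetic
genome generator draws exclusively from one seeded NumPy generator.
Repeated runs are byte-identical.
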