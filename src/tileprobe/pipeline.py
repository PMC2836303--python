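"""End-to-end orchestration of the six-stage probe design.

1. Build the pseudo-molecule (circular extensions + spacers).
2. Enumerate every probe of the maximum length on both strands; trim each
   for the synthesis-cycle budget and toward the genome-wide median Tm;
   merge identical final sequences into non-redundant candidates.
3. Score cross-hybridization (PI/IS, four levels) for every candidate.
4. Score self-annealing (folding MFE) for every candidate.
5. Sequential window selection (with the window-size retry rule).
6. Largest-gap filling to the exact requested probe count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import report
from .crosshyb import LevelLimits, PseudoIndex, assign_level
from .enumeration import (FinalOccurrence, ProbeCandidate, deduplicate,
                          enumerate_probes, finalize_occurrence)
from .folding import FoldParams, mfe_fold
from .genome import GenomeMolecule, PseudoMolecule, build_pseudomolecule, load_genome
from .selection import DesignPlan, SelectionState, gap_fill, run_sequential
from .thermo import (ThermoParams, adjust_length_to_median, median_tm,
                     shorten_for_cycles, synthesis_cycles, tm)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    probes: int
    fasta: str | Path | None = None
    molecules: list[GenomeMolecule] | None = None
    topology: dict[str, str] = field(default_factory=dict)
    thermo: ThermoParams = field(default_factory=ThermoParams)
    fold: FoldParams = field(default_factory=FoldParams)
    limits: LevelLimits = field(default_factory=LevelLimits)
    word_size: int = 7
    window_size: int | None = None
    min_distance: int | None = None
    out_prefix: str | Path | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        if self.probes < 1:
            raise ValueError("probes must be >= 1")
        if (self.fasta is None) == (self.molecules is None):
            raise ValueError("provide exactly one of fasta or molecules")
        if self.window_size is not None and self.min_distance is not None:
            if self.min_distance > self.window_size:
                raise ValueError("min_distance must not exceed window_size")


@dataclass
class PipelineResult:
    molecules: list[GenomeMolecule]
    pseudo: PseudoMolecule
    candidates: list[ProbeCandidate]
    median_tm: float
    state: SelectionState
    plan: DesignPlan
    summary: report.DesignSummary
    shortfall: bool
    outputs: dict[str, Path] = field(default_factory=dict)


class ShortfallError(RuntimeError):
    """Raised in strict mode when the exact probe count cannot be reached."""


def build_candidates(
    pseudo: PseudoMolecule, params: ThermoParams, molecule_order: list[str]
) -> tuple[list[ProbeCandidate], float]:
    """Stages 1-2: enumerate, length-adjust, and deduplicate."""
    groups: dict[str, list] = {}
    for raw in enumerate_probes(pseudo):
        groups.setdefault(raw.raw, []).append(raw)
    logger.info(
        "enumerated %d occurrences (%d distinct raw sequences)",
        sum(len(v) for v in groups.values()), len(groups),
    )

    # cycle trimming, then the genome-wide median Tm over all occurrences
    cycle_adjusted: dict[str, tuple[str, bool]] = {}
    tms: list[float] = []
    weights: list[int] = []
    for raw_seq, occ in groups.items():
        seq_c, _, rejected = shorten_for_cycles(raw_seq, params)
        cycle_adjusted[raw_seq] = (seq_c, rejected)
        tms.append(tm(seq_c, params))
        weights.append(len(occ))
    median = median_tm(np.repeat(tms, weights))
    logger.info("median Tm %.3f C", median)

    # isothermal trimming and final-coordinate bookkeeping
    final_metrics: dict[str, tuple[int, float, float, bool]] = {}
    occurrences: list[FinalOccurrence] = []
    for raw_seq, occ in groups.items():
        seq_c, rejected = cycle_adjusted[raw_seq]
        final_seq, t, dev = adjust_length_to_median(seq_c, median, params)
        if final_seq not in final_metrics:
            cycles = synthesis_cycles(
                final_seq, params.flow_order, params.synthesis_direction
            )
            # cycle counts only drop under 3'-truncation, so the final text
            # alone determines feasibility
            final_metrics[final_seq] = (cycles, t, dev, cycles > params.max_cycles)
        for rp in occ:
            occurrences.append(finalize_occurrence(pseudo, rp, len(final_seq)))
    candidates = deduplicate(occurrences, molecule_order)
    for cand in candidates:
        cycles, t, dev, rejected = final_metrics[cand.sequence]
        cand.cycles, cand.tm, cand.tm_dev, cand.rejected = cycles, t, dev, rejected
    logger.info("%d non-redundant candidates after length adjustment", len(candidates))
    return candidates, median


def score_candidates(
    candidates: list[ProbeCandidate],
    pseudo: PseudoMolecule,
    limits: LevelLimits,
    fold_params: FoldParams,
    word_size: int = 7,
) -> None:
    """Stages 3-4: cross-hybridization tiers and folding MFE, in place."""
    index = PseudoIndex(pseudo, word_size)
    for cand in candidates:
        hits = index.summarize(cand.sequence, cand.offsets)
        cand.pi, cand.is_pct = hits.pi, hits.is_pct
        cand.xhyb_level = assign_level(hits.pi, hits.is_pct, limits)
        cand.mfe = mfe_fold(cand.sequence, fold_params)
    levels = [0] * 5
    for c in candidates:
        levels[c.xhyb_level] += 1
    logger.info(
        "cross-hyb levels: 1:%d 2:%d 3:%d 4:%d", *levels[1:]
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    if config.molecules is not None:
        molecules = config.molecules
    else:
        molecules = load_genome(str(config.fasta), config.topology)
    gs = sum(m.length for m in molecules)
    logger.info("genome: %d molecule(s), %d bases combined", len(molecules), gs)

    pseudo = build_pseudomolecule(molecules, config.thermo.max_len)
    candidates, median = build_candidates(
        pseudo, config.thermo, [m.id for m in molecules]
    )
    score_candidates(candidates, pseudo, config.limits, config.fold, config.word_size)

    state = SelectionState(candidates, molecules)
    plan = run_sequential(
        state, gs, config.probes, config.window_size, config.min_distance
    )
    complete = gap_fill(state, plan, config.probes)
    logger.info("final selection: %d probes", len(state.selected))
    if not complete and config.strict:
        raise ShortfallError(
            f"only {len(state.selected)} of {config.probes} probes could be placed"
        )

    summary = report.summarize(state, plan)
    outputs: dict[str, Path] = {}
    if config.out_prefix is not None:
        prefix = Path(config.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        outputs["table"] = Path(f"{prefix}.probes.tsv")
        outputs["bed"] = Path(f"{prefix}.probes.bed")
        outputs["fasta"] = Path(f"{prefix}.probes.fasta")
        outputs["summary"] = Path(f"{prefix}.summary.yaml")
        report.write_probe_table(state, outputs["table"])
        report.write_bed(state, outputs["bed"])
        report.write_fasta(state, outputs["fasta"])
        report.write_summary(summary, outputs["summary"])

    return PipelineResult(
        molecules=molecules,
        pseudo=pseudo,
        candidates=candidates,
        median_tm=median,
        state=state,
        plan=plan,
        summary=summary,
        shortfall=not complete,
        outputs=outputs,
    )
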