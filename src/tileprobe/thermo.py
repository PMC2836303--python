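"""Synthesis-cycle accounting and salt-adjusted melting temperature.

Maskless array synthesis couples one base per reagent *flow*; flows cycle
through a fixed base order, so a probe's cycle count is the number of flows
until its last base couples.  Probes exceeding the synthesizer's cycle
budget are trimmed from the 3' end.

Melting temperatures use the classic salt-adjusted empirical form

    Tm = 81.5 + 16.6 log10[Na+] + 0.41 (%GC) - 675/N        (N <= 50)
    Tm = 81.5 + 16.6 log10[Na+] + 0.41 (%GC) - 675/N - 0.65 F   (N > 50)

with N the probe length, %GC the G+C percentage, [Na+] the monovalent salt
molarity and F the formamide percentage (applied on the long-probe branch
only).  All coefficients are parameters so an alternative dialect of the
formula can be configured without code changes.  Isothermality is
approached by trimming each probe toward the genome-wide median Tm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DIRECTION_3TO5 = "3to5"
DIRECTION_5TO3 = "5to3"


@dataclass(frozen=True)
class ThermoParams:
    na_molar: float = 1.0
    formamide_pct: float = 0.0
    max_cycles: int = 180
    max_len: int = 50
    min_len: int = 45
    flow_order: str = "ACGT"
    synthesis_direction: str = DIRECTION_3TO5
    long_probe_threshold: int = 50
    # Tm = base + salt_coef*log10(Na) + gc_coef*GC% - length_coef/N [- formamide_coef*F]
    tm_base: float = 81.5
    tm_salt_coef: float = 16.6
    tm_gc_coef: float = 0.41
    tm_length_coef: float = 675.0
    tm_formamide_coef: float = 0.65

    def __post_init__(self) -> None:
        if self.na_molar <= 0:
            raise ValueError("na_molar must be positive")
        if not 0 <= self.formamide_pct <= 100:
            raise ValueError("formamide_pct must be in [0, 100]")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if sorted(self.flow_order) != ["A", "C", "G", "T"]:
            raise ValueError("flow_order must be a permutation of ACGT")


def synthesis_cycles(
    sequence: str, flow_order: str = "ACGT", direction: str = DIRECTION_3TO5
) -> int:
    """Reagent flows consumed until the probe's last base couples.

    Bases couple in synthesis order (3'->5' by default, i.e. the sequence
    reversed); each flow offers the next base of the cyclic ``flow_order``
    and a base couples when its flow arrives.
    """
    if not sequence:
        return 0
    deposit = sequence[::-1] if direction == DIRECTION_3TO5 else sequence
    flows = 0
    i = 0
    for b in deposit:
        while True:
            flow = flow_order[i % 4]
            i += 1
            flows += 1
            if flow == b:
                break
    return flows


def shorten_for_cycles(sequence: str, params: ThermoParams) -> tuple[str, int, bool]:
    """Trim from the 3' end until the cycle count fits the budget.

    Returns ``(sequence, cycles, rejected)``; ``rejected`` is True when even
    the minimum-length prefix exceeds ``max_cycles`` (a status, not an
    error: such candidates are carried but never selected).
    """
    seq = sequence
    while True:
        c = synthesis_cycles(seq, params.flow_order, params.synthesis_direction)
        if c <= params.max_cycles:
            return seq, c, False
        if len(seq) <= params.min_len:
            return seq, c, True
        seq = seq[:-1]


def _tm_from_counts(n: int, gc: int, params: ThermoParams) -> float:
    t = (
        params.tm_base
        + params.tm_salt_coef * math.log10(params.na_molar)
        + params.tm_gc_coef * (100.0 * gc / n)
        - params.tm_length_coef / n
    )
    if n > params.long_probe_threshold:
        t -= params.tm_formamide_coef * params.formamide_pct
    return t


def tm(sequence: str, params: ThermoParams) -> float:
    """Salt-adjusted melting temperature in deg C (valid for length >= 8)."""
    n = len(sequence)
    if n < 8:
        raise ValueError("salt-adjusted Tm formula is invalid below 8 nt")
    gc = sequence.count("G") + sequence.count("C")
    return _tm_from_counts(n, gc, params)


def median_tm(tms) -> float:
    """Standard median (mean of middle two for even counts)."""
    arr = np.asarray(list(tms), dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty Tm collection")
    return float(np.median(arr))


def adjust_length_to_median(
    sequence: str, median: float, params: ThermoParams
) -> tuple[str, float, float]:
    """3'-trim to the length whose Tm is closest to the median.

    Evaluates every truncation from the current length down to ``min_len``
    and returns ``(sequence, tm, |tm - median|)`` for the best one; ties go
    to the longer sequence.
    """
    n = len(sequence)
    lo = min(params.min_len, n)
    gc_prefix = 0
    gc_at = [0] * (n + 1)
    for i, b in enumerate(sequence, 1):
        if b in "GC":
            gc_prefix += 1
        gc_at[i] = gc_prefix
    best_len, best_tm, best_dev = None, 0.0, math.inf
    for length in range(n, lo - 1, -1):
        t = _tm_from_counts(length, gc_at[length], params)
        dev = abs(t - median)
        if dev < best_dev:  # strict: ties keep the longer (earlier) length
            best_len, best_tm, best_dev = length, t, dev
    return sequence[:best_len], best_tm, best_dev
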