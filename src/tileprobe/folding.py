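"""Probe self-annealing as DNA secondary-structure minimum free energy.

A probe that folds on itself competes with probe-target hybridization, so
each candidate is scored by the minimum free energy (MFE) over all its
pseudoknot-free secondary structures: Watson-Crick pairs only (DNA, no GU),
unified nearest-neighbor stack energies, tabulated hairpin/bulge/internal
loop penalties with Jacobson-Stockmayer extrapolation, and an affine
multiloop term.  The unfolded chain has energy zero, so MFE <= 0 always;
a *less negative* MFE marks a better probe.  Selection consumes the value
only as a ranking key.

`brute_force_mfe` enumerates every admissible structure of a short sequence
and scores it by explicit loop decomposition; it exists as an independent
oracle for the dynamic program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from numba import njit

_INF = 1e30
_GAS_R = 0.0019872  # kcal/(mol*K)
_MAXLOOP = 30       # cap on bulge/internal total loop size in the DP
_TAB_LEN = 1024     # loop-size tables are pre-extrapolated to this length

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class FoldParams:
    temperature_c: float = 37.0
    min_hairpin_loop: int = 3
    energy_model: str = "dna_nn_unified"

    def __post_init__(self) -> None:
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")


@lru_cache(maxsize=4)
def _load_tables(energy_model: str, temperature_c: float):
    """Parse the parameter file into numba-friendly arrays."""
    text = (
        resources.files("tileprobe.data").joinpath(f"{energy_model}.txt").read_text()
    )
    stack = np.full((4, 4), _INF)
    hp_tab: dict[int, float] = {}
    bu_tab: dict[int, float] = {}
    in_tab: dict[int, float] = {}
    ml = (3.4, 0.4, 0.0)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "stack":
            a, b = parts[1]
            stack[_ENC[a], _ENC[b]] = float(parts[2])
        elif parts[0] == "hairpin":
            hp_tab[int(parts[1])] = float(parts[2])
        elif parts[0] == "bulge":
            bu_tab[int(parts[1])] = float(parts[2])
        elif parts[0] == "internal":
            in_tab[int(parts[1])] = float(parts[2])
        elif parts[0] == "multiloop":
            ml = (float(parts[1]), float(parts[2]), float(parts[3]))

    js = 1.75 * _GAS_R * (273.15 + temperature_c)

    def expand(tab: dict[int, float]) -> np.ndarray:
        arr = np.full(_TAB_LEN, _INF)
        top = max(tab)
        for k, v in tab.items():
            arr[k] = v
        for k in range(min(tab), _TAB_LEN):
            if arr[k] >= _INF / 2:
                arr[k] = tab[top] + js * math.log(k / top)
        return arr

    return stack, expand(hp_tab), expand(bu_tab), expand(in_tab), ml


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_ENC[b] for b in sequence], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"non-ACGT character {e.args[0]!r} in sequence") from None


@njit(cache=True)
def _mfe_dp(enc, stack, hairpin, bulge, internal, ml_a, ml_b, ml_c, min_hp, maxloop):
    n = enc.size
    V = np.full((n, n), _INF)
    WM = np.full((n, n), _INF)  # segment inside a multiloop, >= 1 branch
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            if span > min_hp and enc[i] + enc[j] == 3:
                best = hairpin[span - 1]
                for k in range(i + 1, j - 1):
                    n1 = k - i - 1
                    if n1 > maxloop:
                        break
                    lo = j - 1 - (maxloop - n1)
                    if lo < k + min_hp + 1:
                        lo = k + min_hp + 1
                    for l in range(lo, j):
                        if V[k, l] >= _INF / 2:
                            continue
                        n2 = j - l - 1
                        if n1 == 0 and n2 == 0:
                            e = stack[enc[i], enc[k]] + V[k, l]
                        elif n1 == 0 or n2 == 0:
                            size = n1 + n2
                            e = bulge[size] + V[k, l]
                            if size == 1:
                                e += stack[enc[i], enc[k]]
                        else:
                            e = internal[n1 + n2] + V[k, l]
                        if e < best:
                            best = e
                for m in range(i + 2, j - 1):
                    if WM[i + 1, m - 1] < _INF / 2 and WM[m, j - 1] < _INF / 2:
                        e = ml_a + ml_b + WM[i + 1, m - 1] + WM[m, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            wm = _INF
            if V[i, j] < _INF / 2:
                wm = V[i, j] + ml_b
            if WM[i + 1, j] < _INF / 2 and WM[i + 1, j] + ml_c < wm:
                wm = WM[i + 1, j] + ml_c
            if WM[i, j - 1] < _INF / 2 and WM[i, j - 1] + ml_c < wm:
                wm = WM[i, j - 1] + ml_c
            for m in range(i + 1, j + 1):
                if WM[i, m - 1] < _INF / 2 and WM[m, j] < _INF / 2:
                    e = WM[i, m - 1] + WM[m, j]
                    if e < wm:
                        wm = e
            WM[i, j] = wm
    # exterior loop: unpaired bases and branches are free
    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]
        for i in range(0, j - min_hp):
            if V[i, j] < _INF / 2:
                e = W[i] + V[i, j]
                if e < best:
                    best = e
        W[j + 1] = best
    return min(0.0, W[n])


def mfe_fold(sequence: str, params: FoldParams = FoldParams()) -> float:
    """Minimum free energy (kcal/mol, <= 0) of a probe's self-structure."""
    enc = _encode(sequence)
    if enc.size == 0:
        raise ValueError("empty sequence")
    stack, hp, bu, itab, (a, b, c) = _load_tables(
        params.energy_model, params.temperature_c
    )
    if enc.size < params.min_hairpin_loop + 4:
        return 0.0  # a hairpin is geometrically impossible
    return float(
        _mfe_dp(enc, stack, hp, bu, itab, a, b, c, params.min_hairpin_loop, _MAXLOOP)
    )


def structure_energy(
    sequence: str, pairs: tuple[tuple[int, int], ...], params: FoldParams = FoldParams()
) -> float:
    """Score one structure (0-based pair set) by explicit loop decomposition."""
    enc = _encode(sequence)
    stack, hp, bu, itab, (ml_a, ml_b, ml_c) = _load_tables(
        params.energy_model, params.temperature_c
    )
    n = enc.size
    partner = [-1] * n
    for i, j in pairs:
        partner[i], partner[j] = j, i

    def children_of(lo: int, hi: int) -> tuple[list[tuple[int, int]], int]:
        kids, unpaired, t = [], 0, lo
        while t <= hi:
            if partner[t] > t:
                kids.append((t, partner[t]))
                t = partner[t] + 1
            else:
                unpaired += 1
                t += 1
        return kids, unpaired

    total = 0.0
    stackq: list[tuple[int, int]] = []
    kids, _ = children_of(0, n - 1)  # exterior loop is free
    stackq.extend(kids)
    while stackq:
        i, j = stackq.pop()
        kids, unpaired = children_of(i + 1, j - 1)
        if not kids:
            total += hp[j - i - 1]
        elif len(kids) == 1:
            k, l = kids[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += stack[enc[i], enc[k]]
            elif n1 == 0 or n2 == 0:
                total += bu[n1 + n2]
                if n1 + n2 == 1:
                    total += stack[enc[i], enc[k]]
            else:
                total += itab[n1 + n2]
        else:
            total += ml_a + ml_b * (1 + len(kids)) + ml_c * unpaired
        stackq.extend(kids)
    return total


def _enumerate_structures(enc: np.ndarray, min_hp: int):
    """All pseudoknot-free WC pair sets (hairpin loops >= min_hp)."""
    memo: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def rec(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if j - i < min_hp + 1:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + min_hp + 1, j + 1):
            if enc[i] + enc[k] == 3:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        memo[key] = out
        return out

    return rec(0, enc.size - 1)


def brute_force_mfe(sequence: str, params: FoldParams = FoldParams()) -> float:
    """Exhaustive-structure MFE for short sequences (test oracle, n <= 16)."""
    if len(sequence) > 16:
        raise ValueError("brute-force enumeration limited to 16 nt")
    enc = _encode(sequence)
    best = 0.0
    for pairs in _enumerate_structures(enc, params.min_hairpin_loop):
        if pairs:
            best = min(best, structure_energy(sequence, pairs, params))
    return best
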