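"""Minimum-free-energy folding and ensemble computations.

The fold obeys three constraints: paired bases are at least three apart
(j - i > 3, no sharp U-turns), each base takes part in at most one pair,
and pairs never cross (no pseudoknots).  Energies are loop-additive, so the
MFE is computed with the classical nested dynamic programme over

* ``V(i, j)`` - best energy given (i, j) paired (hairpin, two-loop to an
  immediately interior pair, or multiloop closure),
* ``WM`` / ``WM2`` - multiloop segments with >= 1 / >= 2 branches,
* ``W(j)`` - best energy of the prefix, exterior bases free.

The module also provides exhaustive structure enumeration (the oracle route
for short sequences) and an unambiguous partition-function DP over the same
energy model for Boltzmann ensemble quantities on longer sequences.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Callable

from .loops import structure_energy
from .params import DEFAULT_MODEL, EnergyModel
from .sequences import RnaSequence, can_pair
from .structure import MIN_HAIRPIN_SEP, SecondaryStructure, structure_from_pairs

INF = float("inf")
_EPS = 1e-9


def _pairable(b: str, i: int, j: int, blocked: frozenset[int] = frozenset()) -> bool:
    if j - i <= MIN_HAIRPIN_SEP:
        return False
    if i in blocked or j in blocked:
        return False
    return can_pair(b[i - 1], b[j - 1])


def fold_mfe(
    seq: RnaSequence,
    model: EnergyModel = DEFAULT_MODEL,
    folder: Callable[[RnaSequence], SecondaryStructure] | None = None,
) -> SecondaryStructure:
    """Fold a sequence to its MFE structure under the embedded model.

    ``folder`` is a plug-in hook: when given, it is called instead of the
    embedded dynamic programme (e.g. to delegate to an external
    thermodynamic folder) and its result is returned unchanged.

    A sequence with no admissible pair returns the all-unpaired structure
    at energy 0.  Ties are broken by a fixed, documented traceback order,
    so the result is deterministic.
    """
    if folder is not None:
        return folder(seq)
    b = seq.bases
    n = len(b)
    V = [[INF] * (n + 1) for _ in range(n + 2)]
    WM = [[INF] * (n + 1) for _ in range(n + 2)]
    WM2 = [[INF] * (n + 1) for _ in range(n + 2)]

    # V and the multiloop segment tables interleave by ascending span:
    # V(i,j) consumes WM2 of the enclosed interval (span-2), WM consumes V
    # of the same cell and WM of strictly smaller spans.
    for span in range(0, n):
        for i in range(1, n - span + 1):
            j = i + span
            if span > MIN_HAIRPIN_SEP and _pairable(b, i, j):
                best = model.hairpin(j - i - 1)
                for k in range(i + 1, j):
                    for l in range(k + MIN_HAIRPIN_SEP + 1, j):
                        if V[k][l] < INF:
                            cand = model.two_loop(i, j, k, l) + V[k][l]
                            if cand < best:
                                best = cand
                if WM2[i + 1][j - 1] < INF:
                    cand = model.ml_close + WM2[i + 1][j - 1]
                    if cand < best:
                        best = cand
                V[i][j] = model.pair(b[i - 1], b[j - 1]) + best
            best = INF
            if j - 1 >= i and WM[i][j - 1] < INF:
                best = min(best, WM[i][j - 1] + model.ml_unpaired)
            if i + 1 <= j and WM[i + 1][j] < INF:
                best = min(best, WM[i + 1][j] + model.ml_unpaired)
            if V[i][j] < INF:
                best = min(best, V[i][j] + model.ml_branch)
            best2 = INF
            for k in range(i + 1, j + 1):
                if WM[i][k - 1] < INF and WM[k][j] < INF:
                    cand = WM[i][k - 1] + WM[k][j]
                    best = min(best, cand)
                    best2 = min(best2, cand)
            WM[i][j] = best
            WM2[i][j] = best2

    W = [0.0] * (n + 1)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(1, j):
            if V[i][j] < INF:
                best = min(best, W[i - 1] + V[i][j])
        W[j] = best

    pairs: list[tuple[int, int]] = []

    def trace_v(i: int, j: int) -> None:
        pairs.append((i, j))
        target = V[i][j] - model.pair(b[i - 1], b[j - 1])
        if abs(target - model.hairpin(j - i - 1)) < _EPS:
            return
        for k in range(i + 1, j):
            for l in range(k + MIN_HAIRPIN_SEP + 1, j):
                if V[k][l] < INF and abs(
                    target - (model.two_loop(i, j, k, l) + V[k][l])
                ) < _EPS:
                    trace_v(k, l)
                    return
        trace_wm2(i + 1, j - 1)

    def trace_wm(i: int, j: int) -> None:
        val = WM[i][j]
        if V[i][j] < INF and abs(val - (V[i][j] + model.ml_branch)) < _EPS:
            trace_v(i, j)
            return
        if i + 1 <= j and WM[i + 1][j] < INF and abs(val - (WM[i + 1][j] + model.ml_unpaired)) < _EPS:
            trace_wm(i + 1, j)
            return
        if j - 1 >= i and WM[i][j - 1] < INF and abs(val - (WM[i][j - 1] + model.ml_unpaired)) < _EPS:
            trace_wm(i, j - 1)
            return
        for k in range(i + 1, j + 1):
            if WM[i][k - 1] < INF and WM[k][j] < INF and abs(
                val - (WM[i][k - 1] + WM[k][j])
            ) < _EPS:
                trace_wm(i, k - 1)
                trace_wm(k, j)
                return
        raise AssertionError("multiloop traceback failed")

    def trace_wm2(i: int, j: int) -> None:
        val = WM2[i][j]
        for k in range(i + 1, j + 1):
            if WM[i][k - 1] < INF and WM[k][j] < INF and abs(
                val - (WM[i][k - 1] + WM[k][j])
            ) < _EPS:
                trace_wm(i, k - 1)
                trace_wm(k, j)
                return
        raise AssertionError("multiloop traceback failed")

    j = n
    while j > 0:
        if abs(W[j] - W[j - 1]) < _EPS:
            j -= 1
            continue
        for i in range(1, j):
            if V[i][j] < INF and abs(W[j] - (W[i - 1] + V[i][j])) < _EPS:
                trace_v(i, j)
                j = i - 1
                break
        else:  # pragma: no cover - defensive
            raise AssertionError("exterior traceback failed")

    return structure_from_pairs(pairs, n, energy=W[n])


# ---------------------------------------------------------------------------
# exhaustive enumeration (oracle route, short sequences)
# ---------------------------------------------------------------------------

def enumerate_pair_sets(bases: str) -> list[tuple[tuple[int, int], ...]]:
    """All nested pair sets satisfying the three folding constraints.

    Exponential; intended for sequences up to ~30 nt.
    """
    n = len(bases)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if i >= j:
            return ((),)
        out = list(rec(i + 1, j))
        for k in range(i + MIN_HAIRPIN_SEP + 1, j + 1):
            if _pairable(bases, i, k):
                for left in rec(i + 1, k - 1):
                    base = ((i, k),) + left
                    for right in rec(k + 1, j):
                        out.append(base + right)
        return tuple(out)

    result = list(rec(1, n))
    rec.cache_clear()
    return result


def enumerate_structures(
    seq: RnaSequence, model: EnergyModel = DEFAULT_MODEL
) -> list[SecondaryStructure]:
    """Every admissible structure with its loop-decomposition energy."""
    out = []
    n = len(seq)
    for ps in enumerate_pair_sets(seq.bases):
        s = structure_from_pairs(ps, n)
        out.append(s.with_energy(structure_energy(seq, s, model)))
    return out


def enumeration_mfe(seq: RnaSequence, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Brute-force MFE by exhaustive enumeration (oracle)."""
    return min(s.energy for s in enumerate_structures(seq, model))


# ---------------------------------------------------------------------------
# partition function (unambiguous grammar; longer sequences)
# ---------------------------------------------------------------------------

def partition_function(
    seq: RnaSequence,
    model: EnergyModel = DEFAULT_MODEL,
    blocked: frozenset[int] = frozenset(),
) -> float:
    """Boltzmann partition function Z over all admissible structures.

    ``blocked`` positions are forbidden to pair (they may remain unpaired).
    The multiloop segment recursion conditions on the last branch, so every
    structure is generated exactly once.
    """
    b = seq.bases
    n = len(b)
    rt = model.rt
    w = lambda e: math.exp(-e / rt)
    wc = w(model.ml_unpaired)
    wb = w(model.ml_branch)

    Qb = [[0.0] * (n + 2) for _ in range(n + 2)]
    Qm = [[0.0] * (n + 2) for _ in range(n + 2)]
    Qm2 = [[0.0] * (n + 2) for _ in range(n + 2)]

    for span in range(1, n):
        for i in range(1, n - span + 1):
            j = i + span
            if _pairable(b, i, j, blocked):
                total = w(model.hairpin(j - i - 1))
                for k in range(i + 1, j):
                    for l in range(k + MIN_HAIRPIN_SEP + 1, j):
                        if Qb[k][l]:
                            total += w(model.two_loop(i, j, k, l)) * Qb[k][l]
                total += w(model.ml_close) * Qm2[i + 1][j - 1]
                Qb[i][j] = w(model.pair(b[i - 1], b[j - 1])) * total
            # last-branch recursions (valid for any span)
            qm = wc * Qm[i][j - 1] if j - 1 >= i else 0.0
            qm2 = wc * Qm2[i][j - 1] if j - 1 >= i else 0.0
            for d in range(i, j):
                if Qb[d][j]:
                    qm += (wc ** (d - i) + Qm[i][d - 1]) * Qb[d][j] * wb
                    if d > i:
                        qm2 += Qm[i][d - 1] * Qb[d][j] * wb
            Qm[i][j] = qm
            Qm2[i][j] = qm2

    Q = [1.0] * (n + 1)
    for j in range(1, n + 1):
        total = Q[j - 1]
        for k in range(1, j):
            total += Q[k - 1] * Qb[k][j]
        Q[j] = total
    return Q[n]
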