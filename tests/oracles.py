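"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by direct enumeration or an independent
formulation, never by calling the code path it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from loopscreen.params import EnergyModel
from loopscreen.sequences import CANONICAL_PAIRS, is_watson_crick
from loopscreen.sites import SiteScoringParams


def bracket_pairs(dotbracket: str) -> set[tuple[int, int]]:
    """Stack-based bracket matcher (1-based pairs)."""
    stack, pairs = [], set()
    for idx, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            pairs.add((stack.pop(), idx))
    assert not stack
    return pairs


def scan_loops(pair_table: tuple[int, ...]) -> list[dict]:
    """Per-closing-pair loop scan, written independently of the package.

    For each pair (i, j), walks i+1..j-1 collecting immediately interior
    pairs and unpaired positions by skipping over closed intervals.
    """
    n = len(pair_table) - 1
    pairs = [(i, pair_table[i]) for i in range(1, n + 1) if pair_table[i] > i]
    out = []
    for i, j in pairs:
        interior, unpaired = [], []
        p = i + 1
        while p < j:
            q = pair_table[p]
            if q > p:
                interior.append((p, q))
                p = q + 1
            else:
                unpaired.append(p)
                p += 1
        if not interior:
            cls = "hairpin"
        elif len(interior) >= 2:
            cls = "multiloop"
        elif not unpaired:
            cls = "stack"
        else:
            k, l = interior[0]
            cls = "bulge" if (k == i + 1 or l == j - 1) else "interior"
        out.append(
            {"closing": (i, j), "interior": interior, "unpaired": unpaired, "class": cls}
        )
    return out


def enumerate_duplexes(
    mi: str, m: str, i: int, k: int, j: int, l: int, model: EnergyModel, max_loop: int
):
    """All antiparallel pair chains from (i, l) to (k, j); yields energies.

    Pairs are (miRNA p, mRNA q) with p ascending and q descending; between
    consecutive pairs at most ``max_loop`` unpaired bases per strand.
    Energy = initiation + per-pair terms + inter-pair loop penalties,
    re-derived here from the model's tables.
    """

    def pairable(p, q):
        return (mi[p - 1], m[q - 1]) in CANONICAL_PAIRS

    def link(u1, u2):
        if u1 == 0 and u2 == 0:
            return model.stack_bonus
        if u1 == 0 or u2 == 0:
            return model.bulge(u1 + u2)
        return model.interior(u1 + u2)

    def pair_term(p, q):
        return model.pair(mi[p - 1], m[q - 1]) + model.position_penalty * p

    results = []

    def rec(p, q, acc):
        if (p, q) == (k, j):
            results.append(acc + model.duplex_init)
            return
        for np_ in range(p + 1, min(k, p + max_loop + 1) + 1):
            for nq in range(max(j, q - max_loop - 1), q):
                if (np_ == k) != (nq == j):
                    continue  # the end positions may only appear as the final pair
                if pairable(np_, nq):
                    rec(np_, nq, acc + link(np_ - p - 1, q - nq - 1) + pair_term(np_, nq))

    if pairable(i, l):
        rec(i, l, pair_term(i, l))
    return results


def alignment_oracle(
    mirna: str, utr: str, params: SiteScoringParams
) -> float | None:
    """Best constrained duplex score by top-down recursion with memo.

    Independent formulation of the site-alignment optimum: miRNA core
    global, UTR-reversed local, affine gaps, <= max_seed_events non-WC
    events at seed positions.  Returns None when no alignment passes the
    structural constraints.
    """
    L = len(mirna)
    core = mirna[1 : L - 2]
    m = len(core)
    rev = utr[::-1]
    U = len(rev)
    lo, hi = params.seed_span
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(a: int, u: int, g: int, e: int) -> float:
        """Max score of a suffix alignment starting at core a, rev-UTR u.

        g: 0 = previous column was a pair (or start), 1 = in insertion,
        2 = in deletion.  The alignment must end with a pair consuming the
        final core base.
        """
        if a == m:
            return 0.0 if g == 0 else NEG
        pos = a + 2
        options = []
        if u < U:
            mi_b, t_b = core[a], rev[u]
            ev = int(lo <= pos <= hi and not is_watson_crick(mi_b, t_b))
            if e + ev <= params.max_seed_events:
                nxt = best(a + 1, u + 1, 0, e + ev)
                if nxt > NEG:
                    options.append(
                        params.weight(pos) * params.substitution(mi_b, t_b) + nxt
                    )
        if a >= 1:
            if u < U and a < m:
                ev = int(lo <= a + 1 <= hi - 1)
                if e + ev <= params.max_seed_events:
                    pen = params.gap_extend if g == 1 else params.gap_open
                    nxt = best(a, u + 1, 1, e + ev)
                    if nxt > NEG:
                        options.append(pen + nxt)
            if a < m:
                ev = int(lo <= pos <= hi)
                if e + ev <= params.max_seed_events:
                    pen = params.gap_extend if g == 2 else params.gap_open
                    nxt = best(a + 1, u, 2, e + ev)
                    if nxt > NEG:
                        options.append(pen + nxt)
        return max(options, default=NEG)

    scores = [best(0, u0, 0, 0) for u0 in range(U)]
    best.cache_clear()
    top = max(scores, default=NEG)
    return None if top == NEG else top


def ranksum_oracle(kb: dict[str, float], sb: dict[str, float]) -> list[str]:
    """Brute-force rank-sum ordering over all permutations of ranks.

    kb: molecule -> probability (higher better); sb: molecule -> mean
    affinity (lower better).  Returns molecule ids sorted by rank sum,
    ties broken by better kb rank then id, computed by explicit sorting of
    fully materialized rank tables.
    """
    kb_sorted = sorted(kb, key=lambda x: (-kb[x], x))
    sb_sorted = sorted(sb, key=lambda x: (sb[x], x))
    kb_rank = {mol: r for r, mol in enumerate(kb_sorted, 1)}
    sb_rank = {mol: r for r, mol in enumerate(sb_sorted, 1)}
    return sorted(kb, key=lambda x: (kb_rank[x] + sb_rank[x], kb_rank[x], x))
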