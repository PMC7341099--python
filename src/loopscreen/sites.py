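"""Seed-anchored miRNA target-site prediction.

A weighted dynamic-programming complementarity alignment between the miRNA
and the 3'-UTR, in the style of the miRanda algorithm with the following
modifications: the first 5' base and the last two 3' bases of the miRNA are
excluded from the alignment; substitution scores at seed positions (miRNA
2-8) carry a higher position-specific weight; and at most one G:U wobble
or mismatch event is tolerated inside the seed proper (positions 2-7) -
a gap touching the seed counts as an event.  Sites score at least the
cutoff (default 120, gap open/extend -9/-4).

The duplex is antiparallel: the miRNA 5'->3' aligns against the UTR read
3'->5', so miRNA position 2 pairs near the 3' end of the reported site.
A "canonical" site has a perfect gap-free Watson-Crick 6-mer at miRNA
positions 2-7.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .sequences import CANONICAL_PAIRS, RnaSequence, is_watson_crick

NEG = float("-inf")


@dataclass(frozen=True)
class SiteScoringParams:
    score_cutoff: float = 120.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    seed_weight: float = 2.0
    seed_weight_span: tuple[int, int] = (2, 8)
    seed_span: tuple[int, int] = (2, 7)
    max_seed_events: int = 1

    def __post_init__(self) -> None:
        if self.score_cutoff <= 0:
            raise ValueError("score_cutoff must be > 0")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    def weight(self, mirna_pos: int) -> float:
        lo, hi = self.seed_weight_span
        return self.seed_weight if lo <= mirna_pos <= hi else 1.0

    def substitution(self, mi: str, target: str) -> float:
        if is_watson_crick(mi, target):
            return self.match
        if (mi, target) in CANONICAL_PAIRS:
            return self.wobble
        return self.mismatch


@dataclass(frozen=True)
class DuplexAlignment:
    """A gapped miRNA::target duplex.

    ``mirna_aligned`` is the miRNA core (positions 2..L-2) 5'->3';
    ``mrna_aligned`` is the target site written 3'->5' so complementary
    columns line up.  ``mrna_interval`` is 1-based 5'->3' on the UTR.
    """

    mirna_aligned: str
    mrna_aligned: str
    score: float
    mirna_interval: tuple[int, int]
    mrna_interval: tuple[int, int]
    seed_events: int
    canonical: bool
    utr_id: str = ""


def _column_iter(alignment: DuplexAlignment):
    """Yield (mirna_pos or None, mi_char, target_char) per column."""
    pos = alignment.mirna_interval[0]
    for mc, tc in zip(alignment.mirna_aligned, alignment.mrna_aligned):
        if mc == "-":
            yield None, mc, tc
        else:
            yield pos, mc, tc
            pos += 1


def rescore_alignment(alignment: DuplexAlignment, params: SiteScoringParams) -> float:
    """Recompute the score from the gapped strings (exactly)."""
    score = 0.0
    in_gap = False
    for pos, mc, tc in _column_iter(alignment):
        if mc == "-" or tc == "-":
            score += params.gap_extend if in_gap else params.gap_open
            in_gap = True
        else:
            in_gap = False
            score += params.weight(pos) * params.substitution(mc, tc)
    return score


def is_canonical_site(alignment: DuplexAlignment) -> bool:
    """Perfect gap-free Watson-Crick 6-mer at miRNA positions 2-7."""
    seen = set()
    prev_pos = None
    for pos, mc, tc in _column_iter(alignment):
        if pos is None:
            # insertion; interior to the seed region breaks canonicity
            if prev_pos is not None and 2 <= prev_pos <= 6:
                return False
            continue
        if 2 <= pos <= 7:
            if tc == "-" or not is_watson_crick(mc, tc):
                return False
            seen.add(pos)
        prev_pos = pos
    return seen == set(range(2, 8))


def align_duplex(
    mirna: RnaSequence, utr: RnaSequence, params: SiteScoringParams | None = None
) -> list[DuplexAlignment]:
    """All non-overlapping duplexes with score >= cutoff.

    Constrained DP: global in the miRNA core (positions 2..L-2), local on
    the UTR, affine gaps, and at most ``max_seed_events`` non-Watson-Crick
    events (wobble, mismatch, or gap) inside seed positions 2-7.
    Alignments begin and end with a paired column.  Sorted by score
    descending, then 5'-most on the UTR.
    """
    params = params or SiteScoringParams()
    if len(mirna) < 10:
        raise ValueError("miRNA must be at least 10 nt")
    if len(utr) < 6:
        raise ValueError("UTR must be at least 6 nt")
    L = len(mirna)
    core = mirna.bases[1 : L - 2]  # miRNA positions 2..L-2
    m = len(core)
    rev = utr.bases[::-1]
    U = len(rev)
    seed_lo, seed_hi = params.seed_span

    # dp[a][u][g][e]: best score having consumed a core bases and the first
    # u bases of the reversed UTR; g: 0 after pair, 1 in insertion run,
    # 2 in deletion run; e: seed events so far.
    dp = [
        [[[NEG] * (params.max_seed_events + 1) for _ in range(3)] for _ in range(U + 1)]
        for _ in range(m + 1)
    ]
    parent: dict = {}
    for u in range(U + 1):
        dp[0][u][0][0] = 0.0

    def relax(state, value, prev, col):
        a, u, g, e = state
        if value > dp[a][u][g][e] + 1e-12:
            dp[a][u][g][e] = value
            parent[state] = (prev, col)

    for a in range(m + 1):
        for u in range(U + 1):
            for g in range(3):
                for e in range(params.max_seed_events + 1):
                    s = dp[a][u][g][e]
                    if s == NEG:
                        continue
                    if g != 0 and a == 0:
                        continue
                    pos = a + 2  # next miRNA position to consume
                    # pair column
                    if a < m and u < U:
                        mi, tc = core[a], rev[u]
                        ev = int(
                            seed_lo <= pos <= seed_hi and not is_watson_crick(mi, tc)
                        )
                        if e + ev <= params.max_seed_events:
                            relax(
                                (a + 1, u + 1, 0, e + ev),
                                s + params.weight(pos) * params.substitution(mi, tc),
                                (a, u, g, e),
                                ("P", mi, tc),
                            )
                    if a >= 1:
                        # insertion: UTR base unaligned (gap in miRNA)
                        if a < m and u < U:
                            last = a + 1  # last consumed miRNA position
                            ev = int(seed_lo <= last <= seed_hi - 1)
                            if e + ev <= params.max_seed_events:
                                pen = params.gap_extend if g == 1 else params.gap_open
                                relax(
                                    (a, u + 1, 1, e + ev),
                                    s + pen,
                                    (a, u, g, e),
                                    ("I", "-", rev[u]),
                                )
                        # deletion: miRNA base unaligned (gap in UTR)
                        if a < m:
                            ev = int(seed_lo <= pos <= seed_hi)
                            if e + ev <= params.max_seed_events:
                                pen = params.gap_extend if g == 2 else params.gap_open
                                relax(
                                    (a + 1, u, 2, e + ev),
                                    s + pen,
                                    (a, u, g, e),
                                    ("D", core[a], "-"),
                                )

    candidates = []
    for u in range(1, U + 1):
        for e in range(params.max_seed_events + 1):
            score = dp[m][u][0][e]
            if score == NEG or score < params.score_cutoff:
                continue
            cols = []
            state = (m, u, 0, e)
            while state in parent:
                prev, col = parent[state]
                cols.append(col)
                state = prev
            cols.reverse()
            u0 = state[1]  # reversed-UTR offset where the alignment starts
            mi_str = "".join(c[1] for c in cols)
            t_str = "".join(c[2] for c in cols)
            # reversed-UTR indices u0..u-1 -> UTR coords (1-based, 5'->3')
            interval = (U - u + 1, U - u0)
            aln = DuplexAlignment(
                mirna_aligned=mi_str,
                mrna_aligned=t_str,
                score=score,
                mirna_interval=(2, L - 2),
                mrna_interval=interval,
                seed_events=e,
                canonical=False,
                utr_id=utr.id,
            )
            candidates.append(replace(aln, canonical=is_canonical_site(aln)))

    # greedy non-overlapping site reporting: score desc, then 5'-most
    candidates.sort(key=lambda x: (-x.score, x.mrna_interval[0]))
    chosen: list[DuplexAlignment] = []
    for c in candidates:
        lo, hi = c.mrna_interval
        if all(hi < s.mrna_interval[0] or lo > s.mrna_interval[1] for s in chosen):
            chosen.append(c)
    return chosen


def scan_utr(
    mirna: RnaSequence, utr: RnaSequence, params: SiteScoringParams | None = None
) -> list[DuplexAlignment]:
    """Site scan over a full UTR; deterministic score-desc, 5'-most order."""
    return align_duplex(mirna, utr, params)
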