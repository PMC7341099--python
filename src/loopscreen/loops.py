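"""Loop decomposition of secondary structures.

For each base pair (i, j) the corresponding loop consists of (i, j) itself,
the base pairs immediately interior to (i, j), and the unpaired regions
connecting them.  A stacked base pair constitutes a loop of zero size.  The
unpaired stretches outside all pairs form the exterior loop, which carries
no closing pair and zero energy.  Loop energies sum exactly to the
structure energy (the additivity the folding recursion relies on).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .params import DEFAULT_MODEL, EnergyModel
from .sequences import JoinedInteraction, RnaSequence
from .structure import SecondaryStructure

LOOP_CLASSES = ("stack", "hairpin", "bulge", "interior", "multiloop", "exterior")


@dataclass(frozen=True)
class Loop:
    """One loop of the decomposition."""

    closing_pair: tuple[int, int] | None
    interior_pairs: tuple[tuple[int, int], ...]
    unpaired_positions: tuple[int, ...]
    loop_class: str
    base_composition: dict
    energy: float

    @property
    def size(self) -> int:
        return len(self.unpaired_positions)


def _classify(n_interior: int, u1: int, u2: int, size: int) -> str:
    if n_interior == 0:
        return "hairpin"
    if n_interior >= 2:
        return "multiloop"
    if size == 0:
        return "stack"
    if u1 == 0 or u2 == 0:
        return "bulge"
    return "interior"


def _loop_energy(
    model: EnergyModel,
    seq: RnaSequence,
    closing: tuple[int, int],
    interior: list[tuple[int, int]],
    size: int,
    loop_class: str,
) -> float:
    i, j = closing
    e = model.pair(seq.base(i), seq.base(j))
    if loop_class == "hairpin":
        return e + model.hairpin(size)
    if loop_class == "multiloop":
        return e + model.multiloop(len(interior), size)
    k, l = interior[0]
    return e + model.two_loop(i, j, k, l)


def detect_loops(
    structure: SecondaryStructure,
    seq: RnaSequence | None = None,
    model: EnergyModel = DEFAULT_MODEL,
) -> list[Loop]:
    """Decompose a structure into its loops.

    When ``seq`` is given, loop energies and base compositions are filled
    in; otherwise energies are 0 and compositions empty.  The exterior loop
    is returned last (only when it has content or the structure has no
    pairs at all).
    """
    table = structure.pair_table
    n = structure.length
    loops: list[Loop] = []

    def scan(lo: int, hi: int) -> tuple[list[tuple[int, int]], list[int]]:
        """Immediately interior pairs and unpaired positions in lo..hi."""
        branches, unpaired = [], []
        k = lo
        while k <= hi:
            j = table[k]
            if j > k:
                branches.append((k, j))
                k = j + 1
            else:
                unpaired.append(k)
                k += 1
        return branches, unpaired

    for i, j in structure.pairs:
        branches, unpaired = scan(i + 1, j - 1)
        u1 = (branches[0][0] - i - 1) if branches else 0
        u2 = (j - branches[-1][1] - 1) if branches else 0
        cls = _classify(len(branches), u1, u2, len(unpaired))
        comp: dict = {}
        energy = 0.0
        if seq is not None:
            comp = dict(Counter(seq.base(p) for p in unpaired))
            energy = _loop_energy(model, seq, (i, j), branches, len(unpaired), cls)
        loops.append(
            Loop(
                closing_pair=(i, j),
                interior_pairs=tuple(branches),
                unpaired_positions=tuple(unpaired),
                loop_class=cls,
                base_composition=comp,
                energy=energy,
            )
        )

    ext_branches, ext_unpaired = scan(1, n)
    if ext_unpaired or not loops:
        comp = dict(Counter(seq.base(p) for p in ext_unpaired)) if seq else {}
        loops.append(
            Loop(
                closing_pair=None,
                interior_pairs=tuple(ext_branches),
                unpaired_positions=tuple(ext_unpaired),
                loop_class="exterior",
                base_composition=comp,
                energy=0.0,
            )
        )
    return loops


def structure_energy(
    seq: RnaSequence,
    structure: SecondaryStructure,
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Total energy = sum of loop energies of the decomposition."""
    return sum(lp.energy for lp in detect_loops(structure, seq=seq, model=model))


@dataclass(frozen=True)
class PositionProfile:
    """Per-miRNA-position counts of loop membership."""

    counts: tuple[int, ...]
    seed_region: tuple[int, int] = (1, 10)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def seed_fraction(self) -> float:
        lo, hi = self.seed_region
        if self.total == 0:
            return 0.0
        return sum(self.counts[lo - 1 : hi]) / self.total


def loop_position_profile(
    loops: list[Loop], interaction: JoinedInteraction
) -> PositionProfile:
    """Count, per miRNA position, how often it lies unpaired inside a loop.

    Positions outside the miRNA span (mRNA site, linker) are ignored.  Only
    closed loops contribute; the exterior region is not a loop of the
    duplex.
    """
    lo, hi = interaction.mirna_span
    counts = [0] * len(interaction.mirna)
    for lp in loops:
        if lp.closing_pair is None:
            continue
        for p in lp.unpaired_positions:
            if lo <= p <= hi:
                counts[p - lo] += 1
    return PositionProfile(counts=tuple(counts))
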