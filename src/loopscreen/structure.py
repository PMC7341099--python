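"""Secondary structures: pair tables, dot-bracket notation, validation.

A secondary structure is a set of canonical base pairs that is nested
(pseudoknot-free), has at most one partner per position, and keeps paired
ends at least three bases apart (j - i > 3, i.e. hairpin loops of at least
three unpaired bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequences import RnaSequence, can_pair

MIN_HAIRPIN_SEP = 3  # pairs (i, j) require j - i > 3


class StructureError(ValueError):
    """Invalid secondary structure."""


@dataclass(frozen=True)
class SecondaryStructure:
    """Pair table + dot-bracket for a single strand.

    ``pair_table`` maps 1-based position -> partner (0 = unpaired) and has a
    leading sentinel at index 0 so positions index directly.
    """

    pair_table: tuple[int, ...]
    energy: float = 0.0
    dot_bracket: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dot_bracket", _to_dotbracket(self.pair_table))

    @property
    def length(self) -> int:
        return len(self.pair_table) - 1

    def partner(self, pos: int) -> int:
        return self.pair_table[pos]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Sorted list of (i, j) with i < j."""
        return [
            (i, j)
            for i, j in enumerate(self.pair_table)
            if j > i > 0
        ]

    def is_paired(self, pos: int) -> bool:
        return self.pair_table[pos] != 0

    def with_energy(self, energy: float) -> "SecondaryStructure":
        return SecondaryStructure(pair_table=self.pair_table, energy=energy)


def _to_dotbracket(pair_table: tuple[int, ...]) -> str:
    out = []
    for i in range(1, len(pair_table)):
        j = pair_table[i]
        out.append("." if j == 0 else ("(" if j > i else ")"))
    return "".join(out)


def structure_from_pairs(pairs, length: int, energy: float = 0.0) -> SecondaryStructure:
    table = [0] * (length + 1)
    for i, j in pairs:
        if not (1 <= i < j <= length):
            raise StructureError(f"pair ({i},{j}) outside 1..{length}")
        if table[i] or table[j]:
            raise StructureError(f"position in more than one pair: ({i},{j})")
        table[i], table[j] = j, i
    return SecondaryStructure(pair_table=tuple(table), energy=energy)


def parse_dotbracket(structure: str, energy: float = 0.0) -> SecondaryStructure:
    """Parse a dot-bracket string into a pair table.

    Raises :class:`StructureError` with the offending 1-based index on
    unbalanced brackets.
    """
    table = [0] * (len(structure) + 1)
    stack: list[int] = []
    for idx, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {idx}")
            i = stack.pop()
            table[i], table[idx] = idx, i
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r} at position {idx}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(pair_table=tuple(table), energy=energy)


def validate_structure(seq: RnaSequence, struct: SecondaryStructure) -> None:
    """Check every structural invariant against a sequence.

    Enforces: length match, symmetry, canonical pairs only, j - i > 3,
    nestedness, and that linker placeholders never pair.
    """
    if struct.length != len(seq):
        raise StructureError(
            f"structure length {struct.length} != sequence length {len(seq)}"
        )
    table = struct.pair_table
    for i in range(1, struct.length + 1):
        j = table[i]
        if j == 0:
            continue
        if table[j] != i:
            raise StructureError(f"pair table not symmetric at {i}")
        if j > i:
            if j - i <= MIN_HAIRPIN_SEP:
                raise StructureError(f"hairpin too tight: ({i},{j})")
            a, b = seq.base(i), seq.base(j)
            if not can_pair(a, b):
                raise StructureError(f"non-canonical pair {a}{b} at ({i},{j})")
    pairs = struct.pairs
    for x, (i, j) in enumerate(pairs):
        for k, l in pairs[x + 1 :]:
            if i < k < j < l:
                raise StructureError(f"pseudoknot: ({i},{j}) crosses ({k},{l})")
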