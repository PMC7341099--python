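"""RNA sequences, joined miRNA-mRNA interactions and FASTA I/O.

Sequences are 5'->3' over {A,C,G,U}; DNA input (T) is normalized to U.
Positions are 1-based inclusive throughout the package, matching the
"positions 2 to 7" convention used for seed regions.

A joined interaction concatenates a miRNA and an mRNA site into one strand,
optionally separated by a linker of placeholder symbols.  Linker positions
use the dedicated symbol ``N``: they can never base-pair and are excluded
from all composition statistics, which reproduces the observed invariance of
the fold to inserted placeholders by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
LINKER = "N"

#: canonical Watson-Crick plus G-U wobble pairs
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}


class SequenceError(ValueError):
    """Invalid RNA sequence input."""


def normalize(bases: str) -> str:
    """Uppercase, convert T->U, validate alphabet (linker symbol allowed)."""
    s = bases.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET - {LINKER}
    if bad:
        raise SequenceError(f"invalid characters in RNA sequence: {sorted(bad)}")
    if not s:
        raise SequenceError("empty RNA sequence")
    return s


def can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def is_watson_crick(a: str, b: str) -> bool:
    return (a, b) in WATSON_CRICK


def reverse_complement(bases: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(bases))


@dataclass(frozen=True)
class RnaSequence:
    """A 5'->3' RNA sequence with a stable identifier.

    ``kind`` is one of ``"miRNA"``, ``"mRNA"`` or ``"joined"`` and is purely
    descriptive.
    """

    id: str
    bases: str
    kind: str = "mRNA"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", normalize(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, pos: int) -> str:
        """1-based access."""
        if not 1 <= pos <= len(self.bases):
            raise IndexError(f"position {pos} outside 1..{len(self.bases)}")
        return self.bases[pos - 1]

    def subsequence(self, i: int, k: int) -> str:
        """Bases i..k, 1-based inclusive."""
        if not 1 <= i <= k <= len(self.bases):
            raise IndexError(f"interval {i}..{k} outside 1..{len(self.bases)}")
        return self.bases[i - 1 : k]


@dataclass(frozen=True)
class JoinedInteraction:
    """A miRNA and an mRNA site concatenated 5'->3' into one strand.

    The linker (if any) sits between the two molecules and consists of
    unpairable placeholder symbols.  ``mirna_span`` and ``mrna_span`` are
    1-based inclusive intervals into ``joined``.
    """

    mirna: RnaSequence
    mrna_site: RnaSequence
    linker_length: int = 0
    joined: RnaSequence = field(init=False)
    mirna_span: tuple[int, int] = field(init=False)
    mrna_span: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")
        seq = self.mirna.bases + LINKER * self.linker_length + self.mrna_site.bases
        joined = RnaSequence(
            id=f"{self.mirna.id}::{self.mrna_site.id}", bases=seq, kind="joined"
        )
        object.__setattr__(self, "joined", joined)
        n_mi = len(self.mirna)
        object.__setattr__(self, "mirna_span", (1, n_mi))
        start = n_mi + self.linker_length + 1
        object.__setattr__(self, "mrna_span", (start, start + len(self.mrna_site) - 1))

    @property
    def linker_positions(self) -> range:
        return range(len(self.mirna) + 1, len(self.mirna) + self.linker_length + 1)

    def is_linker(self, pos: int) -> bool:
        return pos in self.linker_positions


def join_interaction(
    mirna: RnaSequence, mrna_site: RnaSequence, linker_length: int = 0
) -> JoinedInteraction:
    """Join a miRNA and an mRNA site 5'->3' with an unpairable linker."""
    return JoinedInteraction(mirna=mirna, mrna_site=mrna_site, linker_length=linker_length)


def read_fasta(path, kind: str = "mRNA") -> list[RnaSequence]:
    return [RnaSequence(id=rec.id, bases=str(rec.seq), kind=kind) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[RnaSequence], path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def iter_kmers(bases: str, k: int) -> Iterator[str]:
    """k-mers over contiguous non-linker windows."""
    for i in range(len(bases) - k + 1):
        w = bases[i : i + k]
        if LINKER not in w:
            yield w
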