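"""Mutation energy scans and the placeholder-robustness check.

The mutation scan substitutes single bases of a joined miRNA-mRNA duplex
and refolds, reporting the energy change relative to the wild-type fold;
destabilizing a seed-region loop raises the predicted energy while
mutations in structure-free tails leave it unchanged.

The placeholder check refolds the joined sequence with unpairable linkers
of several lengths inserted at the ligation site and measures how much of
the base-pair set survives, mirroring the observation that the fold of the
joined sequence is hardly influenced by inserted placeholders.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fold import fold_mfe
from .params import DEFAULT_MODEL, EnergyModel
from .sequences import JoinedInteraction, RnaSequence, join_interaction
from .structure import SecondaryStructure

BASES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class EnergyDelta:
    position: int
    wild_energy: float
    mutant_energy: float
    mutant_base: str

    @property
    def delta(self) -> float:
        return self.mutant_energy - self.wild_energy


def mutation_energy_scan(
    interaction: JoinedInteraction,
    positions: list[int] | None = None,
    alphabet: tuple[str, ...] = BASES,
    model: EnergyModel = DEFAULT_MODEL,
) -> list[EnergyDelta]:
    """Refold after each single-base substitution of the joined sequence.

    One :class:`EnergyDelta` per (position, mutant base != wild base);
    linker positions are not mutable.
    """
    joined = interaction.joined
    wild_energy = fold_mfe(joined, model).energy
    if positions is None:
        positions = [
            p for p in range(1, len(joined) + 1) if not interaction.is_linker(p)
        ]
    out = []
    for pos in positions:
        if interaction.is_linker(pos):
            raise ValueError(f"position {pos} lies in the linker")
        wild = joined.base(pos)
        for mut in alphabet:
            if mut == wild:
                continue
            bases = joined.bases[: pos - 1] + mut + joined.bases[pos:]
            mutant = RnaSequence(id=f"{joined.id}|{wild}{pos}{mut}", bases=bases, kind="joined")
            out.append(
                EnergyDelta(
                    position=pos,
                    wild_energy=wild_energy,
                    mutant_energy=fold_mfe(mutant, model).energy,
                    mutant_base=mut,
                )
            )
    return out


@dataclass(frozen=True)
class PlaceholderFold:
    linker_length: int
    structure: SecondaryStructure
    agreement: float


@dataclass(frozen=True)
class PlaceholderReport:
    folds: tuple[PlaceholderFold, ...]

    @property
    def min_agreement(self) -> float:
        return min(f.agreement for f in self.folds)


def _canonical_pairs(interaction: JoinedInteraction, struct: SecondaryStructure):
    """Pair set in linker-independent coordinates.

    miRNA positions keep their index; mRNA-site positions are re-origined to
    the site so folds with different linker lengths are comparable.  Pairs
    touching the linker cannot occur by construction.
    """
    mi_hi = interaction.mirna_span[1]
    site_lo = interaction.mrna_span[0]

    def tag(p: int):
        if p <= mi_hi:
            return ("mi", p)
        return ("m", p - site_lo + 1)

    return {tuple(sorted((tag(i), tag(j)))) for i, j in struct.pairs}


def placeholder_robustness(
    mirna: RnaSequence,
    mrna_site: RnaSequence,
    linker_lengths: list[int],
    seed: int = 0,
    model: EnergyModel = DEFAULT_MODEL,
) -> PlaceholderReport:
    """Fold the joined sequence for each linker length; compare pair sets.

    Agreement is |P_l intersect P_0| / max(|P_l|, |P_0|) against the
    0-linker fold (1.0 when both folds are identical, and by convention
    when both are empty).  ``seed`` is accepted for interface symmetry with
    generators that draw random placeholder bases; the linker symbol here
    is a fixed unpairable placeholder, so it has no effect.
    """
    if 0 not in linker_lengths:
        raise ValueError("linker_lengths must include 0 (the original sequence)")
    folds = {}
    pair_sets = {}
    for ll in linker_lengths:
        inter = join_interaction(mirna, mrna_site, linker_length=ll)
        s = fold_mfe(inter.joined, model)
        folds[ll] = s
        pair_sets[ll] = _canonical_pairs(inter, s)
    ref = pair_sets[0]
    out = []
    for ll in linker_lengths:
        ps = pair_sets[ll]
        denom = max(len(ps), len(ref))
        agreement = 1.0 if denom == 0 else len(ps & ref) / denom
        out.append(PlaceholderFold(linker_length=ll, structure=folds[ll], agreement=agreement))
    return PlaceholderReport(folds=tuple(out))
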