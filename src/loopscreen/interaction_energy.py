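"""Accessibility-corrected miRNA-mRNA interaction energies.

The combined energy of binding an interval i..k of the miRNA to an
interval j..l of the mRNA is

    E[i,k; j,l] = Ehybrid[i,k; j,l]
                + ED_miRNA[i,k] + (conditional flank terms) * Edangle
                + ED_mRNA[j,l]  + (conditional flank terms) * Edangle

where Ehybrid is the minimal intermolecular duplex energy with both
interval ends base-paired (including a constant duplex-initiation
penalty), ED = -RT log Pu is the energetic cost of opening the
intramolecular structure over the interval (Pu = Boltzmann probability
that the whole interval is unpaired), and each flank dangle is weighted by
the conditional probability that the flanking base is also unpaired given
the interval is.

Pu is computed exactly by structure enumeration for sequences up to 30 nt
and by the unambiguous partition-function DP above that; the two routes
agree on their overlapping range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fold import enumerate_structures, partition_function
from .params import DEFAULT_MODEL, EnergyModel
from .sequences import RnaSequence, can_pair

ENUMERATION_LIMIT = 30
INF = float("inf")


class HybridError(ValueError):
    """Interval ends cannot base-pair."""


# ---------------------------------------------------------------------------
# unpaired probability
# ---------------------------------------------------------------------------

_ensemble_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
_z_cache: dict[tuple[str, int], float] = {}


def _ensemble(seq: RnaSequence, model: EnergyModel):
    """(Boltzmann weights, unpaired masks) over the full structure ensemble."""
    key = (seq.bases, id(model))
    if key not in _ensemble_cache:
        structures = enumerate_structures(seq, model)
        energies = np.array([s.energy for s in structures])
        weights = np.exp(-energies / model.rt)
        masks = np.array(
            [[s.pair_table[p] == 0 for p in range(1, len(seq) + 1)] for s in structures]
        )
        _ensemble_cache[key] = (weights, masks)
    return _ensemble_cache[key]


def unpaired_probability(
    seq: RnaSequence,
    i: int,
    k: int,
    model: EnergyModel = DEFAULT_MODEL,
    method: str = "auto",
) -> float:
    """Probability that all of positions i..k are unpaired at equilibrium.

    ``method`` is ``"enumeration"`` (exact sum over all structures),
    ``"partition"`` (constrained partition function: Z with i..k barred
    from pairing over Z), or ``"auto"`` (enumeration up to 30 nt).
    """
    n = len(seq)
    if not 1 <= i <= k <= n:
        raise ValueError(f"empty or invalid interval {i}..{k}")
    if method == "auto":
        method = "enumeration" if n <= ENUMERATION_LIMIT else "partition"
    if method == "enumeration":
        weights, masks = _ensemble(seq, model)
        covered = masks[:, i - 1 : k].all(axis=1)
        return float(weights[covered].sum() / weights.sum())
    if method == "partition":
        key = (seq.bases, id(model))
        if key not in _z_cache:
            _z_cache[key] = partition_function(seq, model)
        blocked = frozenset(range(i, k + 1))
        return partition_function(seq, model, blocked=blocked) / _z_cache[key]
    raise ValueError(f"unknown method {method!r}")


def accessibility_penalty(
    seq: RnaSequence, i: int, k: int, model: EnergyModel = DEFAULT_MODEL
) -> float:
    """ED[i,k] = -RT log Pu[i..k]; zero iff the interval is always free."""
    pu = unpaired_probability(seq, i, k, model)
    return -model.rt * math.log(pu)


# ---------------------------------------------------------------------------
# intermolecular hybrid energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HybridEnergy:
    mirna_interval: tuple[int, int]
    mrna_interval: tuple[int, int]
    energy: float


def _pair_term(model: EnergyModel, a: str, b: str, mirna_pos: int) -> float:
    return model.pair(a, b) + model.position_penalty * mirna_pos


def _link(model: EnergyModel, u1: int, u2: int) -> float:
    if u1 == 0 and u2 == 0:
        return model.stack_bonus
    if u1 == 0 or u2 == 0:
        return model.bulge(u1 + u2)
    return model.interior(u1 + u2)


def _hybrid_table(
    mirna: RnaSequence,
    mrna: RnaSequence,
    i: int,
    l: int,
    p_max: int,
    q_min: int,
    model: EnergyModel,
    max_loop: int,
) -> dict[tuple[int, int], float]:
    """Forward duplex DP anchored at the pair (miRNA i, mRNA l).

    Returns, for every reachable pair (p, q) with i<=p<=p_max and
    q_min<=q<=l, the minimal path energy (pair terms + inter-pair loop
    penalties, no initiation) of a duplex starting at (i, l) and ending
    with (p, q).  The duplex is antiparallel: miRNA indices ascend while
    mRNA indices descend.
    """
    F: dict[tuple[int, int], float] = {}
    if not can_pair(mirna.base(i), mrna.base(l)):
        return F
    F[(i, l)] = _pair_term(model, mirna.base(i), mrna.base(l), i)
    for p in range(i, p_max + 1):
        for q in range(l, q_min - 1, -1):
            if (p, q) == (i, l):
                continue
            if not can_pair(mirna.base(p), mrna.base(q)):
                continue
            best = INF
            for pp in range(max(i, p - max_loop - 1), p):
                for qq in range(q + 1, min(l, q + max_loop + 1) + 1):
                    prev = F.get((pp, qq))
                    if prev is None:
                        continue
                    cand = prev + _link(model, p - pp - 1, qq - q - 1)
                    if cand < best:
                        best = cand
            if best < INF:
                e = best + _pair_term(model, mirna.base(p), mrna.base(q), p)
                if (p, q) not in F or e < F[(p, q)]:
                    F[(p, q)] = e
    return F


def hybrid_energy(
    mirna: RnaSequence,
    mrna: RnaSequence,
    i: int,
    k: int,
    j: int,
    l: int,
    model: EnergyModel = DEFAULT_MODEL,
    max_loop: int = 8,
) -> HybridEnergy:
    """Minimal duplex energy for miRNA i..k bound to mRNA j..l.

    The interval ends form the terminal base pairs (i with l, k with j);
    interior positions may pair or bulge out, with at most ``max_loop``
    unpaired bases per strand between consecutive pairs.  Includes the
    duplex initiation penalty.
    """
    if not (1 <= i <= k <= len(mirna) and 1 <= j <= l <= len(mrna)):
        raise ValueError("intervals outside sequences")
    if (i == k) != (j == l):
        raise HybridError("single-pair duplex needs both intervals of length 1")
    if not can_pair(mirna.base(i), mrna.base(l)):
        raise HybridError(f"terminal bases {mirna.base(i)}-{mrna.base(l)} cannot pair")
    if not can_pair(mirna.base(k), mrna.base(j)):
        raise HybridError(f"terminal bases {mirna.base(k)}-{mrna.base(j)} cannot pair")
    F = _hybrid_table(mirna, mrna, i, l, k, j, model, max_loop)
    e = F.get((k, j))
    if e is None:
        raise HybridError(
            f"no duplex path from ({i},{l}) to ({k},{j}) within max_loop={max_loop}"
        )
    return HybridEnergy(
        mirna_interval=(i, k), mrna_interval=(j, l), energy=e + model.duplex_init
    )


# ---------------------------------------------------------------------------
# Eq.-1 combined energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinedEnergy:
    mirna_interval: tuple[int, int]
    mrna_interval: tuple[int, int]
    e_hybrid: float
    ed_mirna: float
    ed_mrna: float
    dangle_terms: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return (
            self.e_hybrid
            + self.ed_mirna
            + self.ed_mrna
            + sum(self.dangle_terms.values())
        )


def _dangles(
    seq: RnaSequence, i: int, k: int, tag: str, model: EnergyModel
) -> dict[str, float]:
    """Flank dangle terms weighted by conditional unpaired probabilities.

    Pru(i-1 | i..k) = Pu(i-1..k) / Pu(i..k); a flank beyond the sequence
    end contributes 0.
    """
    out = {}
    pu = unpaired_probability(seq, i, k, model)
    if i > 1:
        out[f"{tag}_5p"] = (
            unpaired_probability(seq, i - 1, k, model) / pu * model.dangle_energy
        )
    if k < len(seq):
        out[f"{tag}_3p"] = (
            unpaired_probability(seq, i, k + 1, model) / pu * model.dangle_energy
        )
    return out


def combined_energy(
    mirna: RnaSequence,
    mrna: RnaSequence,
    i: int,
    k: int,
    j: int,
    l: int,
    model: EnergyModel = DEFAULT_MODEL,
    max_loop: int = 8,
) -> CombinedEnergy:
    """Assemble the accessibility-corrected interaction energy."""
    hyb = hybrid_energy(mirna, mrna, i, k, j, l, model, max_loop)
    dangles = {}
    dangles.update(_dangles(mirna, i, k, "mirna", model))
    dangles.update(_dangles(mrna, j, l, "mrna", model))
    return CombinedEnergy(
        mirna_interval=(i, k),
        mrna_interval=(j, l),
        e_hybrid=hyb.energy,
        ed_mirna=accessibility_penalty(mirna, i, k, model),
        ed_mrna=accessibility_penalty(mrna, j, l, model),
        dangle_terms=dangles,
    )


def minimum_energy_interaction(
    mirna: RnaSequence,
    mrna: RnaSequence,
    max_interval: int = 20,
    model: EnergyModel = DEFAULT_MODEL,
    max_loop: int = 8,
) -> CombinedEnergy | None:
    """Best combined energy over all interval quadruples (i,k; j,l).

    Interval lengths are capped at ``max_interval``.  Returns ``None`` when
    no pairable quadruple exists.  Ties break 5'-most on the miRNA, then on
    the mRNA.
    """
    if max_interval < 4:
        raise ValueError("max_interval must be >= 4")
    n_mi, n_m = len(mirna), len(mrna)

    ed_cache: dict[tuple[str, int, int], float] = {}
    pu_cache: dict[tuple[str, int, int], float] = {}

    def pu(seq: RnaSequence, a: int, b: int) -> float:
        key = (seq.id, a, b)
        if key not in pu_cache:
            pu_cache[key] = unpaired_probability(seq, a, b, model)
        return pu_cache[key]

    def ed(seq: RnaSequence, a: int, b: int) -> float:
        key = (seq.id, a, b)
        if key not in ed_cache:
            ed_cache[key] = -model.rt * math.log(pu(seq, a, b))
        return ed_cache[key]

    best: CombinedEnergy | None = None
    best_key: tuple | None = None
    for i in range(1, n_mi + 1):
        for l in range(n_m, 0, -1):
            if not can_pair(mirna.base(i), mrna.base(l)):
                continue
            p_max = min(n_mi, i + max_interval - 1)
            q_min = max(1, l - max_interval + 1)
            F = _hybrid_table(mirna, mrna, i, l, p_max, q_min, model, max_loop)
            for (k, j), path_e in F.items():
                if (i == k) != (j == l):
                    continue
                dangles = {}
                pu_mi = pu(mirna, i, k)
                if i > 1:
                    dangles["mirna_5p"] = pu(mirna, i - 1, k) / pu_mi * model.dangle_energy
                if k < n_mi:
                    dangles["mirna_3p"] = pu(mirna, i, k + 1) / pu_mi * model.dangle_energy
                pu_m = pu(mrna, j, l)
                if j > 1:
                    dangles["mrna_5p"] = pu(mrna, j - 1, l) / pu_m * model.dangle_energy
                if l < n_m:
                    dangles["mrna_3p"] = pu(mrna, j, l + 1) / pu_m * model.dangle_energy
                cand = CombinedEnergy(
                    mirna_interval=(i, k),
                    mrna_interval=(j, l),
                    e_hybrid=path_e + model.duplex_init,
                    ed_mirna=ed(mirna, i, k),
                    ed_mrna=ed(mrna, j, l),
                    dangle_terms=dangles,
                )
                key = (cand.total, i, k, j, l)
                if best_key is None or key < best_key:
                    best, best_key = cand, key
    return best
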