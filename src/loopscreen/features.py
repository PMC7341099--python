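"""Interaction feature vectors: 226 RNA dimensions + 1024 fingerprint bits.

The RNA block describes the joined miRNA-mRNA sequence in two categories:

* global sequence features - length, GC content, mono-/di-/tri-nucleotide
  ratios (86 values);
* secondary-structure features of the MFE fold - base-pair counts and
  densities, loop-class counts, loop sizes, windowed pair densities,
  paired-state composition ratios and positional pairing indicators
  (140 values).

Linker placeholders are excluded from every composition count and treated
as unpaired in structure features.  The manifest is data: an ordered table
of (name, category, extractor, params) that is serialized alongside any
trained model, so an alternative schema can be dropped in.

The molecule block is a 1024-bit circular (Morgan, radius 2) fingerprint
of the canonicalized SMILES.  The joined vector has 226 + 1024 = 1250
dimensions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .fold import fold_mfe
from .loops import detect_loops
from .params import DEFAULT_MODEL, EnergyModel
from .sequences import LINKER, JoinedInteraction, RnaSequence, iter_kmers
from .structure import SecondaryStructure

RDLogger.DisableLog("rdApp.*")

BASES = ("A", "C", "G", "U")
DINUCLEOTIDES = tuple("".join(p) for p in itertools.product(BASES, repeat=2))
TRINUCLEOTIDES = tuple("".join(p) for p in itertools.product(BASES, repeat=3))
PAIR_STATES = ("p", "u")
WINDOW_SIZES = (5, 10, 15, 20, 25, 30, 40, 50)
LOOP_CLASS_FEATURES = ("stack", "hairpin", "bulge", "interior", "multiloop")
POSITIONAL_RANGE = 50

RNA_FEATURE_DIM = 226
FINGERPRINT_BITS = 1024
INTERACTION_FEATURE_DIM = RNA_FEATURE_DIM + FINGERPRINT_BITS


class FeatureError(ValueError):
    """Feature extraction failure (e.g. unparseable SMILES)."""

    def __init__(self, message: str, record_id: str | None = None):
        super().__init__(message)
        self.record_id = record_id


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    category: str  # "global" | "structure"
    extractor: str
    params: tuple = ()


@dataclass(frozen=True)
class FeatureManifest:
    entries: tuple[FeatureSpec, ...]
    version: str = "loopscreen-226-v1"

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "category": [e.category for e in self.entries],
                "extractor": [e.extractor for e in self.entries],
                "params": [json.dumps(list(e.params)) for e in self.entries],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, version: str = "custom") -> "FeatureManifest":
        entries = tuple(
            FeatureSpec(
                name=r["name"],
                category=r["category"],
                extractor=r["extractor"],
                params=tuple(json.loads(r["params"])),
            )
            for _, r in df.iterrows()
        )
        return cls(entries=entries, version=version)


def default_manifest() -> FeatureManifest:
    """The versioned default: 86 global + 140 structure = 226 features."""
    entries: list[FeatureSpec] = [
        FeatureSpec("length", "global", "length"),
        FeatureSpec("gc_content", "global", "gc_content"),
    ]
    entries += [FeatureSpec(f"mono_{b}", "global", "mono_ratio", (b,)) for b in BASES]
    entries += [FeatureSpec(f"di_{d}", "global", "di_ratio", (d,)) for d in DINUCLEOTIDES]
    entries += [FeatureSpec(f"tri_{t}", "global", "tri_ratio", (t,)) for t in TRINUCLEOTIDES]
    entries += [
        FeatureSpec("bp_count", "structure", "bp_count"),
        FeatureSpec("bp_density", "structure", "bp_density"),
    ]
    entries += [
        FeatureSpec(f"n_{c}", "structure", "loop_class_count", (c,))
        for c in LOOP_CLASS_FEATURES
    ]
    entries += [
        FeatureSpec("mean_loop_size", "structure", "mean_loop_size"),
        FeatureSpec("max_loop_size", "structure", "max_loop_size"),
    ]
    entries += [
        FeatureSpec(f"win_bp_density_{w}", "structure", "window_bp_density", (w,))
        for w in WINDOW_SIZES
    ]
    entries += [
        FeatureSpec(f"state_{b}{s}", "structure", "state_mono_ratio", (b, s))
        for b in BASES
        for s in PAIR_STATES
    ]
    entries += [
        FeatureSpec(f"state_{d}{s1}{s2}", "structure", "state_di_ratio", (d, s1, s2))
        for d in DINUCLEOTIDES
        for s1 in PAIR_STATES
        for s2 in PAIR_STATES
    ]
    entries += [
        FeatureSpec(f"paired_pos_{p}", "structure", "positional_paired", (p,))
        for p in range(1, POSITIONAL_RANGE + 1)
    ]
    entries.append(FeatureSpec("unpaired_fraction", "structure", "unpaired_fraction"))
    manifest = FeatureManifest(entries=tuple(entries))
    assert len(manifest) == RNA_FEATURE_DIM
    return manifest


DEFAULT_MANIFEST = default_manifest()


# ---------------------------------------------------------------------------
# extractors
# ---------------------------------------------------------------------------

def _kmer_ratios(bases: str, k: int, vocabulary: tuple[str, ...]) -> dict:
    counts = {w: 0 for w in vocabulary}
    total = 0
    for w in iter_kmers(bases, k):
        counts[w] += 1
        total += 1
    if total:
        return {w: c / total for w, c in counts.items()}
    return counts


def rna_global_features(seq: RnaSequence) -> dict:
    """Global sequence feature groups (linker symbols excluded)."""
    effective = seq.bases.replace(LINKER, "")
    if not effective:
        raise FeatureError("sequence has no non-linker bases")
    n = len(effective)
    return {
        "length": float(n),
        "gc_content": (effective.count("G") + effective.count("C")) / n,
        "mono_ratio": {b: effective.count(b) / n for b in BASES},
        "di_ratio": _kmer_ratios(seq.bases, 2, DINUCLEOTIDES),
        "tri_ratio": _kmer_ratios(seq.bases, 3, TRINUCLEOTIDES),
    }


def rna_structure_features(
    seq: RnaSequence,
    structure: SecondaryStructure,
    model: EnergyModel = DEFAULT_MODEL,
) -> dict:
    """Secondary-structure feature groups of a fold."""
    n = len(seq)
    if structure.length != n:
        raise FeatureError("structure/sequence length mismatch")
    paired = [structure.is_paired(p) for p in range(1, n + 1)]
    loops = [lp for lp in detect_loops(structure, seq=seq, model=model) if lp.closing_pair]
    class_counts = {c: 0 for c in LOOP_CLASS_FEATURES}
    for lp in loops:
        class_counts[lp.loop_class] += 1
    sizes = [lp.size for lp in loops]
    window = {}
    for w in WINDOW_SIZES:
        if n <= w:
            window[w] = sum(paired) / n
        else:
            counts = [sum(paired[s : s + w]) / w for s in range(n - w + 1)]
            window[w] = float(np.mean(counts))
    state_mono = {(b, s): 0 for b in BASES for s in PAIR_STATES}
    total_mono = 0
    for p in range(n):
        b = seq.bases[p]
        if b == LINKER:
            continue
        state_mono[(b, "p" if paired[p] else "u")] += 1
        total_mono += 1
    if total_mono:
        state_mono = {k: v / total_mono for k, v in state_mono.items()}
    state_di = {
        (d, s1, s2): 0 for d in DINUCLEOTIDES for s1 in PAIR_STATES for s2 in PAIR_STATES
    }
    total_di = 0
    for p in range(n - 1):
        d = seq.bases[p : p + 2]
        if LINKER in d:
            continue
        key = (d, "p" if paired[p] else "u", "p" if paired[p + 1] else "u")
        state_di[key] += 1
        total_di += 1
    if total_di:
        state_di = {k: v / total_di for k, v in state_di.items()}
    bp_count = len(structure.pairs)
    return {
        "bp_count": float(bp_count),
        "bp_density": bp_count / n,
        "loop_class_count": {c: float(v) for c, v in class_counts.items()},
        "mean_loop_size": float(np.mean(sizes)) if sizes else 0.0,
        "max_loop_size": float(max(sizes)) if sizes else 0.0,
        "window_bp_density": window,
        "state_mono_ratio": state_mono,
        "state_di_ratio": state_di,
        "positional_paired": {
            p: float(paired[p - 1]) if p <= n else 0.0
            for p in range(1, POSITIONAL_RANGE + 1)
        },
        "unpaired_fraction": sum(1 for x in paired if not x) / n,
    }


@dataclass(frozen=True)
class RnaFeatureVector:
    values: np.ndarray
    manifest: FeatureManifest
    source_id: str

    def __len__(self) -> int:
        return len(self.values)


def rna_feature_vector(
    interaction: JoinedInteraction | RnaSequence,
    manifest: FeatureManifest = DEFAULT_MANIFEST,
    model: EnergyModel = DEFAULT_MODEL,
    structure: SecondaryStructure | None = None,
) -> RnaFeatureVector:
    """Fold the (joined) sequence and assemble features in manifest order."""
    seq = interaction.joined if isinstance(interaction, JoinedInteraction) else interaction
    if structure is None:
        structure = fold_mfe(seq, model)
    groups = rna_global_features(seq)
    groups.update(rna_structure_features(seq, structure, model))
    values = np.empty(len(manifest))
    for idx, spec in enumerate(manifest.entries):
        g = groups[spec.extractor]
        if not spec.params:
            values[idx] = g
        elif len(spec.params) == 1:
            values[idx] = g[spec.params[0]]
        else:
            values[idx] = g[tuple(spec.params)]
    if not np.isfinite(values).all():
        raise FeatureError(f"non-finite feature values for {seq.id}")
    return RnaFeatureVector(values=values, manifest=manifest, source_id=seq.id)


# ---------------------------------------------------------------------------
# molecule fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeFingerprint:
    bits: np.ndarray
    radius: int
    smiles_canonical: str

    def __len__(self) -> int:
        return len(self.bits)


def molecule_fingerprint(
    smiles: str,
    n_bits: int = FINGERPRINT_BITS,
    radius: int = 2,
    record_id: str | None = None,
) -> MoleculeFingerprint:
    """Hashed circular (Morgan) fingerprint of a canonicalized molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeatureError(f"unparseable SMILES: {smiles!r}", record_id=record_id)
    canonical = Chem.MolToSmiles(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(Chem.MolFromSmiles(canonical))
    bits = np.zeros(n_bits, dtype=np.float64)
    bits[list(fp.GetOnBits())] = 1.0
    return MoleculeFingerprint(bits=bits, radius=radius, smiles_canonical=canonical)


@dataclass(frozen=True)
class InteractionFeatureVector:
    rna: RnaFeatureVector
    molecule: MoleculeFingerprint
    joined: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "joined", np.concatenate([self.rna.values, self.molecule.bits])
        )

    def __len__(self) -> int:
        return len(self.joined)


def interaction_features(
    interaction: JoinedInteraction | RnaSequence,
    smiles: str,
    manifest: FeatureManifest = DEFAULT_MANIFEST,
    model: EnergyModel = DEFAULT_MODEL,
) -> InteractionFeatureVector:
    """RNA features joined with the molecule fingerprint (default 1250-dim)."""
    return InteractionFeatureVector(
        rna=rna_feature_vector(interaction, manifest, model),
        molecule=molecule_fingerprint(smiles),
    )
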