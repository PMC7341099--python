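"""Synthetic fixtures for every input the pipeline consumes.

The interaction-table generator emulates a curated RNA-motif / small-
molecule table: RNA sequences are stem-loops whose loop motif defines a
latent class, molecules are drawn from scaffold families with distinct
circular-fingerprint substructures, and positive (targeted) pairs couple
class to family at a controllable rate (``motif_strength``).  At strength
1 the class-family association is a fully learnable planted signal; at 0
pairs are random and no model should beat chance.  Stated fractions of
corrupt SMILES / sequences exercise the curation step.

Everything is deterministic under a seed and ships a ground-truth key
sufficient to verify downstream stages without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ranking import MAX_MODES
from .sequences import RnaSequence, reverse_complement

BASES = "ACGU"

#: scaffold per molecule family - distinct ring systems, distinct fingerprints
MOLECULE_SCAFFOLDS = (
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "c1ccoc1",         # furan
    "c1ccsc1",         # thiophene
    "C1CCCCC1",        # cyclohexane
    "c1ccc2ccccc2c1",  # naphthalene
    "c1cnc[nH]1",      # imidazole
    "c1cncnc1",        # pyrimidine
    "c1cc[nH]c1",      # pyrrole
    "c1cnco1",         # oxazole
    "c1cncs1",         # thiazole
    "c1cnccn1",        # pyrazine
)
#: homologous side chains distinguish molecules within a family while
#: keeping their fingerprints close (the family signal stays coherent)
SIDE_CHAINS = ("C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC")

#: hairpin-loop motif per RNA class - the plantable composition signal.
#: Motifs use only A and C so the loop cannot pair internally or invade
#: the G/C stems.
LOOP_MOTIFS = (
    "AAAAAAAA", "CCCCCCCC", "ACACACAC", "CACACACA", "AACCAACC", "CCAACCAA",
    "AAACAAAC", "CCCACCCA", "ACCAACCA", "CAACCAAC", "AAAACCCC", "CCCCAAAA",
)
STEM_ARMS = ("GCGCGC", "GGCGCC", "GCCGGC")


@dataclass(frozen=True)
class GeneratorConfig:
    n_rna: int = 36
    n_molecules: int = 36
    n_positive: int = 100
    invalid_smiles_fraction: float = 0.0
    invalid_sequence_fraction: float = 0.0
    motif_strength: float = 1.0
    seed: int = 0
    n_classes: int = 12

    def __post_init__(self) -> None:
        for f in (self.invalid_smiles_fraction, self.invalid_sequence_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must lie in [0, 1]")
        if self.n_positive > self.n_rna * self.n_molecules:
            raise ValueError("n_positive exceeds the RNA x molecule grid")
        if not 1 <= self.n_classes <= len(MOLECULE_SCAFFOLDS):
            raise ValueError(f"n_classes must be in 1..{len(MOLECULE_SCAFFOLDS)}")


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def make_rna(rna_class: int, n_classes: int) -> str:
    """A foldable stem-loop whose hairpin-loop motif encodes the class.

    RNAs of the same class share the identical motif sequence, mirroring a
    curated motif table where one motif entry is paired with several
    molecules.
    """
    arm = STEM_ARMS[rna_class % len(STEM_ARMS)]
    motif = LOOP_MOTIFS[rna_class % n_classes]
    return arm + motif + reverse_complement(arm)


def make_smiles(family: int, variant: int) -> str:
    scaffold = MOLECULE_SCAFFOLDS[family % len(MOLECULE_SCAFFOLDS)]
    return SIDE_CHAINS[variant % len(SIDE_CHAINS)] + scaffold


def generate_interaction_table(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, dict]:
    """Interaction table + ground-truth key.

    Positives pair an RNA with a molecule of its matched family with
    probability ``motif_strength``; otherwise the pair is drawn uniformly
    from the grid, so at strength 0 the table carries no class-family
    association at all.  ``invalid_*_fraction`` of the rows are corrupted
    in place to exercise curation.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_classes
    rna_class = {f"RNA{i:03d}": i % k for i in range(config.n_rna)}
    rna_seq = {rid: make_rna(cls, k) for rid, cls in rna_class.items()}
    mol_family = {f"MOL{j:03d}": j % k for j in range(config.n_molecules)}
    # variant index advances once per family cycle so every molecule id maps
    # to a distinct structure
    mol_smiles = {
        mid: make_smiles(fam, j // k)
        for j, (mid, fam) in enumerate(mol_family.items())
    }
    rna_ids = list(rna_class)
    mol_ids = list(mol_family)
    grid = [(r, m) for r in rna_ids for m in mol_ids]
    matched = [p for p in grid if rna_class[p[0]] == mol_family[p[1]]]
    rng.shuffle(matched)
    rng.shuffle(grid)
    # motif_strength = probability a positive is a matched (class == family)
    # pair; the remainder are uniform grid pairs, so strength 0 carries no
    # association at all
    used: set = set()
    pairs: list[tuple[str, str]] = []
    mi = mm = 0
    while len(pairs) < config.n_positive:
        take_matched = rng.random() < config.motif_strength and mi < len(matched)
        if take_matched:
            p = matched[mi]
            mi += 1
        else:
            if mm >= len(grid):  # pragma: no cover - guarded by config
                raise ValueError("RNA x molecule grid exhausted")
            p = grid[mm]
            mm += 1
        if p in used:
            continue
        used.add(p)
        pairs.append(p)
    df = pd.DataFrame(
        {
            "rna_id": [r for r, _ in pairs],
            "rna_sequence": [rna_seq[r] for r, _ in pairs],
            "molecule_id": [m for _, m in pairs],
            "smiles": [mol_smiles[m] for _, m in pairs],
            "label": "targeted",
        }
    )
    n = len(df)
    n_bad_smiles = int(round(config.invalid_smiles_fraction * n))
    n_bad_seq = int(round(config.invalid_sequence_fraction * n))
    bad_rows = rng.choice(n, size=min(n, n_bad_smiles + n_bad_seq), replace=False)
    smiles_rows = [int(r) for r in bad_rows[:n_bad_smiles]]
    seq_rows = [int(r) for r in bad_rows[n_bad_smiles : n_bad_smiles + n_bad_seq]]
    for r in smiles_rows:
        df.loc[r, "smiles"] = f"not_a_smiles_{r}"
    for r in seq_rows:
        df.loc[r, "rna_sequence"] = f"ACGU123XYZ{r}"
    truth = {
        "rna_class": rna_class,
        "mol_family": mol_family,
        "rna_sequences": rna_seq,
        "mol_smiles": mol_smiles,
        "corrupt_smiles_rows": sorted(smiles_rows),
        "corrupt_sequence_rows": sorted(seq_rows),
        "matched_pairs": [list(p) for p in pairs if rna_class[p[0]] == mol_family[p[1]]],
    }
    return df, truth


def generate_mirna_mrna_pair(
    seed: int,
    seed_complement: bool = True,
    sequester_site: bool = False,
    mirna_length: int = 22,
    complement_span: tuple[int, int] | None = None,
) -> tuple[RnaSequence, RnaSequence, dict]:
    """A (miRNA, UTR) pair with an optionally planted, optionally
    sequestered target site.

    With ``seed_complement``, the UTR contains the exact reverse complement
    of miRNA positions ``complement_span`` (default 2..L-2, covering the
    seed) at a recorded coordinate.  With ``sequester_site``, a downstream
    arm complementary to the planted site folds it into a stable hairpin,
    suppressing its unpaired probability.
    """
    rng = np.random.default_rng(seed)
    mirna = RnaSequence(
        id=f"synthetic-mir-{seed}",
        bases=_random_bases(rng, mirna_length),
        kind="miRNA",
    )
    span = complement_span or (2, mirna_length - 2)
    site = reverse_complement(mirna.subsequence(*span))
    # fixed-length flanks for the sequestered construct push the UTR past
    # the exact-enumeration limit, so accessibility uses the
    # partition-function route (the hairpin arm makes enumeration explode)
    if sequester_site:
        flank5 = _random_bases(rng, 6)
        flank3 = _random_bases(rng, 6)
    else:
        flank5 = _random_bases(rng, int(rng.integers(3, 8)))
        flank3 = _random_bases(rng, int(rng.integers(3, 8)))
    if seed_complement:
        if sequester_site:
            core = site + "GAAA" + reverse_complement(site)
        else:
            core = site
    else:
        core = "".join(rng.permutation(list(site)))
    utr_bases = flank5 + core + flank3
    truth = {
        "site_start": len(flank5) + 1,
        "site_end": len(flank5) + len(site),
        "complement_span": list(span),
        "planted": bool(seed_complement),
        "sequestered": bool(sequester_site),
    }
    utr = RnaSequence(id=f"synthetic-utr-{seed}", bases=utr_bases, kind="mRNA")
    return mirna, utr, truth


_LOG_TEMPLATE = """AutoDock Vina v1.2.3
#################################################################
# If you used AutoDock Vina in your work, please cite:          #
#################################################################

Performing docking (random seed: {seed}) ...

mode |   affinity | dist from best mode
     | (kcal/mol) | rmsd l.b.| rmsd u.b.
-----+------------+----------+----------
{rows}
"""


def generate_docking_logs(
    n_molecules: int,
    modes_per_mol: int = MAX_MODES,
    seed: int = 0,
    outdir=None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Vina-style logs with known affinities + a truth table.

    Returns ({molecule_id: log text}, truth) where truth holds each
    molecule's affinities and their mean.  Caps at nine modes.
    """
    if not 1 <= modes_per_mol <= MAX_MODES:
        raise ValueError(f"modes_per_mol must be in 1..{MAX_MODES}")
    rng = np.random.default_rng(seed)
    logs, rows = {}, []
    for j in range(n_molecules):
        mid = f"MOL{j:03d}"
        aff = np.sort(np.round(rng.uniform(-9.5, -4.0, size=modes_per_mol), 1))
        body = "\n".join(
            f"{m + 1:>4}       {a:6.1f}      {rng.uniform(0, 5):5.3f}      {rng.uniform(0, 8):5.3f}"
            for m, a in enumerate(aff)
        )
        logs[mid] = _LOG_TEMPLATE.format(seed=seed, rows=body)
        rows.append(
            {
                "molecule_id": mid,
                "affinities": list(map(float, aff)),
                "mean_affinity": float(np.mean(aff)),
            }
        )
    truth = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for mid, text in logs.items():
            (outdir / f"{mid}.log").write_text(text)
    return logs, truth
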