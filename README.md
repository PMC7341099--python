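# loopscreen

Virtual screening of small molecules that target the loops formed by
miRNA–mRNA duplexes.

When a mature miRNA binds the 3′-UTR of its target mRNA, the imperfect
duplex leaves unpaired regions — loops — concentrated near the miRNA seed
region. These loops are structurally distinctive and druggable: a small
molecule that binds a specific miRNA–mRNA loop can block the silencing of
that one target without touching the miRNA's other targets. `loopscreen`
implements the computational side of that strategy as a library and
command-line tool for researchers screening compound libraries against
RNA motifs:

* **RNA secondary structure.** Joined miRNA–mRNA sequences (5′→3′, with
  optional unpairable placeholder linkers) are folded by a nested dynamic
  programme under a loop-additive energy model: pairs at least three bases
  apart, one partner per base, no pseudoknots. Every fold decomposes into
  loops (stack, hairpin, bulge, interior, multiloop) whose energies sum
  exactly to the structure energy; a stacked pair is a loop of size zero.
* **Target-site prediction.** A weighted complementarity alignment in the
  miRanda style: score cutoff 120, affine gaps (−9 open, −4 extend),
  position-weighted seed matches, miRNA position 1 and the last two 3′
  bases excluded, and at most one G:U or mismatch at seed positions 2–7.
  Canonical sites carry a perfect Watson–Crick 6-mer at positions 2–7.
* **Accessibility-corrected interaction energy.** For intervals i..k of
  the miRNA and j..l of the mRNA,

  `E[i,k; j,l] = Ehybrid[i,k; j,l] + ED_miRNA[i,k] + ED_mRNA[j,l] + dangle terms`

  where `Ehybrid` is the minimal intermolecular duplex energy with paired
  interval ends (plus an initiation penalty) and `ED = −RT·log Pu` prices
  the opening of intramolecular structure (`Pu` = Boltzmann probability
  that the interval is unpaired). Flank dangles are weighted by the
  conditional probability that the flanking base is also free.
* **Interaction features and the knowledge-based model.** Each RNA motif
  is described by 226 features (global sequence composition + secondary-
  structure descriptors), each molecule by a 1024-bit Morgan fingerprint;
  the joined 1250-dimensional vector feeds a classifier. The protocol is
  fixed: 3 sampled negatives per curated positive, a stratified 4/5–1/5
  split, 10-fold cross-validated comparison of seven classifier families
  (selection bound: mean > 0.8, SD < 0.2), and a production random forest
  (entropy criterion, 200 trees, random_state 100).
* **Structure-based scores and consensus.** Docking logs (Vina-style mode
  tables, at most nine conformations) are parsed, each candidate scored by
  its mean binding affinity, and the knowledge-based and structure-based
  rankings combined by rank sum; candidates in the top K of both lists are
  flagged `dual_high`.
* **Synthetic fixtures.** A seeded generator emulates every input —
  curated interaction tables with a plantable motif→scaffold association
  and corrupt records, miRNA/UTR pairs with planted (optionally
  sequestered) sites, and docking logs with known affinities — so the full
  pipeline is testable offline.

## Worked example

```python
from loopscreen import RnaSequence, fold_mfe, detect_loops

seq = RnaSequence(id="stemloop", bases="GCGCGCAAAAAAAAGCGCGC")
s = fold_mfe(seq)
print(s.dot_bracket, s.energy)
```

prints `((((((........)))))) -18.41`: a six-pair stem (five stacks at
−3.5 kcal/mol each) closed by a hairpin loop of size 8 whose A-rich
composition is exactly the kind of loop descriptor the screening model
consumes.

```python
from loopscreen import generate_mirna_mrna_pair, scan_utr

mirna, utr, truth = generate_mirna_mrna_pair(seed=7)
site = scan_utr(mirna, utr)[0]
print(site.mrna_interval, site.score, site.canonical)
```

prints `(5, 23) 130.0 True` — the planted site is recovered at its
recorded coordinate with a perfect seed (score 130 clears the cutoff of
120; the duplex is reported 5′→3′ miRNA against 3′→5′ UTR).

Training the production forest on a synthetic interaction table with a
fully planted motif→scaffold signal:

```python
from loopscreen import (GeneratorConfig, generate_interaction_table,
                        load_interaction_table, build_dataset, split_dataset,
                        train_model, rf_spec, predict_scores)

table, _ = generate_interaction_table(GeneratorConfig(seed=7))
curated, rejected = load_interaction_table(table)
ds = split_dataset(build_dataset(curated, seed=7), seed=7)
model = train_model(ds, rf_spec())
```

yields a held-out accuracy of 0.975 on the 80-record test split, and
`predict_scores` ranks candidate molecules by their probability of
targeting the motif (e.g. MOL013 at 0.95 down to MOL031 at 0.38 for a
mixed candidate set), the list that the `rank` step then merges with
docking scores.

The same pipeline is available from the shell:

```bash
loopscreen simulate --outdir sim --seed 11
loopscreen curate --table sim/interactions.csv --out curated.csv --log rejected.csv
loopscreen train --table curated.csv --seed 11 --out model.joblib
loopscreen screen --model model.joblib --candidates candidates.csv --out kb.tsv
loopscreen rank --kb kb.tsv --sb-logs 'sim/docking_logs/*.log' --out ranking.tsv
```

plus `fold`, `loops`, `sites`, `energy`, `scan-mutations`,
`placeholder-check`, `features`, `build-dataset` and `compare`
subcommands; every command writes a `run_manifest.json` beside its output
and is byte-reproducible under a fixed seed.

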