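# Methods

This note documents the models, parameters and numerical choices behind
`loopscreen`, and what its synthetic benchmarks do and do not demonstrate.

## Secondary-structure model

A secondary structure on an RNA `r_1…r_n` is a set of canonical pairs
(Watson–Crick or G:U) subject to three constraints: paired bases are more
than three positions apart (no sharp U-turns), each base has at most one
partner, and pairs never cross (no pseudoknots). Every structure
decomposes uniquely into loops — for each pair (i, j), the loop consists
of (i, j), the pairs immediately interior to it, and the unpaired
stretches between them; a stacked pair is a loop of size zero; unpaired
bases outside all pairs form the energy-free exterior loop.

The energy is loop-additive. The embedded model assigns each pair a
stabilization attached to the loop it closes — G:C −3.0, A:U −2.0,
G:U −1.0 kcal/mol — plus a class/size term:

| loop | term (kcal/mol) |
|---|---|
| stack | −0.5 (cooperativity bonus) |
| hairpin of size n | 1.5, 1.7, 1.8, 2.0 for n = 3..6; +0.3·ln(n/6) beyond |
| bulge of size n | 1.0, 1.4, 1.8 for n = 1..3; +0.3·ln(n/3) beyond |
| interior of size n | 1.0, 1.3, 1.6 for n = 2..4; +0.3·ln(n/4) beyond |
| multiloop | 2.0 + 0.3·branches + 0.1·unpaired |

These are deliberately simple, documented magnitudes rather than a full
thermodynamic table: the per-pair form keeps an isolated short helix
(e.g. the single G:C hairpin of `GAAAC`) stabilizing, which makes every
fold verifiable against exhaustive enumeration under the identical model
— the property the test suite leans on. An external thermodynamic folder
can be substituted through the `folder` hook of `fold_mfe` without
touching the rest of the pipeline.

The MFE recursion is the classical nested scheme — `V(i,j)` for closed
intervals (hairpin, two-loop, multiloop closure), `WM`/`WM2` for
multiloop segments with ≥1/≥2 branches, `W(j)` for the exterior — with
`V` and the segment tables interleaved by ascending span. Interior loops
are not size-capped (sequences here are short). Tie-breaking: the
traceback scans candidates in a fixed documented order (hairpin, then
two-loops by ascending (k, l), then multiloop split points ascending) and
takes the first optimum, so results are deterministic; the pair set is
not guaranteed to be the lexicographically smallest among co-optima.

Joined miRNA–mRNA sequences use the placeholder symbol `N` for the
linker: `N` can never pair and is excluded from composition statistics,
so the fold of the biological part is invariant to linker insertion by
construction; `placeholder_robustness` measures that invariance as
`|P_l ∩ P_0| / max(|P_l|, |P_0|)` over linker-independent pair
coordinates (1.0 means identical folds; extra stem pairs enabled by a
long linker lower the score symmetrically).

## Ensemble quantities

The unpaired probability Pu[i..k] — the Boltzmann probability at
T = 310.15 K (R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹) that all of i..k is
unpaired — is computed by exhaustive structure enumeration for sequences
up to 30 nt and, above that, as a ratio of partition functions (all
structures vs. structures with i..k barred from pairing). The partition
function uses an unambiguous grammar (multiloop segments condition on
their last branch), so every structure is counted exactly once; the two
routes agree to better than 1e-9 on their overlapping range and that
agreement is asserted in the tests. Ensembles and partition functions
are cached per sequence.

## Accessibility-corrected interaction energy

The combined energy of binding miRNA interval i..k to mRNA interval j..l
is the sum of: the minimal intermolecular duplex energy `Ehybrid` with
both interval ends paired (computed by a forward DP over antiparallel
pair chains with per-strand loop caps, default 8, plus a +4.1 kcal/mol
initiation penalty and an optional per-position weight, default 0);
opening penalties `ED = −RT·log Pu` for both intervals; and dangling-end
terms, −0.3 kcal/mol per available flank base, weighted by the
conditional probability `Pu(flank ∪ interval)/Pu(interval)` that the
flank is free given the interval is. A flank beyond the sequence end
contributes nothing. The total is assembled as the literal sum of these
components; tests assert bit-for-bit additivity. `minimum_energy_
interaction` scans all interval quadruples (lengths capped, default 20)
and breaks ties 5′-most on the miRNA, then the mRNA.

## Target-site alignment

The site predictor aligns the miRNA core — positions 2..L−2; the first
5′ base and last two 3′ bases are excluded — against the reversed UTR
(antiparallel duplex convention). Substitution scores: Watson–Crick
match +5, G:U wobble +2, mismatch −3, doubled at seed positions 2–8;
affine gaps at −9 for the first gap base and −4 for each additional.
At most one non-Watson–Crick event (wobble, mismatch, or gap) is allowed
inside seed positions 2–7 — the event count is carried in the DP state,
so the constraint can never be violated in output. Alignments begin and
end with a paired column, must clear the score cutoff (default 120), and
overlapping sites are resolved greedily by score, then 5′-most position.
Reported scores are exactly reproducible from the gapped strings, and the
DP optimum is checked against an independently written memoized recursion.

## Feature schema

The RNA feature vector is defined by a versioned manifest of exactly 226
entries in two categories. Global (86): length, GC content, 4 mono-, 16
di- and 64 tri-nucleotide ratios. Structure (140): base-pair count and
density; stack/hairpin/bulge/interior/multiloop counts; mean and maximum
loop size; mean windowed pair densities for windows {5, 10, 15, 20, 25,
30, 40, 50}; 8 paired-state mononucleotide ratios (base × paired state);
64 paired-state dinucleotide ratios; 50 positional pairing indicators
(positions 1–50, zero-padded); and the unpaired fraction. Ratio families
each sum to one on sequences long enough to populate them. Linker
symbols are excluded from every composition count and counted as
unpaired in structure features. The manifest is data — an ordered table
serialized with every trained model — so an alternative schema of the
same length can be dropped in without code changes. Molecules contribute
a 1024-bit hashed circular (Morgan) fingerprint of radius 2, computed on
the canonicalized structure so SMILES spelling cannot change the bits;
226 + 1024 = 1250 dimensions in total.

## Screening protocol

Curation drops records whose RNA sequence is not valid RNA/DNA or whose
SMILES does not parse, logging each removal. Every curated pair is a
positive; negatives are drawn uniformly without replacement from the
unobserved RNA × molecule grid at exactly 3 per positive. The split is
4/5 train, 1/5 test, stratified by label (the class ratio is 1:3, so
unstratified splits would add needless variance). Model selection runs
stratified 10-fold cross-validation over seven families — logistic
regression, linear discriminant analysis, k-nearest neighbours, decision
tree, naive Bayes, support-vector machine, random forest — and flags a
family when mean > 0.8 and SD < 0.2 hold jointly for accuracy and ROC
AUC, recomputed definitionally from the fold table. The production model
is a random forest with `criterion="entropy"`, `n_estimators=200`,
`random_state=100`, `min_samples_leaf=1`, `min_samples_split=2`,
`bootstrap=True`, `min_impurity_decrease=0.0`, and `max_features="auto"`
read as the classical sqrt rule for classification. Trained artifacts
embed the manifest, spec and seed, and reload to identical predictions.

## Structure-based scores and consensus

Docking logs in the Vina mode-table dialect are parsed tolerantly of
banners; at most nine conformations are kept, in listed order. A
candidate's structure-based score is the arithmetic mean of its mode
affinities. Rankings combine by rank sum (Borda and top-K-intersection
are available behind a flag), with ties broken by the better
knowledge-based rank and then molecule id, so the combination is
invariant to input order; `dual_high` marks candidates in the top K
(default 10) of both lists.

## Synthetic data: what it emulates and what it does not

The interaction-table generator emulates a curated RNA-motif/small-
molecule table. RNAs are 20-nt stem-loops whose hairpin-loop motif (8 nt
over {A, C}, unpairable against the G/C stems) defines one of 12 latent
classes; RNAs of a class share the identical motif sequence, as motif
entries in a curated table do. Molecules belong to 12 scaffold families
(benzene, pyridine, furan, thiophene, cyclohexane, naphthalene,
imidazole, pyrimidine, pyrrole, oxazole, thiazole, pyrazine) with
homologous alkyl side chains distinguishing members within a family.
`motif_strength` is the probability that a positive pair couples an RNA
to a molecule of its matched family; the remainder are uniform grid
pairs, so at strength 0 the table carries no association. Defaults (36
RNAs × 36 molecules, 100 positives) were chosen so that at full strength
the positives cover nearly the whole matched set, leaving the sampled
negatives almost free of label noise. Corrupt rows (stated fractions of
invalid SMILES / sequences) exercise curation; a ground-truth key records
classes, families and corrupted rows.

The planted signal is a class↔family *matching* — a pure interaction
with almost no marginal effect per feature — which is the honest
difficulty of motif-specific screening; the benchmark therefore shows
that the pipeline can learn a compositional RNA-motif/chemotype rule and
rank by it, with held-out accuracy above 0.9 at full strength and
ground-truth-informative features leading the importances. The null
(strength 0) is evaluated by generalization to an independently
generated dataset, which sits at ROC AUC 0.5 ± a few points when
averaged over seeds; within-dataset cross-validation is *not* used for
the null because with repeated RNA and molecule entities, holding out a
positive deflates its entities' training rates — the standard dyadic
leakage — biasing chance-level AUC below 0.5. What passing does not
show: real binding data have noisy labels, heterogeneous RNA lengths and
structures, correlated chemistry, and no clean class structure; absolute
performance numbers on the synthetic benchmark say nothing about
performance on experimental tables beyond protocol correctness.

The miRNA/UTR generator plants the exact reverse complement of miRNA
positions 2..L−2 (configurable) at a recorded UTR coordinate; the
sequestered variant adds a downstream complementary arm that folds the
site into a stable hairpin, and uses fixed 6-nt flanks so the construct
exceeds the enumeration limit and exercises the partition-function
accessibility route. Docking-log fixtures carry known affinities so the
parser and averaging recover ground truth exactly.

## Problem sizes and numerical choices

The test suite and acceptance script run on one CPU in a few minutes:
folding optimality on 200 random sequences ≤ 22 nt (exhaustive
enumeration is exact there), dual-route accessibility on 100 sequences
≤ 25 nt, alignment optimality on 15×30-nt inputs (pure enumeration of
gapped alignments at that size is combinatorially infeasible, so the
oracle is an independently formulated memoized recursion, with pure
enumeration on smaller toys), learning benchmarks at 400 records ×
1250 features over 10 seeds. Floating-point comparisons use 1e-9
absolute tolerance for energies (sums of table constants), 1e-12 for
additivity identities. Degenerate inputs are defined, not special-cased:
a sequence with no admissible pair folds to the all-unpaired structure
at energy 0; an interval with Pu = 1 has ED = 0 exactly; an empty
candidate universe or infeasible negative ratio raises with the maximum
feasible ratio stated.

## Known limitations

The embedded energy model is a documented simplification, not a fitted
thermodynamic parameter set — absolute energies are not comparable to
laboratory measurements, only rankings and structural patterns are
meaningful. Pseudoknots, suboptimal-structure ensembles beyond the
partition function, 3D modeling and docking execution are out of scope
(docking output is parsed, not produced). The quartic interval scan in
`minimum_energy_interaction` is intended for site-scale sequences, not
full-length UTRs. The miRanda-style weights beyond the published cutoff
and gap penalties (substitution scores, seed weight ×2 at positions 2–8)
are configurable defaults, not fitted values.
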