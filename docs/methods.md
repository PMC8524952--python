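# Methods

This note records the models, parameter choices and numerical conventions
behind `nporigin`, and what the synthetic test bed does and does not show.

## Curation model

Records are tuples (id, SMILES, free-text taxonomy, DOI). The funnel is:

1. **DOI filter.** Keep records whose DOI, after trimming surrounding
   whitespace, has ≥ 10 characters. A missing DOI counts as empty. The
   rule is a literature-traceability proxy, not DOI syntax validation.
2. **Origin resolution.** The taxonomy string is split on commas; each
   trimmed, lower-cased token is tested for *containment* of the keyword
   sets — plant: {plant, plants}; fungi: {fungi, aspergillus}; bacteria:
   {bacteria, bacillus, bacta}; and, for priority resolution only,
   human: {human, homo}, animal: {animal, animals}, marine: {marine}.
   Containment (not equality) is deliberate: free-text annotations embed
   keywords inside species names ("Aspergillus flavus"). When several
   origins match, the resolved label is the highest-priority one in
   human > animal > bacteria > fungi > plant > marine; no match gives
   `unresolved`. The human/animal/marine keyword lists are minimal design
   choices — only the three retained classes have published lists, but
   the priority order forces the other three sets to exist.
3. **Three-class selection** keeps plant/fungi/bacteria records in order.
4. **Profiling.** MW (average isotopic), Fsp3 (sp3 carbons / all
   carbons), Crippen AlogP, HBD/HBA, TPSA, heavy-atom and bond counts,
   and element counts are computed with RDKit. Two SMARTS flags:
   dipeptide `[NX3,NX4+][CH1,CH2][CX3](=[OX1])[NX3,NX4+][CH1,CH2][CX3](=[OX1])[O,N]`
   and glycoside (cyclic N-/O-acetal) `[CR][OR][CHR]([OR0,NR0])[CR]`.
   Flags only annotate; substructures are never removed.
5. **Category.** First match in: glycoside > peptide > high_MW
   (MW ≥ 800) > high_Fsp3 (≥ 0.8) > low_Fsp3 (≤ 0.2) > low_MW (≤ 200) >
   none. The published bin edges double-count boundaries (MW = 200
   belongs to both "≤ 200" and "200 ≤ MW < 800"); we resolve ties toward
   the *flagged* (extreme) bin, i.e. MW = 200 is low_MW, Fsp3 = 0.8 is
   high_Fsp3. This is a convention choice; only boundary-exact values are
   affected.

Stereochemistry is retained through curation and stripped only at
prediction time, mirroring how an online query service treats input.

## MAP4 fingerprint

For a molecule with heavy atoms 1..n, the shingle set is

    { min(e, e') + "|" + d(i,j) + "|" + max(e, e')
      : i < j, r ∈ {1, 2}, e = env_r(i), e' = env_r(j) }

where `env_r(i)` is the canonical SMILES of the circular environment of
radius r rooted at atom i (no stereo markers), and d(i, j) the
shortest-path distance in bonds. Lexicographic ordering of the two
environment strings canonicalizes the unordered pair. Atom pairs spanning
disconnected fragments have no path and are skipped; molecules with < 2
heavy atoms (or a shingle-less multi-fragment edge case) are rejected as
degenerate. Hydrogens are implicit; only heavy atoms are centers.

**MinHash.** Shingle strings are pre-hashed with CRC-32 (stable across
platforms and sessions, unlike Python's salted `hash`) and reduced modulo
the Mersenne prime p = 2³¹ − 1. Position k of the d-dimensional
fingerprint (d = 1024 by default) is min over shingles x of
h_k(x) = (a_k·x + b_k) mod p, with a_k ∈ [1, p), b_k ∈ [0, p) drawn once
from a seeded RNG (hash seed 42 by default — part of the fingerprint
definition, not an experiment seed). Keeping p < 2³² bounds a_k·x inside
uint64, so the whole sweep vectorizes in NumPy; the 2³¹-value range
makes chance collisions negligible relative to the estimator noise. The
similarity of two fingerprints is the fraction of agreeing positions,
whose expectation is the Jaccard similarity of the shingle sets with
binomial standard error √(J(1−J)/d) ≤ 0.0156 at d = 1024.

Both radii contribute their own shingle per atom pair (two shingles per
pair), consistent with reading the pair list as "all pairs of circular
substructures of radius 1 and 2".

## Classifier

One binary SVM per class (one-vs-rest) over a precomputed kernel:

- `map4_match`: MinHash index-match fraction (above);
- `tanimoto` / `dice`: on folded 1024-bit circular (radius 2) or
  topological atom-pair fingerprints;
- `rbf`: on the 11-descriptor property vector (MW, Fsp3, HBD, HBA,
  AlogP, #C, #O, #N, heavy atoms, bonds, TPSA), standardized to zero
  mean / unit variance with statistics fitted on training data only —
  re-fitted inside every cross-validation fold to avoid leakage.

Sample weights are w_c = n / (K·n_c) (inversely proportional to class
frequency; 1.0 per class when balanced). C is chosen from
{0.01, 0.1, 1, 10, 100} by maximizing mean balanced accuracy over an
inner stratified 5-fold CV on the training portion, ties to the smallest
C (strongest regularization), then the model is refitted on the full
training set. The inner-CV scheme subsumes the alternative single
80/20 validation holdout and is reproducible under a fixed seed.

**Probabilities.** Each sub-model gets a Platt sigmoid
P(y=1 | f) = 1/(1 + exp(−(Af + B))) fitted by logistic regression on
*out-of-fold* decision values (3-fold internal split; in-sample margins
are used only when a class is too small to split). Class probabilities
are the per-sub-model sigmoids normalized to sum to one. Predictions
canonicalize and strip stereochemistry first, so the output is a function
of the molecular graph only. Margins are recomputed from stored support
indices, dual coefficients and intercepts, which makes saved models
(`.npz` archive: JSON manifest + arrays) reproduce predictions
bit-for-bit.

**Metrics** are computed from the confusion matrix: balanced accuracy =
unweighted mean per-class recall (the convention consistent with
multiclass reporting; the precision-based binary variant that sometimes
appears in print is provided separately as
`binary_precision_balanced_accuracy`), F1 aggregated support-weighted by
default (macro available), and the Gorodkin multiclass MCC, which reduces
to (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) in the binary case.
Zero-denominator classes contribute 0 with a warning; an all-zero matrix
raises. Outer evaluation uses stratified k-fold (default k = 5) so every
record appears in exactly one test fold; reported values are mean ± SD
(population SD) across folds.

## Chemical-space layout

The LSH forest stores, per tree, the fingerprints sorted
lexicographically under a random permutation of the MinHash coordinates
(prefix length 16). A query descends to its insertion position in each
tree, collects a window of neighbors (max(2k, 8) per side), unions the
candidates over trees, and ranks them by exact match fraction (ties by
index). Trees are derived from a single seeded stream, so forests with
more trees extend smaller ones — candidate sets are nested and recall
versus the exact oracle is non-decreasing in the tree count. Defaults:
32 trees, k = 20 neighbors.

The kNN graph contains edge (i, j) when either endpoint lists the other,
weighted 1 − similarity. The minimum spanning tree is computed by Kruskal
with edges processed in (weight, i, j) order, making equal-weight
tie-breaks deterministic; disconnected graphs yield a spanning forest
with n − components edges. The published workflow delegates 2D drawing to
an external engine whose exact output is not testable; we use the
deterministic Kamada–Kawai layout per component (on hop counts — using
near-zero edge weights as target distances would collapse duplicate
molecules onto one point) and place components side by side with
disjoint bounding boxes. Exports write coordinates/edges/channels as CSV
with `%.17g` floats (exact round-trip) plus one static image per channel.

## Synthetic data generator

The generator emulates the *categorical* class structure of curated NP
collections, not their chemistry:

- **bacteria**: peptides condensed (on SMILES strings) from the 20
  proteinogenic residues; length uniform on 3–12; 40% head-to-tail
  cyclic. Cyclic *di*peptides cannot embed the dipeptide SMARTS (the
  match would have to reuse the first nitrogen), which the length floor
  of 3 avoids.
- **plant**: 13 polyphenol/terpenoid cores (flavonoids, coumarins,
  stilbenes, lignans, mono-/triterpenoids), randomly decorated at
  aromatic CH positions (0–2 substituents from {Me, OMe, OH, prenyl});
  O-glycosylated with probability 0.24 by bonding a pyranose anomeric
  carbon to a free hydroxyl — the construction guarantees a glycoside
  SMARTS match.
- **fungi**: with probability 0.31 a small scaffold (11 polyketide-like
  cores, decoration capped so MW stays ≤ 200); otherwise a mid-size
  polyketide core (6 scaffolds) with normal decoration.

Defaults (24% plant glycosides, 31% fungal small molecules, lengths
3–12) follow the published per-class composition of the collection this
emulates; the 5% glycosylation probability for the non-plant classes
matches the fungal rate and under-represents the bacterial one (17%),
which only makes the glycoside signal *less* class-discriminating, i.e.
errs conservative. Cyclization at 40% is a design choice representing
the prevalence of cyclic microbial peptides. Each class draws from its
own substream of a single seeded generator, so datasets are byte-identical
across runs and platforms, and changing one class's parameters leaves the
others' molecules unchanged.

**What passing tests show — and don't.** The synthetic classes are
separated by construction (disjoint scaffold libraries plus the
categorical signals), so near-perfect cross-validated accuracy here
demonstrates that the pipeline *can recover a class signal that is
present*, with correct bookkeeping and no leakage — not that real NP
collections are equally separable: real data share scaffolds across
origins, contain annotation errors and are far more diverse. Property
*distributions* (MW, AlogP) only reproduce the published bin ordering
(e.g. fungal NPs most abundant at MW ≤ 200), not the percentages.

## Problem sizes and seeds

Tests and the acceptance script run at desk scale: 200 molecules per
class (600 total) for the classification analog, 300 molecules for the
layout checks, 150 sampled pairs for MinHash fidelity, 100 random
confusion matrices for metric exactness — sizes chosen so the full suite
completes in a few minutes on one core while keeping binomial error bars
well inside the asserted bands. All randomness (dataset generation, fold
assignment, hash coefficients, LSH permutations, pair sampling) flows
from explicit integer seeds.

## Known limitations

- Origin labels reflect the *isolation* annotation; the generator and
  classifier cannot resolve true producers (e.g. endophyte-derived
  "plant" NPs).
- The keyword matcher is intentionally simple (substring containment on
  comma-split tokens); it does no taxonomy ontology lookup and will
  mislabel adversarial free text.
- MinHash similarity is an estimator: duplicate *fingerprints* imply
  equal shingle sets only with high probability, and similarities carry
  ±0.016 (1σ) noise at d = 1024.
- The LSH forest targets datasets of up to a few tens of thousands of
  molecules; its candidate-window scan is not tuned for millions.
- Only SVM variants with the four stated kernels are provided; no other
  calibration method than Platt scaling is implemented.
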