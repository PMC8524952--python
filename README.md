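# nporigin

Predicting the biological origin of natural products from molecular
structure alone.

Natural products (NPs) — secondary metabolites isolated from plants, fungi
and bacteria — are a major source of drug leads, but the organism a
compound was isolated from is not always its true producer (endophytic
microbes living inside plants are a classic confounder). `nporigin`
implements a structure-based pipeline for assigning an NP to its likely
origin class (plant / fungi / bacteria), for researchers in natural-product
chemistry and chemoinformatics:

1. **Curation** — raw database records (SMILES, free-text taxonomy, DOI)
   are filtered (DOI ≥ 10 characters), resolved to an origin by keyword
   matching with a fixed priority order
   (human > animal > bacteria > fungi > plant > marine), profiled
   (MW, Fsp3, AlogP, HBD/HBA, TPSA, atom counts) and flagged for
   dipeptide and glycoside (cyclic N-/O-acetal) substructures by SMARTS.
2. **MAP4 fingerprinting** — each molecule becomes the set of shingles
   `env_r(i) | d(i,j) | env_r(j)` over all heavy-atom pairs (i, j), where
   `env_r` is the canonical SMILES of the circular substructure of radius
   r ∈ {1, 2} and d(i, j) the topological distance in bonds; the set is
   MinHashed to a 1024-dimensional integer vector. For two fingerprints
   **a**, **b**, the fraction of indices with a_k = b_k is an unbiased
   estimator of the Jaccard similarity J(A, B) = |A∩B| / |A∪B| of the
   underlying shingle sets.
3. **Origin classification** — a one-vs-rest SVM over the precomputed
   MAP4 similarity kernel, with class weights inversely proportional to
   class frequency, C selected from {0.01, 0.1, 1, 10, 100} by maximizing
   cross-validated balanced accuracy, and per-class Platt scaling
   P(y=1 | f) = 1 / (1 + exp(Af + B)) for probabilistic output.
   Comparator models: Tanimoto kernel on folded circular fingerprints
   (radius 2, 1024 bits), Dice kernel on topological atom-pair
   fingerprints, and an RBF kernel on 11 standardized physico-chemical
   descriptors. Evaluation: balanced accuracy (mean per-class recall),
   multiclass Matthews correlation coefficient, support-weighted F1.
4. **Chemical-space maps** — an LSH forest (32 prefix trees) over the
   MinHash vectors yields each molecule's 20 approximate nearest
   neighbors; the resulting graph (edge weight 1 − similarity) is reduced
   to its minimum spanning tree and drawn in 2D, colored by MW, Fsp3,
   AlogP, origin or structural category.

Because the large curated NP collections this method targets are external
databases, the package ships a seed-reproducible **synthetic generator**
that emulates their class structure — peptide-rich bacterial NPs (3–12
residues, linear or cyclic), glycosylated polyphenols/terpenoids for
plants (24% glycosides), small moderately lipophilic polyketides for
fungi (31% at MW ≤ 200 Da) — so the entire pipeline is testable offline.

## Worked example

```python
import numpy as np
from nporigin import KernelSpec, SynthConfig, cross_validate, fit, generate_dataset
from nporigin.fingerprints import featurize

dataset = generate_dataset(SynthConfig(n_per_class=60, seed=7))
X = featurize([m.smiles for m in dataset], "map4", strip_stereochemistry=True)
labels = np.array([m.origin for m in dataset])

report = cross_validate(X, labels, KernelSpec("map4_match"), k=5, seed=0)
model = fit(X, labels, KernelSpec("map4_match"), seed=0)
label, pct = model.predict("Cc1cc(O)cc(O)c1C(O)=O")  # orsellinic acid
```

Running `python examples/04_train_and_predict.py` (which does the above)
prints:

```
5-fold balanced accuracy: 0.972 +/- 0.018
5-fold MCC:               0.960 +/- 0.025
5-fold F1:                0.972 +/- 0.018

selected C = 1.0, class weights = {'bacteria': 1.0, 'fungi': 1.0, 'plant': 1.0}

cyclic pentapeptide    -> bacteria  (bacteria=95.2%, fungi=4.8%, plant=0.0%)
flavonoid glycoside    -> plant     (bacteria=0.0%, fungi=0.2%, plant=99.8%)
small polyketide       -> fungi     (bacteria=0.0%, fungi=100.0%, plant=0.0%)
```

The cross-validation numbers say the three synthetic classes are almost
perfectly recoverable from structure alone; the per-query percentages are
Platt-scaled one-vs-rest probabilities normalized to sum to 100%, so a
95% bacteria score means the peptide query sits deep inside the bacterial
region of fingerprint space. The other scripts in `examples/` demonstrate
dataset generation, curation, fingerprint similarity and the
chemical-space map, each printing what it computes.

A thin CLI mirrors the library for shell use:

```bash
nporigin simulate --n-per-class 100 --seed 7 --out ds.csv
nporigin curate --in ds.csv --out curated.csv
nporigin fingerprint --in curated.csv --out fps.npz
nporigin train --fps fps.npz --curated curated.csv --out model.npz
nporigin predict --model model.npz "NCC(=O)NC(C)C(=O)NCC(=O)O"
```

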