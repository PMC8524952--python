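"""Shared fixtures.

The session-scoped fixtures build the study-condition synthetic dataset
(200 molecules per class) and its MAP4 fingerprint matrix once; several
test modules and the end-to-end checks reuse them.
"""

import numpy as np
import pytest

from nporigin import classifier, fingerprints, synthetic


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 200 molecules per class, seed 7."""
    return synthetic.generate_dataset(synthetic.SynthConfig())


@pytest.fixture(scope="session")
def default_fingerprints(default_dataset):
    smiles = [m.smiles for m in default_dataset]
    labels = np.array([m.origin for m in default_dataset])
    X = fingerprints.featurize(smiles, "map4", strip_stereochemistry=True)
    return X, labels


@pytest.fixture(scope="session")
def small_dataset():
    """A light dataset for unit-level checks (30 molecules per class)."""
    return synthetic.generate_dataset(synthetic.SynthConfig(n_per_class=30, seed=11))


@pytest.fixture(scope="session")
def small_fingerprints(small_dataset):
    smiles = [m.smiles for m in small_dataset]
    labels = np.array([m.origin for m in small_dataset])
    X = fingerprints.featurize(smiles, "map4", strip_stereochemistry=True)
    return X, labels


@pytest.fixture(scope="session")
def exact_similarity_oracle():
    """Exact pairwise MinHash match-fraction matrix (brute force)."""

    def _compute(X):
        return classifier.compute_kernel_matrix(
            X, X, classifier.KernelSpec("map4_match")
        )

    return _compute
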