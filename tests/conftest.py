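"""Shared fixtures: one session-scoped synthetic dataset feeds many tests."""

from __future__ import annotations

import numpy as np
import pytest

from allostate import geometry, ml_importance as mli, synthetic


@pytest.fixture(scope="session")
def test_spec() -> synthetic.SyntheticSpec:
    """Small study spec: 20 residues, 4 macrostates, 4 × 2000 frames."""
    return synthetic.SyntheticSpec.test_scale(seed=3)


@pytest.fixture(scope="session")
def test_dataset(test_spec):
    """(ensemble, ground truth) generated once for the whole session."""
    return synthetic.generate(test_spec, seed=3)


@pytest.fixture(scope="session")
def test_features(test_dataset):
    ensemble, _ = test_dataset
    return geometry.pairwise_distances(ensemble)


@pytest.fixture(scope="session")
def ovo_table(test_dataset, test_features):
    """One-vs-one forests trained on the planted macrostate labels."""
    _, truth = test_dataset
    labels = np.concatenate(truth.macro_labels)
    data = mli.LabeledFeatures(features=test_features, labels=labels)
    ovo, table = mli.train_ovo(data, mli.ClassifierSpec(n_trees=100, seed=5))
    return ovo, table


def random_reversible_T(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random reversible transition matrix and its stationary distribution."""
    x = rng.random((n, n)) + 0.1
    x = x + x.T
    T = x / x.sum(axis=1, keepdims=True)
    pi = x.sum(axis=1) / x.sum()
    return T, pi
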