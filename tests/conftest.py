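import numpy as np
import pytest

from emodrop.corpus import Corpus, Document
from emodrop.vectorize import FeatureMatrix


@pytest.fixture
def tiny_corpus() -> Corpus:
    return Corpus(
        [
            Document("I am HAPPY today!", "Happy"),
            Document("so sad, so very sad...", "Sad"),
            Document("happy happy joy", "Happy"),
        ]
    )


@pytest.fixture
def toy_matrix() -> FeatureMatrix:
    """Two well-separated classes on two features; third feature is noise."""
    rng = np.random.default_rng(7)
    n = 40
    y = np.arange(n) % 2
    X = rng.random((n, 3))
    X[y == 0, 0] += 2.0
    X[y == 1, 1] += 2.0
    return FeatureMatrix(
        values=X, labels=y, class_names=("neg", "pos"), feature_names=("f0", "f1", "f2")
    )


@pytest.fixture(scope="session")
def oracle_landscape():
    """Deterministic 10-feature fitness landscape with a unique 3-subset optimum.

    Classes are determined by features 1, 4, 7 with moderate separation, so
    the exhaustive optimum over all C(10,3)=120 subsets is exactly {1, 4, 7}.
    """
    rng = np.random.default_rng(123)
    n, d = 60, 10
    y = np.arange(n) % 3
    X = rng.random((n, d))
    for c, j in zip(range(3), (1, 4, 7)):
        X[y == c, j] += 0.6
    return FeatureMatrix(
        values=X,
        labels=y,
        class_names=("a", "b", "c"),
        feature_names=tuple(f"f{j}" for j in range(d)),
    )


@pytest.fixture(scope="session")
def synth_pipeline_inputs():
    """Scaled six-class synthetic corpus, cleaned and vectorized (computed once)."""
    from emodrop.preprocess import clean_corpus
    from emodrop.synth import default_table1_spec, generate, ground_truth_features
    from emodrop.vectorize import build_vocabulary, vectorize_counts

    spec = default_table1_spec(0.1, seed=1)
    corpus = generate(spec)
    cleaned = clean_corpus(corpus)
    vocab = build_vocabulary(cleaned, (1,))
    matrix = vectorize_counts(cleaned, vocab)
    planted = ground_truth_features(spec, vocab)
    return {
        "spec": spec,
        "corpus": corpus,
        "cleaned": cleaned,
        "vocab": vocab,
        "matrix": matrix,
        "planted": planted,
    }
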