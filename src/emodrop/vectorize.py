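"""n-gram vocabulary, bag-of-n-grams vectorization, resampling, and splitting.

The vocabulary is lexicographically ordered so matrices are bit-identical
across runs. Feature values default to raw occurrence counts; a smoothed
TF-IDF reweighting is available. Class resampling (random over/undersampling)
and the stratified train/test split are seeded and fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocess import TokenizedDocument

__all__ = [
    "Vocabulary",
    "FeatureMatrix",
    "build_vocabulary",
    "vectorize_counts",
    "tfidf_weight",
    "resample",
    "stratified_split",
]


@dataclass(frozen=True)
class Vocabulary:
    """Ordered n-gram inventory; terms are tokens joined by single spaces."""

    terms: tuple[str, ...]
    ngram_orders: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "ngram_orders", tuple(sorted(set(self.ngram_orders))))

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class FeatureMatrix:
    """Dense documents × features matrix with integer-coded labels."""

    values: np.ndarray  # (n_docs, n_features), nonnegative
    labels: np.ndarray  # (n_docs,), int codes 0..K-1
    class_names: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=np.int64)
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if values.shape[0] != labels.shape[0]:
            raise ValueError("row count must equal label count")
        if values.shape[1] != len(self.feature_names):
            raise ValueError("column count must equal number of feature names")
        if values.size and values.min() < 0:
            raise ValueError("feature values must be nonnegative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_names", tuple(self.class_names))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_docs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels, minlength=self.n_classes)
        return {name: int(c) for name, c in zip(self.class_names, counts)}

    def take_rows(self, rows: Sequence[int]) -> "FeatureMatrix":
        rows = np.asarray(rows, dtype=np.int64)
        return FeatureMatrix(
            values=self.values[rows],
            labels=self.labels[rows],
            class_names=self.class_names,
            feature_names=self.feature_names,
        )

    def take_columns(self, cols: Sequence[int]) -> "FeatureMatrix":
        cols = np.asarray(cols, dtype=np.int64)
        return FeatureMatrix(
            values=self.values[:, cols],
            labels=self.labels,
            class_names=self.class_names,
            feature_names=tuple(self.feature_names[c] for c in cols),
        )


def _doc_ngrams(tokens: Sequence[str], orders: Iterable[int]) -> list[str]:
    grams: list[str] = []
    for n in orders:
        if n == 1:
            grams.extend(tokens)
        else:
            grams.extend(
                " ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
            )
    return grams


def build_vocabulary(
    tokenized_docs: Sequence[TokenizedDocument],
    ngram_orders: Iterable[int] = (1,),
) -> Vocabulary:
    """All n-grams of the requested orders occurring in ≥1 document, sorted."""
    orders = tuple(sorted(set(int(n) for n in ngram_orders)))
    if not orders or any(n not in (1, 2, 3) for n in orders):
        raise ValueError("ngram_orders must be a non-empty subset of {1, 2, 3}")
    if not tokenized_docs:
        raise ValueError("build_vocabulary requires at least one document")
    seen: set[str] = set()
    for doc in tokenized_docs:
        seen.update(_doc_ngrams(doc.tokens, orders))
    if not seen:
        raise ValueError(
            "empty vocabulary: every document lost all tokens during cleaning; "
            "relax the common/rare filtering thresholds"
        )
    return Vocabulary(terms=tuple(sorted(seen)), ngram_orders=orders)


def vectorize_counts(
    tokenized_docs: Sequence[TokenizedDocument],
    vocab: Vocabulary,
) -> FeatureMatrix:
    """Bag-of-n-grams occurrence counts; out-of-vocabulary terms are ignored."""
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    index = vocab.index
    values = np.zeros((len(tokenized_docs), len(vocab)), dtype=np.float64)
    for d, doc in enumerate(tokenized_docs):
        for gram in _doc_ngrams(doc.tokens, vocab.ngram_orders):
            j = index.get(gram)
            if j is not None:
                values[d, j] += 1.0
    class_names = tuple(sorted({doc.label for doc in tokenized_docs}))
    code = {c: i for i, c in enumerate(class_names)}
    labels = np.array([code[doc.label] for doc in tokenized_docs], dtype=np.int64)
    return FeatureMatrix(
        values=values,
        labels=labels,
        class_names=class_names,
        feature_names=vocab.terms,
    )


def tfidf_weight(matrix: FeatureMatrix) -> FeatureMatrix:
    """Reweight counts as tf × (1 + ln(N / (1 + df))); zeros stay zero.

    The smoothed idf never reaches zero, so no term is silently erased; for a
    term present in every document the factor is slightly below 1.
    """
    n_docs = matrix.n_docs
    if n_docs == 0:
        return matrix
    df = (matrix.values > 0).sum(axis=0).astype(np.float64)
    idf = 1.0 + np.log(n_docs / (1.0 + df))
    return FeatureMatrix(
        values=matrix.values * idf[np.newaxis, :],
        labels=matrix.labels,
        class_names=matrix.class_names,
        feature_names=matrix.feature_names,
    )


def resample(matrix: FeatureMatrix, mode: str, seed: int) -> FeatureMatrix:
    """Balance class counts exactly by random over- or undersampling.

    ``oversample`` keeps every row and adds rows drawn with replacement until
    every class reaches the majority count; ``undersample`` draws without
    replacement down to the minority count. Reproducible under ``seed``.
    """
    if mode not in ("oversample", "undersample"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    counts = matrix.class_counts()
    empty = [name for name, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"cannot resample: class {empty[0]!r} has no rows")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    if mode == "oversample":
        target = max(counts.values())
        for k in range(matrix.n_classes):
            idx = np.flatnonzero(matrix.labels == k)
            extra = target - idx.size
            picked = rng.choice(idx, size=extra, replace=True) if extra else np.empty(0, np.int64)
            rows.append(np.concatenate([idx, picked.astype(np.int64)]))
    else:
        target = min(counts.values())
        for k in range(matrix.n_classes):
            idx = np.flatnonzero(matrix.labels == k)
            picked = rng.choice(idx, size=target, replace=False)
            rows.append(np.sort(picked.astype(np.int64)))
    return matrix.take_rows(np.concatenate(rows))


def stratified_split(
    matrix: FeatureMatrix,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded stratified train/test split.

    Per class the test set receives round(count × test_fraction) rows
    (half-up), floored at 1 and capped at count − 1 so every class appears on
    both sides. Train and test rows are disjoint and their union is the input.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_rows: list[np.ndarray] = []
    test_rows: list[np.ndarray] = []
    for k in range(matrix.n_classes):
        idx = np.flatnonzero(matrix.labels == k)
        if idx.size < 2:
            raise ValueError(
                f"class {matrix.class_names[k]!r} has {idx.size} row(s); "
                "need at least 2 to split"
            )
        n_test = int(math.floor(idx.size * test_fraction + 0.5))
        n_test = min(max(n_test, 1), idx.size - 1)
        perm = rng.permutation(idx)
        test_rows.append(np.sort(perm[:n_test]))
        train_rows.append(np.sort(perm[n_test:]))
    train = matrix.take_rows(np.sort(np.concatenate(train_rows)))
    test = matrix.take_rows(np.sort(np.concatenate(test_rows)))
    return train, test
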