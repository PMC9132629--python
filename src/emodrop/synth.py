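"""Seeded synthetic health-text corpus generator.

The reference emotion corpus the pipeline targets is not publicly deposited;
this generator reproduces its statistical skeleton instead of its language:
six imbalanced emotion classes (Angry 1343, Sad 358, Fear 742, Excited 1215,
Bored 22, Happy 522 at full scale), documents composed of class-specific
keyword tokens mixed into a shared Zipf-weighted background vocabulary with a
sprinkling of numeric tokens, Poisson-distributed document lengths, and
optional label noise. Keyword pools are disjoint across classes, so the
planted discriminative features form an unambiguous ground truth for
feature-selection experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, Document
from .vectorize import Vocabulary

__all__ = [
    "SynthSpec",
    "TABLE1_CLASS_NAMES",
    "TABLE1_CLASS_COUNTS",
    "default_table1_spec",
    "generate",
    "keyword_pools",
    "ground_truth_features",
]

TABLE1_CLASS_NAMES: tuple[str, ...] = ("Angry", "Sad", "Fear", "Excited", "Bored", "Happy")
TABLE1_CLASS_COUNTS: tuple[int, ...] = (1343, 358, 742, 1215, 22, 522)


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters.

    ``keyword_rate`` is the probability that a token is drawn from the
    document's class keyword pool; ``numeric_token_rate`` the probability of
    a random digit string; the rest come from the shared background
    vocabulary with Zipf weights. ``doc_length_mean`` defaults to the
    per-document mean word count implied by the reference corpus inventory
    (≈1.63M words over 4202 documents). ``label_noise_rate`` reassigns a
    document's label uniformly over all classes.
    """

    class_names: tuple[str, ...] = TABLE1_CLASS_NAMES
    class_counts: tuple[int, ...] = TABLE1_CLASS_COUNTS
    keywords_per_class: int = 5
    keyword_rate: float = 0.35
    background_vocab_size: int = 400
    numeric_token_rate: float = 0.04
    doc_length_mean: int = 390
    doc_length_min: int = 30
    label_noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_names", tuple(self.class_names))
        object.__setattr__(self, "class_counts", tuple(int(c) for c in self.class_counts))
        if len(self.class_names) != len(self.class_counts):
            raise ValueError("class_names and class_counts must have equal length")
        if any(c < 1 for c in self.class_counts):
            raise ValueError("class counts must be positive")
        if self.keyword_rate + self.numeric_token_rate > 1.0:
            raise ValueError("keyword_rate + numeric_token_rate must be <= 1")
        if not (0.0 <= self.label_noise_rate < 1.0):
            raise ValueError("label_noise_rate must be in [0, 1)")
        if self.keywords_per_class < 1 or self.background_vocab_size < 1:
            raise ValueError("keywords_per_class and background_vocab_size must be positive")
        if self.doc_length_min < 1 or self.doc_length_mean < self.doc_length_min:
            raise ValueError("need doc_length_mean >= doc_length_min >= 1")


def default_table1_spec(scale: float = 1.0, **overrides) -> SynthSpec:
    """Spec with the six reference classes scaled by ``scale`` (floor 2 docs).

    ``scale=0.1`` gives counts (134, 36, 74, 122, 2, 52). Keyword arguments
    override any other :class:`SynthSpec` field.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must be in (0, 1]")
    counts = tuple(max(2, int(round(scale * c))) for c in TABLE1_CLASS_COUNTS)
    return SynthSpec(class_counts=counts, **overrides)


def keyword_pools(spec: SynthSpec) -> dict[str, tuple[str, ...]]:
    """Disjoint per-class keyword token pools (deterministic names)."""
    return {
        name: tuple(f"{name.lower()}sym{i}" for i in range(spec.keywords_per_class))
        for name in spec.class_names
    }


def _background_vocab(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    words = np.array([f"bg{k}" for k in range(spec.background_vocab_size)])
    weights = 1.0 / np.arange(1, spec.background_vocab_size + 1)
    return words, weights / weights.sum()


def generate(spec: SynthSpec) -> Corpus:
    """Generate a labeled corpus; fully reproducible under ``spec.seed``.

    Documents are emitted grouped by class in ``class_names`` order with
    exactly ``class_counts`` documents per class; label noise (if any) is
    applied afterwards to the labels only.
    """
    rng = np.random.default_rng(spec.seed)
    pools = keyword_pools(spec)
    bg_words, bg_p = _background_vocab(spec)
    docs: list[Document] = []
    for name, count in zip(spec.class_names, spec.class_counts):
        pool = pools[name]
        for _ in range(count):
            length = max(spec.doc_length_min, int(rng.poisson(spec.doc_length_mean)))
            u = rng.random(length)
            kw_mask = u < spec.keyword_rate
            num_mask = (~kw_mask) & (u < spec.keyword_rate + spec.numeric_token_rate)
            tokens = rng.choice(bg_words, size=length, p=bg_p).astype(object)
            n_kw = int(kw_mask.sum())
            if n_kw:
                tokens[kw_mask] = rng.choice(pool, size=n_kw)
            n_num = int(num_mask.sum())
            if n_num:
                digits = rng.integers(1, 5, size=n_num)
                tokens[num_mask] = [
                    str(rng.integers(0, 10**d)) for d in digits
                ]
            docs.append(Document(text=" ".join(tokens), label=name))
    if spec.label_noise_rate > 0:
        names = list(spec.class_names)
        flip = rng.random(len(docs)) < spec.label_noise_rate
        for i in np.flatnonzero(flip):
            docs[i] = Document(text=docs[i].text, label=names[int(rng.integers(len(names)))])
    return Corpus(docs)


def ground_truth_features(spec: SynthSpec, vocab: Vocabulary) -> frozenset[int]:
    """Vocabulary indices of the planted keyword unigrams that survived.

    Keywords dropped by cleaning (e.g., rarer than the rare-term threshold)
    are simply absent from the vocabulary and hence from the result.
    """
    index = vocab.index
    hits: set[int] = set()
    for pool in keyword_pools(spec).values():
        for kw in pool:
            j = index.get(kw)
            if j is not None:
                hits.add(j)
    return frozenset(hits)
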