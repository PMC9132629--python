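"""Five-step text cleaning chain.

Order is fixed: lowercase → strip punctuation → tokenize → remove stop words →
remove common terms (high document frequency) → remove rare terms (low total
count). Corpus-level filters (common/rare) are computed on the stop-word-free
token streams, so the whole chain is idempotent on its own output. Documents
that become empty are retained (labels must stay aligned with the corpus).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .corpus import Corpus

__all__ = [
    "TokenizedDocument",
    "CleanConfig",
    "default_stopwords",
    "to_lowercase",
    "strip_punctuation",
    "tokenize",
    "remove_stopwords",
    "remove_common_terms",
    "remove_rare_terms",
    "clean_corpus",
]


def default_stopwords() -> frozenset[str]:
    """Packaged standard English stop-word list (one token per line)."""
    text = resources.files("emodrop.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return frozenset(t for t in text.split() if t)


@dataclass(frozen=True)
class TokenizedDocument:
    """Cleaned, tokenized document: lowercase whitespace-free tokens plus label."""

    tokens: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))


@dataclass(frozen=True)
class CleanConfig:
    """Parameters of the cleaning chain.

    ``common_df_threshold`` removes tokens whose document frequency (fraction
    of documents containing them) strictly exceeds the threshold;
    ``rare_min_count`` removes tokens whose total corpus count falls below it
    (the default 3 drops tokens occurring once or twice). Individual steps can
    be disabled via the ``enable_*`` flags.
    """

    stopword_list: frozenset[str] = field(default_factory=default_stopwords)
    common_df_threshold: float = 0.90
    rare_min_count: int = 3
    enable_lowercase: bool = True
    enable_punctuation: bool = True
    enable_stopwords: bool = True
    enable_common: bool = True
    enable_rare: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.common_df_threshold <= 1.0):
            raise ValueError("common_df_threshold must be in (0, 1]")
        if self.rare_min_count < 1:
            raise ValueError("rare_min_count must be >= 1")
        object.__setattr__(self, "stopword_list", frozenset(self.stopword_list))


def to_lowercase(text: str) -> str:
    return text.lower()


def strip_punctuation(text: str) -> str:
    """Replace every punctuation character with a space.

    Punctuation is any character that is neither alphanumeric nor whitespace;
    replacing with a space (rather than deleting) keeps adjacent tokens from
    fusing ("end.start" → two tokens).
    """
    return "".join(c if c.isalnum() or c.isspace() else " " for c in text)


def tokenize(text: str) -> list[str]:
    """Split on runs of whitespace; never yields empty tokens."""
    return text.split()


def remove_stopwords(tokens: Sequence[str], stopword_list: Iterable[str]) -> list[str]:
    stop = set(stopword_list)
    return [t for t in tokens if t not in stop]


def remove_common_terms(
    corpus_tokens: Sequence[Sequence[str]], common_df_threshold: float
) -> list[list[str]]:
    """Drop tokens whose document frequency strictly exceeds the threshold.

    Document frequency is the fraction of documents (including empty ones)
    containing the token at least once.
    """
    n_docs = len(corpus_tokens)
    if n_docs < 1:
        raise ValueError("remove_common_terms requires at least one document")
    df: Counter[str] = Counter()
    for toks in corpus_tokens:
        df.update(set(toks))
    banned = {t for t, c in df.items() if c / n_docs > common_df_threshold}
    return [[t for t in toks if t not in banned] for toks in corpus_tokens]


def remove_rare_terms(
    corpus_tokens: Sequence[Sequence[str]], rare_min_count: int
) -> list[list[str]]:
    """Drop tokens whose total corpus occurrence count is below the minimum."""
    total: Counter[str] = Counter()
    for toks in corpus_tokens:
        total.update(toks)
    banned = {t for t, c in total.items() if c < rare_min_count}
    return [[t for t in toks if t not in banned] for toks in corpus_tokens]


def clean_corpus(corpus: Corpus, config: CleanConfig | None = None) -> list[TokenizedDocument]:
    """Apply the full cleaning chain to every document.

    Documents that end up with no tokens are retained as empty token
    sequences; labels and document order are never altered.
    """
    if config is None:
        config = CleanConfig()
    per_doc: list[list[str]] = []
    for doc in corpus:
        text = doc.text
        if config.enable_lowercase:
            text = to_lowercase(text)
        if config.enable_punctuation:
            text = strip_punctuation(text)
        toks = tokenize(text)
        if config.enable_stopwords:
            toks = remove_stopwords(toks, config.stopword_list)
        per_doc.append(toks)
    if per_doc and config.enable_common:
        per_doc = remove_common_terms(per_doc, config.common_df_threshold)
    if config.enable_rare:
        per_doc = remove_rare_terms(per_doc, config.rare_min_count)
    return [
        TokenizedDocument(tokens=tuple(toks), label=doc.label)
        for toks, doc in zip(per_doc, corpus)
    ]
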