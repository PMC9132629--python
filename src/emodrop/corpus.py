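"""Corpus containers, readers/writers, and corpus-level descriptive statistics.

A corpus is an ordered sequence of labeled raw-text documents. Two plain-text
on-disk formats are supported: a delimited (CSV-dialect, quoted) table and a
record-per-line (JSON lines) format. Descriptive statistics are computed on the
*raw* uncleaned text — they describe the dataset, not the modeling features.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "Document",
    "Corpus",
    "CorpusStats",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "class_distribution",
    "corpus_stats",
]

_DIGITS_RE = re.compile(r"^[0-9]+$")

FORMATS = ("delimited", "record_per_line")


class CorpusFormatError(ValueError):
    """Raised when a corpus file violates the expected record format."""


@dataclass(frozen=True)
class Document:
    """One raw text record with its emotion class label."""

    text: str
    label: str

    def __post_init__(self) -> None:
        if not isinstance(self.text, str):
            raise TypeError("text must be a string")
        if not isinstance(self.label, str) or not self.label:
            raise ValueError("label must be a non-empty string")


@dataclass(frozen=True)
class Corpus:
    """Ordered collection of documents.

    ``label_set`` is always the sorted set of labels occurring in the
    documents; document order is stable under write → read round trips.
    """

    documents: tuple[Document, ...]

    def __init__(self, documents: Iterable[Document]):
        object.__setattr__(self, "documents", tuple(documents))

    @property
    def label_set(self) -> tuple[str, ...]:
        return tuple(sorted({d.label for d in self.documents}))

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def __getitem__(self, i):
        return self.documents[i]


@dataclass(frozen=True)
class CorpusStats:
    """Corpus-level feature inventory computed on raw text.

    Words are whitespace-delimited tokens; characters include internal
    whitespace; numerics are digits-only tokens; n-gram uniqueness is global
    across the corpus but n-grams never span document boundaries.
    """

    n_words: int
    n_characters: int
    n_numerics: int
    n_unique_unigrams: int
    n_unique_bigrams: int
    n_unique_trigrams: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_words": self.n_words,
            "n_characters": self.n_characters,
            "n_numerics": self.n_numerics,
            "n_unique_unigrams": self.n_unique_unigrams,
            "n_unique_bigrams": self.n_unique_bigrams,
            "n_unique_trigrams": self.n_unique_trigrams,
        }

    def as_text(self) -> str:
        rows = [
            ("Number of words", self.n_words),
            ("Characters", self.n_characters),
            ("Numerics", self.n_numerics),
            ("Unique unigrams", self.n_unique_unigrams),
            ("Unique bigrams", self.n_unique_bigrams),
            ("Unique trigrams", self.n_unique_trigrams),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def _check_format(format_tag: str) -> None:
    if format_tag not in FORMATS:
        raise ValueError(f"unknown corpus format {format_tag!r}; expected one of {FORMATS}")


def read_corpus(
    path: str | Path,
    format_tag: str = "delimited",
    text_field: str = "text",
    label_field: str = "label",
) -> Corpus:
    """Read a labeled corpus from ``path``.

    ``delimited`` is a comma-separated table with a header row and standard
    quoting; ``record_per_line`` is one JSON object per line. A record missing
    either field raises :class:`CorpusFormatError` naming the (1-based) record
    index. An empty file yields an empty corpus.
    """
    _check_format(format_tag)
    path = Path(path)
    docs: list[Document] = []
    if format_tag == "delimited":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return Corpus([])
            for i, row in enumerate(reader, start=1):
                text = row.get(text_field)
                label = row.get(label_field)
                if text is None or label is None or label == "":
                    raise CorpusFormatError(
                        f"record {i}: missing field "
                        f"{text_field if text is None else label_field!r}"
                    )
                docs.append(Document(text=text, label=label))
    else:
        with path.open("r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"record {i}: invalid JSON ({exc})") from exc
                if text_field not in rec or label_field not in rec:
                    missing = text_field if text_field not in rec else label_field
                    raise CorpusFormatError(f"record {i}: missing field {missing!r}")
                docs.append(Document(text=str(rec[text_field]), label=str(rec[label_field])))
    return Corpus(docs)


def write_corpus(
    corpus: Corpus,
    path: str | Path,
    format_tag: str = "delimited",
    text_field: str = "text",
    label_field: str = "label",
) -> None:
    """Write ``corpus`` so that :func:`read_corpus` reproduces it exactly."""
    _check_format(format_tag)
    path = Path(path)
    if format_tag == "delimited":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=[text_field, label_field])
            writer.writeheader()
            for doc in corpus:
                writer.writerow({text_field: doc.text, label_field: doc.label})
    else:
        with path.open("w", encoding="utf-8") as fh:
            for doc in corpus:
                fh.write(
                    json.dumps({text_field: doc.text, label_field: doc.label}, ensure_ascii=False)
                )
                fh.write("\n")


def class_distribution(corpus: Corpus) -> dict[str, int]:
    """Count of documents per emotion class; values sum to ``len(corpus)``."""
    counts: Counter[str] = Counter(d.label for d in corpus)
    return dict(counts)


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Compute the raw-text feature inventory of ``corpus``.

    Tokenization here is plain whitespace splitting of the *uncleaned* text;
    the modeling vocabulary (built from cleaned tokens) is a separate concern.
    """
    n_words = 0
    n_chars = 0
    n_numerics = 0
    uni: set[str] = set()
    bi: set[tuple[str, str]] = set()
    tri: set[tuple[str, str, str]] = set()
    for doc in corpus:
        toks = doc.text.split()
        n_words += len(toks)
        n_chars += len(doc.text)
        n_numerics += sum(1 for t in toks if _DIGITS_RE.match(t))
        uni.update(toks)
        bi.update(zip(toks, toks[1:]))
        tri.update(zip(toks, toks[1:], toks[2:]))
    return CorpusStats(
        n_words=n_words,
        n_characters=n_chars,
        n_numerics=n_numerics,
        n_unique_unigrams=len(uni),
        n_unique_bigrams=len(bi),
        n_unique_trigrams=len(tri),
    )
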