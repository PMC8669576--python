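"""Bag-of-CUI corpus construction and summary statistics.

Each post is reduced to a bag of concept identifiers: every annotation
contributes one count to each CUI it maps to (a mention mapped to multiple
CUIs is replaced by all of them; multiple mentions sharing a CUI accumulate
into that CUI's count), and all non-mention words are discarded. The
resulting CUI vocabulary is the topic model's word space.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .preprocess import CleanPost, RawPost
from .annotator import MentionAnnotation
from ._rounding import round_half_away

__all__ = [
    "CuiDocument",
    "CuiCorpus",
    "CorpusStats",
    "AnnotationStats",
    "to_cui_document",
    "build_corpus",
    "corpus_stats",
    "annotation_stats",
    "write_corpus",
    "read_corpus",
]


@dataclass(frozen=True)
class CuiDocument:
    """Bag-of-CUI counts for one post. Empty documents are legal but carry
    no evidence for model fitting."""

    post_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.counts.values()):
            raise ValueError("CUI counts must be >= 1")

    @property
    def n_tokens(self) -> int:
        return sum(self.counts.values())

    @property
    def is_empty(self) -> bool:
        return not self.counts


@dataclass
class CuiCorpus:
    """A list of bag-of-CUI documents plus the ordered CUI vocabulary."""

    documents: list[CuiDocument]
    vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.vocabulary:
            self.vocabulary = sorted({c for d in self.documents for c in d.counts})
        self._vocab_index = {c: i for i, c in enumerate(self.vocabulary)}
        missing = {c for d in self.documents for c in d.counts} - set(self.vocabulary)
        if missing:
            raise ValueError(f"documents contain CUIs outside vocabulary: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(d.n_tokens for d in self.documents)

    @property
    def n_empty(self) -> int:
        return sum(d.is_empty for d in self.documents)

    def nonempty_documents(self) -> list[CuiDocument]:
        return [d for d in self.documents if not d.is_empty]

    def vocab_index(self, cui: str) -> int:
        try:
            return self._vocab_index[cui]
        except KeyError:
            raise KeyError(f"CUI {cui!r} not in corpus vocabulary") from None


@dataclass(frozen=True)
class CorpusStats:
    """Raw-corpus summary: post count/share and word-length statistics
    (whitespace words of the *raw* text, before any cleaning)."""

    n_posts: int
    l_max: int
    l_min: int
    l_avg: float
    l_sd: float
    n_words: int
    pct_posts: float | None = None


@dataclass(frozen=True)
class AnnotationStats:
    """Annotation summary counts.

    annots: annotation instances; maps: distinct (surface, cui) pairs;
    M: distinct surfaces; C: distinct CUIs; S/D/P: distinct surfaces with
    at least one SignSymptom / DiseaseDisorder / Procedure mapping.
    A surface may hold several categories, so S+D+P may exceed M.
    """

    annots: int
    maps: int
    M: int
    C: int
    S: int
    D: int
    P: int

    @property
    def M_over_C(self) -> float | None:
        """Mean distinct mentions per CUI, maps/C, two decimals."""
        return round_half_away(self.maps / self.C, 2) if self.C else None

    @property
    def C_over_M(self) -> float | None:
        """Mean CUIs per distinct mention, maps/M, two decimals."""
        return round_half_away(self.maps / self.M, 2) if self.M else None


def to_cui_document(
    post: CleanPost, annotations: Sequence[MentionAnnotation]
) -> CuiDocument:
    """Replace a post's mentions by their mapped CUIs, discarding all other
    words. Annotations must already be category-filtered and belong to this
    post."""
    counts: Counter[str] = Counter()
    for a in annotations:
        if a.post_id != post.id:
            raise ValueError(
                f"annotation for post {a.post_id!r} passed with post {post.id!r}"
            )
        for cui in a.cuis:
            counts[cui] += 1
    return CuiDocument(post_id=post.id, counts=dict(counts))


def build_corpus(docs: Iterable[CuiDocument]) -> CuiCorpus:
    """Assemble documents into a corpus with a sorted CUI vocabulary.

    Empty documents are retained (they keep their position and identifier)
    but are excluded from model fitting by the topic-model stage.
    """
    return CuiCorpus(documents=list(docs))


def corpus_stats(posts: Sequence[RawPost], whole: int | None = None) -> CorpusStats:
    """Word-count summary of raw posts (whitespace tokenization).

    ``whole`` — total post count of the enclosing collection, for the
    percentage share (two decimals).
    """
    if not posts:
        raise ValueError("empty corpus")
    lengths = [len(p.text.split()) for p in posts]
    n = len(lengths)
    mean = sum(lengths) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in lengths) / n) if n > 1 else 0.0
    return CorpusStats(
        n_posts=n,
        l_max=max(lengths),
        l_min=min(lengths),
        l_avg=mean,
        l_sd=sd,
        n_words=sum(lengths),
        pct_posts=round_half_away(100.0 * n / whole, 2) if whole else None,
    )


def annotation_stats(annotations: Sequence[MentionAnnotation]) -> AnnotationStats:
    """Summary counts over an annotation list (typically one dataset)."""
    if not annotations:
        return AnnotationStats(0, 0, 0, 0, 0, 0, 0)
    maps: set[tuple[str, str]] = set()
    surfaces: set[str] = set()
    cuis: set[str] = set()
    by_cat: dict[str, set[str]] = {"SignSymptom": set(), "DiseaseDisorder": set(), "Procedure": set()}
    for a in annotations:
        surfaces.add(a.surface)
        for cui, cat in a.mappings:
            maps.add((a.surface, cui))
            cuis.add(cui)
            if cat in by_cat:
                by_cat[cat].add(a.surface)
    return AnnotationStats(
        annots=len(annotations),
        maps=len(maps),
        M=len(surfaces),
        C=len(cuis),
        S=len(by_cat["SignSymptom"]),
        D=len(by_cat["DiseaseDisorder"]),
        P=len(by_cat["Procedure"]),
    )


def write_corpus(corpus: CuiCorpus, triplet_path: str | Path, vocab_path: str | Path) -> None:
    """Sparse triplet serialization: rows ``doc_index<TAB>cui<TAB>count``
    plus a one-CUI-per-line vocabulary file."""
    with open(triplet_path, "w", encoding="utf-8") as fh:
        for i, doc in enumerate(corpus.documents):
            fh.write(f"#doc\t{i}\t{doc.post_id}\n")
            for cui in sorted(doc.counts):
                fh.write(f"{i}\t{cui}\t{doc.counts[cui]}\n")
    with open(vocab_path, "w", encoding="utf-8") as fh:
        for cui in corpus.vocabulary:
            fh.write(cui + "\n")


def read_corpus(triplet_path: str | Path, vocab_path: str | Path) -> CuiCorpus:
    vocab = [
        line.strip()
        for line in Path(vocab_path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    ids: dict[int, str] = {}
    counts: dict[int, dict[str, int]] = {}
    with open(triplet_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#doc\t"):
                _, idx, pid = line.split("\t")
                ids[int(idx)] = pid
                counts.setdefault(int(idx), {})
                continue
            idx_s, cui, cnt = line.split("\t")
            counts.setdefault(int(idx_s), {})[cui] = int(cnt)
    docs = [
        CuiDocument(post_id=ids.get(i, str(i)), counts=counts.get(i, {}))
        for i in sorted(set(ids) | set(counts))
    ]
    return CuiCorpus(documents=docs, vocabulary=vocab)
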