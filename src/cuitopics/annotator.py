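"""Dictionary-lookup mention extraction and concept (CUI) mapping.

Emulates a clinical fast-dictionary-lookup annotator configured for exact
string match with *all-term persistence*: every contiguous token
subsequence of a post that exactly equals a dictionary surface form is
emitted as an annotation, so a generic term nested inside a precise one
("pain" inside "back pain") is annotated as well. Matching is on token
boundaries — "pain" never matches inside "spain".

The dictionary maps lower-case surface forms (possibly multi-word) to one
or more concept unique identifiers (CUIs, pattern ``C<digits>``), each with
a semantic category. Lookup uses a token-level trie so a post of n tokens
is scanned in O(n · depth) rather than by testing all O(n^2) subsequences;
the brute-force scan survives in the test suite as the oracle.
"""

from __future__ import annotations

import csv
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .preprocess import CleanPost, RawPost
from ._rounding import round_half_away

__all__ = [
    "CATEGORIES",
    "KEEP_DEFAULT",
    "DictionaryEntry",
    "ConceptDictionary",
    "MentionAnnotation",
    "ConcordanceResult",
    "DictionaryFormatError",
    "load_dictionary",
    "save_dictionary",
    "annotate",
    "filter_categories",
    "concordance",
    "sample_for_review",
    "write_annotations_tsv",
    "read_annotations_tsv",
]

#: Closed set of annotation categories (one per CUI).
CATEGORIES = frozenset(
    {"SignSymptom", "DiseaseDisorder", "Procedure", "Medication", "Anatomy"}
)
#: Categories of interest for illness topic modeling; Medication and
#: Anatomy are extracted but filtered out before the bag-of-CUI stage.
KEEP_DEFAULT = frozenset({"SignSymptom", "DiseaseDisorder", "Procedure"})

_CUI_RE = re.compile(r"^C\d+$")


class DictionaryFormatError(ValueError):
    """A malformed dictionary row (bad CUI, category, or empty surface)."""


@dataclass(frozen=True)
class DictionaryEntry:
    """One surface form -> CUI mapping with its semantic category."""

    cui: str
    category: str
    surface: tuple[str, ...]  # lower-case token sequence, len >= 1

    def __post_init__(self) -> None:
        if not _CUI_RE.match(self.cui):
            raise DictionaryFormatError(f"malformed CUI {self.cui!r}")
        if self.category not in CATEGORIES:
            raise DictionaryFormatError(f"unknown category {self.category!r}")
        if not self.surface or any(not t for t in self.surface):
            raise DictionaryFormatError("empty surface form")

    @property
    def surface_text(self) -> str:
        return " ".join(self.surface)


class _TrieNode:
    __slots__ = ("children", "mappings")

    def __init__(self) -> None:
        self.children: dict[str, _TrieNode] = {}
        self.mappings: set[tuple[str, str]] | None = None


@dataclass
class ConceptDictionary:
    """A set of surface->CUI entries with a trie index over token sequences.

    One surface may map to multiple CUIs (a mention can denote several
    concepts); a (surface, cui) pair appears at most once.
    """

    entries: list[DictionaryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        deduped: dict[tuple[tuple[str, ...], str], DictionaryEntry] = {}
        for e in self.entries:
            deduped.setdefault((e.surface, e.cui), e)
        self.entries = list(deduped.values())
        self._root = _TrieNode()
        self.index: dict[tuple[str, ...], set[tuple[str, str]]] = {}
        for e in self.entries:
            self.index.setdefault(e.surface, set()).add((e.cui, e.category))
            node = self._root
            for tok in e.surface:
                node = node.children.setdefault(tok, _TrieNode())
            if node.mappings is None:
                node.mappings = set()
            node.mappings.add((e.cui, e.category))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def cuis(self) -> set[str]:
        return {e.cui for e in self.entries}

    def scan_from(self, tokens: Sequence[str], start: int):
        """Yield (end_index_exclusive, mappings) for every surface matching
        the token subsequence beginning at ``start``."""
        node = self._root
        for j in range(start, len(tokens)):
            node = node.children.get(tokens[j])
            if node is None:
                return
            if node.mappings is not None:
                yield j + 1, node.mappings


@dataclass(frozen=True)
class MentionAnnotation:
    """A matched span: character offsets into the post's clean_text plus
    the union of (cui, category) mappings for the matched surface."""

    post_id: str
    begin: int
    end: int
    surface: str
    mappings: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.mappings:
            raise ValueError("annotation must carry at least one mapping")
        if not (0 <= self.begin < self.end):
            raise ValueError("invalid span")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.post_id, self.begin, self.end)

    @property
    def cuis(self) -> set[str]:
        return {c for c, _ in self.mappings}


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between a manual and an automatic annotation list, matched
    on (post_id, begin, end) keys."""

    n_manual: int
    n_auto: int
    n_common: int

    @property
    def manual_coverage_pct(self) -> float:
        """% of manual mentions covered by the automatic list (one decimal)."""
        return round_half_away(100.0 * self.n_common / self.n_manual, 1)

    @property
    def auto_confirmation_pct(self) -> float:
        """% of automatic mentions confirmed by the manual list (one decimal)."""
        return round_half_away(100.0 * self.n_common / self.n_auto, 1)


def load_dictionary(path: str | Path) -> ConceptDictionary:
    """Load a concept dictionary from TSV (columns: cui, category, surface).

    '#'-prefixed lines are comments. Surfaces are lower-cased and
    whitespace-normalized; duplicate (surface, cui) rows collapse to one
    entry. Malformed rows raise :class:`DictionaryFormatError` naming the
    line.
    """
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DictionaryFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            cui, category, surface = (p.strip() for p in parts)
            try:
                entries.append(
                    DictionaryEntry(
                        cui=cui, category=category, surface=tuple(surface.lower().split())
                    )
                )
            except DictionaryFormatError as exc:
                raise DictionaryFormatError(f"{path}:{lineno}: {exc}") from None
    return ConceptDictionary(entries)


def save_dictionary(dictionary: ConceptDictionary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(dictionary.entries, key=lambda e: (e.cui, e.surface)):
            fh.write(f"{e.cui}\t{e.category}\t{e.surface_text}\n")


def annotate(post: CleanPost, dictionary: ConceptDictionary) -> list[MentionAnnotation]:
    """Extract every dictionary match in a post (all-term persistence).

    Every contiguous token subsequence equal to a dictionary surface yields
    one annotation carrying the union of that surface's (cui, category)
    pairs; nested and overlapping matches all persist. Offsets index into
    ``post.clean_text``. Output sorted by (begin, end).
    """
    spans = post.token_offsets()
    out = []
    for i in range(len(post.tokens)):
        for j_excl, mappings in dictionary.scan_from(post.tokens, i):
            begin = spans[i][0]
            end = spans[j_excl - 1][1]
            out.append(
                MentionAnnotation(
                    post_id=post.id,
                    begin=begin,
                    end=end,
                    surface=post.clean_text[begin:end],
                    mappings=frozenset(mappings),
                )
            )
    out.sort(key=lambda a: (a.begin, a.end))
    return out


def filter_categories(
    annotations: Iterable[MentionAnnotation],
    keep: frozenset[str] | set[str] = KEEP_DEFAULT,
) -> list[MentionAnnotation]:
    """Restrict annotations to the kept categories.

    Mappings outside ``keep`` are removed; an annotation whose mappings all
    fall outside is dropped entirely.
    """
    unknown = set(keep) - CATEGORIES
    if unknown:
        raise ValueError(f"unknown categories in keep: {sorted(unknown)}")
    out = []
    for a in annotations:
        kept = frozenset((c, cat) for c, cat in a.mappings if cat in keep)
        if kept:
            out.append(
                MentionAnnotation(
                    post_id=a.post_id,
                    begin=a.begin,
                    end=a.end,
                    surface=a.surface,
                    mappings=kept,
                )
            )
    return out


def concordance(
    manual: Iterable[MentionAnnotation], auto: Iterable[MentionAnnotation]
) -> ConcordanceResult:
    """Agreement between manual and automatic annotations.

    A mention belongs to both lists iff it occurs in both with the same
    post identifier and character offsets; each unique key counts once.
    CUI agreement is not required.
    """
    manual_keys = {a.key for a in manual}
    auto_keys = {a.key for a in auto}
    return ConcordanceResult(
        n_manual=len(manual_keys),
        n_auto=len(auto_keys),
        n_common=len(manual_keys & auto_keys),
    )


def sample_for_review(
    posts: Sequence[RawPost], n: int, seed: int
) -> tuple[list[RawPost], float]:
    """Uniform sample of posts without replacement, for manual review.

    Returns the sample and its mean post length in whitespace words.
    """
    if n > len(posts):
        raise ValueError(f"cannot sample {n} from {len(posts)} posts")
    rng = random.Random(seed)
    sample = rng.sample(list(posts), n)
    mean_len = sum(len(p.text.split()) for p in sample) / n if n else 0.0
    return sample, mean_len


def write_annotations_tsv(
    annotations: Iterable[MentionAnnotation], path: str | Path
) -> None:
    """One row per (annotation, mapping) pair:
    post_id, begin, end, surface, cui, category."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a in annotations:
            for cui, cat in sorted(a.mappings):
                w.writerow([a.post_id, a.begin, a.end, a.surface, cui, cat])


def read_annotations_tsv(path: str | Path) -> list[MentionAnnotation]:
    grouped: dict[tuple[str, int, int, str], set[tuple[str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            pid, begin, end, surface, cui, cat = line.split("\t")
            grouped.setdefault((pid, int(begin), int(end), surface), set()).add(
                (cui, cat)
            )
    return [
        MentionAnnotation(
            post_id=pid, begin=b, end=e, surface=s, mappings=frozenset(maps)
        )
        for (pid, b, e, s), maps in sorted(grouped.items())
    ]
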