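"""Normalization of raw social-media posts into clean token streams.

Posts scraped from health forums and Instagram carry markup that conveys no
medical content: URLs, hashtags, @-handles, emoji, digits and other
non-ASCII codepoints. This module strips those, tokenizes, lowercases and
removes stop-words, yielding a :class:`CleanPost` whose ``clean_text``
(tokens joined by single spaces) is the canonical reference string for all
downstream character offsets.

Noise is stripped from the *raw* text before tokenization so that
multi-character artifacts (a URL, a hashtag together with its word) are
removed whole rather than leaking fragments into the token stream.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "RawPost",
    "CleanPost",
    "strip_noise",
    "tokenize",
    "clean_post",
    "load_stopwords",
    "default_stopwords",
    "read_posts_jsonl",
    "write_posts_jsonl",
    "write_clean_jsonl",
]

# Tokens removed whole (marker and word): URLs, hashtags, @-handles.
_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_HASHTAG_RE = re.compile(r"#\w+")
_HANDLE_RE = re.compile(r"@\w+")
# Deleted in place: digits and everything outside printable ASCII.
_DIGIT_RE = re.compile(r"[0-9]")
_NON_ASCII_RE = re.compile(r"[^\x20-\x7e\t\n\r]")

# Word tokens: runs of ASCII letters/digits, allowing internal apostrophes
# (so "don't" survives as one token and matches the stop-word list).
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:'[A-Za-z0-9]+)*")


@dataclass(frozen=True)
class RawPost:
    """A post as collected: identifier, source site label, verbatim text."""

    id: str
    source: str
    text: str
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("post id must be non-empty")


@dataclass(frozen=True)
class CleanPost:
    """A normalized post: ordered lower-case tokens and their canonical text.

    ``clean_text`` is exactly ``" ".join(tokens)``; annotation offsets are
    0-based half-open indices into this string.
    """

    id: str
    tokens: tuple[str, ...]
    clean_text: str = field(default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "clean_text", " ".join(self.tokens))

    def token_offsets(self) -> list[tuple[int, int]]:
        """(begin, end) of each token within ``clean_text``."""
        spans = []
        pos = 0
        for tok in self.tokens:
            spans.append((pos, pos + len(tok)))
            pos += len(tok) + 1
        return spans


def strip_noise(text: str) -> str:
    """Remove social-media noise from raw text.

    URL, hashtag and handle tokens are removed whole; digits, emoji and all
    non-ASCII codepoints are deleted in place. Everything else is preserved
    in order (whitespace included), so the result is still raw text.
    """
    text = _URL_RE.sub("", text)
    text = _HASHTAG_RE.sub("", text)
    text = _HANDLE_RE.sub("", text)
    text = _DIGIT_RE.sub("", text)
    text = _NON_ASCII_RE.sub("", text)
    return text


def tokenize(text: str) -> list[str]:
    """Split text into word tokens, discarding punctuation-only tokens."""
    return _TOKEN_RE.findall(text)


def clean_post(post: RawPost, stoplist: frozenset[str] | set[str]) -> CleanPost:
    """Normalize one post: strip noise, tokenize, lowercase, drop stop-words.

    A post whose content is entirely noise comes back with an empty token
    list; downstream stages tolerate (and flag) empty documents.
    """
    tokens = [
        tok
        for tok in (t.lower() for t in tokenize(strip_noise(post.text)))
        if tok not in stoplist
    ]
    return CleanPost(id=post.id, tokens=tuple(tokens))


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a one-word-per-line stop-word file ('#' lines are comments)."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


def default_stopwords() -> frozenset[str]:
    """The frozen English stop-word list bundled with the package."""
    ref = resources.files("cuitopics.data").joinpath("stopwords.txt")
    words = set()
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


def read_posts_jsonl(path: str | Path) -> list[RawPost]:
    posts = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            pid = str(rec["id"])
            if pid in seen:
                raise ValueError(f"duplicate post id {pid!r} at line {lineno}")
            seen.add(pid)
            posts.append(
                RawPost(
                    id=pid,
                    source=str(rec.get("source", "")),
                    text=str(rec["text"]),
                    timestamp=rec.get("timestamp"),
                )
            )
    return posts


def write_posts_jsonl(posts: Iterable[RawPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            rec: dict = {"id": p.id, "source": p.source, "text": p.text}
            if p.timestamp is not None:
                rec["timestamp"] = p.timestamp
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_clean_jsonl(posts: Iterable[CleanPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(json.dumps({"id": p.id, "tokens": list(p.tokens)}) + "\n")


def read_clean_jsonl(path: str | Path) -> Iterator[CleanPost]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rec = json.loads(line)
                yield CleanPost(id=str(rec["id"]), tokens=tuple(rec["tokens"]))
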