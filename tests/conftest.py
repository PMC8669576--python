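"""Shared fixtures: bundled toy data, a small planted corpus, and the
brute-force annotation oracle used to cross-check the trie annotator."""

from importlib import resources

import numpy as np
import pytest

from cuitopics.annotator import ConceptDictionary, MentionAnnotation
from cuitopics.corpus import CuiCorpus, CuiDocument
from cuitopics.preprocess import CleanPost, default_stopwords


@pytest.fixture(scope="session")
def data_dir(tmp_path_factory):
    """The bundled toy fixture copied into a writable directory."""
    out = tmp_path_factory.mktemp("toydata")
    pkg = resources.files("cuitopics.data")
    for name in ("toy_posts.jsonl", "toy_dictionary.tsv", "stopwords.txt"):
        (out / name).write_text(
            pkg.joinpath(name).read_text(encoding="utf-8"), encoding="utf-8"
        )
    return out


@pytest.fixture(scope="session")
def toy_dictionary(data_dir):
    from cuitopics.annotator import load_dictionary

    return load_dictionary(data_dir / "toy_dictionary.tsv")


@pytest.fixture(scope="session")
def toy_posts(data_dir):
    from cuitopics.preprocess import read_posts_jsonl

    return read_posts_jsonl(data_dir / "toy_posts.jsonl")


@pytest.fixture(scope="session")
def stopwords():
    return default_stopwords()


def brute_force_annotate(
    post: CleanPost, dictionary: ConceptDictionary
) -> list[MentionAnnotation]:
    """Oracle: test every one of the O(n^2) contiguous token subsequences
    against the dictionary index directly. Independent of the trie scan."""
    toks = post.tokens
    spans = post.token_offsets()
    out = []
    for i in range(len(toks)):
        for j in range(i + 1, len(toks) + 1):
            mappings = dictionary.index.get(tuple(toks[i:j]))
            if mappings:
                begin, end = spans[i][0], spans[j - 1][1]
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


def corpus_from_planted(posts, truth) -> CuiCorpus:
    """Bag-of-CUI corpus straight from the planted CUI draws, with the full
    planted vocabulary (so beta columns align with beta_true)."""
    docs = []
    for p, cuis in zip(posts, truth.planted_cuis):
        counts: dict[str, int] = {}
        for c in cuis:
            counts[c] = counts.get(c, 0) + 1
        docs.append(CuiDocument(post_id=p.id, counts=counts))
    return CuiCorpus(documents=docs, vocabulary=list(truth.cui_order))


def block_beta(K: int, V: int, mass: float = 0.9) -> np.ndarray:
    """Well-separated topics: each concentrates ``mass`` on its own block
    of V // K CUIs, the remainder spread uniformly elsewhere."""
    assert V % K == 0
    block = V // K
    beta = np.full((K, V), (1.0 - mass) / (V - block))
    for k in range(K):
        beta[k, k * block : (k + 1) * block] = mass / block
    return beta / beta.sum(axis=1, keepdims=True)


NO_NOISE = {"hashtag": 0.0, "handle": 0.0, "url": 0.0, "emoji": 0.0, "numeral": 0.0}
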