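"""Synthetic social-media corpora from a planted topic process.

The study data this pipeline targets — posts scraped from illness-dedicated
forums and Instagram tags — cannot be redistributed, so every stage is
exercised against corpora generated here with fully known ground truth.

The generator emulates what matters to the pipeline: short posts (word
lengths from a truncated normal matching forum-scale means and spreads), a
mixture of medical-mention phrases (possibly multi-word, with synonym
variants sharing a concept identifier) and filler words, stop-words, and
social-media noise (hashtags, handles, URLs, emoji, numerals). Mentions are
drawn from a planted LDA process: per document theta_d ~ Dirichlet(alpha),
per mention slot a topic z ~ Categorical(theta_d) and a CUI ~
Categorical(beta[z]), rendered as a uniformly chosen synonym.

The planted truth records theta, the topic assignments, the raw CUI draws,
and the *gold annotation set*: every dictionary match present in the
rendered post's canonical clean text, computed by an exhaustive token
subsequence scan. Because all-term persistence annotates a generic form
nested inside a precise one, the gold set includes such induced matches in
addition to the planted spans; a noise-free pipeline run must recover it
exactly.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import RawPost, default_stopwords
from .annotator import ConceptDictionary, DictionaryEntry, MentionAnnotation

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "make_dictionary",
    "generate_corpus",
    "write_truth",
]

_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu la le li lo "
    "lu ma me mi mo mu na ne ni no nu pa pe pi po pu ra re ri ro ru sa se si "
    "so su ta te ti to tu va ve vi vo vu za ze zi zo zu"
).split()

_EMOJI = ("\U0001f600", "\U0001f62d", "\U0001f64f", "❤️", "\U0001f495", "\U0001f629")

_DEFAULT_CATEGORY_MIX = {"SignSymptom": 0.6, "DiseaseDisorder": 0.25, "Procedure": 0.15}

#: Defaults emulate the forum-scale posts the pipeline targets: mean length
#: ~110 words with a comparable spread, roughly one word in ten being part
#: of a medical mention, and a light scatter of Instagram-style noise.
_DEFAULT_NOISE_RATES = {
    "hashtag": 1.0,
    "handle": 0.5,
    "url": 0.5,
    "emoji": 1.0,
    "numeral": 1.0,
}


@dataclass
class SyntheticSpec:
    """Parameters of the planted generative process.

    ``beta_true`` may be omitted; it is then drawn once (from a sparse
    Dirichlet, seeded by ``seed``) when the corpus is generated and
    recorded in the returned truth.
    """

    n_docs: int = 200
    doc_len_mean: float = 110.0
    doc_len_sd: float = 100.0
    K_true: int = 5
    alpha_true: float = 1.5
    beta_true: np.ndarray | None = None
    n_cuis: int = 100
    synonyms_per_cui: int = 3
    filler_vocab_size: int = 500
    mention_fraction: float = 0.1
    noise_rates: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_RATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_docs", "K_true", "n_cuis", "synonyms_per_cui"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.filler_vocab_size < 0:
            raise ValueError("filler_vocab_size must be >= 0")
        if not 0.0 <= self.mention_fraction <= 1.0:
            raise ValueError("mention_fraction must lie in [0, 1]")
        if self.alpha_true <= 0:
            raise ValueError("alpha_true must be positive")
        unknown = set(self.noise_rates) - set(_DEFAULT_NOISE_RATES)
        if unknown:
            raise ValueError(f"unknown noise classes: {sorted(unknown)}")
        if self.beta_true is not None:
            self.beta_true = np.asarray(self.beta_true, dtype=float)
            if self.beta_true.shape != (self.K_true, self.n_cuis):
                raise ValueError("beta_true must be K_true x n_cuis")
            if not np.allclose(self.beta_true.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError("beta_true rows must sum to 1 within 1e-12")


@dataclass
class PlantedTruth:
    """Everything the generator knows that the pipeline must recover."""

    theta_true: np.ndarray  # n_docs x K, rows sum to 1
    z_assignments: list[list[int]]  # per doc, per mention slot
    planted_cuis: list[list[str]]  # per doc, the raw CUI draws
    gold_annotations: list[MentionAnnotation]  # all dictionary matches
    beta_true: np.ndarray
    cui_order: list[str]  # column order of beta_true


def _draw_word(rng: random.Random, n_syllables: int = 3) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables))


def _fresh_words(rng: random.Random, n: int, forbidden: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        w = _draw_word(rng, rng.randint(2, 4))
        if w not in forbidden:
            forbidden.add(w)
            out.append(w)
    return out


def make_dictionary(
    n_cuis: int,
    synonyms_per_cui: int,
    category_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> ConceptDictionary:
    """Generate a toy concept dictionary of ``n_cuis`` concepts with
    ``synonyms_per_cui`` surface forms each.

    Surface forms are pronounceable nonsense words; some are multi-word,
    and whenever ``n_cuis >= 2`` at least one precise two-token form
    strictly contains another concept's single-token generic form (so
    all-term persistence is exercisable, like "pain" within "back pain").
    Deterministic for a fixed seed.
    """
    if n_cuis < 1 or synonyms_per_cui < 1:
        raise ValueError("n_cuis and synonyms_per_cui must be positive")
    mix = dict(category_mix or _DEFAULT_CATEGORY_MIX)
    unknown = set(mix) - {"SignSymptom", "DiseaseDisorder", "Procedure"}
    if unknown:
        raise ValueError(f"unknown categories in category_mix: {sorted(unknown)}")
    rng = random.Random(seed)
    forbidden = set(default_stopwords())
    heads = _fresh_words(rng, n_cuis, forbidden)
    cats, weights = zip(*sorted(mix.items()))
    entries: list[DictionaryEntry] = []
    used_surfaces: set[tuple[str, ...]] = set()
    for i in range(n_cuis):
        cui = f"C{i + 1:07d}"
        category = rng.choices(cats, weights=weights)[0]
        # canonical form: every third concept (from the second on) is a
        # precise modifier+head phrase nesting the previous concept's head
        if i >= 1 and i % 3 == 1:
            canonical: tuple[str, ...] = (
                _fresh_words(rng, 1, forbidden)[0],
                heads[i - 1],
            )
        else:
            canonical = (heads[i],)
        surfaces = [canonical]
        while len(surfaces) < synonyms_per_cui:
            if rng.random() < 0.3:
                cand = (_fresh_words(rng, 1, forbidden)[0], canonical[-1])
            else:
                cand = (_fresh_words(rng, 1, forbidden)[0],)
            if cand not in used_surfaces:
                surfaces.append(cand)
        for s in surfaces:
            used_surfaces.add(s)
            entries.append(DictionaryEntry(cui=cui, category=category, surface=s))
    return ConceptDictionary(entries)


def _exhaustive_scan(
    post_id: str, tokens: Sequence[str], dictionary: ConceptDictionary
) -> list[MentionAnnotation]:
    """All dictionary matches among contiguous token subsequences, by
    direct index lookup (no trie); the generator's own gold standard."""
    max_len = max((len(s) for s in dictionary.index), default=0)
    starts = []
    pos = 0
    for t in tokens:
        starts.append(pos)
        pos += len(t) + 1
    clean_text = " ".join(tokens)
    out = []
    for i in range(len(tokens)):
        for j in range(i + 1, min(i + max_len, len(tokens)) + 1):
            key = tuple(tokens[i:j])
            mappings = dictionary.index.get(key)
            if mappings:
                begin = starts[i]
                end = starts[j - 1] + len(tokens[j - 1])
                out.append(
                    MentionAnnotation(
                        post_id=post_id,
                        begin=begin,
                        end=end,
                        surface=clean_text[begin:end],
                        mappings=frozenset(mappings),
                    )
                )
    out.sort(key=lambda a: (a.begin, a.end))
    return out


def generate_corpus(
    spec: SyntheticSpec, dictionary: ConceptDictionary
) -> tuple[list[RawPost], PlantedTruth]:
    """Render a corpus of raw posts from the planted LDA process.

    Deterministic for a fixed ``spec.seed``. The dictionary must contain at
    least ``spec.n_cuis`` concepts; the first ``n_cuis`` (in identifier
    order) become the beta_true columns.
    """
    cui_order = sorted(dictionary.cuis)
    if len(cui_order) < spec.n_cuis:
        raise ValueError(
            f"dictionary has {len(cui_order)} CUIs, spec requires {spec.n_cuis}"
        )
    cui_order = cui_order[: spec.n_cuis]
    forms_by_cui: dict[str, list[tuple[str, ...]]] = {c: [] for c in cui_order}
    for e in dictionary.entries:
        if e.cui in forms_by_cui:
            forms_by_cui[e.cui].append(e.surface)
    for c, forms in forms_by_cui.items():
        if not forms:
            raise ValueError(f"CUI {c} has no surface forms")
        forms.sort()

    rng = np.random.default_rng(spec.seed)
    wrng = random.Random(spec.seed + 1)
    stoplist = sorted(default_stopwords())
    dict_tokens = {t for s in dictionary.index for t in s}
    forbidden = set(stoplist) | dict_tokens
    filler_vocab = _fresh_words(wrng, spec.filler_vocab_size, forbidden)

    if spec.beta_true is not None:
        beta = spec.beta_true
    else:
        beta = rng.dirichlet(np.full(spec.n_cuis, 0.1), size=spec.K_true)
        beta = beta / beta.sum(axis=1, keepdims=True)

    theta = rng.dirichlet(np.full(spec.K_true, spec.alpha_true), size=spec.n_docs)
    posts: list[RawPost] = []
    z_all: list[list[int]] = []
    cuis_all: list[list[str]] = []
    gold: list[MentionAnnotation] = []
    for d in range(spec.n_docs):
        pid = f"syn-{d:05d}"
        length = max(1, int(round(rng.normal(spec.doc_len_mean, spec.doc_len_sd))))
        n_mentions = int(round(spec.mention_fraction * length))
        if spec.mention_fraction > 0:
            n_mentions = max(1, n_mentions)
        n_filler = length - n_mentions

        zs = [int(z) for z in rng.choice(spec.K_true, size=n_mentions, p=theta[d])] if n_mentions else []
        cuis = [cui_order[int(rng.choice(spec.n_cuis, p=beta[z]))] for z in zs]
        mention_slots = [
            list(forms_by_cui[c][int(rng.integers(len(forms_by_cui[c])))]) for c in cuis
        ]
        # non-mention slots: filler-vocab words, with stop-words mixed in
        filler_slots: list[list[str]] = []
        for _ in range(max(n_filler, 0)):
            if filler_vocab and rng.random() >= 0.3:
                filler_slots.append([filler_vocab[int(rng.integers(len(filler_vocab)))]])
            else:
                filler_slots.append([stoplist[int(rng.integers(len(stoplist)))]])
        slots = mention_slots + filler_slots
        order = rng.permutation(len(slots))
        slots = [slots[int(i)] for i in order]

        raw_tokens = [t for slot in slots for t in slot]
        # social-media noise, inserted whole at random positions
        noise_tokens: list[str] = []
        for kind, rate in spec.noise_rates.items():
            for _ in range(int(rng.poisson(rate))):
                if kind == "hashtag":
                    noise_tokens.append(f"#tag{int(rng.integers(1000))}")
                elif kind == "handle":
                    noise_tokens.append(f"@user{int(rng.integers(1000))}")
                elif kind == "url":
                    noise_tokens.append(f"https://t.co/{int(rng.integers(10**6)):06x}")
                elif kind == "emoji":
                    noise_tokens.append(_EMOJI[int(rng.integers(len(_EMOJI)))])
                elif kind == "numeral":
                    noise_tokens.append(str(int(rng.integers(1, 2030))))
        for tok in noise_tokens:
            raw_tokens.insert(int(rng.integers(len(raw_tokens) + 1)), tok)
        text = " ".join(raw_tokens)
        if text and text[0].isalpha():
            text = text[0].upper() + text[1:]
        posts.append(RawPost(id=pid, source="synthetic", text=text))

        # the clean token stream the preprocessing stage will produce
        stopset = set(stoplist)
        clean_tokens = [t for slot in slots for t in slot if t not in stopset]
        gold.extend(_exhaustive_scan(pid, clean_tokens, dictionary))
        z_all.append(zs)
        cuis_all.append(cuis)

    truth = PlantedTruth(
        theta_true=theta,
        z_assignments=z_all,
        planted_cuis=cuis_all,
        gold_annotations=gold,
        beta_true=beta,
        cui_order=list(cui_order),
    )
    return posts, truth


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Sidecar JSON with the planted parameters and gold annotations."""
    rec = {
        "theta_true": truth.theta_true.tolist(),
        "z_assignments": truth.z_assignments,
        "planted_cuis": truth.planted_cuis,
        "beta_true": truth.beta_true.tolist(),
        "cui_order": truth.cui_order,
        "gold_annotations": [
            {
                "post_id": a.post_id,
                "begin": a.begin,
                "end": a.end,
                "surface": a.surface,
                "mappings": sorted(a.mappings),
            }
            for a in truth.gold_annotations
        ],
    }
    Path(path).write_text(json.dumps(rec) + "\n", encoding="utf-8")
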