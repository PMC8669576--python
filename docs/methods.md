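# Methods

`cuitopics` implements a text-mining pipeline for illnesses that surface on
social media before they are medically defined: posts are cleaned,
medical mentions are extracted by exact dictionary lookup and normalized to
concept unique identifiers (CUIs), each post becomes a bag of CUIs, and
latent Dirichlet allocation (LDA) summarizes the corpus as topics rendered
through representative mentions. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
evaluation corpora do and do not establish.

## Preprocessing

Raw post text is normalized in a fixed order: noise stripping, then
tokenization, then lowercasing, then stop-word removal.

Noise stripping removes URL, hashtag and @-handle tokens *whole* (the
marker together with its word — a hashtag's word is part of the hashtag,
not content), and deletes digits, emoji and every non-ASCII codepoint in
place. Stripping precedes tokenization deliberately: multi-character
artifacts such as URLs cannot survive tokenization cleanly, and stripping
first prevents URL fragments from leaking into the token stream.

The tokenizer is a small regular-expression word tokenizer: maximal runs
of ASCII alphanumerics with internal apostrophes, punctuation-only tokens
discarded. Contractions stay whole ("don't"), which matches the shipped
stop-word list. The English stop-word list (179 function words) is frozen
as a versioned data file in the package rather than looked up from a
library at runtime, so results cannot drift with an NLP library upgrade.

A cleaned post's canonical text is its tokens joined by single spaces.
All annotation character offsets are 0-based half-open indices into this
string; defining the offset reference this precisely is what makes
annotation concordance (matching on exact offsets) well defined. Cleaning
is idempotent and order-preserving; both are property-tested.

By default the annotator consumes the post-stop-word text. A config switch
(`annotate_pre_stopword`) lets the annotator see the pre-stop-word stream
instead, for dictionaries whose multi-word surfaces contain function words.

## Mention extraction and concept mapping

The concept dictionary is a TSV of (CUI, category, surface form) rows,
categories drawn from {SignSymptom, DiseaseDisorder, Procedure,
Medication, Anatomy}. One surface may map to several CUIs; each CUI
carries one category. A bundled toy dictionary serves the tests and
examples; a UMLS-derived dictionary in the same format is a drop-in.

Extraction is exact matching on token-sequence boundaries with *all-term
persistence*: every contiguous token subsequence equal to a dictionary
surface is emitted, so a generic term nested inside a precise one ("pain"
inside "back pain") is annotated too, and a surface occurring k times
yields k span-anchored annotations. Token-boundary matching prevents
"pain" from matching inside "spain". The matcher walks a token-level trie
from every start position — O(n · depth) per post rather than testing all
O(n²) subsequences — and the brute-force subsequence scan is retained in
the test suite as the oracle the trie must agree with exactly.

Only SignSymptom, DiseaseDisorder and Procedure mappings feed the topic
model; Medication and Anatomy mentions are extracted but filtered out, as
the pipeline's object is illness description rather than treatment or
anatomy. Concordance between a manual and an automatic annotation list
counts unique (post id, begin, end) keys, ignoring CUI agreement — span
identity, not sense identity, is the criterion, and exact (not
overlap-based) span equality is used.

## Bag-of-CUI representation

Each annotation contributes one count to *each* CUI it maps to (a mention
with two senses becomes two CUI tokens); repeated mentions accumulate
(bag semantics, no per-post deduplication); all non-mention words are
discarded. The CUI vocabulary is sorted for determinism. Empty documents
are retained with their identifiers — they keep their place in reports —
but are excluded from model fitting and given a uniform topic posterior,
since a zero-token document carries no evidence.

Corpus length statistics are computed on whitespace tokens of the *raw*
text, before any cleaning, because they describe the collected data.
Printed ratios and percentages use round-half-away-from-zero at the
conventional table precision (two decimals for ratios and frequency
percentages, one for post-share percentages).

## Topic model

The generative model is standard LDA: per document a topic mixture
θ_d ~ Dirichlet(α) (symmetric, scalar α per component), per token a topic
z ~ Categorical(θ_d) and a CUI w ~ Categorical(β_z). Inference is
mean-field variational EM in the Blei–Ng–Jordan formulation:

- **E-step.** Per document, coordinate ascent on the variational Dirichlet
  parameters γ_d and token assignments φ_d. With
  E[log θ_dk] = ψ(γ_dk) − ψ(Σ_k γ_dk), the optimal φ gives the vectorized
  update γ = α + exp(E[log θ]) ⊙ ((X / S) βᵀ) with
  S = exp(E[log θ]) β, iterated until the mean absolute γ change falls
  below `var_tol` (default 1e-6, capped at 200 sweeps).
- **M-step.** β_kv ∝ η + Σ_d expected topic-k counts of CUI v, a point
  (MAP-style) update with symmetric smoothing pseudo-count η
  (default 0.01). η > 0 keeps every β entry positive so unseen CUIs never
  produce −∞ likelihoods; η = 0 disables smoothing (used by the exact
  closed-form checks).
- **α is held fixed** at the supplied value. The pipeline explores α by
  grid search; estimating it during EM would override the grid.

The reported objective is the evidence lower bound (ELBO) on
log p(X | α, β) plus the η Σ log β smoothing term; EM increases it
monotonically (asserted within 1e-6 relative tolerance on every fit in the
test suite). The *unpenalized* per-document bound — which never exceeds
the exact marginal likelihood, verified against brute-force enumeration of
all topic assignments on tiny instances — is what perplexity uses:
perplexity = exp(−Σ_d bound_d / Σ_d N_d), with per-document variational
parameters freshly optimized. Perplexity is computed on the training
corpus by default; a seeded held-out document split is available via
`heldout_fraction` (the literature is split on which to report; both are
one flag apart).

Initialization seeds each topic from a randomly chosen document plus
uniform noise; `n_restarts` (default 3) independent initializations are
run and the best final ELBO kept. All randomness flows from a single seed
through `numpy.random.SeedSequence`, so fits are bit-reproducible.
EM stops when the relative ELBO change drops below `em_tol` (default
1e-4) or after `max_iter` (default 100) iterations.

The grid search fits every (K, α) pair — defaults
K ∈ {3, 4, 5, 10, 15, 20} and
α ∈ {0.01, 0.05, 0.1, 0.5, 1, 1.5, 2, 5, 10, 15, 20, 25} — and ranks by
perplexity but deliberately does **not** auto-select a winner: low
perplexity does not guarantee interpretable topics, so the final (K, α)
is an analyst decision recorded in the run config (`chosen_K`,
`chosen_alpha`); absent a choice, the pipeline provisionally takes the
lowest-perplexity cell and logs that it did so.

## Reporting

A post is hard-assigned to its highest-probability topic (ties to the
lowest index, logged). Each topic is summarized by its top-n CUIs by
p(CUI | topic); each CUI is rendered as its *representative mention* — the
surface form with the highest corpus-wide annotation-instance count among
forms mapped to it (ties lexicographically first, logged) — annotated with
the CUI's corpus-wide frequency. That frequency is, by default, the CUI's
share of all CUI tokens pooled over every post (the reading under which
the percentages are interpretable as parts of a whole); a share-of-posts
denominator is configurable. Mention order follows topic probability, not
frequency. Topic labels ("Toxicity", "Mental health", …) are
human-supplied config strings, never inferred. All reported summaries are
invariant to topic relabeling, and every printed mention exists verbatim
among the corpus annotations (smoothing can in principle rank a
never-observed CUI into the top-n; such an entry is rendered as the CUI
identifier and flagged).

## Synthetic corpora

Real corpora of this kind — scraped forum and Instagram posts — cannot be
redistributed, so the package generates its own evaluation data from a
planted process with fully known truth. The generator emulates the
features the pipeline is sensitive to: post lengths from a truncated
normal (default mean 110, SD 100 words, minimum 1 — forum-scale posts);
a mention fraction of 0.1 (roughly one word in ten belongs to a medical
mention, the regime of illness-forum text); multi-word surface forms and
synonym variants sharing a CUI (synonym rendering uniform over a CUI's
forms, as no variant frequencies are available to emulate); stop-words
interleaved among filler words; and per-post Poisson noise (hashtags,
handles, URLs, emoji, numerals) from fixed templates matching the removal
classes the cleaner targets. Mentions are drawn from a planted LDA process
(default K = 5, α = 1.5; β rows drawn sparse unless supplied).

The planted truth records θ, the topic and CUI draws, and the *gold
annotation set*: every dictionary match in the rendered post's canonical
clean text, computed by an exhaustive subsequence scan independent of the
trie matcher. The gold set therefore includes matches induced by all-term
persistence (nested generic forms, incidental cross-mention matches), and
a noise-free pipeline run must reproduce it exactly — a round-trip that
exercises cleaning, offsets, matching and bag construction together.

What the synthetic corpora do not emulate: English grammar and word order,
misspellings, per-source vocabulary differences (sources are treated as
interchangeable), negation and uncertainty, and the long-tail surface
variability of a real UMLS dictionary. Passing tests therefore establish
the pipeline's mechanical and statistical correctness — not that any
particular real-world extraction is clinically complete.

## Evaluation scales and determinism

The heavier checks run at sizes chosen to exercise the statistics
meaningfully while keeping the whole suite interactive: parameter recovery
on 2000 documents, 60 CUIs, 4 well-separated planted topics (best-
permutation mean cosine between fitted and planted topic-CUI rows ≥ 0.9;
observed ≈ 0.997); the enumeration oracle on 25 random instances small
enough (V ≤ 4, N ≤ 4, K ≤ 3) for exact summation over all topic
assignments; annotator/oracle equivalence on 100 random posts; and the
Monte-Carlo check that pooled planted CUI draws match the closed-form
topic mixture within 3 standard errors, with the SE computed in closed
form from the generative process (token-level multinomial noise plus the
between-document Dirichlet dispersion of θ — the naive iid SE would be
anti-conservative because draws within a document share θ).

Known limitations: the E-step densifies the document-term matrix, which is
the right trade at CUI-vocabulary scale (hundreds to a few thousand
types) but not for open-vocabulary corpora; perplexity uses the
variational bound rather than an importance-sampled estimate, so absolute
values are comparable only within this implementation; and hard topic
assignment by argmax discards posterior uncertainty in the post-per-topic
tables, as is conventional for this kind of summary.
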