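# cuitopics

Mining emerging illnesses from social media text. When a condition is
discussed by patients online before it is medically defined — breast
implant illness is the motivating case — the discussion itself is the best
available evidence of its signs, symptoms and associated procedures.
`cuitopics` turns a corpus of such posts into interpretable topics:

1. **Clean** — strip URLs, hashtags, handles, emoji, digits and other
   non-ASCII noise; tokenize; lowercase; remove stop-words. The cleaned,
   space-joined text is the canonical reference for all character offsets.
2. **Extract & map** — exact dictionary lookup of medical mentions with
   *all-term persistence* (for "back pain", the nested generic "pain" is
   annotated too), normalizing each mention to one or more concept unique
   identifiers (CUIs) with semantic categories. Only sign/symptom,
   disease/disorder and procedure mentions are kept.
3. **Bag-of-CUI** — replace each mention by its mapped CUIs and discard
   every other word; the CUI vocabulary is the topic model's word space.
4. **Topic model** — latent Dirichlet allocation fit by variational EM
   (α fixed, β smoothed), with a (K, α) grid search ranked by perplexity.
   In LDA each post d draws a topic mixture θ_d ~ Dirichlet(α) and each
   CUI token draws a topic z ~ Cat(θ_d), then a CUI w ~ Cat(β_z).
5. **Report** — per-topic representative mentions (the corpus-frequent
   surface form of each top CUI), corpus-wide CUI frequencies, and the
   distribution of posts among topics.

Because corpora of this kind cannot be redistributed, the package includes
a synthetic generator that renders social-media-like posts from a planted
LDA process with fully known truth (θ, topic/CUI draws, gold annotation
spans), so every stage — and the pipeline end to end — is testable with no
download. Annotation agreement with a manual gold standard (concordance on
exact post-id + character-offset keys) is built in.

## Worked example

The bundled toy fixture is 12 forum-style posts and a 15-entry concept
dictionary:

```
python -c "from importlib import resources; import shutil
d = resources.files('cuitopics.data')
for f in ('toy_posts.jsonl','toy_dictionary.tsv','toy_config.yaml'):
    shutil.copy(str(d / f), f)"
cuitopics run-all --config toy_config.yaml
```

The run logs each stage and writes all artifacts under `toy_out/`:

```
INFO cuitopics.pipeline: loaded 12 posts, 15 dictionary entries
INFO cuitopics.pipeline: cleaned 12 posts (0 empty)
INFO cuitopics.pipeline: annotations: 31 extracted, 28 after category filter
INFO cuitopics.pipeline: 1 empty bag-of-CUI documents excluded from fitting
INFO cuitopics.pipeline: bag-of-CUI corpus: 12 docs, vocabulary 11, 31 tokens
INFO cuitopics.pipeline: using configured model choice K=2 alpha=1.5
```

31 mentions are extracted; 28 survive the category filter (the toy posts
contain one medication and two anatomy-only mentions, which are dropped).
`toy_out/report.txt` then summarizes the two fitted topics, each as its
top CUIs rendered through representative mentions with corpus-wide
frequency percentages, plus the post-per-topic distribution:

```
topic 0
  pain (16.13); fatigue (12.90); swelling (9.68); ...
posts per topic
  topic 0: 7 (58.3%)
  topic 1: 5 (41.7%)
```

"pain (16.13)" means the CUI behind "pain" accounts for 16.13% of all CUI
tokens in the corpus; mention order follows p(CUI | topic), not frequency.
The summary statistics stage mirrors the usual corpus/annotation tables:

```
$ cuitopics stats --posts toy_posts.jsonl --annotations toy_out/annotations_filtered.tsv
posts=12 l_max=14 l_min=10 l_avg=11.92 (SD 1.32) words=143
annots=28 maps=13 M=12 C=11 M/C=1.18 C/M=1.08 S=6 D=5 P=2
```

(M = distinct mentions, C = distinct CUIs, maps = distinct mention–CUI
pairs; M/C and C/M are the average mapping multiplicities; S/D/P count
distinct mentions per category.)

Every stage is also a library call (`cuitopics.clean_post`,
`cuitopics.annotate`, `cuitopics.fit_lda`, …) and a CLI subcommand
(`clean`, `annotate`, `stats`, `fit`, `grid`, `concordance`, `simulate`,
`run-all`). `cuitopics simulate` writes a synthetic corpus with its
planted truth for experimentation.

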