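"""Topic summaries: representative mentions, CUI frequencies, and the
distribution of posts among topics.

A CUI is an opaque identifier, so each top CUI of a topic is rendered by
its *representative mention* — the surface form with the highest
corpus-wide annotation-instance count among the forms mapped to that CUI.
Mentions are ordered by the CUI's probability under the topic, not by
frequency; the attached percentage is the CUI's share of all CUI tokens
across the whole corpus, not only of posts assigned to the topic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotator import MentionAnnotation
from .corpus import CuiCorpus, CorpusStats
from .topic_model import DocTopicPosterior, LdaModel
from ._rounding import round_half_away

__all__ = [
    "TopicSummary",
    "TopicDistribution",
    "assign_topics",
    "topic_distribution",
    "cui_frequencies",
    "representative_mentions",
    "render_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopicSummary:
    topic_id: int
    top_cuis: tuple[tuple[str, float], ...]  # (cui, p(cui|topic)), prob-ordered
    representative_mentions: tuple[tuple[str, float], ...]  # (surface, corpus %)
    label: str | None = None


@dataclass
class TopicDistribution:
    """Per-topic post counts and percentage shares (one decimal)."""

    rows: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def total_posts(self) -> int:
        return sum(n for _, n, _ in self.rows)


def assign_topics(posterior: DocTopicPosterior) -> dict[str, int]:
    """Hard-assign each post to its highest-probability topic.

    Ties break to the lowest topic index (logged at DEBUG).
    """
    theta = posterior.theta_hat
    out: dict[str, int] = {}
    for pid, row in zip(posterior.post_ids, theta):
        best = int(np.argmax(row))
        if np.sum(row == row[best]) > 1:
            logger.debug("post %s: topic tie broken to lowest index %d", pid, best)
        out[pid] = best
    return out


def topic_distribution(assignments: Mapping[str, int]) -> TopicDistribution:
    """Counts and one-decimal percentages of posts per topic."""
    if not assignments:
        raise ValueError("no topic assignments")
    counts = Counter(assignments.values())
    total = sum(counts.values())
    rows = [
        (t, counts[t], round_half_away(100.0 * counts[t] / total, 1))
        for t in sorted(counts)
    ]
    return TopicDistribution(rows=rows)


def cui_frequencies(
    corpus: CuiCorpus, denominator: str = "tokens"
) -> dict[str, float]:
    """Each CUI's corpus-wide percentage frequency (two decimals).

    ``denominator="tokens"`` (default): share of all CUI tokens pooled over
    every post. ``denominator="posts"``: share of posts containing the CUI
    at least once.
    """
    if denominator not in ("tokens", "posts"):
        raise ValueError("denominator must be 'tokens' or 'posts'")
    if denominator == "posts":
        n_posts = len(corpus.documents)
        if n_posts == 0:
            raise ValueError("corpus has no documents")
        pooled = Counter(c for doc in corpus.documents for c in doc.counts)
        return {
            c: round_half_away(100.0 * n / n_posts, 2) for c, n in sorted(pooled.items())
        }
    total = corpus.n_tokens
    if total == 0:
        raise ValueError("corpus has no CUI tokens")
    pooled = Counter()
    for doc in corpus.documents:
        pooled.update(doc.counts)
    return {c: round_half_away(100.0 * n / total, 2) for c, n in sorted(pooled.items())}


def representative_mentions(
    model: LdaModel,
    annotations: Sequence[MentionAnnotation],
    corpus: CuiCorpus,
    top_n: int = 10,
    labels: Mapping[int, str] | None = None,
    denominator: str = "tokens",
) -> list[TopicSummary]:
    """Summarize each topic by its top CUIs and their representative
    mentions.

    Per topic: the ``top_n`` CUIs by p(cui|topic); each rendered as the
    surface form with the highest corpus-wide annotation-instance count
    among forms mapped to that CUI (ties lexicographically first, logged);
    annotated with the CUI's corpus frequency percentage. Order follows
    the topic-CUI probability. A CUI never observed in the annotations
    (possible only through smoothing) is rendered as its own identifier
    and flagged in the log.
    """
    # corpus-wide instance count per (cui, surface)
    surface_counts: dict[str, Counter[str]] = {}
    for a in annotations:
        for cui in a.cuis:
            surface_counts.setdefault(cui, Counter())[a.surface] += 1
    freqs = cui_frequencies(corpus, denominator=denominator)
    labels = labels or {}
    summaries = []
    for k in range(model.K):
        order = np.argsort(-model.beta[k], kind="stable")[:top_n]
        top = tuple((model.vocabulary[v], float(model.beta[k, v])) for v in order)
        mentions = []
        for cui, _ in top:
            forms = surface_counts.get(cui)
            if not forms:
                logger.warning("topic %d: CUI %s has no observed surface form", k, cui)
                mentions.append((cui, freqs.get(cui, 0.0)))
                continue
            peak = max(forms.values())
            candidates = sorted(s for s, n in forms.items() if n == peak)
            if len(candidates) > 1:
                logger.debug(
                    "topic %d CUI %s: frequency tie among %s, chose %r",
                    k, cui, candidates, candidates[0],
                )
            mentions.append((candidates[0], freqs.get(cui, 0.0)))
        summaries.append(
            TopicSummary(
                topic_id=k,
                top_cuis=top,
                representative_mentions=tuple(mentions),
                label=labels.get(k),
            )
        )
    return summaries


def render_report(
    summaries: Sequence[TopicSummary],
    distribution: TopicDistribution,
    stats: Mapping[str, object] | None,
    out_dir: str | Path,
    config_fingerprint: str | None = None,
) -> list[Path]:
    """Write the topic report: per-topic TSV, distribution TSV, and a
    human-readable summary. Deterministic for fixed inputs."""
    if not summaries:
        raise ValueError("no topic summaries to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topics_path = out / "topics.tsv"
    with open(topics_path, "w", encoding="utf-8") as fh:
        fh.write("topic\trank\tcui\tp_cui_given_topic\tmention\tcorpus_pct\n")
        for s in summaries:
            for rank, ((cui, p), (mention, pct)) in enumerate(
                zip(s.top_cuis, s.representative_mentions), 1
            ):
                fh.write(f"{s.topic_id}\t{rank}\t{cui}\t{p:.6f}\t{mention}\t{pct:.2f}\n")
    dist_path = out / "topic_distribution.tsv"
    with open(dist_path, "w", encoding="utf-8") as fh:
        fh.write("topic\tn_posts\tpct_posts\n")
        for t, n, pct in distribution.rows:
            fh.write(f"{t}\t{n}\t{pct:.1f}\n")
    text_path = out / "report.txt"
    with open(text_path, "w", encoding="utf-8") as fh:
        if config_fingerprint:
            fh.write(f"run: {config_fingerprint}\n\n")
        if stats:
            fh.write("corpus statistics\n")
            for key, val in stats.items():
                fh.write(f"  {key}: {val}\n")
            fh.write("\n")
        for s in summaries:
            label = f" ({s.label})" if s.label else ""
            fh.write(f"topic {s.topic_id}{label}\n")
            fh.write(
                "  "
                + "; ".join(f"{m} ({pct:.2f})" for m, pct in s.representative_mentions)
                + "\n"
            )
        fh.write("\nposts per topic\n")
        for t, n, pct in distribution.rows:
            fh.write(f"  topic {t}: {n} ({pct:.1f}%)\n")
    return [topics_path, dist_path, text_path]


def parse_distribution_tsv(path: str | Path) -> TopicDistribution:
    rows = []
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            t, n, pct = line.rstrip("\n").split("\t")
            rows.append((int(t), int(n), float(pct)))
    return TopicDistribution(rows=rows)
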