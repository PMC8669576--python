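"""End-to-end orchestration: clean -> annotate -> filter -> bag-of-CUI ->
grid search -> report, driven by a validated YAML config.

Every artifact is stamped with a fingerprint of the config and seed;
re-running an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotator, corpus as corpus_mod, preprocess, report, topic_model

__all__ = ["RunConfig", "ConfigError", "PipelineError", "validate_config", "run"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Config schema violations; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    posts: str = ""
    dictionary: str = ""
    stoplist: str | None = None  # None -> bundled frozen list
    out_dir: str = "cuitopics_out"
    keep_categories: list[str] = field(
        default_factory=lambda: sorted(annotator.KEEP_DEFAULT)
    )
    K_grid: list[int] = field(default_factory=lambda: list(topic_model.K_GRID_DEFAULT))
    alpha_grid: list[float] = field(
        default_factory=lambda: list(topic_model.ALPHA_GRID_DEFAULT)
    )
    chosen_K: int | None = None
    chosen_alpha: float | None = None
    chosen_override: bool = False
    eta: float = 0.01
    em_tol: float = 1e-4
    var_tol: float = 1e-6
    max_iter: int = 100
    n_restarts: int = 3
    seed: int = 0
    heldout_fraction: float = 0.0
    annotate_pre_stopword: bool = False
    frequency_denominator: str = "tokens"
    top_n: int = 10
    topic_labels: dict[int, str] = field(default_factory=dict)

    def fingerprint(self) -> str:
        """Digest of the analysis parameters (output location excluded, so
        the same analysis written elsewhere reproduces identical bytes)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def lda_options(self) -> topic_model.LdaOptions:
        return topic_model.LdaOptions(
            max_iter=self.max_iter,
            em_tol=self.em_tol,
            var_tol=self.var_tol,
            eta=self.eta,
            seed=self.seed,
            n_restarts=self.n_restarts,
        )


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, applying defaults.

    All schema violations are collected and reported together; unknown
    keys are errors (typo guard).
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    errors = [f"unknown key {k!r}" for k in raw if k not in _FIELDS]
    cfg = RunConfig()
    for key, val in raw.items():
        if key in _FIELDS:
            setattr(cfg, key, val)
    if not cfg.posts:
        errors.append("'posts' path is required")
    if not cfg.dictionary:
        errors.append("'dictionary' path is required")
    if not cfg.K_grid:
        errors.append("K_grid must be non-empty")
    elif any((not isinstance(k, int)) or k < 1 for k in cfg.K_grid):
        errors.append("K_grid entries must be positive integers")
    if not cfg.alpha_grid:
        errors.append("alpha_grid must be non-empty")
    elif any(a <= 0 for a in cfg.alpha_grid):
        errors.append("alpha_grid entries must be positive")
    unknown_cats = set(cfg.keep_categories) - annotator.CATEGORIES
    if unknown_cats:
        errors.append(f"unknown keep_categories: {sorted(unknown_cats)}")
    if cfg.frequency_denominator not in ("tokens", "posts"):
        errors.append("frequency_denominator must be 'tokens' or 'posts'")
    if not 0.0 <= cfg.heldout_fraction < 1.0:
        errors.append("heldout_fraction must lie in [0, 1)")
    if cfg.eta < 0:
        errors.append("eta must be >= 0")
    if not cfg.chosen_override:
        if cfg.chosen_K is not None and cfg.K_grid and cfg.chosen_K not in cfg.K_grid:
            errors.append(
                f"chosen_K={cfg.chosen_K} not in K_grid (set chosen_override to allow)"
            )
        if (
            cfg.chosen_alpha is not None
            and cfg.alpha_grid
            and cfg.chosen_alpha not in cfg.alpha_grid
        ):
            errors.append(
                f"chosen_alpha={cfg.chosen_alpha} not in alpha_grid "
                "(set chosen_override to allow)"
            )
    if cfg.topic_labels:
        cfg.topic_labels = {int(k): str(v) for k, v in cfg.topic_labels.items()}
    if errors:
        raise ConfigError(errors)
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns a map of artifact names to paths."""
    for path, what in ((config.posts, "posts"), (config.dictionary, "dictionary")):
        if not Path(path).exists():
            raise PipelineError(f"{what} path does not exist: {path}")
    if config.stoplist and not Path(config.stoplist).exists():
        raise PipelineError(f"stoplist path does not exist: {config.stoplist}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fp = config.fingerprint()
    artifacts: dict[str, Path] = {}

    posts = _stage("load")(preprocess.read_posts_jsonl)(config.posts)
    dictionary = _stage("load")(annotator.load_dictionary)(config.dictionary)
    stoplist = (
        preprocess.load_stopwords(config.stoplist)
        if config.stoplist
        else preprocess.default_stopwords()
    )
    logger.info("loaded %d posts, %d dictionary entries", len(posts), len(dictionary))

    @_stage("clean")
    def _clean():
        active = frozenset() if config.annotate_pre_stopword else stoplist
        cleaned = [preprocess.clean_post(p, active) for p in posts]
        path = out / "clean_posts.jsonl"
        preprocess.write_clean_jsonl(cleaned, path)
        return cleaned, path

    cleaned, artifacts["clean"] = _clean()
    logger.info("cleaned %d posts (%d empty)", len(cleaned), sum(not c.tokens for c in cleaned))

    @_stage("annotate")
    def _annotate():
        anns = [a for post in cleaned for a in annotator.annotate(post, dictionary)]
        path = out / "annotations.tsv"
        annotator.write_annotations_tsv(anns, path)
        return anns, path

    anns, artifacts["annotations"] = _annotate()

    @_stage("filter")
    def _filter():
        kept = annotator.filter_categories(anns, frozenset(config.keep_categories))
        path = out / "annotations_filtered.tsv"
        annotator.write_annotations_tsv(kept, path)
        return kept, path

    kept, artifacts["annotations_filtered"] = _filter()
    logger.info("annotations: %d extracted, %d after category filter", len(anns), len(kept))

    @_stage("stats")
    def _stats():
        cstats = corpus_mod.corpus_stats(posts)
        astats = corpus_mod.annotation_stats(kept)
        path = out / "stats.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# corpus\nn_posts\tl_max\tl_min\tl_avg\tl_sd\tn_words\n")
            fh.write(
                f"{cstats.n_posts}\t{cstats.l_max}\t{cstats.l_min}"
                f"\t{cstats.l_avg:.2f}\t{cstats.l_sd:.2f}\t{cstats.n_words}\n"
            )
            fh.write("# annotations\nannots\tmaps\tM\tC\tM_over_C\tC_over_M\tS\tD\tP\n")
            fh.write(
                f"{astats.annots}\t{astats.maps}\t{astats.M}\t{astats.C}"
                f"\t{astats.M_over_C}\t{astats.C_over_M}"
                f"\t{astats.S}\t{astats.D}\t{astats.P}\n"
            )
        return cstats, astats, path

    cstats, astats, artifacts["stats"] = _stats()

    @_stage("bag-of-cui")
    def _bag():
        by_post: dict[str, list] = {}
        for a in kept:
            by_post.setdefault(a.post_id, []).append(a)
        docs = [
            corpus_mod.to_cui_document(c, by_post.get(c.id, [])) for c in cleaned
        ]
        cui_corpus = corpus_mod.build_corpus(docs)
        if cui_corpus.n_empty:
            logger.info(
                "%d empty bag-of-CUI documents excluded from fitting",
                cui_corpus.n_empty,
            )
        corpus_mod.write_corpus(cui_corpus, out / "corpus.tsv", out / "vocabulary.txt")
        return cui_corpus

    cui_corpus = _bag()
    artifacts["corpus"] = out / "corpus.tsv"
    logger.info(
        "bag-of-CUI corpus: %d docs, vocabulary %d, %d tokens",
        len(cui_corpus), len(cui_corpus.vocabulary), cui_corpus.n_tokens,
    )

    @_stage("grid")
    def _grid():
        result = topic_model.grid_search(
            cui_corpus,
            config.K_grid,
            config.alpha_grid,
            config.lda_options(),
            heldout_fraction=config.heldout_fraction,
        )
        path = out / "grid.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("K\talpha\tperplexity\telbo\n")
            for K, alpha, perp, elbo in result.as_table():
                fh.write(f"{K}\t{alpha}\t{perp:.6f}\t{elbo:.6f}\n")
        return result, path

    grid, artifacts["grid"] = _grid()

    @_stage("fit")
    def _fit():
        if config.chosen_K is not None and config.chosen_alpha is not None:
            K, alpha = config.chosen_K, config.chosen_alpha
            logger.info("using configured model choice K=%d alpha=%s", K, alpha)
        else:
            K, alpha = grid.rows[0]["K"], grid.rows[0]["alpha"]
            logger.info(
                "no chosen (K, alpha) in config; provisionally taking the "
                "lowest-perplexity grid point K=%d alpha=%s", K, alpha,
            )
        model, posterior = topic_model.fit_lda(
            cui_corpus, K, alpha, config.lda_options()
        )
        topic_model.save_model(model, posterior, out / "model")
        return model, posterior

    model, posterior = _fit()
    artifacts["model"] = out / "model"

    @_stage("report")
    def _report():
        assignments = report.assign_topics(posterior)
        distribution = report.topic_distribution(assignments)
        summaries = report.representative_mentions(
            model,
            kept,
            cui_corpus,
            top_n=config.top_n,
            labels=config.topic_labels,
            denominator=config.frequency_denominator,
        )
        stats_map = {
            "n_posts": cstats.n_posts,
            "n_words": cstats.n_words,
            "l_avg": f"{cstats.l_avg:.2f}",
            "annots": astats.annots,
            "C": astats.C,
            "vocabulary": len(cui_corpus.vocabulary),
            "seed": config.seed,
        }
        return report.render_report(
            summaries, distribution, stats_map, out, config_fingerprint=fp
        )

    for p in _report():
        artifacts[p.name] = p
    logger.info("pipeline complete; artifacts in %s (run %s)", out, fp)
    return artifacts
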