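"""End-to-end orchestration: config, run stages, manifests.

Each stage is a plain function taking a :class:`RunConfig` and returning
the paths it wrote, so the CLI stays a thin shell and the whole pipeline
is scriptable from Python.  Every run writes a JSON manifest (config hash,
seed, package version, per-forum summary counts) and pairs every figure
with the TSV behind it, so numbers are auditable without image parsing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from forumlens import __version__
from forumlens.corpus_io import (
    Corpus,
    read_doc_topics,
    read_posts,
    read_stop_words,
    write_doc_topics,
    write_posts,
    StopWordList,
)
from forumlens.errors import ValidationError
from forumlens.lexicon_prevalence import (
    default_lexicons,
    load_lexicons,
    prevalence,
    render_heatmap,
)
from forumlens.synthetic_data import SimConfig, simulate_corpus
from forumlens.topic_bars import (
    DEFAULT_THRESHOLD_GRID,
    TopicCategoryMap,
    calibrate_threshold,
    category_proportions,
    count_document_topics,
    proportions_to_tsv,
    render_topic_bars,
    run_manifest,
    topic_proportions,
)
from forumlens.topic_model import (
    LdaParams,
    estimate_phi,
    estimate_theta,
    fit_lda,
    top_words_table,
)

logger = logging.getLogger("forumlens")

__all__ = ["ForumSpec", "RunConfig", "run_simulate", "run_prevalence",
           "run_lda", "run_topicbars", "run_all"]


@dataclass
class ForumSpec:
    """One forum's inputs: corpus path, K, optional external doc-topics."""

    forum_id: str
    path: str | None = None
    k: int = 20
    doc_topics: str | None = None  # skip LDA, use these compositions
    topic_map: str | None = None

    def __post_init__(self) -> None:
        if not self.forum_id:
            raise ValidationError("forum_id must be non-empty")
        if self.path is None and self.doc_topics is None:
            raise ValidationError(
                f"forum {self.forum_id!r}: need a corpus path or doc_topics"
            )


@dataclass
class RunConfig:
    """Validated pipeline configuration (usually loaded from YAML)."""

    output_dir: str = "forumlens_out"
    seed: int = 0
    forums: list[ForumSpec] = field(default_factory=list)
    lexicons: str | None = None          # packaged starter set when None
    stopwords: list[str] = field(default_factory=list)
    threshold_grid: list[float] = field(
        default_factory=lambda: list(DEFAULT_THRESHOLD_GRID)
    )
    lda: dict = field(default_factory=dict)  # n_iterations, burn_in, ...
    simulate: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        ids = [f.forum_id for f in self.forums]
        if len(set(ids)) != len(ids):
            raise ValidationError("forum ids must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        with path.open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        forums = [ForumSpec(**spec) for spec in raw.pop("forums", [])]
        cfg = cls(forums=forums, **raw)
        base = path.parent
        for f in cfg.forums:
            for attr in ("path", "doc_topics", "topic_map"):
                val = getattr(f, attr)
                if val is not None and not Path(val).is_absolute():
                    setattr(f, attr, str(base / val))
        if cfg.lexicons is not None and not Path(cfg.lexicons).is_absolute():
            cfg.lexicons = str(base / cfg.lexicons)
        cfg.stopwords = [
            str(base / s) if not Path(s).is_absolute() else s
            for s in cfg.stopwords
        ]
        return cfg

    def validate_paths(self) -> None:
        for f in self.forums:
            for val in (f.path, f.doc_topics, f.topic_map):
                if val is not None and not Path(val).exists():
                    raise ValidationError(f"missing input file: {val}")
        if self.lexicons is not None and not Path(self.lexicons).exists():
            raise ValidationError(f"missing lexicon file: {self.lexicons}")
        for s in self.stopwords:
            if not Path(s).exists():
                raise ValidationError(f"missing stop-word file: {s}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "output_dir": self.output_dir,
                "seed": self.seed,
                "forums": [vars(f) for f in self.forums],
                "lexicons": self.lexicons,
                "stopwords": self.stopwords,
                "threshold_grid": self.threshold_grid,
                "lda": self.lda,
                "simulate": self.simulate,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def load_lexicons(self):
        if self.lexicons is None:
            return default_lexicons()
        return load_lexicons(self.lexicons)

    def load_stops(self) -> StopWordList:
        from importlib.resources import files

        if not self.stopwords:
            return read_stop_words(files("forumlens.data").joinpath("stopwords.txt"))  # type: ignore[arg-type]
        return read_stop_words(*self.stopwords)


def _write_manifest(out_dir: Path, stage: str, cfg: RunConfig, payload: dict) -> Path:
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        **payload,
    }
    path = out_dir / f"{stage}_manifest.json"
    with path.open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_simulate(cfg: RunConfig) -> dict[str, Path]:
    """Generate a synthetic corpus (+ ground truth) under output_dir."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(cfg.simulate)
    sim_kwargs.setdefault("seed", cfg.seed)
    if "injection" in sim_kwargs:
        sim_kwargs["injection"] = tuple(
            (str(c), float(p)) for c, p in sim_kwargs["injection"]
        )
    sim_cfg = SimConfig(**sim_kwargs)
    corpus, truth = simulate_corpus(sim_cfg, lexicons=cfg.load_lexicons())
    corpus_path = write_posts(corpus, out_dir / f"{sim_cfg.forum_id}.jsonl")
    truth_path = truth.save(out_dir / f"{sim_cfg.forum_id}_truth.npz")
    manifest = _write_manifest(
        out_dir,
        "simulate",
        cfg,
        {
            "sim_config": sim_cfg.to_dict(),
            "n_posts": len(corpus),
            "corpus": str(corpus_path),
            "ground_truth": str(truth_path),
        },
    )
    logger.info("simulated %d posts -> %s", len(corpus), corpus_path)
    return {"corpus": corpus_path, "ground_truth": truth_path, "manifest": manifest}


def _load_corpora(cfg: RunConfig) -> list[Corpus]:
    corpora = []
    for f in cfg.forums:
        if f.path is None:
            continue
        corpora.append(read_posts(f.path, forum_id=f.forum_id))
    if not corpora:
        raise ValidationError("no forum corpora configured")
    return corpora


def run_prevalence(cfg: RunConfig) -> dict[str, Path]:
    """Lexicon prevalence matrix + heat map over all configured forums."""
    cfg.validate_paths()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lexicons = cfg.load_lexicons()
    corpora = _load_corpora(cfg)
    matrix = prevalence(corpora, lexicons)
    tsv = matrix.to_tsv(out_dir / "prevalence.tsv")
    fig = render_heatmap(matrix, out_dir / "prevalence_heatmap.png")
    import matplotlib.pyplot as plt

    plt.close(fig)
    manifest = _write_manifest(
        out_dir,
        "prevalence",
        cfg,
        {
            "forums": matrix.forums,
            "categories": matrix.categories,
            "n_posts": {c.forum_id: len(c) for c in corpora},
        },
    )
    logger.info("prevalence over %d forums x %d categories -> %s",
                len(matrix.forums), len(matrix.categories), tsv)
    return {
        "prevalence": tsv,
        "heatmap": out_dir / "prevalence_heatmap.png",
        "manifest": manifest,
    }


def run_lda(cfg: RunConfig) -> dict[str, Path]:
    """Fit LDA per forum; write doc-topics TSV, top-words TSV and state."""
    cfg.validate_paths()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stops = cfg.load_stops()
    outputs: dict[str, Path] = {}
    summary = {}
    for f in cfg.forums:
        if f.doc_topics is not None:
            logger.info("forum %s: external doc-topics supplied, skipping LDA",
                        f.forum_id)
            continue
        corpus = read_posts(f.path, forum_id=f.forum_id)  # type: ignore[arg-type]
        corpus.tokenize_posts(stops)
        params = LdaParams(k=f.k, seed=cfg.seed, **cfg.lda)
        state = fit_lda(corpus, params)
        theta = estimate_theta(state)
        phi = estimate_phi(state)
        dt_path = write_doc_topics(
            theta.theta,
            out_dir / f"{f.forum_id}_doc_topics.tsv",
            doc_names=[p.post_id for p in corpus.posts],
        )
        tw_path = out_dir / f"{f.forum_id}_top_words.tsv"
        with tw_path.open("w", encoding="utf-8") as fh:
            fh.write("topic\trank\tterm\tprobability\n")
            for topic, rank, term, prob in top_words_table(phi, min(10, phi.n_vocab)):
                fh.write(f"{topic}\t{rank}\t{term}\t{prob:.6f}\n")
        state_path = state.save(out_dir / f"{f.forum_id}_lda_state.npz")
        outputs[f"{f.forum_id}_doc_topics"] = dt_path
        outputs[f"{f.forum_id}_top_words"] = tw_path
        outputs[f"{f.forum_id}_state"] = state_path
        summary[f.forum_id] = {
            "n_posts": len(corpus),
            "k": f.k,
            "n_tokens": int(state.doc_lengths.sum()),
            "params": params.to_dict(),
        }
        logger.info("forum %s: fitted K=%d on %d posts", f.forum_id, f.k, len(corpus))
    outputs["manifest"] = _write_manifest(out_dir, "lda", cfg, {"forums": summary})
    return outputs


def run_topicbars(cfg: RunConfig) -> dict[str, Path]:
    """Threshold calibration, proportions and the Topic Bars figure.

    Per forum: obtain θ (from the LDA stage's doc-topics TSV, or an
    externally supplied one), calibrate the document-topic threshold on
    the configured grid, count document-topics, aggregate per-category and
    render one stacked bar per forum.  The manifest records the summary
    counts (posts, topics, threshold, document-topics) per forum.
    """
    cfg.validate_paths()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    manifests = []
    shared_colors: dict[str, str] = {}
    for f in cfg.forums:
        dt_path = (
            Path(f.doc_topics)
            if f.doc_topics is not None
            else out_dir / f"{f.forum_id}_doc_topics.tsv"
        )
        if not dt_path.exists():
            raise ValidationError(
                f"forum {f.forum_id!r}: no doc-topics at {dt_path}; "
                "run the lda stage first or supply doc_topics"
            )
        theta = read_doc_topics(dt_path)
        k = theta.shape[1]
        threshold = calibrate_threshold(theta, cfg.threshold_grid)
        dts = count_document_topics(theta, threshold)
        fractions = topic_proportions(dts, k)
        tc_map = (
            TopicCategoryMap.from_csv(f.topic_map)
            if f.topic_map is not None
            else TopicCategoryMap.identity(k)
        )
        shared_colors.update(tc_map.colors)
        row = category_proportions(fractions, tc_map, forum_id=f.forum_id)
        rows.append(row)
        manifests.append(
            run_manifest(
                f.forum_id,
                n_posts=theta.shape[0],
                k=k,
                threshold=threshold,
                n_document_topics=len(dts),
                grid=cfg.threshold_grid,
            )
        )
        logger.info(
            "forum %s: threshold %.2f -> %d document-topics over %d posts",
            f.forum_id, threshold, len(dts), theta.shape[0],
        )
    tsv = proportions_to_tsv(rows, out_dir / "topic_bars.tsv")
    fig = render_topic_bars(rows, shared_colors, out_dir / "topic_bars.png")
    import matplotlib.pyplot as plt

    plt.close(fig)
    manifest = _write_manifest(out_dir, "topicbars", cfg, {"forums": manifests})
    return {
        "proportions": tsv,
        "figure": out_dir / "topic_bars.png",
        "manifest": manifest,
    }


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """prevalence + lda + topicbars over the configured forums."""
    outputs = {}
    outputs.update({f"prevalence_{k}": v for k, v in run_prevalence(cfg).items()})
    outputs.update({f"lda_{k}": v for k, v in run_lda(cfg).items()})
    outputs.update({f"topicbars_{k}": v for k, v in run_topicbars(cfg).items()})
    return outputs
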