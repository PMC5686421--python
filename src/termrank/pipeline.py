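"""End-to-end orchestration: extract -> termhood -> label -> features ->
train -> rank -> evaluate, from a single YAML-loadable configuration.

Reruns with an identical configuration produce byte-identical artifacts; the
run manifest records the configuration hash, seeds, package version and the
SHA-256 of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as trio
from .datatypes import (
    ConfigurationError,
    ExtractionConfig,
    LabelingConfig,
    SplitProtocol,
    TransferConfig,
)
from .evaluation import evaluate_systems, make_splits
from .extract import DEFAULT_STOPWORDS, extract_candidates
from .features import FeatureBuilder
from .labeling import build_source_set
from .models import model_to_dict, predict_scores, train_system
from .termhood import c_value, corpus_tfidf

log = logging.getLogger("termrank")


@dataclass
class PipelineConfig:
    corpus_dir: str
    lexicon: str
    embeddings: str
    ngrams: str
    concepts: str
    annotated: str
    out_dir: str
    seed: int = 0
    stopwords: str | None = None          # optional stopword file, one token per line
    familiarity_threshold: float = 0.6
    n_source_pos: int = 3000
    n_source_neg: int = 3000
    system: str = "ADS-sds"               # system used for the ranking deliverable
    eval_systems: tuple[str, ...] = ("SourceOnly", "TargetOnly", "ADS-fsa", "ADS-sds")
    n_repeats: int = 100
    target_pool_size: int = 1000
    L_values: tuple[int, ...] = (100, 200, 500, 1000)
    cv_folds: int = 5
    ablation: tuple[str, ...] = ()
    top_n: int | None = None
    run_evaluation: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("eval_systems", "L_values", "ablation"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location is not
        part of what the artifacts depend on)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the four pipeline stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 1: data extraction
    log.info("stage extract: reading corpus and mining candidates")
    try:
        corpus = trio.read_corpus(config.corpus_dir)
        stop = DEFAULT_STOPWORDS
        if config.stopwords:
            stop = frozenset(
                w.strip().lower() for w in Path(config.stopwords).read_text().split() if w.strip()
            )
        candidates = extract_candidates(corpus, ExtractionConfig(stopwords=stop))
        trio.write_candidates(candidates, out / "candidates.tsv")
    except Exception as e:
        raise ConfigurationError(f"stage extract failed: {e}") from e

    # stage 2: distant labeling
    log.info("stage label: distant supervision from the lexicon")
    try:
        lexicon = trio.read_lexicon(config.lexicon)
        annotated = trio.read_annotated_terms(config.annotated)
        annotated_terms = {t for t, _ in annotated}
        lab_cfg = LabelingConfig(
            familiarity_threshold=config.familiarity_threshold,
            n_pos=config.n_source_pos,
            n_neg=config.n_source_neg,
            seed=config.seed,
        )
        source_train = build_source_set(candidates, annotated_terms, lexicon, lab_cfg)
        trio.write_annotated_terms(source_train, out / "source_train.tsv")
    except ConfigurationError:
        raise
    except Exception as e:
        raise ConfigurationError(f"stage label failed: {e}") from e

    # stage 3: features + adapted training, ranking deliverable
    log.info("stage train: features and %s model", config.system)
    try:
        embeddings = trio.read_embeddings(config.embeddings)
        ngrams = trio.read_ngram_table(config.ngrams)
        concepts = trio.read_concepts(config.concepts)
        builder = FeatureBuilder(
            embeddings=embeddings,
            concept_dict=concepts,
            ngrams=ngrams,
            c_values=c_value(candidates),
            tfidf=corpus_tfidf(candidates, len(corpus)),
            ablate=config.ablation,
        )
        cand_terms = [c.surface for c in candidates]
        all_terms = list(dict.fromkeys(cand_terms + [t for t, _ in annotated]))
        raw = {t: builder.raw(t) for t in all_terms}

        src_terms = [t for t, _ in source_train]
        ys = np.array([l for _, l in source_train], dtype=float)
        tgt_terms = [t for t, _ in annotated]
        ytr = np.array([l for _, l in annotated], dtype=float)
        train_terms = src_terms + tgt_terms
        train_X = np.vstack([raw[t] for t in train_terms])
        mu, sd = train_X.mean(axis=0), train_X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        std = lambda M: (M - mu) / sd
        Xs = std(np.vstack([raw[t] for t in src_terms]))
        Xt = std(np.vstack([raw[t] for t in tgt_terms]))
        transfer_cfg = TransferConfig(cv_folds=config.cv_folds, seed=config.seed)
        model = train_system(config.system, Xs, ys, Xt, ytr, transfer_cfg)
        with open(out / "model.json", "w", encoding="utf-8") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")

        Xc = std(np.vstack([raw[t] for t in cand_terms]))
        scores = predict_scores(model, Xc)
        ranked = sorted(zip(cand_terms, scores), key=lambda r: (-r[1], r[0]))
        if config.top_n is not None:
            ranked = ranked[: config.top_n]
        trio.write_ranking([(t, float(s)) for t, s in ranked], out / "ranking.tsv")
    except ConfigurationError:
        raise
    except Exception as e:
        raise ConfigurationError(f"stage train failed: {e}") from e

    # stage 4: repeated-split evaluation
    outputs = ["candidates.tsv", "source_train.tsv", "model.json", "ranking.tsv"]
    if config.run_evaluation:
        log.info("stage evaluate: repeated-split protocol")
        try:
            protocol = SplitProtocol(
                n_repeats=config.n_repeats,
                target_pool_size=config.target_pool_size,
                L_values=config.L_values,
                seed=config.seed,
            )
            splits = make_splits(annotated, protocol)
            report = evaluate_systems(
                systems=list(config.eval_systems),
                splits=splits,
                raw_features=raw,
                source_train=source_train,
                transfer_cfg=transfer_cfg,
                L_values=config.L_values,
            )
            trio.write_report(report, out / "report.json")
            outputs.append("report.json")
        except ConfigurationError:
            raise
        except Exception as e:
            raise ConfigurationError(f"stage evaluate failed: {e}") from e

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
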