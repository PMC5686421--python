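"""Synthetic world generator for the term-ranking pipeline.

Real inputs to this pipeline (clinical notes, a consumer-health lexicon with
familiarity scores, embeddings trained on clinical text, general-domain
n-gram counts, a concept dictionary, expert importance annotations) are
licensed and cannot ship.  This module generates all six artifacts from one
seed, with a known generative truth, so that the full pipeline and the
transfer-learning properties are testable offline.

Generative model
----------------
Each pseudo-word ``w`` carries a latent medicalness ``m_w ~ Beta(2,2)``.
A planted term (1-4 words) has three latent factors mirroring the criteria
experts use to judge importance:

* familiarity      ``fam = clip(1 - mean(m_w) + eps)`` — compounds of
  familiar words are familiar;
* corpus termhood  ``tho ~ Beta(2,2)`` — how strongly the term denotes a
  domain concept in this corpus; independent of familiarity;
* compound quality ``qual = m_head`` — medicalness of the head word; a
  compound headed by a familiar word is a low-quality compound whose
  meaning is the sum of its parts.

Gold importance is ``y ~ Bernoulli(sigmoid(a_f (thr - fam) + a_t (tho - 1/2)
+ a_q (qual - 1/2) [compounds only]))``.

The lexicon stores ``fam`` plus small observation noise, so the distant rule
"familiarity <= thr" recovers the familiarity factor but is structurally
blind to termhood and compound quality — the source/target task mismatch.
Two further documented error modes are injected: scores within
``boundary_width`` of the threshold are reflected across it with probability
``boundary_flip`` (no clear boundary between familiar and unfamiliar terms
near the cut-off), and low-quality compounds slightly above the threshold
are pushed below it with probability ``compound_mislabel`` (lexicon-positive
compounds the experts would reject).

Each factor is planted in a feature channel with deliberately different
dimensionality: familiarity is carried almost entirely by the
``embedding_dim``-dimensional word embeddings (diffuse — many labels are
needed to estimate the direction, which is what makes the large distantly
labeled source set valuable), termhood by corpus frequency and hence the
two automatic-term-recognition features (compact — a small expert-labeled
set suffices, which is what the transfer learners exploit), and compound
quality by the head-word semantic-type bits.  General-domain counts decay
mildly with medicalness.  Latent factors are kept alongside the artifacts
so Bayes-optimal rankings and parameter-recovery assertions are computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as trio
from .datatypes import (
    CandidateTerm,
    ConfigurationError,
    Corpus,
    EmbeddingTable,
    ExtractionConfig,
    LabeledExample,
    LabelingConfig,
    LexiconEntry,
    NgramFrequencyTable,
)
from .extract import DEFAULT_STOPWORDS, extract_candidates
from .features import FeatureBuilder
from .labeling import build_source_set
from .termhood import c_value, corpus_tfidf

_SYL_ONSET = "b c d f g l m n p r s t v z br cr dr gl pr st tr".split()
_SYL_NUCLEUS = "a e i o u ae ia eo".split()


def _make_words(n: int, rng: np.random.Generator) -> list[str]:
    """Deterministic pronounceable pseudo-words, unique, non-stopword."""
    words: list[str] = []
    seen: set[str] = set(DEFAULT_STOPWORDS)
    while len(words) < n:
        k = rng.integers(2, 5)
        w = "".join(
            _SYL_ONSET[rng.integers(len(_SYL_ONSET))] + _SYL_NUCLEUS[rng.integers(len(_SYL_NUCLEUS))]
            for _ in range(k)
        )
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


@dataclass
class SyntheticConfig:
    """Sizes, the importance model and the source-label noise model.

    Defaults are the desk-scale study conditions: a 600-example balanced
    source set drawn from 3400 planted terms, 2600 annotated terms
    (pool 1000 / evaluation 1600 downstream) and boundary noise 0.15 within
    +-0.05 of the familiarity threshold 0.6.
    """

    vocab_size: int = 1000
    n_docs: int = 150
    doc_length: int = 150         # mean term occurrences per document
    embedding_dim: int = 96
    n_semantic_codes: int = 6
    n_terms: int = 3400
    n_annotated: int = 2600
    # importance model
    familiarity_threshold: float = 0.6
    fam_coef: float = 10.0
    termhood_coef: float = 6.0
    qual_coef: float = 3.0
    # source-label noise
    boundary_flip: float = 0.15
    boundary_width: float = 0.05
    compound_mislabel: float = 0.20
    familiarity_noise: float = 0.02
    lexicon_missing_rate: float = 0.30
    component_lexicon_coverage: float = 0.85
    # resource signal/noise: how strongly each feature channel encodes the
    # latent medicalness, and how noisily
    embedding_noise: float = 0.50
    embedding_signal: float = 3.0
    ngram_log_noise: float = 1.2
    ngram_fam_slope: float = 0.5
    corpusfreq_fam_slope: float = 0.15
    corpusfreq_termhood_slope: float = 0.8
    semantic_m_threshold: float = 0.8
    # optional biased annotation pool: annotate only the top fraction of a
    # noisy medicalness ranking (mirrors pre-filtering by earlier rankers)
    prefilter_top_frac: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("boundary_flip", "compound_mislabel", "lexicon_missing_rate",
                     "familiarity_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        for name in ("vocab_size", "n_docs", "doc_length", "embedding_dim",
                     "n_semantic_codes", "n_terms", "n_annotated"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_annotated > self.n_terms:
            raise ConfigurationError("n_annotated cannot exceed n_terms")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "SyntheticConfig":
        """Sizes mirroring the full study (6038 annotated, 3000/3000 source
        pool feasible); an order of magnitude slower than the defaults."""
        return cls(
            vocab_size=4000,
            n_docs=800,
            doc_length=80,
            embedding_dim=200,
            n_terms=24000,
            n_annotated=6038,
            seed=seed,
        )


@dataclass
class SyntheticWorld:
    """The six generated artifacts plus generative truth and extraction output."""

    cfg: SyntheticConfig
    corpus: Corpus
    lexicon: list[LexiconEntry]
    embeddings: EmbeddingTable
    ngrams: NgramFrequencyTable
    concepts: list[LexiconEntry]
    annotated: list[tuple[str, int]]
    truth: dict[str, dict] = field(default_factory=dict)
    candidates: list[CandidateTerm] = field(default_factory=list)
    terms: list[str] = field(default_factory=list)

    def feature_builder(self, ablate: tuple[str, ...] = ()) -> FeatureBuilder:
        cv = c_value(self.candidates)
        tfidf = corpus_tfidf(self.candidates, len(self.corpus))
        return FeatureBuilder(
            embeddings=self.embeddings,
            concept_dict=self.concepts,
            ngrams=self.ngrams,
            c_values=cv,
            tfidf=tfidf,
            ablate=ablate,
        )

    def bayes_scores(self, terms: list[str]) -> np.ndarray:
        """Posterior importance probability under the generative truth."""
        return np.array([self.truth[t]["gold_p"] for t in terms])


def generate_world(cfg: SyntheticConfig) -> SyntheticWorld:
    """Generate the six input artifacts deterministically from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    thr = cfg.familiarity_threshold

    words = _make_words(cfg.vocab_size, rng)
    m = rng.beta(2.0, 2.0, size=cfg.vocab_size)
    m_of = dict(zip(words, m))

    # --- embeddings: medicalness along a planted unit direction + noise
    u = rng.normal(size=cfg.embedding_dim)
    u /= np.linalg.norm(u)
    vectors = {
        w: (m_of[w] - 0.5) * cfg.embedding_signal * u
        + rng.normal(0.0, cfg.embedding_noise, cfg.embedding_dim)
        for w in words
    }
    embeddings = EmbeddingTable(dimension=cfg.embedding_dim, vectors=vectors)

    # --- general-domain unigram counts: frequent iff familiar
    counts: dict[str, float] = {
        w: float(np.round(np.exp(3.0 + cfg.ngram_fam_slope * 2.0 * (1.0 - m_of[w])
                          + rng.normal(0.0, cfg.ngram_log_noise))))
        for w in words
    }

    # --- planted terms
    # single-word terms draw from a reserved slice of the vocabulary so that
    # a planted single word never occurs inside a compound: its corpus
    # frequency then reflects its own prominence, not other terms'
    length_probs = np.array([0.35, 0.40, 0.18, 0.07])
    n_single = min(int(round(cfg.n_terms * length_probs[0])), cfg.vocab_size // 2)
    singles = list(rng.choice(n_single + (cfg.vocab_size - n_single) // 4, size=n_single, replace=False))
    term_words: list[tuple[str, ...]] = [(words[i],) for i in singles]
    seen = set(term_words)
    compound_lo = max(singles) + 1 if singles else 0
    lengths = rng.choice([2, 3, 4], size=4 * cfg.n_terms, p=length_probs[1:] / length_probs[1:].sum())
    li = 0
    while len(term_words) < cfg.n_terms:
        L = int(lengths[li % len(lengths)])
        li += 1
        tw = tuple(
            words[i]
            for i in compound_lo + rng.choice(cfg.vocab_size - compound_lo, size=L, replace=False)
        )
        if tw not in seen:
            seen.add(tw)
            term_words.append(tw)
    terms = [" ".join(tw) for tw in term_words]

    # --- latent factors and gold labels
    truth: dict[str, dict] = {}
    for t, tw in zip(terms, term_words):
        ms = np.array([m_of[w] for w in tw])
        fam = float(np.clip(1.0 - ms.mean() + rng.normal(0.0, 0.04), 0.0, 1.0))
        qual = float(m_of[tw[-1]])   # head-word medicalness: the compound-quality factor
        tho = float(rng.beta(2.0, 2.0))  # corpus termhood, independent of familiarity
        logit = (
            cfg.fam_coef * (thr - fam)
            + cfg.termhood_coef * (tho - 0.5)
            + (cfg.qual_coef * (qual - 0.5) if len(tw) >= 2 else 0.0)
        )
        gold_p = float(1.0 / (1.0 + np.exp(-logit)))
        gold = int(rng.random() < gold_p)
        truth[t] = {"fam": fam, "qual": qual, "termhood": tho, "logit": logit,
                    "gold_p": gold_p, "gold": gold}

    # --- lexicon with the three documented noise modes; covers the planted
    # terms and the single words that occur inside compounds (a real
    # consumer-health lexicon lists both), so that high-frequency component
    # words are distant-labeled by familiarity like everything else
    component_words = sorted({w for tw in term_words if len(tw) >= 2 for w in tw}
                             - {tw[0] for tw in term_words if len(tw) == 1})
    lexicon: list[LexiconEntry] = []
    for w_ in component_words:
        if rng.random() < cfg.component_lexicon_coverage:
            wfam = float(np.clip(1.0 - m_of[w_] + rng.normal(0.0, cfg.familiarity_noise), 0.0, 1.0))
            if rng.random() < cfg.lexicon_missing_rate:
                lexicon.append(LexiconEntry(w_, None))
            else:
                lexicon.append(LexiconEntry(w_, wfam))
    for t in terms:
        fam, qual = truth[t]["fam"], truth[t]["qual"]
        include_p = 0.9 if fam <= thr else 0.8
        if rng.random() >= include_p:
            truth[t]["in_lexicon"] = False
            continue
        truth[t]["in_lexicon"] = True
        if rng.random() < cfg.lexicon_missing_rate:
            lexicon.append(LexiconEntry(t, None))
            continue
        is_compound = len(t.split()) >= 2
        if (
            is_compound
            and qual < 0.3
            and thr < fam <= thr + 0.15
            and rng.random() < cfg.compound_mislabel
        ):
            lex_fam = thr - 0.05 * rng.random()  # mislabeled low-quality compound
        elif abs(fam - thr) <= cfg.boundary_width and rng.random() < cfg.boundary_flip:
            lex_fam = float(np.clip(2 * thr - fam + rng.normal(0.0, cfg.familiarity_noise), 0.0, 1.0))
        else:
            lex_fam = float(np.clip(fam + rng.normal(0.0, cfg.familiarity_noise), 0.0, 1.0))
        lexicon.append(LexiconEntry(t, lex_fam))

    # --- concept dictionary: medical head words and some exact compounds
    code_of = lambda mv: f"T{40 + min(max(int((mv - 0.6) / 0.4 * cfg.n_semantic_codes), 0), cfg.n_semantic_codes - 1):03d}"
    concepts: list[LexiconEntry] = []
    for w in words:
        if m_of[w] > cfg.semantic_m_threshold:
            concepts.append(LexiconEntry(w, None, frozenset({code_of(m_of[w])})))
    for t in terms:
        tw = t.split()
        if len(tw) >= 2 and truth[t]["fam"] <= 0.45 and rng.random() < 0.5:
            head_m = m_of[tw[-1]]
            code = code_of(head_m) if head_m > 0.6 else f"T{40 + int(rng.integers(cfg.n_semantic_codes)):03d}"
            concepts.append(LexiconEntry(t, None, frozenset({code})))

    # --- corpus: occurrences rise with medicalness; stopword separators keep
    # each occurrence a maximal noun-phrase span for the linguistic filter
    base = max(0.2, cfg.n_docs * cfg.doc_length / cfg.n_terms - 1.0)
    # linear intensity link in the termhood factor keeps the raw-frequency
    # ATR features linearly sufficient for it
    tho_arr = np.array([truth[t]["termhood"] for t in terms])
    fam_arr = np.array([truth[t]["fam"] for t in terms])
    intensity = base * np.clip(
        1.0 + cfg.corpusfreq_termhood_slope * 2.0 * (tho_arr - 0.5), 0.05, None
    ) * np.exp(cfg.corpusfreq_fam_slope * 2.0 * (0.5 - fam_arr)
               + 0.1 * rng.normal(size=cfg.n_terms))
    freqs = 1 + rng.poisson(intensity)
    doc_occurrences: list[list[str]] = [[] for _ in range(cfg.n_docs)]
    for t, f in zip(terms, freqs):
        truth[t]["corpus_freq_planted"] = int(f)
        # clinical terms are bursty: occurrences concentrate in a term-specific
        # subset of notes, which decouples document frequency from raw
        # frequency (and hence TF-IDF from C-value)
        spread = rng.uniform(0.15, 1.0)
        n_home = max(1, int(round(spread * int(f))))
        home = rng.choice(cfg.n_docs, size=min(n_home, cfg.n_docs), replace=False)
        for d in home[rng.integers(0, len(home), size=int(f))]:
            doc_occurrences[d].append(t)
    stop_list = sorted(DEFAULT_STOPWORDS)
    documents = []
    for d, occ in enumerate(doc_occurrences):
        occ = list(occ)
        rng.shuffle(occ)
        pieces = []
        for k, t in enumerate(occ):
            pieces.append(t)
            if (k + 1) % 8 == 0:
                pieces.append(".")
            else:
                nsep = 1 + int(rng.integers(2))
                pieces.append(" ".join(stop_list[i] for i in rng.integers(0, len(stop_list), nsep)))
        text = " ".join(pieces).replace(" .", ".") + "."
        documents.append((f"note{d:04d}.txt", text))
    corpus = Corpus(documents=documents)

    # --- term n-gram counts in the general domain (familiar phrases only)
    for t in terms:
        if 2 <= len(t.split()) <= 3 and rng.random() < truth[t]["fam"]:
            counts[t] = float(np.round(np.exp(1.0 + 5.0 * truth[t]["fam"]
                                              + rng.normal(0.0, cfg.ngram_log_noise))))
    ngrams = NgramFrequencyTable(counts=counts)

    # --- expert-annotated terms (gold labels)
    if cfg.prefilter_top_frac is not None:
        ranker = np.array([-truth[t]["fam"] for t in terms]) + rng.normal(0.0, 0.3, cfg.n_terms)
        top_n = max(cfg.n_annotated, int(cfg.prefilter_top_frac * cfg.n_terms))
        pool_idx = np.argsort(-ranker)[:top_n]
    else:
        pool_idx = np.arange(cfg.n_terms)
    ann_idx = rng.choice(pool_idx, size=cfg.n_annotated, replace=False)
    annotated = [(terms[i], truth[terms[i]]["gold"]) for i in sorted(ann_idx)]

    world = SyntheticWorld(
        cfg=cfg,
        corpus=corpus,
        lexicon=lexicon,
        embeddings=embeddings,
        ngrams=ngrams,
        concepts=concepts,
        annotated=annotated,
        truth=truth,
        terms=terms,
    )
    world.candidates = extract_candidates(
        corpus, ExtractionConfig(stopwords=DEFAULT_STOPWORDS)
    )
    return world


def write_world(world: SyntheticWorld, out_dir: str | Path) -> None:
    """Write the six artifacts in the pipeline's external formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trio.write_corpus(world.corpus, out / "corpus")
    trio.write_lexicon(world.lexicon, out / "lexicon.tsv")
    trio.write_embeddings(world.embeddings, out / "embeddings.txt")
    trio.write_ngram_table(world.ngrams, out / "ngrams.tsv")
    trio.write_concepts(world.concepts, out / "concepts.tsv")
    trio.write_annotated_terms(world.annotated, out / "annotated.tsv")


def generate_shift_dataset(
    cfg: SyntheticConfig,
    n_source_pos: int = 300,
    n_source_neg: int = 300,
    world: SyntheticWorld | None = None,
    ablate: tuple[str, ...] = (),
) -> tuple[list[LabeledExample], list[LabeledExample], SyntheticWorld]:
    """Source examples with noisy distant labels and target examples with gold
    labels, in one shared (raw, unstandardized) feature space.

    Returns (source, target, world); the world carries the generative truth
    so Bayes-optimal rankings remain computable.
    """
    if world is None:
        world = generate_world(cfg)
    builder = world.feature_builder(ablate=ablate)
    annotated_terms = {t for t, _ in world.annotated}
    lab_cfg = LabelingConfig(
        familiarity_threshold=cfg.familiarity_threshold,
        n_pos=n_source_pos,
        n_neg=n_source_neg,
        seed=cfg.seed,
    )
    source_pairs = build_source_set(world.candidates, annotated_terms, world.lexicon, lab_cfg)
    source = [
        LabeledExample(term=t, features=builder.raw(t), label=l, domain="source")
        for t, l in source_pairs
    ]
    target = [
        LabeledExample(term=t, features=builder.raw(t), label=l, domain="target")
        for t, l in world.annotated
    ]
    return source, target, world
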