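"""Domain types shared across the term-ranking pipeline.

The pipeline ranks candidate terms mined from a clinical-note corpus by how
important they are for a patient's comprehension of their own notes.  Labels
come from two places: a consumer-health lexicon with per-term familiarity
scores (the noisy "source" domain, obtained by distant supervision) and a
small expert-annotated term list (the "target" domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class TermRankError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(TermRankError):
    """A path, size or parameter in the run configuration is invalid."""


class FormatError(TermRankError):
    """An input file violates its declared format.

    Carries the offending path and 1-based line number when known.
    """

    def __init__(self, message: str, path: Optional[str] = None, line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


@dataclass
class Corpus:
    """A collection of plain-text notes, one (doc_id, text) pair per document."""

    documents: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [d for d, _ in self.documents]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate doc_ids in corpus")
        for doc_id, text in self.documents:
            if text is None:
                raise ConfigurationError(f"document {doc_id!r} has null text")

    def __len__(self) -> int:
        return len(self.documents)


@dataclass
class CandidateTerm:
    """A normalized candidate term with corpus statistics.

    ``nests_in`` holds the surfaces of other candidates whose token sequence
    strictly contains this term's token sequence (contiguously).
    """

    surface: str
    length_words: int
    corpus_freq: int
    doc_freq: int
    nests_in: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.length_words != len(self.surface.split()):
            raise ValueError(
                f"length_words={self.length_words} inconsistent with surface {self.surface!r}"
            )
        if self.doc_freq > self.corpus_freq:
            raise ValueError(f"doc_freq > corpus_freq for {self.surface!r}")
        if self.corpus_freq < 0 or self.doc_freq < 0:
            raise ValueError("negative frequency")


@dataclass
class LexiconEntry:
    """A lexicon term with an optional familiarity score in [0, 1].

    Familiarity estimates the likelihood an average reader understands the
    term (1 = most familiar).  Terms at or below the familiarity threshold
    are treated as medical terms by the distant-labeling rule.
    """

    term: str
    familiarity: Optional[float] = None
    semantic_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.familiarity is not None and not (0.0 <= self.familiarity <= 1.0):
            raise ValueError(f"familiarity {self.familiarity} outside [0,1] for {self.term!r}")


@dataclass
class EmbeddingTable:
    """Word -> dense vector map; all vectors share one dimension."""

    dimension: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("embedding dimension must be positive")
        for w, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise ValueError(f"vector for {w!r} has shape {v.shape}, expected ({self.dimension},)")


@dataclass
class NgramFrequencyTable:
    """General-domain n-gram (1-3 tokens) -> count table, Google-Ngram style."""

    counts: dict[str, float]

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {g!r}")

    def get(self, ngram: str) -> float:
        return self.counts.get(ngram, 0.0)


@dataclass
class LabeledExample:
    """A term with its feature vector, binary label and domain tag."""

    term: str
    features: np.ndarray
    label: int
    domain: str  # "source" | "target"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        if self.domain not in ("source", "target"):
            raise ValueError(f"domain must be source|target, got {self.domain}")


@dataclass
class DatasetSplit:
    """One repeat of the repeated-split protocol.

    ``target_pool`` is the shuffled pool of annotated (term, label) pairs from
    which the first L form the target training set; ``evaluation`` is the
    disjoint remainder of the annotated data.
    """

    target_pool: list[tuple[str, int]]
    evaluation: list[tuple[str, int]]

    def target_train(self, L: int) -> list[tuple[str, int]]:
        if L > len(self.target_pool):
            raise ConfigurationError(f"L={L} exceeds target pool size {len(self.target_pool)}")
        return self.target_pool[:L]


@dataclass
class ExtractionConfig:
    """Settings for the linguistic filter that mines candidate terms."""

    stopwords: frozenset[str] = frozenset()
    min_corpus_freq: int = 1
    max_term_words: int = 6
    pos_tagger: object = None  # callable: list[str] -> list[str], or None for heuristic

    def __post_init__(self) -> None:
        if self.max_term_words < 1:
            raise ConfigurationError("max_term_words must be >= 1")
        if self.min_corpus_freq < 0:
            raise ConfigurationError("min_corpus_freq must be >= 0")


@dataclass
class LabelingConfig:
    """Distant-labeling rule and balanced-sampling sizes for the source set."""

    familiarity_threshold: float = 0.6
    n_pos: int = 3000
    n_neg: int = 3000
    seed: int = 0
    missing_familiarity: str = "negative"  # negative | positive | exclude

    def __post_init__(self) -> None:
        if not (0.0 <= self.familiarity_threshold <= 1.0):
            raise ConfigurationError("familiarity_threshold must be in [0,1]")
        if self.missing_familiarity not in ("negative", "positive", "exclude"):
            raise ConfigurationError(
                f"missing_familiarity must be negative|positive|exclude, got {self.missing_familiarity}"
            )


#: hyperparameter grids used for model selection
DEFAULT_C_GRID = (1.0, 0.1, 0.001, 0.0001)
DEFAULT_BETA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class TransferConfig:
    """Hyperparameters for the transfer trainers.

    ``C`` is the inverse regularization strength of the L2 log-linear model
    (small C = strong regularization).  ``beta`` scales the source-corpus
    weight through alpha = beta * (K / N), where N and K are the source and
    target training sizes.
    """

    C: float = 1.0
    beta: float = 1.0
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID
    cv_folds: int = 5
    cv_repeats: int = 2  # repeated stratified CV stabilizes selection at small K
    selection_metric: str = "ap"
    seed: int = 0

    def alpha(self, K: int, N: int) -> float:
        if N <= 0:
            raise ConfigurationError("N must be positive to derive alpha")
        return self.beta * (K / N)


@dataclass
class SplitProtocol:
    """Repeated-random-subsampling evaluation protocol."""

    n_repeats: int = 100
    target_pool_size: int = 1000
    L_values: tuple[int, ...] = (100, 200, 500, 1000)
    seed: int = 0

    def __post_init__(self) -> None:
        for L in self.L_values:
            if L > self.target_pool_size:
                raise ConfigurationError(f"L={L} exceeds target_pool_size={self.target_pool_size}")


@dataclass
class EvalReport:
    """Per-split scores, per-system means and pairwise paired t-tests.

    ``per_split`` rows are (system_name, L, repeat_index, AP, AUC); means are
    keyed by (system_name, L); ``paired_t`` maps ((system_a, L), (system_b, L))
    to (t, p, df) on the per-split AP differences.
    """

    per_split: list[tuple[str, int, int, float, float]] = field(default_factory=list)
    means: dict = field(default_factory=dict)
    paired_t: dict = field(default_factory=dict)

    def scores(self, system: str, L: int, metric: str = "ap") -> np.ndarray:
        col = 3 if metric == "ap" else 4
        return np.array(
            [row[col] for row in self.per_split if row[0] == system and row[1] == L]
        )
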