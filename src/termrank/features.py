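"""Five-family feature assembly for candidate terms.

Families, in fixed block order:

1. ``embedding``    — mean of component-word embedding vectors (d dims)
2. ``semantic``     — one 0/1 per semantic-type code in the concept
                      dictionary, set on exact or head-noun match
3. ``atr``          — automatic term recognition scores (C-value, TF-IDF)
4. ``general_freq`` — ln(1+x) of mean/min/max component-word general-domain
                      counts and of the full term's n-gram count
5. ``term_length``  — number of words

Source- and target-domain examples share the same space; per-dimension
z-scoring is fitted on the designated training terms only.
"""

from __future__ import annotations

import math

import numpy as np

from .datatypes import EmbeddingTable, LexiconEntry, NgramFrequencyTable

BLOCK_NAMES = ("embedding", "semantic", "atr", "general_freq", "term_length")


def embed_term(term: str, table: EmbeddingTable) -> np.ndarray:
    """Mean of the vectors of the term's component words present in the table;
    absent words are skipped; all-absent terms map to the zero vector."""
    vecs = [table.vectors[w] for w in term.split() if w in table.vectors]
    if not vecs:
        return np.zeros(table.dimension)
    return np.mean(vecs, axis=0)


def head_noun(term: str) -> str:
    """Head of an English noun phrase, taken as its final token."""
    return term.split()[-1]


def semantic_type_features(
    term: str, concept_dict: list[LexiconEntry], code_universe: tuple[str, ...]
) -> np.ndarray:
    """0/1 vector over the code universe; a bit is set for every code of a
    dictionary entry matching the term exactly or matching its head noun."""
    head = head_noun(term)
    codes: set[str] = set()
    for e in concept_dict:
        if e.term == term or e.term == head:
            codes |= e.semantic_types
    idx = {c: i for i, c in enumerate(code_universe)}
    v = np.zeros(len(code_universe))
    for c in codes:
        if c in idx:  # unseen codes at predict time are ignored
            v[idx[c]] = 1.0
    return v


def general_freq_features(term: str, table: NgramFrequencyTable) -> np.ndarray:
    """(mean, min, max) of component-word counts and the full-term n-gram
    count, each mapped through ln(1+count).  Statistics are taken over raw
    counts first, then log-transformed."""
    word_counts = [table.get(w) for w in term.split()]
    mean_c = sum(word_counts) / len(word_counts)
    min_c = min(word_counts)
    max_c = max(word_counts)
    term_c = table.get(term)
    return np.array([math.log1p(mean_c), math.log1p(min_c), math.log1p(max_c), math.log1p(term_c)])


def term_length_feature(term: str) -> int:
    """Number of whitespace-separated words."""
    return len(term.split())


class FeatureSpace:
    """Fixed block layout (optionally with families ablated) plus an optional
    per-dimension standardization fitted on training terms."""

    def __init__(self, embedding_dim: int, code_universe: tuple[str, ...], ablate: tuple[str, ...] = ()):
        for name in ablate:
            if name not in BLOCK_NAMES:
                raise ValueError(f"unknown feature block {name!r}")
        dims = {
            "embedding": embedding_dim,
            "semantic": len(code_universe),
            "atr": 2,
            "general_freq": 4,
            "term_length": 1,
        }
        self.blocks: list[tuple[str, int]] = [
            (name, dims[name]) for name in BLOCK_NAMES if name not in ablate
        ]
        self.code_universe = code_universe
        self.ablate = tuple(ablate)
        self.F = sum(d for _, d in self.blocks)
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit_standardization(self, X_train: np.ndarray) -> None:
        """Fit per-dimension (mean, sd); sd=0 dimensions are centered only."""
        self.mean_ = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            return X
        return (X - self.mean_) / self.scale_


class FeatureBuilder:
    """Pure term -> raw feature vector function over loaded resources."""

    def __init__(
        self,
        embeddings: EmbeddingTable,
        concept_dict: list[LexiconEntry],
        ngrams: NgramFrequencyTable,
        c_values: dict[str, float],
        tfidf: dict[str, float],
        ablate: tuple[str, ...] = (),
    ):
        self.embeddings = embeddings
        self.concept_dict = concept_dict
        # closed-world code universe: codes present in the dictionary, sorted
        self.code_universe = tuple(sorted(set().union(*(e.semantic_types for e in concept_dict)) if concept_dict else set()))
        self.ngrams = ngrams
        self.c_values = c_values
        self.tfidf = tfidf
        self.space = FeatureSpace(embeddings.dimension, self.code_universe, ablate)
        # head-noun lookup index for speed
        self._concept_index: dict[str, set[str]] = {}
        for e in concept_dict:
            self._concept_index.setdefault(e.term, set()).update(e.semantic_types)

    def _semantic(self, term: str) -> np.ndarray:
        codes = set(self._concept_index.get(term, ()))
        codes |= self._concept_index.get(head_noun(term), set())
        v = np.zeros(len(self.code_universe))
        for i, c in enumerate(self.code_universe):
            if c in codes:
                v[i] = 1.0
        return v

    def raw(self, term: str) -> np.ndarray:
        parts = []
        for name, _dim in self.space.blocks:
            if name == "embedding":
                parts.append(embed_term(term, self.embeddings))
            elif name == "semantic":
                parts.append(self._semantic(term))
            elif name == "atr":
                # termhood scores are heavy-tailed (frequency-scaled); a
                # signed log transform keeps high-frequency outliers from
                # dominating the standardized dimension, mirroring the
                # ln(1+count) treatment of the general-domain frequencies
                raw = np.array([self.c_values.get(term, 0.0), self.tfidf.get(term, 0.0)])
                parts.append(np.sign(raw) * np.log1p(np.abs(raw)))
            elif name == "general_freq":
                parts.append(general_freq_features(term, self.ngrams))
            elif name == "term_length":
                parts.append(np.array([float(term_length_feature(term))]))
        v = np.concatenate(parts) if parts else np.zeros(0)
        if v.shape != (self.space.F,):
            raise ValueError(f"feature dimension mismatch: {v.shape} vs F={self.space.F}")
        return v

    def matrix(self, terms: list[str]) -> np.ndarray:
        return np.vstack([self.raw(t) for t in terms]) if terms else np.zeros((0, self.space.F))


def build_features(
    terms: list[str],
    builder: FeatureBuilder,
    fit_standardization_on: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Standardized feature vectors for ``terms``.

    z-scoring is fitted only on ``fit_standardization_on`` (training terms);
    when omitted, it is fitted on ``terms`` themselves.
    """
    fit_terms = fit_standardization_on if fit_standardization_on is not None else terms
    builder.space.fit_standardization(builder.matrix(fit_terms))
    X = builder.space.transform(builder.matrix(terms))
    return {t: X[i] for i, t in enumerate(terms)}
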