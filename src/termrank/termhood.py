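"""Automatic term recognition statistics used as learning features.

Two termhood scores are computed over the candidate set: C-value, which
rewards frequent long terms while discounting frequency explained by longer
containing terms, and corpus-level TF-IDF.
"""

from __future__ import annotations

import math

from .datatypes import CandidateTerm, ConfigurationError


def c_value(
    candidates: list[CandidateTerm], weight: str = "log2_plus1"
) -> dict[str, float]:
    """C-value termhood score for every candidate.

    For term ``a`` with word count ``|a|`` and corpus frequency ``f(a)``::

        w(a) = log2(|a| + 1)            (default; "log2" gives classic log2|a|)
        C(a) = w(a) * f(a)                                 if a nests in nothing
        C(a) = w(a) * (f(a) - mean_{b in T_a} f(b))        otherwise

    where ``T_a`` is the set of candidates strictly containing ``a``.  The
    ``log2(|a|+1)`` weight departs from the classic formulation so that
    single-word candidates receive nonzero scores and can be ranked.
    """
    if weight not in ("log2_plus1", "log2"):
        raise ConfigurationError(f"unknown C-value weight {weight!r}")
    freq = {c.surface: c.corpus_freq for c in candidates}
    scores: dict[str, float] = {}
    for c in candidates:
        w = math.log2(c.length_words + 1) if weight == "log2_plus1" else (
            math.log2(c.length_words) if c.length_words > 1 else 0.0
        )
        containers = [b for b in c.nests_in if b in freq]
        if containers:
            discount = sum(freq[b] for b in containers) / len(containers)
            scores[c.surface] = w * (c.corpus_freq - discount)
        else:
            scores[c.surface] = w * c.corpus_freq
    return scores


def corpus_tfidf(candidates: list[CandidateTerm], corpus_doc_count: int) -> dict[str, float]:
    """Corpus-level TF-IDF: ``f(a) * ln(D / df(a))``, 0 when df(a)=0."""
    if corpus_doc_count <= 0:
        raise ConfigurationError("corpus_doc_count must be positive")
    scores = {}
    for c in candidates:
        if c.doc_freq > corpus_doc_count:
            raise ConfigurationError(
                f"doc_freq {c.doc_freq} exceeds corpus_doc_count {corpus_doc_count} for {c.surface!r}"
            )
        if c.doc_freq == 0:
            scores[c.surface] = 0.0
        else:
            scores[c.surface] = c.corpus_freq * math.log(corpus_doc_count / c.doc_freq)
    return scores
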