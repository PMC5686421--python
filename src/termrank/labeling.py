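"""Distant labeling: build the noisy source-domain training set from a
consumer-health-style lexicon.

The heuristic rule labels a term positive (a medical term important for
comprehension) iff it appears in the lexicon with a familiarity score at or
below the threshold (default 0.6).  A balanced positive/negative sample of
the distantly labeled candidates, excluding expert-annotated terms, forms
the source-domain training set.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import CandidateTerm, LabelingConfig, LexiconEntry


def lexicon_index(lexicon: list[LexiconEntry]) -> dict[str, LexiconEntry]:
    return {e.term: e for e in lexicon}


def distant_label(
    term: str, lexicon: dict[str, LexiconEntry] | list[LexiconEntry], cfg: LabelingConfig
) -> int:
    """1 iff the term is a lexicon entry whose familiarity is at or below the
    threshold.  Entries lacking a familiarity score follow
    ``cfg.missing_familiarity`` (default: negative)."""
    index = lexicon if isinstance(lexicon, dict) else lexicon_index(lexicon)
    entry = index.get(term)
    if entry is None:
        return 0
    if entry.familiarity is None:
        return 1 if cfg.missing_familiarity == "positive" else 0
    return 1 if entry.familiarity <= cfg.familiarity_threshold else 0


def build_source_set(
    candidates: list[CandidateTerm] | list[str],
    exclude: set[str],
    lexicon: list[LexiconEntry] | dict[str, LexiconEntry],
    cfg: LabelingConfig,
) -> list[tuple[str, int]]:
    """Balanced source-domain training pairs (term, distant label).

    Annotated terms in ``exclude`` are removed before labeling; positives and
    negatives are sampled without replacement under ``cfg.seed``.  When a
    class has fewer available terms than requested, all of them are taken and
    a warning is issued.
    """
    index = lexicon if isinstance(lexicon, dict) else lexicon_index(lexicon)
    surfaces = [c.surface if isinstance(c, CandidateTerm) else c for c in candidates]
    pool = [t for t in dict.fromkeys(surfaces) if t not in exclude]
    if cfg.missing_familiarity == "exclude":
        pool = [t for t in pool if not (t in index and index[t].familiarity is None)]
    pos = [t for t in pool if distant_label(t, index, cfg) == 1]
    neg = [t for t in pool if distant_label(t, index, cfg) == 0]
    rng = np.random.default_rng(cfg.seed)
    if len(pos) < cfg.n_pos:
        warnings.warn(
            f"only {len(pos)} positive terms available, requested {cfg.n_pos}", stacklevel=2
        )
    if len(neg) < cfg.n_neg:
        warnings.warn(
            f"only {len(neg)} negative terms available, requested {cfg.n_neg}", stacklevel=2
        )
    take_pos = sorted(rng.choice(len(pos), size=min(cfg.n_pos, len(pos)), replace=False))
    take_neg = sorted(rng.choice(len(neg), size=min(cfg.n_neg, len(neg)), replace=False))
    out = [(pos[i], 1) for i in take_pos] + [(neg[i], 0) for i in take_neg]
    return out
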