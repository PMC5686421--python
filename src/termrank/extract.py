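"""Linguistic filter for mining candidate words and noun phrases.

The filter combines a word extractor (single alphabetic non-stopword tokens),
a noun-phrase extractor (maximal spans matching a simple NP tag pattern
within one sentence) and a stopword list.  Part-of-speech tagging is
pluggable: any callable mapping a token list to a tag list over
{"ADJ", "NOUN", "PROPN", "OTHER"} can be supplied; the shipped default is a
lexicon-free heuristic that treats every alphabetic non-stopword token as
NP-eligible, which is adequate for corpora whose non-content tokens are
covered by the stopword list.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict

from .datatypes import CandidateTerm, Corpus, ExtractionConfig

# a small general-English stopword list; users may supply their own
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be been by for from had has have he her his i if in into is it its
    no not of on or our she that the their them they this to was we were which will with would
    you your""".split()
)

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")
_SENT_SPLIT_RE = re.compile(r"[.!?]+(?=\s|$)")
_ALPHA_RE = re.compile(r"^[A-Za-z]+(?:-[A-Za-z]+)*$")

NP_TAGS = frozenset({"ADJ", "NOUN", "PROPN"})
HEAD_TAGS = frozenset({"NOUN", "PROPN"})


def tokenize(text: str) -> list[tuple[str, int]]:
    """Split text into (lowercased token, sentence_index) pairs.

    Sentence boundaries are ``. ! ?`` runs followed by whitespace or end of
    text; tokens split on whitespace and punctuation, keeping internal
    hyphens ("community-acquired" is one token).
    """
    out: list[tuple[str, int]] = []
    sentences = _SENT_SPLIT_RE.split(text)
    for si, sent in enumerate(sentences):
        for m in _TOKEN_RE.finditer(sent):
            out.append((m.group(0).lower(), si))
    return out


def heuristic_tagger(tokens: list[str], stopwords: frozenset[str]) -> list[str]:
    """Default tagger: alphabetic non-stopword tokens are NOUN, rest OTHER."""
    return [
        "NOUN" if (_ALPHA_RE.match(t) and t not in stopwords) else "OTHER" for t in tokens
    ]


def _sentence_spans(
    tokens: list[str], tags: list[str], stopwords: frozenset[str], max_words: int
) -> list[tuple[str, ...]]:
    """Maximal NP-pattern spans within one sentence.

    A span is a maximal run of tokens tagged ADJ/NOUN/PROPN, trimmed of
    stopword edges, whose final token is a NOUN/PROPN; runs longer than
    ``max_words`` after trimming are dropped (their single words remain
    candidates through the word extractor).
    """
    spans = []
    i = 0
    n = len(tokens)
    while i < n:
        if tags[i] in NP_TAGS:
            j = i
            while j < n and tags[j] in NP_TAGS:
                j += 1
            lo, hi = i, j  # [lo, hi) run; trim stopword edges
            while lo < hi and tokens[lo] in stopwords:
                lo += 1
            while hi > lo and tokens[hi - 1] in stopwords:
                hi -= 1
            if hi - lo >= 2 and hi - lo <= max_words and tags[hi - 1] in HEAD_TAGS:
                spans.append(tuple(tokens[lo:hi]))
            i = j
        else:
            i += 1
    return spans


def count_occurrences(
    doc_tokens: list[list[str]], sequences: set[tuple[str, ...]]
) -> tuple[dict[tuple[str, ...], int], dict[tuple[str, ...], int]]:
    """Sliding-window corpus and document frequencies for token sequences.

    Overlapping occurrences count; an occurrence may cross a sentence
    boundary only for single words (multiword sequences are matched on the
    raw token stream, which in practice keeps them within sentences because
    they were mined per sentence).
    """
    by_first: dict[str, list[tuple[str, ...]]] = defaultdict(list)
    for seq in sequences:
        by_first[seq[0]].append(seq)
    corpus_freq: dict[tuple[str, ...], int] = Counter()
    doc_freq: dict[tuple[str, ...], int] = Counter()
    for tokens in doc_tokens:
        seen: set[tuple[str, ...]] = set()
        for pos, tok in enumerate(tokens):
            for seq in by_first.get(tok, ()):
                if tuple(tokens[pos : pos + len(seq)]) == seq:
                    corpus_freq[seq] += 1
                    seen.add(seq)
        for seq in seen:
            doc_freq[seq] += 1
    return dict(corpus_freq), dict(doc_freq)


def compute_nesting(surfaces: list[str]) -> dict[str, set[str]]:
    """nests_in relation: b nests in a iff b's token sequence is a contiguous
    strict subsequence of a's."""
    seq_of = {s: tuple(s.split()) for s in surfaces}
    index = {seq: s for s, seq in seq_of.items()}
    nests: dict[str, set[str]] = {s: set() for s in surfaces}
    for a in surfaces:
        seq = seq_of[a]
        n = len(seq)
        for width in range(1, n):
            for start in range(0, n - width + 1):
                sub = seq[start : start + width]
                b = index.get(sub)
                if b is not None and b != a:
                    nests[b].add(a)
    return nests


def extract_candidates(corpus: Corpus, cfg: ExtractionConfig) -> list[CandidateTerm]:
    """Mine candidate terms: single non-stopword alphabetic words plus maximal
    noun-phrase spans, with whole-corpus frequencies and nesting relations."""
    tagger = cfg.pos_tagger or (lambda toks: heuristic_tagger(toks, cfg.stopwords))
    doc_tokens: list[list[str]] = []
    sequences: set[tuple[str, ...]] = set()
    for _doc_id, text in corpus.documents:
        toks_si = tokenize(text)
        tokens = [t for t, _ in toks_si]
        doc_tokens.append(tokens)
        tags = tagger(tokens)
        # group per sentence for span mining
        start = 0
        for i in range(1, len(toks_si) + 1):
            if i == len(toks_si) or toks_si[i][1] != toks_si[start][1]:
                sent_toks = tokens[start:i]
                sent_tags = tags[start:i]
                for span in _sentence_spans(sent_toks, sent_tags, cfg.stopwords, cfg.max_term_words):
                    sequences.add(span)
                start = i
        for tok, tag in zip(tokens, tags):
            if tag in NP_TAGS and _ALPHA_RE.match(tok) and tok not in cfg.stopwords:
                sequences.add((tok,))
    if not sequences:
        return []
    corpus_freq, doc_freq = count_occurrences(doc_tokens, sequences)
    surfaces = sorted(" ".join(seq) for seq in sequences)
    nests = compute_nesting(surfaces)
    out = []
    for surf in surfaces:
        seq = tuple(surf.split())
        f = corpus_freq.get(seq, 0)
        if f < cfg.min_corpus_freq:
            continue
        out.append(
            CandidateTerm(
                surface=surf,
                length_words=len(seq),
                corpus_freq=f,
                doc_freq=doc_freq.get(seq, 0),
                nests_in=nests[surf],
            )
        )
    # restrict nesting to surviving candidates
    kept = {c.surface for c in out}
    for c in out:
        c.nests_in &= kept
    return out
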