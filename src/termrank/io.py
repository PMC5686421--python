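"""Readers and writers for every external format the pipeline touches.

All tabular formats are plain TSV with no quoting; lines starting with ``#``
are comments.  Embeddings use the word2vec text format (``<vocab> <dim>``
header, then ``word v1 ... vd`` rows).  Ranked output and evaluation reports
are TSV and JSON respectively.
"""

from __future__ import annotations

import json
import math
import os
import re
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .datatypes import (
    CandidateTerm,
    ConfigurationError,
    Corpus,
    EmbeddingTable,
    EvalReport,
    FormatError,
    LexiconEntry,
    NgramFrequencyTable,
)

_EDGE_PUNCT = re.compile(r"^[^\w]+$")


def normalize_term(term: str) -> str:
    """Normalize a term: lowercase, collapse whitespace, strip punctuation-only
    edge tokens.  Hyphens inside tokens are kept ("community-acquired" is one
    token)."""
    tokens = term.lower().split()
    while tokens and _EDGE_PUNCT.match(tokens[0]):
        tokens.pop(0)
    while tokens and _EDGE_PUNCT.match(tokens[-1]):
        tokens.pop()
    return " ".join(tokens)


def _data_lines(path: str | Path):
    """Yield (line_number, stripped_line) for non-comment, non-blank lines."""
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


# ---------------------------------------------------------------------------
# corpus

def read_corpus(path: str | Path) -> Corpus:
    """Read a directory of UTF-8 ``.txt`` files as a corpus.

    One document per file, doc_id = filename, sorted by filename for
    determinism.
    """
    p = Path(path)
    if not p.is_dir():
        raise ConfigurationError(f"corpus path {p} does not exist or is not a directory")
    docs = []
    for f in sorted(p.iterdir()):
        if not f.is_file():
            continue
        try:
            text = f.read_text(encoding="utf-8")
        except UnicodeDecodeError as e:
            raise FormatError(f"file is not valid UTF-8: {e}", path=str(f)) from e
        docs.append((f.name, text))
    return Corpus(documents=docs)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    for doc_id, text in corpus.documents:
        (p / doc_id).write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# lexicon

def read_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Read a lexicon TSV: term <TAB> familiarity (number or NA) <TAB>
    semicolon-separated semantic-type codes (optional column).

    Terms are normalized; duplicate terms collapse keeping the minimum
    familiarity (the most conservative choice for flagging medical terms).
    """
    entries: dict[str, LexiconEntry] = {}
    for ln, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 2:
            raise FormatError("expected at least 2 tab-separated columns", str(path), ln)
        term = normalize_term(cols[0])
        if not term:
            raise FormatError("empty term", str(path), ln)
        fam_raw = cols[1].strip()
        if fam_raw.upper() in ("NA", ""):
            fam: Optional[float] = None
        else:
            try:
                fam = float(fam_raw)
            except ValueError:
                raise FormatError(f"unparsable familiarity {fam_raw!r}", str(path), ln)
            if not (0.0 <= fam <= 1.0):
                raise FormatError(f"familiarity {fam} outside [0,1]", str(path), ln)
        codes = frozenset(
            c.strip() for c in (cols[2].split(";") if len(cols) > 2 and cols[2].strip() else []) if c.strip()
        )
        if term in entries:
            prev = entries[term]
            fams = [f for f in (prev.familiarity, fam) if f is not None]
            merged_fam = min(fams) if fams else None
            entries[term] = LexiconEntry(term, merged_fam, prev.semantic_types | codes)
        else:
            entries[term] = LexiconEntry(term, fam, codes)
    return list(entries.values())


def write_lexicon(entries: Iterable[LexiconEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# term\tfamiliarity\tsemantic_types\n")
        for e in entries:
            fam = "NA" if e.familiarity is None else repr(float(e.familiarity))
            fh.write(f"{e.term}\t{fam}\t{';'.join(sorted(e.semantic_types))}\n")


# ---------------------------------------------------------------------------
# concept dictionary (term -> semantic-type codes)

def read_concepts(path: str | Path) -> list[LexiconEntry]:
    """Read a concept dictionary TSV: term <TAB> semicolon-separated codes."""
    entries = []
    for ln, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 2:
            raise FormatError("expected 2 tab-separated columns", str(path), ln)
        term = normalize_term(cols[0])
        codes = frozenset(c.strip() for c in cols[1].split(";") if c.strip())
        entries.append(LexiconEntry(term, None, codes))
    return entries


def write_concepts(entries: Iterable[LexiconEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# term\tsemantic_types\n")
        for e in entries:
            fh.write(f"{e.term}\t{';'.join(sorted(e.semantic_types))}\n")


# ---------------------------------------------------------------------------
# embeddings (word2vec text format)

def read_embeddings(path: str | Path) -> EmbeddingTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError("expected header '<vocab> <dim>'", str(path), 1)
        n, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            word = parts[0]
            vals = [v for v in parts[1:] if v]
            if len(vals) != dim:
                raise FormatError(
                    f"row has {len(vals)} values, expected dimension {dim}", str(path), ln
                )
            vectors[word] = np.array([float(v) for v in vals], dtype=float)
    if len(vectors) != n:
        raise FormatError(f"header declares {n} words, found {len(vectors)}", str(path))
    return EmbeddingTable(dimension=dim, vectors=vectors)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dimension}\n")
        for word, vec in table.vectors.items():
            fh.write(word + " " + " ".join(repr(float(v)) for v in vec) + "\n")


# ---------------------------------------------------------------------------
# n-gram frequency table

def read_ngram_table(path: str | Path) -> NgramFrequencyTable:
    counts: dict[str, float] = {}
    for ln, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 2:
            raise FormatError("expected 2 tab-separated columns", str(path), ln)
        gram = normalize_term(cols[0])
        try:
            c = float(cols[1])
        except ValueError:
            raise FormatError(f"unparsable count {cols[1]!r}", str(path), ln)
        if c < 0:
            raise FormatError(f"negative count {c}", str(path), ln)
        counts[gram] = c
    return NgramFrequencyTable(counts=counts)


def write_ngram_table(table: NgramFrequencyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ngram\tcount\n")
        for gram, c in table.counts.items():
            fh.write(f"{gram}\t{c:g}\n")


# ---------------------------------------------------------------------------
# annotated terms

def read_annotated_terms(path: str | Path) -> list[tuple[str, int]]:
    """Read expert-annotated terms: term <TAB> 0/1 importance label."""
    out = []
    for ln, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 2:
            raise FormatError("expected 2 tab-separated columns", str(path), ln)
        term = normalize_term(cols[0])
        if cols[1].strip() not in ("0", "1"):
            raise FormatError(f"label must be 0 or 1, got {cols[1]!r}", str(path), ln)
        out.append((term, int(cols[1])))
    return out


def write_annotated_terms(rows: Iterable[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# term\tlabel\n")
        for term, label in rows:
            fh.write(f"{term}\t{label}\n")


# ---------------------------------------------------------------------------
# candidate terms

def read_candidates(path: str | Path) -> list[CandidateTerm]:
    cands = []
    for ln, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 4:
            raise FormatError("expected >=4 tab-separated columns", str(path), ln)
        nests = set(cols[4].split(";")) - {""} if len(cols) > 4 else set()
        cands.append(
            CandidateTerm(
                surface=cols[0],
                length_words=int(cols[1]),
                corpus_freq=int(cols[2]),
                doc_freq=int(cols[3]),
                nests_in=nests,
            )
        )
    return cands


def write_candidates(cands: Iterable[CandidateTerm], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# term\tlength\tcorpus_freq\tdoc_freq\tnests_in\n")
        for c in cands:
            fh.write(
                f"{c.surface}\t{c.length_words}\t{c.corpus_freq}\t{c.doc_freq}\t"
                f"{';'.join(sorted(c.nests_in))}\n"
            )


# ---------------------------------------------------------------------------
# ranked output

def write_ranking(
    ranked: list[tuple], path: str | Path
) -> None:
    """Write a ranked term list as TSV (rank, term, score, label).

    Input tuples are (term, score) or (term, score, label).  Rows are sorted
    by descending score, ties broken by ascending term string.
    """
    rows = []
    for tup in ranked:
        term, score = tup[0], float(tup[1])
        label = tup[2] if len(tup) > 2 else ""
        if not math.isfinite(score):
            raise ValueError(f"non-finite score {score} for term {term!r}")
        rows.append((term, score, label))
    rows.sort(key=lambda r: (-r[1], r[0]))
    try:
        fh = open(path, "w", encoding="utf-8")
    except OSError as e:
        raise ConfigurationError(f"cannot write ranking to {path}: {e}") from e
    with fh:
        fh.write("rank\tterm\tscore\tlabel\n")
        for rank, (term, score, label) in enumerate(rows, start=1):
            fh.write(f"{rank}\t{term}\t{score!r}\t{label}\n")


def read_ranking(path: str | Path) -> list[tuple[int, str, float, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            rank, term, score, label = line.rstrip("\n").split("\t")
            out.append((int(rank), term, float(score), label))
    return out


# ---------------------------------------------------------------------------
# evaluation report JSON

def report_to_dict(report: EvalReport) -> dict:
    return {
        "per_split": [list(r) for r in report.per_split],
        "means": {f"{s}|{L}": v for (s, L), v in report.means.items()},
        "paired_t": {
            f"{a}|{La}|vs|{b}|{Lb}": list(v) for ((a, La), (b, Lb)), v in report.paired_t.items()
        },
    }


def report_from_dict(d: dict) -> EvalReport:
    means = {}
    for k, v in d["means"].items():
        s, L = k.rsplit("|", 1)
        means[(s, int(L))] = tuple(v) if isinstance(v, list) else v
    paired = {}
    for k, v in d["paired_t"].items():
        a, La, _, b, Lb = k.split("|")
        paired[((a, int(La)), (b, int(Lb)))] = tuple(v)
    return EvalReport(
        per_split=[tuple(r) for r in d["per_split"]],
        means=means,
        paired_t=paired,
    )


def write_report(report: EvalReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> EvalReport:
    with open(path, encoding="utf-8") as fh:
        return report_from_dict(json.load(fh))
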