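"""Corpus ingestion and bag-of-words construction.

Policy documents arrive as token streams (pre-segmented text; Chinese
policy prose is typically run through an external segmenter first).  This
module normalizes tokens (synonym merging, stopword removal), builds a
deterministic vocabulary, and produces the sparse bag-of-words corpus
that the topic model consumes.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "TokenDoc",
    "Vocabulary",
    "BowCorpus",
    "normalize_tokens",
    "build_vocabulary",
    "to_bow",
    "whitespace_tokenizer",
    "read_text_dir",
    "read_jsonl",
    "load_stopwords",
    "load_synonyms",
]


@dataclass(frozen=True)
class TokenDoc:
    """One document as an ordered token list.

    ``usable`` is False when normalization removed every token; such
    documents are carried through for bookkeeping but excluded from
    model fitting.
    """

    doc_id: str
    tokens: tuple[str, ...]
    usable: bool = True

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class Vocabulary:
    """Ordered term list with a term -> integer index map (a bijection)."""

    terms: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_terms(cls, terms: Sequence[str]) -> "Vocabulary":
        terms = tuple(terms)
        if len(set(terms)) != len(terms):
            raise ValueError("vocabulary terms must be unique")
        if not terms:
            raise ValueError("vocabulary must contain at least one term")
        return cls(terms=terms, index={t: i for i, t in enumerate(terms)})

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


@dataclass(frozen=True)
class BowCorpus:
    """Sparse term-count vectors over a shared vocabulary.

    ``counts[d]`` maps term index -> count (all stored counts >= 1);
    ``doc_lengths[d]`` is N_d, the number of surviving tokens of
    document d.  Empty documents (N_d = 0) are retained in order but
    skipped by the fitting and perplexity routines.
    """

    vocab: Vocabulary
    doc_ids: tuple[str, ...]
    counts: tuple[Mapping[int, int], ...]
    doc_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.doc_ids) != len(self.counts) or len(self.counts) != len(self.doc_lengths):
            raise ValueError("doc_ids, counts and doc_lengths must align")
        for c, n in zip(self.counts, self.doc_lengths):
            if any(v < 1 for v in c.values()):
                raise ValueError("stored counts must be >= 1")
            if sum(c.values()) != n:
                raise ValueError("N_d must equal the sum of the document's counts")

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def n_terms(self) -> int:
        return len(self.vocab)

    @property
    def total_tokens(self) -> int:
        return sum(self.doc_lengths)

    def nonempty_indices(self) -> list[int]:
        return [d for d, n in enumerate(self.doc_lengths) if n > 0]

    # -- serialization (JSON keeps the sparse maps and ordering intact) --

    def to_json(self) -> str:
        payload = {
            "terms": list(self.vocab.terms),
            "docs": [
                {"id": i, "counts": {str(k): v for k, v in sorted(c.items())}}
                for i, c in zip(self.doc_ids, self.counts)
            ],
        }
        return json.dumps(payload, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "BowCorpus":
        payload = json.loads(text)
        vocab = Vocabulary.from_terms(payload["terms"])
        ids, counts, lengths = [], [], []
        for rec in payload["docs"]:
            c = {int(k): int(v) for k, v in rec["counts"].items()}
            ids.append(rec["id"])
            counts.append(c)
            lengths.append(sum(c.values()))
        return cls(vocab=vocab, doc_ids=tuple(ids), counts=tuple(counts),
                   doc_lengths=tuple(lengths))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "BowCorpus":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def normalize_tokens(
    doc: TokenDoc,
    synonym_map: Mapping[str, str] | None = None,
    stopwords: Iterable[str] | None = None,
) -> TokenDoc:
    """Merge synonyms and drop stopwords, preserving token order.

    The synonym map is applied exactly once (no transitive chains): each
    token is replaced by its canonical form if present in the map, then
    checked against the stopword set.  A document left empty is returned
    flagged unusable rather than dropped, so collection bookkeeping
    stays aligned.
    """
    synonym_map = synonym_map or {}
    stop = frozenset(stopwords or ())
    out = []
    for tok in doc.tokens:
        tok = synonym_map.get(tok, tok)
        if tok not in stop:
            out.append(tok)
    return TokenDoc(doc_id=doc.doc_id, tokens=tuple(out), usable=bool(out))


def build_vocabulary(docs: Sequence[TokenDoc], min_doc_freq: int = 1) -> Vocabulary:
    """Vocabulary of terms appearing in at least ``min_doc_freq`` documents.

    Terms are ordered by descending corpus frequency, ties broken
    lexicographically, so every downstream index is reproducible.
    """
    if not docs:
        raise ValueError("cannot build a vocabulary from zero documents")
    corpus_freq: Counter[str] = Counter()
    doc_freq: Counter[str] = Counter()
    for doc in docs:
        corpus_freq.update(doc.tokens)
        doc_freq.update(set(doc.tokens))
    kept = [t for t, df in doc_freq.items() if df >= min_doc_freq]
    if not kept:
        raise ValueError(
            f"no term appears in >= {min_doc_freq} documents; filtering removed everything"
        )
    kept.sort(key=lambda t: (-corpus_freq[t], t))
    return Vocabulary.from_terms(kept)


def to_bow(docs: Sequence[TokenDoc], vocab: Vocabulary) -> BowCorpus:
    """Bag-of-words counts per document; out-of-vocabulary tokens dropped."""
    ids, counts, lengths = [], [], []
    seen = set()
    for doc in docs:
        if doc.doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        seen.add(doc.doc_id)
        c: Counter[int] = Counter(vocab.index[t] for t in doc.tokens if t in vocab)
        ids.append(doc.doc_id)
        counts.append(dict(c))
        lengths.append(sum(c.values()))
    return BowCorpus(vocab=vocab, doc_ids=tuple(ids), counts=tuple(counts),
                     doc_lengths=tuple(lengths))


# ---------------------------------------------------------------------------
# input readers

Tokenizer = Callable[[str], list[str]]


def whitespace_tokenizer(text: str) -> list[str]:
    return text.split()


def read_text_dir(path: str | Path, tokenizer: Tokenizer = whitespace_tokenizer) -> list[TokenDoc]:
    """Read a directory of UTF-8 ``.txt`` files; doc_id is the filename stem."""
    path = Path(path)
    docs = []
    for f in sorted(path.glob("*.txt")):
        toks = tuple(tokenizer(f.read_text(encoding="utf-8")))
        docs.append(TokenDoc(doc_id=f.stem, tokens=toks, usable=bool(toks)))
    if not docs:
        raise FileNotFoundError(f"no .txt files under {path}")
    return docs


def read_jsonl(path: str | Path) -> list[TokenDoc]:
    """Read pre-tokenized documents from JSONL records {"id": ..., "tokens": [...]}."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            toks = tuple(rec["tokens"])
            docs.append(TokenDoc(doc_id=str(rec["id"]), tokens=toks, usable=bool(toks)))
    if not docs:
        raise ValueError(f"no records in {path}")
    return docs


def load_stopwords(path: str | Path) -> frozenset[str]:
    """One stopword per line; blank lines ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(w.strip() for w in lines if w.strip())


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Tab-separated ``variant<TAB>canonical`` pairs, one per line."""
    out: dict[str, str] = {}
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        ln = ln.strip()
        if not ln:
            continue
        try:
            variant, canonical = ln.split("\t")
        except ValueError as exc:
            raise ValueError(f"malformed synonym line: {ln!r}") from exc
        out[variant.strip()] = canonical.strip()
    return out
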