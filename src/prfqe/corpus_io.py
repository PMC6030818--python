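"""Corpus, topic and stopword I/O plus the inverted index.

The index keeps the count statistics every downstream formula consumes:
per-term document frequency (df), per-(term, document) term frequency (tf),
document lengths and their mean (avdl).  Pre-processing is lowercasing,
splitting on non-alphanumeric characters, stopword removal and (optionally)
Porter stemming, applied in that order; the stemming flag is recorded on the
index so queries are preprocessed identically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .stemming import porter_stem_word

__all__ = [
    "DEFAULT_STOPWORDS",
    "Document",
    "Index",
    "Topic",
    "CorpusFormatError",
    "tokenize",
    "remove_stopwords",
    "porter_stem",
    "preprocess",
    "build_index",
    "read_corpus",
    "read_topics",
    "read_stopwords",
    "make_topic",
]

#: The classic 33-word Lucene/Solr English stoplist (Solr's stop.txt).
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be but by for if in into is it no not of on or such
    that the their then there these they this to was will with""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class CorpusFormatError(ValueError):
    """Raised for malformed corpus, topic or qrels inputs."""


@dataclass(frozen=True)
class Document:
    """A raw document: unique id, raw text, and (after indexing) its tokens."""

    doc_id: str
    text: str
    tokens: tuple[str, ...] = ()


@dataclass(frozen=True)
class Topic:
    """A query: id plus the ordered, normalized query terms."""

    topic_id: str
    terms: tuple[str, ...]


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any character that is neither a letter nor a digit.

    Mixed alphanumerics such as gene-variant names ("v600e", "int1999") are
    kept intact as single tokens.
    """
    return _TOKEN_RE.findall(text.lower())


def remove_stopwords(tokens: Iterable[str], stoplist: frozenset[str] | set[str] = DEFAULT_STOPWORDS) -> list[str]:
    """Order-preserving stopword filter; idempotent."""
    return [t for t in tokens if t not in stoplist]


def porter_stem(tokens: Iterable[str]) -> list[str]:
    """Apply the original (1980) Porter stemming algorithm to each token."""
    return [porter_stem_word(t) for t in tokens]


def preprocess(text: str, stoplist: frozenset[str] | set[str] = DEFAULT_STOPWORDS, stem: bool = False) -> list[str]:
    """Full pre-processing pipeline: tokenize, remove stopwords, then stem."""
    tokens = remove_stopwords(tokenize(text), stoplist)
    if stem:
        tokens = porter_stem(tokens)
    return tokens


class Index:
    """Inverted index with document-frequency and term-frequency statistics.

    Attributes
    ----------
    n_docs : int
        Corpus size N.
    postings : dict[str, dict[str, int]]
        term -> {doc_id -> tf}; tf >= 1 whenever recorded, so
        df(term) == len(postings[term]).
    doc_len : dict[str, int]
        doc_id -> token count dl (after stopword removal / stemming).
    avdl : float
        Mean document length.
    stemmed : bool
        Whether the corpus was indexed with Porter stemming; queries must be
        preprocessed the same way.
    """

    def __init__(
        self,
        postings: dict[str, dict[str, int]],
        doc_len: dict[str, int],
        stemmed: bool,
    ) -> None:
        if not doc_len:
            raise ValueError("cannot build an index from an empty corpus")
        self.postings = postings
        self.doc_len = doc_len
        self.stemmed = stemmed
        self.n_docs = len(doc_len)
        self.avdl = sum(doc_len.values()) / self.n_docs
        self.total_tokens = sum(doc_len.values())

    @property
    def vocabulary(self) -> set[str]:
        return set(self.postings)

    def df(self, term: str) -> int:
        return len(self.postings.get(term, ()))

    def tf(self, term: str, doc_id: str) -> int:
        return self.postings.get(term, {}).get(doc_id, 0)

    def corpus_tf(self, term: str) -> int:
        """Total number of occurrences of *term* in the whole corpus."""
        return sum(self.postings.get(term, {}).values())

    def doc_terms(self, doc_id: str) -> set[str]:
        # O(vocabulary); acceptable at the scales this package targets.
        return {t for t, plist in self.postings.items() if doc_id in plist}

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self.doc_len


def build_index(
    docs: Iterable[Document],
    use_stemming: bool = False,
    stoplist: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> Index:
    """Tokenize, filter and count every document into an :class:`Index`.

    Raises ``ValueError`` on an empty corpus or duplicate doc ids.
    """
    postings: dict[str, dict[str, int]] = {}
    doc_len: dict[str, int] = {}
    for doc in docs:
        if doc.doc_id in doc_len:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        tokens = doc.tokens if doc.tokens else tuple(preprocess(doc.text, stoplist, use_stemming))
        doc_len[doc.doc_id] = len(tokens)
        for tok in tokens:
            postings.setdefault(tok, {}).setdefault(doc.doc_id, 0)
            postings[tok][doc.doc_id] += 1
    return Index(postings, doc_len, stemmed=use_stemming)


def read_corpus(path: str | Path, format: str = "plain-dir") -> list[Document]:
    """Read a corpus from disk.

    ``plain-dir``: one document per file, doc_id = filename stem.
    ``trec-tagged``: documents delimited by <DOC>/<DOCNO>/<TEXT> tags,
    doc_id = DOCNO content stripped of whitespace.
    """
    path = Path(path)
    if format == "plain-dir":
        if not path.is_dir():
            raise CorpusFormatError(f"{path} is not a directory")
        docs = []
        for f in sorted(path.iterdir()):
            if f.is_file():
                docs.append(Document(doc_id=f.stem, text=f.read_text()))
        seen = set()
        for d in docs:
            if d.doc_id in seen:
                raise CorpusFormatError(f"duplicate doc_id {d.doc_id!r}")
            seen.add(d.doc_id)
        return docs
    if format == "trec-tagged":
        return _read_trec_tagged(path)
    raise ValueError(f"unknown corpus format {format!r}")


_DOC_RE = re.compile(rb"<DOC>(.*?)</DOC>", re.S)
_DOCNO_RE = re.compile(rb"<DOCNO>(.*?)</DOCNO>", re.S)
_TEXT_RE = re.compile(rb"<TEXT>(.*?)</TEXT>", re.S)


def _read_trec_tagged(path: Path) -> list[Document]:
    data = path.read_bytes()
    docs: list[Document] = []
    seen: set[str] = set()
    pos = 0
    while True:
        start = data.find(b"<DOC>", pos)
        if start == -1:
            break
        end = data.find(b"</DOC>", start)
        if end == -1:
            raise CorpusFormatError(f"unclosed <DOC> tag at byte offset {start} in {path}")
        block = data[start : end + len(b"</DOC>")]
        m_no = _DOCNO_RE.search(block)
        if m_no is None:
            raise CorpusFormatError(f"<DOC> block at byte offset {start} lacks a <DOCNO>")
        doc_id = m_no.group(1).decode().strip()
        if doc_id in seen:
            raise CorpusFormatError(f"duplicate DOCNO {doc_id!r} at byte offset {start}")
        seen.add(doc_id)
        m_tx = _TEXT_RE.search(block)
        text = m_tx.group(1).decode() if m_tx else ""
        docs.append(Document(doc_id=doc_id, text=text))
        pos = end + len(b"</DOC>")
    return docs


def read_topics(path: str | Path) -> list[tuple[str, str]]:
    """Read topics as TSV lines ``topic_id <TAB> free text``."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t", 1)
        if len(parts) != 2:
            raise CorpusFormatError(f"{path}:{lineno}: expected 'topic_id<TAB>text'")
        out.append((parts[0].strip(), parts[1]))
    return out


def read_stopwords(path: str | Path) -> frozenset[str]:
    """One term per line; '#' comments and blank lines allowed."""
    words = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return frozenset(words)


def make_topic(
    topic_id: str,
    text: str,
    index: Index,
    stoplist: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> Topic:
    """Preprocess query text consistently with how *index* was built."""
    terms = preprocess(text, stoplist, stem=index.stemmed)
    if not terms:
        raise ValueError(f"topic {topic_id!r} is empty after stopword removal")
    return Topic(topic_id=topic_id, terms=tuple(terms))
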