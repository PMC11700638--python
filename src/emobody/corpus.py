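"""Reading, filtering and writing lemmatized corpora in Oracc token notation.

Tokens follow the ``lemma[guideword]EPOS`` convention used by the Open Richly
Annotated Cuneiform Corpus (Oracc): *lemma* is the dictionary headword,
*guideword* the first dictionary translation, and *EPOS* the effective part of
speech (N, V, AJ, AV, ...).  Tokens that could not be lemmatized — broken or
uncertain signs — are written as a single underscore ``_`` and are kept in the
token stream because they still consume textual distance when counting
co-occurrences.

A corpus on disk is a directory of UTF-8 ``.txt`` files, one document each: a
header block of ``#key: value`` lines (``id``, ``language``, ``period``)
followed by whitespace-separated token keys.  All text is NFC-normalized on
read so that composed and decomposed spellings of the same accented lemma
compare equal.
"""

from __future__ import annotations

import io
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

logger = logging.getLogger(__name__)

EMPTY_MARKER = "_"

TOKENS_PER_LINE = 12  # wrap width used by write_document


class MalformedTokenError(ValueError):
    """A token key does not follow ``lemma[guideword]EPOS`` (or ``_``)."""


class CorpusError(ValueError):
    """Structural corpus problem: duplicate ids, empty corpus, bad header."""


@dataclass(frozen=True)
class Token:
    """One lemmatized token; ``is_empty`` marks the ``_`` placeholder."""

    lemma: str = ""
    guideword: str = ""
    epos: str = ""
    is_empty: bool = False

    def __post_init__(self) -> None:
        if self.is_empty:
            if self.lemma or self.guideword or self.epos:
                raise ValueError("empty token must not carry lemma/guideword/epos")
        elif not (self.lemma and self.guideword and self.epos):
            raise ValueError("non-empty token requires lemma, guideword and epos")

    def key(self) -> str:
        """Serialize back to ``lemma[guideword]EPOS`` (or ``_``)."""
        if self.is_empty:
            return EMPTY_MARKER
        return f"{self.lemma}[{self.guideword}]{self.epos}"


EMPTY_TOKEN = Token(is_empty=True)


def parse_token(s: str, *, lenient: bool = False) -> Token:
    """Parse one token key.

    The lemma is everything before the *first* ``[`` and the EPOS everything
    after the *last* ``]``, so guidewords containing ``(``, ``)``, ``-`` or
    even brackets survive a round trip.  ``_`` yields the empty token.

    With ``lenient=True`` malformed keys are logged and mapped to the empty
    token instead of raising :class:`MalformedTokenError`.
    """
    s = unicodedata.normalize("NFC", s.strip())
    if not s:
        raise MalformedTokenError("empty string is not a token key")
    if s == EMPTY_MARKER:
        return EMPTY_TOKEN
    i = s.find("[")
    j = s.rfind("]")
    if i <= 0 or j < i or j == len(s) - 1 or j - i <= 1:
        if lenient:
            logger.warning("malformed token %r mapped to empty token", s)
            return EMPTY_TOKEN
        raise MalformedTokenError(f"malformed token key: {s!r}")
    return Token(lemma=s[:i], guideword=s[i + 1 : j], epos=s[j + 1 :])


@dataclass
class Document:
    """An ordered token stream with Oracc-style metadata tags."""

    id: str
    language: str = ""
    period: str = ""
    tokens: list[Token] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    """An ordered document collection; document ids must be unique."""

    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.id for d in self.documents]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusError(f"duplicate document ids: {dupes}")

    @property
    def token_count(self) -> int:
        """Total tokens across documents, empty (``_``) tokens included."""
        return sum(len(d) for d in self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


def read_document(source: IO[str] | str | Path, *, lenient: bool = False) -> Document:
    """Read one document from a stream or path (header lines, then tokens)."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return read_document(fh, lenient=lenient)
    meta: dict[str, str] = {}
    tokens: list[Token] = []
    for raw in source:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" not in line:
                raise CorpusError(f"malformed header line: {line!r}")
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = unicodedata.normalize("NFC", value.strip())
        else:
            tokens.extend(parse_token(t, lenient=lenient) for t in line.split())
    if "id" not in meta:
        raise CorpusError("document header is missing '#id:'")
    return Document(
        id=meta["id"],
        language=meta.get("language", ""),
        period=meta.get("period", ""),
        tokens=tokens,
    )


def read_corpus(
    sources: Iterable[IO[str] | str | Path] | str | Path,
    *,
    lenient: bool = False,
) -> Corpus:
    """Read a corpus from an iterable of streams/paths or a directory.

    Source order is preserved; a directory is read as its sorted ``*.txt``
    files.  Duplicate document ids raise :class:`CorpusError`.
    """
    if isinstance(sources, (str, Path)) and Path(sources).is_dir():
        sources = sorted(Path(sources).glob("*.txt"))
    docs = [read_document(src, lenient=lenient) for src in sources]
    return Corpus(documents=docs)


def write_document(doc: Document, sink: IO[str] | str | Path) -> None:
    """Write one document in the corpus dialect (deterministic layout)."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_document(doc, fh)
        return
    sink.write(f"#id: {doc.id}\n")
    sink.write(f"#language: {doc.language}\n")
    sink.write(f"#period: {doc.period}\n")
    keys = [t.key() for t in doc.tokens]
    for start in range(0, len(keys), TOKENS_PER_LINE):
        sink.write(" ".join(keys[start : start + TOKENS_PER_LINE]) + "\n")


def write_corpus(corpus: Corpus, directory: str | Path) -> list[Path]:
    """Write one ``<id>.txt`` file per document; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for doc in corpus:
        path = directory / f"{doc.id}.txt"
        write_document(doc, path)
        paths.append(path)
    return paths


def document_to_string(doc: Document) -> str:
    buf = io.StringIO()
    write_document(doc, buf)
    return buf.getvalue()


def filter_corpus(
    corpus: Corpus, languages: Iterable[str], periods: Iterable[str]
) -> Corpus:
    """Keep documents whose language AND period tags are in the given sets.

    Matching is exact string comparison after trimming (Oracc metadata tags
    are curated strings, so no fuzzy matching).  The input is not mutated; an
    empty result is legal.
    """
    lang_set = {l.strip() for l in languages}
    period_set = {p.strip() for p in periods}
    if not lang_set or not period_set:
        raise ValueError("language and period tag sets must be non-empty")
    kept = [
        d
        for d in corpus
        if d.language.strip() in lang_set and d.period.strip() in period_set
    ]
    return Corpus(documents=list(kept))


def export_token_lines(corpus: Corpus, sink: IO[str] | str | Path) -> None:
    """Export the raw token stream, one token key per line (interop format)."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            export_token_lines(corpus, fh)
        return
    for doc in corpus:
        for tok in doc.tokens:
            sink.write(tok.key() + "\n")
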