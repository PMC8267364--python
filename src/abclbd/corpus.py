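"""Concept-annotated document streams and the concept vocabulary.

A corpus here is an ordered collection of documents, each of which is an
ordered sequence of UMLS-style concept identifiers (CUIs, ``C`` followed by
seven digits).  This is the minimal surrogate for concept-mapped biomedical
abstracts: stopwords are already gone (they map to no concept) and synonyms
are already collapsed onto a single identifier, so the only structure the
downstream co-occurrence counter needs is token order within a document.

The vocabulary is a miniature Metathesaurus: one entry per CUI carrying a
preferred term, one or more semantic-type codes (e.g. ``T047`` for Disease
or Syndrome) and a semantic-group code (e.g. ``DISO``).  Vocabulary
completeness is deliberately not required — concepts that appear in a corpus
but not in the vocabulary are counted normally, fail semantic-type filters,
and render with the preferred term ``UNKNOWN``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

CUI_PATTERN = re.compile(r"^C\d{7}$")

#: Preferred term reported for concepts absent from the vocabulary.
UNKNOWN_TERM = "UNKNOWN"


class CorpusFormatError(ValueError):
    """A corpus or vocabulary file violates its line format."""


def is_valid_cui(cui: str) -> bool:
    """True if *cui* is ``C`` followed by exactly seven digits."""
    return bool(CUI_PATTERN.match(cui))


@dataclass(frozen=True)
class ConceptToken:
    """A single concept occurrence at a 0-based position in its document."""

    cui: str
    position: int

    def __post_init__(self) -> None:
        if not is_valid_cui(self.cui):
            raise ValueError(f"malformed CUI: {self.cui!r}")
        if self.position < 0:
            raise ValueError(f"negative token position: {self.position}")


@dataclass(frozen=True)
class Document:
    """An ordered concept stream (one title+abstract's worth of concepts)."""

    doc_id: str
    tokens: tuple[ConceptToken, ...] = ()

    def __post_init__(self) -> None:
        for i, tok in enumerate(self.tokens):
            if tok.position != i:
                raise ValueError(
                    f"document {self.doc_id!r}: token at index {i} has "
                    f"position {tok.position}; positions must be contiguous from 0"
                )

    @classmethod
    def from_cuis(cls, doc_id: str, cuis: Iterable[str]) -> "Document":
        return cls(doc_id, tuple(ConceptToken(c, i) for i, c in enumerate(cuis)))

    def cuis(self) -> list[str]:
        return [t.cui for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Corpus:
    """An ordered sequence of documents with unique identifiers."""

    documents: tuple[Document, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id: {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(len(d) for d in self.documents)


@dataclass(frozen=True)
class VocabEntry:
    """One concept: preferred term plus semantic types and group."""

    cui: str
    preferred_term: str
    semantic_types: frozenset[str]
    semantic_group: str

    def __post_init__(self) -> None:
        if not is_valid_cui(self.cui):
            raise ValueError(f"malformed CUI: {self.cui!r}")
        if not self.semantic_types:
            raise ValueError(f"{self.cui}: semantic_types must be non-empty")


@dataclass(frozen=True)
class Vocabulary:
    """CUI -> VocabEntry map (a miniature Metathesaurus)."""

    entries: Mapping[str, VocabEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cui, entry in self.entries.items():
            if cui != entry.cui:
                raise ValueError(f"vocabulary key {cui!r} != entry CUI {entry.cui!r}")

    def __contains__(self, cui: str) -> bool:
        return cui in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, cui: str) -> VocabEntry | None:
        return self.entries.get(cui)

    def preferred_term(self, cui: str) -> str:
        """Preferred term for *cui*, or ``UNKNOWN`` if unmapped."""
        entry = self.entries.get(cui)
        return entry.preferred_term if entry is not None else UNKNOWN_TERM

    def has_any_type(self, cui: str, types: Iterable[str]) -> bool:
        """True if *cui* is in the vocabulary and carries one of *types*."""
        entry = self.entries.get(cui)
        return entry is not None and not self.entries[cui].semantic_types.isdisjoint(types)

    def concepts_with_types(self, types: Iterable[str]) -> set[str]:
        """All CUIs carrying at least one of the given semantic types."""
        wanted = set(types)
        return {
            cui
            for cui, entry in self.entries.items()
            if not entry.semantic_types.isdisjoint(wanted)
        }


@dataclass(frozen=True)
class ReadReport:
    """Tally of what a lenient corpus read kept and dropped."""

    n_documents: int
    n_tokens_kept: int
    n_tokens_dropped: int


def read_corpus(path: str | Path, strict: bool = True) -> Corpus:
    """Read a corpus file: one document per line, ``doc_id<TAB>cui( cui)*``.

    Blank lines and ``#``-prefixed comment lines are ignored.  In strict mode
    any malformed CUI aborts with :class:`CorpusFormatError`; in lenient mode
    malformed tokens are dropped and counted (see :func:`read_corpus_lenient`
    for access to the tally).  Duplicate document identifiers are always an
    error.
    """
    corpus, _ = read_corpus_lenient(path, strict=strict)
    return corpus


def read_corpus_lenient(
    path: str | Path, strict: bool = False
) -> tuple[Corpus, ReadReport]:
    """Like :func:`read_corpus` but also returns the kept/dropped tally."""
    path = Path(path)
    documents: list[Document] = []
    seen_ids: set[str] = set()
    n_kept = 0
    n_dropped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" not in line:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 'doc_id<TAB>cui ...', got {line!r}"
                )
            doc_id, _, rest = line.partition("\t")
            if not doc_id:
                raise CorpusFormatError(f"{path}:{lineno}: empty doc_id")
            if doc_id in seen_ids:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen_ids.add(doc_id)
            cuis: list[str] = []
            for token in rest.split():
                if is_valid_cui(token):
                    cuis.append(token)
                elif strict:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: malformed CUI {token!r}"
                    )
                else:
                    n_dropped += 1
            n_kept += len(cuis)
            documents.append(Document.from_cuis(doc_id, cuis))
    if n_dropped:
        logger.warning("read_corpus: dropped %d malformed tokens from %s", n_dropped, path)
    report = ReadReport(len(documents), n_kept, n_dropped)
    return Corpus(tuple(documents)), report


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write *corpus* in the line format read by :func:`read_corpus`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(doc.doc_id + "\t" + " ".join(doc.cuis()) + "\n")


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load a 4-column TSV vocabulary.

    Columns: ``cui``, ``preferred_term``, comma-separated ``semantic_types``,
    ``semantic_group``.  A header line is optional and detected by its first
    cell equalling ``cui``.  Duplicate CUIs are an error.
    """
    path = Path(path)
    entries: dict[str, VocabEntry] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if lineno == 1 and cells and cells[0] == "cui":
                continue
            if len(cells) != 4:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(cells)}"
                )
            cui, term, types_field, group = cells
            types = frozenset(t for t in types_field.split(",") if t)
            if not types:
                raise CorpusFormatError(f"{path}:{lineno}: empty semantic-type field")
            if cui in entries:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate CUI {cui!r}")
            entries[cui] = VocabEntry(cui, term, types, group)
    return Vocabulary(entries)


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    """Write a vocabulary as the 4-column TSV read by :func:`load_vocabulary`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("cui\tpreferred_term\tsemantic_types\tsemantic_group\n")
        for cui in sorted(vocab.entries):
            e = vocab.entries[cui]
            fh.write(
                f"{cui}\t{e.preferred_term}\t{','.join(sorted(e.semantic_types))}\t{e.semantic_group}\n"
            )


def resolve_concept(vocab: Vocabulary, cui: str) -> VocabEntry | None:
    """Look up *cui*; returns ``None`` (never raises) for unmapped concepts."""
    return vocab.get(cui)
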