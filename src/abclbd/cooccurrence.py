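"""Windowed concept co-occurrence counting and the flat pair-count file.

Two concepts co-occur when they appear within ``window_size`` token
positions of each other inside the same document; sentence boundaries carry
no weight and windows never cross documents.  Each unordered position pair
(i, j) with i < j and j - i <= window_size contributes exactly one count to
the unordered CUI pair — equivalent to the classic symmetric sliding-window
description, but without double-counting each pair once per focus token.
Same-concept pairs (the diagonal) are never stored: self co-occurrence has
no meaning for A-B-C linking.

The default window of eight token positions matches the average
concept-stream length of a sentence in concept-mapped MEDLINE, a width that
balances missed associations (too narrow) against noise (too wide).

The serialized form is a deterministic flat TSV: two ``#key=value`` header
lines (window size, document count) followed by one ``cui_a TAB cui_b TAB
count`` line per pair, pairs normalized so cui_a < cui_b and sorted
lexicographically, so identical matrices produce byte-identical files.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .corpus import Corpus, is_valid_cui

#: Window width (token positions either side of the focus concept) used
#: throughout unless a caller overrides it.
DEFAULT_WINDOW_SIZE = 8


class MatrixFormatError(ValueError):
    """A flat co-occurrence file violates its format contract."""


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"diagonal pair ({a!r}, {a!r}) is not representable")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric sparse map from unordered CUI pairs to window co-occurrence counts.

    ``counts`` keys are normalized pairs (lexicographically smaller CUI
    first); all stored counts are >= 1 and an absent pair means zero.
    """

    counts: Mapping[tuple[str, str], int] = field(default_factory=dict)
    window_size: int = DEFAULT_WINDOW_SIZE
    n_documents: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError(f"window_size must be >= 1, got {self.window_size}")
        for (a, b), count in self.counts.items():
            if a >= b:
                raise ValueError(f"pair ({a}, {b}) is not normalized (need a < b)")
            if count < 1:
                raise ValueError(f"pair ({a}, {b}) has non-positive count {count}")

    def pair_count(self, a: str, b: str) -> int:
        """Symmetric lookup; 0 for absent pairs; a == b is an error."""
        return self.counts.get(_norm_pair(a, b), 0)

    def neighbours(self, cui: str) -> dict[str, int]:
        """All concepts co-occurring with *cui*, mapped to their counts."""
        out: dict[str, int] = {}
        for (a, b), count in self.counts.items():
            if a == cui:
                out[b] = count
            elif b == cui:
                out[a] = count
        return out

    def concepts(self) -> set[str]:
        seen: set[str] = set()
        for a, b in self.counts:
            seen.add(a)
            seen.add(b)
        return seen

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.counts)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def pair_count(matrix: CooccurrenceMatrix, a: str, b: str) -> int:
    """Functional alias for :meth:`CooccurrenceMatrix.pair_count`."""
    return matrix.pair_count(a, b)


def count_cooccurrences(
    corpus: Corpus, window_size: int = DEFAULT_WINDOW_SIZE
) -> CooccurrenceMatrix:
    """Count windowed co-occurrences over *corpus*.

    For every document and every position pair (i, j) with i < j,
    j - i <= window_size and distinct CUIs, the unordered CUI pair is
    incremented by one.  Duplicate concepts count once per qualifying
    position pair: the stream ``[X, Y, X]`` yields count(X, Y) = 2.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    counts: Counter[tuple[str, str]] = Counter()
    for doc in corpus:
        cuis = doc.cuis()
        for j in range(1, len(cuis)):
            cj = cuis[j]
            for i in range(max(0, j - window_size), j):
                ci = cuis[i]
                if ci != cj:
                    counts[_norm_pair(ci, cj)] += 1
    return CooccurrenceMatrix(dict(counts), window_size, len(corpus))


def write_matrix(matrix: CooccurrenceMatrix, path: str | Path) -> None:
    """Write the flat pair-count file (deterministic, byte-exact)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#window_size={matrix.window_size}\n")
        fh.write(f"#n_documents={matrix.n_documents}\n")
        for a, b in sorted(matrix.counts):
            fh.write(f"{a}\t{b}\t{matrix.counts[(a, b)]}\n")


def read_matrix(path: str | Path) -> CooccurrenceMatrix:
    """Read a flat pair-count file written by :func:`write_matrix`.

    Pair normalization is applied on read, so a file listing ``B A`` is
    accepted — but listing both ``A B`` and ``B A`` is a duplicate-pair
    error, as is any repeated pair line.
    """
    path = Path(path)
    headers: dict[str, int] = {}
    counts: dict[tuple[str, str], int] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, sep, value = line[1:].partition("=")
                if sep and key in ("window_size", "n_documents"):
                    try:
                        headers[key] = int(value)
                    except ValueError:
                        raise MatrixFormatError(
                            f"{path}:{lineno}: non-integer header value {value!r}"
                        ) from None
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected 'cui<TAB>cui<TAB>count', got {line!r}"
                )
            a, b, count_str = cells
            if not (is_valid_cui(a) and is_valid_cui(b)):
                raise MatrixFormatError(f"{path}:{lineno}: malformed CUI in {line!r}")
            try:
                count = int(count_str)
            except ValueError:
                raise MatrixFormatError(
                    f"{path}:{lineno}: non-integer count {count_str!r}"
                ) from None
            if count < 1:
                raise MatrixFormatError(f"{path}:{lineno}: count must be >= 1, got {count}")
            if a == b:
                raise MatrixFormatError(f"{path}:{lineno}: diagonal pair {a}")
            key_pair = _norm_pair(a, b)
            if key_pair in counts:
                raise MatrixFormatError(
                    f"{path}:{lineno}: duplicate unordered pair {key_pair}"
                )
            counts[key_pair] = count
    if "window_size" not in headers or "n_documents" not in headers:
        raise MatrixFormatError(
            f"{path}: missing #window_size= or #n_documents= header"
        )
    return CooccurrenceMatrix(counts, headers["window_size"], headers["n_documents"])
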