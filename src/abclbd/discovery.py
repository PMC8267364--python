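"""Open-discovery A-B-C linking and Linking-Term-Count ranking.

The A-B-C co-occurrence model generates hypotheses of the form "start
concept A may be related to target concept C" from two layers of explicit
co-occurrence: A co-occurs with linking concepts B, and each B co-occurs
with candidate targets C.  A and C need never co-occur directly — that gap
is precisely where new knowledge hides.  Targets are ranked by the Linking
Term Count (LTC): the number of distinct B concepts connecting A to C.
LTC is deliberately simple; it rewards breadth of independent evidence
rather than raw frequency.

The pipeline has four stages, each exposed as a function so every
intermediate is testable:

1. :func:`link_b_terms` — find the B concepts co-occurring with A (optionally
   restricted to a candidate set, e.g. laboratory-identified metabolites);
2. :func:`generate_c_candidates` — expand each linked B to everything it
   co-occurs with;
3. :func:`apply_filters` — drop weak B-C edges (below ``min_bc_count``),
   drop targets outside the requested semantic types, and (optionally) drop
   targets that already co-occur with A;
4. :func:`rank_by_ltc` — score and order the surviving targets.

Targets directly co-occurring with A are *kept* by default: known
associations reassure the investigator that the ranking is sane, and a
"known to science" link may still be new to the reader.  Ties are broken by
ascending CUI so that runs are reproducible (a deliberate choice; frequency
ranking itself gives no order among equals).

:class:`AbcDiscovery` wraps the stages in a model object: construct it from
a co-occurrence matrix and vocabulary, call :meth:`AbcDiscovery.fit` with a
query, and read the ranked hypotheses (with a ``summary()`` table) off the
returned :class:`DiscoveryResult`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

from .cooccurrence import CooccurrenceMatrix
from .corpus import Vocabulary, is_valid_cui

logger = logging.getLogger(__name__)

#: Disease or Syndrome — the default target semantic type.
DISEASE_TYPE = "T047"


@dataclass(frozen=True)
class DiscoveryQuery:
    """An open-discovery question: start term, B restriction, target filter.

    Parameters
    ----------
    a_term:
        CUI of the start concept.
    b_restriction:
        Optional candidate set of linking CUIs (e.g. metabolites already
        implicated experimentally).  ``None`` means every concept
        co-occurring with the start term is a potential linker.
    c_semantic_types:
        Semantic-type codes a target must carry; defaults to disease.
    min_ab_count:
        Minimum A-B co-occurrence count for B to qualify as a linker
        (default 1: any co-occurrence constitutes a link).
    min_bc_count:
        Minimum B-C co-occurrence count for an edge to survive filtering
        (default 2: singleton co-occurrences are treated as noise).
    keep_direct:
        Keep targets that directly co-occur with the start term
        (default True).
    """

    a_term: str
    b_restriction: frozenset[str] | None = None
    c_semantic_types: frozenset[str] = frozenset({DISEASE_TYPE})
    min_ab_count: int = 1
    min_bc_count: int = 2
    keep_direct: bool = True

    def __post_init__(self) -> None:
        if not is_valid_cui(self.a_term):
            raise ValueError(f"malformed start-term CUI: {self.a_term!r}")
        if self.b_restriction is not None:
            object.__setattr__(self, "b_restriction", frozenset(self.b_restriction))
            if self.a_term in self.b_restriction:
                raise ValueError("a_term must not appear in b_restriction")
        object.__setattr__(self, "c_semantic_types", frozenset(self.c_semantic_types))
        if not self.c_semantic_types:
            raise ValueError("c_semantic_types must be non-empty")
        if self.min_ab_count < 1:
            raise ValueError("min_ab_count must be >= 1")
        if self.min_bc_count < 1:
            raise ValueError("min_bc_count must be >= 1")


@dataclass(frozen=True)
class LinkedTermSet:
    """Outcome of A-B linking: retained linkers and excluded candidates."""

    links: Mapping[str, int]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = set(self.links) & set(self.excluded)
        if overlap:
            raise ValueError(f"links and excluded overlap: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.links)


@dataclass(frozen=True)
class Hypothesis:
    """A ranked target: its LTC score and per-linker co-occurrence counts."""

    c_term: str
    ltc: int
    b_breakdown: tuple[tuple[str, int], ...]
    direct_ac_count: int = 0

    def __post_init__(self) -> None:
        if self.ltc != len(self.b_breakdown):
            raise ValueError(
                f"{self.c_term}: ltc {self.ltc} != breakdown length {len(self.b_breakdown)}"
            )


@dataclass(frozen=True)
class DiscoveryResult:
    """Ranked output of one discovery run, with stage outputs retained."""

    query: DiscoveryQuery
    linked: LinkedTermSet
    hypotheses: tuple[Hypothesis, ...]
    vocab: Vocabulary | None = field(default=None, compare=False, repr=False)

    def __len__(self) -> int:
        return len(self.hypotheses)

    def hypothesis_for(self, c_term: str) -> Hypothesis | None:
        for h in self.hypotheses:
            if h.c_term == c_term:
                return h
        return None

    def ltc(self, c_term: str) -> int:
        """LTC score of *c_term*; 0 if it is not among the hypotheses."""
        h = self.hypothesis_for(c_term)
        return h.ltc if h is not None else 0

    def summary(self, max_terms: int = 20) -> str:
        """Human-readable ranked listing (see the report module for detail)."""
        from .report import render_hypothesis_list

        vocab = self.vocab if self.vocab is not None else Vocabulary({})
        header = (
            f"ABC discovery from {self.a_preferred_term()} ({self.query.a_term})\n"
            f"linked B terms: {len(self.linked)}"
            f" (excluded: {len(self.linked.excluded)});"
            f" ranked targets: {len(self.hypotheses)}\n\n"
        )
        return header + render_hypothesis_list(self, vocab, max_terms=max_terms)

    def a_preferred_term(self) -> str:
        if self.vocab is None:
            return self.query.a_term
        return self.vocab.preferred_term(self.query.a_term)


def link_b_terms(query: DiscoveryQuery, matrix: CooccurrenceMatrix) -> LinkedTermSet:
    """Stage 1: find linking B terms by direct co-occurrence with the A term.

    With a ``b_restriction``, every candidate lands either in ``links``
    (A-B count >= ``min_ab_count``) or in ``excluded``; without one, every
    concept co-occurring with A at or above threshold is a linker and
    ``excluded`` is empty.
    """
    neighbours = matrix.neighbours(query.a_term)
    if query.b_restriction is not None:
        links = {
            b: neighbours[b]
            for b in query.b_restriction
            if neighbours.get(b, 0) >= query.min_ab_count
        }
        excluded = frozenset(query.b_restriction - set(links))
    else:
        links = {b: c for b, c in neighbours.items() if c >= query.min_ab_count}
        excluded = frozenset()
    return LinkedTermSet(links, excluded)


def generate_c_candidates(
    linked: LinkedTermSet, matrix: CooccurrenceMatrix
) -> dict[str, dict[str, int]]:
    """Stage 2: expand each linked B term to all of its co-occurring concepts.

    Returns ``{c_term: {b_term: bc_count}}`` for every concept co-occurring
    with at least one linker (count >= 1, pre-filter).  The A term itself is
    retained as a candidate here; the keep-direct policy is applied later.
    Linked B terms can themselves appear as candidates via other linkers.
    """
    candidates: dict[str, dict[str, int]] = {}
    for b in linked.links:
        # no diagonal in the matrix, so b never lists itself as a neighbour
        for c, count in matrix.neighbours(b).items():
            candidates.setdefault(c, {})[b] = count
    return candidates


def apply_filters(
    candidates: Mapping[str, Mapping[str, int]],
    query: DiscoveryQuery,
    vocab: Vocabulary,
    matrix: CooccurrenceMatrix | None = None,
) -> dict[str, dict[str, int]]:
    """Stage 3: count filter, semantic-type filter, keep-direct policy.

    Edges below ``min_bc_count`` are removed first; targets left with no
    edges are dropped; targets whose vocabulary entry lacks every requested
    semantic type are dropped (concepts missing from the vocabulary cannot
    pass a type filter and are dropped too).  When ``keep_direct`` is off,
    targets with any direct A co-occurrence — including the A term itself —
    are removed; *matrix* is required in that case.
    """
    filtered: dict[str, dict[str, int]] = {}
    for c, b_map in candidates.items():
        kept = {b: n for b, n in b_map.items() if n >= query.min_bc_count}
        if not kept:
            continue
        if not vocab.has_any_type(c, query.c_semantic_types):
            continue
        if not query.keep_direct:
            if c == query.a_term:
                continue
            if matrix is None:
                raise ValueError("matrix required to apply keep_direct=False")
            if matrix.pair_count(query.a_term, c) >= 1:
                continue
        filtered[c] = kept
    return filtered


def rank_by_ltc(
    candidates: Mapping[str, Mapping[str, int]],
    matrix: CooccurrenceMatrix | None = None,
    a_term: str | None = None,
) -> tuple[Hypothesis, ...]:
    """Stage 4: score targets by distinct-linker count and order them.

    Hypotheses are sorted by LTC descending, ties by CUI ascending; each
    breakdown is sorted by B-C count descending, ties by CUI ascending.
    """
    hypotheses: list[Hypothesis] = []
    for c, b_map in candidates.items():
        breakdown = tuple(sorted(b_map.items(), key=lambda kv: (-kv[1], kv[0])))
        direct = 0
        if matrix is not None and a_term is not None and c != a_term:
            direct = matrix.pair_count(a_term, c)
        hypotheses.append(Hypothesis(c, len(breakdown), breakdown, direct))
    hypotheses.sort(key=lambda h: (-h.ltc, h.c_term))
    return tuple(hypotheses)


def run_discovery(
    query: DiscoveryQuery, matrix: CooccurrenceMatrix, vocab: Vocabulary
) -> DiscoveryResult:
    """Run all four stages and return the ranked result."""
    if query.a_term not in vocab:
        logger.warning(
            "start term %s is not in the vocabulary; proceeding anyway", query.a_term
        )
    linked = link_b_terms(query, matrix)
    candidates = generate_c_candidates(linked, matrix)
    filtered = apply_filters(candidates, query, vocab, matrix)
    hypotheses = rank_by_ltc(filtered, matrix, query.a_term)
    return DiscoveryResult(query, linked, hypotheses, vocab)


class AbcDiscovery:
    """ABC discovery model over a co-occurrence matrix and vocabulary.

    Examples
    --------
    >>> model = AbcDiscovery(matrix, vocab)                    # doctest: +SKIP
    >>> result = model.fit(DiscoveryQuery(a_term="C0018790"))  # doctest: +SKIP
    >>> print(result.summary())                                # doctest: +SKIP
    """

    def __init__(self, matrix: CooccurrenceMatrix, vocab: Vocabulary) -> None:
        self.matrix = matrix
        self.vocab = vocab

    def fit(self, query: DiscoveryQuery) -> DiscoveryResult:
        """Execute the query against this model's matrix and vocabulary."""
        return run_discovery(query, self.matrix, self.vocab)

    def refit(self, result: DiscoveryResult, **query_changes) -> DiscoveryResult:
        """Re-run a previous result's query with some fields changed."""
        return self.fit(replace(result.query, **query_changes))
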