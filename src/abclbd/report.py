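"""Render discovery results: ranked listing, score histogram, threshold listing.

Three views mirror how an investigator consumes open-discovery output:

* the ranked hypothesis listing — each target on a header line
  ``<ltc> - <cui> - <preferred term>``, followed by one tab-indented line
  per linking concept with its target co-occurrence count, strongest first;
* the LTC histogram — how many targets score exactly k and how many score
  at least k, down to the zero row (targets passing the semantic filter but
  sharing no linker), which is why a universe size is needed;
* the threshold listing — the targets at or above a chosen score, the
  "short list worth manual review".

Rendering never re-ranks: all ordering comes from the discovery result.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .corpus import Vocabulary
from .discovery import DiscoveryResult


@dataclass(frozen=True)
class HistogramRow:
    """One score bin: exact-count and cumulative (at-or-above) tallies."""

    ltc: int
    n_terms: int
    n_at_or_above: int


def render_hypothesis_list(
    result: DiscoveryResult, vocab: Vocabulary, max_terms: int | None = None
) -> str:
    """Ranked listing with per-linker breakdowns (deterministic text)."""
    lines: list[str] = []
    hypotheses = result.hypotheses
    if max_terms is not None:
        hypotheses = hypotheses[:max_terms]
    for h in hypotheses:
        lines.append(f"{h.ltc} - {h.c_term} - {vocab.preferred_term(h.c_term)}")
        for b, count in h.b_breakdown:
            lines.append(f"\t{count}\t{b}\t{vocab.preferred_term(b)}")
    return "\n".join(lines) + ("\n" if lines else "")


def histogram_from_counts(
    per_score: Mapping[int, int], universe_size: int
) -> list[HistogramRow]:
    """Build histogram rows from a {score: n_terms} distribution.

    ``universe_size`` is the total number of concepts eligible as targets
    (everything passing the semantic filter); the zero row absorbs the
    eligible concepts absent from ``per_score``.
    """
    scored = {s: n for s, n in per_score.items() if s >= 1}
    n_scored = sum(scored.values())
    if universe_size < n_scored:
        raise ValueError(
            f"universe_size {universe_size} < {n_scored} scored terms"
        )
    explicit_zero = per_score.get(0)
    n_zero = universe_size - n_scored
    if explicit_zero is not None and explicit_zero != n_zero:
        raise ValueError(
            f"explicit zero-score count {explicit_zero} inconsistent with "
            f"universe_size {universe_size} minus {n_scored} scored terms"
        )
    max_score = max(scored, default=0)
    rows: list[HistogramRow] = []
    cumulative = 0
    for score in range(max_score, 0, -1):
        n = scored.get(score, 0)
        cumulative += n
        rows.append(HistogramRow(score, n, cumulative))
    rows.append(HistogramRow(0, n_zero, cumulative + n_zero))
    return rows


def ltc_histogram(result: DiscoveryResult, universe_size: int) -> list[HistogramRow]:
    """Histogram of the result's scores over a target universe of given size."""
    per_score: dict[int, int] = {}
    for h in result.hypotheses:
        per_score[h.ltc] = per_score.get(h.ltc, 0) + 1
    return histogram_from_counts(per_score, universe_size)


def cumulative_at(rows: list[HistogramRow], min_ltc: int) -> int:
    """Number of terms scoring at least *min_ltc* according to *rows*."""
    total = 0
    for row in rows:
        if row.ltc >= min_ltc:
            total += row.n_terms
    return total


def threshold_listing(
    result: DiscoveryResult, vocab: Vocabulary, min_ltc: int
) -> list[tuple[int, str, str]]:
    """Targets with LTC >= *min_ltc*, in result order, as (ltc, cui, term)."""
    if min_ltc < 0:
        raise ValueError("min_ltc must be >= 0")
    return [
        (h.ltc, h.c_term, vocab.preferred_term(h.c_term))
        for h in result.hypotheses
        if h.ltc >= min_ltc
    ]


def write_histogram_tsv(rows: list[HistogramRow], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("ltc\tn_terms\tn_at_or_above\n")
        for row in rows:
            fh.write(f"{row.ltc}\t{row.n_terms}\t{row.n_at_or_above}\n")


def write_threshold_tsv(
    listing: list[tuple[int, str, str]], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("ltc\tcui\tpreferred_term\n")
        for ltc, cui, term in listing:
            fh.write(f"{ltc}\t{cui}\t{term}\n")
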