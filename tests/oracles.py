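"""Independent brute-force oracles the implementation is checked against.

These deliberately take the slow, obvious route: enumerate *all* position
pairs and test the distance condition, rather than sliding a window.
"""

from collections import Counter

from abclbd import Corpus


def brute_force_counts(corpus: Corpus, window_size: int) -> dict[tuple[str, str], int]:
    """O(n^2) pairwise-distance count of windowed co-occurrences."""
    counts: Counter[tuple[str, str]] = Counter()
    for doc in corpus:
        cuis = doc.cuis()
        n = len(cuis)
        for i in range(n):
            for j in range(n):
                if i < j and j - i <= window_size and cuis[i] != cuis[j]:
                    a, b = sorted((cuis[i], cuis[j]))
                    counts[(a, b)] += 1
    return dict(counts)


def brute_force_ltc(candidates: dict[str, dict[str, int]]) -> dict[str, int]:
    """Recount distinct linkers per target straight from the candidate map."""
    return {c: len(set(b_map)) for c, b_map in candidates.items()}
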