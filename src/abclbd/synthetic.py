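"""Synthetic corpora with prescribed co-occurrence structure, plus packaged fixtures.

The real corpus behind this kind of discovery work — tens of millions of
concept-mapped citation abstracts — is licensed and enormous.  For testing,
what matters is not the text but the co-occurrence counts the pipeline
consumes, so this module generates corpora whose windowed counts are known
*by construction*:

* :func:`generate_corpus` plants each requested pair count k as k minimal
  two-token documents ``[x, y]`` (a two-token document realizes exactly one
  co-occurrence under any window >= 1 and can create no other pair), mixed
  with noise documents drawn from a reserved identifier range disjoint from
  all planted concepts.  Recounting the corpus therefore recovers the
  requested counts exactly, noise or not.
* :func:`plant_abc_scenario` assembles a full open-discovery test case —
  a start term, a bank of linkers, and target concepts with chosen
  linker-sharing profiles — whose correct ranking is known in advance.
* :func:`fixture_matrix` loads the packaged worked example: a cardiac-arrest
  start term, 19 candidate metabolite linkers (17 with a start-term link,
  2 without), and the full per-metabolite co-occurrence breakdowns for the
  fish-eye-disease and Wiskott-Aldrich-syndrome targets, with a vocabulary
  covering every concept involved.

Start/linker/target A-B co-occurrence counts for the packaged fixture are
not derivable from the breakdowns (only their existence is); the fixture
sets them to 2 so that each surviving linker also carries the start term
itself past the default edge filter, keeping the start term at the top of
the ranked list with a score equal to the linker count.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, NamedTuple

from .cooccurrence import CooccurrenceMatrix, count_cooccurrences
from .corpus import Corpus, Document, Vocabulary, is_valid_cui, load_vocabulary
from .discovery import DISEASE_TYPE, DiscoveryQuery

#: Noise concepts are drawn from C9000000-C9999999; planted concepts must
#: stay outside this range so noise can never contaminate a planted pair.
NOISE_CUI_PREFIX = "C9"

#: Start term of the packaged fixture (cardiac arrest).
FIXTURE_A_TERM = "C0018790"

#: The 19 candidate linking metabolites of the packaged fixture.
FIXTURE_B_TERMS = frozenset(
    {
        "C0368608", "C0003765", "C0007745", "C0008405", "C0556150",
        "C0058624", "C2348386", "C2348388", "C0017770", "C0019602",
        "C0023401", "C0024360", "C0028375", "C0070662", "C0031716",
        "C0031951", "C0037906",
        # candidates with no recorded start-term co-occurrence
        "C2348307", "C0069409",
    }
)


def _is_noise_cui(cui: str) -> bool:
    return cui.startswith(NOISE_CUI_PREFIX)


@dataclass(frozen=True)
class PlantSpec:
    """Pair counts to realize exactly, plus background noise parameters.

    ``pair_counts`` maps unordered CUI pairs to the windowed count the
    generated corpus must reproduce.  Noise documents of ``noise_doc_length``
    tokens are sampled uniformly from a reserved ``noise_vocab_size``-concept
    identifier range; they add realistic bulk without touching planted pairs.
    """

    pair_counts: Mapping[tuple[str, str], int] = field(default_factory=dict)
    noise_vocab_size: int = 0
    noise_documents: int = 0
    noise_doc_length: int = 10
    window_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        norm: dict[tuple[str, str], int] = {}
        for (a, b), count in self.pair_counts.items():
            if a == b:
                raise ValueError(f"diagonal pair ({a}, {b}) cannot be planted")
            if not (is_valid_cui(a) and is_valid_cui(b)):
                raise ValueError(f"malformed CUI in planted pair ({a}, {b})")
            if _is_noise_cui(a) or _is_noise_cui(b):
                raise ValueError(
                    f"planted pair ({a}, {b}) uses the reserved noise range "
                    f"{NOISE_CUI_PREFIX}*"
                )
            if count < 1:
                raise ValueError(f"planted count for ({a}, {b}) must be >= 1")
            key = (a, b) if a < b else (b, a)
            if key in norm:
                raise ValueError(f"pair ({a}, {b}) planted twice")
            norm[key] = count
        object.__setattr__(self, "pair_counts", norm)
        if self.noise_vocab_size < 0 or self.noise_documents < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.noise_documents > 0 and self.noise_vocab_size < 1:
            raise ValueError("noise documents require noise_vocab_size >= 1")
        if self.noise_doc_length < 1:
            raise ValueError("noise_doc_length must be >= 1")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


def generate_corpus(spec: PlantSpec) -> Corpus:
    """Generate a corpus whose windowed counts equal ``spec.pair_counts``.

    Each planted pair (x, y) with target count k yields k two-token
    documents ``[x, y]``.  Noise documents contain only reserved-range
    concepts.  Document order is shuffled deterministically by the seed;
    identical spec and seed give a token-identical corpus.
    """
    rng = random.Random(spec.seed)
    streams: list[list[str]] = []
    for (a, b) in sorted(spec.pair_counts):
        streams.extend([a, b] for _ in range(spec.pair_counts[(a, b)]))
    noise_vocab = [f"C9{i:06d}" for i in range(spec.noise_vocab_size)]
    for _ in range(spec.noise_documents):
        streams.append(rng.choices(noise_vocab, k=spec.noise_doc_length))
    rng.shuffle(streams)
    width = max(6, len(str(max(len(streams), 1))))
    documents = tuple(
        Document.from_cuis(f"d{i:0{width}d}", cuis) for i, cuis in enumerate(streams)
    )
    return Corpus(documents)


class PlantedScenario(NamedTuple):
    """A generated open-discovery test case with its query and vocabulary."""

    corpus: Corpus
    query: DiscoveryQuery
    vocab: Vocabulary
    a_term: str
    b_terms: tuple[str, ...]
    c_terms: tuple[str, ...]


def plant_abc_scenario(
    n_b: int,
    bc_profile: list[int],
    direct_ac: bool = False,
    seed: int = 0,
    window_size: int = 8,
) -> PlantedScenario:
    """Build a corpus where the correct discovery ranking is known by design.

    A designated start term co-occurs with ``n_b`` linker concepts; the i-th
    planted target shares ``bc_profile[i]`` of those linkers (each linker-
    target pair planted with count 2, so it survives the default edge
    filter).  Start-target documents are added only when ``direct_ac`` is
    true.  Targets are typed as diseases in the returned vocabulary, the
    start term included (so it can appear in its own ranked output).
    """
    if n_b < 0:
        raise ValueError("n_b must be >= 0")
    for k in bc_profile:
        if not (0 <= k <= n_b):
            raise ValueError(f"profile entry {k} exceeds the {n_b} available linkers")
    a_term = "C0000001"
    b_terms = tuple(f"C01{i:05d}" for i in range(n_b))
    c_terms = tuple(f"C02{i:05d}" for i in range(len(bc_profile)))

    pair_counts: dict[tuple[str, str], int] = {}
    for b in b_terms:
        pair_counts[(a_term, b)] = 2
    for c, k in zip(c_terms, bc_profile):
        for b in b_terms[:k]:
            pair_counts[(b, c)] = 2
        if direct_ac:
            pair_counts[(a_term, c)] = 1
    spec = PlantSpec(pair_counts, window_size=window_size, seed=seed)
    corpus = generate_corpus(spec)

    from .corpus import VocabEntry

    entries = {a_term: VocabEntry(a_term, "Start term", frozenset({DISEASE_TYPE}), "DISO")}
    for i, b in enumerate(b_terms):
        entries[b] = VocabEntry(b, f"Linker {i}", frozenset({"T109"}), "CHEM")
    for i, c in enumerate(c_terms):
        entries[c] = VocabEntry(c, f"Target {i}", frozenset({DISEASE_TYPE}), "DISO")
    vocab = Vocabulary(entries)
    query = DiscoveryQuery(a_term=a_term, b_restriction=frozenset(b_terms))
    return PlantedScenario(corpus, query, vocab, a_term, b_terms, c_terms)


def recount(corpus: Corpus, spec: PlantSpec) -> CooccurrenceMatrix:
    """Recount a generated corpus at the spec's window (convenience wrapper)."""
    return count_cooccurrences(corpus, spec.window_size)


def _fixture_path(name: str):
    return resources.files("abclbd.fixtures").joinpath(name)


def fixture_vocabulary() -> Vocabulary:
    """The packaged vocabulary: start term, 19 metabolites, 21 disease targets."""
    with resources.as_file(_fixture_path("vocabulary.tsv")) as p:
        return load_vocabulary(p)


def fixture_matrix() -> tuple[CooccurrenceMatrix, Vocabulary]:
    """The packaged worked-example matrix and vocabulary.

    The matrix carries start-metabolite edges (count 2) for the 17 linked
    metabolites, and the full printed metabolite breakdowns for the
    fish-eye-disease (15 edges) and Wiskott-Aldrich-syndrome (14 edges)
    targets.  The two metabolites with no recorded start-term co-occurrence
    are present in the vocabulary but have no start-term edge.
    """
    from .cooccurrence import read_matrix

    with resources.as_file(_fixture_path("cooccurrence.tsv")) as p:
        matrix = read_matrix(p)
    return matrix, fixture_vocabulary()


def fixture_query(**overrides) -> DiscoveryQuery:
    """The packaged worked-example query: metabolite-restricted disease discovery."""
    params = dict(
        a_term=FIXTURE_A_TERM,
        b_restriction=frozenset(FIXTURE_B_TERMS),
        c_semantic_types=frozenset({DISEASE_TYPE}),
        min_ab_count=1,
        min_bc_count=2,
        keep_direct=True,
    )
    params.update(overrides)
    return DiscoveryQuery(**params)


def fixture_ltc_distribution() -> dict[int, int]:
    """Packaged score distribution of the full-corpus run: LTC -> number of terms.

    These per-score tallies are inputs (the full corpus cannot be shipped);
    cumulative columns are recomputed from them by the report module.
    """
    dist: dict[int, int] = {}
    with resources.as_file(_fixture_path("ltc_distribution.tsv")) as p:
        for line in p.read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith(("#", "ltc")):
                continue
            score_str, n_str = line.split("\t")
            dist[int(score_str)] = int(n_str)
    return dist
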