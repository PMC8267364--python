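# Methods

## Model

`abclbd` implements open-mode ABC literature-based discovery: given a start
concept *A*, find target concepts *C* connected to *A* through shared
linking concepts *B*, where every A–B and B–C relationship is an explicit
windowed co-occurrence in a concept-annotated corpus and the A–C
relationship may be absent from the literature entirely. Targets are ranked
by the Linking Term Count (LTC), the number of distinct B concepts whose
A–B and B–C edges both survive filtering. LTC rewards breadth of
independent intermediate evidence; it deliberately ignores edge magnitudes,
which are instead shown to the reader in the per-target breakdown.

Assumptions inherited from the co-occurrence paradigm: concept mapping has
already collapsed synonyms onto single identifiers and removed
non-concept tokens; co-occurrence within a small window is a (noisy) proxy
for a semantic relationship; and a document — one title-plus-abstract
stream — is the natural unit within which proximity is meaningful.

## Counting

Two concepts co-occur when their token positions are within `window_size`
of each other in the same document. Each unordered *position* pair (i, j)
with i < j and j − i ≤ w contributes exactly one count to its unordered
*concept* pair: this is equal to the symmetric sliding-window description
without double-counting each pair once per focus token. Consequences that
tests pin down:

- duplicate concepts count once per qualifying position pair
  (`[X, Y, X]` at w ≥ 2 gives count(X, Y) = 2);
- the diagonal is never stored — self co-occurrence has no role in A–B–C
  linking;
- windows ignore sentence boundaries but never cross documents;
- counts are monotone non-decreasing in window size.

Default `window_size = 8` token positions, the average concept-stream
length of a sentence in concept-mapped MEDLINE and a width previous
relatedness work found to balance noise against missed associations.

The matrix is held as a plain pair-keyed integer map and serialized as a
flat TSV (two `#key=value` headers, then `cui_a TAB cui_b TAB count` with
pairs normalized and sorted), so equal matrices always produce
byte-identical files.

## Pipeline parameters

| parameter | default | meaning |
| --- | --- | --- |
| `min_ab_count` | 1 | A–B co-occurrences needed for B to count as a linker; any explicit co-occurrence constitutes a link |
| `min_bc_count` | 2 | B–C co-occurrences needed for an edge to survive; singleton co-occurrences are treated as noise |
| `c_semantic_types` | `{T047}` | semantic types a target must carry (Disease or Syndrome by default) |
| `keep_direct` | true | keep targets that directly co-occur with A |

The count filter is applied to B–C edges only; A–B linking needs just one
co-occurrence. Both thresholds are exposed because the boundary between
them is a judgement call: the shipped defaults keep a printed bc-count-2
edge alive while pruning singletons.

Concepts absent from the vocabulary are counted normally but cannot pass
the semantic-type filter (type membership is the filter's definition) and
render with preferred term `UNKNOWN` — mirroring real corpora where some
laboratory species simply have no concept mapping.

Directly co-occurring targets are *kept* by default, including the start
term itself, which therefore tops the ranking whenever every linker's A
edge survives the B–C filter — a useful sanity check, and the reason the
packaged fixture gives the start term LTC 17. Overly general targets
("disease, NOS"-type concepts) are not removed automatically; that
remains a manual review step, as automating it would require a concept
hierarchy the pipeline does not consume.

Ties — between targets with equal LTC and between breakdown entries with
equal counts — are broken by ascending CUI. Frequency ranking itself gives
no order among equals; a deterministic tie-break makes runs reproducible
at the cost of an ordering the underlying scores do not justify.

## Synthetic corpora

The real corpus this pipeline is aimed at (tens of millions of
concept-mapped citations) is licensed and far too large to ship, so
testing rests on two stand-ins:

- **Planted corpora.** `PlantSpec` requests exact pair counts; the
  generator emits, for each pair with target k, k two-token documents
  `[x, y]`. A two-token document realizes exactly one co-occurrence under
  any window ≥ 1 and cannot create any other pair, so recounting recovers
  the request *exactly*, for every seed — the seed only shuffles document
  order and samples noise documents, which are drawn from a reserved
  identifier range (`C9…`) disjoint from plantable concepts.
  `plant_abc_scenario` builds full discovery test cases (linker bank,
  per-target linker-sharing profiles, optional direct A–C documents) whose
  correct ranking is known by construction; all planted edges use count 2
  so they sit exactly at the default filter boundary.
- **The packaged fixture.** A flat matrix plus vocabulary encoding a
  published worked example: 17 of 19 candidate metabolites linked to the
  cardiac-arrest start term, and the full printed per-metabolite
  breakdowns for the fish-eye-disease (15 edges, 503 down to 3) and
  Wiskott-Aldrich-syndrome (14 edges) targets. The source material prints
  B–C counts but not A–B counts; the fixture sets every A–B edge to 2 so
  each linker also carries the start term past the default `min_bc_count`
  filter, which is what puts the start term at the top of the ranking with
  a score equal to the linker count. Also packaged: the published
  full-corpus LTC score distribution (55,376-disease universe) as
  per-score tallies, from which the report module recomputes the
  cumulative columns (21 terms at LTC ≥ 10; 3,122 at LTC ≥ 1).

What passing tests on these corpora do **not** show: planted two-token
documents have none of real text's burstiness, skewed concept frequencies,
or window-interior structure, so they validate the counting and ranking
*arithmetic*, not retrieval quality on real literature; and fixture-derived
scores are only as good as the printed edge lists they encode.

## Numerical and degenerate-input choices

- Empty corpus → empty matrix; empty candidate set → empty result; a
  result with no hypotheses renders as empty text and a histogram with
  only the zero row.
- A start term missing from the vocabulary is a warning, not an error
  (exploratory queries should degrade, not crash); an unknown start term
  with no matrix neighbours yields an empty result and exit status 0 from
  the CLI.
- The LTC histogram's zero row needs a universe size (targets that pass
  the semantic filter but share no linker never appear in a result); in
  CLI runs the universe is the count of vocabulary concepts carrying a
  queried semantic type. A universe smaller than the number of scored
  terms is rejected.
- Duplicate document identifiers, duplicate vocabulary CUIs, duplicate
  matrix pairs (in either order), counts below 1 and diagonal pairs are
  hard errors in strict and lenient modes alike; lenient corpus reading
  drops only malformed *tokens*, and reports the kept/dropped tally so
  the two always sum to the file's token count.
- All randomness (noise sampling, document shuffling) flows through the
  explicit `PlantSpec.seed`; there is no hidden global random state.

## Problem sizes

Tests and the acceptance script run on deliberately small inputs: random
corpora of up to ~10 documents × 30 tokens for oracle comparisons (the
brute-force oracle is quadratic), planted corpora of ≤ ~600 documents, and
the packaged 46-pair fixture. The counting core is a single pass with an
O(w) inner loop per token, so scaling to larger corpora is linear in token
count; corpus-scale streaming optimizations are out of scope.

## Known limitations

- Open discovery only: no closed-discovery mode (fixed C), no relation-type
  filters, no indirect association measures beyond LTC.
- One CUI per token: many-to-one concept mappings must be resolved
  upstream.
- No automatic general-term suppression; top-ranked lists need manual
  review.
- Sentence structure is not represented, so window widths calibrated in
  sentence-length units are approximations.
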