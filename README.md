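# abclbd

Open literature-based discovery (LBD) over concept-annotated text, using the
ABC co-occurrence model with Linking-Term-Count ranking.

## The problem

A biomedical researcher has a concept of interest *A* (say, cardiac arrest)
and wants disease candidates *C* that the literature connects to *A* only
*indirectly* — through shared intermediate concepts *B* (say, metabolites
found dysregulated in patient plasma). Two papers may separately report
"A co-occurs with B" and "B co-occurs with C" while no paper ever connects
A and C: that gap is a hypothesis worth generating. `abclbd` implements
this pipeline for corpora that have already been mapped to UMLS-style
Concept Unique Identifiers (CUIs), as concept-mapped MEDLINE is.

## The method

1. **Co-occurrence counting.** Two concepts co-occur when they appear within
   a symmetric window of *w* token positions (default *w* = 8, the average
   concept-stream length of a sentence in concept-mapped MEDLINE) inside the
   same document; sentence boundaries are ignored, document boundaries are
   not. Counts are stored as a symmetric sparse pair map and serialized as a
   deterministic flat TSV.
2. **Term linking.** Every concept co-occurring with the start term *A*
   (optionally restricted to a candidate list, e.g. experimentally
   implicated metabolites) becomes a linking term *B*.
3. **Term filtering.** B–C edges with fewer than `min_bc_count`
   co-occurrences (default 2) are dropped as noise; targets are restricted
   to chosen semantic types (default `T047`, Disease or Syndrome). Targets
   that directly co-occur with *A* are kept by default — known links help
   the reader trust the ranking.
4. **Term ranking.** Each surviving target *C* is scored by its
   **Linking Term Count**: `LTC(C) = |{B : A–B and B–C links survive}|`.
   Ties are broken by ascending CUI for reproducibility.

## Worked example

The package ships a small fixture encoding a published metabolomics use
case: start term C0018790 (cardiac arrest), 19 candidate metabolite linkers,
and the full linker breakdowns for the two most interesting targets.

```python
from abclbd import AbcDiscovery, fixture_matrix, fixture_query

matrix, vocab = fixture_matrix()
result = AbcDiscovery(matrix, vocab).fit(fixture_query())
print(result.summary(max_terms=2))
```

prints (first block truncated here):

```
ABC discovery from Cardiac arrest (C0018790)
linked B terms: 17 (excluded: 2); ranked targets: 3

17 - C0018790 - Cardiac arrest
	2	C0003765	Arginine
	...
15 - C0342895 - Disease, fish-eye
	503	C0556150	Docosahexaenoic acid
	481	C0008405	Choline
	...
	3	C2348386	Eicosadienoic acid
```

Reading the output: 17 of the 19 candidate metabolites co-occur with
cardiac arrest (the two excluded ones — docosadienoic acid and
oleoylcarnitine — have no recorded co-occurrence and are themselves a
finding). The start term tops its own ranking with LTC 17, a sanity check.
Fish-eye disease (partial LCAT deficiency) scores LTC 15: fifteen distinct
metabolites connect it to cardiac arrest, led by docosahexaenoic acid with
503 co-occurrences — the indirect A–B–C chain that motivated investigating
LCAT as a drug target. Wiskott-Aldrich syndrome follows at LTC 14.

The same flow is available from the shell:

```sh
abclbd build-cooc corpus.tsv matrix.tsv --window 8
abclbd discover matrix.tsv vocab.tsv query.yaml out/   # report + histogram + threshold TSVs
abclbd simulate plant.yaml corpus.tsv                  # synthetic corpus with planted counts
```

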