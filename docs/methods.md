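# Methods

This note documents the statistical and algorithmic choices behind
`metamine`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate.

## Corpus model and sentence segmentation

The unit of analysis is the sentence of a PubMed abstract record (MEDLINE
flat file, tags `PMID`/`TI`/`AB`). Titles are treated as one additional
sentence preceding the abstract's sentences: a gene named in a title is
plainly part of the record, and nothing in the counting semantics
distinguishes the two. This is an assumption — title mining can be disabled
only by stripping `TI` fields upstream.

Sentence segmentation is rule-based: a boundary is a run of `. ? !`
followed by whitespace and an uppercase letter or digit, suppressed when
the preceding text ends with an entry of an editable abbreviation list
(`et al.`, `Fig.`, `e.g.`, `i.e.`, `vs.`, ...). A rule-based splitter was
chosen over a trained model because it is deterministic, auditable and
sufficient for abstract prose; its failure modes (unusual abbreviations,
sentence-initial lowercase) merely shift sentence boundaries and therefore
perturb counts by at most the affected sentences.

## Gene recognition and normalization

Statistical NER taggers recover surface forms that still have to be mapped
to gene symbols by hand. Here the lexicon *is* the vocabulary: recognition
is dictionary matching over all aliases, and normalization to the canonical
symbol is immediate. Matching rules:

* word boundaries are the text edges or any character that is neither
  alphanumeric nor `-` (so `E-cadherin` is one token, and `MMP2` inside
  `MMP2-positive` is not a standalone match);
* aliases of ≥ 4 characters match case-insensitively; shorter aliases match
  case-sensitively. This is a standard precision guard for symbols that
  collide with English words (`MET`, `FAK` vs "met");
* overlapping candidates resolve leftmost-longest;
* ambiguous aliases (one string claimed by two genes after case folding)
  are rejected at lexicon load — disambiguation is explicitly out of scope.

The shipped `demo_lexicon.tsv` is illustrative, not authoritative: real
analyses should supply a curated Entrez-derived lexicon.

## Counting semantics

One rule everywhere: **a gene (or a gene–phenotype pair) contributes at
most once per sentence**, however many times its tokens repeat. The
frequency of a gene is therefore its number of supporting sentences across
the corpus, and a co-occurrence count is bounded by both the gene's and the
phenotype's sentence support. Whether published "counts" in this style of
analysis are mention-level or sentence-level is generally ambiguous; a
single semantics keeps frequencies and co-occurrences directly comparable.

Phenotype keywords match case-insensitively as exact whole words:
"invasion" does not match "invasive". Morphological variants can be added
as surface forms in the phenotype lexicon (2-column TSV). "metastasis" is
in the default lexicon but excluded from the four-phenotype bipartite and
clustering views, because it is the retrieval topic of the corpus rather
than a cascade step, and negation is deliberately ignored ("did not affect
invasion" counts) — this is a pure co-occurrence method.

## Cross-corpus normalization and partitioning

Two etiology arms of different sizes are compared by (i) dropping genes
with frequency < 5 (default), (ii) partitioning gene sets into
shared/A-only/B-only, and (iii) scaling the smaller arm's frequencies by
the paper-count ratio larger/smaller, reported rounded to three decimals
(262/136 → 1.926) while full precision is used internally.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail; it is the
standard replacement for legacy web tools whose internal statistics are
unavailable. Filtering uses the raw p ≤ α (default 0.05) to match common
practice in this literature; Benjamini–Hochberg adjusted values are
computed across all sets of the collection (via
`scipy.stats.false_discovery_control`) and reported alongside rather than
filtered on, so multiplicity is visible without silently changing the gene
lists. The universe defaults to the union of set members, or — in the
pipeline — to the lexicon's symbols present in the collection: enrichment
must be judged relative to the minable vocabulary.

The calibration test draws null queries of 500 from a universe of 5,000
against sets of 50–400 members. These sizes make the discrete
hypergeometric p-value nearly continuous; with small sets the test is
conservative (P(p ≤ 0.05) can sit well below 0.05 purely from
discreteness), which would be a property of the configuration, not a defect
of the statistic.

## PPI network

Interaction data enter as a pre-exported TSV (interactorA, interactorB,
source, evidence); only rows tagged `experimental` survive, duplicate
unordered pairs collapse, and multiple sources supporting one pair count as
one edge, because degree is defined as the number of *distinct* interaction
partners. The analysis network is induced on the query genes (neighbours
outside the query are excluded), with self-loops and isolates removed. Only
degree centrality is computed. Note that ubiquitin-family proteins acquire
extreme degrees in experimental interaction data for biochemical rather
than regulatory reasons; no correction is applied.

## Clustering

"Linear normalization" is per-row min–max scaling (x − min)/(max − min),
with constant rows mapped to zeros; a global min–max mode is available.
Per-row is the default because it makes genes of very different overall
frequency comparable across a heatmap row.

Complete ("maximum") linkage on Euclidean distance is implemented directly
with the Lance–Williams max-update, rather than calling a library routine,
because the merge order under tied distances is part of the output
contract: ties are broken by the smallest pair of lowest original row
indices, and within each merge the subtree containing the lower original
index is placed left. This makes dendrograms and heatmap row orders exactly
reproducible. The implementation is cross-checked in the test suite against
`scipy.cluster.hierarchy.linkage` (identical cophenetic distances on
distinct-distance inputs) and against a literal O(n³) re-maximisation
oracle (identical merge sequences, including ties). Complete linkage is
monotone, so merge heights never decrease; this is asserted on every tree.
Columns (the four phenotypes) are never clustered.

## Synthetic data

The generators emulate the *structure* the pipeline consumes — abstracts
whose sentences embed gene aliases and phenotype words at configured rates
— not natural language. Default demo conditions: 200 abstracts of 3–8
sentences (≈ 1,100 sentences), 20 genes with 2 synthetic aliases each,
background gene-mention and phenotype rates of 0.01 per sentence, and four
planted genes tied to ≥ 2 phenotypes at per-sentence joint rates of
0.03–0.04. Over ≈ 1,100 sentences a planted pair expects ≈ 35 counts
(far above the multi-phenotype threshold of 7) while a background
gene–phenotype pair expects ≈ 1, so planted and background signal are
separated by an order of magnitude and exact recovery of the planted set is
the expected outcome, not a coin flip. Ground truth is tallied during
generation from the same per-sentence token sets that produce the text, so
truth and corpus agree by construction under the once-per-sentence rule —
which is precisely what makes truth an independent oracle for the mining
path. Sentence templates avoid the splitter's abbreviation list, keeping
ground-truth sentence counts unambiguous.

What passing these tests shows: the parsing–NER–counting chain is exact on
text whose token placement is known. What it does not show: robustness to
real abstract prose (unusual punctuation, alias ambiguity, morphological
phenotype variants, negated statements), which the rule set handles by
explicit, documented convention rather than by learning.

## Pipeline and determinism

All thresholds live in one YAML config (defaults: min_freq 5,
co-occurrence min_freq 7, min_phenotypes 2, α 0.05, top-N 20). Every stage
is a pure function of inputs + config; reruns produce byte-identical
TSV/JSON artifacts, and the run manifest records versions, seed, thresholds
and per-stage counts. A stage failure aborts the run but still writes a
partial manifest naming the failed stage.

## Problem sizes

The test suite and the acceptance script use corpora of 200 abstracts,
oracle sweeps of 100–150 small instances, 20 recovery seeds and 1,000
calibration replicates; these sizes give stable rates and complete in a few
seconds on one CPU while exercising every code path at the same rates per
sentence as larger corpora would.

## Known limitations

* No alias disambiguation, species resolution or statistical NER.
* Co-occurrence is symmetric and negation-blind; it measures discussion,
  not causation or direction.
* Enrichment ignores pathway topology and gene multiplicity within sets.
* Only degree centrality; no betweenness/closeness or module detection.
* MEDLINE flat file only (no PubMed XML, no live Entrez retrieval).
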