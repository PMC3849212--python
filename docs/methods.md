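# Methods

## Evidence model

An *evidence instance* is one literature-derived link between an age
mention, a 1–3-sentence snippet, and at least one disease/phenotype
concept. Instances lacking either an age or a phenotype are never stored;
one instance is produced per (abstract, age-bearing sentence) pair, so an
abstract discussing two ages yields two instances. The store is three TSV
tables — evidence, evidence-age, evidence-phenotype — with referential
integrity checked on read and write. Plain TSV was chosen over a relational
engine because the schema, not the storage, is the content; the tables load
directly into pandas and round-trip byte-identically.

## Age grammar

Ages are recognized by a small regular-expression grammar covering point
ages ("6-week-old", "aged 6 weeks", "at 3 months of age"), explicit ranges
("12–15 months", "6 to 8 weeks"), and open-ended relational expressions
("under age 30", "older than 12 months"). All values are normalized to days
with fixed conversions **day = 1, week = 7, month = 30, year = 365**; these
round constants are recorded in output metadata and keep the worked
arithmetic stable. A bare "age N" with no unit is read as days, which suits
a mouse corpus. Relational expressions are flagged `inferred`: "under N"
is stored as the range [0, N], "over N" with both bounds at N (the upper
bound is unknown). Inferred mentions remain queryable evidence but are
excluded from the quantitative matrices, since placing an open-ended range
in a bin would be arbitrary. Gestational/embryonic ages (E14.5) are not
captured. Overlapping grammar matches resolve longest-first.

Sentence boundaries are deterministic: split at `[.?!]` followed by
whitespace and a capital/digit, with a small abbreviation stoplist (e.g.,
i.e., vs., fig., et al.). The snippet is the mention's sentence plus one
neighbour on each side — a symmetric, testable reading of "usually 1–3
sentences".

## Lexicon and matching

The disease lexicon is compiled from an OBO 1.2 ontology (names and exact
synonyms of non-obsolete terms, lower-cased) plus an optional two-column
concept/synonym term list standing in for licence-restricted vocabularies.
Matching is case-insensitive, token-boundary, longest-match-wins; shorter
matches overlapping a longer one are suppressed, and duplicate concept hits
collapse to one per snippet. Synonym collisions across concepts resolve to
the first concept in file order and are logged. Strain assignment takes the
first (leftmost, then longest) match from a strain list; gender is assigned
only when exactly one of the male/female term classes occurs in the
snippet. Snippets naming a blocklisted organism (default: rat(s), human(s),
patient(s), zebrafish, drosophila) are discarded — the corpus is mouse
literature and cross-species sentences would contaminate the mouse axis.

## Matrices

The mouse matrix counts contributions per disease per 1-day bin over
0..1028 days; the human matrix per 1-year bin over 0..120 years. Each
non-inferred age row of a stored instance contributes +1 per distinct
linked concept at its point-age bin, or at the floor-midpoint of an
explicit range (`range_policy="start"` is available for sensitivity
analysis). Ages beyond the axis are dropped and logged. Rows are normalized
to frequencies by the disease's total count so literature volume does not
dominate; a minimum-instance filter (default 5 for clustering) removes
sparsely evidenced diseases before analysis. The 1028-day mouse axis is the
span over which a full-length shift scan is meaningful; day-resolution can
be rebinned to weeks, and rebinning commutes with normalization.

## Shift estimation

For each disease in both matrices, Pearson correlation is computed between
the human vector and the mouse vector at every shift s = 0..1028, aligning
human bin y with mouse bin y + s (one human year bin against one mouse day
bin — the scale implied by the worked conversions). A shift is skipped when
the aligned window is under `min_overlap = 10` bins or either window has
zero variance. The best shift maximizes **r itself**, with ties broken
toward the smaller (more conservative) shift, and acceptance requires
r² > 0.5 **and r > 0**: a pure r² criterion would admit strong
anti-correlation, which is meaningless for an age map. A strict
`score="r2"` compatibility mode maximizes |r| instead. Because Pearson is
affine-invariant, raw and normalized rows give identical shifts. Accepted
diseases form the age map; conversions are the additive identities
`human_years = mouse_days - shift` and `mouse_days = human_years + shift`,
exact inverses with unit slope, with mouse ages below the shift rejected as
out of domain.

## Clustering

Disease rows are compared by d = 1 − r (anti-correlated patterns are
maximally distant — deliberately not 1 − |r|), and clustered
agglomeratively via scipy. Average linkage is the default (the legacy
clustering tool's defaults are not reproducible, so the linkage is a
flag), zero-variance rows are removed, and the dendrogram exports to
Newick with branch lengths equal to merge-height differences (labels with
reserved characters quoted).

## Synthetic data

The generator defines the study conditions and carries its own ground
truth. A disease spec is (concept id, name, synonyms, a Gaussian-mixture
age model on the human year index, an instance count, a planted shift, and
a related/unrelated flag).

* **Ontology**: one OBO term per spec; round-trips through the lexicon.
* **Corpus**: MEDLINE-format abstracts from ~10 sentence frames, each
  embedding one grammar-covered age phrase (unit chosen among clean
  divisors of the sampled day age; 20% explicit ranges) and one disease
  surface form; mouse ages are drawn at (model mean + shift) days.
  Distractors cycle age-only / disease-only / neither, and optional
  "blocked" abstracts put the age and disease in a sentence about rats.
  Gold annotations (age-relatedness, day-normalized ages, concept ids,
  gender, strain) are exact by construction. The default panel uses 12
  instances per disease with ~30 distractors; the mining-fidelity check
  uses 5 diseases × 30 instances + 60 distractors (≥200 abstracts).
* **Matrix pairs**: the human row is the mixture density on the year axis;
  the mouse row is the same curve placed `shift` bins later on the day axis
  (unrelated diseases get an independent uniform-noise row). Per-cell
  multiplicative gamma noise with mean 1 and a chosen coefficient of
  variation is applied before normalization.

Everything is a pure function of (specs, parameters, seed). What passing
tests show is that the estimator and miner are correct under these
conditions; templates do not emulate real PubMed linguistic diversity, real
corpora are noisier in both language and age usage, and real cross-species
patterns need not be a clean additive shift, so perfect recovery here does
not promise the same on mined literature.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| mouse axis / resolution | 0–1028 d / 1 d | day-level mouse ages; full shift scan |
| human axis / resolution | 0–120 y / 1 y | year-level human ages |
| max_shift | 1028 d | human vector slid its entire length |
| r2_threshold | 0.5 | acceptance: r² > 0.5 (and r > 0) |
| min_overlap | 10 bins | smallest window for a defined correlation |
| min_instances | 5 | disease inclusion filter for clustering |
| range_policy | midpoint | bin for explicit age ranges |
| linkage | average | clustering linkage (flaggable) |
| noise_cv (generator) | 0.0–0.3 | per-cell multiplicative noise level |

## Numerical notes and limitations

Correlations are computed with centred dot products and clipped to
[−1, 1]; equal-score shifts keep the smallest s deterministically; matrix
row order does not affect clustering merges beyond leaf-order ambiguity.
The replicate studies in the acceptance tests use 200 (shift robustness)
and 100 (clustering robustness) seeded replicates on single-disease and
8-disease panels respectively — sizes at which the binomial pass criteria
are well resolved. Known limitations: abstracts only (no full text), no
machine-learned NER, no nonlinear or piecewise age warping, no smoothing
of patterns before correlation, and corpus-dependent headline counts from
a mined 2012 literature snapshot are not reproducible here — the pipeline
instead verifies the analogous manifest counts against generator truth.
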