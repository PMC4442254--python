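# Methods

This note documents the conventions, models and design choices behind
`treatkit`: what each stage assumes, which knobs matter, and what the
synthetic corpora do and do not establish about real marked-up
literature.

## Domain model and validation

A corpus is a list of articles; an article holds ordered authors,
journal, publication year (validated to [1750, 2100]) and treatments; a
treatment holds a rank-keyed taxon name, status flags and materials
citations.  A citation's specimen counts live in a `CountTriple`
(males, females, other, total) whose constructor enforces
`total = males + females + other`, so the conservation laws downstream
cannot be broken by construction.

Validation is a separate pass returning findings (severity, record id,
message) rather than raising: legacy data should load first and be
audited afterwards.  Unknown type-status and treatment-status tokens
are preserved verbatim and reported, never coerced — auditability of
legacy text beats tidiness.  The type-status vocabulary is the
seven-member set holotype/paratype/syntype/lectotype/neotype/allotype/
none; "primary types" are the four name-bearing ones (holotype,
syntype, lectotype, neotype).

A "species-rank treatment" means `rank = species`; species-group and
higher treatments are "higher treatments" throughout.

## Field normalization

**Sex field.**  Tokens `<int> <classword>` separated by commas,
semicolons or "and"; class words (case-insensitive, optional plural and
trailing period) are male/♂, female/♀, and
juvenile/juv/imm/immature/subadult/other for the "other" class; a bare
class word counts 1.  Unrecognized tokens are surfaced in
`unparsed_tokens` rather than guessed.

**Count reconciliation.**  With a stated sex sum *s* and an independent
`individualCount` *n*: absent *n* gives total *s*; *n ≥ s* gives total
*n* with the surplus added to "other" (unsexed material); *n < s*
keeps the larger stated sum and attaches a warning — a stated count of
sexed specimens cannot shrink.  Consequently `total ≥ males + females`
and `other ≥ 0` always.

**Collectors.**  Split on `&`, `and`, commas and semicolons, trimming
whitespace only.  Order is preserved and no name matching is attempted:
"A & B" and "B & A" stay distinct teams, because initials-matching and
person disambiguation are unsolved for this data and silently merging
would fabricate attributions.

**Dates.**  A closed grammar: ISO at year/month/day precision,
`DD.MM.YYYY`, `D Month YYYY`, and day ranges (start date used).
Anything else yields no date plus a finding.  Decades are
`floor(year/10)·10`, labelled "1990s".

**Elevation.**  500 m bands, upper-inclusive: `(k·500, (k+1)·500]`,
labelled `"1,001–1,500"`; 0 m maps to the lowest band; values outside
[0, 9000] m are rejected.  An elevation given as a range in source text
should be binned by its midpoint.

## Faceted aggregation

Filters are conjunctions of `key=value` clauses over a fixed 16-key
vocabulary (`doc.*`, `tax.*`, `mat.*`).  Document clauses select
articles — `doc.author` matches the lead author by default, because an
author dashboard should reflect authored works, not every contributed
page; `author_scope="any"` is available.  Taxon clauses select
treatments, `mat.*` clauses select individual citations; records
emptied by lower-level clauses are dropped, and the empty query is the
identity.  Filtering composes: filtering by A then B equals filtering
by A∧B.

Aggregation portions three measures by one facet.  The **specimens**
column assigns each citation's total to exactly one label, so the
column (with its `missing` row) always sums to the filtered corpus
total.  A citation with zero or several collection codes contributes
its specimens to `missing` — with several listed depositories and one
event-level count, the per-institution split is unknowable — while the
**treatments**/**articles** columns count distinct treatments/articles
with at least one qualifying citation, and such an ambiguous citation
marks presence in *each* listed code.  Rows with a zero value in the
selected measure are dropped; the rest sort by that measure descending,
ties broken lexicographically for determinism.  A genuine facet value
equal to `missing` is escaped to `"missing"` (quoted) on output.

Collector attribution offers three modes: `raw` (verbatim team
strings), `fractional` (each member of a team of *k* gets total/*k*;
conserves the corpus total to 1e−9), and `full_credit` (each member
gets the full total; may exceed the corpus total by design).

Zero-citation treatments (common in faunistic checklists) never appear
in facet tables — aggregation is citation-driven — but are counted by
the corpus summary.

## Dashboard

The canonical page has 16 charts covering sex composition, month×sex
phenology (12 month columns plus `missing` for coarser-dated lots),
decade, elevation bands, collections (specimens, treatments and
primary-type specimens), countries, collectors, families, statuses,
publication years and treatments per article.  Charts are views of
facet tables, never recomputations, so their totals agree with the
engine by construction.  `extra_charts` hooks in custom charts; JSON
output has a fixed key order and is byte-stable.

## Corpus statistics

Summary ratios are exact quotients of integer counts, displayed at one
decimal.  Sex percentages are computed over species-treatment
specimens.  Rarity takes new-species treatments as denominator:
singleton = one specimen in total; unique = one distinct collection
event, with event identity the tuple (normalized locality text, event
date, verbatim collector); single-locality = one distinct locality
text.  Because faunistic corpora describe almost nothing new, the
singleton share among all specimen-citing species treatments is
reported alongside.  Note singletons and uniques are independent
definitions; neither count bounds the other.

Description lag is publication year minus the earliest cited collection
year, at year precision (legacy dates are often year-only); species
with no dated citations — or only dates after publication, which would
imply a negative lag — are excluded and counted.  The standard error is
the sample (n−1) standard deviation over √n.

## Synthetic corpora

The generator emulates the two corpus shapes found in marked-up spider
literature: a legacy-journal profile (few articles, ~7 treatments each,
~22.5 specimens per species treatment, ~43% new species) and a
prospective-journal profile (few articles with hundreds of faunistic
treatments, ~5 specimens per species treatment, many zero-citation
treatments).  Defaults follow those observed conditions: sex split
(0.515, 0.407, 0.078), ~17% of lots without a depository, ~5%
ambiguous multi-collection lots, ~79% without elevation, ~60% without
specimen codes, teams on ~30% of collector strings, publication years
2002–2014, and a geometric collection-to-description lag with mean 17
years.

Two mechanisms make the generator a test instrument rather than a demo:

* **Exact totals** pin corpus-level counts (articles, treatments,
  species treatments, citing treatments, specimens, new species,
  singletons, single-locality species, sex totals, citations, coded
  citations).  Designations are satisfied structurally — singletons get
  exactly one one-specimen citation, other citing treatments at least
  two specimens, non-single-locality new species at least two citations
  with two distinct (and forcibly present) locality texts — and
  infeasible combinations raise a config error rather than degrade.
  Everything not pinned still flows from the seed.
* **Ground truth** is computed by a second, independent counting path:
  plain nested loops over the finished corpus, sharing no code with the
  facet engine or stats module.  Tests assert exact equality between
  the two paths over many seeds, so a bug in either shows up as a
  mismatch.

One seeded `numpy` generator drives all randomness; identical configs
produce byte-identical XML.

**What passing tests show — and don't.**  Synthetic corpora draw field
values from small pools and clean grammars; they contain no OCR noise,
no free-text localities, no misspelled collector names, no
inconsistent secondary sources.  Green tests therefore establish the
correctness of the *accounting* — parsing rules, reconciliation,
aggregation, conservation, statistics — on well-formed input, not the
robustness of extraction from arbitrary legacy text, which is exactly
the part of the original workflow (OCR, markup editing) that is out of
scope here.  The real-corpus lag values (a mean near 17 years with
median 7) depend on the actual hosted documents and are not reproduced
at desk scale; the lag machinery is instead validated by parameter
recovery: with full date coverage the per-species lags equal the
generator's drawn values exactly, and pooled means match the configured
geometric mean within sampling error.

## Numerical and determinism choices

* Ties in facet rankings break lexicographically; JSON serialization
  fixes key order; the XML writer fixes attribute order and indent so
  output is byte-stable.
* Fractional attribution is compared to 1e−9; all other accounting is
  integer-exact.
* Degenerate inputs: an empty corpus summarizes to zeros with an
  undefined-means flag; an empty filtered dashboard page carries
  all-zero charts; zero new species flags rarity rates as undefined
  (NaN), never raising mid-pipeline.
* Problem sizes in the test suite (hundreds of small corpora of 2–6
  articles, plus the two full exact-totals profiles of 254 and 742
  treatments) keep the whole suite in a few seconds while still
  crossing every aggregation path; scale is in treatment counts, not in
  algorithmic depth, so small corpora exercise the same code as large
  ones.

## Known limitations

* No geocoding, gazetteer lookup, or person-name disambiguation; the
  collection-event identity tuple treats textual variants of one
  locality as distinct events.
* The XML dialect is original to this package (deliberately small and
  hand-writable); it is not TaxonX/TaxPub/NLM-DTD compliant, and the
  Darwin Core export is a flat occurrence CSV, not a Darwin Core
  Archive.
* Coordinates are not modelled; none of the supported charts use them.
* Per-collection specimen splits inside ambiguous multi-collection
  citations are unknowable from the data model and are reported as
  `missing` rather than imputed.
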