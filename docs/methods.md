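# Methods

## The screening model

The workflow treats search-term selection as a two-sample document-frequency
comparison. For a term *t*, let n_dev(t) be the number of development-set
records whose title or abstract contains *t* at least once, and n_pop(t) the
same count in a random sample of the target database. The screen keeps terms
with

* sens_dev(t) = n_dev(t)/N_dev ≥ 0.20 (the term characterizes the relevant
  records), and
* sens_pop(t) = n_pop(t)/N_pop ≤ 0.02 (the term is rare in the database at
  large).

Both comparisons are inclusive and both thresholds are configurable.
Frequencies are document frequencies, never occurrence counts: the published
frequency table of the canonical worked example reports sensitivities that
are exact multiples of 1/25, which forces per-record presence counting.
Sensitivities are stored as exact rationals (`fractions.Fraction`), so
`sens_dev * N_dev == n_dev` holds as an integer identity and threshold
comparisons at exactly 20%/2% are not perturbed by binary floating point
(thresholds given as floats are converted via their decimal string).

A term frequent in the development set but above the population threshold is
kept as a **near miss** rather than discarded: the reference workflow itself
promotes such a term ("cancer", 5% population sensitivity) into its candidate
list after manual relevance review, so the partition is
auto_pass / near_miss / excluded, and the category map is the instrument of
promotion. Terms named in the category map that did not pass the screen at
all enter as `manual_add` with their statistics computed on demand.

### Tokenization

Tokens are maximal runs of letters, casefolded; anything else (hyphens,
digits, parentheses) splits. Tokens shorter than 2 characters are dropped.
There is deliberately **no stemming and no stopword list**: the population
comparison is the filter ("patients", "results", "using" are all screened
out by their population frequency, not by a word list), and stemming would
blur distinctions the analyst may want ("treated" vs "treatment"). The exact
tokenizer of any particular analysis toolchain can differ in convention;
frequency tables are therefore reproducible up to tokenization convention,
which is why the minimum token length is a parameter.

### Controlled vocabulary

Heading assignments are aggregated before counting: the major-topic marker
`*` and any `/subheading` suffix are stripped and the heading casefolded, so
`*Brachytherapy/methods` and `Brachytherapy/adverse effects` both count the
heading "brachytherapy", once per record. No thesaurus hierarchy ships with
the package, so heading matching in the query engine is non-exploded by
construction.

## The query engine

The engine evaluates the restricted Ovid dialect that routine content
strategies use. Semantics:

* a text `Term` matches a record if some token of the selected fields equals
  it; a trailing `*` makes it an unbounded prefix pattern;
* `.ab,ti.` / `:ti,ab,kw` restrict matching to abstract, title, and (for
  `kw`) tokens of the controlled-vocabulary strings;
* `Heading/` matches on the aggregated heading;
* `and`/`or` are set intersection/union, with `and` binding tighter;
  `or/a-b` unions a line range, `and/m,n` intersects listed lines;
* `"id".ui.` lists match the accession field verbatim;
* line numbers must run consecutively from 1 (ranges are only well defined
  without gaps) and references may only point backwards.

Multi-token groups are not phrases: only explicit boolean operators combine
terms. `NOT`, `adjN`, frequency operators and mid-word wildcards are parse
errors, not silent approximations. The test suite checks the engine against
an independent naive evaluator that decides each line per record with plain
boolean logic.

## Strategy assembly

All categorized health-condition and intervention candidates enter their OR
blocks unconditionally (the reference workflow ORs the whole block rather
than minimizing it); the two blocks are ANDed. The manual trial-and-error
step is operationalized as deterministic greedy set cover over the
questionable terms: while development records remain uncovered, the
questionable term covering the most of them is added (ties broken by higher
development-set sensitivity, then alphabetically) to the block its user hint
assigns (default: intervention). A term whose match set adds nothing is never
added. This is an artifact design decision — the original step is manual and
subjective — but it preserves the two properties that matter: if the
candidate family covers the development set the loop terminates at
sensitivity 1.0, and the outcome is reproducible. An optional `minimize`
mode prunes lines whose removal leaves coverage intact, for precision
tuning; precision (and its reciprocal, the number needed to read) is
reported but never thresholded, because no acceptance level is defined for
it.

Rendering hints (`term_map`) let the analyst truncate (`prostate →
prostat*`) or fold several candidates into one composite line
(`(prostat* and (cancer or adenocarcinoma))`), reproducing the published
block layout; candidates mapping to the same rendering are emitted once.

## Splitting and validation

`split_test_set` draws the development set uniformly without replacement
after sorting the ids (so the draw depends only on the id set and the seed).
The development fraction is rounded to the nearest integer, half away from
zero: 38 ids at ratio 2/3 give the canonical 25/13 split, 3 ids give 2/1.
The seed is mandatory — a strategy validated this way is a "one-shot"
instrument, and the split must be auditable. Development/validation
disjointness is enforced when both id sets are supplied.

Validation appends an accession-list line for the held-out ids and a final
`AND` with the strategy's content line, mirroring the published validation
table: the appended line's count is the validation-set size and the final
line's count the number retrieved. The report's sensitivity always satisfies
sensitivity = 1 − |missed|/|validation|.

## The synthetic corpus generator

The generator emulates the statistical structure the screen assumes, not
language: each relevant record independently contains each topical term with
probability p_relevant (inserted at a random position of title or abstract)
and each heading with its p_relevant (subheading attached with probability
0.5, major-topic marker with 0.25); population records use p_background.
Remaining tokens are drawn from a Zipf(V = 2000, s = 1.4) background
vocabulary of synthetic alphabetic pseudo-words, with title and abstract
lengths Poisson(9) and Poisson(90). Every planted occurrence is recorded in
a truth structure.

The packaged scenario (`table2_scenario`) takes its planting probabilities
from the published frequency tables of the brachytherapy/prostate worked
example — e.g. the brachytherapy analogue at (0.76, 0.0006), prostate at
(0.96, 0.0068), "patients"-like ubiquitous words near (1.0, 0.2) — with
25 relevant and 7,180 population records by default. The population size is
the scale back-calculated from those tables (1419/0.1976 ≈ 7,180); it is a
documented inference about scale, not an asserted fact. Terms absent from
the published extract (adenocarcinoma, seed, permanent, implantation and the
questionable tier) carry probabilities chosen once to be realistic for their
roles: topical intervention terms at 0.36–0.48 relevant / ≤0.7% background,
questionable terms frequent enough to screen in but not needed for coverage.

`ensure_category_coverage` force-plants the category's most probable text
word into any relevant record the independent draws left without a
health-condition or intervention term. This encodes the method's working
assumption that the quasi-gold standard is reachable by topical terms; with
the flag off, non-coverage is a legitimate, reported outcome. The generator
config also carries the category map and rendering hints because they are
part of the study conditions, not tuning knobs.

**What passing on synthetic data does and does not show.** The generator
plants terms independently per record, has no phrases, synonymy, correlated
topics or indexing drift, and its background vocabulary is disjoint from the
topical terms. End-to-end recall of 1.0 on the scenario therefore
demonstrates that the pipeline's mechanics (counting, screening,
composition, evaluation, splitting) are correct under the method's own
assumptions — not that any real strategy will reach 100% sensitivity on a
real database, where relevant records may simply not contain any candidate
term.

## Numerical and interface choices

* All text comparison is casefolded; I/O never lowercases stored fields.
* MEDLINE parsing is delegated to `Bio.Medline`, with blocks pre-split so
  malformed records can be reported with their line numbers; the package
  writes the same dialect back, and round-trips preserve all four analyzed
  fields. RIS records without any id get the deterministic surrogate
  `ris:<ordinal>`.
* Frequency ranking ties are broken alphabetically; documentation-bundle
  output is deterministic (byte-identical given a fixed timestamp).
* Statistical property tests (split uniformity, planting frequencies) use
  exact binomial intervals with a Šidák correction across the simultaneous
  per-id/per-term checks, holding the family-wise false-alarm rate at 1%.
* Test and acceptance runs use the scenario sizes above (38/7,180, with a
  40-to-200-record population in the smallest unit tests); these are the
  package's canonical problem sizes for the worked example it models.

## Known limitations

* No MeSH hierarchy: `exp Heading/` is unsupported, and `kw` search sees
  controlled-vocabulary tokens rather than a database's separate keyword
  field.
* The engine is an offline evaluator; printed hit counts from live databases
  are version-dependent and not reproducible offline.
* Derivation of methodological study-design filters, and statistical
  assembly of strategies (logistic regression, factor analysis), are out of
  scope; the engine can evaluate such filters but does not derive them.
* Phrase/adjacency searching is absent, so strategies relying on `adjN`
  cannot be expressed.
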