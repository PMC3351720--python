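# osd — objectively derived search strategy development

`osd` implements the empirically guided ("objectively derived") workflow for
developing and validating the content part of systematic-review search
strategies, as practiced in health-technology-assessment information
retrieval. It is aimed at information specialists and methods researchers who
want search strategies that are derived from data and validated against a
held-out reference standard, rather than assembled purely from subject
knowledge.

## The method

1. **Test set (quasi-gold standard).** Relevant references are extracted from
   existing systematic reviews on the topic and split at random: two-thirds
   form the *development set*, one-third is held out as the *validation set*
   (38 references split 25/13 in the canonical worked example).
2. **Term screening.** For every text word *t* in the development set's
   titles and abstracts, the document-frequency sensitivities

   sens_dev(t) = n_dev(t) / N_dev    and    sens_pop(t) = n_pop(t) / N_pop

   are computed, where the population set is a large random sample of the
   target database (e.g. MEDLINE). Terms with sens_dev ≥ 0.20 and
   sens_pop ≤ 0.02 are *overrepresented*: frequent among relevant records but
   rare in the database. Controlled-vocabulary headings are aggregated over
   subheadings and major-topic markers before counting. Candidate terms are
   then assigned by the user to *health condition*, *intervention*, or
   *questionable* categories — topical relevance is never guessed by the tool.
3. **Strategy assembly.** Candidates become an Ovid-style numbered Boolean
   strategy: one OR block per category, ANDed together. If the blocks miss
   development records, questionable terms are added greedily (largest number
   of still-uncovered records first) until development-set sensitivity
   reaches 100%.
4. **Validation.** The finished strategy is run against the database sample
   and scored on the held-out validation set via its accession numbers;
   sensitivity = |retrieved ∩ validation| / |validation|.
5. **Documentation.** Frequency tables, candidate list, strategy, build log
   and validation report are written as a deterministic documentation bundle.

The package also contains a seeded synthetic-corpus generator that plants
topical terms with known per-record probabilities (and Zipf background
vocabulary), so the whole pipeline can be exercised and tested without any
database download.

## Worked example

```python
from osd import *

config = table2_scenario(n_relevant=38)          # packaged synthetic scenario
relevant, population, truth = generate(config, seed=1)

split = split_test_set(relevant.accessions, seed=1)
dev = relevant.subset(split.dev_ids, "development")

stats = term_stats(dev, population)              # the frequency table
screen = select_candidates(stats)                # 20% / 2% thresholds
candidates, _ = categorize(screen, config.screening_category_map(),
                           dev, population)
result = build(candidates, dev, term_map=config.term_renderings)
print(result.strategy.text())
print(f"development sensitivity: {float(result.dev_sensitivity):.0%}")

searchable = merge_dedupe([relevant, population], label="database")
report = validate(result.strategy, searchable, split.val_ids,
                  dev_ids=split.dev_ids)
print(f"validation sensitivity: {float(report.sensitivity):.0%}")
```

prints

```
1 prostatic neoplasms/
2 prostat*.ab,ti.
3 cancer.ab,ti.
4 adenocarcinoma.ab,ti.
5 or/1-4 [Health condition]
6 brachytherapy/
7 brachytherapy.ab,ti.
8 seed*.ab,ti.
9 permanent*.ab,ti.
10 implant*.ab,ti.
11 or/6-10 [Intervention]
12 and/5,11
development sensitivity: 100%
validation sensitivity: 100%
```

The 38-record test set was split 25/13; the two category blocks alone covered
every development record (no questionable terms were needed), and all 13
held-out validation records were retrieved — full recall on references the
strategy was not derived from.

The same steps are available from the shell: `osd generate`, `osd split`,
`osd analyze`, `osd candidates`, `osd build`, `osd evaluate`, `osd validate`,
`osd report` (see `osd --help`). Real reference files in PubMed `.nbib` or
RIS format are read the same way as generated ones.

## Scope

The engine evaluates the restricted Ovid dialect used in routine content
strategies (fielded text words with `*` truncation, non-exploded headings,
`or/a-b`, `and/m,n`, accession lists); `NOT`, adjacency operators and MeSH
explosion are out of scope, as are live database connections — evaluation
runs against local record collections.

See `docs/methods.md` for the model, parameter defaults and limitations.
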