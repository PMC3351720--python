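from __future__ import annotations

import pytest

from osd.corpus_io import Corpus, ReferenceRecord


def make_record(accession, title="", abstract="", cv=(), source="test"):
    return ReferenceRecord(
        accession=str(accession),
        title=title,
        abstract=abstract,
        cv_terms=tuple(cv),
        source=source,
    )


def make_corpus(specs, label="test"):
    """Corpus from (accession, title[, abstract[, cv_terms]]) tuples."""
    records = []
    for spec in specs:
        acc, title = spec[0], spec[1]
        abstract = spec[2] if len(spec) > 2 else ""
        cv = spec[3] if len(spec) > 3 else ()
        records.append(make_record(acc, title, abstract, cv))
    return Corpus(records, label=label)


@pytest.fixture
def three_record_corpus():
    """The brachytherapy/prostate toy corpus used for engine hand checks."""
    return make_corpus([
        ("r1", "Prostate cancer brachytherapy"),
        ("r2", "Prostate cancer"),
        ("r3", "Breast cancer"),
    ])
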