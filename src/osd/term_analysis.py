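"""Term frequency analysis and candidate-term screening.

The empirically guided approach compares how often each text word (and each
controlled-vocabulary heading) occurs in a small *development set* of known
relevant references against a large random *population sample* of the target
database.  Terms frequent among relevant records (sensitivity in the
development set >= 20% by default) but rare in the database at large
(sensitivity in the population set <= 2%) are "overrepresented" and become
candidate search terms.

All frequencies are **document frequencies**: a term is counted once per
record in which it appears, regardless of how many times it occurs inside
that record.  Sensitivities are exact rational numbers (``fractions.Fraction``)
so that ``sens_dev * n_dev == freq_dev`` holds as an integer identity.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import Corpus

__all__ = [
    "TEXT_WORD",
    "CONTROLLED_VOCABULARY",
    "CATEGORIES",
    "TermStats",
    "CandidateTerm",
    "ScreenResult",
    "tokenize",
    "record_tokens",
    "doc_frequencies",
    "term_stats",
    "normalize_heading",
    "cv_frequencies",
    "select_candidates",
    "categorize",
    "stats_to_frame",
    "cv_to_frame",
    "candidates_to_frame",
]

TEXT_WORD = "text_word"
CONTROLLED_VOCABULARY = "controlled_vocabulary"

#: The three relevance categories a candidate term may be assigned to.
CATEGORIES = ("health_condition", "intervention", "questionable")

_SCREEN_STATUSES = ("auto_pass", "near_miss", "manual_add")

# Runs of Unicode letters; digits and punctuation split tokens.
_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def tokenize(text: str, min_len: int = 2) -> list[str]:
    """Lowercase word tokens of *text*.

    Splits on every non-alphabetic character (hyphens, parentheses, digits,
    ...), drops tokens shorter than *min_len*, and applies no stemming and no
    stopword removal: the population-set comparison, not a stopword list, is
    what filters uninformative words.
    """
    return [t for t in _TOKEN_RE.findall(text.casefold()) if len(t) >= min_len]


def record_tokens(record, min_len: int = 2) -> set[str]:
    """Distinct tokens of a record's title and abstract."""
    return set(tokenize(record.title, min_len)) | set(tokenize(record.abstract, min_len))


@dataclass(frozen=True)
class TermStats:
    """Document frequencies and sensitivities of one term in two corpora.

    ``sens_dev = freq_dev / n_dev`` and ``sens_pop = freq_pop / n_pop`` are
    exact fractions of the stored integers.
    """

    term: str
    kind: str
    freq_dev: int
    freq_pop: int
    n_dev: int
    n_pop: int

    def __post_init__(self) -> None:
        if self.kind not in (TEXT_WORD, CONTROLLED_VOCABULARY):
            raise ValueError(f"unknown term kind: {self.kind!r}")
        if not (0 <= self.freq_dev <= self.n_dev):
            raise ValueError(f"{self.term!r}: freq_dev outside [0, n_dev]")
        if not (0 <= self.freq_pop <= self.n_pop):
            raise ValueError(f"{self.term!r}: freq_pop outside [0, n_pop]")

    @property
    def sens_dev(self) -> Fraction:
        return Fraction(self.freq_dev, self.n_dev)

    @property
    def sens_pop(self) -> Fraction:
        return Fraction(self.freq_pop, self.n_pop)


@dataclass(frozen=True)
class CandidateTerm:
    """A screened term with its relevance category.

    ``screen_status`` records how the term entered the candidate list:
    ``auto_pass`` (met both frequency thresholds), ``near_miss`` (frequent in
    the development set but above the population threshold; promoted by manual
    relevance review), or ``manual_add`` (named in the category map without
    passing the screen).
    """

    term: str
    kind: str
    category: str
    screen_status: str
    stats: TermStats | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if self.screen_status not in _SCREEN_STATUSES:
            raise ValueError(f"unknown screen_status: {self.screen_status!r}")


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def doc_frequencies(corpus: Corpus, min_len: int = 2) -> dict[str, int]:
    """Number of records of *corpus* containing each token at least once.

    Tokens are drawn from title and abstract jointly.  Raises ``ValueError``
    on an empty corpus.
    """
    if len(corpus) == 0:
        raise ValueError("doc_frequencies: corpus is empty")
    counts: Counter[str] = Counter()
    for rec in corpus:
        counts.update(record_tokens(rec, min_len))
    return dict(counts)


def term_stats(dev: Corpus, pop: Corpus, min_len: int = 2) -> list[TermStats]:
    """Per-token document frequencies and sensitivities, development vs population.

    One entry per token appearing in the development set, sorted by
    development-set frequency descending with alphabetical tie-break.
    """
    if len(dev) == 0 or len(pop) == 0:
        raise ValueError("term_stats: both corpora must be non-empty")
    freq_dev = doc_frequencies(dev, min_len)
    freq_pop = doc_frequencies(pop, min_len)
    stats = [
        TermStats(
            term=term,
            kind=TEXT_WORD,
            freq_dev=fd,
            freq_pop=freq_pop.get(term, 0),
            n_dev=len(dev),
            n_pop=len(pop),
        )
        for term, fd in freq_dev.items()
    ]
    stats.sort(key=lambda s: (-s.freq_dev, s.term))
    return stats


def normalize_heading(cv_term: str) -> str:
    """Aggregate form of a controlled-vocabulary assignment.

    Strips the leading ``*`` major-topic marker and any ``/subheading``
    suffix, then casefolds: ``"*Brachytherapy/methods"`` -> ``"brachytherapy"``.
    """
    return cv_term.strip().lstrip("*").split("/", 1)[0].strip().casefold()


def cv_frequencies(corpus: Corpus) -> dict[str, int]:
    """Document frequency of each aggregated controlled-vocabulary heading.

    A heading counts once per record even if the record lists it with several
    subheadings.
    """
    counts: Counter[str] = Counter()
    for rec in corpus:
        headings = {normalize_heading(t) for t in rec.cv_terms}
        headings.discard("")
        counts.update(headings)
    return dict(counts)


# ---------------------------------------------------------------------------
# Candidate screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    """Exhaustive, disjoint partition of screened terms.

    ``auto_pass``: frequent in the development set *and* rare in the
    population.  ``near_miss``: frequent in the development set but above the
    population threshold (kept for manual relevance review).  ``excluded``:
    below the development-set threshold.
    """

    auto_pass: tuple[TermStats, ...]
    near_miss: tuple[TermStats, ...]
    excluded: tuple[TermStats, ...]
    dev_threshold: Fraction
    pop_threshold: Fraction

    def find(self, term: str) -> TermStats | None:
        for tier in (self.auto_pass, self.near_miss, self.excluded):
            for s in tier:
                if s.term == term:
                    return s
        return None


def _as_fraction(x) -> Fraction:
    # Fraction(str(0.2)) == 1/5; Fraction(0.2) is the binary float, which
    # would break the inclusive comparison at exactly the threshold.
    return x if isinstance(x, Fraction) else Fraction(str(x))


def select_candidates(
    stats: Sequence[TermStats],
    dev_threshold: float | Fraction = 0.20,
    pop_threshold: float | Fraction = 0.02,
) -> ScreenResult:
    """Partition terms by the frequency/overrepresentation screen.

    Both comparisons are inclusive: a term passes the development condition if
    ``sens_dev >= dev_threshold`` and the population condition if
    ``sens_pop <= pop_threshold``.
    """
    dev_t = _as_fraction(dev_threshold)
    pop_t = _as_fraction(pop_threshold)
    for name, t in (("dev_threshold", dev_t), ("pop_threshold", pop_t)):
        if not (0 < t < 1):
            raise ValueError(f"{name} must lie in (0, 1), got {t}")
    auto_pass, near_miss, excluded = [], [], []
    for s in stats:
        if s.sens_dev >= dev_t:
            (auto_pass if s.sens_pop <= pop_t else near_miss).append(s)
        else:
            excluded.append(s)
    return ScreenResult(
        tuple(auto_pass), tuple(near_miss), tuple(excluded), dev_t, pop_t
    )


def _stats_on_demand(term: str, kind: str, dev: Corpus, pop: Corpus) -> TermStats:
    if kind == TEXT_WORD:
        fd = sum(1 for r in dev if term in record_tokens(r))
        fp = sum(1 for r in pop if term in record_tokens(r))
    else:
        fd = cv_frequencies(dev).get(term, 0)
        fp = cv_frequencies(pop).get(term, 0)
    return TermStats(term, kind, fd, fp, len(dev), len(pop))


def categorize(
    screen: ScreenResult,
    category_map: Mapping[str, object],
    dev: Corpus | None = None,
    pop: Corpus | None = None,
) -> tuple[list[CandidateTerm], list[str]]:
    """Assign relevance categories from a user-supplied map.

    ``category_map`` maps a lowercase term either to a category name or to a
    mapping ``{"category": ..., "kind": "text_word"|"controlled_vocabulary"}``.
    A key with a trailing slash (``"brachytherapy/"``, mirroring the strategy
    dialect) names a controlled-vocabulary heading rather than a text word.
    Topical relevance is never guessed: screened terms absent from the map are
    returned as *uncategorized*.  Mapped terms that did not pass the screen
    (or name a controlled-vocabulary heading) enter as ``manual_add`` with
    stats computed on demand from *dev*/*pop* when those corpora are given.

    Returns ``(candidates, uncategorized_terms)``.
    """
    screened = {s.term: ("auto_pass", s) for s in screen.auto_pass}
    screened.update({s.term: ("near_miss", s) for s in screen.near_miss})
    excluded = {s.term: s for s in screen.excluded}

    candidates: list[CandidateTerm] = []
    for raw_term, value in category_map.items():
        term = raw_term.casefold()
        kind = TEXT_WORD
        if term.endswith("/"):
            term, kind = term[:-1].strip(), CONTROLLED_VOCABULARY
        if isinstance(value, Mapping):
            category = value.get("category")
            kind = value.get("kind", kind)
        else:
            category = value
        if category not in CATEGORIES:
            raise ValueError(
                f"category for {term!r} must be one of {CATEGORIES}, "
                f"got {category!r}"
            )
        if kind == TEXT_WORD and term in screened:
            status, stats = screened[term]
        else:
            status = "manual_add"
            if kind == TEXT_WORD and term in excluded:
                stats = excluded[term]
            elif dev is not None and pop is not None:
                stats = _stats_on_demand(term, kind, dev, pop)
            else:
                stats = None
        candidates.append(CandidateTerm(term, kind, category, status, stats))

    mapped = {c.term for c in candidates if c.kind == TEXT_WORD}
    uncategorized = sorted(set(screened) - mapped)
    return candidates, uncategorized


# ---------------------------------------------------------------------------
# Table rendering
# ---------------------------------------------------------------------------

def stats_to_frame(stats: Sequence[TermStats]) -> pd.DataFrame:
    """Frequency table with columns term, freq_dev, freq_pop, sens_dev, sens_pop."""
    return pd.DataFrame(
        {
            "term": [s.term for s in stats],
            "freq_dev": [s.freq_dev for s in stats],
            "freq_pop": [s.freq_pop for s in stats],
            "sens_dev": [round(float(s.sens_dev), 4) for s in stats],
            "sens_pop": [round(float(s.sens_pop), 4) for s in stats],
        }
    )


def cv_to_frame(freqs: Mapping[str, int]) -> pd.DataFrame:
    """Controlled-vocabulary frequency table, most frequent first."""
    items = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame({"term": [k for k, _ in items],
                         "frequency": [v for _, v in items]})


def candidates_to_frame(candidates: Sequence[CandidateTerm]) -> pd.DataFrame:
    """Candidate list with columns category, term, kind (category-sorted)."""
    order = {c: i for i, c in enumerate(CATEGORIES)}
    ranked = sorted(candidates, key=lambda c: (order[c.category], c.kind, c.term))
    return pd.DataFrame(
        {
            "category": [c.category for c in ranked],
            "term": [c.term for c in ranked],
            "kind": [c.kind for c in ranked],
        }
    )
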