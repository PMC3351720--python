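"""Seeded synthetic corpora with known term-planting probabilities.

The generator emulates the statistical structure the empirical screening
method relies on: a small set of relevant records in which topical text words
and controlled-vocabulary headings occur with high per-record probability,
and a large database population sample in which the same terms are rare.
Background vocabulary is drawn from a Zipf distribution, so the population
set also contains high-frequency uninformative words ("patients"-like terms
are modelled by planting with a high background probability).  Everything is
reproducible from a single integer seed, and a truth record of every planted
occurrence is returned alongside the corpora.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .corpus_io import Corpus, ReferenceRecord

__all__ = ["TermSpec", "CVSpec", "GeneratorConfig", "generate", "table2_scenario"]


@dataclass(frozen=True)
class TermSpec:
    """Planting probabilities of a topical text word."""
    p_relevant: float
    p_background: float

    def __post_init__(self) -> None:
        for name in ("p_relevant", "p_background"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability, got {p}")


@dataclass(frozen=True)
class CVSpec:
    """Planting probabilities of a controlled-vocabulary heading.

    When a heading is planted, a subheading from *subheadings* is attached
    with probability 0.5 and a major-topic marker ``*`` with probability 0.25.
    """
    p_relevant: float
    p_background: float
    subheadings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("p_relevant", "p_background"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability, got {p}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic development/population pair.

    ``categories`` maps a term (text word or heading) to its relevance
    category; it doubles as the category map fed to candidate screening and
    is what the ``ensure_category_coverage`` flag consults: with the flag on,
    every relevant record is guaranteed at least one planted health-condition
    and one intervention text word (the category's most probable term is
    force-planted where the independent draws produced none), so the
    quasi-gold standard is reachable by topical terms — the situation the
    screening method presumes.  ``term_renderings`` carries truncation and
    grouping hints for strategy assembly (e.g. ``prostate -> prostat*``).
    """

    n_relevant: int = 25
    n_population: int = 7180
    topic_terms: Mapping[str, TermSpec] = field(default_factory=dict)
    cv_terms: Mapping[str, CVSpec] = field(default_factory=dict)
    categories: Mapping[str, str] = field(default_factory=dict)
    term_renderings: Mapping[str, str] = field(default_factory=dict)
    background_vocab: int = 2000
    zipf_exponent: float = 1.4
    title_mean: float = 9.0
    abstract_mean: float = 90.0
    ensure_category_coverage: bool = False

    def __post_init__(self) -> None:
        if self.n_relevant < 3:
            raise ValueError("n_relevant must be at least 3")
        if self.background_vocab < 100:
            raise ValueError("background_vocab must be at least 100")

    def screening_category_map(self) -> dict[str, str]:
        """Category map in the form :func:`~osd.term_analysis.categorize` takes.

        Controlled-vocabulary headings are keyed with a trailing slash so a
        name planted both as a text word and as a heading (e.g.
        "brachytherapy") yields two candidates.
        """
        out: dict[str, str] = {}
        for term in self.topic_terms:
            cat = self.categories.get(term)
            if cat:
                out[term] = cat
        for heading in self.cv_terms:
            cat = self.categories.get(heading)
            if cat:
                out[heading + "/"] = cat
        return out


def _background_words(v: int) -> list[str]:
    """Deterministic alphabetic pseudo-words bg-a, bg-b, ... (rank order)."""
    letters = string.ascii_lowercase
    words = []
    for i in range(v):
        suffix = ""
        j = i
        while True:
            suffix = letters[j % 26] + suffix
            j = j // 26 - 1
            if j < 0:
                break
        words.append("bg" + suffix)
    return words


def _zipf_probs(v: int, s: float) -> np.ndarray:
    ranks = np.arange(1, v + 1, dtype=float)
    p = ranks ** (-s)
    return p / p.sum()


def generate(
    config: GeneratorConfig, seed: int
) -> tuple[Corpus, Corpus, dict]:
    """Generate (relevant corpus, population corpus, truth record).

    Each relevant record includes each topical text word independently with
    its ``p_relevant`` (inserted at a random position of the title or
    abstract) and each heading with its ``p_relevant``; population records
    use the ``p_background`` probabilities.  Remaining tokens are Zipf
    background vocabulary.  The truth dict records every planted term per
    record, including force-planted ones under ``"forced"``.
    """
    rng = np.random.default_rng(seed)
    vocab = np.array(_background_words(config.background_vocab))
    probs = _zipf_probs(config.background_vocab, config.zipf_exponent)

    primary: dict[str, str] = {}  # category -> highest-p_relevant text word
    for term, spec in config.topic_terms.items():
        cat = config.categories.get(term)
        if cat in ("health_condition", "intervention"):
            if cat not in primary or (spec.p_relevant
                                      > config.topic_terms[primary[cat]].p_relevant):
                primary[cat] = term

    truth: dict[str, dict] = {"seed": seed, "relevant": {}, "population": {}}
    relevant = _generate_set(config, rng, vocab, probs, relevant=True,
                             primary=primary, truth=truth["relevant"])
    population = _generate_set(config, rng, vocab, probs, relevant=False,
                               primary=primary, truth=truth["population"])
    return relevant, population, truth


def _generate_set(config, rng, vocab, probs, relevant, primary, truth):
    n = config.n_relevant if relevant else config.n_population
    prefix = "rel" if relevant else "pop"
    label = "relevant" if relevant else "population"

    title_lens = np.maximum(rng.poisson(config.title_mean, size=n), 3)
    abstract_lens = np.maximum(rng.poisson(config.abstract_mean, size=n), 10)
    total = int(title_lens.sum() + abstract_lens.sum())
    background = vocab[rng.choice(len(vocab), size=total, p=probs)]

    # per-record Bernoulli draws for every topical term / heading
    term_names = list(config.topic_terms)
    term_hits = {
        t: rng.random(n) < (spec.p_relevant if relevant else spec.p_background)
        for t, spec in config.topic_terms.items()
    }
    cv_hits = {
        h: rng.random(n) < (spec.p_relevant if relevant else spec.p_background)
        for h, spec in config.cv_terms.items()
    }

    records = []
    offset = 0
    width = max(4, len(str(n)))
    for i in range(n):
        t_len, a_len = int(title_lens[i]), int(abstract_lens[i])
        tokens = list(background[offset:offset + t_len + a_len])
        offset += t_len + a_len

        planted = [t for t in term_names if term_hits[t][i]]
        forced = []
        if relevant and config.ensure_category_coverage:
            for cat, anchor in primary.items():
                cat_terms = [t for t in planted
                             if config.categories.get(t) == cat]
                if not cat_terms:
                    planted.append(anchor)
                    forced.append(anchor)
        for t in planted:
            tokens.insert(int(rng.integers(0, len(tokens) + 1)), t)

        title = " ".join(tokens[:t_len])
        abstract = " ".join(tokens[t_len:])

        cv_list = []
        planted_cv = []
        for h, spec in config.cv_terms.items():
            if not cv_hits[h][i]:
                continue
            planted_cv.append(h)
            entry = h
            if spec.subheadings and rng.random() < 0.5:
                entry += "/" + spec.subheadings[
                    int(rng.integers(0, len(spec.subheadings)))]
            if rng.random() < 0.25:
                entry = "*" + entry
            cv_list.append(entry)

        accession = f"{prefix}{i + 1:0{width}d}"
        records.append(ReferenceRecord(
            accession=accession,
            title=title.capitalize() + ".",
            abstract=abstract,
            cv_terms=tuple(cv_list),
            source="synthetic",
        ))
        if planted or planted_cv:
            truth[accession] = {"terms": sorted(planted),
                                "cv": sorted(planted_cv),
                                "forced": sorted(forced)}
    return Corpus(records, label=label)


def table2_scenario(n_relevant: int = 25,
                    n_population: int = 7180) -> GeneratorConfig:
    """The packaged prostate-cancer/brachytherapy-like study conditions.

    Topical planting probabilities follow the published frequency table of
    the worked example (e.g. the brachytherapy analogue appears in 76% of
    relevant records but 0.06% of the population); generic clinical-writing
    words ("patients", "results", ...) are planted with high background
    probability so the population comparison — not a stopword list — filters
    them out.  The default 7,180 population records reproduce the scale the
    published sensitivities imply.
    """
    topic_terms = {
        # health condition
        "prostate": TermSpec(0.96, 0.0068),
        "cancer": TermSpec(0.96, 0.0503),
        "adenocarcinoma": TermSpec(0.36, 0.0040),
        # intervention
        "brachytherapy": TermSpec(0.76, 0.0006),
        "seed": TermSpec(0.44, 0.0050),
        "permanent": TermSpec(0.40, 0.0060),
        "implantation": TermSpec(0.48, 0.0070),
        # questionable
        "localized": TermSpec(0.60, 0.0092),
        "gleason": TermSpec(0.52, 0.0006),
        "psa": TermSpec(0.40, 0.0106),
        # frequent-everywhere distractors (never candidates after screening)
        "patients": TermSpec(1.00, 0.1976),
        "results": TermSpec(1.00, 0.1985),
        "treatment": TermSpec(0.84, 0.1311),
        "compared": TermSpec(0.68, 0.1354),
        "using": TermSpec(0.48, 0.2340),
    }
    cv_terms = {
        "prostatic neoplasms": CVSpec(0.92, 0.0090,
                                      ("radiotherapy", "surgery", "pathology")),
        "brachytherapy": CVSpec(0.80, 0.0019, ("methods", "adverse effects")),
        "iodine radioisotopes": CVSpec(0.12, 0.0010, ("therapeutic use",)),
        "prostate-specific antigen": CVSpec(0.48, 0.0050, ("blood",)),
        "humans": CVSpec(0.92, 0.88, ()),
        "male": CVSpec(0.92, 0.44, ()),
    }
    categories = {
        "prostatic neoplasms": "health_condition",
        "prostate": "health_condition",
        "adenocarcinoma": "health_condition",
        "cancer": "health_condition",
        "brachytherapy": "intervention",
        "seed": "intervention",
        "permanent": "intervention",
        "implantation": "intervention",
        "iodine radioisotopes": "questionable",
        "prostate-specific antigen": "questionable",
        "localized": "questionable",
        "gleason": "questionable",
        "psa": "questionable",
    }
    term_renderings = {
        "prostate": "prostat*",
        "seed": "seed*",
        "permanent": "permanent*",
        "implantation": "implant*",
    }
    return GeneratorConfig(
        n_relevant=n_relevant,
        n_population=n_population,
        topic_terms=topic_terms,
        cv_terms=cv_terms,
        categories=categories,
        term_renderings=term_renderings,
        ensure_category_coverage=True,
    )
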