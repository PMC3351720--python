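from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from osd.corpus_io import Corpus
from osd.term_analysis import (
    CandidateTerm,
    TermStats,
    categorize,
    cv_frequencies,
    doc_frequencies,
    normalize_heading,
    select_candidates,
    term_stats,
    tokenize,
)

from conftest import make_corpus, make_record


class TestTokenize:
    @pytest.mark.parametrize("text,expected", [
        ("Brachytherapy versus radical prostatectomy",
         ["brachytherapy", "versus", "radical", "prostatectomy"]),
        # hyphens, parentheses and digits all split; no stopword removal
        ("follow-up of PSA (prostate-specific antigen)",
         ["follow", "up", "of", "psa", "prostate", "specific", "antigen"]),
        ("", []),
        ("125I seeds implanted in 2004", ["seeds", "implanted", "in"]),
        ("dose of 145 Gy", ["dose", "of", "gy"]),
    ])
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    def test_no_stemming(self):
        # "treated" and "treatment" stay distinct terms
        assert tokenize("treated treatment") == ["treated", "treatment"]


class TestDocFrequencies:
    def test_counts_records_not_occurrences(self):
        corpus = make_corpus([
            ("1", "seed seed seed", "more seed talk"),
            ("2", "no match here"),
        ])
        assert doc_frequencies(corpus)["seed"] == 1

    def test_title_and_abstract_jointly(self):
        corpus = make_corpus([("1", "only title word", "abstractword")])
        freqs = doc_frequencies(corpus)
        assert freqs["title"] == 1 and freqs["abstractword"] == 1

    def test_absent_token_absent_from_mapping(self):
        assert "brachytherapy" not in doc_frequencies(
            make_corpus([("1", "something else")]))

    def test_empty_corpus_error(self):
        with pytest.raises(ValueError):
            doc_frequencies(Corpus([]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.text(alphabet="abcd", min_size=2, max_size=4),
                             min_size=1, max_size=8),
                    min_size=1, max_size=20))
    def test_matches_bruteforce_membership_scan(self, docs):
        corpus = Corpus([
            make_record(str(i), " ".join(words), "")
            for i, words in enumerate(docs)
        ])
        freqs = doc_frequencies(corpus)
        vocab = {w for words in docs for w in words}
        for term in vocab:
            expected = sum(1 for words in docs if term in words)
            assert freqs.get(term, 0) == expected


def _planted_dev(freq_by_term, n=25):
    """n-record corpus where each term appears in exactly its given count."""
    records = []
    for i in range(n):
        words = ["filler"] + [t for t, k in freq_by_term.items() if i < k]
        records.append(make_record(f"d{i}", " ".join(words)))
    return Corpus(records, label="development")


class TestTermStats:
    def test_published_sensitivity_ratios(self):
        # 19/25, 24/25 and 25/25 must come out as the exact printed ratios
        dev = _planted_dev({"brachytherapy": 19, "prostate": 24,
                            "patients": 25})
        pop = make_corpus([("p1", "unrelated background")])
        by_term = {s.term: s for s in term_stats(dev, pop)}
        assert by_term["brachytherapy"].sens_dev == Fraction(19, 25)
        assert round(float(by_term["brachytherapy"].sens_dev), 4) == 0.7600
        assert by_term["prostate"].sens_dev == Fraction(24, 25)
        assert round(float(by_term["prostate"].sens_dev), 4) == 0.9600
        assert by_term["patients"].sens_dev == Fraction(25, 25) == 1.0

    def test_absent_from_population_gives_zero(self):
        dev = make_corpus([("1", "brachytherapy works")])
        pop = make_corpus([("2", "nothing related")])
        by_term = {s.term: s for s in term_stats(dev, pop)}
        assert by_term["brachytherapy"].sens_pop == 0

    def test_sorted_by_dev_frequency_then_alphabetical(self):
        dev = _planted_dev({"zeta": 5, "alpha": 5, "beta": 9}, n=10)
        pop = make_corpus([("p", "x y")])
        terms = [s.term for s in term_stats(dev, pop)]
        assert terms.index("beta") < terms.index("alpha") < terms.index("zeta")

    def test_integer_identity(self):
        dev = _planted_dev({"alpha": 7, "beta": 13}, n=25)
        pop = _planted_dev({"alpha": 3}, n=40)
        for s in term_stats(dev, pop):
            assert s.sens_dev * s.n_dev == s.freq_dev
            assert s.sens_pop * s.n_pop == s.freq_pop

    def test_empty_corpus_error(self):
        dev = make_corpus([("1", "t")])
        with pytest.raises(ValueError):
            term_stats(dev, Corpus([]))


class TestCVFrequencies:
    def test_subheading_and_major_marker_aggregation(self):
        corpus = make_corpus([
            ("1", "t", "", ["Brachytherapy/methods"]),
            ("2", "t", "", ["*Brachytherapy"]),
        ])
        assert cv_frequencies(corpus)["brachytherapy"] == 2

    def test_heading_once_per_record(self):
        corpus = make_corpus([
            ("1", "t", "", ["Brachytherapy/methods",
                            "Brachytherapy/adverse effects"]),
        ])
        assert cv_frequencies(corpus)["brachytherapy"] == 1

    def test_document_frequency_at_scale(self):
        corpus = Corpus([
            make_record(str(i), "t", "",
                        ["Prostatic Neoplasms/radiotherapy"] if i < 23 else [])
            for i in range(25)
        ])
        assert cv_frequencies(corpus)["prostatic neoplasms"] == 23

    @pytest.mark.parametrize("raw,expected", [
        ("*Brachytherapy/methods", "brachytherapy"),
        ("Prostatic Neoplasms", "prostatic neoplasms"),
        ("Aged, 80 and over", "aged, 80 and over"),
    ])
    def test_normalize_heading(self, raw, expected):
        assert normalize_heading(raw) == expected


def _stats(term, fd, fp, n_dev=25, n_pop=7180):
    return TermStats(term, "text_word", fd, fp, n_dev, n_pop)


class TestSelectCandidates:
    def test_screen_tiers(self):
        screen = select_candidates([
            _stats("brachytherapy", 19, 4),    # frequent + rare -> auto
            _stats("cancer", 24, 361),         # frequent but common -> near miss
            _stats("rare", 3, 1),              # infrequent -> excluded
        ])
        assert [s.term for s in screen.auto_pass] == ["brachytherapy"]
        assert [s.term for s in screen.near_miss] == ["cancer"]
        assert [s.term for s in screen.excluded] == ["rare"]

    def test_thresholds_inclusive(self):
        # exactly 20% dev sensitivity and exactly 2% population sensitivity pass
        screen = select_candidates([_stats("edge", 5, 20, n_dev=25, n_pop=1000)])
        assert screen.auto_pass and not screen.near_miss

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            select_candidates([], dev_threshold=0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 25), st.integers(0, 500)),
                    max_size=30))
    def test_partition_exhaustive_and_disjoint(self, counts):
        stats = [_stats(f"t{i}", fd, fp, n_pop=500)
                 for i, (fd, fp) in enumerate(counts)]
        screen = select_candidates(stats)
        tiers = [screen.auto_pass, screen.near_miss, screen.excluded]
        assert sum(len(t) for t in tiers) == len(stats)
        names = [s.term for t in tiers for s in t]
        assert len(names) == len(set(names))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 25), st.integers(0, 500)),
                    max_size=30),
           st.integers(1, 10), st.integers(1, 10))
    def test_lower_pop_threshold_never_grows_auto_pass(self, counts, a, b):
        lo, hi = sorted([Fraction(a, 100), Fraction(b, 100)])
        stats = [_stats(f"t{i}", fd, fp, n_pop=500)
                 for i, (fd, fp) in enumerate(counts)]
        auto_lo = {s.term for s in
                   select_candidates(stats, pop_threshold=lo).auto_pass}
        auto_hi = {s.term for s in
                   select_candidates(stats, pop_threshold=hi).auto_pass}
        assert auto_lo <= auto_hi


class TestCategorize:
    def _screen(self):
        return select_candidates([
            _stats("brachytherapy", 19, 4),
            _stats("prostate", 24, 49),
            _stats("gleason", 13, 4),
            _stats("cancer", 24, 361),
        ])

    def test_categories_applied(self):
        cands, uncategorized = categorize(self._screen(), {
            "brachytherapy": "intervention",
            "prostate": "health_condition",
            "gleason": "questionable",
        })
        by_term = {c.term: c for c in cands}
        assert by_term["brachytherapy"].category == "intervention"
        assert by_term["prostate"].category == "health_condition"
        assert by_term["gleason"].category == "questionable"
        assert uncategorized == ["cancer"]

    def test_near_miss_promoted_through_map(self):
        cands, _ = categorize(self._screen(), {"cancer": "health_condition"})
        (cancer,) = [c for c in cands if c.term == "cancer"]
        assert cancer.screen_status == "near_miss"

    def test_empty_map_everything_uncategorized(self):
        cands, uncategorized = categorize(self._screen(), {})
        assert cands == []
        assert set(uncategorized) == {"brachytherapy", "prostate", "gleason",
                                      "cancer"}

    def test_absent_term_manual_add_with_zero_frequency(self):
        dev = make_corpus([("1", "something")])
        pop = make_corpus([("2", "else")])
        cands, _ = categorize(self._screen(),
                              {"cryotherapy": "intervention"}, dev, pop)
        (c,) = [c for c in cands if c.term == "cryotherapy"]
        assert c.screen_status == "manual_add"
        assert c.stats.freq_dev == 0

    def test_trailing_slash_marks_heading(self):
        dev = make_corpus([("1", "t", "", ["Brachytherapy/methods"])])
        pop = make_corpus([("2", "u")])
        cands, _ = categorize(self._screen(),
                              {"brachytherapy/": "intervention"}, dev, pop)
        (c,) = [c for c in cands if c.kind == "controlled_vocabulary"]
        assert c.term == "brachytherapy" and c.stats.freq_dev == 1

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            categorize(self._screen(), {"brachytherapy": "modality"})
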