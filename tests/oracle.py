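"""Independent naive evaluator and random strategy generator for engine tests.

The oracle evaluates a strategy record by record: for each record it decides
every line's predicate with plain Python booleans (no set algebra, no token
indexes), expanding line references through an environment of earlier line
outcomes.  It shares nothing with the engine's evaluation path except the
parsed AST and the tokenizer contract.
"""

from __future__ import annotations

import random

from osd.corpus_io import Corpus, ReferenceRecord
from osd.strategy_engine import (
    AccessionList,
    And,
    CVHeading,
    FieldedText,
    LineListAnd,
    LineRangeOr,
    LineRef,
    Or,
    SearchStrategy,
    Term,
)
from osd.term_analysis import normalize_heading, tokenize


def _record_matches(node, record: ReferenceRecord, env: dict[int, bool],
                    fields=None) -> bool:
    if isinstance(node, Term):
        assert fields is not None
        for f in fields:
            if f == "ti":
                toks = tokenize(record.title)
            elif f == "ab":
                toks = tokenize(record.abstract)
            else:  # kw
                toks = [t for cv in record.cv_terms for t in tokenize(cv)]
            if node.truncated:
                if any(t.startswith(node.token) for t in toks):
                    return True
            elif node.token in toks:
                return True
        return False
    if isinstance(node, FieldedText):
        return _record_matches(node.expr, record, env, node.fields)
    if isinstance(node, CVHeading):
        return any(normalize_heading(cv) == node.heading
                   for cv in record.cv_terms)
    if isinstance(node, And):
        return all(_record_matches(c, record, env, fields)
                   for c in node.children)
    if isinstance(node, Or):
        return any(_record_matches(c, record, env, fields)
                   for c in node.children)
    if isinstance(node, LineRef):
        return env[node.n]
    if isinstance(node, LineRangeOr):
        return any(env[n] for n in range(node.first, node.last + 1))
    if isinstance(node, LineListAnd):
        return all(env[n] for n in node.lines)
    if isinstance(node, AccessionList):
        return record.accession in node.ids
    raise TypeError(node)


def naive_evaluate(strategy: SearchStrategy, corpus: Corpus) -> dict[int, set]:
    """Per-line retrieved accession sets, computed record by record."""
    results: dict[int, set] = {line.number: set() for line in strategy}
    for record in corpus:
        env: dict[int, bool] = {}
        for line in strategy:
            hit = _record_matches(line.expr, record, env)
            env[line.number] = hit
            if hit:
                results[line.number].add(record.accession)
    return results


# ---------------------------------------------------------------------------
# Random inputs
# ---------------------------------------------------------------------------

_VOCAB = [
    "prostate", "prostatectomy", "cancer", "carcinoma", "brachytherapy",
    "seed", "seeds", "implant", "implantation", "radiation", "therapy",
    "survival", "outcome", "cohort", "trial", "dose", "toxicity", "grade",
    "biopsy", "antigen",
]
_HEADINGS = ["prostatic neoplasms", "brachytherapy", "humans",
             "treatment outcome", "neoplasm staging"]
_SUBHEADINGS = ["methods", "adverse effects", "therapy"]


def random_corpus(rng: random.Random, max_records: int = 200) -> Corpus:
    n = rng.randint(5, max_records)
    records = []
    for i in range(n):
        title = " ".join(rng.choices(_VOCAB, k=rng.randint(2, 6)))
        abstract = " ".join(rng.choices(_VOCAB, k=rng.randint(0, 25)))
        cv = []
        for h in rng.sample(_HEADINGS, k=rng.randint(0, 3)):
            entry = h
            if rng.random() < 0.5:
                entry += "/" + rng.choice(_SUBHEADINGS)
            if rng.random() < 0.3:
                entry = "*" + entry
            cv.append(entry)
        records.append(ReferenceRecord(f"id{i}", title, abstract, tuple(cv)))
    return Corpus(records, label="random")


def _random_term(rng: random.Random) -> str:
    word = rng.choice(_VOCAB)
    if rng.random() < 0.3:
        cut = rng.randint(3, len(word))
        return word[:cut] + "*"
    return word


def _random_text_line(rng: random.Random) -> str:
    fields = rng.choice(["ab,ti", "ti", "ab", "ti,ab,kw"])
    n_terms = rng.randint(1, 3)
    if n_terms == 1:
        expr = _random_term(rng)
        return f"{expr}.{fields}."
    op1, op2 = rng.choice(["and", "or"]), rng.choice(["and", "or"])
    terms = [_random_term(rng) for _ in range(n_terms)]
    if n_terms == 2:
        expr = f"{terms[0]} {op1} {terms[1]}"
    else:
        expr = f"({terms[0]} {op1} {terms[1]}) {op2} {terms[2]}"
    return f"({expr}).{fields}."


def random_strategy_text(rng: random.Random, corpus: Corpus,
                         max_lines: int = 8) -> str:
    n_lines = rng.randint(1, max_lines)
    lines = []
    for number in range(1, n_lines + 1):
        kinds = ["text", "cv"]
        if number >= 3:
            kinds += ["or_range", "and_list", "ref_bool"]
        if rng.random() < 0.15:
            kinds.append("accessions")
        kind = rng.choice(kinds)
        if kind == "text":
            body = _random_text_line(rng)
        elif kind == "cv":
            body = f"{rng.choice(_HEADINGS)}/"
        elif kind == "or_range":
            a = rng.randint(1, number - 2)
            b = rng.randint(a + 1, number - 1)
            body = f"or/{a}-{b}"
        elif kind == "and_list":
            refs = rng.sample(range(1, number), k=2)
            body = f"and/{min(refs)},{max(refs)}"
        elif kind == "ref_bool":
            a, b = rng.sample(range(1, number), k=2)
            body = f"{a} {rng.choice(['and', 'or'])} {b}"
        else:
            ids = rng.sample([r.accession for r in corpus],
                             k=rng.randint(1, min(4, len(corpus))))
            body = "(" + " or ".join(f'"{i}"' for i in ids) + ").ui." \
                if len(ids) > 1 else f'"{ids[0]}".ui.'
        if rng.random() < 0.2:
            body += " [Annotation]"
        lines.append(f"{number} {body}")
    return "\n".join(lines)
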