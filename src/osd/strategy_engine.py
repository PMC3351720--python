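"""Parse and evaluate Ovid-style numbered search strategies.

A strategy is a sequence of numbered lines, each holding one of:

* a controlled-vocabulary heading search  —  ``Prostatic Neoplasms/``
* a fielded text-word search              —  ``(prostat* and (cancer or adenocarcinoma)).ab,ti.``
  (the Cochrane suffix ``:ti,ab,kw`` parses to the same node)
* a line combinator                       —  ``or/1-2`` or ``and/3,7``
* a boolean over earlier lines            —  ``8 and 9``
* an accession-number list                —  ``("18374503" or "11104883").ui.``

and an optional trailing bracketed annotation, e.g. ``[Health condition]``.

Evaluation runs against a local :class:`~osd.corpus_io.Corpus` with
database-faithful semantics: a text term matches a record if some
title/abstract token equals it (or has it as a prefix when truncated with
``*``); a heading search matches on the subheading-stripped,
major-marker-stripped heading; ``and``/``or`` are set intersection/union.
Matching is case-insensitive throughout.  ``NOT``, adjacency operators,
explosion and floating subheadings are not part of the dialect and raise
parse errors.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, Union

import pandas as pd

from .corpus_io import Corpus
from .term_analysis import normalize_heading, tokenize

__all__ = [
    "Term", "And", "Or", "FieldedText", "CVHeading", "LineRef",
    "LineRangeOr", "LineListAnd", "AccessionList",
    "StrategyLine", "SearchStrategy", "ResultSet",
    "StrategyParseError", "StrategyEvalError",
    "parse_strategy", "serialize", "evaluate", "hit_counts", "render_markdown",
]

VALID_FIELDS = ("ti", "ab", "kw")


class StrategyParseError(ValueError):
    """Syntax or structural error in a strategy, naming the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StrategyEvalError(RuntimeError):
    """Internal evaluation failure (e.g. a dangling line reference)."""


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """A single query token; ``truncated`` marks a trailing ``*`` wildcard."""
    token: str
    truncated: bool = False


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]


@dataclass(frozen=True)
class FieldedText:
    """A boolean expression over terms restricted to the named fields."""
    expr: "Node"
    fields: tuple[str, ...]
    dialect: str = "ovid"  # "ovid" -> .ab,ti.   "cochrane" -> :ti,ab,kw


@dataclass(frozen=True)
class CVHeading:
    """Controlled-vocabulary heading search, non-exploded (no tree walk)."""
    heading: str
    exploded: bool = False


@dataclass(frozen=True)
class LineRef:
    n: int


@dataclass(frozen=True)
class LineRangeOr:
    """``or/a-b``: union of the results of lines a..b."""
    first: int
    last: int


@dataclass(frozen=True)
class LineListAnd:
    """``and/a,b,...``: intersection of the listed lines' results."""
    lines: tuple[int, ...]


@dataclass(frozen=True)
class AccessionList:
    """``(".." or "..").ui.``: records whose accession is in the list."""
    ids: tuple[str, ...]


Node = Union[Term, And, Or, FieldedText, CVHeading, LineRef,
             LineRangeOr, LineListAnd, AccessionList]


@dataclass(frozen=True)
class StrategyLine:
    number: int
    expr: Node
    annotation: str | None = None

    @property
    def text(self) -> str:
        out = f"{self.number} {serialize(self.expr)}"
        if self.annotation is not None:
            out += f" [{self.annotation}]"
        return out


@dataclass(frozen=True)
class SearchStrategy:
    lines: tuple[StrategyLine, ...]

    @property
    def last_number(self) -> int:
        return self.lines[-1].number

    def text(self) -> str:
        return "\n".join(line.text for line in self.lines)

    def __iter__(self) -> Iterator[StrategyLine]:
        return iter(self.lines)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_ANNOTATION_RE = re.compile(r"\s*\[([^\[\]]*)\]\s*$")
_LINE_RE = re.compile(r"^\s*#?(\d+)[.)]?\s+(.*\S)\s*$")
_COMBINATOR_RE = re.compile(r"^(or|and)\s*/\s*(.+)$", re.I)
_OVID_SUFFIX_RE = re.compile(r"^(.*)\.([a-z]{1,3}(?:\s*,\s*[a-z]{1,3})*)\.$", re.I | re.S)
_COCHRANE_SUFFIX_RE = re.compile(r"^(.*):([a-z]{2}(?:\s*,\s*[a-z]{2})*)$", re.I | re.S)
_SCAN_RE = re.compile(r'\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<quoted>"[^"]*")'
                      r'|(?P<hash>#\d+)|(?P<word>[A-Za-z0-9*]+))')
_UNSUPPORTED_OPS = re.compile(r"^(not|adj\d*|freq)$", re.I)


def parse_strategy(text: str) -> SearchStrategy:
    """Parse a multi-line numbered strategy.

    Line numbers must run consecutively from 1 and every line reference must
    point to an earlier line.  Raises :class:`StrategyParseError` naming the
    line and construct otherwise.
    """
    lines: list[StrategyLine] = []
    expected = 1
    for raw in text.splitlines():
        if not raw.strip():
            continue
        m = _LINE_RE.match(raw)
        if not m:
            raise StrategyParseError(
                f"cannot parse numbered line: {raw.strip()!r}", line=expected)
        number = int(m.group(1))
        if number != expected:
            raise StrategyParseError(
                f"line numbers must run consecutively from 1; got {number}",
                line=number)
        body = m.group(2)
        annotation = None
        am = _ANNOTATION_RE.search(body)
        if am:
            annotation = am.group(1).strip()
            body = body[: am.start()].strip()
        expr = _parse_line_body(body, number)
        _check_refs(expr, number)
        lines.append(StrategyLine(number, expr, annotation))
        expected += 1
    if not lines:
        raise StrategyParseError("strategy contains no lines")
    return SearchStrategy(tuple(lines))


def _parse_line_body(body: str, number: int) -> Node:
    body = body.strip()

    m = _COMBINATOR_RE.match(body)
    if m:
        return _parse_combinator(m.group(1).lower(), m.group(2), number)

    m = _OVID_SUFFIX_RE.match(body)
    if m:
        inner, tags = m.group(1).strip(), _split_tags(m.group(2))
        if tags == ["ui"]:
            return AccessionList(_parse_accession_list(inner, number))
        bad = [t for t in tags if t not in VALID_FIELDS]
        if bad:
            raise StrategyParseError(
                f"unknown field tag(s) {bad} in {body!r}", line=number)
        return FieldedText(_parse_bool(inner, number, in_fields=True),
                           tuple(tags), dialect="ovid")

    m = _COCHRANE_SUFFIX_RE.match(body)
    if m and all(t in VALID_FIELDS for t in _split_tags(m.group(2))):
        inner, tags = m.group(1).strip(), _split_tags(m.group(2))
        return FieldedText(_parse_bool(inner, number, in_fields=True),
                           tuple(tags), dialect="cochrane")

    if body.endswith("/") and "(" not in body:
        heading = body[:-1].strip()
        if not heading:
            raise StrategyParseError("empty heading before '/'", line=number)
        return CVHeading(heading.casefold())

    # Boolean over earlier lines, e.g. "8 and 9" or "(#1)".
    return _parse_bool(body, number, in_fields=False)


def _split_tags(raw: str) -> list[str]:
    return [t.strip().lower() for t in raw.split(",")]


def _parse_combinator(op: str, spec: str, number: int) -> Node:
    spec = spec.strip()
    range_m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", spec)
    list_m = re.fullmatch(r"\d+(\s*,\s*\d+)+", spec)
    if op == "or" and range_m:
        a, b = int(range_m.group(1)), int(range_m.group(2))
        if a > b:
            raise StrategyParseError(f"empty range or/{a}-{b}", line=number)
        return LineRangeOr(a, b)
    if op == "and" and list_m:
        return LineListAnd(tuple(int(x) for x in spec.split(",")))
    raise StrategyParseError(
        f"unsupported combinator form {op}/{spec!r} "
        "(supported: or/a-b and and/a,b,...)", line=number)


def _parse_accession_list(inner: str, number: int) -> tuple[str, ...]:
    if inner.startswith("(") and inner.endswith(")"):
        inner = inner[1:-1]
    ids: list[str] = []
    for part in re.split(r"\s+or\s+", inner.strip(), flags=re.I):
        part = part.strip()
        qm = re.fullmatch(r'"([^"]+)"', part)
        ids.append(qm.group(1) if qm else part)
    if not ids or any(not i for i in ids):
        raise StrategyParseError("empty accession list", line=number)
    return tuple(ids)


# --- boolean expressions ----------------------------------------------------

def _scan(text: str, number: int) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _SCAN_RE.match(text, pos)
        if not m or m.end() == pos:
            raise StrategyParseError(
                f"cannot tokenize {text[pos:pos+20]!r}", line=number)
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
    return tokens


class _BoolParser:
    """Recursive-descent parser: ``or`` < ``and`` < atom; parens group."""

    def __init__(self, tokens: list[tuple[str, str]], number: int,
                 in_fields: bool):
        self.tokens = tokens
        self.i = 0
        self.number = number
        self.in_fields = in_fields

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise StrategyParseError("unexpected end of expression",
                                     line=self.number)
        self.i += 1
        return tok

    def parse(self) -> Node:
        node = self.or_expr()
        if self.peek() is not None:
            raise StrategyParseError("unbalanced parentheses",
                                     line=self.number)
        return node

    def or_expr(self) -> Node:
        children = [self.and_expr()]
        while self._is_kw("or"):
            self.next()
            children.append(self.and_expr())
        self._trailing_check()
        return children[0] if len(children) == 1 else Or(tuple(children))

    def _trailing_check(self) -> None:
        tok = self.peek()
        if tok is None or tok[0] == "rparen":
            return
        kind, val = tok
        if kind == "word" and _UNSUPPORTED_OPS.match(val):
            raise StrategyParseError(f"unsupported operator {val!r}",
                                     line=self.number)
        raise StrategyParseError(
            f"unexpected {val!r} — adjacent terms must be joined with "
            "an explicit boolean operator", line=self.number)

    def and_expr(self) -> Node:
        children = [self.atom()]
        while self._is_kw("and"):
            self.next()
            children.append(self.atom())
        return children[0] if len(children) == 1 else And(tuple(children))

    def _is_kw(self, word: str) -> bool:
        tok = self.peek()
        return (tok is not None and tok[0] == "word"
                and tok[1].lower() == word)

    def atom(self) -> Node:
        kind, val = self.next()
        if kind == "lparen":
            node = self.or_expr()
            tok = self.peek()
            if tok is None or tok[0] != "rparen":
                raise StrategyParseError("unbalanced parentheses",
                                         line=self.number)
            self.next()
            return node
        if kind == "rparen":
            raise StrategyParseError("unbalanced parentheses", line=self.number)
        if kind == "hash":
            return LineRef(int(val[1:]))
        if kind == "quoted":
            return self._term(val[1:-1])
        # word
        if _UNSUPPORTED_OPS.match(val):
            raise StrategyParseError(
                f"unsupported operator {val!r}", line=self.number)
        if val.lower() in ("and", "or"):
            raise StrategyParseError(
                f"misplaced operator {val!r}", line=self.number)
        if val.isdigit() and not self.in_fields:
            return LineRef(int(val))
        return self._term(val)

    def _term(self, raw: str) -> Node:
        if not self.in_fields:
            raise StrategyParseError(
                f"bare term {raw!r} without a field qualifier "
                "(use e.g. term.ab,ti.)", line=self.number)
        truncated = raw.endswith("*")
        token = raw.rstrip("*")
        if "*" in token:
            raise StrategyParseError(
                f"mid-word wildcard unsupported in {raw!r}", line=self.number)
        if not token:
            raise StrategyParseError("empty term", line=self.number)
        return Term(token.casefold(), truncated)


def _parse_bool(text: str, number: int, in_fields: bool) -> Node:
    return _BoolParser(_scan(text, number), number, in_fields).parse()


def _line_refs(node: Node) -> Iterator[int]:
    if isinstance(node, LineRef):
        yield node.n
    elif isinstance(node, LineRangeOr):
        yield from (node.first, node.last)
    elif isinstance(node, LineListAnd):
        yield from node.lines
    elif isinstance(node, (And, Or)):
        for child in node.children:
            yield from _line_refs(child)
    elif isinstance(node, FieldedText):
        yield from _line_refs(node.expr)


def _check_refs(node: Node, number: int) -> None:
    for ref in _line_refs(node):
        if ref >= number:
            raise StrategyParseError(
                f"reference to line {ref} is not an earlier line", line=number)
        if ref < 1:
            raise StrategyParseError(f"invalid line reference {ref}",
                                     line=number)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def serialize(node: Node) -> str:
    """Render a node in the strategy text dialect; inverse of the parser."""
    if isinstance(node, Term):
        return node.token + ("*" if node.truncated else "")
    if isinstance(node, And):
        return " and ".join(_child(c) for c in node.children)
    if isinstance(node, Or):
        return " or ".join(_child(c) for c in node.children)
    if isinstance(node, FieldedText):
        inner = serialize(node.expr)
        if isinstance(node.expr, (And, Or)):
            inner = f"({inner})"
        if node.dialect == "cochrane":
            return f"{inner}:{','.join(node.fields)}"
        return f"{inner}.{','.join(node.fields)}."
    if isinstance(node, CVHeading):
        return f"{node.heading}/"
    if isinstance(node, LineRef):
        return str(node.n)
    if isinstance(node, LineRangeOr):
        return f"or/{node.first}-{node.last}"
    if isinstance(node, LineListAnd):
        return "and/" + ",".join(str(n) for n in node.lines)
    if isinstance(node, AccessionList):
        body = " or ".join(f'"{i}"' for i in node.ids)
        return f"({body}).ui." if len(node.ids) > 1 else f'"{node.ids[0]}".ui.'
    raise TypeError(f"cannot serialize {node!r}")


def _child(node: Node) -> str:
    s = serialize(node)
    return f"({s})" if isinstance(node, (And, Or)) else s


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

class _RecordIndex:
    __slots__ = ("accession", "fields", "cv_headings")

    def __init__(self, record):
        self.accession = record.accession
        ti = tuple(sorted(set(tokenize(record.title))))
        ab = tuple(sorted(set(tokenize(record.abstract))))
        kw = tuple(sorted({t for cv in record.cv_terms for t in tokenize(cv)}))
        self.fields = {"ti": ti, "ab": ab, "kw": kw}
        self.cv_headings = {normalize_heading(t) for t in record.cv_terms}

    def matches_term(self, term: Term, fields: Sequence[str]) -> bool:
        for f in fields:
            toks = self.fields[f]
            if term.truncated:
                i = bisect_left(toks, term.token)
                if i < len(toks) and toks[i].startswith(term.token):
                    return True
            else:
                i = bisect_left(toks, term.token)
                if i < len(toks) and toks[i] == term.token:
                    return True
        return False


@dataclass(frozen=True)
class ResultSet:
    """Per-line retrieved accession sets for one strategy/corpus evaluation."""

    lines: Mapping[int, frozenset[str]]
    texts: Mapping[int, str]

    @property
    def counts(self) -> dict[int, int]:
        return {n: len(s) for n, s in self.lines.items()}

    @property
    def final(self) -> frozenset[str]:
        return self.lines[max(self.lines)]


def evaluate(strategy: SearchStrategy, corpus: Corpus) -> ResultSet:
    """Evaluate every line of *strategy* against *corpus*.

    Returns the full per-line result sets; the last line is the strategy's
    overall retrieval.
    """
    if len(corpus) == 0:
        raise ValueError("evaluate: corpus is empty")
    index = [_RecordIndex(r) for r in corpus]
    results: dict[int, frozenset[str]] = {}
    texts: dict[int, str] = {}
    for line in strategy:
        results[line.number] = _eval_node(line.expr, index, results, corpus)
        texts[line.number] = line.text
    return ResultSet(results, texts)


def _eval_node(node: Node, index: list[_RecordIndex],
               results: Mapping[int, frozenset[str]], corpus: Corpus,
               fields: Sequence[str] | None = None) -> frozenset[str]:
    if isinstance(node, Term):
        if fields is None:
            raise StrategyEvalError("term outside a fielded context")
        return frozenset(r.accession for r in index
                         if r.matches_term(node, fields))
    if isinstance(node, FieldedText):
        return _eval_node(node.expr, index, results, corpus, node.fields)
    if isinstance(node, CVHeading):
        return frozenset(r.accession for r in index
                         if node.heading in r.cv_headings)
    if isinstance(node, And):
        sets = [_eval_node(c, index, results, corpus, fields)
                for c in node.children]
        return frozenset.intersection(*sets)
    if isinstance(node, Or):
        sets = [_eval_node(c, index, results, corpus, fields)
                for c in node.children]
        return frozenset.union(*sets)
    if isinstance(node, LineRef):
        return _line_result(node.n, results)
    if isinstance(node, LineRangeOr):
        sets = [_line_result(n, results)
                for n in range(node.first, node.last + 1)]
        return frozenset.union(*sets)
    if isinstance(node, LineListAnd):
        sets = [_line_result(n, results) for n in node.lines]
        return frozenset.intersection(*sets)
    if isinstance(node, AccessionList):
        return frozenset(node.ids) & corpus.accessions
    raise StrategyEvalError(f"cannot evaluate node {node!r}")


def _line_result(n: int, results: Mapping[int, frozenset[str]]) -> frozenset[str]:
    try:
        return results[n]
    except KeyError:
        raise StrategyEvalError(f"reference to unevaluated line {n}") from None


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def hit_counts(result: ResultSet) -> pd.DataFrame:
    """Hit-count table with columns number, searches, results."""
    numbers = sorted(result.lines)
    return pd.DataFrame({
        "number": numbers,
        "searches": [_strip_number(result.texts[n]) for n in numbers],
        "results": [len(result.lines[n]) for n in numbers],
    })


def _strip_number(line_text: str) -> str:
    return line_text.split(" ", 1)[1] if " " in line_text else line_text


def render_markdown(result: ResultSet) -> str:
    """The hit-count table as a markdown table (Number / Searches / Results)."""
    df = hit_counts(result)
    rows = ["| Number | Searches | Results |", "| --- | --- | --- |"]
    for _, r in df.iterrows():
        rows.append(f"| {r['number']} | {r['searches']} | {r['results']:,} |")
    return "\n".join(rows)
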