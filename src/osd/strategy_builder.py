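"""Assemble candidate terms into a Boolean strategy covering the development set.

A strategy is built as one OR block per relevance category (health condition,
intervention) ANDed together; the target is 100% sensitivity on the
development set.  The manual "trial and error" step of the original workflow
is operationalized deterministically: if the two category blocks leave
development-set records unretrieved, questionable terms are added greedily —
each step picks the questionable term covering the most still-uncovered
records (ties broken by higher development-set sensitivity, then
alphabetically) — until the set is covered or the questionable terms are
exhausted.  Non-coverage is a reported outcome, never an exception.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .corpus_io import Corpus
from .strategy_engine import (
    SearchStrategy,
    evaluate,
    parse_strategy,
)
from .term_analysis import (
    CONTROLLED_VOCABULARY,
    TEXT_WORD,
    CandidateTerm,
)

__all__ = ["BuildResult", "assemble_block", "build", "sensitivity", "precision"]

#: Annotations used on the closing OR line of each block.
CATEGORY_LABELS = {
    "health_condition": "Health condition",
    "intervention": "Intervention",
    "questionable": "Questionable terms",
}


@dataclass(frozen=True)
class BuildResult:
    """Outcome of strategy assembly against a development corpus.

    ``dev_sensitivity`` is the exact fraction of development records the
    final line retrieves; success means ``uncovered`` is empty and
    sensitivity is 1.
    """

    strategy: SearchStrategy
    dev_sensitivity: Fraction
    used_questionable: tuple[str, ...]
    uncovered: frozenset[str]
    log: tuple[dict, ...] = ()

    @property
    def success(self) -> bool:
        return not self.uncovered


def _render_text_term(candidate: CandidateTerm,
                      term_map: Mapping[str, str]) -> str:
    """Line body for a text-word candidate, honoring user rendering overrides.

    The term map may replace a single token with a truncated pattern
    (``prostate -> prostat*``) or with a composite boolean expression that
    groups several candidates into one line
    (``(prostat* and (cancer or adenocarcinoma))``).
    """
    rendered = term_map.get(candidate.term, candidate.term)
    if re.search(r"[\s()]", rendered) and not _fully_parenthesized(rendered):
        rendered = f"({rendered})"
    return f"{rendered}.ab,ti."


def _fully_parenthesized(s: str) -> bool:
    if not (s.startswith("(") and s.endswith(")")):
        return False
    depth = 0
    for i, ch in enumerate(s):
        depth += ch == "("
        depth -= ch == ")"
        if depth == 0:
            return i == len(s) - 1
    return False


def assemble_block(
    candidates: Sequence[CandidateTerm],
    start: int = 1,
    term_map: Mapping[str, str] | None = None,
) -> list[str]:
    """Render one category's candidates as strategy lines plus a closing OR.

    Controlled-vocabulary candidates come first (one heading line each), then
    text-word candidates as ``.ab,ti.`` lines; candidates whose rendering
    collapses to the same line (composite expressions) are emitted once.  The
    final line ``or/<start>-<end>`` unions the block and carries the category
    label as its annotation.  A single-member block still gets its
    (degenerate) OR line so every block is referenced the same way.
    """
    if not candidates:
        raise ValueError("assemble_block: empty category")
    categories = {c.category for c in candidates}
    if len(categories) != 1:
        raise ValueError(f"assemble_block: mixed categories {sorted(categories)}")
    category = categories.pop()
    term_map = dict(term_map or {})

    bodies: list[str] = []
    for c in candidates:
        if c.kind == CONTROLLED_VOCABULARY:
            bodies.append(f"{c.term}/")
    for c in candidates:
        if c.kind == TEXT_WORD:
            body = _render_text_term(c, term_map)
            if body not in bodies:
                bodies.append(body)

    lines = [f"{start + i} {body}" for i, body in enumerate(bodies)]
    end = start + len(bodies) - 1
    label = CATEGORY_LABELS.get(category, category)
    lines.append(f"{end + 1} or/{start}-{end} [{label}]")
    return lines


def _compose(hc: Sequence[CandidateTerm], iv: Sequence[CandidateTerm],
             term_map: Mapping[str, str] | None) -> SearchStrategy:
    hc_lines = assemble_block(hc, start=1, term_map=term_map)
    hc_or = len(hc_lines)
    iv_lines = assemble_block(iv, start=hc_or + 1, term_map=term_map)
    iv_or = hc_or + len(iv_lines)
    final = f"{iv_or + 1} and/{hc_or},{iv_or}"
    return parse_strategy("\n".join([*hc_lines, *iv_lines, final]))


def _match_set(candidate: CandidateTerm, dev: Corpus,
               term_map: Mapping[str, str] | None) -> frozenset[str]:
    """Development-set records a single candidate term retrieves on its own."""
    if candidate.kind == CONTROLLED_VOCABULARY:
        body = f"{candidate.term}/"
    else:
        body = _render_text_term(candidate, dict(term_map or {}))
    strat = parse_strategy(f"1 {body}")
    return evaluate(strat, dev).final


def build(
    candidates: Sequence[CandidateTerm],
    dev: Corpus,
    term_map: Mapping[str, str] | None = None,
    questionable_hints: Mapping[str, str] | None = None,
    minimize: bool = False,
) -> BuildResult:
    """Build the category-block strategy and push development sensitivity to 1.

    Questionable candidates are held back and added (greedily, by uncovered
    records gained) only if the health-condition AND intervention blocks miss
    development records.  ``questionable_hints`` maps a questionable term to
    the block ("health_condition" or "intervention") it should join; the
    default is the intervention block.  With ``minimize=True``, lines whose
    removal leaves development coverage intact are pruned after coverage is
    reached (precision tuning).
    """
    hints = dict(questionable_hints or {})
    hc = [c for c in candidates if c.category == "health_condition"]
    iv = [c for c in candidates if c.category == "intervention"]
    pool = [c for c in candidates if c.category == "questionable"]
    if not hc or not iv:
        raise ValueError(
            "build requires at least one health_condition and one "
            "intervention candidate")

    dev_ids = dev.accessions
    used: list[str] = []
    log: list[dict] = []

    def run(hc_now, iv_now):
        strategy = _compose(hc_now, iv_now, term_map)
        retrieved = evaluate(strategy, dev).final
        return strategy, dev_ids - retrieved

    strategy, uncovered = run(hc, iv)
    log.append({"step": "initial-blocks",
                "uncovered": sorted(uncovered),
                "covered": len(dev_ids) - len(uncovered)})

    while uncovered and pool:
        gains = []
        for c in pool:
            gain = _match_set(c, dev, term_map) & uncovered
            if gain:
                sens = c.stats.sens_dev if c.stats is not None else Fraction(0)
                gains.append((len(gain), sens, c))
        if not gains:
            break
        # most uncovered records, then higher dev sensitivity, then A-Z
        gains.sort(key=lambda g: (-g[0], -g[1], g[2].term))
        best = gains[0][2]
        pool.remove(best)
        target = hints.get(best.term, "intervention")
        promoted = CandidateTerm(best.term, best.kind, target,
                                 best.screen_status, best.stats)
        (hc if target == "health_condition" else iv).append(promoted)
        used.append(best.term)
        strategy, uncovered = run(hc, iv)
        log.append({"step": "add-questionable", "term": best.term,
                    "block": target, "gained": gains[0][0],
                    "uncovered": sorted(uncovered)})

    if minimize and not uncovered:
        for block in (hc, iv):
            for c in list(block):
                if len(block) == 1:
                    break
                block.remove(c)
                _, trial_uncovered = run(hc, iv)
                if trial_uncovered:
                    block.append(c)
                else:
                    log.append({"step": "prune", "term": c.term})
        strategy, uncovered = run(hc, iv)

    sens = Fraction(len(dev_ids) - len(uncovered), len(dev_ids))
    return BuildResult(strategy, sens, tuple(used), frozenset(uncovered),
                       tuple(log))


def sensitivity(strategy: SearchStrategy, corpus: Corpus,
                reference_ids: Iterable[str]) -> Fraction:
    """Fraction of *reference_ids* retrieved by the strategy's final line."""
    refs = set(reference_ids)
    if not refs:
        raise ValueError("sensitivity: reference_ids is empty")
    retrieved = evaluate(strategy, corpus).final
    return Fraction(len(retrieved & refs), len(refs))


def precision(strategy: SearchStrategy, corpus: Corpus,
              relevant_ids: Iterable[str]) -> Fraction | None:
    """Fraction of retrieved records that are relevant (None if none retrieved).

    The reciprocal is the number needed to read.  Reported for precision
    tuning; no threshold is applied.
    """
    retrieved = evaluate(strategy, corpus).final
    if not retrieved:
        return None
    rel = set(relevant_ids)
    return Fraction(len(retrieved & rel), len(retrieved))
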