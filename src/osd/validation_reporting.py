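"""Test-set splitting, held-out validation, and the documentation bundle.

The test set of known relevant references (the quasi-gold standard extracted
from existing systematic reviews) is split at random: two-thirds become the
development set the strategy is derived from, one-third is held out for
validation.  Validation mirrors the published table layout: an
accession-number line for the held-out ids is appended to the strategy and
intersected with its final content line, so the last line's count over the
held-out ids *is* the validation sensitivity numerator.

Every artifact of the process (frequency tables, candidate list, strategy,
build log, validation report) can be written as a deterministic documentation
bundle for internal quality control.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Corpus
from .strategy_engine import (
    SearchStrategy,
    evaluate,
    hit_counts,
    parse_strategy,
    render_markdown,
)

__all__ = [
    "SplitResult",
    "ValidationReport",
    "split_test_set",
    "validate",
    "report_bundle",
]


@dataclass(frozen=True)
class SplitResult:
    """A reproducible development/validation partition of the test-set ids."""

    dev_ids: frozenset[str]
    val_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.dev_ids & self.val_ids:
            raise ValueError("development and validation ids overlap")


def split_test_set(
    ids: Iterable[str], seed: int, ratio: float | Fraction = Fraction(2, 3)
) -> SplitResult:
    """Uniform random split of the test-set ids into development/validation.

    The development set gets ``round(ratio * n)`` ids (nearest integer, half
    away from zero — 38 ids at ratio 2/3 give a 25/13 split); the remainder is
    the validation set.  The draw is reproducible from *seed* and independent
    of input ordering (ids are sorted before sampling).
    """
    id_list = sorted(set(ids))
    n = len(id_list)
    if n < 3:
        raise ValueError(
            f"need at least 3 ids to form a development/validation split, got {n}")
    ratio = Fraction(str(ratio)) if not isinstance(ratio, Fraction) else ratio
    if not (0 < ratio < 1):
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    n_dev = math.floor(ratio * n + Fraction(1, 2))  # half away from zero
    n_dev = min(max(n_dev, 1), n - 1)  # both sets non-empty
    rng = np.random.default_rng(seed)
    picked = rng.choice(n, size=n_dev, replace=False)
    dev = frozenset(id_list[i] for i in picked)
    return SplitResult(dev, frozenset(id_list) - dev, seed)


@dataclass(frozen=True)
class ValidationReport:
    """Held-out performance of a strategy, in the published table layout."""

    strategy_text: str
    line_counts: tuple[tuple[int, str, int], ...]
    sensitivity: Fraction
    missed: frozenset[str]
    n_validation: int
    corpus_label: str
    timestamp: str

    def __post_init__(self) -> None:
        assert self.sensitivity == 1 - Fraction(len(self.missed),
                                                self.n_validation)

    def to_markdown(self) -> str:
        rows = ["| Number | Searches | Results |", "| --- | --- | --- |"]
        for number, text, count in self.line_counts:
            rows.append(f"| {number} | {text} | {count:,} |")
        n_retrieved = self.n_validation - len(self.missed)
        pct = float(self.sensitivity) * 100
        lines = [
            f"# Validation report ({self.corpus_label})",
            "",
            f"Generated: {self.timestamp}",
            "",
            "\n".join(rows),
            "",
            f"Validation sensitivity: {n_retrieved}/{self.n_validation} "
            f"retrieved ({pct:.1f}%)",
        ]
        if self.missed:
            lines.append(f"Missed accessions: {', '.join(sorted(self.missed))}")
        return "\n".join(lines) + "\n"


def validate(
    strategy: SearchStrategy,
    corpus: Corpus,
    val_ids: Iterable[str],
    dev_ids: Iterable[str] | None = None,
    timestamp: str | None = None,
) -> ValidationReport:
    """Run *strategy* against *corpus* and score it on the held-out ids.

    An accession list line for ``val_ids`` is appended and ANDed with the
    strategy's final content line; the appended line's count is
    ``|val_ids|`` present in the corpus and the last line's count is the
    number retrieved.  If ``dev_ids`` is given, any overlap with ``val_ids``
    is an error (the validation set must contain different references than
    the development set).
    """
    vids = sorted(set(val_ids))
    if not vids:
        raise ValueError("validate: val_ids is empty")
    missing = set(vids) - corpus.accessions
    if missing:
        raise ValueError(
            f"validation ids not present in corpus: {sorted(missing)}")
    if dev_ids is not None:
        overlap = set(vids) & set(dev_ids)
        if overlap:
            raise ValueError(
                "validation ids overlap the development set: "
                f"{sorted(overlap)}")

    n = strategy.last_number
    ui_body = " or ".join(f'"{v}"' for v in vids)
    ui_body = f"({ui_body}).ui." if len(vids) > 1 else f'"{vids[0]}".ui.'
    extended = parse_strategy(
        strategy.text()
        + f"\n{n + 1} {ui_body} [validation set]"
        + f"\n{n + 2} {n} and {n + 1}"
    )
    result = evaluate(extended, corpus)
    retrieved = result.final
    missed = frozenset(vids) - retrieved
    sens = Fraction(len(vids) - len(missed), len(vids))
    table = tuple(
        (int(r["number"]), str(r["searches"]), int(r["results"]))
        for _, r in hit_counts(result).iterrows()
    )
    return ValidationReport(
        strategy_text=extended.text(),
        line_counts=table,
        sensitivity=sens,
        missed=missed,
        n_validation=len(vids),
        corpus_label=corpus.label,
        timestamp=timestamp or datetime.now(timezone.utc).isoformat(),
    )


# ---------------------------------------------------------------------------
# Documentation bundle
# ---------------------------------------------------------------------------

_MANDATORY = ("term_table", "strategy")


def report_bundle(
    out_dir: str | Path,
    *,
    term_table: pd.DataFrame | None = None,
    cv_table: pd.DataFrame | None = None,
    candidate_table: pd.DataFrame | None = None,
    strategy: SearchStrategy | None = None,
    build_log: Sequence[Mapping] | None = None,
    validation_report: ValidationReport | None = None,
    preliminary_search: str | None = None,
    sr_list: Sequence[str] | None = None,
    timestamp: str | None = None,
) -> list[Path]:
    """Write the standardized internal documentation bundle.

    Mandatory artifacts are the text-word frequency table and the strategy;
    everything else is included when supplied.  Output is deterministic: two
    runs on identical inputs (with a fixed *timestamp*) are byte-identical.
    Returns the list of files written.
    """
    missing = [name for name, val in
               (("term_table", term_table), ("strategy", strategy))
               if val is None]
    if missing:
        raise ValueError(f"report_bundle: missing mandatory artifact(s): "
                         f"{', '.join(missing)}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts = timestamp or datetime.now(timezone.utc).isoformat()
    written: list[Path] = []
    index: list[str] = [
        "# Search strategy documentation bundle", "",
        f"Generated: {ts}", "",
    ]

    def emit(name: str, writer, description: str) -> None:
        path = out / name
        writer(path)
        written.append(path)
        index.append(f"- [{description}]({name})")

    emit("term_frequencies.csv",
         lambda p: term_table.to_csv(p, index=False, float_format="%.4f"),
         "Text-word frequency table (development vs population)")
    if cv_table is not None:
        emit("cv_frequencies.csv",
             lambda p: cv_table.to_csv(p, index=False),
             "Controlled-vocabulary frequency table")
    if candidate_table is not None:
        emit("candidate_terms.csv",
             lambda p: candidate_table.to_csv(p, index=False),
             "Candidate terms by category")
    emit("strategy.txt",
         lambda p: p.write_text(strategy.text() + "\n", encoding="utf-8"),
         "Search strategy")
    if build_log is not None:
        emit("build_log.json",
             lambda p: p.write_text(
                 json.dumps(list(build_log), indent=2, sort_keys=True) + "\n",
                 encoding="utf-8"),
             "Strategy assembly log")
    if validation_report is not None:
        emit("validation.md",
             lambda p: p.write_text(validation_report.to_markdown(),
                                    encoding="utf-8"),
             "Validation report")
    if preliminary_search is not None:
        emit("preliminary_search.txt",
             lambda p: p.write_text(preliminary_search.rstrip() + "\n",
                                    encoding="utf-8"),
             "Preliminary search record")
    if sr_list is not None:
        emit("systematic_reviews.txt",
             lambda p: p.write_text("\n".join(sr_list) + "\n",
                                    encoding="utf-8"),
             "Systematic reviews used for the test set")

    index_path = out / "index.md"
    index_path.write_text("\n".join(index) + "\n", encoding="utf-8")
    written.insert(0, index_path)
    return written
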