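"""Reading, writing, and merging bibliographic reference collections.

Records travel through the pipeline as :class:`ReferenceRecord` objects
bundled into a :class:`Corpus`.  Supported on-disk formats are the PubMed
MEDLINE flat file (``.nbib``, ``PMID``/``TI``/``AB``/``MH`` tags), RIS, and a
JSON-lines serialization used for fixtures.  Text is never case-normalized at
I/O time; lowercasing happens in the tokenizer downstream.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import Medline

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceRecord",
    "Corpus",
    "CorpusError",
    "RecordFormatError",
    "DuplicateAccessionError",
    "read_medline",
    "write_medline",
    "read_ris",
    "read_jsonl",
    "write_jsonl",
    "merge_dedupe",
]


class CorpusError(ValueError):
    """Base class for corpus construction and parsing failures."""


class RecordFormatError(CorpusError):
    """A record block is malformed (e.g. no accession); carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DuplicateAccessionError(CorpusError):
    """Two records share an accession within one corpus."""

    def __init__(self, accession: str):
        self.accession = accession
        super().__init__(f"duplicate accession: {accession!r}")


@dataclass(frozen=True)
class ReferenceRecord:
    """One bibliographic record.

    Parameters
    ----------
    accession
        Database unique identifier (e.g. PMID).  Non-empty; unique within a
        :class:`Corpus`.
    title, abstract
        Free text.  The title may be empty only if the abstract is not.
    cv_terms
        Controlled-vocabulary assignments exactly as stored in the source
        record: they may carry a ``/subheading`` suffix and a leading ``*``
        major-topic marker (e.g. ``"*Brachytherapy/methods"``).
    source
        Tag naming the database of origin.
    """

    accession: str
    title: str = ""
    abstract: str = ""
    cv_terms: tuple[str, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise CorpusError("accession must be non-empty")
        if not self.title and not self.abstract:
            raise CorpusError(
                f"record {self.accession!r}: title may be empty only if "
                "abstract is not"
            )
        object.__setattr__(self, "cv_terms", tuple(self.cv_terms))


class Corpus:
    """An ordered collection of records with unique accessions."""

    def __init__(self, records: Iterable[ReferenceRecord], label: str = ""):
        self.records: tuple[ReferenceRecord, ...] = tuple(records)
        self.label = label
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise DuplicateAccessionError(rec.accession)
            seen.add(rec.accession)
        self._by_accession = {r.accession: r for r in self.records}

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(self._by_accession)

    def get(self, accession: str) -> ReferenceRecord:
        return self._by_accession[accession]

    def subset(self, accessions: Iterable[str], label: str | None = None) -> "Corpus":
        """Records whose accession is in *accessions*, original order kept."""
        wanted = set(accessions)
        missing = wanted - self.accessions
        if missing:
            raise CorpusError(f"accessions not in corpus: {sorted(missing)}")
        return Corpus(
            (r for r in self.records if r.accession in wanted),
            label=label if label is not None else self.label,
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __contains__(self, accession: object) -> bool:
        return accession in self._by_accession

    def __repr__(self) -> str:
        return f"Corpus(label={self.label!r}, n={len(self)})"


def _read_text(path: str | Path) -> str:
    """UTF-8 with Latin-1 fallback; never fails on odd bytes."""
    data = Path(path).read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


# ---------------------------------------------------------------------------
# MEDLINE flat file (.nbib)
# ---------------------------------------------------------------------------

def read_medline(path: str | Path, label: str = "") -> Corpus:
    """Read a PubMed-format MEDLINE flat file.

    Each blank-line-delimited block becomes one record; ``TI``/``AB``
    continuation lines are joined with single spaces and each ``MH`` line is
    kept verbatim as one controlled-vocabulary term.

    Raises
    ------
    RecordFormatError
        For a block without a ``PMID``, with the block's starting line number.
    DuplicateAccessionError
        If the same PMID occurs twice.
    """
    text = _read_text(path)
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for start_line, block in _blocks(text):
        parsed = Medline.read(io.StringIO(block))
        pmid = parsed.get("PMID", "")
        if not pmid:
            raise RecordFormatError("MEDLINE block without PMID", line=start_line)
        if pmid in seen:
            raise DuplicateAccessionError(pmid)
        seen.add(pmid)
        records.append(
            ReferenceRecord(
                accession=pmid,
                title=parsed.get("TI", ""),
                abstract=parsed.get("AB", ""),
                cv_terms=tuple(parsed.get("MH", [])),
                source="medline",
            )
        )
    return Corpus(records, label=label or Path(path).stem)


def _blocks(text: str) -> Iterator[tuple[int, str]]:
    """Yield (1-based start line, block text) for blank-line-separated blocks."""
    current: list[str] = []
    start = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not current:
                start = lineno
            current.append(line)
        elif current:
            yield start, "\n".join(current) + "\n"
            current = []
    if current:
        yield start, "\n".join(current) + "\n"


def write_medline(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus as a MEDLINE flat file (inverse of :func:`read_medline`)."""
    lines: list[str] = []
    for rec in corpus:
        lines.append(f"PMID- {rec.accession}")
        if rec.title:
            lines.append(f"TI  - {rec.title}")
        if rec.abstract:
            lines.append(f"AB  - {rec.abstract}")
        for mh in rec.cv_terms:
            lines.append(f"MH  - {mh}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# RIS
# ---------------------------------------------------------------------------

_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def read_ris(path: str | Path, label: str = "") -> Corpus:
    """Read an RIS reference file.

    ``ID`` (or ``AN``) supplies the accession, ``TI``/``T1`` the title,
    ``AB``/``N2`` the abstract, and ``KW`` lines the controlled-vocabulary
    terms.  Records lacking any accession get the deterministic surrogate
    ``"ris:<ordinal>"`` (1-based position in the file).  Records with neither
    title nor abstract are skipped with a logged warning.
    """
    text = _read_text(path)
    records: list[ReferenceRecord] = []
    fields: dict[str, list[str]] = {}
    ordinal = 0
    skipped = 0
    seen: set[str] = set()

    def flush() -> None:
        nonlocal ordinal, skipped
        if not fields:
            return
        ordinal += 1
        accession = _first(fields, "ID", "AN") or f"ris:{ordinal}"
        title = _first(fields, "TI", "T1")
        abstract = _first(fields, "AB", "N2")
        kw = tuple(fields.get("KW", []))
        fields.clear()
        if not title and not abstract:
            skipped += 1
            logger.warning("RIS record %d (%s): no title or abstract; skipped",
                           ordinal, accession)
            return
        if accession in seen:
            raise DuplicateAccessionError(accession)
        seen.add(accession)
        records.append(
            ReferenceRecord(accession, title, abstract, kw, source="ris")
        )

    for line in text.splitlines():
        m = _RIS_TAG.match(line)
        if not m:
            continue
        tag, value = m.group(1), m.group(2).strip()
        if tag == "TY" and fields:
            flush()
        if tag == "ER":
            flush()
        elif value:
            fields.setdefault(tag, []).append(value)
    flush()
    if skipped:
        logger.warning("read_ris: skipped %d record(s) without title/abstract",
                       skipped)
    return Corpus(records, label=label or Path(path).stem)


def _first(fields: Mapping[str, list[str]], *tags: str) -> str:
    for tag in tags:
        if fields.get(tag):
            return " ".join(fields[tag])
    return ""


# ---------------------------------------------------------------------------
# JSON lines (fixtures) and merging
# ---------------------------------------------------------------------------

def read_jsonl(path: str | Path, label: str = "") -> Corpus:
    records = []
    for line in _read_text(path).splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        records.append(
            ReferenceRecord(
                accession=d["accession"],
                title=d.get("title", ""),
                abstract=d.get("abstract", ""),
                cv_terms=tuple(d.get("cv_terms", [])),
                source=d.get("source", ""),
            )
        )
    return Corpus(records, label=label or Path(path).stem)


def write_jsonl(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write(json.dumps({
                "accession": rec.accession,
                "title": rec.title,
                "abstract": rec.abstract,
                "cv_terms": list(rec.cv_terms),
                "source": rec.source,
            }, ensure_ascii=False) + "\n")


def merge_dedupe(corpora: Sequence[Corpus], label: str = "merged") -> Corpus:
    """Union of several corpora; the first occurrence of an accession wins."""
    if not corpora:
        raise CorpusError("merge_dedupe requires at least one corpus")
    out: list[ReferenceRecord] = []
    seen: set[str] = set()
    for corpus in corpora:
        for rec in corpus:
            if rec.accession not in seen:
                seen.add(rec.accession)
                out.append(rec)
    return Corpus(out, label=label)
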