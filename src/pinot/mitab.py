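"""PSI-MITAB input and PINOT table output.

Reads tab-separated molecular-interaction records in the PSI-MITAB 2.5
(15-column) and 2.7 (>=15-column) dialects served by PSICQUIC providers,
keeping only the fields the downstream quality-control and scoring stages
need, and writes the three result files: the 11-column network table,
the discarded-items log and the provider-status log.

The parser is deliberately policy-free: it collects every ``pubmed:`` token
and every ``MI:nnnn`` detection code it finds, including none at all, and
leaves completeness decisions to the QC stage.  Malformed lines (fewer than
15 columns) are skipped and reported, never raised.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

MI_CODE_RE = re.compile(r"MI:(\d{4})")
PUBMED_RE = re.compile(r"pubmed:\s*(\d+)", re.IGNORECASE)
TAXID_RE = re.compile(r"taxid:\s*(-?\d+)", re.IGNORECASE)

#: Column names of the network table, in output order.
NETWORK_COLUMNS = (
    "NameA",
    "SwissA",
    "EntrezA",
    "NameB",
    "SwissB",
    "EntrezB",
    "Method.Score",
    "Method",
    "Publication.Score",
    "PMIDS",
    "Final.Score",
)

NETWORK_FILENAME = "final_network.txt"
LOG_FILENAME = "final_network_log.txt"
PROVIDERS_FILENAME = "final_network_providers.txt"

MISSING = "-"  # MITAB null token


@dataclass(frozen=True)
class RawRecord:
    """One parsed PSI-MITAB line, tagged with its source database.

    ``detection_codes`` and ``pmids`` may be empty; QC handles that
    downstream.  Taxids are ``None`` when the column carried no
    ``taxid:`` token (2.5 files from some providers omit them).
    """

    source_db: str
    id_a: str
    id_b: str
    alt_ids_a: tuple[str, ...] = ()
    alt_ids_b: tuple[str, ...] = ()
    taxid_a: int | None = None
    taxid_b: int | None = None
    detection_codes: tuple[str, ...] = ()
    pmids: tuple[str, ...] = ()
    line_no: int = 1

    def __post_init__(self) -> None:
        if self.line_no < 1:
            raise ValueError("line_no must be >= 1")
        for code in self.detection_codes:
            if not re.fullmatch(r"MI:\d{4}", code):
                raise ValueError(f"malformed detection code {code!r}")
        for pmid in self.pmids:
            if not pmid.isdigit():
                raise ValueError(f"malformed PMID {pmid!r}")


@dataclass(frozen=True)
class MalformedLine:
    """A skipped input line, kept for the run report."""

    source_db: str
    line_no: int
    reason: str


@dataclass
class ParseResult:
    records: list[RawRecord] = field(default_factory=list)
    malformed: list[MalformedLine] = field(default_factory=list)


def _split_multivalue(cell: str) -> tuple[str, ...]:
    if cell.strip() in ("", MISSING):
        return ()
    return tuple(tok.strip() for tok in cell.split("|") if tok.strip())


def _first_taxid(cell: str) -> int | None:
    m = TAXID_RE.search(cell)
    return int(m.group(1)) if m else None


def parse_mitab(text: str | TextIO, source_db: str) -> ParseResult:
    """Parse MITAB text into :class:`RawRecord` objects.

    Parameters
    ----------
    text
        MITAB content as a string or an open text stream.  Lines starting
        with ``#`` are treated as headers/comments; empty lines are ignored.
    source_db
        Provider label recorded on every record (lowercased).

    Returns
    -------
    ParseResult
        Parsed records plus one :class:`MalformedLine` entry per skipped
        line (fewer than 15 tab-separated columns).
    """
    if isinstance(text, str):
        stream: Iterable[str] = io.StringIO(text)
    else:
        stream = text
    source_db = source_db.lower()
    result = ParseResult()
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            result.malformed.append(
                MalformedLine(source_db, line_no, "short_line")
            )
            continue
        codes = tuple(
            f"MI:{m}" for m in dict.fromkeys(MI_CODE_RE.findall(cols[6]))
        )
        pmids = tuple(dict.fromkeys(PUBMED_RE.findall(cols[8])))
        result.records.append(
            RawRecord(
                source_db=source_db,
                id_a=cols[0].strip(),
                id_b=cols[1].strip(),
                alt_ids_a=_split_multivalue(cols[2]),
                alt_ids_b=_split_multivalue(cols[3]),
                taxid_a=_first_taxid(cols[9]),
                taxid_b=_first_taxid(cols[10]),
                detection_codes=codes,
                pmids=pmids,
                line_no=line_no,
            )
        )
    return result


def parse_mitab_file(path: str | Path, source_db: str) -> ParseResult:
    with open(path, encoding="utf-8") as fh:
        return parse_mitab(fh, source_db)


@dataclass(frozen=True)
class OutputRow:
    """One row of the 11-column network table.

    Invariants: ``final_score = method_score + publication_score``;
    the two component scores equal the number of ``;``-delimited entries
    in their list columns; ``final_score >= 2``.
    """

    name_a: str
    swiss_a: str
    entrez_a: str
    name_b: str
    swiss_b: str
    entrez_b: str
    method_score: int
    method: str
    publication_score: int
    pmids: str
    final_score: int

    def __post_init__(self) -> None:
        if self.final_score != self.method_score + self.publication_score:
            raise ValueError("final_score must equal MS + PS")
        if self.final_score < 2:
            raise ValueError("final_score below the floor of 2")
        if self.method_score != len(self.method.split(";")):
            raise ValueError("method_score does not count Method entries")
        if self.publication_score != len(self.pmids.split(";")):
            raise ValueError("publication_score does not count PMIDS entries")
        for cell in self.as_fields():
            if "\t" in cell or "\n" in cell:
                raise ValueError("tab/newline forbidden inside a field")

    def as_fields(self) -> tuple[str, ...]:
        return (
            self.name_a,
            self.swiss_a,
            self.entrez_a,
            self.name_b,
            self.swiss_b,
            self.entrez_b,
            str(self.method_score),
            self.method,
            str(self.publication_score),
            self.pmids,
            str(self.final_score),
        )


def sanitize_label(label: str) -> str:
    """Replace characters that would break the tab-separated output."""
    return label.replace("\t", " ").replace("\n", " ").replace(";", ",")


def write_network(rows: Sequence[OutputRow], path: str | Path) -> None:
    """Write the network table: one header line plus one line per row."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(NETWORK_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row.as_fields()) + "\n")


def read_network(path: str | Path) -> list[OutputRow]:
    """Re-read a network table written by :func:`write_network`."""
    rows: list[OutputRow] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != NETWORK_COLUMNS:
            raise ValueError(f"unexpected network header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != 11:
                raise ValueError(f"expected 11 fields, got {len(f)}")
            rows.append(
                OutputRow(
                    f[0], f[1], f[2], f[3], f[4], f[5],
                    int(f[6]), f[7], int(f[8]), f[9], int(f[10]),
                )
            )
    return rows


def write_logs(report, out_dir: str | Path, *, providers_file: bool = True) -> None:
    """Write the discard log and (optionally) the provider-status log.

    ``report`` is a :class:`pinot.pipeline.RunReport` (duck-typed here to
    keep this module free of pipeline imports).  Worm runs set
    ``providers_file=False``: their output has no providers log.
    """
    out_dir = Path(out_dir)
    with open(out_dir / LOG_FILENAME, "w", encoding="utf-8") as fh:
        for seed, reason in report.discarded_seeds:
            fh.write(f"{seed}\t{reason}\n")
        for entry in report.discards:
            fh.write(f"{entry.payload}\t{entry.stage}:{entry.reason}\n")
    if providers_file:
        with open(out_dir / PROVIDERS_FILENAME, "w", encoding="utf-8") as fh:
            for status in report.provider_statuses:
                fh.write(f"{status.name}\t{status.state}\t{status.records_returned}\n")
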