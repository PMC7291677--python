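"""Record-level quality control.

A raw MITAB record survives only if it is complete and unambiguous:
within-species (when taxids are annotated), exactly one PubMed ID, at
least one detection-method code, and both interactors resolvable to a
univocal identifier triple.  Each surviving record yields one
:class:`EvidenceUnit` per detection code; each failing record yields
exactly one :class:`DiscardEntry`, so records are always conserved:
``#records yielding units + #discards == #input records``.

The lenient/stringent distinction lives entirely in :class:`FilterPolicy`
so the two extra stringent screens (taxid completeness, discard of
out-of-table method codes) can be adjusted in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .idmap import IdTriple, MappingTable, Unresolved, resolve_triple
from .methods import MethodTable, convert_method
from .mitab import RawRecord


@dataclass(frozen=True)
class FilterPolicy:
    """QC regime: which optional screens are active.

    ``lenient`` tolerates missing taxid annotations and keeps unmapped
    detection codes as singleton categories; ``stringent`` requires taxid
    completeness and drops unmapped codes.
    """

    name: str
    require_taxids: bool
    drop_unmapped_codes: bool

    @classmethod
    def from_mode(cls, mode: str) -> "FilterPolicy":
        if mode == "lenient":
            return cls("lenient", require_taxids=False, drop_unmapped_codes=False)
        if mode == "stringent":
            return cls("stringent", require_taxids=True, drop_unmapped_codes=True)
        raise ValueError(f"unknown filter mode {mode!r}")


@dataclass(frozen=True)
class EvidenceUnit:
    """One QC-passing (pair, method category, PMID) evidence tuple."""

    triple_a: IdTriple
    triple_b: IdTriple
    category: str
    pmid: str
    source_db: str


@dataclass(frozen=True)
class DiscardEntry:
    """One discarded input with the stage and reason of its rejection."""

    stage: str  # parse | taxonomy | pmid | method | mapping | seed
    reason: str
    payload: str


def _record_ref(rec: RawRecord) -> str:
    return f"{rec.source_db}:{rec.line_no}:{rec.id_a}|{rec.id_b}"


Resolver = Callable[[str, tuple[str, ...]], IdTriple | Unresolved]


def filter_record(
    rec: RawRecord,
    species_taxid: int,
    table: MethodTable,
    mapping: MappingTable | None,
    filter_mode: str = "lenient",
    resolver: Resolver | None = None,
) -> list[EvidenceUnit] | DiscardEntry:
    """Apply the QC screens to one record.

    Screens, in order: species taxonomy, PMID presence and uniqueness,
    detection-method presence, identifier resolution, and (stringent)
    method-code mappability.  Returns the record's evidence units or a
    single discard entry; never raises on record content.

    ``resolver`` overrides mapping-snapshot resolution (the worm pipeline
    resolves WBGene identifiers its own way); by default interactors are
    resolved against ``mapping``.
    """
    policy = FilterPolicy.from_mode(filter_mode)
    ref = _record_ref(rec)

    for taxid in (rec.taxid_a, rec.taxid_b):
        if taxid is not None and taxid != species_taxid:
            return DiscardEntry("taxonomy", "wrong_taxid", ref)
        if taxid is None and policy.require_taxids:
            return DiscardEntry("taxonomy", "missing_taxid", ref)

    if not rec.pmids:
        return DiscardEntry("pmid", "no_pmid", ref)
    if len(set(rec.pmids)) > 1:
        return DiscardEntry("pmid", "multiple_pmids", ref)
    pmid = rec.pmids[0]

    if not rec.detection_codes:
        return DiscardEntry("method", "no_method", ref)

    if resolver is None:
        if mapping is None:
            raise ValueError("either a mapping table or a resolver is required")
        resolver = lambda pid, alts: resolve_triple(pid, alts, mapping)
    triple_a = resolver(rec.id_a, rec.alt_ids_a)
    if isinstance(triple_a, Unresolved):
        return DiscardEntry("mapping", triple_a.reason, ref)
    triple_b = resolver(rec.id_b, rec.alt_ids_b)
    if isinstance(triple_b, Unresolved):
        return DiscardEntry("mapping", triple_b.reason, ref)

    # one evidence unit per detection code, each converted independently;
    # units sharing a category collapse later, at aggregation
    units = []
    for code in rec.detection_codes:
        cat = convert_method(code, table, policy.name)
        if cat is not None:
            units.append(EvidenceUnit(triple_a, triple_b, cat, pmid, rec.source_db))
    if not units:
        # stringent mode dropped every code on this record
        return DiscardEntry("method", "unmapped_method", ref)
    return units


def filter_batch(
    records: list[RawRecord],
    species_taxid: int,
    table: MethodTable,
    mapping: MappingTable | None,
    filter_mode: str = "lenient",
    resolver: Resolver | None = None,
) -> tuple[list[EvidenceUnit], list[DiscardEntry]]:
    """Filter a batch of records, concatenating per-record results.

    Exact accounting holds: every input record contributes >=1 evidence
    unit or exactly one discard entry.
    """
    units: list[EvidenceUnit] = []
    discards: list[DiscardEntry] = []
    for rec in records:
        out = filter_record(rec, species_taxid, table, mapping, filter_mode, resolver)
        if isinstance(out, DiscardEntry):
            discards.append(out)
        else:
            units.extend(out)
    return units, discards
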