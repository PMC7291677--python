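"""*C. elegans* internal network.

Worm queries are not answered live: a WormBase/Alliance molecular-
interactions dump (MITAB-like TSV, gene-centric ``WBGene`` identifiers)
is processed once into a :class:`WormStore` through the same parse →
taxonomy(6239) → PMID → method QC stages as human data, and seed queries
are answered from the store through the same aggregation and scoring.

The 11-column output layout is preserved: WBGene identifiers occupy the
name fields, and the Swiss-Prot/Entrez fields come from an optional worm
mapping snapshot, with the WBGene ID echoed when unmapped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .idmap import IdTriple, MappingTable, Unresolved, WORM_TAXID
from .methods import MethodTable
from .mitab import MalformedLine, parse_mitab_file
from .qc import DiscardEntry, EvidenceUnit, filter_batch
from .scoring import ScoredInteraction, aggregate

_WBGENE_RE = re.compile(r"WBGene\d{8}")


@dataclass
class WormStore:
    """QC-passing worm evidence, queryable by WBGene identifier."""

    units: list[EvidenceUnit] = field(default_factory=list)
    discards: list[DiscardEntry] = field(default_factory=list)
    malformed: list[MalformedLine] = field(default_factory=list)
    n_records: int = 0
    provenance: str = ""

    def genes(self) -> set[str]:
        out: set[str] = set()
        for u in self.units:
            out.add(u.triple_a.gene_name)
            out.add(u.triple_b.gene_name)
        return out


def _extract_wbgene(token: str) -> str | None:
    m = _WBGENE_RE.search(token)
    return m.group(0) if m else None


def make_worm_resolver(mapping: MappingTable | None):
    """Resolver mapping MITAB identifier tokens to worm IdTriples.

    With a mapping snapshot the symbol/Swiss-Prot/Entrez fields are
    filled from it (keyed on WBGene in the ``symbol`` column); without
    one, or for unmapped genes, the WBGene ID is echoed into all three
    fields so the output keeps its 11-column shape.
    """

    def resolver(primary_id: str, alt_ids: tuple[str, ...]):
        for token in (primary_id, *alt_ids):
            gene = _extract_wbgene(token)
            if gene:
                if mapping is not None:
                    hit = mapping.lookup(gene, "symbol")
                    if isinstance(hit, IdTriple):
                        return hit
                return IdTriple(gene, gene, gene)
        return Unresolved("unmapped")

    return resolver


def build_worm_store(
    dump_path,
    table: MethodTable,
    filter_mode: str = "lenient",
    mapping: MappingTable | None = None,
) -> WormStore:
    """Process an interactions dump into a queryable store.

    Records pass the same QC stages as human data with the worm taxonomy
    ID (6239).  An empty result is allowed (empty store), not an error.
    """
    parsed = parse_mitab_file(dump_path, "wormbase")
    units, discards = filter_batch(
        parsed.records,
        WORM_TAXID,
        table,
        mapping=None,
        filter_mode=filter_mode,
        resolver=make_worm_resolver(mapping),
    )
    return WormStore(
        units=units,
        discards=discards,
        malformed=parsed.malformed,
        n_records=len(parsed.records),
        provenance=str(dump_path),
    )


def query_worm(
    seeds: list[str], store: WormStore
) -> tuple[list[ScoredInteraction], list[tuple[str, str]]]:
    """Answer a seed query from the store.

    Seeds are WBGene identifiers (validated upstream).  Returns the
    scored seed-centred interactions plus (seed, reason) log entries for
    seeds with no interactions in the store.
    """
    present = store.genes()
    seed_triples = set()
    missing: list[tuple[str, str]] = []
    for seed in seeds:
        if seed not in present:
            missing.append((seed, "no_interactions"))
            continue
        for u in store.units:
            for t in (u.triple_a, u.triple_b):
                if t.gene_name == seed:
                    seed_triples.add(t)
    return aggregate(store.units, seed_triples), missing
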