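"""Evidence merging and confidence scoring.

Evidence units from all providers are grouped by unordered interactor
pair; pairs containing at least one seed become one output interaction
each.  Three integer scores summarize the support for an interaction:

* Method Score (MS) — number of distinct method categories, counted
  after conversion-table reassignment;
* Publication Score (PS) — number of distinct PubMed IDs;
* Final Score (FS) — MS + PS.

Every retained interaction has at least one method and one publication,
so FS >= 2 always; FS == 2 marks a single-study, single-technique
interaction that has not been independently replicated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .idmap import IdTriple
from .mitab import OutputRow, sanitize_label
from .qc import EvidenceUnit


def canonical_pair(a: IdTriple, b: IdTriple) -> tuple[IdTriple, IdTriple]:
    """Order-invariant key for an undirected interactor pair.

    Ordered by Swiss-Prot accession (gene name, then Entrez, as
    tie-breaks for identically accessioned triples), so
    ``canonical_pair(a, b) == canonical_pair(b, a)``.  Self-pairs
    (homodimers) are valid keys.
    """
    ka = (a.swiss, a.gene_name, a.entrez)
    kb = (b.swiss, b.gene_name, b.entrez)
    return (a, b) if ka <= kb else (b, a)


@dataclass(frozen=True)
class ScoredInteraction:
    """One unique seed-centred interaction with its merged evidence.

    The seed side is always reported as interactor A.  Invariants:
    ``ms >= 1``, ``ps >= 1``, ``fs == ms + ps`` (hence ``fs >= 2``).
    """

    seed_triple: IdTriple
    partner_triple: IdTriple
    categories: frozenset[str]
    pmid_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.categories or not self.pmid_set:
            raise ValueError("an interaction needs >=1 category and >=1 PMID")

    @property
    def ms(self) -> int:
        return len(self.categories)

    @property
    def ps(self) -> int:
        return len(self.pmid_set)

    @property
    def fs(self) -> int:
        return self.ms + self.ps

    def to_output_row(self) -> OutputRow:
        a, b = self.seed_triple, self.partner_triple
        return OutputRow(
            name_a=a.gene_name, swiss_a=a.swiss, entrez_a=a.entrez,
            name_b=b.gene_name, swiss_b=b.swiss, entrez_b=b.entrez,
            method_score=self.ms,
            method=";".join(sorted(sanitize_label(c) for c in self.categories)),
            publication_score=self.ps,
            pmids=";".join(sorted(self.pmid_set)),
            final_score=self.fs,
        )


def aggregate(
    units: list[EvidenceUnit], seeds: set[IdTriple]
) -> list[ScoredInteraction]:
    """Merge evidence units into unique scored interactions.

    Units are grouped by canonical pair; only pairs containing at least
    one seed are retained (seed-centred output).  Duplicate evidence —
    the same (pair, category, PMID) from different providers — counts
    once.  When both members are seeds the pair is emitted once, oriented
    to the lexicographically earlier seed.  Output is sorted by
    (NameA, NameB) for deterministic files.
    """
    grouped: dict[tuple[IdTriple, IdTriple], tuple[set[str], set[str]]] = {}
    for u in units:
        key = canonical_pair(u.triple_a, u.triple_b)
        cats, pmids = grouped.setdefault(key, (set(), set()))
        cats.add(u.category)
        pmids.add(u.pmid)

    out: list[ScoredInteraction] = []
    for (x, y), (cats, pmids) in grouped.items():
        if x in seeds:
            seed_side, partner = x, y  # covers seed-seed: x is lexic. earlier
        elif y in seeds:
            seed_side, partner = y, x
        else:
            continue
        out.append(
            ScoredInteraction(seed_side, partner, frozenset(cats), frozenset(pmids))
        )
    out.sort(key=lambda s: (s.seed_triple.gene_name, s.partner_triple.gene_name))
    return out


def score_threshold(
    interactions: list[ScoredInteraction], min_fs: int = 2
) -> list[ScoredInteraction]:
    """Keep interactions with Final Score >= ``min_fs``.

    ``min_fs=2`` is the no-op default: scores below 2 are unreachable,
    so asking for one is an argument error.
    """
    if min_fs < 2:
        raise ValueError("min_fs below 2 is unreachable: FS >= 2 by construction")
    return [s for s in interactions if s.fs >= min_fs]
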