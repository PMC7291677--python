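"""Seed validation and interactor identifier resolution.

Every interactor in the output must carry a univocal (gene name,
Swiss-Prot accession, Entrez gene ID) triple.  Resolution goes through a
tab-separated mapping snapshot (columns ``symbol``, ``uniprot``,
``entrez``); interactors whose identifiers match zero rows, or more than
one row, are discarded with a reason rather than guessed at.  A miniature
synthetic snapshot ships with the package for offline use and testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

HUMAN_TAXID = 9606
WORM_TAXID = 6239

SPECIES_TAXIDS = {"human": HUMAN_TAXID, "celegans": WORM_TAXID}

# UniProt accession grammar (6- or 10-character forms).
UNIPROT_RE = re.compile(
    r"(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})"
)
# HGNC-style symbol: uppercase alphanumerics with limited -/@, not digit-led.
HGNC_RE = re.compile(r"[A-Z][A-Z0-9\-@]*")
WBGENE_RE = re.compile(r"WBGene\d{8}")

# Identifier namespaces that denote non-protein molecules in MITAB columns.
NON_PROTEIN_NAMESPACES = {
    "chebi", "chembl", "chembl compound", "pubchem", "drugbank",
    "rnacentral", "mirbase", "ensemblgenomes",
}
PROTEIN_NAMESPACES = {
    "uniprotkb", "uniprot", "swissprot", "entrez gene/locuslink",
    "entrezgene/locuslink", "hgnc", "wormbase",
}


@dataclass(frozen=True)
class IdTriple:
    """Univocal (gene name, Swiss-Prot, Entrez) identity of one interactor."""

    gene_name: str
    swiss: str
    entrez: str

    def __post_init__(self) -> None:
        if not (self.gene_name and self.swiss and self.entrez):
            raise ValueError("IdTriple fields must all be nonempty")


@dataclass(frozen=True)
class Unresolved:
    """Resolution failure with a one-token reason."""

    reason: str  # unmapped | ambiguous | non_protein


def validate_seed(seed: str, species: str) -> tuple[bool, str]:
    """Check a seed identifier's lexical form for the given species.

    Human seeds may be HGNC gene symbols or Swiss-Prot UniProt accessions;
    worm seeds must be ``WBGene`` followed by exactly eight digits.
    Returns ``(True, "")`` or ``(False, reason_token)``.  Total function:
    never raises on any string.
    """
    seed = seed.strip()
    if not seed:
        return False, "empty"
    if species == "celegans":
        if WBGENE_RE.fullmatch(seed):
            return True, ""
        return False, "format"
    if species == "human":
        if UNIPROT_RE.fullmatch(seed) or HGNC_RE.fullmatch(seed):
            return True, ""
        return False, "format"
    return False, "unknown_species"


class MappingTable:
    """Symbol <-> Swiss-Prot <-> Entrez snapshot with univocality checks.

    Duplicate rows are tolerated; an identifier matching rows that
    disagree on the remaining fields resolves as ambiguous.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"symbol", "uniprot", "entrez"}
        if not required.issubset(frame.columns):
            raise ValueError(f"mapping snapshot needs columns {sorted(required)}")
        frame = frame.loc[:, ["symbol", "uniprot", "entrez"]].astype(str)
        self._frame = frame.drop_duplicates().reset_index(drop=True)
        self._by_uniprot = self._index("uniprot")
        self._by_symbol = self._index("symbol")
        self._by_entrez = self._index("entrez")

    def _index(self, col: str) -> dict[str, list[tuple[str, str, str]]]:
        out: dict[str, list[tuple[str, str, str]]] = {}
        for sym, uni, ent in self._frame.itertuples(index=False):
            out.setdefault(getattr_row(col, sym, uni, ent), []).append((sym, uni, ent))
        return out

    def __len__(self) -> int:
        return len(self._frame)

    def lookup(self, value: str, namespace: str) -> IdTriple | Unresolved:
        """Resolve one identifier in a given index (uniprot/symbol/entrez)."""
        index = {
            "uniprot": self._by_uniprot,
            "symbol": self._by_symbol,
            "entrez": self._by_entrez,
        }[namespace]
        rows = index.get(value, [])
        if not rows:
            return Unresolved("unmapped")
        if len(rows) > 1:
            return Unresolved("ambiguous")
        sym, uni, ent = rows[0]
        return IdTriple(sym, uni, ent)


def getattr_row(col: str, sym: str, uni: str, ent: str) -> str:
    return {"symbol": sym, "uniprot": uni, "entrez": ent}[col]


def load_mapping_table(path: str | Path | None = None) -> MappingTable:
    """Load a mapping snapshot; defaults to the bundled synthetic miniature."""
    if path is None:
        ref = resources.files("pinot.data") / "synthetic_mapping_human.tsv"
        with resources.as_file(ref) as p:
            return MappingTable(pd.read_csv(p, sep="\t", dtype=str))
    return MappingTable(pd.read_csv(path, sep="\t", dtype=str))


_ISOFORM_RE = re.compile(r"-(?:\d+|PRO_\d+)$")


def strip_uniprot_suffix(accession: str) -> str:
    """Drop isoform (``-2``) and PRO-chain (``-PRO_...``) suffixes."""
    return _ISOFORM_RE.sub("", accession)


def _split_namespaced(token: str) -> tuple[str, str]:
    ns, _, value = token.partition(":")
    value = value.strip().strip('"')
    return ns.strip().lower(), value


def resolve_triple(
    primary_id: str,
    alt_ids: tuple[str, ...],
    table: MappingTable,
) -> IdTriple | Unresolved:
    """Resolve a MITAB interactor to a univocal identifier triple.

    The primary identifier is tried first; alternative identifiers are
    consulted only when the primary namespace is unusable or unmapped.
    A chemical/RNA namespace on the primary identifier marks the
    interactor non-protein.  Total function.
    """
    candidates = [primary_id, *alt_ids]
    saw_ambiguous = False
    for token in candidates:
        if not token or token == "-":
            continue
        ns, value = _split_namespaced(token)
        if ns in NON_PROTEIN_NAMESPACES:
            return Unresolved("non_protein")
        if ns in ("uniprotkb", "uniprot", "swissprot"):
            hit = table.lookup(strip_uniprot_suffix(value), "uniprot")
        elif ns in ("entrez gene/locuslink", "entrezgene/locuslink"):
            hit = table.lookup(value, "entrez")
        elif ns == "hgnc":
            hit = table.lookup(value, "symbol")
        else:
            continue  # unusable namespace (intact:EBI-..., etc.)
        if isinstance(hit, IdTriple):
            return hit
        if hit.reason == "ambiguous":
            saw_ambiguous = True
    return Unresolved("ambiguous" if saw_ambiguous else "unmapped")


def resolve_seed(seed: str, table: MappingTable) -> IdTriple | Unresolved:
    """Resolve a validated human seed (symbol or accession) to its triple.

    Accession-form seeds are resolved through the accession index so both
    entry forms behave identically downstream.
    """
    if UNIPROT_RE.fullmatch(seed):
        hit = table.lookup(strip_uniprot_suffix(seed), "uniprot")
        if isinstance(hit, IdTriple):
            return hit
    return table.lookup(seed, "symbol")
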