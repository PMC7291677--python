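"""Synthetic PSI-MITAB fixture generation with ground truth.

Generates, fully offline, everything a pipeline run consumes: per-provider
MITAB files in deliberately heterogeneous dialects, a mapping snapshot, a
worm-style dump, and — crucially — a *manifest* recording each record's
intended fate (retained or discarded, with the injected defect as reason)
and the true per-pair (MS, PS, FS) under both filter modes.  The manifest
is computed during generation from the planned evidence, independently of
the parsing/QC/scoring code it later checks, so it serves as the oracle
for end-to-end tests.

The generator emulates the curation landscape that motivates evidence
integration: the same experiment surfacing from several databases,
incomplete entries lacking PMIDs or detection methods, off-species rows,
and identifiers that do not map univocally.  It makes no attempt at
biologically realistic network topology.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .methods import load_method_table
from .providers import DEFAULT_PROVIDER_NAMES

#: Accession present twice (two Entrez IDs) in the generated snapshot.
AMBIGUOUS_ACCESSION = "P88888"

DEFECTS = ("no_pmid", "multiple_pmids", "no_method", "wrong_taxid", "ambiguous")

#: reason -> QC stage expected to discard it
DEFECT_STAGE = {
    "no_pmid": "pmid",
    "multiple_pmids": "pmid",
    "no_method": "method",
    "wrong_taxid": "taxonomy",
    "ambiguous": "mapping",
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic corpus.

    Defect probabilities apply independently per written record; a
    record drawn defective is excluded from the ground truth.  The MI
    palette always contains the three two-hybrid codes (which share one
    category) and one out-of-table code, so conversion and the
    lenient/stringent split are always exercised.
    """

    n_seeds: int = 6
    n_partners: int = 20
    partners_per_seed: tuple[int, int] = (3, 8)
    evidence_per_pair: tuple[int, int] = (1, 4)
    p_no_pmid: float = 0.05
    p_multi_pmid: float = 0.04
    p_no_method: float = 0.05
    p_wrong_taxid: float = 0.04
    p_ambiguous: float = 0.03
    overlap_fraction: float = 0.3
    mi_palette: tuple[str, ...] = (
        "MI:0018", "MI:0397", "MI:0398",  # one shared two-hybrid category
        "MI:0019", "MI:0096", "MI:0114", "MI:0107", "MI:0416",
        "MI:9999",  # out-of-table: singleton in lenient, dropped in stringent
    )
    n_pmids: int = 40
    providers: tuple[str, ...] = DEFAULT_PROVIDER_NAMES
    random_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_no_pmid, self.p_multi_pmid, self.p_no_method,
                  self.p_wrong_taxid, self.p_ambiguous, self.overlap_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def defect_probs(self) -> dict[str, float]:
        return {
            "no_pmid": self.p_no_pmid,
            "multiple_pmids": self.p_multi_pmid,
            "no_method": self.p_no_method,
            "wrong_taxid": self.p_wrong_taxid,
            "ambiguous": self.p_ambiguous,
        }


@dataclass
class _Protein:
    symbol: str
    uniprot: str
    entrez: str


def _make_universe(spec: FixtureSpec) -> tuple[list[_Protein], list[_Protein]]:
    seeds = [
        _Protein(f"SEED{i + 1}", f"P{10000 + i + 1}", str(500000 + i + 1))
        for i in range(spec.n_seeds)
    ]
    partners = [
        _Protein(f"PROT{i + 1:03d}", f"P{20000 + i + 1}", str(600000 + i + 1))
        for i in range(spec.n_partners)
    ]
    return seeds, partners


def _draw_defect(rng: random.Random, probs: dict[str, float]) -> str | None:
    u = rng.random()
    acc = 0.0
    for name, p in probs.items():
        acc += p
        if u < acc:
            return name
    return None


# Per-provider MITAB dialect knobs: column count, quoting of MI terms,
# whether alt-id columns are populated.  Mirrors real provider drift.
_DIALECTS = [
    {"n_cols": 15, "quote": True, "alt_ids": True},
    {"n_cols": 17, "quote": True, "alt_ids": False},
    {"n_cols": 15, "quote": False, "alt_ids": True},
    {"n_cols": 17, "quote": False, "alt_ids": True},
]

_MI_LABELS = {
    "MI:0018": "two hybrid",
    "MI:0397": "two hybrid array",
    "MI:0398": "two hybrid pooling approach",
    "MI:0019": "coimmunoprecipitation",
    "MI:0096": "pull down",
    "MI:0114": "x-ray crystallography",
    "MI:0107": "surface plasmon resonance",
    "MI:0416": "fluorescence microscopy",
    "MI:9999": "unnamed assay",
}


def _mi_token(code: str, quote: bool) -> str:
    label = _MI_LABELS.get(code, "assay")
    return f'psi-mi:"{code}"({label})' if quote else f"psi-mi:{code}({label})"


def _mitab_line(
    a: _Protein,
    b: _Protein,
    code: str,
    pmid: str,
    dialect: dict,
    defect: str | None,
) -> str:
    id_a = f"uniprotkb:{a.uniprot}"
    id_b = f"uniprotkb:{b.uniprot}"
    alt_a = f"entrez gene/locuslink:{a.entrez}|uniprotkb:{a.symbol}" if dialect["alt_ids"] else "-"
    alt_b = f"entrez gene/locuslink:{b.entrez}|uniprotkb:{b.symbol}" if dialect["alt_ids"] else "-"
    method = _mi_token(code, dialect["quote"])
    pub = f"pubmed:{pmid}"
    tax_a = "taxid:9606(human)"
    tax_b = "taxid:9606(human)"
    if defect == "no_pmid":
        pub = "-"
    elif defect == "multiple_pmids":
        pub = f"pubmed:{pmid}|pubmed:{int(pmid) + 1}"
    elif defect == "no_method":
        method = "-"
    elif defect == "wrong_taxid":
        tax_b = "taxid:10090(mouse)"
    elif defect == "ambiguous":
        id_b = f"uniprotkb:{AMBIGUOUS_ACCESSION}"
        alt_b = "-"
    cols = [
        id_a, id_b, alt_a, alt_b,
        f"uniprotkb:{a.symbol}(gene name)", f"uniprotkb:{b.symbol}(gene name)",
        method, "-", pub, tax_a, tax_b,
        'psi-mi:"MI:0915"(physical association)',
        'psi-mi:"MI:0469"(source)', "-", "-",
    ]
    if dialect["n_cols"] > 15:
        cols += ["-"] * (dialect["n_cols"] - 15)
    return "\t".join(cols)


def generate_fixtures(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write an offline corpus and return (and save) its manifest.

    Layout under ``out_dir``: ``providers/<name>/<SEED>.mitab``,
    ``mapping.tsv``, ``method_table.tsv``, ``seeds.txt`` and
    ``manifest.json``.  Same spec + same random seed give byte-identical
    output.
    """
    rng = random.Random(spec.random_seed)
    out_dir = Path(out_dir)
    providers_dir = out_dir / "providers"
    seeds, partners = _make_universe(spec)
    method_table = load_method_table()

    pmid_pool = [str(30000000 + i) for i in range(spec.n_pmids)]

    # Plan evidence per seed-partner pair.
    planned: list[dict] = []  # one entry per written record
    lo, hi = spec.partners_per_seed
    elo, ehi = spec.evidence_per_pair
    for seed in seeds:
        k = rng.randint(lo, min(hi, len(partners)))
        chosen = rng.sample(partners, k)
        for partner in chosen:
            for _ in range(rng.randint(elo, ehi)):
                code = rng.choice(spec.mi_palette)
                pmid = rng.choice(pmid_pool)
                copies = 1
                if rng.random() < spec.overlap_fraction and len(spec.providers) > 1:
                    copies = 2
                provs = rng.sample(list(spec.providers), copies)
                for prov in provs:
                    planned.append(
                        {
                            "provider": prov,
                            "seed": seed.symbol,
                            "pair": sorted([seed.symbol, partner.symbol]),
                            "code": code,
                            "pmid": pmid,
                            "defect": _draw_defect(rng, spec.defect_probs),
                            "a": seed,
                            "b": partner,
                        }
                    )

    # Ground truth from clean records only, computed straight from the
    # planned evidence (no parsing/QC code involved).
    truth: dict[str, dict[str, dict]] = {"lenient": {}, "stringent": {}}
    acc: dict[str, dict[str, tuple[set, set]]] = {"lenient": {}, "stringent": {}}
    for rec in planned:
        if rec["defect"] is not None:
            continue
        key = "|".join(rec["pair"])
        code = rec["code"]
        cat_lenient = method_table.mapping.get(code, code)
        cats, pmids = acc["lenient"].setdefault(key, (set(), set()))
        cats.add(cat_lenient)
        pmids.add(rec["pmid"])
        if code in method_table.mapping:
            cats, pmids = acc["stringent"].setdefault(key, (set(), set()))
            cats.add(method_table.mapping[code])
            pmids.add(rec["pmid"])
    for mode, pairs in acc.items():
        for key, (cats, pmids) in sorted(pairs.items()):
            truth[mode][key] = {
                "ms": len(cats),
                "ps": len(pmids),
                "fs": len(cats) + len(pmids),
                "categories": sorted(cats),
                "pmids": sorted(pmids),
            }

    # Write provider files (grouped by provider/seed, stable order).
    files: dict[tuple[str, str], list[str]] = {}
    record_manifest: list[dict] = []
    for rec in planned:
        dialect = _DIALECTS[list(spec.providers).index(rec["provider"]) % len(_DIALECTS)]
        line = _mitab_line(
            rec["a"], rec["b"], rec["code"], rec["pmid"], dialect, rec["defect"]
        )
        files.setdefault((rec["provider"], rec["seed"]), []).append(line)
        entry = {
            "provider": rec["provider"],
            "seed": rec["seed"],
            "pair": rec["pair"],
            "code": rec["code"],
            "pmid": rec["pmid"],
        }
        if rec["defect"] is None:
            entry["fate"] = "retained"
        else:
            entry["fate"] = "discarded"
            entry["reason"] = rec["defect"]
            entry["stage"] = DEFECT_STAGE[rec["defect"]]
        record_manifest.append(entry)

    for prov in spec.providers:
        pdir = providers_dir / prov
        pdir.mkdir(parents=True, exist_ok=True)
        for seed in seeds:
            lines = files.get((prov, seed.symbol), [])
            path = pdir / f"{seed.symbol}.mitab"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("#ID(s) interactor A\tID(s) interactor B\t...\n")
                for line in lines:
                    fh.write(line + "\n")

    # Mapping snapshot: every generated protein once, plus the ambiguous
    # accession twice so the injected mapping defect actually trips QC.
    with open(out_dir / "mapping.tsv", "w", encoding="utf-8") as fh:
        fh.write("symbol\tuniprot\tentrez\n")
        for prot in seeds + partners:
            fh.write(f"{prot.symbol}\t{prot.uniprot}\t{prot.entrez}\n")
        fh.write(f"AMBA\t{AMBIGUOUS_ACCESSION}\t900001\n")
        fh.write(f"AMBB\t{AMBIGUOUS_ACCESSION}\t900002\n")

    with open(out_dir / "method_table.tsv", "w", encoding="utf-8") as fh:
        for code, cat in sorted(method_table.mapping.items()):
            fh.write(f"{code}\t{cat}\n")

    with open(out_dir / "seeds.txt", "w", encoding="utf-8") as fh:
        for seed in seeds:
            fh.write(seed.symbol + "\n")

    manifest = {
        "spec": {k: v for k, v in asdict(spec).items()},
        "n_records": len(record_manifest),
        "records": record_manifest,
        "truth": truth,
        "seeds": [s.symbol for s in seeds],
        "offline_root": "providers",
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def generate_worm_dump(
    path: str | Path,
    n_pairs: int = 10,
    n_defective: int = 2,
    random_seed: int = 0,
) -> dict:
    """Write a small worm-style interactions dump plus its ground truth.

    ``n_defective`` of the generated rows lack a PMID (the commonest
    completeness defect in gene-centric dumps); the rest are clean,
    within-species rows.  Returns a manifest with the expected retained
    pairs.
    """
    rng = random.Random(random_seed)
    genes = [f"WBGene{i + 1:08d}" for i in range(max(4, n_pairs // 2))]
    rows = []
    truth: dict[str, dict] = {}
    codes = ["MI:0018", "MI:0397", "MI:0019", "MI:0096"]
    for i in range(n_pairs):
        a, b = rng.sample(genes, 2)
        code = rng.choice(codes)
        pmid = str(20000000 + rng.randint(0, 20))
        defective = i < n_defective
        pub = "-" if defective else f"pubmed:{pmid}"
        cols = [
            f"wormbase:{a}", f"wormbase:{b}", "-", "-", "-", "-",
            f'psi-mi:"{code}"(assay)', "-", pub,
            "taxid:6239(caeel)", "taxid:6239(caeel)",
            'psi-mi:"MI:0915"(physical association)',
            'psi-mi:"MI:0487"(wormbase)', "-", "-",
        ]
        rows.append("\t".join(cols))
        if not defective:
            key = "|".join(sorted([a, b]))
            slot = truth.setdefault(key, {"categories": set(), "pmids": set()})
            slot["categories"].add(code)
            slot["pmids"].add(pmid)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#worm molecular interactions (synthetic)\n")
        for row in rows:
            fh.write(row + "\n")
    return {
        "n_rows": n_pairs,
        "n_defective": n_defective,
        "truth": {
            k: {"categories": sorted(v["categories"]), "pmids": sorted(v["pmids"])}
            for k, v in sorted(truth.items())
        },
    }
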