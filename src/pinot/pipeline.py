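"""End-to-end run orchestration.

Wires the stages together — validate seeds → acquire records (PSICQUIC
or offline files, or the worm store) → QC filter → method conversion →
merge/score → threshold → write outputs — and accounts for every seed
and every record in a :class:`RunReport`.

A run succeeds (exit code 0 at the CLI) even when seeds or records are
discarded; only run-level failures (no seeds, no data source, unwritable
output) raise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import mitab
from .idmap import (
    IdTriple,
    SPECIES_TAXIDS,
    load_mapping_table,
    resolve_seed,
    validate_seed,
)
from .methods import load_method_table
from .mitab import MalformedLine, RawRecord, write_logs, write_network
from .providers import (
    NoDataSourceError,
    ProviderConfig,
    ProviderStatus,
    default_providers,
    fetch_seed_records,
)
from .qc import DiscardEntry, filter_batch
from .scoring import aggregate, score_threshold
from .worm import build_worm_store, query_worm


@dataclass
class SeedQuery:
    """One run request: species, ordered seed list, filter regime."""

    species: str  # human | celegans
    seeds: list[str]
    filter_mode: str = "lenient"

    def __post_init__(self) -> None:
        if self.species not in SPECIES_TAXIDS:
            raise ValueError(f"unknown species {self.species!r}")
        if not self.seeds:
            raise ValueError("seed list is empty")
        # deduplicate, case-sensitively, preserving order
        self.seeds = list(dict.fromkeys(self.seeds))


@dataclass
class RunReport:
    """Per-run accounting: what came in, what survived, what was discarded."""

    seeds_in: int = 0
    seeds_valid: int = 0
    discarded_seeds: list[tuple[str, str]] = field(default_factory=list)
    discards: list[DiscardEntry] = field(default_factory=list)
    malformed: list[MalformedLine] = field(default_factory=list)
    provider_statuses: list[ProviderStatus] = field(default_factory=list)
    records_in: int = 0
    records_retained: int = 0
    interactions_out: int = 0

    def reconcile(self) -> None:
        """Check the counting identities; raises on an accounting bug."""
        assert self.seeds_in == self.seeds_valid + len(
            {s for s, _ in self.discarded_seeds}
        )
        assert self.records_in == self.records_retained + len(self.discards)

    def to_json(self) -> dict:
        return {
            "seeds_in": self.seeds_in,
            "seeds_valid": self.seeds_valid,
            "discarded_seeds": [list(t) for t in self.discarded_seeds],
            "record_discards": [
                {"stage": d.stage, "reason": d.reason, "payload": d.payload}
                for d in self.discards
            ],
            "malformed_lines": [
                {"source_db": m.source_db, "line_no": m.line_no, "reason": m.reason}
                for m in self.malformed
            ],
            "providers": [
                {"name": s.name, "state": s.state, "records": s.records_returned}
                for s in self.provider_statuses
            ],
            "records_in": self.records_in,
            "records_retained": self.records_retained,
            "interactions_out": self.interactions_out,
        }


def _merge_statuses(per_seed: list[list[ProviderStatus]]) -> list[ProviderStatus]:
    """Aggregate per-seed provider statuses into one line per provider.

    A provider counts as responded if it answered any seed; records are
    summed over seeds.
    """
    order: list[str] = []
    agg: dict[str, tuple[str, int]] = {}
    rank = {"responded": 2, "failed": 1, "skipped": 0}
    for statuses in per_seed:
        for s in statuses:
            if s.name not in agg:
                order.append(s.name)
                agg[s.name] = (s.state, s.records_returned)
            else:
                state, n = agg[s.name]
                best = s.state if rank[s.state] > rank[state] else state
                agg[s.name] = (best, n + s.records_returned)
    return [
        ProviderStatus(name, agg[name][0],
                       agg[name][1] if agg[name][0] == "responded" else 0)
        for name in order
    ]


def run_pipeline(
    query: SeedQuery,
    out_dir: str | Path,
    *,
    mode: str = "offline",
    offline_root: str | Path | None = None,
    providers: list[ProviderConfig] | None = None,
    mapping_path: str | Path | None = None,
    method_table_path: str | Path | None = None,
    worm_dump: str | Path | None = None,
    min_score: int = 2,
) -> RunReport:
    """Execute a full run and write the output files into ``out_dir``.

    Human runs write ``final_network.txt``, ``final_network_log.txt``,
    ``final_network_providers.txt`` and ``run_report.json``; worm runs
    omit the providers file.  Returns the populated :class:`RunReport`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = load_method_table(method_table_path)
    report = RunReport(seeds_in=len(query.seeds))

    valid_seeds: list[str] = []
    for seed in query.seeds:
        ok, reason = validate_seed(seed, query.species)
        if ok:
            valid_seeds.append(seed)
        else:
            report.discarded_seeds.append((seed, reason))
    report.seeds_valid = len(valid_seeds)

    if query.species == "celegans":
        if worm_dump is None:
            raise ValueError("a worm interactions dump is required for celegans runs")
        store = build_worm_store(worm_dump, table, query.filter_mode)
        report.records_in = store.n_records
        report.discards = store.discards
        report.malformed = store.malformed
        report.records_retained = store.n_records - len(store.discards)
        interactions, missing = query_worm(valid_seeds, store)
        report.discarded_seeds.extend(missing)
        # worm seeds logged no_interactions remain valid seeds; keep
        # the seed identity: seeds_valid counts format-valid ones
        report.seeds_valid -= len(missing)
        providers_file = False
    else:
        mapping = load_mapping_table(mapping_path)
        providers = providers if providers is not None else default_providers()
        if not any(p.enabled for p in providers):
            raise NoDataSourceError("no data source available")
        records: list[RawRecord] = []
        per_seed_statuses: list[list[ProviderStatus]] = []
        fetched_seeds: list[str] = []
        for seed in valid_seeds:
            try:
                recs, statuses, malformed = fetch_seed_records(
                    seed, providers, mode=mode, offline_root=offline_root
                )
            except NoDataSourceError:
                report.discarded_seeds.append((seed, "no_interactions"))
                report.seeds_valid -= 1
                continue
            records.extend(recs)
            per_seed_statuses.append(statuses)
            report.malformed.extend(malformed)
            fetched_seeds.append(seed)
        if not fetched_seeds and valid_seeds:
            raise NoDataSourceError("no data source available")
        report.provider_statuses = _merge_statuses(per_seed_statuses)
        report.records_in = len(records)

        units, discards = filter_batch(
            records,
            SPECIES_TAXIDS[query.species],
            table,
            mapping,
            query.filter_mode,
        )
        report.discards = discards
        report.records_retained = report.records_in - len(discards)

        seed_triples: set[IdTriple] = set()
        for seed in list(fetched_seeds):
            triple = resolve_seed(seed, mapping)
            if isinstance(triple, IdTriple):
                seed_triples.add(triple)
            else:
                report.discarded_seeds.append((seed, triple.reason))
                report.seeds_valid -= 1
        interactions = aggregate(units, seed_triples)
        providers_file = True

    interactions = score_threshold(interactions, min_score)
    report.interactions_out = len(interactions)

    write_network([s.to_output_row() for s in interactions],
                  out_dir / mitab.NETWORK_FILENAME)
    write_logs(report, out_dir, providers_file=providers_file)
    with open(out_dir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_json(), fh, indent=1, sort_keys=True)
    report.reconcile()
    return report
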