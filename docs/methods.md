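# Methods

## Pipeline model

The package treats PPI curation as an evidence-integration problem. The
atomic object after quality control is the **evidence unit**: a tuple
(unordered interactor pair, method category, PubMed ID, source
database). Everything upstream of scoring exists to turn heterogeneous
PSI-MITAB records into a clean multiset of such units; everything
downstream is set arithmetic over them.

Stages, in order, with where records can be discarded:

1. **Parse** (`pinot.mitab`). PSI-MITAB 2.5 (15 columns) and 2.7
   (≥ 15 columns) are both accepted; only columns 1–11 are consulted.
   Detection codes are any `MI:nnnn` token in column 7, publications any
   `pubmed:<digits>` token in column 9 (`imex:`/`doi:` references are
   ignored: QC and output are PubMed-based), taxids the first
   `taxid:<int>` token in columns 10–11. The parser is policy-free —
   empty code/PMID lists are legal at this stage — and total: a line
   with < 15 columns becomes a malformed-line report entry, never an
   exception.
2. **Taxonomy**. Any annotated taxid differing from the query species
   (9606 human, 6239 worm) discards the record. Host-organism columns
   are ignored; within-species edges are what a species-specific network
   means. Records with *missing* taxids are kept in lenient mode and
   discarded in stringent mode.
3. **Publication completeness**. No PMID → discard (`no_pmid`). More
   than one *distinct* PMID → discard (`multiple_pmids`): such entries
   conflate publications and would corrupt the publication count.
   Repeated identical tokens count as one publication — they are a
   curation artifact, not replication.
4. **Method completeness**. No detection code → discard (`no_method`).
5. **Identifier resolution** (`pinot.idmap`). Each interactor must map
   one-to-one to a (gene name, Swiss-Prot, Entrez) triple through the
   mapping snapshot; UniProt isoform (`-2`) and PRO-chain (`-PRO_…`)
   suffixes are stripped before lookup; alternative-identifier columns
   are consulted when the primary namespace is unusable. Zero matches →
   `unmapped`; several conflicting matches → `ambiguous`; chemical/RNA
   namespaces → `non_protein`. All three discard.
6. **Method conversion** (`pinot.methods`). Each code is reassigned to
   its technique-family category; a record with several codes yields one
   unit per code. Out-of-table codes: singleton category (lenient) or
   dropped (stringent; if every code on a record drops, the record is
   discarded `unmapped_method`).
7. **Merge and score** (`pinot.scoring`). Units group by canonical
   unordered pair (ordered internally by Swiss-Prot accession, with gene
   name and Entrez as tie-breaks). Only pairs containing ≥ 1 seed are
   reported (seed-centred output). MS = |distinct categories|,
   PS = |distinct PMIDs|, FS = MS + PS. Cross-provider duplicates of the
   same (pair, category, PMID) count once by construction.

Conservation holds exactly at the record level: every parsed record
either sources ≥ 1 evidence unit or produces exactly one discard entry,
and the run report reconciles these counts (an assertion, not a hope).

## Design choices where the design was open

* **Lenient vs stringent.** The two extra stringent screens — taxid
  completeness and out-of-table-code discard — are this package's
  reconstruction of "stringent screening largely based on completeness
  of curated data entries". They are centralized in one `FilterPolicy`
  object so an alternative rule set is a one-place change. Whatever the
  exact rules, the intended invariant — stringent output ⊆ lenient
  output — is property-tested.
* **Method conversion table.** The bundled table groups the PSI-MI
  detection-method branch at assay-family level (37 codes, 11
  families); the three two-hybrid rows (`MI:0018`, `MI:0397`, `MI:0398`
  → "Two Hybrid (2Hyb)") are fixed. Category labels may not contain
  tabs or `;` (output delimiters). Any user table in the same
  two-column TSV format drops in via `--method-table`; a code mapped to
  two categories is a load error.
* **Self-interactions** (homodimers) are retained: databases curate
  them routinely and nothing in the scoring breaks on A = A.
* **Seed–seed pairs** are emitted once, oriented to the
  lexicographically earlier seed, preserving the uniqueness invariant.
* **Both seed entry forms** (symbol or accession) resolve to the same
  triple before querying, so they behave identically. Seeds are used
  case-sensitively; no folding, so user typos surface in the log
  instead of silently matching.
* **Determinism.** Output rows sort by (NameA, NameB); `Method` and
  `PMIDS` entries sort lexicographically and join with `;`. Two offline
  runs of the same command are byte-identical — this is tested.
* **Provider failures** never abort a run: each provider gets one retry
  (live mode), then is marked `failed` in the providers log and the run
  continues on the remainder. Only the degenerate case — no provider
  usable at all — is a run-level error.
* **Worm pipeline.** Worm queries reuse the same QC and scoring code
  paths verbatim against a locally built store; only identifier
  resolution differs (WBGene IDs, echoed into the Swiss-Prot/Entrez
  columns when no worm mapping snapshot is supplied, preserving the
  11-column shape).

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `--filter` | `lenient` | QC regime; lenient maximizes recall, stringent completeness |
| `--min-score` | 2 | FS threshold; 2 is a no-op since FS ≥ 2 by construction, values < 2 are rejected |
| `--method-table` | bundled | detection-code → category TSV |
| `--mapping` | bundled miniature | symbol/Swiss-Prot/Entrez snapshot (TSV) |
| `--providers-config` | built-in seven | YAML provider list |
| `--offline` | — | offline root `<dir>/<provider>/<seed>.mitab`; omit for live PSICQUIC |

The bundled mapping snapshot is a ~50-row synthetic miniature for
offline use and testing; real analyses should supply a full,
versioned snapshot, since resolution coverage directly bounds network
coverage (everything unmapped is discarded, visibly, in the log).

## The fixture generator and what passing tests mean

`pinot.fixtures` generates complete offline corpora: per-provider MITAB
files in four deliberately different dialects (15 vs 17 columns, quoted
vs bare `MI:` tokens, populated vs empty alt-id columns), a mapping
snapshot, a seeds file, and a manifest. Defects are injected per record
with configurable probabilities (defaults: no PMID 0.05, multiple PMIDs
0.04, no method 0.05, wrong taxid 0.04, ambiguous mapping 0.03 — a
realistic minority of entries; cross-provider duplication 0.3, matching
the heavy overlap among curated databases). The default corpus is 6
seeds × 3–8 partners × 1–4 evidence units per pair, ≈ 100–150 records;
the conservation test uses a ≈ 1000-record corpus (20 seeds).

The manifest records each record's intended fate and the true per-pair
(MS, PS, FS) under both regimes, computed at generation time directly
from the planned evidence — no parsing, QC or scoring code involved —
so manifest agreement is a genuinely independent end-to-end oracle.

What the fixtures do **not** emulate: biologically realistic network
topology or degree distributions, provider-specific MIQL quirks, PSI-MI
XML, live-service drift, or genuinely malformed encodings beyond short
lines. Passing tests therefore demonstrate the correctness of parsing,
QC, conversion, merging and scoring under controlled heterogeneity —
not recall against any real database snapshot, which changes as
providers update and is explicitly out of scope for automated testing.

## Numerical and degenerate-input conventions

Scores are small exact integers; no floating point enters the pipeline.
Empty inputs degrade gracefully: an empty seed list is a run error; a
valid seed with no data yields a header-only network plus a
`no_interactions` log entry; an empty MITAB stream parses to zero
records; an empty method table is valid (every code is then
out-of-table). Tie-breaks are lexicographic everywhere a choice exists.

## Known limitations

* Live PSICQUIC mode is implemented (stdlib HTTP, one retry per
  provider) but untested by design; offline mode is the tested surface.
* The stringent rule set is a reconstruction (see above), not a claim
  about any particular web service's internals.
* No interaction-type (physical vs genetic) or tissue filtering; no
  ortholog/interolog projection; no PSI-MI XML.
* Identifier mapping is snapshot-based; no live HGNC/UniProt queries.
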