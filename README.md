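# pinot-ppi

Seed-centred integration, quality control and confidence scoring of
protein–protein interaction (PPI) evidence.

## The problem

No single curated database covers the PPI literature. A researcher who
wants "everything published about the interactors of my proteins" must
query several repositories (IntAct, BioGRID, MINT, …), each serving
PSI-MITAB records in a slightly different dialect, with different
completeness standards, and then merge, de-duplicate and quality-filter
the result by hand. This package automates that workflow: given a list
of query proteins (*seeds*, HGNC symbols or Swiss-Prot accessions for
human, `WBGene` IDs for *C. elegans*), it

1. collects binary interaction records per seed from seven PSICQUIC
   providers (bhf-ucl, BioGRID, InnateDB, IntAct, MBInfo, MINT,
   UniProt), live or from local files;
2. discards incomplete or ambiguous records — off-species rows, entries
   without a PubMed ID or with multiple PubMed IDs, entries without a
   detection-method annotation, interactors that do not map univocally
   to a (gene name, Swiss-Prot, Entrez) triple;
3. groups technically similar detection methods into categories using a
   conversion table (e.g. `MI:0018`, `MI:0397`, `MI:0398` are all one
   "Two Hybrid (2Hyb)" family);
4. merges the evidence into unique undirected seed-centred interactions
   and scores each one.

## The score

For an interaction *i* with merged evidence:

* **Method Score**  MS(*i*) = number of distinct method categories
  (counted after conversion-table reassignment);
* **Publication Score**  PS(*i*) = number of distinct PubMed IDs;
* **Final Score**  FS(*i*) = MS(*i*) + PS(*i*).

Every retained interaction has ≥ 1 method and ≥ 1 publication, so
FS ≥ 2 always; FS = 2 flags a single-study, single-technique
interaction with no independent replication, and larger FS indicates
replication across techniques and/or publications.

Two QC regimes are available: **lenient** (default) tolerates records
without taxonomy annotations and keeps out-of-table method codes as
singleton categories; **stringent** additionally discards both. The
stringent output is always a subset of the lenient output.

## Worked example

Generate a synthetic offline corpus (no network needed) and run the
pipeline on it:

```bash
pinot gen-fixtures --out fx --random-seed 7
pinot query --seeds fx/seeds.txt --out results \
    --offline fx/providers --mapping fx/mapping.tsv \
    --method-table fx/method_table.tsv
```

which prints:

```
wrote 116 records for 6 seeds under fx
{"n_records": 116}
seeds: 6/6 usable; records: 79/116 retained; interactions written: 31
```

meaning: the generator injected completeness defects into 37 of the 116
records (no PMID, multiple PMIDs, no method, wrong species, ambiguous
mapping), QC discarded exactly those, and the 79 surviving records
merged into 31 unique scored interactions. `results/` then contains:

* `final_network.txt` — tab-separated, 11 columns
  (`NameA SwissA EntrezA NameB SwissB EntrezB Method.Score Method
  Publication.Score PMIDS Final.Score`), one row per interaction,
  directly importable into Cytoscape with `NameA`/`NameB` as
  source/target nodes;
* `final_network_log.txt` — every discarded seed and record with a
  reason token;
* `final_network_providers.txt` — per-provider status
  (responded/failed/skipped) and record counts;
* `run_report.json` — machine-readable accounting of the run.

One data line of `final_network.txt` reads, for example:

```
SEED6	P10006	500006	PROT003	P20003	600003	3	Affinity Purification (AP);Structure (Struct);Two Hybrid (2Hyb)	3	30000018;30000019;30000021	6
```

an interaction between SEED6 and PROT003 supported by 3 distinct
technique families and 3 publications, hence FS = 6.

For *C. elegans*, queries are answered from a pre-processed
WormBase-style interactions dump instead of live providers
(`--species celegans --worm-dump <file>`); the output layout is the
same minus the providers log.

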