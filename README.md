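# targetfish

Ligand-centric target fishing: predict the protein targets of a query
molecule from the known targets of its most similar database molecules, and
benchmark that prediction per query as a binary classification over the
qualifying target universe.

The toolkit covers the full workflow:

- **activity_store** (`targetfish.activity`) — parse bioactivity tables
  (CSV/TSV, configurable column dialect) and apply qualification filters
  (activity type ∈ {EC50, Ki, Kd, IC50}, relation `=`, units nM, binding
  assays, top confidence, single-protein targets, potency ≤ threshold,
  minimum ligands per target) to build a molecule → known-target map.
- **similarity_engine** (`targetfish.similarity`) — 166-key structural
  fingerprints (via RDKit), Dice similarity `2c/(a+b)`, deterministic
  database ranking (ties broken by molecule id), and a plain-text
  fingerprint cache (`id<TAB>42-hex-chars`).
- **tf_predictor** (`targetfish.predict`) — predicted targets = the
  deduplicated union of the known targets of the top-k hits, with
  per-target hit support retained for reporting.
- **benchmark_eval** (`targetfish.benchmark`) — query/random-control
  partitions, per-query confusion matrices (TP/FP/FN/TN over the target
  universe), accuracy/precision/recall/MCC with explicit degenerate flags,
  boxplot-style summaries with Tukey outliers, neglected-target coverage
  rows, and Venn-style overlap reports.
- **synthetic_data** (`targetfish.synthetic`) — a chemogenomics simulator
  with chemical series, heavy-tailed promiscuity, log-uniform activity
  values and role-dependent observation masks, so the whole pipeline is
  testable without any external database.
- **cli_reports** (`targetfish.cli`) — the `targetfish` command.

## CLI

```bash
# generate a synthetic database with known ground truth
targetfish simulate --out sim/ --seed 7 --n-series 20 --activity-max-nm 5000

# filter an activity table into a known-target map + fingerprint cache
targetfish build-db --activities sim/activities.csv \
    --cache sim/fingerprints.tsv --threshold-nm 10000 --out db/

# predict targets for one query
targetfish fish --db db/ --query-id S000M00 -k 5
targetfish fish --db db/ --query-smiles 'CCOc1ccccc1' -k 5

# partitioned benchmark: per-query CSV, aggregate JSON, coverage CSV
targetfish benchmark --db db/ --queries sim/queries.txt --seed 11 --out bench/

# neglected-target coverage across method classes
targetfish coverage --db db/ --min-ligands 1 --min-ligands 5 --out coverage.csv
```

Every run writes a `provenance.json` (criteria, k values, seed, input
digests) sufficient to reproduce it. Structures can come from an
`id<TAB>smiles` file or an SDF; a fingerprint cache short-circuits
structure parsing. Unparseable or multi-component structures are reported
as unavailable, never raised.

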