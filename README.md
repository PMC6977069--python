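# segnet

Segregation analysis of annotated plankton co-occurrence networks.

`segnet` takes an annotated co-occurrence edge list (barcode pairs with
correlation scores, size-fraction/depth metadata and biotic/abiotic
driver labels), a barcode→lineage table, and a barcode×station
abundance table, and provides:

- **network_model** — typed data model and TSV/GraphML I/O; ordered
  first-match group assignment from lineage tokens; multi-stratum
  network merging.
- **segregation_stats** — per-group copresence/exclusion tallies,
  network shares, positive:negative (P:N) ratios and segregator
  classification; partner breakdowns by group or trophic mode; exact
  upper-tail binomial exclusion-enrichment tests (optional
  Benjamini–Hochberg adjustment); biotic vs abiotic driver partitions.
- **subnet_topology** — bipartite pair-subnetwork extraction and
  topology metrics: connected components, density, Freeman degree
  centralization, largest-component diameter, mean degree, normalized
  betweenness, exclusion-score strength, and Welch two-sample
  comparison of score samples.
- **genus_barcode** — genus connectivity vs read abundance, Spearman
  rank correlation with exact permutation p-values for n ≤ 8,
  per-barcode partner profiles, top-excluder ranking, station
  distributions with an endemicity index.
- **literature_db** — GloBI-style literature interaction CSV parsing
  with label/habitat normalization, hierarchical aggregation, habitat
  summaries, and genus-level overlap quantification against the
  network.
- **synthetic_data** — seeded generators for networks, abundance
  tables, and literature records with exactly planted ground truth
  (pair exclusion probabilities, endemic barcodes, literature overlap
  counts), so every stage is testable offline.
- **cli_report** — the `segnet` CLI and a full-report orchestrator.

## Test

```sh
python -m pytest -q tests/
```

The suite includes independent brute-force oracles (union-find
components, exhaustive shortest-path enumeration for betweenness, exact
rational binomial tails, full-permutation Spearman p-values) that the
implementations are checked against, plus parameter-recovery tests on
generated data.

## CLI

```sh
# generate synthetic inputs with known ground truth
segnet simulate --spec spec.yaml --out data/

# group-level tallies and segregator classification
segnet summarize --edges data/edges.tsv --annotations data/annotations.tsv \
    --group Bacillariophyta

# binomial exclusion enrichment for a group pair
segnet enrich --edges data/edges.tsv --annotations data/annotations.tsv \
    --focal Bacillariophyta --partner Copepoda

# pair-subnetwork topology report (+ optional GraphML export)
segnet subnet --edges data/edges.tsv --annotations data/annotations.tsv \
    --focal Bacillariophyta --partner Copepoda --graphml sub.graphml

# genus connectivity, barcode profiles, literature overlap
segnet genus --edges ... --annotations ... --abundance data/abundance.tsv \
    --group Bacillariophyta
segnet barcode --edges ... --annotations ... --id <barcode>
segnet litcompare --edges ... --annotations ... --litdb data/litdb.csv \
    --group Bacillariophyta

# run every stage from a YAML config into one JSON/TSV bundle
segnet report --config run.yaml
```

A simulation spec looks like:

```yaml
groups:
  - {label: Bacillariophyta, n_barcodes: 20, genus_pool: [Chaetoceros, Synedra]}
  - {label: Copepoda, n_barcodes: 25, genus_pool: [Oithona, Calanus]}
pair_params:
  - {group_a: Bacillariophyta, group_b: Copepoda, n_edges: 120,
     exclusion_probability: 0.6}
abiotic_fraction: 0.1
litdb_overlap: {n_records: 15, n_potential: 8, n_recovered: 3}
seed: 5
```

## File formats

- **Edge TSV**: `node_a, node_b, score, sign, size_fraction,
  depth_layer, driver, driver_parameter`. Sign is recomputed from the
  score and cross-checked; scores of exactly 0 are rejected.
- **Annotation TSV**: `barcode_id, lineage` (semicolon-separated
  ranks), `genus, species, trophic_mode`.
- **Abundance TSV**: barcode × station matrix of read counts.
- **Literature CSV**: `interaction_raw_label, diatom_genus,
  diatom_species, partner_class, partner_genus, partner_species,
  habitat, source_ref`; a `column_map` argument adapts foreign layouts.

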