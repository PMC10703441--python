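# crosspath

Genetics-driven cross-species comparison of gene sets and regulatory
networks. The pipeline maps gene sets (pathways, co-expression modules) into
GWAS marker space through tissue-specific eQTLs, scores them for enrichment
of strong association signal, merges redundant hits into supersets, matches
supersets across two species through a 1:1 ortholog table, and predicts key
driver genes by neighborhood enrichment on a directed gene-regulatory
network. A synthetic-data module generates every input with controllable
planted structure, so the whole pipeline is testable without external data.

## Method summary

- **Mapping** (`crosspath.mapping`) — eQTLs are filtered at FDR < 5% per
  tissue, eSNPs are pruned to one marker per LD block (keeping the smallest
  GWAS p-value), and each gene set becomes the pruned union of its members'
  eSNPs against a single global background.
- **Enrichment** (`crosspath.msea`) — each eSNP set is scored with a
  modified chi-square statistic summed over 10 log-spaced top-signal
  quantile cutoffs (top 50% … top 99.9%):
  `chi = sum_i (O_i - E_i) / sqrt(E_i + kappa)`, kappa = 1. Calibration is
  against eSNP sets mapped from randomly drawn gene sets of matched size
  (Gaussian tail by default, empirical tail via config), with
  Benjamini-Hochberg FDR across sets.
- **Supersets** (`crosspath.supersets`) — significant sets sharing >33% of
  genes with a Bonferroni-corrected one-tailed Fisher exact p < 5% are
  merged (connected components), re-tested, and annotated against a pathway
  collection by hypergeometric overlap.
- **Cross-species matching** (`crosspath.cross_species`) — supersets are
  translated through a 1:1 ortholog table; a pair matches when the adjusted
  hypergeometric p < 5% and either the Jaccard index is >50% or a one-sided
  overlap is >90%. Supersets with at least one match are shared, the rest
  species-specific.
- **Key driver analysis** (`crosspath.kda`) — candidate nodes (>= 5
  neighbors) are scored with the same `(O - E)/sqrt(E + kappa)` form applied
  to the superset-membership weight of their network neighborhood,
  calibrated by random node sets, BH-corrected; KD subnetworks are
  extracted, GWAS hits overlaid, and KD-trait correlations computed.
- **Simulation** (`crosspath.simulate`) — planted gene sets receive
  Beta(a, 1) GWAS p-values on their eSNPs (a = 1 is the null), LD blocks are
  index partitions, networks are preferential-attachment DAGs with planted
  hub drivers, and species pairs share an ortholog core with
  shared/specific planted sets. Everything is a pure function of its
  configuration and seed.

## CLI

Every stage is exposed under one entry point:

```bash
crosspath simulate --config sim.yaml --out bundle/
crosspath map   --gwas gwas.tsv --eqtl eqtl.tsv --ld ld.tsv --gmt sets.gmt \
                --tissue synthetic --fdr 0.05 --out esnp_sets.json
crosspath msea  --gwas gwas.tsv --eqtl eqtl.tsv --ld ld.tsv --gmt sets.gmt \
                --tissue synthetic --nperm 1000 --seed 7 --out msea.tsv
crosspath merge --msea msea.tsv --gmt sets.gmt --fdr 0.05 --ratio 0.33 \
                --gwas gwas.tsv --eqtl eqtl.tsv --ld ld.tsv --tissue synthetic \
                --out supersets.json
crosspath match --supersets-a a.json --supersets-b b.json \
                --orthologs orthologs.tsv --out matches.tsv
crosspath kda   --net network.tsv --supersets supersets.json --nperm 1000 \
                --seed 7 --min-neighbors 5 --out kda.tsv
crosspath subnet --kda kda.tsv --net network.tsv --top 5 \
                 --recent-hits hits_recent.txt --prior-hits hits_prior.txt \
                 --out subnet.json
crosspath run-all --config pipeline.yaml --out results/
```

`run-all` drives mapping → MSEA → supersets → cross-species matching → KDA
for one or two species from a single YAML file (paths, thresholds, grid,
seed); re-running an identical configuration reproduces byte-identical
outputs. See `tests/test_pipeline_cli.py::reference_pair` for a complete
configuration example.

### File formats

Tab-separated with headers: GWAS (`MARKER, PVALUE`), eQTL
(`MARKER, GENE, TISSUE, CIS_TRANS, FDR`), LD (`MARKER, BLOCK`), network
edge list (`SRC, DST[, WEIGHT]`), orthologs (`GENE_A, GENE_B`), expression
(genes x samples, first column `GENE`), trait (`SAMPLE, VALUE`); gene sets
as GMT. Stage outputs are plain TSV/JSON plus a run manifest.

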