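# difnet

Differential co-expression network analysis toolkit: given gene-by-sample
expression matrices for a control condition and one or more perturbations,
`difnet` nominates "core regulator" genes by chaining

1. **differential expression** — per-gene fold change plus Welch's t-test on
   `log2(value + pseudocount)`; default rule: `|log2fc| >= 1` and raw
   `P < 0.05` (Benjamini–Hochberg q values reported alongside);
2. **term enrichment** — one-sided Fisher's exact test of the DE set against
   GMT annotation terms, BH-corrected;
3. **candidate selection** — DE genes inside chosen (or automatically
   intersected) enriched "focus" terms, overlapped across perturbations;
4. **co-expression networks** — per-condition Pearson correlation on the log
   scale, pair p-values from the t-transform, edges kept at pairwise
   `FDR < 0.05`;
5. **hub nomination** — degree centrality, k-core numbers, the per-gene
   degree difference between control and perturbation ("dif degree"), genes
   with dif degree strictly above 8 selected per perturbation and
   intersected into the final core-regulator list.

The package also ships small assay quantifications (2^−ΔΔCt relative qPCR
expression, dual-luciferase ratio normalization, outcome-proportion and
germ-layer scoring arithmetic) and a **synthetic-data generator** that plants
co-expression modules, rewired hub genes, differential expression, and
enriched annotation terms — with a ground-truth manifest — so the whole
pipeline can be validated end to end without external data.

## CLI

```bash
difnet simulate --outdir sim/ --n-genes 200 --n-samples 30 --n-hubs 2 --seed 1
difnet de --matrix sim/expression_perturbed.tsv --conditions sim/conditions.tsv \
    --control-label control --perturbed-label perturbed --out de.tsv   # merged matrices also work
difnet enrich --genes de_genes.txt --gmt sim/annotations.gmt --out enrichment.tsv
difnet network --matrix sim/expression_control.tsv --conditions sim/conditions.tsv \
    --genes-file genes.txt --condition-label control --out net_control.tsv
difnet hubs --control-net net_control.tsv --perturbed-net net_perturbed.tsv \
    --dif-threshold 8 --out hubs.txt
difnet run-all --config config.yaml
difnet qpcr --table ct.tsv
difnet phenotype --counts counts.tsv --total 54
```

`run-all` takes a YAML file mirroring `difnet.pipeline.PipelineConfig`; see
`tests/test_cli.py::test_run_all_from_yaml` for a worked example.  Input
errors exit with status 2, statistical precondition failures with status 3.

## File formats (all plain text, tab-separated)

- **expression matrix**: header `gene_id<TAB>sample ids...`, one row per gene
  (nonnegative, linear-scale normalized values); companion two-column
  condition map `sample_id / condition`;
- **annotations**: GMT (`term<TAB>description<TAB>gene...`);
- **network**: `# condition=` / `# n_samples=` / `# nodes=` header comments
  followed by an edge table `gene_a gene_b r p_value q_value sign`;
- **truth manifest**: `[section]` blocks (`gene_ids`, `de_genes`, `modules`,
  `hubs`, `edges:<condition>`, `expected_dif_degree`).

## Simulator model (summary)

Log2-scale Gaussian latent-factor model, exponentiated to linear scale:
module members share a per-module factor calibrated to the requested
within-module Pearson correlation; each hub gene loads on the factors of a
"kept" and a "removed" partner group, and the removed-group loading is
replaced by equal-variance noise in the perturbed condition, so the hub
loses exactly `hub_degree − ceil((1 − rewire_fraction) × hub_degree)` planted
edges while every other marginal stays unchanged.  Factors are
orthogonalized in-sample so planted structure is not blurred by incidental
factor overlap at small sample sizes.  A fixed integer seed drives named
sub-streams per artifact; identical configurations reproduce byte-identical
outputs.
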