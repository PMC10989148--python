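# coexpanel

Detection of coexpressed gene panels from (meta)transcriptomic expression
matrices, using a graph neural network trained without labels, plus the
downstream analytics to interpret the panels.

The pipeline, per test condition (e.g. a light treatment vs. a dark control):

1. **Preprocess** — differential expression (Welch t-test on
   `log10(FPKM+1)` replicates, pseudocount log2 fold change; or an imported
   DEG table), DEG thresholds `|log2FC| > 1` and `p < 0.05`, then removal of
   DEGs with mean expression below 1 FPKM.
2. **Graph construction** — node features are the log-normalized expression
   columns (test + control replicates) concatenated with two binary
   subcellular flags (signal peptide, transmembrane domain). A 2D
   tSNE layout (perplexity 20, 1000 iterations, Barnes–Hut angle 0.4) gives
   pairwise distances; edges connect genes closer than a threshold that is
   bisected until the mean degree hits 5.
3. **Embedding** — a 2-layer GCN encoder over the self-loop-augmented,
   symmetrically normalized adjacency `(1−α)A + αI` (α = 0.8), trained by
   contrasting real node embeddings against a feature-permuted corruption
   through a bilinear discriminator and a mean-pooled graph summary. Pure
   NumPy with hand-derived gradients: no GPU or deep-learning framework
   needed, and training is bitwise reproducible per seed.
4. **Panels** — PCA then K-means on the embeddings for candidate cluster
   numbers {24, 10, 7}; the silhouette index (computed on the expression
   matrix) and the functional assignment score (FAS, a softplus statistic of
   how strongly a pathway concentrates into the top-k clusters) select the
   cluster number. Hierarchical and K-means baselines on raw features, with
   and without the subcellular columns, are included.
5. **Analytics** — keyword extraction of functional genes from descriptions,
   hub/signaling panel designation by plurality membership, per-panel
   pathway enrichment (Wilcoxon light-vs-dark, fold-change and expression
   filters), Pearson correlation topology networks (r ≥ 0.9, p ≤ 0.05) with
   Louvain modularity classes, standard node metrics, and top-3 landmark
   genes per class ranked by light-condition expression. Networks export to
   GEXF/GraphML.

A synthetic-fixture module generates planted datasets (coexpressed blocks,
a concentrated "Phototransduction" pathway, nitrate/nitrite keyword
descriptions, Bernoulli subcellular flags) so the whole pipeline is testable
offline.

## CLI

```sh
# planted synthetic dataset
coexpanel simulate --out fixture/ --n-genes 600 --seed 0

# end-to-end run (two test conditions vs dark control by default)
coexpanel run \
    --expression fixture/expression.tsv \
    --design fixture/design.tsv \
    --annotations fixture/annotations.tsv \
    --out run/ --seed 0
```

`run/` then contains, per condition: DEG tables, node features, the 2D
layout and edge list, embeddings and the training log, panel assignments for
every candidate cluster number, evaluation reports (silhouette + FAS),
panel designations, enrichment tables, correlation networks with metrics,
landmark-gene tables, and a `manifest.json` with seeds, thresholds, stage
counts and checksums (two runs with the same config and seed produce
identical manifests).

Stage verbs (`preprocess`, `build-graph`, `train`, `cluster`, `evaluate`,
`analyze`) run the pipeline up to that stage; `--config cfg.json|yaml`
supplies the full configuration (see `coexpanel.pipeline.PipelineConfig`).

## Input formats

- expression: TSV/CSV, first column gene id, sample ids in the header,
  values in FPKM;
- design: two-column TSV `sample<TAB>condition`;
- annotations: TSV with `gene_id, signal_peptide {0,1}, transmembrane {0,1},
  pathway` (semicolon-separated), `description`;
- optional DEG table: TSV with `gene_id, log2_fold_change, p_value,
  mean_expression, is_deg` (bypasses the built-in test).

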