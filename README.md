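# tnbc-targets

A tested, reusable re-implementation of a multi-omics target-discovery
pipeline for **triple-negative breast cancer (TNBC)** — the breast-cancer
subtype defined by absent estrogen-receptor (*ESR1*) and progesterone-receptor
(*PGR*) expression and no *ERBB2*/HER2 amplification. TNBC does not respond to
hormone therapy, so finding druggable proteins that are selectively
overexpressed in these tumors is a recurring analysis task for computational
oncology groups working with bulk RNA-seq, 450k methylation arrays and
protein-abundance panels.

The package is aimed at bioinformaticians who want each stage of such a
pipeline as a plain, testable Python function — and at anyone who needs to
validate a pipeline like this end-to-end without access to controlled data:
a synthetic-cohort generator plants known ground truth (latent receptor
status, differential genes, promoter methylation shifts, protein
concordance, a single druggable target) so every stage can be scored
exactly.

## What the pipeline computes

1. **Receptor status from expression.** For each marker gene the log2(x+1),
   upper-quartile-normalized expression is fit with a two-component Gaussian
   mixture (EM), either with equal ("E") or variable ("V") component
   variances. A sample is called positive when the posterior of the
   higher-mean component exceeds 0.5. The E/V choice per marker is the
   combination (out of 2³) with the highest pooled concordance against
   available immunohistochemistry labels. TNBC ⇔ all three markers negative.
2. **Differential expression.** One empirical-Bayes moderated-t engine
   serves every comparison. Per-gene variances s²_g (d = n_A+n_B−2 df) are
   shrunk toward a moment-matched prior (d₀, s₀²):

       s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),
       t_g = (x̄_A − x̄_B) / (s̃_g · √(1/n_A + 1/n_B)),  df = d₀ + d

   with Benjamini–Hochberg FDR, and gates |log2FC| ≥ 1 (two-fold) at
   FDR ≤ 0.05. Category enrichment uses Wallenius' noncentral
   hypergeometric distribution.
3. **Methylation.** β-values are quantile normalized and logit transformed
   to M-values (M = log2 β/(1−β)); probes are tested with the same
   moderated-t engine, annotated by CpG context (island / shore ≤ 2 kb /
   shelf 2–4 kb / open sea), linked to the nearest TSS, averaged per gene
   over promoter-island probes, and correlated against expression
   fold-changes (also binned genome-wide in 5-Mbp windows).
4. **Proteomics.** Protein log-abundance fold-changes from the same engine,
   correlated with mRNA fold-changes.
5. **Triage.** Genes upregulated in all three comparisons (TNBC vs
   non-TNBC tissue, TNBC vs normal tissue, TNBC vs non-TNBC cell lines)
   pass four sequential druggability gates — fewer than 2 publications,
   structure available, structure druggable, ligand-based druggability
   percentile ≥ 75 — and survivors are ranked by percentile.

## Worked example

Simulate a cohort (60 TNBC / 120 non-TNBC / 40 normal tissues plus 14 cell
lines, 2000 genes with planted effects) and run every stage:

```sh
$ tnbc-targets run-all --seed 11 --out demo/
TNBC call accuracy 1.000; common up 40 -> passing 1; meth-expr r -0.996; protein r 0.525
```

Every tumor's TNBC status was recovered from the expression mixtures; the 40
genes planted as upregulated in all three comparisons were all found; the
planted promoter-methylation shifts produce the expected strong negative
methylation–expression correlation; the protein fold-change correlation
lands on the generator's calibrated 0.5. `demo/manifest.yaml` records the
cascade:

```yaml
stage_counts:
  common_up: 40
  novelty: 32
  structure: 24
  druggable: 16
  percentile: 1
```

and `demo/triage.tsv` shows the single survivor — the planted target —
at rank 1:

```text
gene_id     in_common_up  pub_count  has_structure  structure_druggable  ligand_percentile  passes_all  rank
GENE00650   True          0          True           True                 95.35              True        1.0
GENE00708   True          24         True           True                 97.84              False
...
```

The same stages are available as subcommands on real tables (`normalize`,
`classify-markers`, `diffexp`, `enrich`, `methylation`, `integrate`,
`triage`) and as plain library functions; see `docs/methods.md` for the
model details and file dialects.

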