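# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `tnbc_targets`, in the spirit of a statistical methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Normalization

**Upper-quartile scaling.** Each sample's counts are divided by the 75th
percentile of its *nonzero* counts and multiplied by the across-sample mean
of those percentiles, so the 75th nonzero percentile is identical across
samples afterwards and the transform is idempotent. The quartile uses the
nearest-rank rule (index ⌈0.75·n⌉ of the ascending sort): it is exactly
reproducible across languages, unlike interpolating quantile definitions.
Restricting to nonzero counts follows common RNA-seq practice; whether the
quartile should include zeros is a genuine convention choice and is
documented here rather than asserted as the only option. An all-zero sample
is a hard error naming the sample.

**log2(x+1)** is applied after upper-quartile scaling and is the scale on
which both the mixture classifier and the moderated-t engine operate. Log
base 2 is used everywhere (expression, M-values, fold-changes).

**β ↔ M.** M = log2(β/(1−β)), with β clipped into [10⁻³, 1−10⁻³] first so
boundary values cannot produce infinite M. The clip width is a numerical
guard, not a biological statement; on the clipped domain the two transforms
are mutually inverse to ≲10⁻¹² and M→β maps all of ℝ into (0,1).

**Quantile normalization** replaces each sample's values by the
across-sample mean of order statistics at its ranks; ties within a sample
receive the mean of the reference values they span, so tied inputs stay
tied and the sorted vectors of all samples are bitwise identical
afterwards.

## Receptor-status mixtures

Each marker's log2 expression is modelled as a two-component Gaussian
mixture; component 2 is the higher-mean ("expressing") component by
relabeling. Modes: "E" ties the two variances, "V" frees them.

* **EM details.** Convergence when |Δ log-likelihood| < 10⁻⁸ or after 500
  iterations; the log-likelihood is non-decreasing every iteration (the
  test suite audits this from 100 random starting points). Variances are
  floored at 10⁻⁴ × the sample variance, which prevents singular components
  on tied values without ever being reached on non-degenerate data.
* **Initialization.** Sorted-data split at the median, component moments
  from the two halves; four further restarts jitter the split quantile
  uniformly in ±0.2 using the supplied seed; the best final log-likelihood
  wins. This makes fits deterministic given (data, seed) while still
  escaping poor local optima.
* **Calls.** A sample is positive when the posterior of component 2
  exceeds 0.5 (the Bayes rule); an exact tie is called negative, the
  conservative direction for TNBC inclusion (a borderline marker does not
  rescue a tumor from positivity). The cutoff is configurable
  (`posterior_cutoff`).
* **E/V selection.** All 2³ combinations are scored jointly by pooled
  concordance — the fraction of non-missing (sample, marker) IHC pairs
  whose mixture call matches — and the argmax is selected; ties break
  toward more E modes, then lexicographically in marker order. Pooling over
  markers (rather than per-marker selection) matches the notion of a single
  best combination of assumptions scored by overall agreement. With no IHC
  labels at all, every marker falls back to E with a logged warning.

TNBC status is the conjunction: negative for all three markers. Normal
tissues are never assigned a TNBC label.

## Differential expression

One engine serves tissues, cell lines, methylation probes and proteins: an
empirical-Bayes moderated two-sample t on log-scale values. The source
analyses this package re-implements used a negative-binomial Wald model for
tissue counts and a moderated t for arrays/proteins; collapsing onto one
fully specified statistic was a deliberate design decision — the gate
semantics (two-fold change, FDR ≤ 0.05) are preserved, and a single bespoke
engine is testable end-to-end, at the cost of not modelling count-level
dispersion explicitly (the log2(x+1) transform after upper-quartile scaling
stabilizes variances instead).

* Residual variances s²_g carry d = n_A + n_B − 2 df. The prior (d₀, s₀²)
  is estimated by moment matching on log s²: under s² ~ s₀²·F(d, d₀) the
  mean and variance of log s² have closed forms in digamma/trigamma
  functions; the trigamma is inverted by Newton iteration to tolerance
  10⁻⁸. When the spread of log s² does not exceed the sampling noise the
  prior df is infinite and s₀² is the arithmetic mean of the variances.
  Zero variances are excluded from prior estimation with a logged warning.
* The statistic's reference distribution is t with d₀ + d df, capped at the
  pooled residual df across genes (numerically a normal tail for large
  panels, but always a proper t). Two-sided p-values. The limit d₀ = 0
  reproduces the ordinary pooled t exactly; d₀ = ∞ is pure shrinkage. The
  test suite verifies the full path against limma's `eBayes` on a fixture
  to ~10⁻⁹.
* Fold-change sign convention: group A minus group B, and the pipeline
  always passes TNBC as group A, so positive log2FC means higher in TNBC.
* **BH adjustment** is the literal step-up rule q_i = min_{j≥i} m·p_(j)/j,
  clipped at 1, returned in input order.
* **Gates.** "up" ⇔ log2FC ≥ +1 and FDR ≤ 0.05, both inclusive;
  "down" symmetric. Thresholds live in `PipelineConfig`.
* **Enrichment.** Upper-tail probability under Wallenius' noncentral
  hypergeometric with odds ω = (mean gene weight inside the category) /
  (mean weight outside); the distribution itself is evaluated by
  `scipy.stats.nchypergeom_wallenius`. ω = 1 reduces exactly to the central
  hypergeometric tail. Weights default to 1: the original analyses do not
  specify their bias weights, so the interface is kept generic rather than
  guessing a gene-length model.

## Methylation

Differential methylation is the same moderated-t contract applied to
M-values; `delta_m` is the M-scale group difference, and the ±2
"fold-change" gates used elsewhere apply on this difference-of-logits
scale, the coherent analogue of probe fold-change after logit transform.

* **CpG context.** Distance to an island is 0 inside (intervals are
  0-based half-open; islands may overlap), otherwise the distance to the
  nearest interval edge with the right edge measured at the last contained
  base (end − 1). Context: shore ≤ 2000 bp, shelf ≤ 4000 bp (both
  inclusive, reading "up to 2 kb" and "2–4 kb" literally), open sea beyond.
  A chromosome without islands is entirely open sea.
* **Gene linking.** Nearest TSS on the same chromosome by absolute
  distance; ties (including several genes sharing a TSS) go to the
  lexicographically smallest gene id so results are order-independent.
  Gene-level methylation change averages `delta_m` over island-context
  probes within 2000 bp of the TSS. The 2 kb promoter window is a
  documented default — "TSS proximity" is not quantified in the source
  analyses — and is configurable per call. M-values (not β) are averaged,
  keeping the summary on the testing scale.
* **Binning.** Half-open bins [k·5 Mbp, (k+1)·5 Mbp) tile each chromosome
  from zero past the last datum; empty bins are emitted with NaN so tracks
  are gap-free; a value exactly on a boundary belongs to the higher bin.

Both interval operations are verified against brute-force all-pairs scans
on 10⁴ randomized probes/islands/genes in the test suite.

## Integration and triage

Common up/down sets are plain intersections of the per-comparison gene-id
sets; genes absent from any comparison cannot appear. Cross-layer
concordance is the Pearson correlation of fold-changes over shared genes
(error below 3 shared genes, where the quantity is undefined).

The druggability cascade applies four sequential gates to the common-up
set: publication count < 2 (novelty), structure available, structure-based
druggability, ligand-based percentile ≥ 75 (inclusive). Annotations are
consumed from a static per-gene table — live literature/structure-database
queries are irreproducible and out of scope; the cascade logic is the
computation. A missing percentile fails the percentile gate rather than
erroring (an unscored target cannot pass), and a gene with no annotation
row fails everything with a logged warning. Survivors get dense ranks
1..k by descending percentile, ties by gene id.

Knockdown effects from paired cell counts: with growth ratios
R = treated(t₁₉₂)/treated(t₉₆) and C = control(t₁₉₂)/control(t₉₆), cultures
that still grew (R ≥ 1) report percentage of proliferation 100·R/C;
cultures that shrank report percentage of cell loss 100·(1−R). The branch
point at R = 1 separates "died" from "proliferated less".

## Synthetic cohorts

The generator (`tnbc_targets.simulate`) produces the statistical structure
the analysis assumes, not a facsimile of real tumors:

* **Markers.** Per-marker two-component Gaussians on the log2 scale,
  inverse-transformed to counts (so the mixture is exact on the scale the
  classifier sees). Defaults: μ_neg = 5, μ_pos = 11, σ = 1 — components six
  pooled SD apart, i.e. three SD on either side of the decision boundary,
  keeping per-marker Bayes error ≈ 0.1% so triple-negative status is
  recoverable at the ≥ 98% level; reducing the separation populates the
  boundary region for model-selection studies. The variable-variance study
  condition uses σ_neg = 1.5, σ_pos = 0.5 for ER. Positive fractions
  (ER 0.7, PR 0.6, HER2 0.2 among non-TNBC tumors, conditioned on at least
  one positive marker) give a realistically ER-dominated cohort. IHC labels
  equal the latent component, flipped with probability 0.02 and hidden with
  probability 0.1 (typical clinical-annotation noise and missingness).
* **Counts.** Negative binomial parameterized by mean and dispersion α
  (variance μ + αμ²), α = 0.1 — typical bulk RNA-seq overdispersion.
  Baseline means are log-normal (median 2⁷ = 128, log2-SD 1.5); per-sample
  library factors are log-normal (log2-SD 0.25) so upper-quartile scaling
  has real work to do. Planted genes shift group means by ±2 log2 units
  (the pipeline's own two-fold gate, at an effect size the engine should
  recover nearly completely at the default group sizes). Each comparison
  gets its own exclusive up/down sets plus shared common-up/common-down
  sets planted in all three, making the triple intersection non-trivial;
  normals share the non-TNBC baseline except where TNBC-vs-normal genes
  are planted.
* **Cohort sizes.** Defaults 60 TNBC / 120 non-TNBC / 40 normal tissues
  and 8 + 6 cell lines, 2000 genes — small enough that a full pipeline run
  takes under a second, large enough for near-complete DE recall at the
  planted effect size. Cell-line receptor labels are recorded exactly
  (authenticated lines), so the cell-line comparison isolates DE behaviour
  from classification noise.
* **Methylome.** Half of the tissue-comparison up/down genes receive a
  500-bp promoter island containing the TSS with three probes inside;
  their TNBC M-values shift by −2 (up genes, promoter hypomethylation) or
  +2 (down genes), anti-correlating methylation with expression change.
  Background probes have bimodal baseline M (±3), per-sample noise SD 0.5;
  β is clipped to (0.001, 0.999). Islands are one-per-promoter by design —
  the simplest geometry exercising island/shore/shelf logic.
* **Proteome.** Protein = scale × log2 mRNA signal + Gaussian noise whose
  variance is calibrated from the observed spread of mRNA fold-changes so
  the expected protein–mRNA fold-change correlation equals `protein_corr`
  (default 0.5, in the range reported for tumor proteogenomics). With
  `protein_corr = 1` the noise is exactly zero.
* **Annotations.** Exactly one randomly chosen common-up gene passes all
  four triage gates (0 publications, druggable structure, percentile
  ≥ 95); every other common-up gene is assigned at least one failing gate.

What the generator does **not** emulate: real marginal count distributions,
batch structure, gene–gene correlation, chromosome-scale genome
organization, array probe chemistry (detection p-values, dye bias), or
survival outcomes. Passing tests therefore demonstrate that the
*computations* are correct and that planted structure of realistic
magnitude is recovered — not that the pipeline's biological conclusions
transfer to any particular real cohort.

Everything is deterministic under a fixed seed; sub-generators derive
offset seeds so the scenario writer is reproducible as a whole.

## Problem sizes in the acceptance checks

The acceptance studies use: 1000-tumor cohorts (5 seeds for accuracy, 50
for variance-model recovery); 20 replicates of 10 000 genes × 40 + 40
samples for FDR/recall calibration; 1000 random p-vectors for the BH
oracle; all hypergeometric tables up to N = 30 plus a 10⁶-draw weighted-urn
Monte Carlo for enrichment; 10⁴ randomized features for the interval
oracles; 5000/2000 genes for correlation recovery; and 20 full pipeline
runs for the end-to-end triage study. These sizes give comfortably
resolvable Monte-Carlo error at each stated tolerance while keeping the
whole suite fast.

## Known limitations

* One DE engine for counts and abundances: no negative-binomial dispersion
  shrinkage, no covariates/batch terms, no outlier handling.
* Enrichment weights are user-supplied; no gene-length or selection-bias
  model is estimated.
* No array preprocessing (the probe table is taken as already summarized
  β-values) and no island calling (islands are an input).
* The mixture classifier assumes exactly two components per marker and
  independence across markers; copy-number evidence for HER2 is not used.
* Ranking uses the ligand percentile only; no network, pocket-geometry or
  survival modelling.
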