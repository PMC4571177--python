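# xsmono

Cross-species conservation analysis of two-group transcriptomes, built
around the question: does the gene-expression response of circulating
monocytes to acute myocardial infarction (AMI) look the same in mouse and
human? The package is for computational biologists who have two two-group
expression studies (one per species), an ortholog table and a gene-set
compendium, and want a fully scripted, permutation-tested answer — plus a
synthetic-data generator with planted ground truth so every stage of the
pipeline can be validated before touching real data.

## What it computes

**Differential ranking.** Per gene, a pooled-variance two-sample *t* on
log2 intensities, linear fold change `2^(μ_t − μ_c)`, and ranked lists
under the signal-to-noise metric `(μ_t − μ_c)/(σ_c + σ_t)` (σ floored).
Significant-gene lists use strict thresholds, shipped as two named
profiles (FC > 1.5, p < 0.05 and FC > 2, p < 0.01).

**Gene-set enrichment (from scratch).** For a gene set *S* against a
ranked list *L* of length *N*, the running sum increments by
`|r_j|^p / N_R` at members (with `N_R = Σ_{j∈S} |r_j|^p`) and decrements
by `1/(N − N_H)` at non-members; the enrichment score ES is its signed
maximum deviation. Significance is an empirical permutation test
(phenotype-label shuffles, or random same-size gene sets when groups are
small), with the add-one convention `p = (1 + #{|ES_π| ≥ |ES|}) / (n_π + 1)`
over same-sign permutations. NES divides ES by the mean |ES_π| of the same
sign; the gene-set-level FDR *q* is the sign-stratified NES-ratio
estimate. Leading edges are the members at or before (ES ≥ 0) / at or
after (ES < 0) the running-sum peak. A single-sample (ssGSEA-style)
rank-weighted score is included.

**Cross-species conservation.** Each species' top-200 up-signature is
ortholog-translated and tested in the other species' ranked list
(reciprocal enrichment, 10,000 permutations). A shared compendium is
screened in both species; sets positively enriched at FDR < 0.01 in both
are intersected, and each gene's leading-edge occurrence count across the
shared sets is compared between species by Spearman correlation.

**Metagenes.** Leading-edge genes of the significantly enriched sets form
a binary occurrence matrix, clustered by average linkage on 1 − Pearson
distance (default two clusters); each cluster is annotated by a one-sided
hypergeometric test against an annotation GMT with Benjamini–Hochberg
correction.

**Synthetic studies.** `xsmono.simulate` generates paired cohorts (mouse
6 sham vs 6 AMI, human 24 control vs 30 AMI, ~20,000 genes, Gaussian log2
noise) with a planted conserved module shared through orthologs, optional
species-specific modules, and a compendium whose module-loaded fraction is
known — so recall, false-positive rate and representation correlation are
all measurable.

## Worked example

The numbered scripts under `analysis/` run the benchmark study (seed 1).
`analysis/01_simulate_cohorts.py` plants a 100-gene conserved module
(+1.5 log2 in the AMI groups of both species) and writes the data to
`scratch/benchmark/`; the later scripts print, among other things:

```
mouse [figure3] FC>2.0, p<0.01: 101 up, 106 down
human [figure3] FC>2.0, p<0.01: 99 up, 0 down
mouse_in_human: ES=0.641, NES=2.88, p=0.00015
human_in_mouse: ES=0.678, NES=3.20, p=0.00019
20 sets enriched in both species
leading-edge representation over 183 genes: rho=0.773 (r^2=0.598, p=1.2e-37)
metagene sizes at k=2: [158, 41]
cluster 0 (158 genes): top term TERM_CONSERVED_MODULE (k=94/100, q=7.4e-194)
```

Reading: both directions of the reciprocal test are strongly positive
(the planted response is "conserved"), the shared-set screen recovers
exactly the 20 module-loaded sets out of 200 with no false positives, the
per-gene leading-edge counts correlate across species, and the larger of
the two metagenes is annotated by the planted module's term. Recovery
against the planted truth (`analysis/06_evaluate_recovery.py`) reports
signature recall 0.99 (0.97 human-only, 0.40 mouse-only — six arrays per
group resolve far less than 24 vs 30), shared-set recall 1.0 and
false-positive rate 0.0.

The same pipeline runs on real data via a YAML config
(`xsmono run --config cfg.yaml`) or the stage subcommands
(`xsmono simulate|de|gsea|xspecies|metagenes`).

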