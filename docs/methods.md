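# Methods

## Problem and model

The pipeline asks whether the transcriptional response of a cell
population to a perturbation is conserved between two species. It takes
one two-group expression study per species (log2 intensities, genes ×
samples), a mouse→human ortholog table and a gene-set compendium, and
answers at three levels: single genes (differential expression), whole
signatures (reciprocal enrichment), and biological programs (shared
compendium sets, leading-edge representation, metagenes).

All inference is rank-based or permutation-based downstream of the
per-gene statistics, so the only distributional assumption that matters is
approximate exchangeability of samples within groups; the *t*-test
additionally assumes roughly Gaussian log2 intensities per gene.

## Differential expression and ranking

- Pooled-variance (Student) two-sample *t* per gene, two-tailed p; Welch
  available via `equal_var=False`. The treatment group is the AMI/case
  label; `log2fc = μ_treatment − μ_control`, `fold_change = 2^log2fc`.
- Degenerate genes (zero pooled variance) are flagged: equal means give
  t = 0, p = 1; unequal means give p = 0 with t = ±∞.
- Two strict-threshold profiles are shipped rather than one canonical cut,
  because both appear in practice: `methods` (FC > 1.5, p < 0.05) for
  permissive screening, `figure3` (FC > 2, p < 0.01) for headline counts.
  No multiple-testing correction is applied at the gene level; FDR control
  enters only at the gene-set level.
- Ranking metrics: `signal_to_noise` (default), `log2fc`, `t_stat`. The
  signal-to-noise denominator floors each group σ at
  max(σ, 0.2·|μ|, 0.2), the established convention for array data; it
  keeps constant genes finite and damps low-variance artifacts.
- Every ordering in the package breaks score ties by ascending
  lexicographic gene symbol, so outputs are identical across platforms.

## Enrichment engine

The enrichment score is the signed maximum deviation of the weighted
running sum (weight exponent p = 1 for two-group analyses; p = 0 recovers
the classic Kolmogorov–Smirnov form). Members absent from the ranked list
are dropped and counted; a set covering the whole list is rejected (the
miss penalty is undefined). If all member scores are exactly zero
(N_R = 0), hit increments fall back to uniform 1/N_H rather than 0/0. The
peak is the first index attaining the maximal |running sum|.

Permutation significance:

- *Phenotype* permutation shuffles sample labels and recomputes the metric
  and ranking per permutation — the default when both groups have ≥ 7
  samples. Below that (e.g. 6 vs 6, which admits only 924 distinct
  splits), the engine falls back to *gene-set* permutation (random
  same-size member sets on the fixed ranked list) with a warning.
- p uses the add-one convention over same-sign permutation scores, so it
  is a valid empirical p that never returns 0:
  P(p ≤ α) ≤ α + 1/(n_perm + 1) under the null.
- NES = ES / mean |same-sign permutation ES|; a set with no same-sign
  permutations gets NES = NaN and q = 1.
- FDR (`nes_ratio`): permutation ES are normalized per set by the same
  sign-stratified mean, pooled across sets, and q is the ratio of the
  pooled permutation tail fraction to the observed tail fraction at each
  set's |NES|, clipped to [0, 1]. A BH-style step-up pass (cumulative
  minimum from the weakest threshold upward) makes q monotone in |NES|
  within each sign stratum — running the pass in the opposite direction
  lets null sets inherit the q of strong sets, which a planted-truth
  audit exposes immediately. Benjamini–Hochberg on the permutation p is
  available via `fdr_method="bh"`.

The single-sample score ranks one profile (absolute expression or change
vs the control-group mean), weights member positions by rank^α with rank
running from N at the top to 1 at the bottom (α = 0.25), and integrates
the gap between the weighted member ECDF and the non-member ECDF. It
depends on the profile only through ranks, hence is invariant to monotone
transforms.

## Cross-species stages

- Ortholog translation is order-preserving and never silently drops
  genes: unmapped symbols are returned separately. Policy
  `table_then_casefold` adds a symbol-convention fallback (uppercase for
  mouse→human, title-case for the reverse) for tables with gaps. Two
  sources colliding on one target keep the first and log the collision.
- Reciprocal enrichment treats each 200-gene up-signature as a single
  fixed gene set in the other species' ranked list, so significance uses
  gene-set permutation (n = 10,000 by default). A signature less than half
  mappable is an error rather than a silent partial test. "Conserved" at
  level α means positive ES with p ≤ α in *both* directions.
- The shared-set screen requires positive ES and q < 0.01 in both species
  over a common translated compendium (sets losing all members in
  translation are excluded from both sides). The 0.01 threshold matches
  the leading-edge convention; the more permissive 0.25 compendium
  significance threshold is reported alongside.
- Representation counts each gene's appearances in the shared sets'
  leading edges, in human symbol space, and the Spearman correlation is
  taken over the union of represented genes with zero-filled absences —
  so species-specific leading-edge genes lower the correlation rather
  than being ignored.

## Metagenes

The occurrence matrix (leading-edge genes × significant sets, binary) is
clustered by average-linkage agglomeration on 1 − Pearson distance
between gene occurrence profiles; constant profiles are assigned distance
1 to everything. The default cut is k = 2 clusters; a height cut is
available. Over-representation per cluster is the one-sided
hypergeometric upper tail P(X ≥ k) with BH correction across terms, with
the universe set to all platform genes (after ortholog mapping when the
annotation is in the other species' symbols) — using only leading-edge
genes as the universe would build the answer into the question.

## Synthetic data

The generator emulates the target study design: mouse 6 sham vs 6 AMI,
human 24 control vs 30 AMI, ~20,000 genes per species. Per gene, a
baseline drawn from N(8, 2) log2 units plus i.i.d. N(0, 1) noise; a
conserved module (default 100 ortholog pairs) gains +1.5 log2 units in
the AMI samples of both species; optional species-specific modules do the
same in one species. Ortholog coverage defaults to 0.8 of the genome — a
realistic one-to-one mouse–human coverage — with module genes always
covered. The compendium (default 2,000 sets of 40–160 human symbols,
immune-compendium scale) contains a known 10% of "module-loaded" sets
(60% planted genes, capped so the planted share stays ≥ half) and pure
random sets. Optional per-sample effect multipliers ~ U(0.3, 1) emulate
the blunter group effect of a heterogeneous human cohort (off by
default).

What the generator does *not* emulate: probe effects, batch structure,
correlated co-expression beyond the planted modules, heavy-tailed noise,
and realistic gene-set overlap topology. Passing the recovery benchmark
therefore shows the pipeline's statistics behave as designed under the
stated design, not that any particular biological dataset would yield the
same counts.

### Benchmark and recovery metrics

The recovery benchmark (`benchmark_config`) keeps the full cohort and
genome sizes but uses a 200-set compendium (20 loaded / 180 random) so a
two-species screen at 1,000 permutations per set completes in well under
a minute per species on one core; the planted structure is unchanged.

`evaluate_recovery` reports signature recall per species and a headline
`signature_recall` that counts a planted ortholog pair as recovered when
either species' signature contains it. The cross-species stages consume
both signatures, so the module is available downstream if either cohort
surfaces it; the per-species numbers are always reported alongside
because they differ sharply — with 6 arrays per group the mouse
signal-to-noise ordering tops out near 0.4 recall at effect 1.5 and noise
σ = 1 (the null metric spread, ≈ 0.29, is comparable to the planted
mean of 0.75 across ~19,900 null genes), while the 24 vs 30 human design
reaches ≈ 0.97.

## Numerical and reproducibility choices

- Strict inequalities at every threshold; first-index tie-break at the
  running-sum peak; lexicographic tie-breaks in all orderings.
- Spearman p: *t*-approximation for n ≥ 10, exhaustive permutation
  enumeration below (the approximation is poor at small n); constant
  vectors are an error, not rho = 0.
- RNK scores are written with 17 significant digits and parsed with
  Python's exact float parser, so write∘read round-trips bit-exactly.
- Every stochastic stage takes an explicit seed; the pipeline derives
  fixed per-stage offsets from the config seed and a rerun of the same
  config produces a byte-identical `summary.json` (the output directory
  is excluded from the recorded config for this reason).

## Known limitations

- Gene-set permutation understates inter-gene correlation relative to
  phenotype permutation; with ≥ 7 samples per group prefer the latter.
- The NES-ratio FDR is an estimate, not a proof of control; the planted
  benchmark measures its behaviour (20/20 recovered, 1/180 false at
  q < 0.01 at seed 1) only under the simulated conditions.
- The duplicate-row collapse (max-mean) and ortholog fallback policies
  are pragmatic defaults for array data and symbol conventions; both are
  configurable and should be revisited for other platforms.
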