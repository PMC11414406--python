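# Methods

## The pleiotropy statistic

Counting DEGs overstates pleiotropy because coregulated genes respond as
blocks. `pleiokit` instead counts the number of coexpression modules in
which a knockout's DEGs disperse; the morphological analogue counts trait
clusters containing at least one significantly altered trait. Both counts
ignore unassigned items (module/cluster id 0) and are monotone under set
inclusion, so the pleiotropy of a subset of effects (e.g. the conserved
subset) can never exceed the overall value.

A background-A DEG is *conserved* when the same gene is also a DEG in
background B. The default rule requires significance in both backgrounds
but not direction concordance, because conservation is defined by
cross-background comparison of DEG calls rather than of signs; a
direction-matched rule (`significant_both_same_direction`) is available by
flag. The partition is exact: conserved + nonconserved counts always sum to
the A-DEG count. By default B is tested at the same thresholds as A;
`threshold_sweep` re-runs the partition over a grid of B-thresholds, where
loosening B monotonically grows the conserved sets.

## Differential expression

Per-gene counts follow a negative-binomial GLM with log link,
`K_gj ~ NB(mean = s_j * q_gj, dispersion = alpha_g)` and
`log q_gj = beta0 + beta1 * knockout_j`. Choices that matter:

* **Size factors** are median-of-ratios over genes expressed in every
  sample, reported unscaled (only ratios enter the model).
* **Fitting** is iteratively reweighted least squares, vectorized across
  genes (batched 2x2 solves), clipped at |log mean| <= 30 for stability.
* **Dispersion**: gene-wise estimates maximize the Cox–Reid adjusted
  likelihood (penalty `0.5*logdet(X'WX)`) on an 80-point log-spaced grid
  over [1e-8, 30] with parabolic refinement. Without the CR adjustment the
  small-sample ML estimates are biased low and the Wald test inflates. A
  parametric trend `alpha(mu) = a0 + a1/mu` is fit by nonnegative least
  squares to the interior gene-wise estimates; gene-wise values are then
  shrunk toward the trend in log space with prior variance 0.25 and an
  approximate sampling variance `2/(m - p)`. Gene-wise estimates that hit
  the grid boundary carry no information and take the trend value directly.
* **Wald test**: `beta1 / se(beta1)` against the standard normal, two
  sided; `se` from the expected information at the final fit. Under a
  2000-gene null simulation (dispersion 0.05, 2 vs 2 replicates) the
  empirical type-I rate at nominal 0.05 is ~0.05 (see
  `tests/test_acceptance.py`).
* **Fold-change shrinkage**: posterior mode under a zero-mean normal prior
  whose variance is the empirical spread of raw estimates in excess of
  their median sampling variance — the precision-weighted ridge estimate.
  This is a deliberately simple stand-in for heavier-tailed priors; the
  raw fold change is always reported alongside, and the DEG gate
  (`fc_source`) can use either (default: shrunk).
* **DEG thresholds** default to fold change > 1.2 in either direction and
  BH-adjusted p < 0.01, applied within each contrast over the analyzed
  gene set.

No exact replication of any external DE tool's numerics is attempted; the
model class and the calibration, not bit-level agreement, are the contract.

## Preprocessing

TPM is computed per sample (`1e6 * rate / sum(rates)`, rate = count/length);
columns sum to 1e6 by construction. The analyzable gene set keeps genes
with mean wild-type TPM >= 1 — evaluated in each background's own wild
type when both are analyzed — minus a user-editable exclusion list
(shipped default: the uracil-biosynthesis pathway genes, perturbed by the
URA3 selection cassette rather than by the deleted TF). The >= boundary is
deliberate: a gene at exactly TPM 1 is retained. Batch correction operates
on log2(TPM + 1) (pseudocount configurable) by per-gene least squares with
intercept, batch indicators, and optional group covariates; the batch term
is recentred to mean zero before subtraction, so a planted constant offset
is removed exactly. A batch confounded 1:1 with a biological group makes
the design rank-deficient and is refused.

## Coexpression modules

Input profiles are replicate-averaged, batch-corrected log2 TPM per strain,
clustered per background. The pipeline is unsigned adjacency `|cor|^power`
(signed-hybrid by flag), standard unsigned topological overlap, average
linkage on TOM dissimilarity, a static cut, a minimum module size of 10,
and merging of modules whose eigengene dissimilarity (1 - correlation of
first principal components) falls below 0.1. Numerical choices:

* **Static cut** at 0.98 x the tallest merge height (`cut_height="auto"`).
  On block-structured data the merge-height distribution has a plateau of
  near-unit dissimilarities (unrelated genes); a quantile-based cut lands
  inside that plateau and fuses everything, whereas a fraction-of-maximum
  cut separates planted blocks from it. An explicit numeric height is
  accepted.
* **Soft power** defaults to 6, the conventional unsigned-network choice
  at a few dozen samples. The scale-free criterion
  (`pick_soft_threshold`, smallest power with signed fit R^2 >= 0.8, else
  the maximizing power) is available as `"auto"` but is unstable on small
  strain panels: its fallback can select extreme powers that zero out the
  network.
* Zero-variance genes are dropped to id 0; module ids are renumbered by
  decreasing size; eigengenes are sign-oriented to correlate positively
  with the mean member profile. Merging is idempotent.

## Morphology

Observations are quantile-normalized across traits (rank-average ties;
constant columns map to the median reference value). Trait clustering uses
affinity propagation on negative squared Euclidean distances between
knockout-averaged trait profiles, per background, with the median
similarity as shared preference, damping 0.9, a 50-iteration convergence
window and at most 2000 iterations; non-convergence raises rather than
returning a partial answer.

Altered traits are tested per (TF, trait) with a linear mixed model —
fixed mutation effect, random intercept per biological replicate, fit by
maximum likelihood because the likelihood-ratio test targets a fixed
effect — against the same-batch wild-type controls; singular fits fall
back to fixed-effects ANOVA. Two named threshold profiles exist because
the source conventions differ: `"methods"` (p < 0.01 plus a fold-change
gate) and `"results"` (p < 0.05 only). Every call and every report names
its profile; there is no silent default. The fold-change gate is two-sided
(`max(FC, 1/FC) > threshold`) since a one-sided reading would discard all
trait decreases; the default threshold 1 means "any change".

## eQTL ages

A marker polymorphic between the focal backgrounds is polarized by
unanimity: the allele carried by every Taiwanese-lineage strain and the
outgroup is ancestral, the other focal allele derived; any disagreement or
missing call leaves the marker unresolved (absence of evidence is treated
conservatively — CHN, TW and outgroup states must all be observed).
Classification is a pure function of presence patterns: *old* if the
derived allele occurs in any Chinese-lineage strain; *new* if it is
confined to the BY lineage or to the RM lineage; derived alleles in both
focal lineages or only in other clades stay unclassified (and are counted
in logs). New/old contrasts on affected-gene counts and variance explained
use a two-sided Wilcoxon rank-sum test: exact by full enumeration (valid
under ties) when both classes have <= 10 members, otherwise the
tie-corrected normal approximation.

Chi-square tests on contingency tables omit the continuity correction
(counts in the intended comparisons are large); Fisher's exact test is
offered for small tables. GO-term enrichment uses the hypergeometric upper
tail with the enrichment rule fold > 2 and p < 0.05. Proportions are
reported as percentages to one decimal.

## The synthetic-data generator

The generator emulates a two-background TF-knockout study at desk scale
and plants ground truth for recovery testing. One global seed drives a
hierarchical stream with one substream per dataset kind (expression,
morphology, panel), so regenerating one dataset never perturbs another,
and a fixed seed fixes every artifact bit for bit.

**Expression** (defaults): 600 genes, 6 planted modules of 80 genes, 20
TFs x 2 backgrounds x 2 biological replicates, NB dispersion 0.05,
baseline log2 counts ~ N(7, 1.5). Gene-level structure on the log2 scale:
baseline + module loading x per-strain factor score + knockout effect +
per-batch offset (SD 0.3, gene-independent, hence exactly removable by the
batch stage). Each knockout plants 30 DEGs at |log2FC| = 2, of which
round-half-up(0.15 x 30) = 5 are shared between backgrounds, drawn from
the TF's home module (conserved effects are compact); the background-
specific remainder is scattered genome-wide with random signs. Conserved
effects of activators are negative (targets drop on knockout), of
repressors positive. The module amplitude defaults to 0.3 log2 units
(~1.23-fold): large enough for modules to be detectable across strain
means over replicate noise, small enough that strain-level coexpression
variation does not itself exceed the 1.2-fold DEG gate — the regime in
which a knockout study is interpretable at all.

**Morphology**: 184 traits in 28 planted clusters sharing per-observation
latent factors (within-cluster correlation 0.7), baseline 10, unit trait
SD, 3 biological x 3 technical replicates with a per-biological-replicate
random intercept (SD 0.2) and per-batch offsets (SD 0.1) — the structure
the mixed model assumes. Knockout alterations shift 20 traits by 5 SD in
both backgrounds.

**Allele panel**: 2 BY-lineage, 2 RM-lineage, 5 Chinese, 3 Taiwanese, 21
other and 1 outgroup strain; 55% of markers planted "new" (derived allele
confined to one focal lineage), the rest "old" (derived allele in all
Chinese strains, one focal lineage, and ~30% of other strains); Taiwanese
strains and the outgroup always ancestral. Affected-gene counts are
1 + Poisson (mean 3 for new, 1.5 for old); variance explained is Beta
(means ~0.07 new, ~0.25 old). The real eQTL effect distributions are not
published at this granularity; these placeholders exist for
parameter-recovery testing, not for quantitative comparison.

**What passing tests do and do not show.** The generator produces clean
biallelic calls, independent markers (no linkage), module structure from
orthogonal latent factors, and NB counts with a smooth mean-dispersion
trend. Real data add linkage disequilibrium, overlapping regulatory
programs, dispersion outliers, missing genotype calls and batch-by-group
interactions; recovery on the generator therefore validates the
*machinery* (calibration, partition exactness, classifier logic), not
field performance on any particular organism's data.

## Problem sizes

The shipped tests and `scripts/acceptance.py` run the recovery study at
600 genes / 20 TFs, the DE null calibration at 2,000 genes, module
recovery at 100 genes x 40 strains, the mixed-model calibration at 1,000
trait draws and the allele panels at 500–600 markers — sizes chosen so
every planted signal is comfortably identifiable while a full run stays in
the minutes range on one CPU.

## Known limitations

* The NB Wald test assumes enough genes (hundreds) to fit the dispersion
  trend; on very small gene sets the trend degrades to a constant.
* Fold-change shrinkage uses a normal prior; very large true effects are
  shrunk more than a heavy-tailed prior would — the raw estimate is the
  escape hatch.
* The mixed model treats technical replicates as exchangeable within a
  biological replicate; nested technical structure beyond one level is not
  modelled.
* Module detection at 21 strains is power-limited; detected modules split
  planted ones before they mix them, which biases pleiotropy counts upward
  for scattered sets but preserves the conserved/nonconserved contrast.
* eQTL classification requires complete CHN/TW/outgroup calls; panels with
  heavy missingness will classify few markers.
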