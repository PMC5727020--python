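# Methods

## Design being modelled

A cohort of young and aged rats is characterised on cue and spatial
water-maze tasks (five blocks of three trials each) followed by a
free-swim probe trial. Hippocampal subfields CA1, CA3 and DG are
dissected from every animal, and the same RNA is profiled on two
sequencing platforms: a deeper "A" (discovery) platform and a "B"
(validation) platform with different chemistry, lower effective depth and
extra technical noise. All downstream statistics operate on gene-level
count matrices; alignment and quantification are out of scope.

## Behavioral measures

* Learning curves are summarised as percent change of mean escape path
  length from the block-1 baseline; block 1 is 0 by construction and
  negative values mean improvement.
* The probe-trial discrimination index is DI = (G − O)/(G + O), with G
  and O the percent time in the goal and opposite quadrants. DI ∈ [−1, 1],
  0 is chance. It is undefined (an error) when G = O = 0.
* Aged animals are classified against the **minimum DI among young
  animals of the same cohort**: below the cutoff → aged-impaired (AI),
  otherwise aged-unimpaired (AU). The comparison at exact equality is not
  defined by the rule's usual statement (AI: DI < cutoff; AU: DI >
  cutoff); we assign the unimpaired label at equality, the conservative
  choice. Note the cutoff is an extreme order statistic: its sampling
  distribution depends strongly on the number of young animals, so
  classification behaviour is only meaningful at a stated cohort size.
* The cue-task mean split assigns animals at or below the mean block-5
  path length to the better-performing ("good") group; ties go to "good"
  since a larger path length is worse.

## Differential expression engine

A deliberately transparent, simplified DESeq2-style negative-binomial
Wald test. Per two-group contrast:

1. **Normalization** — median-of-ratios size factors computed on the
   contrast's samples (reference: geometric mean over genes with nonzero
   counts in all samples). A single sample gets factor 1. Only factor
   *ratios* are identifiable; rescaling a sample's counts by c multiplies
   its factor by c relative to the others.
2. **Detection** — a gene is detected on a platform when it has nonzero
   counts in ≥ 3 of the contrast's samples (configurable). Undetected
   genes carry no statistics and are excluded from the BH family.
3. **Dispersion** — method of moments on normalized counts,
   α = max((s² − m)/m², 10⁻⁸), estimated **within groups** and pooled by
   degrees of freedom. The plain across-sample estimator absorbs the
   (true or chance) group-mean difference into apparent overdispersion;
   measured on a 10,000-gene null at 12 animals/group it makes the test
   conservative and detectably non-uniform, which is why the group-aware
   form is the engine's default. The plain estimator is kept as
   `estimate_dispersion` for descriptive use.
4. **Fit** — the two-group model is saturated, so each group's mean
   solves a 1-D NB score equation by damped Newton iteration (tolerance
   10⁻⁸ on the log-mean, max 100 iterations). All-zero groups are clamped
   at a normalized-mean floor of 10⁻⁶, where the Fisher information
   vanishes and the Wald test is conservative by construction;
   non-converged genes are flagged, logged and excluded from p-values.
5. **Test** — log₂FC = log₂(q₂/q₁) oriented level2-vs-level1, SE from the
   inverse Fisher information of the two independent group fits, and the
   Wald statistic referred to **t with n_samples − 2 df** rather than a
   normal. The t reference absorbs the plug-in noise of the estimated
   dispersion (the exact analogy of using t rather than z in a linear
   model with estimated variance). Empirically, with a normal reference
   the same 10,000-gene null fails a KS uniformity test (p ≈ 2·10⁻⁴);
   with the t reference p-values are uniform (KS p ≈ 0.3–0.65) and the
   type-I error at 0.05 is nominal.
6. **Multiplicity** — Benjamini–Hochberg step-up per contrast and
   platform over detected, converged genes.

Deliberately omitted relative to full DESeq2: Cox–Reid adjusted
likelihood, dispersion-trend and LFC shrinkage, independent filtering,
outlier replacement, multi-factor designs. The downstream staged
validation only consumes (log2fc, p) pairs and is agnostic to these
refinements.

## Staged cross-platform validation

* **Seed list** (platform A): detected genes with raw two-tailed
  p < 0.01 and nonzero log₂FC. The seed threshold is raw, not adjusted:
  the design pairs it with a second-stage test, and its printed contrast
  with the BH-adjusted subfield threshold supports that reading. Each
  seed gene fixes a direction hypothesis.
* **Validation** (platform B): one-tailed p < 0.05 in the seed direction,
  computed as p₂/2 when the observed sign matches, 1 − p₂/2 when it is
  opposite, and 1 at exactly zero fold change. Seed genes undetected on B
  stay in n_seed and fail validation.
* **Combined level**: under independent nulls, a gene passes stage 1 with
  probability 0.01 and stage 2 with probability ½·0.1 = 0.05 (the
  coin-flip direction match halves the 0.1 two-sided mass), so the joint
  per-gene level is 0.01 × 0.05 = 5·10⁻⁴. `null_calibration` verifies
  this by direct simulation. The independence assumption is approximate
  when both platforms sequence the same RNA; the formula is implemented
  as defined and this caveat is the user's to weigh.
* **Empirical FDR** of a validated list: n_seed × 5·10⁻⁴ / n_validated
  (expected null survivors over observed survivors). Undefined at
  n_validated = 0 and reported as not-computable, never as 0 or ∞.
  Logged at two significant figures, stored at full precision.

## Subfield signatures

For each ordered region pair (CA1,CA3), (CA1,DG), (CA3,DG), the two
platforms' tables are joined; a gene is *mutual* (detected both),
*significant-both* (BH adj-p < 0.05 on both) and *concordant* (same
nonzero FC sign), with n_discordant ≡ n_significant − n_concordant. A
gene is called region-specific when it is significant and
direction-consistent against both other regions on both platforms (four
tables). "Average FC" is the mean of log₂ fold changes — averaged within
platform first, then across platforms, so each platform counts equally —
and the pre-enrichment filter keeps |avg log₂FC| > 0.50 strictly. A gene
can satisfy the criterion in two regions (highest in one, lowest in
another); it is called in both and flagged `multi_region`. Discordant
genes can never be signature candidates (they fail concordance by
definition).

## Over-representation analysis

One-sided hypergeometric upper tail P(X ≥ k) for a study list of size n
against a universe of N assayed genes, per gene set (K = members in
universe). The universe is the genes detected on both platforms for the
relevant comparisons, not a whole-genome annotation — enrichment against
an unassayed background inflates significance. Both Bonferroni and BH
adjusted p-values are reported, matching the two portal conventions in
common use. Database snapshots are user-supplied GMT files; no live
queries.

## Synthetic study generator

`simulate_counts` draws counts gene-wise from NB(μ, α) with
μ_gs = s_sample · q_gene · 2^(planted log₂ effects), variance μ + αμ².

Defaults (all configurable; chosen to emulate the target design):

| parameter | default | meaning |
|---|---|---|
| n_genes | 20,000 | transcriptome-scale gene count |
| animals | 10 young, 12 AU, 12 AI | cohort of the emulated study |
| baseline log-mean/sd | 4.0 / 1.5 | log-normal q_gene, median ≈ 55 counts |
| dispersion log-mean/sd | −2.5 / 0.6 | log-normal α, median ≈ 0.08 (bulk-tissue typical) |
| frac region/age/cognition | 0.10 / 0.05 / 0.05 | disjoint truth classes |
| effect size | 1.0 log₂ unit | planted |log₂FC| |
| age region weights | CA1 0.5, CA3 0.5, DG 1.0 | aging signal largest in DG |
| age direction | 80% up | aging skews toward induction |
| cognition region | CA1 | impairment signal placed in CA1 |
| platform B libsize factor | 0.7 | validation platform is shallower |
| platform B extra dispersion | +0.05 | validation platform is noisier |
| dropout rate | 0.02 | gene undetected on exactly one platform |
| library size log-sd | 0.2 | per-sample depth variation |

Truth classes are disjoint so recovery metrics are unambiguous.
Region-specific genes shift one region in all animals; age genes shift
aged samples in all regions scaled by the region weights; cognition genes
shift AI samples in one region. Because age effects differ across
regions, they leak slightly into subfield contrasts (as they would in a
real animal); recovery tests therefore compare each class against nulls
on its own contrast. Behavior: path lengths decay exponentially toward a
floor (young rate 0.7/block, aged 0.35/block, log-normal noise sd 0.15);
probe quadrant percentages are Dirichlet draws over four quadrants with
concentrations (20, 8, 8, 7) for young/AU (E[DI] ≈ 0.48) and
(12, 11, 11, 11) for AI (E[DI] ≈ 0.04), yielding a young-minimum cutoff
near 0.2–0.25 at the default cohort size and class orderings
young ≈ AU > AI.

What the generator does **not** emulate: GC/length biases, correlated
gene modules, batch effects beyond the platform contrast (site is carried
as a label only), overlapping truth classes, read-level error. Passing
tests therefore demonstrate the statistical machinery on an idealised
NB world, not robustness to those artefacts.

## Problem sizes used by the test suite

Unit tests run on 200–2,000-gene fixtures; the calibration check uses a
10,000-gene null cohort at 12 animals/group; fold-change recovery uses
4,000 genes at 50 animals/group; staged-validation recovery uses
1,500-gene cohorts at three effect sizes; the null joint-pass-rate
simulation uses 2,000,000 genes (it is closed-form per gene and
vectorised, so it completes in seconds). These sizes give Monte-Carlo
error comfortably inside the asserted bands while keeping the default
suite fast.

## Known limitations

* The Wald test is conservative for groups with all-zero counts
  (information → 0); a likelihood-ratio or exact test would be needed
  there.
* The empirical FDR formula assumes cross-platform independence of null
  p-values; shared RNA violates this in an unquantified direction.
* The min-young-DI cutoff makes classification cohort-size dependent;
  comparisons across cohorts of different sizes are not exchangeable.
* No multi-factor or interaction designs: every question must be posed
  as a two-group contrast on a sample subset.
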