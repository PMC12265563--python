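# Methods

This note documents the statistical models, numerical conventions and design
choices behind `splicediv`, and what the synthetic-data experiments do and do
not demonstrate about real data.

## PSI model and the differential-splicing LRT

An event's per-sample PSI is the length-normalised inclusion fraction
ψ = (I/l_I)/(I/l_I + S/l_S); Δψ between groups is the difference of
per-group means over informative samples (samples with I + S = 0 are
dropped; an event is untestable when a group has fewer than two informative
samples). Effective form lengths are small integers (e.g. a skipped-exon
inclusion form spans two junctions, the skip form one), so equal lengths
reduce ψ to I/(I+S) exactly.

Significance comes from a likelihood-ratio test on the counts. Each
sample's (I, S) is binomial with inclusion-read probability
p(ψ) = ψ·l_I/(ψ·l_I + (1−ψ)·l_S); the null shares one ψ across groups, the
alternative fits one ψ per group, and the statistic is referred to χ²₁.
Because p(ψ) is a monotone bijection for fixed lengths, the maximum-likelihood
fits come in closed form from pooled counts, which keeps the scan fully
vectorised. This is a deliberate, documented replacement for the hierarchical
model inside rMATS-style tools: it captures the same length-aware PSI
contrast with a transparent likelihood, but makes no attempt to reproduce any
external tool's p-values numerically.

Two practical consequences are worth knowing:

* **Overdispersion.** The binomial LRT assumes counts at the binomial limit.
  On overdispersed replicates it overcalls; the `betabinom` variant (shared
  method-of-moments concentration, ψ maximised numerically per group)
  restores conservatism at some power cost. Calibration experiments for the
  binomial test are therefore run in the generator's binomial limit — its
  matched null — where the 5%-level rejection rate sits in [0.03, 0.07] and
  p-values are near-uniform (KS distance well under 0.05 at 2,000 events,
  depth 100, n = 5 per group).
* **Coverage filter.** Events are testable when every sample has
  I + S ≥ 10 (config-exposed; the regulatory-assignment stage raises this to
  20 to match its read-support rule). Untestable events carry missing
  p-values and are excluded from FDR adjustment.

BH adjustment is standard step-up (via statsmodels), pooled across event
classes by default. Calls use q < 0.05, optionally with the conservative
|Δψ| ≥ 0.10 magnitude filter; the per-gene representative event is the
significant event with the largest |Δψ|.

## Allele-specific splicing

Hybrid data arrive as paired per-replicate (I, S) counts for the two parental
alleles. The read-support rule — at least 20 supporting reads per replicate —
is applied at event level as min over alleles of I + S per replicate, a
conservative proxy for per-junction filtering (counts here are already
event-aggregated). The ASAS test is the same LRT contrasting allele-1 vs
allele-2 counts across the paired replicates, pooled without a random-effect
term; allelic Δψ is the difference of mean allelic PSIs. Swapping allele
labels flips the sign of allelic Δψ and leaves the p-value unchanged.

## Cis/trans assignment

Ratios are natural-log PSI ratios with pseudocount ε = 0.01 on PSI
(symmetric, zero-safe; config-exposed). For hybrid alleles (paired within
animals) the estimate is the mean of per-replicate log ratios with
SE = sd/√n; for parents (independent groups) it is the log ratio of group
means with a delta-method SE. The difference D = L_P − L_H is tested with
Z = D/√(SE_P² + SE_H²) against a standard normal, two-sided.

The decomposition cis = L_H, trans = L_P − L_H is additive by definition.
Categories come from three BH-thresholded flags at FDR 0.05 — parental
difference (from the parental LRT), allelic difference (from the ASAS test),
ratio difference (from Z): cis-only = parents and alleles differ but the
ratios agree; trans-only = parents differ, alleles do not, ratios differ.
These two rules are the core of the assignment; the remaining grid
(cis+trans for same-sign significant components, compensatory for
opposite-sign or parent-silent patterns, conserved, ambiguous) is a
McManus-style extension provided for completeness and labelled as such in
the output. Unequal group sizes can be equalised by seeded random dropping
(default target 5 per group, matching the study design).

**Known limitation — small-sample size of the Z test.** With n = 5
replicates the replicate-based SEs are themselves noisy, so the nominal-5%
Z test behaves like a Welch t with ≈ 8 degrees of freedom read against a
normal: its true size is ≈ 0.085–0.09, converging to the nominal level as
replication grows (≈ 0.056 at n = 20). This mild anti-conservatism is a
property of the published construction, not an implementation artefact; it
slightly inflates the ratio-difference flag and hence the compensatory bin.
Count-level SEs or a t reference would calibrate exactly but would change
the method.

Cis-by-diet interactions reuse the Z machinery on L_H(HF) vs L_H(STD),
BH-adjusted and reported at FDR < 0.1 (interaction power is limited, hence
the looser headline threshold). Cross-diet stability of the cis and trans
components is quantified by Spearman correlation; the comparison of per-gene
diet divergences |log2FC(HF) − log2FC(STD)| between components uses the
Wilcoxon signed-rank test (zeros dropped; exact null for n ≤ 25 without
ties, normal approximation with continuity correction otherwise). log2
fold-change proxies are L/ln 2 of the respective component.

## Selection scan

Per-site Fst uses the Weir & Cockerham (1984) two-population
variance-components estimator computed from per-population genotype tallies
(sample sizes, allele frequencies, observed heterozygosity). Sites enter the
scan when they are biallelic SNPs polymorphic across the three-population
union with at least six genotyped focal individuals. Blocks are five retained
SNPs in genomic order per chromosome (trailing partial blocks dropped); block
Fst is the ratio of summed components Σa/Σ(a+b+c) — the standard WC
recommendation — with negative per-site components entering unclipped and
only the block ratio clipped to [0, 1 − 10⁻⁶] so branch lengths
T = −ln(1 − Fst) stay finite. Per-branch PBS values are floored at zero
before the normalisation PBSn1 = PBS_A/(1 + PBS_A + PBS_B + PBS_C). Outliers
are the top 1% of focal PBSn1 (ties at the threshold included); no
neutral-model p-values are attached. Gene intersection is half-open interval
overlap (≥ 1 bp), BED conventions throughout (VCF positions stay 1-based).

## Pleiotropy contrasts

Tissue breadth counts tissue-timepoint columns at FPKM ≥ 3 (cut-off read
inclusively); interaction degree counts distinct partners over edges scored
strictly above 0.7 (duplicates collapsed, self-loops dropped); term counts
are distinct ontology terms per gene. Permutation tests shuffle group labels
(default 10,000 times) and use the +1-corrected two-sided p, so p is never
zero and exhaustive enumeration is available for small instances. Fisher
overlap tests are two-sided exact tests (tail = sum of hypergeometric point
probabilities ≤ the observed table's). Expression binning drops genes under
20 mean reads and forms five quantile bins with deterministic tie-breaking
by input order.

## Synthetic-data generator

The generator emulates the study design, not the sequencing process: no
reads, alignments or mapping bias — junction counts and allele frequencies
are simulated directly.

* **Splicing counts.** Total event depth per sample is log-normal around
  `depth_mean` (σ = 0.5); the inclusion/skipping split is beta-binomial
  around the length-weighted inclusion probability. The default
  concentration of 50 produces realistic replicate overdispersion; setting
  it to `None` gives the clean binomial limit used for calibrating the
  binomial LRT. Baseline PSI is uniform on [0.2, 0.8] ([0.3, 0.7] for the
  F1 design) so planted ±Δψ/2 shifts stay interior after clipping.
* **Effects.** A configured fraction of events gets a strain effect of
  magnitude `effect_dpsi` (random sign), optionally diet-specific (present
  on the high-fat diet only). F1 data plant cis-only (parental difference
  riding with the hybrid allele), trans-only (parental difference with
  equal hybrid alleles), and cis-by-diet (cis pattern on HF only) events.
  Default recovery experiments use Δψ = 0.2–0.25 at depth ≈ 200 with five
  replicates — effect sizes and replication a desk-scale version of the
  study design.
* **Genotypes.** Balding–Nichols drift: ancestral frequency uniform on
  [0.1, 0.9], per-population frequency Beta(p(1−F)/F, (1−p)(1−F)/F) with
  per-branch F (default 0.05); a sweep multiplies the focal population's F
  by 20 within chosen 5-SNP blocks. Sites monomorphic across the union are
  redrawn (capped retries) so planted block indices align with scan blocks.
  Genotypes are hard binomial calls with optional missingness, written as
  GT-only VCF 4.2.
* **Annotations.** Per-gene log-normal expression over 94 tissue-timepoint
  columns, uniform edge scores, Poisson term counts; an optional log2
  mean-shift planted in a labelled gene set drives the permutation-test
  recovery and calibration experiments.

Every generated table has a truth-ledger row (closed category vocabulary)
and all outputs are bitwise-reproducible from the seed.

**What passing tests show.** Recovery and calibration results demonstrate
correctness of the implemented statistics under their own generative
assumptions at desk scale (hundreds to thousands of events, 200 blocks).
They do not establish performance on real RNA-seq: mapping bias, junction
ambiguity, depth-expression correlation, linkage between SNPs, and
population structure beyond the drift model are all outside the simulation.

## File formats

Event tables are a single TSV with a `#samples=` header line, per-sample
comma-separated IJC/SJC lists and rMATS-style `IncFormLen`/`SkipFormLen`
columns; one event class per row keeps all five classes in one file (a
per-class writer is provided for tools expecting split files). BED intervals
are 0-based half-open; VCF is 4.x via cyvcf2 with multi-allelic records
skipped and counted. All readers validate loudly and name the offending
record.
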