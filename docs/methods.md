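# Methods

This note documents the models, parameter choices and numerical decisions
behind `bindqtl`, and what the synthetic-data generator does and does not
emulate.

## Pipeline overview

The package follows the order a binding-QTL study runs: binding regions are
called per sample from fragment density (`peaks`), fragments are counted
per region per sample and normalized into the NABI matrix (`quantnorm`),
cis associations are mapped and post-processed (`qtl`), regions are
annotated with motif matches (`motif`), and two corroborating analyses run
on the same data: allele-specific binding (`asb`) and X-chromosome binding
modes (`xclass`). The generator (`synthio`) produces seeded inputs with the
statistical structure each stage assumes.

## Peak calling

Fragment midpoints are smoothed with a Gaussian (Parzen) kernel. Defaults:
bandwidth 150 bp (on the order of a nucleosome-scale binding footprint),
grid step 10 bp. Candidate peaks are local maxima above a noise floor set
to the summit density of two fragments within one bandwidth — below that,
a "peak" is indistinguishable from a pair of stray fragments. Each peak's
site is the interquartile interval of the density mass inside its
watershed (the segment between neighbouring density minima). Enrichment
over the input library is a one-sided binomial test after scaling the
deeper library down by the depth ratio (scaling down avoids manufacturing
fractional pseudo-counts in the shallower library); sites whose scaled
ChIP count does not exceed the scaled input are discarded as
input-dominated. Per-sample peaks are BH-adjusted, thresholded at adjusted
P ≤ 1e-5, merged across samples by interval union with the calling-sample
set preserved, and single-caller regions are dropped. Blacklist removal is
rule-per-category: repeat-class intervals remove a region only when they
contain it entirely; locus-class intervals (immunoglobulin heavy chain,
MHC) remove on any overlap. Copy-number artifact regions enter through the
same blacklist interface rather than being re-derived. All coordinates are
0-based half-open.

## Counting and NABI normalization

Fragments are counted into a region when they overlap it by at least 1 bp,
after filtering to MAPQ ≥ 30, proper pairing, non-duplicate, and mate
distance ≤ 1 kb. Regions with mean count < 6 *and* SD < 5.14 are removed —
the conjunction matters: a low-mean, high-variance region is still
informative for association.

NABI applies six steps strictly in order, and the output records the
provenance:

1. rescale each lane to the mean lane total;
2. subtract the per-lane median count within GC-percentile bins
   (median, not mean — robust to a few extreme regions per bin). The
   nominal 100 bins are capped so each bin keeps ≥ ~20 regions: with
   sparser bins the bin median tracks individual regions and subtracting
   it destroys signal rather than removing composition bias;
3. merge lanes per individual by the mean;
4. centre-scale each region across samples (a zero-SD region here is a
   hard error naming the region — it should have been removed upstream);
5. map each sample's values to normal quantiles Φ⁻¹(rank/(M+1)), with
   average ranks on ties; the +1 denominator keeps the extreme quantiles
   finite;
6. remove the top principal component by SVD truncation of the
   column-centred matrix (truncation rather than regression for
   determinism). The removed scores/loadings/variance fractions are kept
   on the result.

## Association mapping

Variants are testable against a region when MAF > 0.05 (strict), the exact
conditional Hardy-Weinberg test P > 1e-4, and the variant lies within
±50 kb of the *region centre* (centre anchoring is configurable). The
association model is OLS of NABI on dosage with an intercept and a
two-sided t-test on the slope (n−2 df); X-chromosome males are coded
{0, 2}, so the same additive code path serves autosomes and X (hemizygous
dose equals two copies of one allele under an additive model). Genome-wide
FDR uses Storey q-values: π₀(λ) on the grid 0.05–0.95 (step 0.05) is
smoothed with a cubic fit read off at the largest λ, falling back to
π₀(0.5) when the fit leaves (0, 1] or when fewer than 100 P-values are
available. With π₀ forced to 1 the q-values are exactly BH. Leads are
minimum-P variants (ties broken leftmost), clusters collect variants with
P ≤ 10 × P_lead. |D′| between unphased variants is computed by EM over the
double-heterozygote phase ambiguity. Distal leads (> 1 kb from the region)
are resolved to the smallest-P proximal variant with |D′| > 0.5 to the
lead. Peak-shape traits (midpoint IQR "extent", density-mode "summit") are
quantitative traits for the same regression.

Seven directed linear-Gaussian structures among {variant V, focal region
BR1, neighbour BR2} are compared by summed per-equation BIC: V→BR1;
V→BR2; V→BR1→BR2; V→BR1 and V→BR2; V→BR2→BR1; V→BR2→BR1 plus V→BR1; and
the empty model. This particular structure set is a package choice — a
catalogue of the directed ways one variant can touch two neighbouring
regions — and is exposed as configuration rather than asserted as the only
reasonable set.

## Motif scanning

Log-odds scores (pseudocount 1e-4 on zero PWM entries, uniform background
by default) are computed on both strands; score P-values come from the
exact null score distribution built by dynamic programming over scores
discretized at 1e-3 bits, so the P of a hit is the exact tail mass of the
discretized distribution (which sums to 1 by construction). Windows
containing N are skipped. Instances at P ≤ 1e-4 annotate QTLs: a variant
inside an instance gets distance 0 and its offset within the motif,
otherwise distance to the best-scoring instance; regions without instances
yield missing distances.

## Allele-specific binding

Counts are oriented ancestral/derived (ancestral = allele shared with the
outgroup) rather than ref/alt, which decouples the test from
reference-alignment bias; sites without ancestral annotation are analysed
in ref/alt orientation and flagged. The per-sample test is the exact
two-sided binomial at θ = 0.5 under the minimum-likelihood convention (sum
of all outcome probabilities ≤ the observed outcome's). Only sample-site
pairs with ≥ 2 reads on each allele and ≥ 2 reads difference enter BH
adjustment at 5% FDR, and a site is called only when significant in ≥ 2
individuals. Sites are consistent when all significant individuals favour
the same allele, otherwise switching; switching sites are searched for an
explanatory variant whose carrier status partitions individuals by bias
direction (Fisher exact, BH over candidates within the site's cis window).

## X-chromosome classes

Classification uses raw depth-adjusted counts, not NABI — quantile
normalization would flatten exactly the male/female signal difference
being tested. The Mann-Whitney U test is exact for tie-free groups up to
20, asymptotic with tie correction otherwise. Non-significant sites
(α = 0.01) are single-active; significant sites are both-active unless
male signal is at background (≤ the 10th percentile of male region means)
*and* the female/male fold change is ≥ 4 — well beyond the ~2× expected
from a site bound on both female X copies — in which case female-specific.
The fold condition is what separates a genuinely male-absent site from a
both-active site that merely sits at the low end of the intensity
distribution. Pseudoautosomal regions are excluded before testing.
Clonality of female lines is called from allelic RNA expression at
strictly X-inactivated genes: aggregate minor-allele fraction ≤ 0.15 is
clonal (the threshold is configurable); clonal lines then validate the
classes via near-monoallelic binding at single-active versus balanced
binding at both-active sites.

## The synthetic generator

Defaults are the study conditions: 51 individuals, ±50 kb cis window, 3%
of regions with a causal variant, target effect R² 0.38, batch share
24.1%, 68% ancestral bias, 8.5% switching sites, X classes at 87%
both-active / ~12% single-active / ~1% female-specific with 24 males and
27 females.

* **Genotypes.** Haplotypes follow a block-copy model: global LD blocks
  (expected 10 variants) share a block allele frequency drawn uniformly
  from the MAF range; within a block each site copies the haplotype's
  block core allele with a 3% per-site flip, making block-mates strong but
  imperfect proxies — the structure that produces multi-variant QTL
  clusters, as real human LD does. Haplotypes are i.i.d. across
  chromosomes, so sites are in Hardy-Weinberg equilibrium. Block size 1
  gives independent sites. ~9.3% of variants are flagged as indels,
  matching the study panel's indel share.
* **Counts.** Log-linear mean with per-region baseline (log-normal around
  50 fragments), additive genetic effect, quadratic-in-GC bias with
  sample-specific slope, rank-1 batch term, per-sample biological noise
  (SD 0.25 — the between-individual non-genetic noise level is not pinned
  down by any reported quantity, so it is an explicit knob), and ≥ 2-fold
  depth variation. Counts are Poisson-gamma (NB2); the `overdispersion`
  parameter is the variance inflation factor at the reference mean, so 1
  recovers a pure Poisson. The genetic effect size is calibrated per
  region so dosage explains the target share of non-batch variance; the
  batch loading is calibrated so the batch explains the target share of
  total variance, shrunk by the Marchenko-Pastur noise-edge term
  (1+√(n/m))²/n so the *observable* PC1 fraction of the finite matrix —
  the quantity a study reports — lands on the configured share rather
  than above it.
* **Allele counts.** Per het sample, binomial reads at the site's θ
  (0.8 toward the favoured allele at biased sites), depth Poisson(30);
  the favoured allele is ancestral with the configured probability, and a
  configurable fraction of sites switches direction per individual.
* **X counts.** Class means follow the construction in the classifier's
  contract (female = 2× male; equal; male at background), with NB noise
  and depth variation.

What the generator does **not** emulate: read-level sequences and mapping
artifacts, reference-genome context (GC is a per-region number, not a
sequence property), coalescent genealogy and population structure,
long-range LD beyond one block, imprinting and allelic exclusion, and
trans effects. Passing tests therefore demonstrate the statistical
machinery under the study's assumed structure, not robustness to every
failure mode of real ChIP-seq data.

## Problem sizes and tolerances in the test suite

Simulation-backed checks use sizes chosen to keep the suite fast while
leaving the assertions well-powered: null calibration pools ten 500-region
null scans (~180k tests) for the KS uniformity check; power is measured on
two 1000-region studies (60 planted QTLs); ASB rate recovery uses 600
sites; X-class recall pools three 500-region panels. Oracle-equivalence
tests run at tolerances matched to the arithmetic: 1e-9 relative for the
kernel-density oracle, 1e-12 for exact binomial/HWE/MWU enumerations,
1e-10 for OLS against the normal equations, 2e-3 for PWM tail
probabilities (the DP discretization granularity dominates). Degenerate
inputs are contracts, not accidents: empty fragment tables yield empty
profiles, zero-variance phenotypes and monomorphic dosages raise, (0,0)
allele counts are flagged untestable rather than significant.

## Known limitations

* The EM for |D′| assumes random mating and bi-allelic variants; it is not
  a phaser and inherits the usual small-sample bias of haplotype-frequency
  estimation.
* π₀ smoothing uses a cubic polynomial rather than a spline; for the
  P-value ensembles produced here the difference is well below the
  q-value tolerances, but heavily structured P distributions may prefer
  the spline.
* The peak caller's noise floor and bandwidth are global; variable
  fragment-length libraries would warrant per-sample bandwidths.
* `compare_causal_models` scores observational fits; with n near 50 its
  BIC differences between mediation structures are small, and the
  small-sample warning flag (n < 10) is deliberately conservative.
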