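# bindqtl

Quantitative genetics of transcription-factor binding. `bindqtl` implements
the full analysis chain used to map *binding QTLs* — genetic variants
associated with how strongly a transcription factor (the motivating case is
CTCF, profiled by ChIP-seq across a panel of genotyped lymphoblastoid cell
lines) binds each of its genomic sites — together with the two orthogonal
analyses that corroborate such QTLs: allele-specific binding at heterozygous
sites, and classification of X-chromosome binding modes in males versus
females.

It is aimed at statistical geneticists and regulatory genomicists who want a
tested, reusable implementation of this pipeline, exercisable end-to-end on
a built-in synthetic-data generator that reproduces the statistical
structure of a real binding study (overdispersed counts, GC bias, a
dominant batch component, additive cis effects, allele bias, X dosage
structure) without any external data.

## The model

For binding region *i* and individual *l*, the normalized adjusted binding
intensity (NABI) is obtained from raw fragment counts by six ordered steps —
depth rescaling, GC-bin median subtraction, lane merging, per-region
centre-scaling, per-sample quantile mapping to N(0,1), and removal of the
top principal component (which absorbs batch structure). The cis-QTL model
is ordinary least squares on alternate-allele dosage g ∈ {0,1,2}:

    y_il = α_i + β_i g_lv + ε_il,   v within ±50 kb of region i

with a two-sided t-test on β (n−2 df), genome-wide FDR by Storey's q-value
(π₀ estimated from the flat tail of the P distribution), and a Bonferroni
threshold α/m reported alongside. Per region the lead variant is the
minimum-P variant and its cluster holds every variant with P within one
order of magnitude of the lead; distal leads are resolved to proximal
candidates through |D′| (EM haplotype frequencies from unphased dosages).
Allele-specific binding uses an exact two-sided binomial test of
ancestral/derived read counts at θ = 0.5 with Benjamini–Hochberg control at
5% FDR and a two-individual replication rule. X-chromosome sites are
classified single-active / both-active / female-specific from a
Mann–Whitney U test on sex plus depth-adjusted fold change.

## Worked example

```python
from bindqtl import SimConfig, nabi_normalize, scan_qtl
from bindqtl.synthio import simulate_genotypes, simulate_binding_counts

cfg = SimConfig(n_regions=1000, seed=1)          # 51 samples, 3% causal regions
genotypes = simulate_genotypes(cfg)
counts, truth = simulate_binding_counts(genotypes, cfg)
nabi = nabi_normalize(counts)
tests, summary, pi0 = scan_qtl(nabi, genotypes, counts.regions)

planted = set(truth.loc[truth.causal_idx >= 0, "region"])
found = set(summary.loc[summary.significant, "region"])
print(f"pi0 = {pi0:.3f}")
print(f"planted QTL regions: {len(planted)}, detected at 1% FDR: "
      f"{len(found & planted)} (+{len(found - planted)} extra)")
```

Output:

```
pi0 = 1.000
planted QTL regions: 30, detected at 1% FDR: 27 (+2 extra)
```

30 of the 1,000 simulated regions carry a causal variant whose dosage
explains ~38% of the region's (non-batch) variance; at n = 51 the scan
recovers 27 of them at 1% FDR with two extra calls, and π₀ ≈ 1 reflects
that almost all of the ~100k (region, variant) tests are null.

The same library surface drives peak calling (`bindqtl.peaks`), fragment
counting and normalization (`bindqtl.quantnorm`), motif annotation
(`bindqtl.motif`), allele-specific binding (`bindqtl.asb`) and X-chromosome
classification (`bindqtl.xclass`). A thin CLI wraps the simulate/scan loop:

```bash
bqtl simulate --config cfg.yaml --out sim/ --seed 3
bqtl scan --counts sim/counts.tsv --vcf sim/genotypes.vcf \
          --regions sim/regions.bed --out scan/
```

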