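"""Seeded synthetic data generators for the binding-QTL pipeline.

These generators emulate the statistical structure of a transcription-factor
ChIP-seq binding study across a panel of genotyped cell lines: per-region
fragment counts with overdispersed Poisson noise, GC-correlated library bias,
one dominant batch component, additive cis-genetic effects at a chosen
fraction of regions, heterozygous-site allele counts with ancestral-allele
bias, and male/female X-chromosome count structure with three site classes.

Every generator is a pure function of its configuration and seed: the same
inputs yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GenotypeTable",
    "RawCountMatrix",
    "simulate_genotypes",
    "simulate_binding_counts",
    "simulate_fragments",
    "simulate_allele_counts",
    "simulate_x_counts",
    "write_vcf",
    "write_bed",
    "write_counts_tsv",
]

# Fraction of variants flagged as indels, mirroring the study's variant set
# (436,436 indels among 4,687,317 variants).
INDEL_FRACTION = 436436 / 4687317

# Reference mean fragment count per region; overdispersion is expressed as the
# variance inflation factor at this mean.
_MU_REF = 50.0


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Defaults reproduce the study conditions: 51 individuals, a ±50 kb cis
    window, ~3% of regions carrying a causal variant whose effect explains a
    median R² of 0.38, and a single batch component responsible for 24.1% of
    the phenotypic variance.

    Parameters
    ----------
    n_samples : int
        Number of individuals (>= 4).
    n_regions : int
        Number of binding regions.
    cis_window : int
        Half-width in bp of the cis window around each region centre.
    qtl_fraction : float
        Fraction of regions with a planted causal variant.
    effect_r2 : float
        Target fraction of per-region (non-batch) phenotypic variance
        explained by the causal genotype.
    maf_range : tuple of float
        Minor-allele-frequency range for simulated variants.
    batch_var_frac : float
        Fraction of per-region variance contributed by the batch component.
    overdispersion : float
        Variance inflation factor (>= 1) of counts at the reference mean;
        1 recovers a pure Poisson. Implemented as a Poisson-gamma
        (negative-binomial) mixture.
    bio_sd : float
        SD of non-genetic biological noise on the log scale (a free knob:
        the underlying study does not pin this quantity down).
    causal_maf_min : float
        Minimum MAF of variants eligible to be planted as causal.
    ld_block_size : int
        Expected number of variants per LD block in the copy-with-
        recombination haplotype model; 1 gives independent variants.
    lanes_per_sample : int
        Sequencing lanes per individual (lanes are merged by the
        normalization pipeline).
    seed : int
        Base seed for all randomness.
    """

    n_samples: int = 51
    n_regions: int = 1000
    cis_window: int = 50_000
    qtl_fraction: float = 0.03
    effect_r2: float = 0.38
    maf_range: tuple[float, float] = (0.05, 0.5)
    batch_var_frac: float = 0.241
    overdispersion: float = 1.5
    bio_sd: float = 0.25
    causal_maf_min: float = 0.2
    ld_block_size: int = 10
    lanes_per_sample: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        for name in ("qtl_fraction", "effect_r2", "batch_var_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GenotypeTable:
    """Samples x variants dosage matrix with variant metadata.

    ``dosages`` holds alternate-allele dosages in {0, 1, 2}; on the X
    chromosome males are coded {0, 2} so one additive regression codebase
    serves autosomes and X. ``variants`` carries chrom, pos, id, ref, alt,
    ancestral allele, indel flag and the realised minor allele frequency.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray  # (n_samples, n_variants) int8

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def het_mask(self) -> np.ndarray:
        return self.dosages == 1


@dataclass
class RawCountMatrix:
    """Lanes (or samples) x regions fragment-count matrix.

    ``regions`` carries chrom, start, end and GC fraction per region;
    ``lane_map`` maps each count row to its individual.
    """

    counts: np.ndarray  # (n_lanes, n_regions) float (integer-valued)
    regions: pd.DataFrame
    lanes: list[str]
    lane_map: dict[str, str]  # lane -> sample
    sample_meta: pd.DataFrame | None = None

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def _block_starts(rng: np.random.Generator, m: int, block_size: int) -> np.ndarray:
    """Global LD-block boundaries: each site starts a new block with
    probability 1/block_size. Returns the block index per site."""
    if block_size <= 1:
        return np.arange(m)
    new_block = rng.random(m) < 1.0 / block_size
    new_block[0] = True
    return np.cumsum(new_block) - 1


def _haplotypes(rng: np.random.Generator, n_hap: int, block_freqs: np.ndarray,
                block_of: np.ndarray, mutation: float) -> np.ndarray:
    """Block-copy haplotypes with per-site recombination.

    Within an LD block every site copies the haplotype's block core allele
    (Bernoulli at the block frequency), flipped independently with a small
    ``mutation`` probability, so sites in a block are near-perfect proxies
    of one another; recombination (a new block) breaks the copying. With
    block size 1 every site is its own block and sites are independent.
    Haplotypes are i.i.d. across chromosomes, so genotypes are in
    Hardy-Weinberg equilibrium at each site's marginal frequency.
    """
    n_blocks = block_of.max() + 1
    core = rng.random((n_hap, n_blocks)) < block_freqs[None, :]
    alleles = core[:, block_of]
    m = len(block_of)
    if mutation > 0:
        flip = rng.random((n_hap, m)) < mutation
        alleles = alleles ^ flip
    return alleles.astype(np.int8)


def simulate_genotypes(config: SimConfig, n_variants: int | None = None,
                       chrom: str = "chr1", spacing: int = 1_000) -> GenotypeTable:
    """Simulate a Hardy-Weinberg genotype panel with block LD structure.

    Variants are placed ~``spacing`` bp apart along ``chrom``; allele
    frequencies are uniform over ``config.maf_range`` (so the generated panel
    spans the MAF>5% association filter boundary when the range allows).
    About 9.3% of variants are flagged as indels, mirroring the study's
    SNP/indel proportions. The ancestral allele is annotated per variant
    (the reference allele is ancestral ~70% of the time).
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(config.seed)
    if n_variants is None:
        n_variants = max(50, config.n_regions * 20)
    lo, hi = config.maf_range
    block_of = _block_starts(rng, n_variants, config.ld_block_size)
    n_blocks = block_of.max() + 1
    block_freqs = rng.uniform(lo, hi, n_blocks) if hi > lo \
        else np.full(n_blocks, lo)
    mut = 0.03 if config.ld_block_size > 1 else 0.0
    hap = _haplotypes(rng, 2 * config.n_samples, block_freqs, block_of, mut)
    dosages = hap[0::2] + hap[1::2]
    freqs = block_freqs[block_of] * (1 - mut) + (1 - block_freqs[block_of]) * mut

    pos = np.cumsum(rng.integers(max(1, spacing // 2), spacing * 3 // 2 + 1,
                                 n_variants))
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n_variants)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + rng.integers(1, 4, n_variants)) % 4]
    is_indel = rng.random(n_variants) < INDEL_FRACTION
    alt = np.where(is_indel, np.char.add(ref, alt), alt)
    ref_is_anc = rng.random(n_variants) < 0.7
    ancestral = np.where(ref_is_anc, ref, alt)
    maf_obs = dosages.mean(axis=0) / 2.0
    maf_obs = np.minimum(maf_obs, 1.0 - maf_obs)
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": pos.astype(np.int64),
        "id": [f"var{i}" for i in range(n_variants)],
        "ref": ref,
        "alt": alt,
        "ancestral": ancestral,
        "is_indel": is_indel,
        "target_maf": freqs,
        "maf": maf_obs,
    })
    samples = [f"S{j:03d}" for j in range(config.n_samples)]
    return GenotypeTable(samples=samples, variants=variants, dosages=dosages)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               overdispersion: float) -> np.ndarray:
    """Poisson-gamma counts with variance phi*mu at mu = _MU_REF."""
    if overdispersion <= 1.0:
        return rng.poisson(mu).astype(float)
    alpha = (overdispersion - 1.0) / _MU_REF  # NB2 dispersion
    shape = 1.0 / alpha
    g = rng.gamma(shape, 1.0 / shape, size=mu.shape)
    return rng.poisson(mu * g).astype(float)


def simulate_binding_counts(genotypes: GenotypeTable, config: SimConfig,
                            ) -> tuple[RawCountMatrix, pd.DataFrame]:
    """Simulate per-region fragment counts with planted cis effects.

    Log-mean model for lane j of sample l and region i::

        log mu = baseline_i + beta_i * dosage_li + gc_i * gc_slope_l
                 + batch_loading_i * batch_score_l + log(depth_j)

    Counts are negative-binomial around the log-mean. ``beta_i`` is nonzero
    for a ``qtl_fraction`` of regions and is calibrated so the genotype
    explains ``effect_r2`` of the region's non-batch variance; the batch
    loading is calibrated so the batch explains ``batch_var_frac`` of total
    per-region variance (so the first principal component of the count
    matrix carries that share). Sequencing depth varies >= 2-fold across
    lanes. Returns the count matrix and a truth table with the causal
    variant index and true log-scale beta per region.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n, m = cfg.n_samples, cfg.n_regions
    pos_max = int(genotypes.variants["pos"].max())
    # Regions spread across the variant span, away from its edges.
    centers = np.sort(rng.integers(cfg.cis_window,
                                   max(pos_max - cfg.cis_window, cfg.cis_window + 1),
                                   m)).astype(np.int64)
    half_width = rng.integers(150, 350, m)
    start = centers - half_width
    end = centers + half_width
    gc = rng.uniform(0.3, 0.7, m)

    baseline = rng.normal(np.log(_MU_REF), 0.4, m)
    mu_ref = np.exp(baseline)
    alpha = (cfg.overdispersion - 1.0) / _MU_REF
    count_noise_var = 1.0 / mu_ref + alpha  # delta-method log-scale noise

    # GC bias: smooth quadratic in region GC with a sample-specific slope.
    gc_shape = (gc - 0.5) ** 2 - np.mean((gc - 0.5) ** 2)
    gc_slope = rng.normal(0.0, 2.0, n)
    gc_var = gc_shape**2 * 4.0  # per-region variance across samples

    nongenetic_var = cfg.bio_sd**2 + count_noise_var + gc_var

    # Plant causal variants.
    vpos = genotypes.variants["pos"].to_numpy()
    vmaf = genotypes.variants["maf"].to_numpy()
    causal_idx = np.full(m, -1, dtype=np.int64)
    true_beta = np.zeros(m)
    n_qtl = int(round(cfg.qtl_fraction * m))
    qtl_regions = rng.choice(m, size=n_qtl, replace=False) if n_qtl else np.array([], int)
    dos = genotypes.dosages.astype(float)
    for i in qtl_regions:
        lo = np.searchsorted(vpos, centers[i] - cfg.cis_window)
        hi = np.searchsorted(vpos, centers[i] + cfg.cis_window, side="right")
        cand = np.arange(lo, hi)
        cand = cand[vmaf[cand] >= cfg.causal_maf_min]
        if len(cand) == 0:
            continue
        v = int(rng.choice(cand))
        g = dos[:, v]
        var_g = g.var()
        if var_g <= 0:
            continue
        r2 = cfg.effect_r2
        beta = np.sqrt(r2 / (1.0 - r2) * nongenetic_var[i] / var_g)
        beta *= rng.choice([-1.0, 1.0])
        causal_idx[i] = v
        true_beta[i] = beta

    # Batch: two batches, loading scaled to the target variance share.
    batch_label = (np.arange(n) % 2).astype(float)
    batch_score = (batch_label - batch_label.mean()) / batch_label.std()
    genetic_var = np.where(causal_idx >= 0,
                           true_beta**2 * dos[:, np.maximum(causal_idx, 0)].var(axis=0),
                           0.0)
    nonbatch_var = nongenetic_var + genetic_var
    # The observable PC1 fraction of a finite samples x regions matrix sits
    # above the planted batch share by roughly the Marchenko-Pastur noise
    # edge lam = (1 + sqrt(n/m))^2 / n; shrink the planted share so the
    # matrix PC1 lands on batch_var_frac.
    lam = (1.0 + np.sqrt(n / m)) ** 2 / n
    f = cfg.batch_var_frac
    if 0.0 < f < 1.0 and f > lam:
        f = (f - lam) / (1.0 - lam)
    batch_loading = np.sqrt(f / (1.0 - f) * nonbatch_var) if f > 0 else np.zeros(m)
    batch_loading *= rng.choice([-1.0, 1.0], m)

    bio = rng.normal(0.0, cfg.bio_sd, (n, m))
    g_term = np.zeros((n, m))
    has_qtl = causal_idx >= 0
    if has_qtl.any():
        gmat = dos[:, causal_idx[has_qtl]]
        gmat = gmat - gmat.mean(axis=0)
        g_term[:, has_qtl] = gmat * true_beta[has_qtl]

    log_mu_sample = (baseline[None, :] + g_term
                     + np.outer(gc_slope, gc_shape)
                     + np.outer(batch_score, batch_loading)
                     + bio)

    lanes, lane_samples, rows = [], [], []
    depth_rng = rng
    for l, s in enumerate(genotypes.samples):
        for k in range(cfg.lanes_per_sample):
            lane = f"{s}_L{k}" if cfg.lanes_per_sample > 1 else s
            depth = np.exp(depth_rng.uniform(0.0, np.log(2.5)))
            mu = np.exp(log_mu_sample[l] + np.log(depth))
            rows.append(_nb_counts(rng, mu, cfg.overdispersion))
            lanes.append(lane)
            lane_samples.append(s)
    counts = np.vstack(rows)

    regions = pd.DataFrame({
        "chrom": "chr1", "start": start, "end": end,
        "center": centers, "gc": gc,
        "id": [f"BR{i}" for i in range(m)],
    })
    truth = pd.DataFrame({
        "region": regions["id"],
        "causal_idx": causal_idx,
        "causal_id": [genotypes.variants["id"].iloc[v] if v >= 0 else ""
                      for v in causal_idx],
        "true_beta": true_beta,
        "batch_loading": batch_loading,
    })
    meta = pd.DataFrame({"sample": genotypes.samples,
                         "batch": batch_label.astype(int)})
    return (RawCountMatrix(counts=counts, regions=regions, lanes=lanes,
                           lane_map=dict(zip(lanes, lane_samples)),
                           sample_meta=meta),
            truth)


def simulate_fragments(region_spec: tuple[str, int, int], n_fragments: int,
                       summit_positions, seed: int, *,
                       summit_sd: float = 35.0, background_frac: float = 0.0,
                       fragment_length: int = 200, n_samples: int = 1,
                       duplicate_frac: float = 0.0, lowq_frac: float = 0.0,
                       improper_frac: float = 0.0) -> pd.DataFrame:
    """Simulate sequenced fragments around binding summits.

    Fragment midpoints are drawn from a mixture of Gaussians at
    ``summit_positions`` (sd ``summit_sd``) plus a uniform background over
    the region (mixture weight ``background_frac``). Each fragment carries
    sample, MAPQ, proper-pair flag, mate distance and duplicate flag so the
    counting filters can be exercised.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")
    chrom, rstart, rend = region_spec
    rng = np.random.default_rng(seed)
    summits = np.asarray(list(summit_positions), dtype=float)
    mids = np.empty(n_fragments)
    is_bg = rng.random(n_fragments) < background_frac
    n_bg = int(is_bg.sum())
    mids[is_bg] = rng.uniform(rstart, rend, n_bg)
    n_sig = n_fragments - n_bg
    if n_sig:
        if len(summits) == 0:
            mids[~is_bg] = rng.uniform(rstart, rend, n_sig)
        else:
            which = rng.integers(0, len(summits), n_sig)
            mids[~is_bg] = rng.normal(summits[which], summit_sd)
    mids = np.clip(mids, rstart, rend - 1)
    length = np.maximum(20, rng.normal(fragment_length, fragment_length / 10,
                                       n_fragments)).astype(int)
    start = (mids - length / 2).astype(np.int64)
    end = start + length
    mapq = np.where(rng.random(n_fragments) < lowq_frac,
                    rng.integers(0, 30, n_fragments),
                    rng.integers(30, 61, n_fragments))
    df = pd.DataFrame({
        "chrom": chrom,
        "start": start,
        "end": end,
        "midpoint": mids,
        "sample": [f"S{j:03d}" for j in rng.integers(0, n_samples, n_fragments)],
        "mapq": mapq,
        "proper_pair": rng.random(n_fragments) >= improper_frac,
        "mate_distance": length,
        "duplicate": rng.random(n_fragments) < duplicate_frac,
    })
    return df


def simulate_allele_counts(genotypes: GenotypeTable, n_sites: int,
                           mean_depth: float = 30.0,
                           ancestral_bias: float = 0.68,
                           switching_rate: float = 0.085,
                           theta_strong: float = 0.8,
                           effect_fraction: float = 1.0,
                           seed: int = 0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate heterozygous-site allele counts with allele bias.

    Sites are drawn from variants heterozygous in >= 2 individuals. A
    fraction ``effect_fraction`` of sites carries true allelic imbalance
    (theta = ``theta_strong`` toward one allele); among biased,
    non-switching sites the favoured allele is ancestral with probability
    ``ancestral_bias``. A fraction ``switching_rate`` of biased sites
    switches direction between individuals (each heterozygote favours a
    random allele). Per het sample, ancestral/derived read counts are
    binomial at the site's per-sample theta with Poisson(``mean_depth``)
    total depth.

    Returns (allele-count table, per-site truth).
    """
    rng = np.random.default_rng(seed)
    het = genotypes.het_mask()
    eligible = np.flatnonzero(het.sum(axis=0) >= 2)
    if len(eligible) == 0:
        raise ValueError("no variants heterozygous in >= 2 samples")
    take = min(n_sites, len(eligible))
    sites = rng.choice(eligible, size=take, replace=False)

    ref_is_anc = (genotypes.variants["ancestral"].to_numpy()
                  == genotypes.variants["ref"].to_numpy())
    recs, truths = [], []
    for v in sites:
        has_effect = rng.random() < effect_fraction
        switching = bool(has_effect and rng.random() < switching_rate)
        favors_anc = bool(rng.random() < ancestral_bias)
        theta_site = (theta_strong if favors_anc else 1.0 - theta_strong) \
            if has_effect else 0.5
        vid = genotypes.variants["id"].iloc[v]
        for j in np.flatnonzero(het[:, v]):
            if switching:
                theta = theta_strong if rng.random() < 0.5 else 1.0 - theta_strong
            else:
                theta = theta_site
            depth = rng.poisson(mean_depth)
            anc = rng.binomial(depth, theta) if depth > 0 else 0
            recs.append((vid, genotypes.samples[j], anc, depth - anc,
                         bool(ref_is_anc[v])))
        truths.append((vid, has_effect, switching, favors_anc, theta_site))
    counts = pd.DataFrame(recs, columns=["site", "sample", "ancestral_count",
                                         "derived_count", "ref_is_ancestral"])
    truth = pd.DataFrame(truths, columns=["site", "has_effect", "switching",
                                          "favors_ancestral", "theta"])
    return counts, truth


X_CLASS_MIX = {"both-active": 0.87, "single-active": 0.118,
               "female-specific": 0.012}


def simulate_x_counts(n_male: int = 24, n_female: int = 27,
                      class_mix: dict[str, float] | None = None,
                      n_regions: int = 500, seed: int = 0,
                      overdispersion: float = 1.5,
                      background_mean: float = 2.0,
                      ) -> tuple[RawCountMatrix, pd.DataFrame]:
    """Simulate X-chromosome binding counts for three site classes.

    both-active sites are bound on both female X copies (female mean ~ 2x
    male); single-active sites are bound on one copy in both sexes (equal
    means); female-specific sites have male signal at background. The
    default class mix follows the study (87% both-active, ~1% female-
    specific). Depth varies >= 2-fold across samples.
    """
    if n_male < 3 or n_female < 3:
        raise ValueError("need >= 3 samples per sex")
    mix = dict(X_CLASS_MIX if class_mix is None else class_mix)
    total = sum(mix.values())
    mix = {k: v / total for k, v in mix.items()}
    rng = np.random.default_rng(seed)
    labels = rng.choice(list(mix), size=n_regions, p=list(mix.values()))

    n = n_male + n_female
    sex = np.array(["M"] * n_male + ["F"] * n_female)
    samples = [f"{s}{j:03d}" for j, s in enumerate(sex)]
    depth = np.exp(rng.uniform(0.0, np.log(2.5), n))
    base = np.exp(rng.normal(np.log(40.0), 0.4, n_regions))

    male_mean = np.where(labels == "female-specific", background_mean, base)
    female_mean = np.where(labels == "both-active", 2.0 * base, base)
    mu = np.where(sex[:, None] == "M", male_mean[None, :], female_mean[None, :])
    mu = mu * depth[:, None]
    counts = _nb_counts(rng, mu, overdispersion)

    start = np.sort(rng.integers(0, 150_000_000, n_regions)).astype(np.int64)
    regions = pd.DataFrame({
        "chrom": "chrX", "start": start, "end": start + 400,
        "gc": rng.uniform(0.3, 0.7, n_regions),
        "id": [f"XR{i}" for i in range(n_regions)],
    })
    meta = pd.DataFrame({"sample": samples, "sex": sex, "depth": depth})
    truth = pd.DataFrame({"region": regions["id"], "true_class": labels})
    return (RawCountMatrix(counts=counts, regions=regions, lanes=samples,
                           lane_map={s: s for s in samples},
                           sample_meta=meta),
            truth)


# ---------------------------------------------------------------------------
# Plain-text writers (minimal VCF / BED / TSV)

def write_vcf(genotypes: GenotypeTable, path) -> None:
    """Write the genotype table as a minimal VCF with AA= ancestral INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
        v = genotypes.variants
        for i in range(len(v)):
            row = v.iloc[i]
            gts = "\t".join(gt_of[int(d)] for d in genotypes.dosages[:, i])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\tAA={row.ancestral}\tGT\t{gts}\n")


def write_bed(regions: pd.DataFrame, path) -> None:
    """Write regions as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            name = r.get("id", ".")
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t+\n")


def write_counts_tsv(matrix: RawCountMatrix, path) -> None:
    """Write the count matrix as TSV, lanes as rows."""
    df = pd.DataFrame(matrix.counts, index=matrix.lanes,
                      columns=matrix.regions["id"])
    df.to_csv(path, sep="\t", index_label="lane")
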