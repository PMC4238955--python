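"""cis-QTL mapping of binding intensity and peak shape.

For every binding region, variants within the cis window (±50 kb of the
region centre) passing MAF and Hardy-Weinberg filters are tested by
least-squares linear regression of the normalized binding phenotype on
alternate-allele dosage (additive coding 0/1/2), with a two-sided t-test on
the slope. Genome-wide FDR is controlled by Storey's q-value; a Bonferroni
threshold is reported alongside. Per significant region, the lead variant
and its cluster (P within one order of magnitude of the lead) are reported,
distal leads are resolved to proximal candidates through |D'| linkage, and
three-variable causal structures between a variant and two neighbouring
regions are compared by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import parzen_density
from .quantnorm import NABIMatrix
from .synthio import GenotypeTable

__all__ = [
    "filter_variants",
    "hwe_test",
    "linear_qtl",
    "linear_qtl_many",
    "storey_qvalue",
    "bonferroni_threshold",
    "cluster_variants",
    "ld_dprime",
    "resolve_distal",
    "shape_phenotypes",
    "compare_causal_models",
    "scan_qtl",
    "CAUSAL_MODELS",
]


# ---------------------------------------------------------------------------
# Variant filtering

def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """Exact conditional Hardy-Weinberg test P-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose probability does not exceed that of the
    observed configuration (two-sided exact test).
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count is zero")
    n_a = 2 * n_aa + n_ab  # minor-allele count, by convention below
    if n_a > n:  # work with the rarer allele
        n_a = 2 * n - n_a
    hets = np.arange(n_a % 2, n_a + 1, 2)
    # log P(n_het | n, n_a) up to a constant, via log-factorials
    lf = np.zeros(2 * n + 1)
    lf[1:] = np.cumsum(np.log(np.arange(1, 2 * n + 1)))

    def logp(h):
        a = (n_a - h) // 2
        b = n - a - h
        return (h * np.log(2) - lf[h] - lf[a] - lf[b])

    logs = np.array([logp(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_ab)[0]]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def hwe_pass_mask(genotypes: GenotypeTable, hwe_min: float = 1e-4) -> np.ndarray:
    """Per-variant exact-HWE pass mask (P > hwe_min), computed once.

    The test depends only on the genotype counts, so results are cached by
    (n_AA, n_Aa, n_aa) across variants.
    """
    cache: dict[tuple[int, int, int], bool] = {}
    d = genotypes.dosages
    n0 = (d == 0).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n2 = (d == 2).sum(axis=0)
    out = np.empty(genotypes.n_variants, dtype=bool)
    for j in range(genotypes.n_variants):
        key = (int(n0[j]), int(n1[j]), int(n2[j]))
        if key not in cache:
            cache[key] = hwe_test(key) > hwe_min
        out[j] = cache[key]
    return out


def filter_variants(genotypes: GenotypeTable, region: pd.Series,
                    window: int = 50_000, maf_min: float = 0.05,
                    hwe_min: float = 1e-4,
                    hwe_mask: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, dict[str, int]]:
    """Indices of variants testable against one region, with exclusion tally.

    A variant is kept iff its MAF is strictly greater than ``maf_min``, its
    exact Hardy-Weinberg P exceeds ``hwe_min``, and its position is within
    ``window`` bp of the region centre. A precomputed ``hwe_mask`` (from
    :func:`hwe_pass_mask`) avoids re-testing HWE per region.
    """
    v = genotypes.variants
    center = int(region["center"]) if "center" in region.index else \
        (int(region["start"]) + int(region["end"])) // 2
    pos = v["pos"].to_numpy()
    tally = {"window": 0, "maf": 0, "hwe": 0}
    in_window = np.abs(pos - center) <= window
    tally["window"] = int((~in_window).sum())
    idx = np.flatnonzero(in_window)
    dosages = genotypes.dosages[:, idx]
    maf = dosages.mean(axis=0) / 2.0
    maf = np.minimum(maf, 1 - maf)
    pass_maf = maf > maf_min
    tally["maf"] = int((~pass_maf).sum())
    idx = idx[pass_maf]
    if hwe_mask is None:
        hwe_mask_local = np.empty(len(idx), dtype=bool)
        for k, j in enumerate(idx):
            d = genotypes.dosages[:, j]
            counts = (int((d == 0).sum()), int((d == 1).sum()),
                      int((d == 2).sum()))
            hwe_mask_local[k] = hwe_test(counts) > hwe_min
    else:
        hwe_mask_local = hwe_mask[idx]
    tally["hwe"] = int((~hwe_mask_local).sum())
    return idx[hwe_mask_local].astype(np.int64), tally


# ---------------------------------------------------------------------------
# Association

def linear_qtl(y: np.ndarray, g: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of phenotype on dosage with intercept; t-test on the slope.

    Returns (beta, se, t, P) with P two-sided on n-2 degrees of freedom.
    """
    beta, se, t, p = linear_qtl_many(np.asarray(y, float),
                                     np.asarray(g, float)[:, None])
    return float(beta[0]), float(se[0]), float(t[0]), float(p[0])


def linear_qtl_many(y: np.ndarray, G: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized simple linear regression of y on each column of G."""
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need >= 3 samples")
    gc = G - G.mean(axis=0)
    sxx = (gc**2).sum(axis=0)
    if np.any(sxx == 0):
        raise ValueError("monomorphic in sample")
    yc = y - y.mean()
    sxy = gc.T @ yc
    beta = sxy / sxx
    syy = (yc**2).sum()
    rss = np.maximum(syy - beta * sxy, 0.0)
    df = n - 2
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 0.0)
    return beta, se, t, p


def storey_qvalue(p: np.ndarray, pi0: float | None = None,
                  lambdas: np.ndarray | None = None,
                  ) -> tuple[np.ndarray, float]:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a grid
    (default 0.05..0.95 by 0.05), smoothed with a cubic fit and read off at
    the largest lambda; if the smoothed estimate leaves (0, 1] the fallback
    is pi0(0.5). With pi0 forced to 1 the q-values reduce exactly to
    Benjamini-Hochberg adjusted P-values.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        raise ValueError("empty P-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam))
                          for lam in lambdas])
        if m < 100:
            pi0 = min(1.0, float(pi0_l[np.argmin(np.abs(lambdas - 0.5))]))
        else:
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas.max()))
            if not 0.0 < pi0 <= 1.0:
                pi0 = float(pi0_l[np.argmin(np.abs(lambdas - 0.5))])
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out, float(pi0)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def cluster_variants(region_results: pd.DataFrame,
                     fold: float = 10.0) -> pd.DataFrame:
    """Lead variant and cluster membership for one region's tests.

    The lead is the minimum-P variant (ties broken by leftmost genomic
    position); the cluster contains every variant with P <= fold * P_lead.
    Adds ``is_lead`` and ``in_cluster`` columns.
    """
    df = region_results.copy()
    if len(df) == 0:
        raise ValueError("no tested variants in region")
    order = np.lexsort((df["pos"].to_numpy(), df["p"].to_numpy())) \
        if "pos" in df.columns else np.argsort(df["p"].to_numpy())
    lead_i = df.index[order[0]]
    p_lead = float(df.loc[lead_i, "p"])
    df["is_lead"] = False
    df.loc[lead_i, "is_lead"] = True
    df["in_cluster"] = df["p"] <= fold * p_lead
    df.loc[lead_i, "in_cluster"] = True
    return df


# ---------------------------------------------------------------------------
# Linkage disequilibrium

def ld_dprime(g1: np.ndarray, g2: np.ndarray, max_iter: int = 1000,
              tol: float = 1e-10) -> float:
    """|D'| between two variants from unphased dosages, by EM.

    Haplotype frequencies are estimated by expectation-maximisation over the
    double-heterozygote phase ambiguity; D = p_AB - p_A p_B is normalized by
    its bound D_max to give |D'| in [0, 1].
    """
    g1 = np.asarray(g1, dtype=int)
    g2 = np.asarray(g2, dtype=int)
    if g1.var() == 0 or g2.var() == 0:
        raise ValueError("both variants must be polymorphic")
    n = len(g1)
    pA = g1.mean() / 2.0
    pB = g2.mean() / 2.0
    # haplotype freqs: [ab, aB, Ab, AB] with A/B the alternate alleles
    f = np.array([(1 - pA) * (1 - pB), (1 - pA) * pB,
                  pA * (1 - pB), pA * pB])
    dh = (g1 == 1) & (g2 == 1)  # ambiguous double heterozygotes
    n_dh = int(dh.sum())
    # fixed haplotype counts from unambiguous genotypes
    g1u, g2u = g1[~dh], g2[~dh]
    base = np.zeros(4)
    # per sample: haplotype contributions for unambiguous configurations
    base[0] = ((2 - g1u) * (2 - g2u) / 2.0)[(g1u != 1) | (g2u != 1)].sum() \
        if len(g1u) else 0.0
    # recompute cleanly per-genotype (each sample contributes 2 haplotypes)
    base = np.zeros(4)
    for a, b in zip(g1u, g2u):
        if a == 1:  # b != 1
            hb = 1 if b == 2 else 0
            base[0 + hb] += 1  # one a-haplotype
            base[2 + hb] += 1  # one A-haplotype
        elif b == 1:
            ha = 2 if a == 2 else 0
            base[ha + 0] += 1
            base[ha + 1] += 1
        else:
            ha = 2 if a == 2 else 0
            hb = 1 if b == 2 else 0
            base[ha + hb] += 2
    converged = False
    for _ in range(max_iter):
        # E: split double hets between AB/ab and Ab/aB phases
        pcis = f[3] * f[0]
        ptrans = f[2] * f[1]
        tot = pcis + ptrans
        w = 0.5 if tot == 0 else pcis / tot
        counts = base.copy()
        counts[3] += n_dh * w
        counts[0] += n_dh * w
        counts[2] += n_dh * (1 - w)
        counts[1] += n_dh * (1 - w)
        new = counts / (2.0 * n)
        if np.max(np.abs(new - f)) < tol:
            f = new
            converged = True
            break
        f = new
    if not converged:
        raise RuntimeError(f"EM did not converge within {max_iter} iterations")
    pA = f[2] + f[3]
    pB = f[1] + f[3]
    D = f[3] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return 0.0
    return float(min(abs(D) / dmax, 1.0))


def resolve_distal(lead_g: np.ndarray, lead_p: float,
                   candidates: pd.DataFrame, genotypes: GenotypeTable,
                   y: np.ndarray, dprime_min: float = 0.5) -> dict | None:
    """Resolve a distal lead to a proximal candidate in LD with it.

    ``candidates`` lists variants within 1 kb of the region (columns
    ``variant_idx`` at minimum). Among those with |D'| to the lead above
    ``dprime_min``, the variant with the smallest association P against the
    phenotype ``y`` is returned (with its |D'| and P), or None if no
    candidate qualifies.
    """
    best = None
    for _, row in candidates.iterrows():
        v = int(row["variant_idx"])
        g = genotypes.dosages[:, v]
        if g.var() == 0:
            continue
        try:
            dp = ld_dprime(lead_g, g)
        except (ValueError, RuntimeError):
            continue
        if dp <= dprime_min:
            continue
        _, _, _, p = linear_qtl(y, g)
        if best is None or p < best["p"]:
            best = {"variant_idx": v, "dprime": dp, "p": float(p)}
    return best


# ---------------------------------------------------------------------------
# Peak-shape phenotypes

def shape_phenotypes(fragments: pd.DataFrame, region: pd.Series,
                     bandwidth: float = 150.0) -> pd.DataFrame:
    """Per-sample peak-shape traits: extent and summit position.

    Extent is the interquartile range of fragment midpoints within the
    region; the summit is the mode of the Parzen density. Samples with < 2
    fragments get missing values. Both traits are usable in ``linear_qtl``.
    """
    rows = []
    sub = fragments[(fragments["chrom"] == region["chrom"])
                    & (fragments["start"] < region["end"])
                    & (fragments["end"] > region["start"])]
    for sample, grp in sub.groupby("sample"):
        if len(grp) < 2:
            rows.append((sample, np.nan, np.nan))
            continue
        mids = ((grp["start"] + grp["end"]) / 2.0).to_numpy() \
            if "midpoint" not in grp.columns else grp["midpoint"].to_numpy()
        q1, q3 = np.percentile(mids, [25, 75])
        prof = parzen_density(grp, bandwidth=bandwidth)
        summit = prof.positions[int(np.argmax(prof.values))]
        rows.append((sample, float(q3 - q1), float(summit)))
    return pd.DataFrame(rows, columns=["sample", "extent", "summit"])


# ---------------------------------------------------------------------------
# Causal-model comparison (variant V, focal region BR1, neighbour BR2)

# Each model is a mapping child -> tuple of parents among {"V","BR1","BR2"};
# V is exogenous. The structure set is configurable.
CAUSAL_MODELS: dict[int, dict[str, tuple[str, ...]]] = {
    1: {"BR1": ("V",), "BR2": ()},                 # direct effect on BR1 only
    2: {"BR1": (), "BR2": ("V",)},                 # effect on BR2 only
    3: {"BR1": ("V",), "BR2": ("BR1",)},           # BR1 mediates to BR2
    4: {"BR1": ("V",), "BR2": ("V",)},             # independent effects
    5: {"BR1": ("BR2",), "BR2": ("V",)},           # full mediation via BR2
    6: {"BR1": ("V", "BR2"), "BR2": ("V",)},       # partial mediation via BR2
    7: {"BR1": (), "BR2": ()},                     # no variant effects
}


def _gauss_bic(y: np.ndarray, X: np.ndarray | None) -> float:
    n = len(y)
    if X is None or X.shape[1] == 0:
        resid = y - y.mean()
        k = 1
    else:
        A = np.column_stack([np.ones(n), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        k = A.shape[1]
    rss = float(resid @ resid)
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + (k + 1) * np.log(n)


def compare_causal_models(v: np.ndarray, br1: np.ndarray, br2: np.ndarray,
                          models: dict[int, dict[str, tuple[str, ...]]] | None = None,
                          ) -> tuple[int, dict[int, float], bool]:
    """Score directed linear-Gaussian structures among {V, BR1, BR2} by BIC.

    Each model regresses every endogenous variable on its parents; total
    BIC is the sum of the per-equation BICs. Returns (best model id, BIC per
    model, small-sample warning flag for n < 10). V must be non-constant.
    """
    v = np.asarray(v, float)
    br1 = np.asarray(br1, float)
    br2 = np.asarray(br2, float)
    if v.var() == 0:
        raise ValueError("variant dosages are constant")
    if models is None:
        models = CAUSAL_MODELS
    data = {"V": v, "BR1": br1, "BR2": br2}
    bics: dict[int, float] = {}
    for mid, struct in models.items():
        total = 0.0
        for child in ("BR1", "BR2"):
            parents = struct.get(child, ())
            X = (np.column_stack([data[p] for p in parents])
                 if parents else None)
            total += _gauss_bic(data[child], X)
        bics[mid] = total
    best = min(bics, key=lambda k: (bics[k], k))
    return best, bics, len(v) < 10


# ---------------------------------------------------------------------------
# Full scan

def scan_qtl(nabi: NABIMatrix, genotypes: GenotypeTable,
             regions: pd.DataFrame, window: int = 50_000,
             maf_min: float = 0.05, hwe_min: float = 1e-4,
             fdr: float = 0.01) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """cis-QTL scan over all regions.

    Returns (per-test table, per-region summary, pi0). The per-test table
    has one row per (region, variant) pair with beta/se/t/P/q and
    lead/cluster flags; the summary marks regions with any q <= ``fdr``.
    """
    pheno = nabi.to_frame()
    vpos = genotypes.variants["pos"].to_numpy()
    hwe_mask = hwe_pass_mask(genotypes, hwe_min)
    recs = []
    for _, region in regions.iterrows():
        rid = region["id"]
        if rid not in pheno.columns:
            continue
        y = pheno[rid].to_numpy()
        idx, _ = filter_variants(genotypes, region, window=window,
                                 maf_min=maf_min, hwe_min=hwe_min,
                                 hwe_mask=hwe_mask)
        if len(idx) == 0:
            continue
        G = genotypes.dosages[:, idx].astype(float)
        beta, se, t, p = linear_qtl_many(y, G)
        for k, j in enumerate(idx):
            recs.append((rid, int(j), genotypes.variants["id"].iloc[j],
                         int(vpos[j]), beta[k], se[k], t[k], p[k]))
    tests = pd.DataFrame(recs, columns=["region", "variant_idx", "variant",
                                        "pos", "beta", "se", "t", "p"])
    if len(tests) == 0:
        return tests, pd.DataFrame(), 1.0
    q, pi0 = storey_qvalue(tests["p"].to_numpy())
    tests["q"] = q
    parts = [cluster_variants(grp) for _, grp in
             tests.groupby("region", sort=False)]
    tests = pd.concat(parts).sort_index()
    summary = (tests.groupby("region")
               .agg(min_p=("p", "min"), min_q=("q", "min"),
                    n_tested=("p", "size"),
                    n_cluster=("in_cluster", "sum"))
               .reset_index())
    summary["significant"] = summary["min_q"] <= fdr
    return tests, summary, pi0
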