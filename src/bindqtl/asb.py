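"""Allele-specific binding at heterozygous sites.

Reads covering a heterozygous variant inside a binding region are split by
allele — oriented as ancestral (shared with chimpanzee) versus derived to
sidestep reference-alignment bias — and tested against a binomial null of
equal occupancy of the two alleles. Testable sample-site pairs (>= 2 reads
per allele, >= 2 reads difference) are adjusted by Benjamini-Hochberg at 5%
FDR; a site counts as allele-specific when significant in at least two
individuals. Sites are then classified as consistent (all significant
individuals favour the same allele) or switching, switching sites are
searched for an explanatory linked variant, and the population-level
preference for the ancestral allele is summarised.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "asb_test",
    "testability_filter",
    "fdr_and_replicate",
    "consistency_classify",
    "explain_switching",
    "ancestral_bias_summary",
    "asb_qtl_concordance",
]


def asb_test(ancestral_count: int, derived_count: int) -> tuple[float, bool]:
    """Exact two-sided binomial P at theta = 0.5.

    Two-sided by the minimum-likelihood convention: the P-value sums the
    probabilities of all outcomes no more probable than the observed one.
    Returns (P, testable-at-all flag); (0, 0) gives P = 1 flagged
    untestable.
    """
    a, d = int(ancestral_count), int(derived_count)
    if a < 0 or d < 0:
        raise ValueError("counts must be >= 0")
    n = a + d
    if n == 0:
        return 1.0, False
    return _binom_two_sided(a, n), True


@lru_cache(maxsize=100_000)
def _binom_two_sided(k: int, n: int) -> float:
    return float(stats.binomtest(k, n, 0.5).pvalue)


def testability_filter(ancestral_count: int, derived_count: int) -> bool:
    """True iff both alleles have >= 2 reads and they differ by >= 2 reads."""
    a, d = int(ancestral_count), int(derived_count)
    return min(a, d) >= 2 and abs(a - d) >= 2


def fdr_and_replicate(counts: pd.DataFrame, fdr: float = 0.05,
                      min_samples: int = 2) -> pd.DataFrame:
    """Per-site ASB calls with BH adjustment and replication requirement.

    ``counts`` has one row per (site, sample) heterozygote with columns
    ``site``, ``sample``, ``ancestral_count``, ``derived_count``. BH runs
    across all testable sample-site tests; a site is kept when significant
    in >= ``min_samples`` individuals. Returns a per-site table with the
    number of significant samples, mean ancestral proportion over all het
    samples, and per-direction counts of significant samples.
    """
    df = counts.copy()
    df["testable"] = [testability_filter(a, d) for a, d in
                      zip(df["ancestral_count"], df["derived_count"])]
    df["p"] = [asb_test(a, d)[0] for a, d in
               zip(df["ancestral_count"], df["derived_count"])]
    df["significant"] = False
    testable = df.index[df["testable"]]
    if len(testable):
        rej, _, _, _ = multipletests(df.loc[testable, "p"], alpha=fdr,
                                     method="fdr_bh")
        df.loc[testable, "significant"] = rej
    tot = df["ancestral_count"] + df["derived_count"]
    df["prop_ancestral"] = np.where(tot > 0, df["ancestral_count"] / tot, np.nan)
    sig = df[df["significant"]]
    rows = []
    for site, grp in df.groupby("site", sort=False):
        s = sig[sig["site"] == site]
        n_sig = len(s)
        if n_sig < min_samples:
            continue
        n_up = int((s["prop_ancestral"] > 0.5).sum())
        n_down = int((s["prop_ancestral"] < 0.5).sum())
        rows.append({
            "site": site,
            "n_het": len(grp),
            "n_significant": n_sig,
            "n_favor_ancestral": n_up,
            "n_favor_derived": n_down,
            "mean_prop_ancestral": float(grp["prop_ancestral"].mean()),
        })
    sites = pd.DataFrame(rows)
    if len(sites):
        sites["consistency"] = [consistency_classify(r)
                                for _, r in sites.iterrows()]
    else:
        sites = pd.DataFrame(columns=["site", "n_het", "n_significant",
                                      "n_favor_ancestral", "n_favor_derived",
                                      "mean_prop_ancestral", "consistency"])
    sites.attrs["per_test"] = df
    return sites


def consistency_classify(site_row: pd.Series) -> str:
    """'consistent' if all significant individuals favour the same allele,
    'switching' otherwise."""
    up = int(site_row["n_favor_ancestral"])
    down = int(site_row["n_favor_derived"])
    if up + down < 2:
        raise ValueError("classification needs >= 2 significant samples")
    return "consistent" if (up == 0 or down == 0) else "switching"


def explain_switching(site_counts: pd.DataFrame, genotypes,
                      candidate_idx: np.ndarray,
                      alpha: float = 0.05) -> dict | None:
    """Search for a linked variant explaining a switching site.

    For each candidate variant, significant heterozygous samples at the
    switching site are partitioned by bias direction and cross-tabulated
    against carrying the candidate's alternate allele; Fisher's exact test
    P-values are BH-adjusted over candidates and the best variant with
    adjusted P < ``alpha`` is returned, else None.

    ``site_counts`` rows are the significant samples at the site with
    ``sample`` and ``prop_ancestral`` columns.
    """
    if len(candidate_idx) == 0:
        return None
    sample_pos = {s: i for i, s in enumerate(genotypes.samples)}
    rows = site_counts.dropna(subset=["prop_ancestral"])
    samples = [sample_pos[s] for s in rows["sample"]]
    direction = (rows["prop_ancestral"] > 0.5).to_numpy()
    if len(set(direction)) < 2:
        return None
    results = []
    for v in candidate_idx:
        carrier = genotypes.dosages[samples, int(v)] > 0
        table = [[int((direction & carrier).sum()),
                  int((direction & ~carrier).sum())],
                 [int((~direction & carrier).sum()),
                  int((~direction & ~carrier).sum())]]
        _, p = stats.fisher_exact(table)
        results.append((int(v), float(p)))
    pvals = np.array([p for _, p in results])
    rej, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    if not rej.any():
        return None
    best = int(np.argmin(p_adj))
    return {"variant_idx": results[best][0], "p": float(pvals[best]),
            "p_adjusted": float(p_adj[best])}


def ancestral_bias_summary(sites: pd.DataFrame) -> tuple[float, float]:
    """Fraction of consistent sites favouring the ancestral allele and the
    two-sided binomial P against 0.5."""
    cons = sites[sites["consistency"] == "consistent"]
    if len(cons) == 0:
        raise ValueError("no consistent sites")
    favoring = int((cons["mean_prop_ancestral"] > 0.5).sum())
    n = len(cons)
    p = float(stats.binomtest(favoring, n, 0.5).pvalue)
    return favoring / n, p


def asb_qtl_concordance(asb_sites: pd.DataFrame, qtl_records: pd.DataFrame,
                        ) -> tuple[pd.DataFrame, dict]:
    """Pair per-site allele-specific proportions with in-region QTL betas.

    ``asb_sites`` must carry ``site`` and ``mean_prop_ancestral``;
    ``qtl_records`` must carry ``variant`` (matching ``site``) and ``beta``
    oriented so positive means more binding to the counted (ancestral)
    allele. Returns the paired table and Pearson/Spearman correlations
    (flagged undefined with < 2 pairs).
    """
    merged = asb_sites.merge(qtl_records, left_on="site", right_on="variant",
                             how="inner")
    if len(merged) < 2:
        return merged, {"pearson": np.nan, "spearman": np.nan,
                        "undefined": True}
    x = merged["mean_prop_ancestral"].to_numpy()
    y = merged["beta"].to_numpy()
    pear = float(stats.pearsonr(x, y)[0])
    spear = float(stats.spearmanr(x, y)[0])
    return merged, {"pearson": pear, "spearman": spear, "undefined": False}
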