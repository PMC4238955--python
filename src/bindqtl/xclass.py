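"""X-chromosome binding-mode classification.

In females one X is randomly inactivated; a binding site bound on both the
active and inactive X ("both-active") shows roughly twice the female signal
relative to males, a site bound only on the active copy ("single-active")
shows equal signal in both sexes, and a small "female-specific" class shows
male signal at background. Classification uses a Mann-Whitney U test of
male versus female depth-adjusted raw counts (raw, not NABI, so the
normalization cannot erase the sex effect) plus the female/male fold
change. Clonality of female lines is inferred from allelic RNA expression
at known X-inactivated genes, and clonal lines are used to validate the
classes by allele-specific binding balance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mwu_gender_test",
    "dosage_metric",
    "classify_x_sites",
    "assess_clonality",
    "x_allele_validation",
    "aggregate_signal",
]

PAR_INTERVALS = (  # pseudoautosomal regions, GRCh37 chrX coordinates
    (60001, 2699520),
    (154931044, 155260560),
)


def mwu_gender_test(counts: np.ndarray, sex_labels: np.ndarray,
                    ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of one region's counts by sex.

    Exact enumeration for small tie-free groups, normal approximation with
    tie correction otherwise. Returns (U of the female group, P).
    """
    counts = np.asarray(counts, dtype=float)
    sex = np.asarray(sex_labels)
    f = counts[sex == "F"]
    m = counts[sex == "M"]
    if len(f) == 0 or len(m) == 0:
        raise ValueError("both sexes must be represented")
    has_ties = len(np.unique(counts)) < len(counts)
    method = "exact" if (max(len(f), len(m)) <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(f, m, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def dosage_metric(counts: np.ndarray, sex_labels: np.ndarray,
                  depths: np.ndarray) -> float:
    """Female-minus-male mean depth-adjusted signal, scaled by region mean.

    ~0 for single-active sites, positive (toward +2/3 of the region mean
    difference scale) for both-active sites, extreme for female-specific
    sites.
    """
    counts = np.asarray(counts, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if np.any(depths <= 0):
        raise ValueError("depths must be > 0")
    sex = np.asarray(sex_labels)
    adj = counts / depths
    fmean = adj[sex == "F"].mean()
    mmean = adj[sex == "M"].mean()
    scale = adj.mean()
    return float((fmean - mmean) / scale) if scale > 0 else 0.0


def classify_x_sites(counts: np.ndarray, sex_labels: np.ndarray,
                     depths: np.ndarray, region_ids=None,
                     mwu_alpha: float = 0.01,
                     female_specific_male_max: float | None = None,
                     female_specific_fold_min: float = 4.0,
                     par_intervals=PAR_INTERVALS,
                     region_starts: np.ndarray | None = None,
                     region_ends: np.ndarray | None = None) -> pd.DataFrame:
    """Label X-chromosome regions by binding mode.

    Non-significant MWU -> single-active; significant -> both-active unless
    the site is consistent with no male binding at all: male signal at or
    below the background threshold (default: the 10th percentile of male
    mean depth-adjusted signal across regions) *and* a female/male fold
    change of at least ``female_specific_fold_min`` (well beyond the ~2x of
    a site bound on both female X copies), in which case female-specific.
    Regions intersecting a pseudoautosomal interval are excluded before
    testing when coordinates are provided.
    """
    X = np.asarray(counts, dtype=float)
    n_regions = X.shape[1]
    if region_ids is None:
        region_ids = [f"XR{i}" for i in range(n_regions)]
    keep = np.ones(n_regions, dtype=bool)
    if region_starts is not None and region_ends is not None:
        for lo, hi in par_intervals:
            keep &= ~((region_starts < hi) & (region_ends > lo))
    sex = np.asarray(sex_labels)
    depths = np.asarray(depths, dtype=float)
    adj = X / depths[:, None]
    male_means = adj[sex == "M"].mean(axis=0)
    if female_specific_male_max is None:
        female_specific_male_max = float(np.quantile(male_means[keep], 0.10))
    rows = []
    for i in np.flatnonzero(keep):
        u, p = mwu_gender_test(X[:, i], sex)
        metric = dosage_metric(X[:, i], sex, depths)
        fmean = adj[sex == "F", i].mean()
        mmean = male_means[i]
        fold = fmean / mmean if mmean > 0 else np.inf
        if p >= mwu_alpha:
            label = "single-active"
        elif mmean <= female_specific_male_max and fold >= female_specific_fold_min:
            label = "female-specific"
        else:
            label = "both-active"
        rows.append({"region": region_ids[i], "mwu_p": p,
                     "male_mean": float(mmean), "female_mean": float(fmean),
                     "dosage_metric": metric, "fold_change": float(fold),
                     "label": label})
    return pd.DataFrame(rows)


def assess_clonality(rna_allele_counts: pd.DataFrame,
                     strict_genes: set[str] | None = None,
                     minor_fraction_max: float = 0.15) -> pd.DataFrame:
    """Call clonal versus polyclonal X inactivation per female sample.

    ``rna_allele_counts`` rows are heterozygous RNA sites with columns
    ``sample``, ``gene``, ``ref_count``, ``alt_count`` and ``xi_status``
    ("inactivated" for strictly silenced genes). A sample is clonal when its
    aggregate minor-allele fraction across strictly inactivated genes is at
    most ``minor_fraction_max`` (monoallelic expression); samples without
    informative sites are uncallable.
    """
    df = rna_allele_counts
    strict = df[df["xi_status"] == "inactivated"]
    if strict_genes is not None:
        strict = strict[strict["gene"].isin(strict_genes)]
    rows = []
    for sample, grp in df.groupby("sample", sort=False):
        g = strict[strict["sample"] == sample]
        tot = (g["ref_count"] + g["alt_count"]).sum()
        if tot == 0:
            rows.append({"sample": sample, "minor_fraction": np.nan,
                         "call": "uncallable"})
            continue
        minor = np.minimum(g["ref_count"], g["alt_count"]).sum()
        frac = minor / tot
        rows.append({"sample": sample, "minor_fraction": float(frac),
                     "call": "clonal" if frac <= minor_fraction_max
                     else "polyclonal"})
    return pd.DataFrame(rows)


def x_allele_validation(het_counts: pd.DataFrame,
                        class_labels: pd.DataFrame,
                        clonal_samples: set[str]) -> dict:
    """Allele-balance distributions per X class in clonal female lines.

    ``het_counts`` rows carry ``region``, ``sample``, ``a_count``,
    ``b_count`` at heterozygous sites; only samples in ``clonal_samples``
    are used. Single-active sites should show near-monoallelic binding
    (max-allele fraction near 1), both-active sites balanced (near 0.5);
    a one-sided MWU P for single-active > both-active is reported.
    """
    df = het_counts[het_counts["sample"].isin(clonal_samples)].copy()
    tot = df["a_count"] + df["b_count"]
    df = df[tot > 0]
    df["max_frac"] = np.maximum(df["a_count"], df["b_count"]) / (
        df["a_count"] + df["b_count"])
    lab = class_labels.set_index("region")["label"]
    df["label"] = df["region"].map(lab)
    out = {"distributions": {}}
    for cls, grp in df.groupby("label"):
        out["distributions"][cls] = grp["max_frac"].to_numpy()
    sa = out["distributions"].get("single-active", np.empty(0))
    ba = out["distributions"].get("both-active", np.empty(0))
    if len(sa) and len(ba):
        res = stats.mannwhitneyu(sa, ba, alternative="greater")
        out["mwu_p"] = float(res.pvalue)
    else:
        out["mwu_p"] = np.nan
    return out


def aggregate_signal(regions: pd.DataFrame, signal_track: pd.DataFrame,
                     labels: pd.Series | None = None,
                     nbins: int = 50) -> pd.DataFrame:
    """Class-averaged signal profiles over length-rescaled regions.

    Each region is rescaled to ``nbins`` bins; the mean of the step-wise
    ``signal_track`` (columns ``pos``, ``value``, one value per position
    run, sorted) is taken per bin, and profiles are averaged within each
    class. Regions shorter than ``nbins`` bp are interpolated and flagged.
    """
    pos = signal_track["pos"].to_numpy()
    val = signal_track["value"].to_numpy()

    def value_at(x):
        i = np.clip(np.searchsorted(pos, x, side="right") - 1, 0, len(pos) - 1)
        return val[i]

    profiles, flags = [], []
    for _, r in regions.iterrows():
        length = int(r["end"]) - int(r["start"])
        flags.append(length < nbins)
        edges = np.linspace(r["start"], r["end"], nbins + 1)
        binned = np.empty(nbins)
        for b in range(nbins):
            xs = np.arange(int(np.floor(edges[b])),
                           max(int(np.ceil(edges[b + 1])), int(np.floor(edges[b])) + 1))
            binned[b] = value_at(xs).mean()
        profiles.append(binned)
    prof = np.vstack(profiles)
    if labels is None:
        labels = pd.Series(["all"] * len(regions), index=regions.index)
    rows = {}
    for cls in labels.unique():
        rows[cls] = prof[(labels == cls).to_numpy()].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.columns = [f"bin{b}" for b in range(nbins)]
    out.attrs["short_region_flags"] = flags
    return out
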