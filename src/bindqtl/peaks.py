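"""Binding-region calling: kernel density peaks, input correction, merging.

Per sample, fragment midpoints are smoothed with a Gaussian (Parzen) kernel
on a fixed grid; local maxima of the density define candidate summits, and
the interquartile range of the density mass in each summit's watershed
defines the binding site. Candidate sites are tested for enrichment over the
input (control) library with a depth-scaled one-sided binomial test,
adjusted by Benjamini-Hochberg, thresholded, merged across samples keeping
the set of calling samples, and filtered against a blacklist.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DensityProfile",
    "CandidatePeak",
    "parzen_density",
    "call_candidates",
    "input_correct",
    "adjust_and_threshold",
    "merge_across_samples",
    "blacklist_filter",
]

DEFAULT_BANDWIDTH = 150.0
DEFAULT_GRID_STEP = 10


@dataclass
class DensityProfile:
    """Gaussian-kernel density of fragment midpoints on a regular grid."""

    chrom: str
    start: int
    step: int
    values: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self.values))


@dataclass
class CandidatePeak:
    chrom: str
    summit: int
    site_start: int
    site_end: int
    chip_count: int = 0
    input_count: int = 0
    p_value: float = np.nan
    p_adjusted: float = np.nan
    input_dominated: bool = False
    sample: str = ""


def parzen_density(fragments: pd.DataFrame, bandwidth: float = DEFAULT_BANDWIDTH,
                   step: int = DEFAULT_GRID_STEP,
                   pad: float | None = None) -> DensityProfile:
    """Gaussian kernel density of fragment midpoints on a fixed grid.

    The density at grid position x is sum_i N(x; m_i, bandwidth^2), so it
    integrates to the fragment count. Empty input yields an empty profile.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if len(fragments) == 0:
        return DensityProfile(chrom="", start=0, step=step,
                              values=np.empty(0))
    chroms = fragments["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError("fragments must lie on a single chromosome")
    mids = _midpoints(fragments)
    lo = int(np.floor(mids.min() - (pad if pad is not None else 4 * bandwidth)))
    hi = int(np.ceil(mids.max() + (pad if pad is not None else 4 * bandwidth)))
    grid = np.arange(lo, hi + step, step, dtype=float)
    norm = 1.0 / (bandwidth * np.sqrt(2.0 * np.pi))
    # Direct kernel sum, chunked over fragments to bound memory.
    values = np.zeros_like(grid)
    for chunk in np.array_split(mids, max(1, len(mids) // 2000 + 1)):
        z = (grid[None, :] - chunk[:, None]) / bandwidth
        values += norm * np.exp(-0.5 * z * z).sum(axis=0)
    return DensityProfile(chrom=str(chroms[0]), start=lo, step=step,
                          values=values)


def _midpoints(fragments: pd.DataFrame) -> np.ndarray:
    if "midpoint" in fragments.columns:
        return fragments["midpoint"].to_numpy(dtype=float)
    return (fragments["start"].to_numpy(dtype=float)
            + fragments["end"].to_numpy(dtype=float)) / 2.0


def call_candidates(profile: DensityProfile,
                    bandwidth: float = DEFAULT_BANDWIDTH,
                    noise_fragments: float = 2.0) -> list[CandidatePeak]:
    """Candidate peaks at local maxima of the density above a noise floor.

    The noise floor is the peak density contributed by ``noise_fragments``
    fragments within one bandwidth. Each local maximum's site is the
    interquartile interval of the density mass within its watershed (the
    grid segment delimited by the adjacent local minima).
    """
    v = profile.values
    if len(v) < 3:
        return []
    floor = noise_fragments / (bandwidth * np.sqrt(2.0 * np.pi))
    interior = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])) + 1
    maxima = [i for i in interior if v[i] > floor]
    if not maxima:
        return []
    # Watershed boundaries: minima between consecutive retained maxima.
    bounds = [0]
    for a, b in zip(maxima[:-1], maxima[1:]):
        bounds.append(a + int(np.argmin(v[a:b + 1])))
    bounds.append(len(v) - 1)
    peaks = []
    pos = profile.positions
    for k, i in enumerate(maxima):
        lo, hi = bounds[k], bounds[k + 1]
        seg = v[lo:hi + 1]
        mass = np.cumsum(seg)
        if mass[-1] <= 0:
            continue
        mass = mass / mass[-1]
        q1 = lo + int(np.searchsorted(mass, 0.25))
        q3 = lo + int(np.searchsorted(mass, 0.75))
        peaks.append(CandidatePeak(chrom=profile.chrom, summit=int(pos[i]),
                                   site_start=int(pos[q1]),
                                   site_end=int(pos[q3]) + profile.step))
    return peaks


def input_correct(chip_count: float, input_count: float,
                  chip_depth: float, input_depth: float) -> tuple[float, bool]:
    """One-sided binomial enrichment P of ChIP over input.

    The library with higher sequencing depth is scaled down by the depth
    ratio before testing; the null is that a fragment is equally likely to
    come from either library. Returns (P, input_dominated) where the flag
    marks sites whose depth-scaled ChIP count does not exceed the scaled
    input count (these are discarded downstream).
    """
    if chip_count < 0 or input_count < 0:
        raise ValueError("counts must be >= 0")
    if chip_depth <= 0 or input_depth <= 0:
        raise ValueError("depths must be > 0")
    chip_s, input_s = float(chip_count), float(input_count)
    if chip_depth > input_depth:
        chip_s *= input_depth / chip_depth
    elif input_depth > chip_depth:
        input_s *= chip_depth / input_depth
    k = int(round(chip_s))
    n = k + int(round(input_s))
    if n == 0:
        return 1.0, True
    p = float(stats.binom.sf(k - 1, n, 0.5))
    return p, chip_s <= input_s


def adjust_and_threshold(candidates: list[CandidatePeak],
                         alpha: float = 1e-5) -> list[CandidatePeak]:
    """Benjamini-Hochberg adjustment; keep adjusted P <= alpha.

    Input-dominated candidates are dropped before adjustment.
    """
    testable = [c for c in candidates if not c.input_dominated]
    if not testable:
        return []
    pvals = np.array([c.p_value for c in testable])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    kept = []
    for c, pa in zip(testable, p_adj):
        c.p_adjusted = float(pa)
        if pa <= alpha:
            kept.append(c)
    return kept


def merge_across_samples(per_sample_peaks: dict[str, list[CandidatePeak]],
                         min_callers: int = 2) -> pd.DataFrame:
    """Union overlapping per-sample sites into merged binding regions.

    The set of calling samples is preserved per merged region; regions
    called by fewer than ``min_callers`` samples are discarded.
    """
    if len(per_sample_peaks) < 2:
        raise ValueError("need peaks from >= 2 samples to merge")
    rows = []
    for sample, peaks in per_sample_peaks.items():
        for c in peaks:
            rows.append((c.chrom, c.site_start, c.site_end, sample))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "callers",
                                     "n_callers"])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample"])
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"]).reset_index(drop=True)
        cur_start, cur_end = int(grp.start[0]), int(grp.end[0])
        callers = {grp["sample"][0]}
        for _, r in grp.iloc[1:].iterrows():
            if r.start < cur_end:  # overlap (half-open)
                cur_end = max(cur_end, int(r.end))
                callers.add(r["sample"])
            else:
                out.append((chrom, cur_start, cur_end, sorted(callers)))
                cur_start, cur_end, callers = int(r.start), int(r.end), {r["sample"]}
        out.append((chrom, cur_start, cur_end, sorted(callers)))
    merged = pd.DataFrame(out, columns=["chrom", "start", "end", "callers"])
    merged["n_callers"] = merged["callers"].map(len)
    return merged[merged["n_callers"] >= min_callers].reset_index(drop=True)


def blacklist_filter(regions: pd.DataFrame, blacklist: pd.DataFrame,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove blacklisted regions; record the removal reason per category.

    ``blacklist`` rows carry chrom, start, end and a category. Regions
    *completely contained* in a "repeat" interval are removed; regions
    *overlapping* a "locus" interval (e.g. the immunoglobulin heavy-chain or
    MHC loci) are removed. Returns (kept regions, removal log).
    """
    if len(blacklist) == 0:
        return regions.reset_index(drop=True), pd.DataFrame(
            columns=["chrom", "start", "end", "reason"])
    removed_reason = {}
    for _, b in blacklist.iterrows():
        cat = b.get("category", "repeat")
        same = regions["chrom"] == b.chrom
        if cat == "repeat":
            hit = same & (regions["start"] >= b.start) & (regions["end"] <= b.end)
        else:  # locus-level: any overlap removes
            hit = same & (regions["start"] < b.end) & (regions["end"] > b.start)
        for i in regions.index[hit]:
            removed_reason.setdefault(i, str(cat))
    keep = regions.loc[~regions.index.isin(removed_reason)].reset_index(drop=True)
    log = regions.loc[sorted(removed_reason)].copy()
    log["reason"] = [removed_reason[i] for i in sorted(removed_reason)]
    return keep, log.reset_index(drop=True)[["chrom", "start", "end", "reason"]]
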