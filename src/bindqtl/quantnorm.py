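"""Fragment counting, low-signal filtering and NABI normalization.

The normalized adjusted binding intensity (NABI) pipeline transforms the raw
lanes x regions fragment-count matrix in six ordered steps: (1) rescale each
lane to the mean total depth; (2) remove GC-composition bias by subtracting
the per-lane median within 100 GC-percentile bins; (3) merge lanes of the
same individual by the mean; (4) centre-scale each region across samples;
(5) quantile-map each sample's values to normal quantiles; (6) remove the
top principal component(s), which absorb batch and other latent confounders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import RawCountMatrix

__all__ = [
    "NABIMatrix",
    "count_fragments",
    "filter_low_signal",
    "nabi_normalize",
    "pc_scan",
    "quantile_to_normal",
]

NABI_STEPS = ("depth", "gc", "lane_merge", "center_scale", "quantile", "pca")


@dataclass
class NABIMatrix:
    """Samples x regions normalized adjusted binding intensities.

    ``steps`` is the provenance log of applied normalization steps;
    ``removed_components`` records the PCs removed in step 6 (scores,
    loadings, variance fractions).
    """

    values: np.ndarray
    samples: list[str]
    region_ids: list[str]
    steps: tuple[str, ...] = ()
    removed_components: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples,
                            columns=self.region_ids)


def count_fragments(fragments: pd.DataFrame, regions: pd.DataFrame,
                    min_mapq: int = 30, max_mate_distance: int = 1000,
                    ) -> pd.DataFrame:
    """Count filtered fragments per region per sample.

    Fragments failing MAPQ >= ``min_mapq``, proper pairing, duplicate
    removal, or mate distance <= ``max_mate_distance`` are excluded. A
    fragment increments every region it intersects by >= 1 bp (half-open
    intervals). Returns a samples x regions count DataFrame.
    """
    samples = sorted(fragments["sample"].unique()) if len(fragments) else []
    region_ids = list(regions["id"]) if "id" in regions.columns else \
        [f"R{i}" for i in range(len(regions))]
    out = pd.DataFrame(0, index=samples, columns=region_ids, dtype=int)
    if len(regions) == 0 or len(fragments) == 0:
        return out
    ok = ((fragments["mapq"] >= min_mapq)
          & fragments["proper_pair"]
          & ~fragments["duplicate"]
          & (fragments["mate_distance"] <= max_mate_distance))
    frag = fragments.loc[ok]
    for chrom, rgrp in regions.groupby("chrom"):
        fg = frag[frag["chrom"] == chrom]
        if len(fg) == 0:
            continue
        fs = fg["start"].to_numpy()
        fe = fg["end"].to_numpy()
        fsample = fg["sample"].to_numpy()
        for ridx, r in rgrp.iterrows():
            rid = region_ids[ridx] if "id" not in regions.columns else r["id"]
            hit = (fs < r["end"]) & (fe > r["start"])
            if hit.any():
                vc = pd.Series(fsample[hit]).value_counts()
                out.loc[vc.index, rid] += vc.to_numpy()
    return out


def filter_low_signal(matrix: RawCountMatrix, mean_thresh: float = 6.0,
                      sd_thresh: float = 5.14,
                      ) -> tuple[RawCountMatrix, list[str]]:
    """Drop regions with little signal *and* little variation.

    A region is removed only when its mean count per sample is below
    ``mean_thresh`` and its SD is below ``sd_thresh`` (both conditions
    must hold). Returns the filtered matrix and the removed region ids.
    """
    mean = matrix.counts.mean(axis=0)
    sd = matrix.counts.std(axis=0, ddof=1)
    low = (mean < mean_thresh) & (sd < sd_thresh)
    removed = [matrix.regions["id"].iloc[i] for i in np.flatnonzero(low)]
    keep = ~low
    filtered = RawCountMatrix(
        counts=matrix.counts[:, keep],
        regions=matrix.regions.loc[keep].reset_index(drop=True),
        lanes=matrix.lanes, lane_map=matrix.lane_map,
        sample_meta=matrix.sample_meta)
    return filtered, removed


def quantile_to_normal(x: np.ndarray) -> np.ndarray:
    """Map values to normal quantiles Phi^-1(rank/(M+1)), average-rank ties."""
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (len(x) + 1.0))


def nabi_normalize(matrix: RawCountMatrix, gc_bins: int = 100,
                   n_pcs: int = 1) -> NABIMatrix:
    """Run the six-step NABI normalization on a raw count matrix.

    Steps are applied strictly in order (see module docstring); the output
    records the provenance and the removed principal components. A region
    with zero SD at the centre-scale step raises an error naming the region
    (such regions should have been removed by the low-signal filter).
    """
    X = matrix.counts.astype(float).copy()
    region_ids = list(matrix.regions["id"])
    gc = matrix.regions["gc"].to_numpy()
    steps: list[str] = []

    # 1. Rescale by sequence depth: lane total -> mean lane total.
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("lane with zero total count")
    X = X * (totals.mean() / totals)[:, None]
    steps.append("depth")

    # 2. GC bias: subtract the per-lane median within GC-percentile bins.
    # Bin count is capped so each bin holds >= ~20 regions: with sparsely
    # populated bins the bin median tracks individual regions and the
    # subtraction destroys signal instead of removing composition bias.
    n_bins = max(1, min(gc_bins, len(gc) // 20))
    edges = np.quantile(gc, np.linspace(0, 1, n_bins + 1))
    bin_of = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        cols = bin_of == b
        if cols.any():
            X[:, cols] -= np.median(X[:, cols], axis=1, keepdims=True)
    steps.append("gc")

    # 3. Merge lanes per individual by the mean.
    sample_of = [matrix.lane_map[lane] for lane in matrix.lanes]
    samples = list(dict.fromkeys(sample_of))
    merged = np.vstack([
        X[[i for i, s in enumerate(sample_of) if s == smp]].mean(axis=0)
        for smp in samples])
    X = merged
    steps.append("lane_merge")

    # 4. Centre-scale each region across samples.
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(
            f"region {region_ids[zero[0]]} has zero variance across samples; "
            "run the low-signal filter first")
    X = (X - mu) / sd
    steps.append("center_scale")

    # 5. Quantile-map each sample to normal quantiles.
    X = np.vstack([quantile_to_normal(row) for row in X])
    steps.append("quantile")

    # 6. Remove the top principal components by SVD truncation.
    removed: dict = {}
    if n_pcs > 0:
        center = X.mean(axis=0)
        Xc = X - center
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        var_frac = (S**2) / (S**2).sum()
        k = min(n_pcs, len(S))
        X = center + Xc - (U[:, :k] * S[:k]) @ Vt[:k]
        removed = {"scores": U[:, :k] * S[:k], "loadings": Vt[:k],
                   "variance_fraction": var_frac[:k]}
    steps.append("pca")

    return NABIMatrix(values=X, samples=samples, region_ids=region_ids,
                      steps=tuple(steps), removed_components=removed)


def pc_scan(values: np.ndarray, covariates: pd.DataFrame | None = None,
            n_components: int = 10) -> pd.DataFrame:
    """Principal-component scan with covariate correlations.

    Returns one row per component with its variance fraction and, for each
    covariate column, the Spearman correlation between component scores and
    the covariate across samples.
    """
    X = np.asarray(values, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var_frac = (S**2) / (S**2).sum()
    k = min(n_components, len(S))
    scores = U[:, :k] * S[:k]
    rows = []
    for c in range(k):
        row = {"component": c + 1, "variance_fraction": float(var_frac[c])}
        if covariates is not None:
            for name in covariates.columns:
                rho, _ = stats.spearmanr(scores[:, c],
                                         covariates[name].to_numpy())
                row[f"rho_{name}"] = float(rho)
        rows.append(row)
    return pd.DataFrame(rows)
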