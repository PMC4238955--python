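"""Readers for the plain-text formats the pipeline exchanges.

Minimal VCF (GT-only), 6-column BED and header-ed count TSV — the inverse
of the writers in :mod:`bindqtl.synthio`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthio import GenotypeTable, RawCountMatrix

__all__ = ["read_vcf", "read_bed_regions", "read_counts_tsv"]

_GT_DOSAGE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2,
              "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2}


def read_vcf(path) -> GenotypeTable:
    """Read a minimal VCF with GT fields and AA= ancestral INFO tag."""
    samples: list[str] = []
    rows, dosage_rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[:5]
            info = parts[7]
            anc = ref
            for kv in info.split(";"):
                if kv.startswith("AA="):
                    anc = kv[3:]
            gts = [p.split(":")[0] for p in parts[9:]]
            dosage_rows.append([_GT_DOSAGE.get(g, 0) for g in gts])
            rows.append((chrom, int(pos), vid, ref, alt, anc,
                         len(ref) != len(alt)))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref",
                                           "alt", "ancestral", "is_indel"])
    dosages = np.array(dosage_rows, dtype=np.int8).T
    maf = dosages.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(maf, 1 - maf)
    return GenotypeTable(samples=samples, variants=variants, dosages=dosages)


def read_bed_regions(path) -> pd.DataFrame:
    """Read a BED file into the region table (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[3] if len(parts) > 3 else f"BR{len(rows)}"
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
    df["center"] = (df["start"] + df["end"]) // 2
    return df


def read_counts_tsv(path, regions: pd.DataFrame | None = None,
                    ) -> RawCountMatrix:
    """Read a lanes x regions count TSV written by ``write_counts_tsv``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lanes = list(df.index)
    if regions is None:
        regions = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(df.shape[1]) * 1000,
            "end": np.arange(df.shape[1]) * 1000 + 400,
            "id": list(df.columns),
        })
    regions = regions.set_index("id").loc[list(df.columns)].reset_index()
    if "gc" not in regions.columns:
        regions["gc"] = 0.5
    if "center" not in regions.columns:
        regions["center"] = (regions["start"] + regions["end"]) // 2
    return RawCountMatrix(counts=df.to_numpy(dtype=float), regions=regions,
                          lanes=lanes, lane_map={l: l.split("_L")[0]
                                                 for l in lanes})
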