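"""IBD vs polymorphic (non-IBD) window calling from a two-strain SNP catalog.

Two inbred strains descended from common ancestors share long chromosome
stretches identical by descent; regions where they differ carry the causal
variation for a cross between them. Windows tiling a locus are classified
by the count of discordant SNPs they contain. Two dialects of the rule are
supported:

* ``150kb`` - 150,000-bp windows, polymorphic iff count > 50 (strict);
* ``250kb`` - 250,000-bp windows, polymorphic iff count >= 100.

Coordinates: SNP positions are 1-based; windows, blocks and loci are
half-open ``[start, end)`` intervals in the same coordinate, compared
directly (a position exactly on a boundary belongs to the right-hand
window). BED output shifts starts/ends by -1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

IBD = "IBD"
POLYMORPHIC = "POLYMORPHIC"


@dataclass(frozen=True)
class Dialect:
    name: str
    window_bp: int
    min_count: int
    strict: bool  # True: polymorphic iff count > min_count; False: >=

    def is_polymorphic(self, count: int) -> bool:
        return count > self.min_count if self.strict else count >= self.min_count


DIALECTS = {
    "150kb": Dialect("150kb", 150_000, 50, strict=True),
    "250kb": Dialect("250kb", 250_000, 100, strict=False),
}


def read_snp_catalog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return df.sort_values(["chromosome", "position_bp"], ignore_index=True)


def read_snp_catalog_vcf(path: str | Path) -> pd.DataFrame:
    """Read a minimal VCF with per-strain GT columns into the catalog frame
    (chromosome, position_bp, ref, one allele column per sample); missing
    genotypes become '.'."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    rows = []
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        calls = []
        for gt in var.genotypes:
            a = gt[0]
            calls.append("." if a is None or a < 0 else alleles[a])
        rows.append([var.CHROM, var.POS, var.REF] + calls)
    return pd.DataFrame(
        rows, columns=["chromosome", "position_bp", "ref"] + strains
    ).sort_values(["chromosome", "position_bp"], ignore_index=True)


def discordant_positions(
    catalog: pd.DataFrame,
    strain_a: str = "C3H",
    strain_b: str = "NZO",
    chromosome: str | None = None,
) -> np.ndarray:
    """Sorted unique positions where the two strain calls differ and both
    are called (no-calls '.' or empty are excluded)."""
    for strain in (strain_a, strain_b):
        if strain not in catalog.columns:
            raise ValueError(f"strain {strain!r} not in catalog")
    sub = catalog
    if chromosome is not None:
        sub = sub[sub["chromosome"] == chromosome]
    a = sub[strain_a].astype(str).to_numpy()
    b = sub[strain_b].astype(str).to_numpy()
    called = ~(np.isin(a, (".", "")) | np.isin(b, (".", "")))
    diff = called & (a != b)
    return np.unique(sub.loc[diff, "position_bp"].to_numpy(dtype=int))


@dataclass
class WindowSet:
    """Tiling windows over one region with per-window SNP counts and,
    after classification, an IBD/POLYMORPHIC class column."""

    df: pd.DataFrame  # chromosome, start_bp, end_bp, snp_count[, cls]
    window_bp: int
    region: tuple[str, int, int]
    dialect: str | None = None

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def window_counts(
    positions, region: tuple[str, int, int], window_bp: int
) -> WindowSet:
    """Count positions in non-overlapping half-open windows tiling
    ``region``; the last window truncates at the region end."""
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    if window_bp <= 0:
        raise ValueError("window size must be positive")
    pos = np.asarray(positions, dtype=int)
    pos = pos[(pos >= start) & (pos < end)]
    n_windows = int(np.ceil((end - start) / window_bp))
    counts = np.bincount((pos - start) // window_bp, minlength=n_windows)
    starts = start + window_bp * np.arange(n_windows)
    ends = np.minimum(starts + window_bp, end)
    df = pd.DataFrame(
        {"chromosome": chrom, "start_bp": starts, "end_bp": ends, "snp_count": counts}
    )
    return WindowSet(df, window_bp, region)


def classify_windows(window_set: WindowSet, dialect: str | Dialect = "150kb") -> WindowSet:
    """Attach the IBD/POLYMORPHIC class per the dialect's count rule; the
    window size of the set must match the dialect."""
    d = DIALECTS[dialect] if isinstance(dialect, str) else dialect
    if window_set.window_bp != d.window_bp:
        raise ValueError(
            f"window size {window_set.window_bp} does not match dialect "
            f"{d.name} ({d.window_bp})"
        )
    df = window_set.df.copy()
    df["cls"] = [
        POLYMORPHIC if d.is_polymorphic(c) else IBD for c in df["snp_count"]
    ]
    return WindowSet(df, window_set.window_bp, window_set.region, d.name)


def merge_blocks(classified: WindowSet) -> pd.DataFrame:
    """Merge maximal runs of adjacent POLYMORPHIC windows into blocks.

    Returns a frame with columns chromosome, start_bp, end_bp, total_snps,
    n_windows (empty when all windows are IBD).
    """
    df = classified.df
    if "cls" not in df.columns:
        raise ValueError("windows not classified")
    rows = []
    run_start = None
    run_snps = run_n = 0
    for rec in df.itertuples(index=False):
        if rec.cls == POLYMORPHIC:
            if run_start is None:
                run_start = rec.start_bp
                run_snps = run_n = 0
            run_snps += rec.snp_count
            run_n += 1
            run_end = rec.end_bp
        elif run_start is not None:
            rows.append((rec.chromosome, run_start, run_end, run_snps, run_n))
            run_start = None
    if run_start is not None:
        chrom = df["chromosome"].iloc[-1]
        rows.append((chrom, run_start, run_end, run_snps, run_n))
    return pd.DataFrame(
        rows, columns=["chromosome", "start_bp", "end_bp", "total_snps", "n_windows"]
    )


def interval_snp_count(positions, interval: tuple[int, int]) -> int:
    """Number of positions in the half-open interval [start, end)."""
    start, end = interval
    if end < start:
        raise ValueError("malformed interval")
    pos = np.sort(np.asarray(positions, dtype=int))
    return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))


def write_blocks_bed(blocks: pd.DataFrame, path: str | Path) -> None:
    """Blocks as BED (0-based half-open), score column = total SNPs."""
    with open(path, "w") as fh:
        for i, rec in enumerate(blocks.itertuples(index=False)):
            fh.write(
                f"{rec.chromosome}\t{rec.start_bp - 1}\t{rec.end_bp - 1}\t"
                f"block{i}\t{rec.total_snps}\n"
            )


def write_blocks_summary(
    blocks: pd.DataFrame, window_set: WindowSet, path: str | Path
) -> None:
    summary = {
        "region": {
            "chromosome": window_set.region[0],
            "start_bp": int(window_set.region[1]),
            "end_bp": int(window_set.region[2]),
        },
        "dialect": window_set.dialect,
        "window_bp": int(window_set.window_bp),
        "n_windows": int(len(window_set.df)),
        "n_polymorphic_windows": int((window_set.df.get("cls") == POLYMORPHIC).sum()),
        "n_blocks": int(len(blocks)),
        "total_snps_in_blocks": int(blocks["total_snps"].sum()) if len(blocks) else 0,
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
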