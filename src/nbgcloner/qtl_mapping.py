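"""Single-QTL LOD scan for an N2 backcross, permutation genome-wide
threshold, and 1.5-LOD support intervals snapped to genotyped markers.

With every marker genotyped and only two genotype classes (homozygous N/N
vs heterozygous N/C), marker regression is the scan statistic: at each
marker the LOD score is

    LOD = (n/2) * log10(RSS0 / RSS1)

where RSS0 is the residual sum of squares about the grand phenotype mean
and RSS1 about the two genotype-group means. This is algebraically
identical to -(n/2)*log10(1 - r^2) for the genotype-phenotype correlation
r, an identity the test suite verifies to 1e-9 and which the vectorized
permutation engine exploits.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype_metrics import PhenotypeTable
from .synthetic_data import GeneticMap

log = logging.getLogger(__name__)

LOD_DROP = 1.5


def marker_lod(genotypes_at_marker, phenotype) -> float:
    """Marker-regression LOD at one marker.

    Missing values (NaN) in either vector are removed pairwise first. Each
    genotype class must keep >= 2 members and the phenotype must vary. A
    perfect within-group fit (RSS1 = 0) is reported as +inf with a warning.
    """
    g = np.asarray(genotypes_at_marker, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.shape != y.shape:
        raise ValueError("genotype and phenotype vectors differ in length")
    mask = ~(np.isnan(g) | np.isnan(y))
    g, y = g[mask], y[mask]
    n = len(y)
    n1 = int(g.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("each genotype class needs >= 2 individuals")
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss0 == 0.0:
        raise ValueError("phenotype has zero variance")
    rss1 = float(
        np.sum((y[g == 0] - y[g == 0].mean()) ** 2)
        + np.sum((y[g == 1] - y[g == 1].mean()) ** 2)
    )
    if rss1 == 0.0:
        warnings.warn("perfect genotype fit: LOD reported as +inf")
        return math.inf
    return (n / 2.0) * math.log10(rss0 / rss1)


def lod_scan(
    genotypes: pd.DataFrame, phenotype, gmap: GeneticMap
) -> pd.DataFrame:
    """LOD curve over all usable markers, ordered by map position.

    ``phenotype`` must be aligned to ``genotypes.index``. Markers violating
    the marker_lod preconditions (degenerate class counts) are skipped with
    a logged warning; if none survive the scan is rejected.

    Returns a frame with columns marker, chromosome, position_bp,
    position_cM, lod, n_used.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(genotypes):
        raise ValueError("phenotype not aligned to genotype rows")
    rows = []
    for rec in gmap.df.itertuples(index=False):
        if rec.marker not in genotypes.columns:
            continue
        g = genotypes[rec.marker].to_numpy(dtype=float)
        mask = ~(np.isnan(g) | np.isnan(y))
        try:
            lod = marker_lod(g, y)
        except ValueError as exc:
            log.warning("marker %s skipped: %s", rec.marker, exc)
            continue
        rows.append(
            (rec.marker, rec.chromosome, rec.position_bp, rec.position_cM,
             lod, int(mask.sum()))
        )
    if not rows:
        raise ValueError("no usable markers in scan")
    return pd.DataFrame(
        rows,
        columns=["marker", "chromosome", "position_bp", "position_cM", "lod", "n_used"],
    )


def _max_lod_batch(genotypes: pd.DataFrame, Y: np.ndarray) -> np.ndarray:
    """Genome-wide max LOD for each phenotype column of Y (n x p), via the
    correlation identity, with per-marker casewise deletion of missing
    genotypes."""
    n_total, p = Y.shape
    best = np.zeros(p)
    for marker in genotypes.columns:
        g = genotypes[marker].to_numpy(dtype=float)
        mask = ~np.isnan(g)
        gm = g[mask]
        n = len(gm)
        n1 = gm.sum()
        if n1 < 2 or n - n1 < 2:
            continue
        Ym = Y[mask, :]
        gc = gm - gm.mean()
        Yc = Ym - Ym.mean(axis=0)
        denom = np.sqrt((gc @ gc) * np.einsum("ij,ij->j", Yc, Yc))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (gc @ Yc) / denom
        r2 = np.clip(np.nan_to_num(r) ** 2, 0.0, 1.0 - 1e-300)
        lod = -(n / 2.0) * np.log10(1.0 - r2)
        np.maximum(best, lod, out=best)
    return best


def threshold_from_max_lods(max_lods, alpha: float = 0.05) -> float:
    """Genome-wide threshold as the ceil((1-alpha)*n)-th smallest of the
    permutation max-LOD values (a conservative order statistic for small
    permutation counts)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    values = np.sort(np.asarray(max_lods, dtype=float))
    if values.size == 0:
        raise ValueError("no permutation values")
    k = math.ceil((1 - alpha) * values.size)
    return float(values[k - 1])


def permutation_threshold(
    genotypes: pd.DataFrame,
    phenotype,
    gmap: GeneticMap,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide significance threshold from ``n_perm`` phenotype
    permutations against intact genotype rows."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(seed)
    Y = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    markers = [m for m in gmap.markers if m in genotypes.columns]
    max_lods = _max_lod_batch(genotypes[markers], Y)
    return threshold_from_max_lods(max_lods, alpha)


def support_interval(
    curve: pd.DataFrame, drop: float = LOD_DROP
) -> tuple[int, int, str, str]:
    """1.5-LOD support interval snapped to genotyped markers.

    Finds the maximal contiguous run of markers around the peak (on the
    peak's chromosome) with LOD >= peak - drop, then extends each end
    outward by one genotyped marker where one exists. Ties at the peak
    break toward the smaller bp coordinate. Returns
    (left_bp, right_bp, left_marker, right_marker).
    """
    if curve.empty:
        raise ValueError("empty LOD curve")
    peak_row = curve.loc[curve["lod"].idxmax()]
    chrom = curve[curve["chromosome"] == peak_row["chromosome"]].sort_values(
        "position_bp", ignore_index=True
    )
    lods = chrom["lod"].to_numpy()
    peak_idx = int(np.argmax(lods))  # first max = smallest bp on ties
    cutoff = lods[peak_idx] - drop
    left = peak_idx
    while left > 0 and lods[left - 1] >= cutoff:
        left -= 1
    right = peak_idx
    while right < len(lods) - 1 and lods[right + 1] >= cutoff:
        right += 1
    left = max(0, left - 1)          # nearest genotyped marker beyond the run
    right = min(len(lods) - 1, right + 1)
    return (
        int(chrom.loc[left, "position_bp"]),
        int(chrom.loc[right, "position_bp"]),
        str(chrom.loc[left, "marker"]),
        str(chrom.loc[right, "marker"]),
    )


@dataclass
class QtlResult:
    """Outcome of one genome scan with its permutation threshold."""

    peak_marker: str
    peak_lod: float
    threshold: float
    significant: bool
    support_interval: tuple[int, int, str, str]

    def to_dict(self) -> dict:
        left_bp, right_bp, left_m, right_m = self.support_interval
        return {
            "peak_marker": self.peak_marker,
            "peak_lod": self.peak_lod,
            "threshold": self.threshold,
            "significant": self.significant,
            "support_interval": {
                "left_bp": left_bp,
                "right_bp": right_bp,
                "left_marker": left_m,
                "right_marker": right_m,
            },
        }


def scan_with_threshold(
    genotypes: pd.DataFrame,
    phenotype,
    gmap: GeneticMap,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    drop: float = LOD_DROP,
) -> tuple[pd.DataFrame, QtlResult]:
    """Full scan: LOD curve, permutation threshold, peak and 1.5-LOD
    support interval."""
    curve = lod_scan(genotypes, phenotype, gmap)
    threshold = permutation_threshold(genotypes, phenotype, gmap, n_perm, alpha, seed)
    # peak tie-break toward smaller bp
    ordered = curve.sort_values("position_bp", ignore_index=True)
    peak = ordered.loc[ordered["lod"].idxmax()]
    result = QtlResult(
        peak_marker=str(peak["marker"]),
        peak_lod=float(peak["lod"]),
        threshold=threshold,
        significant=bool(peak["lod"] >= threshold),
        support_interval=support_interval(curve, drop),
    )
    return curve, result


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch two-sample t statistic, Satterthwaite df and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def allelic_segregation(
    genotypes: pd.DataFrame,
    marker_id: str,
    phenotypes: PhenotypeTable,
) -> pd.DataFrame:
    """Per-week glucose comparison between the two genotype groups at one
    marker: group means, SEMs, Welch t, Satterthwaite df and two-sided p.

    Weeks where either group has fewer than two glucose observations are
    dropped; if no week qualifies the call is rejected.
    """
    if marker_id not in genotypes.columns:
        raise ValueError(f"unknown marker {marker_id!r}")
    g = genotypes[marker_id]
    groups = {0: g.index[g == 0], 1: g.index[g == 1]}
    if len(groups[0]) == 0 or len(groups[1]) == 0:
        raise ValueError("a genotype group is empty")
    data = phenotypes.data
    rows = []
    for week in sorted(data["week"].unique()):
        at_week = data[data["week"] == week]
        y0 = at_week.loc[at_week["animal"].isin(groups[0]), "glucose"].to_numpy()
        y1 = at_week.loc[at_week["animal"].isin(groups[1]), "glucose"].to_numpy()
        if len(y0) < 2 or len(y1) < 2:
            continue
        t, df, p = welch_test(y0, y1)
        rows.append(
            (int(week),
             y0.mean(), stats.sem(y0), len(y0),
             y1.mean(), stats.sem(y1), len(y1),
             t, df, p)
        )
    if not rows:
        raise ValueError("no week with >= 2 observations per group")
    return pd.DataFrame(
        rows,
        columns=["week", "mean_NN", "sem_NN", "n_NN",
                 "mean_NC", "sem_NC", "n_NC", "t", "df", "p"],
    )
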