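"""Tissue-specificity scoring of an expression matrix and qPCR ΔCt
arithmetic.

A gene is islet-specific when its islet/other-tissue expression ratio is
extreme relative to the rest of the genes, in every strain and against
every comparison tissue. For each (strain, tissue) cell the per-gene
log2 ratio L(g) = log2(islet / tissue) is standardized across genes
(population SD); a gene's combined score is the minimum z over all cells,
so only genes enriched everywhere score high.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qtl_mapping import welch_test

TARGET_TISSUE = "islet"


def read_expression_csv(path: str | Path) -> pd.DataFrame:
    """Expression matrix: first column gene id, remaining columns named
    ``strain.tissue`` with positive linear-scale intensities."""
    return pd.read_csv(path, index_col=0)


def floor_zeros(matrix: pd.DataFrame, pseudo: float | None = None) -> pd.DataFrame:
    """Replace non-positive intensities by a pseudo-value (default: half the
    smallest positive value in the matrix)."""
    values = matrix.to_numpy(dtype=float)
    if (values > 0).sum() == 0:
        raise ValueError("expression matrix has no positive values")
    if pseudo is None:
        pseudo = values[values > 0].min() / 2.0
    out = matrix.copy().astype(float)
    out[out <= 0] = pseudo
    return out


def _parse_conditions(columns) -> dict[str, list[str]]:
    strains: dict[str, list[str]] = {}
    for col in columns:
        if "." not in col:
            raise ValueError(f"column {col!r} not in 'strain.tissue' form")
        strain, tissue = col.split(".", 1)
        strains.setdefault(strain, []).append(tissue)
    return strains


def specificity_zscores(
    matrix: pd.DataFrame,
    target_tissue: str = TARGET_TISSUE,
    log_scale: bool = True,
    combine: str = "min",
) -> pd.DataFrame:
    """Per-gene specificity z-scores with one column per (strain,
    comparison tissue) cell, a ``combined`` column (min or mean over
    cells) and a 1-based ``rank`` by combined score descending.

    Within each cell the z-vector over genes has mean 0 and population
    (n-denominator) SD 1. A cell whose ratios are identical across genes
    (zero spread) yields z = 0 for every gene.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 genes to standardize ratios")
    if combine not in ("min", "mean"):
        raise ValueError("combine must be 'min' or 'mean'")
    mat = floor_zeros(matrix)
    strains = _parse_conditions(mat.columns)
    cells = {}
    for strain, tissues in strains.items():
        if target_tissue not in tissues:
            raise ValueError(f"strain {strain} lacks target tissue {target_tissue!r}")
        others = [t for t in tissues if t != target_tissue]
        if not others:
            raise ValueError(f"strain {strain} has no comparison tissue")
        islet = mat[f"{strain}.{target_tissue}"].to_numpy()
        for tissue in others:
            ratio = islet / mat[f"{strain}.{tissue}"].to_numpy()
            L = np.log2(ratio) if log_scale else ratio
            sd = L.std()  # population SD (ddof=0)
            z = (L - L.mean()) / sd if sd > 0 else np.zeros_like(L)
            cells[f"z_{strain}_{tissue}"] = z
    scores = pd.DataFrame(cells, index=mat.index)
    scores["combined"] = (
        scores.min(axis=1) if combine == "min" else scores.mean(axis=1)
    )
    scores["rank"] = (
        scores["combined"].rank(ascending=False, method="first").astype(int)
    )
    return scores.sort_values("rank")


def select_candidates(scores: pd.DataFrame, min_combined_z: float) -> list[str]:
    """Genes with combined specificity score >= ``min_combined_z``, sorted
    by score descending."""
    passing = scores[scores["combined"] >= min_combined_z]
    return list(passing.sort_values("combined", ascending=False).index)


# ---------------------------------------------------------------------------
# qPCR ΔCt


def delta_ct_relative_expression(target_ct: float, reference_ct: float) -> float:
    """Relative expression 2^-(Ct_target - Ct_reference) against a
    housekeeping gene (e.g. Actb)."""
    t, r = float(target_ct), float(reference_ct)
    if not (np.isfinite(t) and np.isfinite(r)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-(t - r)))


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["sample_id", "group", "target_ct", "reference_ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    return df


def compare_qpcr_groups(
    measurements: pd.DataFrame, group_a: str, group_b: str
) -> dict:
    """ΔCt group comparison: per-sample relative expressions, fold change
    mean(A)/mean(B), and a two-sided Welch test on the relative
    expressions."""
    rel = measurements.apply(
        lambda r: delta_ct_relative_expression(r["target_ct"], r["reference_ct"]),
        axis=1,
    )
    a = rel[measurements["group"] == group_a].to_numpy()
    b = rel[measurements["group"] == group_b].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty qPCR group")
    fold = float(a.mean() / b.mean())
    if len(a) >= 2 and len(b) >= 2:
        t, df, p = welch_test(a, b)
    else:
        t = df = p = float("nan")
    return {
        "group_a": group_a,
        "group_b": group_b,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "fold_change": fold,
        "t": t,
        "df": df,
        "p": p,
    }
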