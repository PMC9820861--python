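"""Candidate-gene filtering by predicted variant consequence and SIFT score,
restriction to polymorphic blocks, and conservation of mutated residues.

Consequence impact classes (HIGH/MODERATE/LOW/MODIFIER) and SIFT scores are
consumed from an annotation table as produced by variant-effect prediction
tools; neither predictor is reimplemented here. The deleteriousness rule:
a gene survives when it carries at least one HIGH-impact variant, or a
MODERATE-impact variant with SIFT strictly below the cutoff (default 0.5,
lower = more deleterious). LOW and MODIFIER never qualify.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
SIFT_CUTOFF = 0.5
CONSERVATION_THRESHOLD = 0.9

ANNOTATION_COLUMNS = [
    "gene_id", "gene_symbol", "chromosome", "position_bp",
    "consequence", "impact", "sift_score", "amino_acid_change",
]


def read_annotations_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in ANNOTATION_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return df


def filter_by_impact(
    annotations: pd.DataFrame,
    sift_cutoff: float = SIFT_CUTOFF,
    include_missing_sift: bool = False,
) -> pd.DataFrame:
    """Retain genes with deleterious-looking variants; report the best
    variant per gene.

    HIGH impact qualifies unconditionally; MODERATE qualifies iff
    sift < sift_cutoff (strict), or, when ``include_missing_sift``, also
    with no SIFT score. Records with malformed impact labels are rejected
    with a warning rather than silently dropped. Per-gene evidence is the
    best qualifying variant: HIGH beats any MODERATE, then minimum SIFT.

    Returns one row per retained gene with columns gene_id, gene_symbol,
    chromosome, position_bp, consequence, impact, sift_score,
    amino_acid_change, n_qualifying_variants.
    """
    if annotations.empty:
        raise ValueError("empty annotation table")
    ann = annotations.copy()
    bad = ~ann["impact"].isin(IMPACT_CLASSES)
    if bad.any():
        warnings.warn(
            f"rejecting {int(bad.sum())} record(s) with malformed impact "
            f"label(s): {sorted(ann.loc[bad, 'impact'].unique())}"
        )
        ann = ann[~bad]
    sift = pd.to_numeric(ann["sift_score"], errors="coerce")
    if ((sift < 0) | (sift > 1)).any():
        raise ValueError("SIFT scores must lie in [0, 1]")
    qualifies = (ann["impact"] == "HIGH") | (
        (ann["impact"] == "MODERATE")
        & (sift.lt(sift_cutoff) | (sift.isna() & include_missing_sift))
    )
    hits = ann[qualifies].copy()
    if hits.empty:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS + ["n_qualifying_variants"])
    # HIGH sorts before MODERATE; within class, smallest SIFT first (NaN last)
    hits["_rank"] = hits["impact"].map({"HIGH": 0, "MODERATE": 1})
    hits = hits.sort_values(
        ["gene_id", "_rank", "sift_score"], na_position="last", kind="mergesort"
    )
    counts = hits.groupby("gene_id").size().rename("n_qualifying_variants")
    best = hits.drop_duplicates("gene_id").drop(columns="_rank")
    best = best.merge(counts, on="gene_id")
    return best.reset_index(drop=True)


def genes_in_blocks(
    gene_table: pd.DataFrame,
    blocks: pd.DataFrame,
    locus: tuple[str, int, int] | None = None,
) -> set[str]:
    """Gene ids whose half-open span overlaps at least one polymorphic block
    and lies within the locus interval (when given).

    Overlap means a nonempty intersection of half-open intervals; a gene
    abutting a block end-to-start does not overlap.
    """
    for col in ("gene_id", "chromosome", "start_bp", "end_bp"):
        if col not in gene_table.columns:
            raise ValueError(f"gene table missing column {col!r}")
    if (gene_table["end_bp"] <= gene_table["start_bp"]).any():
        raise ValueError("malformed gene interval")
    if len(blocks) and (blocks["end_bp"] <= blocks["start_bp"]).any():
        raise ValueError("malformed block interval")
    genes = gene_table
    if locus is not None:
        chrom, lo, hi = locus
        genes = genes[
            (genes["chromosome"].astype(str) == str(chrom))
            & (genes["start_bp"] >= lo)
            & (genes["end_bp"] <= hi)
        ]
    retained: set[str] = set()
    for gene in genes.itertuples(index=False):
        for block in blocks.itertuples(index=False):
            if str(block.chromosome) != str(gene.chromosome):
                continue
            if gene.start_bp < block.end_bp and block.start_bp < gene.end_bp:
                retained.add(gene.gene_id)
                break
    return retained


# ---------------------------------------------------------------------------
# conservation from a protein MSA


@dataclass
class Msa:
    """Aligned protein sequences keyed by species, with one sequence (the
    query strain) carrying the putative mutation; all aligned lengths must
    match and the reference species must be present."""

    sequences: dict[str, str]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.sequences:
            raise ValueError(f"reference {self.reference!r} not in alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences differ in length")

    @classmethod
    def from_fasta(cls, path: str | Path, reference: str) -> "Msa":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs, reference)

    def alignment_column(self, ref_position: int) -> int:
        """Alignment column index (0-based) of the reference's 1-based
        ungapped position; round-trips exactly with the inverse mapping."""
        if ref_position < 1:
            raise ValueError("reference position is 1-based")
        count = 0
        for col, residue in enumerate(self.sequences[self.reference]):
            if residue != "-":
                count += 1
                if count == ref_position:
                    return col
        raise ValueError(
            f"position {ref_position} beyond reference ungapped length {count}"
        )


@dataclass
class ConservationResult:
    fraction_identical: float
    conserved: bool
    residues: dict[str, str]
    modal_residue: str
    query_residue: str
    query_deviates: bool

    @property
    def mutation_in_conserved_site(self) -> bool:
        return self.conserved and self.query_deviates


def column_conservation(
    msa: Msa,
    ref_position: int,
    query_species: str | None = None,
    threshold: float = CONSERVATION_THRESHOLD,
) -> ConservationResult:
    """Conservation of one reference-coordinate column.

    The modal residue is taken over the non-query, non-gap sequences;
    ``fraction_identical`` is the share of those sequences carrying it
    (ties break to the alphabetically smallest residue). The column is
    conserved at ``threshold``, and the query strain is flagged when its
    residue deviates from the modal one.
    """
    query = query_species or msa.reference
    col = msa.alignment_column(ref_position)
    residues = {sp: seq[col] for sp, seq in msa.sequences.items()}
    others = [r for sp, r in residues.items() if sp != query and r != "-"]
    if not others:
        raise ValueError("no non-gap residues outside the query at this column")
    counts = pd.Series(others).value_counts()
    top = counts.max()
    modal = min(counts[counts == top].index)
    query_res = residues.get(query, "-")
    return ConservationResult(
        fraction_identical=float(top / len(others)),
        conserved=bool(top / len(others) >= threshold),
        residues=residues,
        modal_residue=str(modal),
        query_residue=query_res,
        query_deviates=bool(query_res != "-" and query_res != modal),
    )


def parse_aa_change(aa_change: str) -> tuple[str, int, str] | None:
    """Split an amino-acid change like 'E96V' into (ref, position, alt)."""
    m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", str(aa_change).strip())
    if not m:
        return None
    return m.group(1), int(m.group(2)), m.group(3)
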