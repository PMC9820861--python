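"""End-to-end positional-cloning pipeline: confirm the locus with a LOD
scan, call polymorphic (non-IBD) blocks between the parental strains,
filter annotated variants by impact/SIFT, intersect surviving genes with
the blocks, require islet-specific expression, and rank the remaining
candidates into a report.

Stage order mirrors the narrative of such studies (haplotype blocks, then
deleteriousness, then expression); each stage can be toggled for ablation,
and disabling a stage can only enlarge the candidate set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    expression_scoring,
    haplotype_blocks,
    qtl_mapping,
    synthetic_data,
    variant_prioritization,
)
from .phenotype_metrics import PhenotypeTable

log = logging.getLogger(__name__)

_IMPACT_ORDER = {"HIGH": 0, "MODERATE": 1}


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse 'chr15:50000000-80000000' (or '15:...') into (chrom, start, end)."""
    chrom, span = text.split(":")
    start, end = span.replace(",", "").split("-")
    return chrom.removeprefix("chr"), int(start), int(end)


@dataclass
class PipelineConfig:
    """Inputs and tuning knobs of one pipeline run.

    Paths may be None to skip the corresponding stage (e.g. no genotype /
    phenotype files skips the confirmatory scan). The sublocus boundary
    defaults to the midpoint between the proximal and distal peak
    positions.
    """

    genotypes: str | None = None
    phenotypes: str | None = None
    genetic_map: str | None = None
    snp_catalog: str | None = None
    genes_bed: str | None = None
    annotations: str | None = None
    expression: str | None = None
    msa: str | None = None
    msa_gene: str | None = None          # gene symbol the MSA belongs to
    msa_query_species: str = "NZO_mouse"

    locus: tuple[str, int, int] = ("15", 50_000_000, 80_000_000)
    proximal_peak_bp: int = 63_000_000
    distal_peak_bp: int = 79_000_000
    sublocus_boundary_bp: int | None = None
    dialect: str = "150kb"
    sift_cutoff: float = 0.5
    min_combined_z: float = 1.0
    n_perm: int = 100
    alpha: float = 0.05
    drop: float = 1.5
    seed: int = 0
    use_block_filter: bool = True
    use_impact_filter: bool = True
    use_expression_filter: bool = True

    def __post_init__(self) -> None:
        chrom, start, end = self.locus
        if end <= start:
            raise ValueError("malformed locus interval")
        if not 0 <= self.sift_cutoff <= 1:
            raise ValueError("sift_cutoff must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sublocus_boundary_bp is None:
            self.sublocus_boundary_bp = (self.proximal_peak_bp + self.distal_peak_bp) // 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if isinstance(raw.get("locus"), str):
            raw["locus"] = parse_region(raw["locus"])
        elif isinstance(raw.get("locus"), list):
            raw["locus"] = tuple(raw["locus"])
        return cls(**raw)


@dataclass
class CandidateReport:
    """Ranked candidate genes with per-stage evidence flags and the filter
    funnel counts (total -> impact-pass -> block-pass -> expression-pass
    -> final)."""

    table: pd.DataFrame
    funnel: dict[str, int]
    qtl: qtl_mapping.QtlResult | None = None
    config: dict = field(default_factory=dict)

    COLUMNS = [
        "gene_id", "gene_symbol", "chromosome", "start_bp", "end_bp",
        "sublocus", "in_polymorphic_block", "impact", "min_sift",
        "amino_acid_change", "combined_specificity_z",
        "conserved_site_flag", "final_rank",
    ]


def _rank_key(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic candidate ranking: HIGH before MODERATE, then
    ascending min SIFT (missing last), then descending combined z, then
    coordinate."""
    out = df.copy()
    out["_impact"] = out["impact"].map(_IMPACT_ORDER).fillna(9)
    out["_sift"] = out["min_sift"].fillna(np.inf)
    out = out.sort_values(
        ["_impact", "_sift", "combined_specificity_z", "start_bp"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop(columns=["_impact", "_sift"])
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def run_positional_cloning(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> CandidateReport:
    """Execute the full chain; every intermediate is written to ``out_dir``
    when given, and the run is fully reproducible for a fixed seed."""
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

    # --- confirmatory QTL scan -------------------------------------------
    qtl_result = None
    if config.genotypes and config.phenotypes and config.genetic_map:
        genotypes = synthetic_data.read_genotypes_csv(config.genotypes)
        gmap = synthetic_data.GeneticMap.from_tsv(config.genetic_map)
        pheno = PhenotypeTable.from_csv(config.phenotypes)
        # scan phenotype: per-animal mean random blood glucose over observed weeks
        mean_glucose = pheno.data.groupby("animal")["glucose"].mean()
        y = mean_glucose.reindex(genotypes.index).to_numpy()
        curve, qtl_result = qtl_mapping.scan_with_threshold(
            genotypes, y, gmap,
            n_perm=config.n_perm, alpha=config.alpha,
            seed=config.seed, drop=config.drop,
        )
        log.info("scan peak %s LOD %.2f (threshold %.2f)",
                 qtl_result.peak_marker, qtl_result.peak_lod, qtl_result.threshold)
        if out is not None:
            curve.to_csv(out / "lod_curve.tsv", sep="\t", index=False)
            with open(out / "qtl_result.json", "w") as fh:
                json.dump(qtl_result.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")

    # --- gene universe ----------------------------------------------------
    genes = synthetic_data.read_genes_bed(config.genes_bed)
    annotations = variant_prioritization.read_annotations_tsv(config.annotations)
    expr = expression_scoring.read_expression_csv(config.expression)

    gene_ids = set(genes["gene_id"])
    ann_extra = set(annotations["gene_id"]) - gene_ids
    expr_extra = set(expr.index) - gene_ids
    if ann_extra or expr_extra:
        raise ValueError(
            "inconsistent gene universes: annotation-only ids "
            f"{sorted(ann_extra)}, expression-only ids {sorted(expr_extra)}"
        )

    # --- polymorphic blocks ----------------------------------------------
    chrom, lo, hi = config.locus
    catalog_path = str(config.snp_catalog)
    if catalog_path.endswith(".vcf"):
        catalog = haplotype_blocks.read_snp_catalog_vcf(catalog_path)
    else:
        catalog = haplotype_blocks.read_snp_catalog_tsv(catalog_path)
    positions = haplotype_blocks.discordant_positions(catalog, "C3H", "NZO", chrom)
    window_set = haplotype_blocks.window_counts(
        positions, config.locus, haplotype_blocks.DIALECTS[config.dialect].window_bp
    )
    classified = haplotype_blocks.classify_windows(window_set, config.dialect)
    blocks = haplotype_blocks.merge_blocks(classified)
    if out is not None:
        classified.to_tsv(out / "windows.tsv")
        haplotype_blocks.write_blocks_bed(blocks, out / "blocks.bed")
        haplotype_blocks.write_blocks_summary(blocks, classified, out / "blocks.json")

    # --- filters ----------------------------------------------------------
    funnel = {"total_genes": len(genes)}

    if config.use_impact_filter:
        impact_pass = variant_prioritization.filter_by_impact(
            annotations, config.sift_cutoff
        )
    else:
        impact_pass = annotations.drop_duplicates("gene_id").copy()
        impact_pass["n_qualifying_variants"] = 1
    impact_ids = set(impact_pass["gene_id"])
    funnel["impact_pass"] = len(impact_ids)

    block_ids = variant_prioritization.genes_in_blocks(genes, blocks, config.locus)
    if config.use_block_filter:
        after_blocks = impact_ids & block_ids
    else:
        after_blocks = impact_ids
    funnel["block_pass"] = len(after_blocks)

    scores = expression_scoring.specificity_zscores(expr)
    if out is not None:
        scores.to_csv(out / "specificity_scores.tsv", sep="\t")
    if config.use_expression_filter:
        expressed = set(
            expression_scoring.select_candidates(scores, config.min_combined_z)
        )
        final_ids = after_blocks & expressed
    else:
        final_ids = after_blocks
    funnel["expression_pass"] = len(final_ids)

    # --- assemble report --------------------------------------------------
    rows = []
    for gene in genes[genes["gene_id"].isin(final_ids)].itertuples(index=False):
        evid = impact_pass[impact_pass["gene_id"] == gene.gene_id]
        midpoint = (gene.start_bp + gene.end_bp) // 2
        conserved = None
        if (
            config.msa
            and config.msa_gene
            and gene.gene_symbol == config.msa_gene
        ):
            aa = evid["amino_acid_change"].iloc[0] if len(evid) else ""
            parsed = variant_prioritization.parse_aa_change(aa)
            if parsed is not None:
                msa = variant_prioritization.Msa.from_fasta(
                    config.msa, reference=config.msa_query_species
                )
                cons = variant_prioritization.column_conservation(
                    msa, parsed[1], query_species=config.msa_query_species
                )
                conserved = cons.mutation_in_conserved_site
        rows.append(
            {
                "gene_id": gene.gene_id,
                "gene_symbol": gene.gene_symbol,
                "chromosome": gene.chromosome,
                "start_bp": gene.start_bp,
                "end_bp": gene.end_bp,
                "sublocus": "distal" if midpoint >= config.sublocus_boundary_bp else "proximal",
                "in_polymorphic_block": gene.gene_id in block_ids,
                "impact": evid["impact"].iloc[0] if len(evid) else None,
                "min_sift": float(evid["sift_score"].iloc[0]) if len(evid) and pd.notna(evid["sift_score"].iloc[0]) else np.nan,
                "amino_acid_change": evid["amino_acid_change"].iloc[0] if len(evid) else "",
                "combined_specificity_z": float(scores.loc[gene.gene_id, "combined"]),
                "conserved_site_flag": conserved,
            }
        )
    table = pd.DataFrame(rows, columns=[c for c in CandidateReport.COLUMNS if c != "final_rank"])
    table = _rank_key(table) if len(table) else table.assign(final_rank=pd.Series(dtype=int))
    funnel["final"] = len(table)

    report = CandidateReport(
        table=table[CandidateReport.COLUMNS] if len(table) else table,
        funnel=funnel,
        qtl=qtl_result,
        config={k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
    )
    if out is not None:
        write_report(report, out / "candidates")
    return report


def write_report(report: CandidateReport, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the report as TSV (one row per surviving gene) and JSON
    (config echo + funnel counts)."""
    prefix = Path(out_prefix)
    tsv = prefix.with_suffix(".tsv")
    js = prefix.with_suffix(".json")
    if len(report.table):
        report.table.to_csv(tsv, sep="\t", index=False)
    else:
        with open(tsv, "w") as fh:
            fh.write("\t".join(CandidateReport.COLUMNS) + "\n")
    payload = {
        "config": report.config,
        "funnel": report.funnel,
        "qtl": report.qtl.to_dict() if report.qtl else None,
        "n_candidates": int(len(report.table)),
    }
    with open(js, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tsv, js


def read_report_tsv(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the candidate TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if list(df.columns) != CandidateReport.COLUMNS:
        raise ValueError("unexpected report columns")
    return df
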