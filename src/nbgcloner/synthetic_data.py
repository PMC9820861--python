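"""Synthetic study generator for the positional-cloning pipeline.

Emulates every input the analysis consumes, with the statistical structure
the method assumes planted and therefore recoverable: an N2 backcross with
one additive causal marker on a genetic map, longitudinal glucose series
with a genotype-dependent diabetic drift and a glucose-conditional death
process, a two-strain SNP catalog with Poisson-planted polymorphic blocks,
a variant annotation table with one deleterious (MODERATE, SIFT < 0.5)
variant on the planted causal gene, an expression matrix in which that gene
is islet-enriched in every strain, and a protein alignment in which its
mutated residue sits in a conserved column.

All randomness flows from one top-level seed through named
``numpy.random.SeedSequence`` substreams, so each simulated artifact is
reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotype_metrics import PhenotypeTable

STRAINS = ("NZO", "C3H", "B6")
TISSUES = ("islet", "liver", "quadriceps", "gWAT", "BAT")
_BASES = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# substream labels: keep stable so fixed seed => byte-identical outputs
_STREAMS = ("backcross", "phenotypes", "snp_catalog", "annotations", "msa")


def _rng(seed: int, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(len(_STREAMS))[idx])


# ---------------------------------------------------------------------------
# genetic map


@dataclass
class GeneticMap:
    """Ordered genotyping markers with physical (bp) and genetic (cM)
    coordinates; positions must be strictly increasing within a chromosome
    and marker ids unique."""

    df: pd.DataFrame  # columns: marker, chromosome, position_bp, position_cM

    COLUMNS = ("marker", "chromosome", "position_bp", "position_cM")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"genetic map missing columns: {missing}")
        if self.df.empty:
            raise ValueError("empty genetic map")
        if self.df["marker"].duplicated().any():
            raise ValueError("duplicate marker ids")
        if (self.df["position_bp"] < 1).any() or (self.df["position_cM"] < 0).any():
            raise ValueError("invalid marker positions")
        for _, chrom in self.df.groupby("chromosome", sort=False):
            bp = chrom["position_bp"].to_numpy()
            cm = chrom["position_cM"].to_numpy()
            if not (np.all(np.diff(bp) > 0) and np.all(np.diff(cm) > 0)):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def markers(self) -> list[str]:
        return list(self.df["marker"])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))


def uniform_map(
    n_markers: int,
    chromosome: str = "15",
    start_bp: int = 50_000_000,
    end_bp: int = 80_000_000,
    total_cM: float = 15.0,
    prefix: str = "rs",
) -> GeneticMap:
    """Evenly spaced markers across one chromosome segment."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    bp = np.linspace(start_bp, end_bp, n_markers).round().astype(int)
    cm = np.linspace(0.0, total_cM, n_markers)
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": [f"{prefix}{i:04d}" for i in range(n_markers)],
                "chromosome": chromosome,
                "position_bp": bp,
                "position_cM": cm,
            }
        )
    )


# ---------------------------------------------------------------------------
# backcross genotypes


def haldane_recombination(d_cM: float) -> float:
    """Haldane map function r = 0.5*(1 - exp(-2 d / 100)) for d in cM."""
    d = float(d_cM)
    if not np.isfinite(d) or d < 0:
        raise ValueError("map distance must be finite and non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def simulate_backcross(gmap: GeneticMap, n: int, seed: int) -> pd.DataFrame:
    """Simulate N2 backcross genotypes (0 = homozygous N/N, 1 = heterozygous
    N/C) along the map under a Markov chain with Haldane switch
    probabilities between adjacent markers; the first marker of each
    chromosome is a fair coin."""
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = _rng(seed, "backcross")
    cols: dict[str, np.ndarray] = {}
    for _, chrom in gmap.df.groupby("chromosome", sort=False):
        cm = chrom["position_cM"].to_numpy()
        markers = list(chrom["marker"])
        state = (rng.random(n) < 0.5).astype(np.int8)
        cols[markers[0]] = state.copy()
        for j in range(1, len(markers)):
            r = haldane_recombination(cm[j] - cm[j - 1])
            switch = rng.random(n) < r
            state = np.where(switch, 1 - state, state).astype(np.int8)
            cols[markers[j]] = state.copy()
    index = [f"ind{i:04d}" for i in range(n)]
    # column order must follow the map, not the per-chromosome grouping
    return pd.DataFrame(cols, index=index)[gmap.markers]


def write_genotypes_csv(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.to_csv(path, index_label="individual", na_rep="NA")


def read_genotypes_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="individual", na_values=["NA"])


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class SimulationConfig:
    """Parameters of the simulated cohort.

    ``additive_effect`` lowers glucose (mg/dL) in heterozygous carriers;
    ``diabetic_drift`` (mg/dL per week) acts only on the susceptible
    homozygous genotype, mimicking progressive hyperglycemia. Weekly
    measurements run from age ``first_week`` for ``weekly_weeks`` weeks
    (default ages 3-20). Death is a per-week Bernoulli event conditional on
    that week's glucose exceeding ``death_glucose_threshold``.
    """

    n_individuals: int = 150
    causal_marker_id: str = ""
    additive_effect: float = 30.0
    residual_sd: float = 60.0
    weekly_weeks: int = 18
    first_week: int = 3
    glucose_baseline: float = 200.0
    diabetic_drift: float = 22.0
    death_glucose_threshold: float = 500.0
    death_prob_per_week: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if not 0.0 <= self.death_prob_per_week <= 1.0:
            raise ValueError("death_prob_per_week must be in [0, 1]")
        if self.weekly_weeks < 1:
            raise ValueError("weekly_weeks must be >= 1")


def simulate_phenotypes(genotypes: pd.DataFrame, cfg: SimulationConfig) -> PhenotypeTable:
    """Simulate weekly glucose/weight/insulin series given backcross
    genotypes, planting an additive protective effect and a
    genotype-dependent drift at the causal marker; series truncate at
    death."""
    if cfg.causal_marker_id not in genotypes.columns:
        raise ValueError(f"causal marker {cfg.causal_marker_id!r} not in genotypes")
    g = genotypes[cfg.causal_marker_id].to_numpy()
    n = len(genotypes)
    rng = _rng(cfg.seed, "phenotypes")
    weeks = np.arange(cfg.first_week, cfg.first_week + cfg.weekly_weeks)

    rows = []
    death: dict[str, int] = {}
    for i, animal in enumerate(genotypes.index):
        group = "N/C" if g[i] == 1 else "N/N"
        weight = 35.0 + rng.normal(0.0, 2.0)
        for k, week in enumerate(weeks):
            glucose = (
                cfg.glucose_baseline
                + k * cfg.diabetic_drift * (1 - g[i])
                - cfg.additive_effect * g[i]
                + rng.normal(0.0, cfg.residual_sd)
            )
            glucose = max(glucose, 40.0)  # physiological floor
            weight += rng.normal(0.9, 0.4)
            insulin = max(0.1, 2.0 + 1.5 * g[i] + rng.normal(0.0, 0.8))
            rows.append(
                (animal, group, int(week), glucose, weight, insulin)
            )
            if glucose > cfg.death_glucose_threshold:
                if rng.random() < cfg.death_prob_per_week:
                    death[animal] = int(week)
                    break
    data = pd.DataFrame(
        rows,
        columns=["animal", "genotype_group", "week", "glucose", "weight", "insulin"],
    )
    return PhenotypeTable(data, death)


# ---------------------------------------------------------------------------
# SNP catalog


def simulate_snp_catalog(
    region: tuple[str, int, int],
    block_spec: list[tuple[int, int, float]],
    seed: int,
    background_per_kb: float = 0.3,
) -> pd.DataFrame:
    """Two-strain SNP catalog over ``region`` = (chrom, start_bp, end_bp).

    Inside each ``(start_bp, end_bp, density_per_kb)`` block the NZO allele
    differs from C3H at Poisson-placed positions with the given density
    (the polymorphic / non-IBD signal); everywhere else calls are identical
    (IBD), laid down at ``background_per_kb``. Positions are 1-based,
    sorted, unique. Columns: chromosome, position_bp, ref, C3H, NZO.
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    blocks = sorted(block_spec)
    for b_start, b_end, dens in blocks:
        if b_start < start or b_end > end or b_end <= b_start:
            raise ValueError("block outside region or empty")
        if dens < 0:
            raise ValueError("negative SNP density")
    for (s1, e1, _), (s2, e2, _) in zip(blocks, blocks[1:]):
        if s2 < e1:
            raise ValueError("overlapping blocks")

    rng = _rng(seed, "snp_catalog")
    positions: list[np.ndarray] = []
    discordant: list[np.ndarray] = []

    n_bg = rng.poisson(background_per_kb * (end - start) / 1000.0)
    bg = rng.integers(start, end, size=n_bg)
    positions.append(bg)
    discordant.append(np.zeros(n_bg, dtype=bool))

    for b_start, b_end, dens in blocks:
        n_b = rng.poisson(dens * (b_end - b_start) / 1000.0)
        pos = rng.integers(b_start, b_end, size=n_b)
        positions.append(pos)
        discordant.append(np.ones(n_b, dtype=bool))

    pos = np.concatenate(positions)
    disc = np.concatenate(discordant)
    pos, keep = np.unique(pos, return_index=True)
    disc = disc[keep]

    ref = _BASES[rng.integers(0, 4, size=len(pos))]
    alt = _BASES[(np.char.find("".join(_BASES), ref) + rng.integers(1, 4, size=len(pos))) % 4]
    # concordant sites: both strains carry the same (alt) allele relative to
    # the B6 reference; discordant sites: NZO carries alt, C3H the reference
    c3h = np.where(disc, ref, alt)
    nzo = alt
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "position_bp": pos.astype(int),
            "ref": ref,
            "C3H": c3h,
            "NZO": nzo,
        }
    )


# ---------------------------------------------------------------------------
# gene table, annotations, expression, MSA


def make_gene_table(
    n_genes: int = 20,
    chromosome: str = "15",
    start_bp: int = 50_000_000,
    end_bp: int = 80_000_000,
    gene_length: int = 40_000,
) -> pd.DataFrame:
    """Evenly spaced synthetic genes across the locus; half-open 1-based
    spans. Columns: gene_id, gene_symbol, chromosome, start_bp, end_bp."""
    starts = np.linspace(start_bp, end_bp - gene_length, n_genes).round().astype(int)
    return pd.DataFrame(
        {
            "gene_id": [f"GENE{i:04d}" for i in range(n_genes)],
            "gene_symbol": [f"Syng{i:02d}" for i in range(n_genes)],
            "chromosome": chromosome,
            "start_bp": starts,
            "end_bp": starts + gene_length,
        }
    )


def simulate_annotations_and_expression(
    genes: pd.DataFrame,
    planted_causal: str | None,
    seed: int,
    islet_fold: float = 10.0,
    n_moderate_decoys: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant annotation table + gene x (strain, tissue) expression matrix.

    The planted causal gene receives a MODERATE missense variant with
    SIFT < 0.5 and islet expression at least 8-fold above every other
    tissue in all three strains. Decoy genes get tolerated variants
    (SIFT >= 0.5) or LOW/MODIFIER consequences and tissue-flat expression;
    a few decoys carry deleterious-looking variants but no islet
    enrichment, so the expression filter is load-bearing.
    """
    if planted_causal is not None and planted_causal not in set(genes["gene_id"]):
        raise ValueError(f"unknown planted gene {planted_causal!r}")
    rng = _rng(seed, "annotations")

    ann_rows = []
    decoy_ids = [g for g in genes["gene_id"] if g != planted_causal]
    hot_decoys = set(decoy_ids[:n_moderate_decoys]) if planted_causal else set()
    for rec in genes.itertuples(index=False):
        pos = int(rng.integers(rec.start_bp, rec.end_bp))
        if rec.gene_id == planted_causal:
            sift = float(np.round(rng.uniform(0.02, 0.3), 3))
            aa = f"E{int(rng.integers(40, 200))}V"
            ann_rows.append(
                (rec.gene_id, rec.gene_symbol, rec.chromosome, pos,
                 "missense_variant", "MODERATE", sift, aa)
            )
        elif rec.gene_id in hot_decoys:
            sift = float(np.round(rng.uniform(0.05, 0.45), 3))
            ann_rows.append(
                (rec.gene_id, rec.gene_symbol, rec.chromosome, pos,
                 "missense_variant", "MODERATE", sift, f"Q{int(rng.integers(40, 200))}H")
            )
        elif rng.random() < 0.5:
            sift = float(np.round(rng.uniform(0.5, 1.0), 3))
            ann_rows.append(
                (rec.gene_id, rec.gene_symbol, rec.chromosome, pos,
                 "missense_variant", "MODERATE", sift, f"V{int(rng.integers(40, 200))}I")
            )
        else:
            ann_rows.append(
                (rec.gene_id, rec.gene_symbol, rec.chromosome, pos,
                 "synonymous_variant", "LOW", np.nan, "")
            )
    annotations = pd.DataFrame(
        ann_rows,
        columns=["gene_id", "gene_symbol", "chromosome", "position_bp",
                 "consequence", "impact", "sift_score", "amino_acid_change"],
    )

    base = rng.lognormal(mean=5.0, sigma=0.6, size=len(genes))
    cols: dict[str, np.ndarray] = {}
    for strain in STRAINS:
        for tissue in TISSUES:
            noise = rng.lognormal(mean=0.0, sigma=0.1, size=len(genes))
            cols[f"{strain}.{tissue}"] = base * noise
    expr = pd.DataFrame(cols, index=genes["gene_id"])
    expr.index.name = "gene_id"
    if planted_causal is not None:
        # hard guarantee of >= islet_fold enrichment per strain
        for strain in STRAINS:
            others = [f"{strain}.{t}" for t in TISSUES if t != "islet"]
            expr.loc[planted_causal, f"{strain}.islet"] = (
                islet_fold * expr.loc[planted_causal, others].max()
            )
    return annotations, expr


def simulate_msa(
    seed: int,
    length: int = 120,
    mutated_position: int = 96,
    species: tuple[str, ...] = (
        "NZO_mouse", "C3H_mouse", "rat", "human", "macaque", "dog", "chicken", "zebrafish",
    ),
    query_species: str = "NZO_mouse",
    conserved_residue: str = "E",
    mutant_residue: str = "V",
) -> dict[str, str]:
    """Protein multiple alignment (no gaps) in which every species carries
    ``conserved_residue`` at ``mutated_position`` (1-based) except the query
    strain, which carries ``mutant_residue`` - the planted
    mutation-in-conserved-site signal."""
    rng = _rng(seed, "msa")
    consensus = _AA[rng.integers(0, len(_AA), size=length)]
    seqs = {}
    for sp in species:
        seq = consensus.copy()
        n_subs = rng.integers(2, max(3, length // 15))
        sites = rng.choice(length, size=n_subs, replace=False)
        seq[sites] = _AA[rng.integers(0, len(_AA), size=n_subs)]
        seq[mutated_position - 1] = conserved_residue
        seqs[sp] = "".join(seq)
    seqs[query_species] = (
        seqs[query_species][: mutated_position - 1]
        + mutant_residue
        + seqs[query_species][mutated_position:]
    )
    return seqs


# ---------------------------------------------------------------------------
# file writers


def write_map_tsv(gmap: GeneticMap, path: str | Path) -> None:
    gmap.to_tsv(path)


def write_snp_catalog_tsv(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def write_snp_catalog_vcf(catalog: pd.DataFrame, path: str | Path) -> None:
    """Minimal uncompressed VCF with one genotype column per strain (0/0 =
    reference allele, 1/1 = alternate)."""
    strains = [c for c in catalog.columns if c not in ("chromosome", "position_bp", "ref")]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(catalog["chromosome"]):
            max_pos = int(catalog.loc[catalog["chromosome"] == chrom, "position_bp"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1_000_000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(strains) + "\n")
        for i, rec in enumerate(catalog.itertuples(index=False)):
            calls = [getattr(rec, s) for s in strains]
            alts = sorted({c for c in calls if c not in (rec.ref, ".", "")})
            alt_field = ",".join(alts) if alts else "."
            gt = []
            for c in calls:
                if c in (".", ""):
                    gt.append("./.")
                elif c == rec.ref:
                    gt.append("0/0")
                else:
                    a = alts.index(c) + 1
                    gt.append(f"{a}/{a}")
            fh.write(
                f"{rec.chromosome}\t{rec.position_bp}\tsnp{i:06d}\t{rec.ref}\t"
                f"{alt_field}\t.\tPASS\t.\tGT\t" + "\t".join(gt) + "\n"
            )


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """BED6-minus (chrom, start, end, name): 0-based half-open on disk."""
    with open(path, "w") as fh:
        for rec in genes.itertuples(index=False):
            fh.write(
                f"{rec.chromosome}\t{rec.start_bp - 1}\t{rec.end_bp - 1}\t"
                f"{rec.gene_id}\t{rec.gene_symbol}\n"
            )


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chromosome", "start_bp", "end_bp", "gene_id", "gene_symbol"],
        dtype={"chromosome": str},
    )
    df["start_bp"] = df["start_bp"] + 1  # back to 1-based half-open
    df["end_bp"] = df["end_bp"] + 1
    return df[["gene_id", "gene_symbol", "chromosome", "start_bp", "end_bp"]]


def write_annotations_tsv(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def write_expression_csv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path)


def write_msa_fasta(seqs: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# full study fixture


@dataclass
class StudyPaths:
    """File locations of one generated synthetic study."""

    out_dir: Path
    genotypes: Path = field(init=False)
    gmap: Path = field(init=False)
    phenotypes: Path = field(init=False)
    snp_catalog: Path = field(init=False)
    snp_vcf: Path = field(init=False)
    genes_bed: Path = field(init=False)
    annotations: Path = field(init=False)
    expression: Path = field(init=False)
    msa: Path = field(init=False)

    def __post_init__(self) -> None:
        d = Path(self.out_dir)
        self.genotypes = d / "genotypes.csv"
        self.gmap = d / "map.tsv"
        self.phenotypes = d / "phenotypes.csv"
        self.snp_catalog = d / "snp_catalog.tsv"
        self.snp_vcf = d / "snp_catalog.vcf"
        self.genes_bed = d / "genes.bed"
        self.annotations = d / "annotations.tsv"
        self.expression = d / "expression.csv"
        self.msa = d / "msa.fasta"


def generate_study(
    out_dir: str | Path,
    seed: int,
    planted: bool = True,
    n_individuals: int = 150,
    n_markers: int = 30,
) -> tuple[StudyPaths, dict]:
    """Write a complete synthetic study to ``out_dir`` and return its file
    paths plus the ground truth (causal marker, causal gene, planted
    blocks).

    With ``planted=False`` no causal structure is inserted anywhere: the
    phenotype carries no marker effect, no variant is deleterious, and no
    gene is islet-enriched - the null fixture for the pipeline.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = StudyPaths(out)

    gmap = uniform_map(n_markers)
    genotypes = simulate_backcross(gmap, n_individuals, seed)
    # causal marker near the distal sublocus peak (79 Mbp)
    bp = gmap.df["position_bp"].to_numpy()
    causal_idx = int(np.argmin(np.abs(bp - 79_000_000)))
    causal_marker = gmap.markers[causal_idx]
    cfg = SimulationConfig(
        n_individuals=n_individuals,
        causal_marker_id=causal_marker,
        additive_effect=SimulationConfig.additive_effect if planted else 0.0,
        diabetic_drift=SimulationConfig.diabetic_drift if planted else 0.0,
        seed=seed,
    )
    phenotypes = simulate_phenotypes(genotypes, cfg)

    region = ("15", 50_000_000, 80_000_000)
    blocks = [
        (61_500_000, 64_000_000, 0.8),   # proximal sublocus block
        (77_500_000, 80_000_000, 1.2),   # distal sublocus block (denser)
    ]
    catalog = simulate_snp_catalog(region, blocks, seed)

    genes = make_gene_table()
    in_distal = (genes["start_bp"] >= 77_500_000) & (genes["end_bp"] <= 80_000_000)
    causal_gene = genes.loc[in_distal, "gene_id"].iloc[0] if planted else None
    annotations, expr = simulate_annotations_and_expression(genes, causal_gene, seed)
    msa = simulate_msa(seed)

    write_genotypes_csv(genotypes, paths.genotypes)
    write_map_tsv(gmap, paths.gmap)
    phenotypes.to_csv(paths.phenotypes)
    write_snp_catalog_tsv(catalog, paths.snp_catalog)
    write_snp_catalog_vcf(catalog, paths.snp_vcf)
    write_genes_bed(genes, paths.genes_bed)
    write_annotations_tsv(annotations, paths.annotations)
    write_expression_csv(expr, paths.expression)
    write_msa_fasta(msa, paths.msa)

    truth = {
        "causal_marker": causal_marker,
        "causal_marker_bp": int(bp[causal_idx]),
        "causal_gene": causal_gene,
        "planted_blocks": blocks,
        "region": region,
        "config": cfg,
    }
    return paths, truth
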