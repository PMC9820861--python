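# Methods

## Study design being modelled

The package analyses an N2 backcross between a diabetes-prone obese strain
(NZO) and a diabetes-resistant strain (C3H). Each animal is, at every
locus, either homozygous NZO (N/N) or heterozygous (N/C); a protective
donor allele therefore shows up as lower blood glucose in heterozygotes.
The chain of evidence mirrors how such loci are dissected in practice:
linkage (LOD scan) defines the locus, strain haplotype comparison removes
regions where the parents are identical by descent (no causal variation
possible), variant-effect prediction and SIFT remove genes without
plausibly deleterious coding changes, and tissue expression profiling keeps
genes active in the tissue the phenotype points to (pancreatic islets).

## QTL scan

**Model.** Single-marker regression. With binary genotype classes the LOD
is `(n/2)·log10(RSS0/RSS1)`, identically `−(n/2)·log10(1−r²)`. The identity
is asserted to 1e-9 in the tests and the permutation engine uses the
correlation form vectorized over permutations, so the two forms
cross-check each other. Base-10 logs throughout. Interval mapping between
markers is out of scope: every marker is genotyped in this design.

**Missing data.** Per-marker casewise deletion. A marker whose genotype
class drops below 2 members is skipped with a logged warning; a perfect
within-group fit returns +inf with a warning.

**Permutation threshold.** Phenotype labels are permuted against intact
genotype rows (`n_perm` default 100, matching the design's convention);
the threshold is the ceil((1−α)·n_perm)-th smallest of the permutation
maximum LOD values — a conservative order statistic for small permutation
counts. Under the null its expected exceedance rate is
(n_perm − ceil((1−α)n_perm) + 1)/(n_perm + 1) ≈ 0.055 at n_perm = 200,
which the calibration check measures against the 0.05 ± 0.025 band.

**Support interval.** The maximal contiguous run of markers around the
peak with LOD ≥ peak − 1.5, then one additional genotyped marker on each
side (the "nearest marker" convention). Peak ties break to the smaller bp
coordinate. Increasing the drop can only widen the interval.

**Scan phenotype.** When the pipeline runs the confirmatory scan it uses
each animal's mean random blood glucose over its observed weeks. Any
per-animal summary could be scanned; the mean is the package's choice and
is stated here because the cohort literature rarely says which summary was
used.

## Cohort metrics

Definitions are locked to the field's conventions: diabetic = glucose
≥ 300 mg/dL (inclusive) in ≥ 3 *consecutive observed* weeks — a missing
week breaks a run, which only matters after a death truncates a series;
case fatality rate = deaths among diabetic animals up to week 20 divided
by diabetic animals (undefined, NaN with a warning, when there are none —
not zero); severe hyperglycemia = strictly > 500 mg/dL at week 15 among
animals still observed at that week. Islet areas are binned half-open
[k·w, (k+1)·w) with w = 10,000 area units; the binning is deliberately
unit-agnostic.

## Haplotype blocks

Discordant positions are those where both strains are called and differ.
Windows are non-overlapping tilings anchored at the region start (the rule
is stated over intervals, not sliding windows); the final window truncates
at the region end and is classified by its raw count, not density-rescaled.
Two dialect rules exist in the source literature and are both implemented:
150 kb with strict "> 50" (default) and 250 kb with "≥ 100". Blocks are
maximal runs of adjacent polymorphic windows; their SNP totals conserve the
window counts exactly, which a brute-force per-position oracle verifies on
random catalogs.

**Coordinates.** SNP positions are 1-based (VCF convention). All in-memory
intervals are half-open [start, end) in the same coordinate and positions
are compared to boundaries directly, so a SNP exactly at a window boundary
belongs to the right-hand window. BED files are converted (−1/+1) at the
I/O boundary only.

## Variant prioritization

A gene survives the deleteriousness filter iff it has ≥ 1 HIGH-impact
variant, or a MODERATE-impact variant with SIFT strictly < 0.5. HIGH
qualifies unconditionally (no SIFT requirement); LOW/MODIFIER never
qualify; MODERATE with a missing SIFT score is excluded by default (a flag
includes it). Per-gene evidence is the best qualifying variant, HIGH
beating any SIFT value. VEP and SIFT themselves are consumed as tables,
never recomputed — the synthetic generator emulates their output.

Conservation: the reference-coordinate residue column is located through
the reference sequence's ungapped positions (the mapping round-trips
exactly); the modal residue is taken over non-query, non-gap sequences,
ties breaking alphabetically; "highly conserved" defaults to a modal
fraction ≥ 0.9 — the threshold is a package choice, exposed in the API,
since no standard number exists.

## Expression scoring

For each strain s and comparison tissue t, L(g) = log2(x[g,s,islet] /
x[g,s,t]) is standardized across genes with the population (n-denominator)
SD; the combined score is the minimum z over all (s, t) cells, encoding
"high in all strains and against all tissues". Arithmetic-scale ratios and
mean-combination are available as options. Non-positive intensities are
floored at half the smallest positive value in the matrix. A cell with
zero spread across genes yields z = 0 for every gene (the 0/0 case). The
matrix is assumed pre-normalized; no microarray processing is performed.

ΔCt relative expression is 2^−(Ct_target − Ct_housekeeping); group fold
change is the ratio of group means of relative expressions, compared by a
two-sided Welch test.

## Pipeline

Stage order: scan (optional) → blocks → impact filter → block intersection
→ expression filter. Each filter can be disabled, and disabling one always
yields a superset of candidates. Ranking: impact class (HIGH before
MODERATE), then ascending minimum SIFT, then descending combined z, ties
by coordinate. Sublocus assignment compares the gene midpoint against a
boundary defaulting to the midpoint of the two sublocus peaks (63 and
79 Mbp), since no published boundary coordinate exists. Reports are
written as TSV + JSON with the filter funnel counts; reruns under a fixed
seed are byte-identical.

## Synthetic data generator

One top-level seed feeds named `SeedSequence` substreams per artifact, so
each output is independently reproducible and a fixed seed gives
byte-identical files.

* **Backcross**: per-chromosome Markov chain; first marker a fair coin,
  adjacent markers switch with the Haldane probability
  r = ½(1 − e^(−2d/100)).
* **Phenotypes**: weekly glucose = baseline + k·drift·(1 − g) −
  effect·g + N(0, σ); drift acts only on the susceptible homozygote.
  Defaults (baseline 200 mg/dL, drift 22 mg/dL/week, additive effect
  30 mg/dL, σ = 60 mg/dL, weeks 3–20, death above 500 mg/dL with
  per-week probability 0.12) were chosen once to give a realistic-looking
  cohort — controls climbing toward severe hyperglycemia with appreciable
  diabetes prevalence, mortality and a severe fraction at week 15 — since
  the source cohort's effect size and residual variance in raw units were
  never published and are free parameters here.
* **SNP catalog**: discordant positions Poisson-placed inside planted
  blocks at a stated density; concordant background everywhere
  (0.3 SNPs/kb).
* **Annotations/expression**: the planted gene gets a MODERATE missense
  variant with SIFT drawn in [0.02, 0.3] and islet expression set to 10×
  the maximum of its other tissues in every strain (guaranteeing ≥ 8-fold
  enrichment); decoys get tolerated or silent variants and tissue-flat
  expression; a few decoys carry deleterious-looking variants without
  islet enrichment so the expression filter is load-bearing.
* **MSA**: an ungapped protein alignment over eight species with the
  mutated column fully conserved except in the query strain.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: between-animal heterogeneity beyond the causal
genotype (no random animal effects, diet arms, litter or sex effects), so
cohort fractions are not calibrated to any published percentages;
multi-QTL architecture and epistasis; genotyping error and linkage to
unmodelled loci; realistic gene structure (introns/exons) and annotation
noise; array normalization artifacts. Passing the end-to-end check shows
the chain recovers the structure it assumes, not that the assumptions hold
in any particular cohort.

## Problem sizes and numerical choices

Calibration checks use 500 null studies (n = 200, 50 markers, 200
permutations) for the type-I error, 200 seeds for planted-QTL recovery
(effect 1.0 σ, n = 150, 50 markers over 100 cM), and 100 generator seeds
for rank-1 recovery of the planted islet gene — sizes chosen so the whole
suite completes in well under a minute while leaving the Monte-Carlo error
of each rate small against its acceptance band. Genetic-map validation
requires strictly increasing cM, so the zero-distance identity of the
backcross simulator is tested at an epsilon distance instead. Floats are
compared at stated absolute tolerances (1e-9 for algebraic identities,
1e-4/1e-5 for worked examples quoted to that precision).

## Known limitations

* Marker regression only; no interval mapping, covariates, or X-chromosome
  handling.
* The block caller assumes a dense, uniformly ascertained SNP catalog;
  ascertainment gaps read as IBD.
* The specificity z-score is relative to the genes supplied in the matrix:
  scores change with the gene universe, as any across-gene
  standardization must.
* Conservation flagging uses a single modal-residue fraction; no
  substitution-matrix weighting.
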